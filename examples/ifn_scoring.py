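"""Score a synthetic qPCR cohort and stratify patients by IFN signature.

Generates an 81-patient SLE + 31-control cohort driven by a latent
interferon activity, computes the cumulative 44-transcript score (delta-Ct
against the GAPDH/ACTB/B2M geomean, 2^-dCt, per-gene max normalization,
sum), and splits SLE patients into IFN-H / IFN-L quartile strata.
"""

from ifncyto import ifnscore, stats, synth

ctm, truth = synth.generate_qpcr_cohort(n_sle=81, n_hc=31, seed=1)
expr = ifnscore.normalize_to_housekeeping(ifnscore.collapse_replicates(ctm))
table = ifnscore.stratify_quartiles(ifnscore.compute_ifn_score(expr, groups=truth.groups))

sle = table["group"] == "SLE"
mw = stats.mann_whitney(table.loc[sle, "score"], table.loc[~sle, "score"])
print(f"median IFN score  SLE {table.loc[sle, 'score'].median():.2f}   "
      f"HC {table.loc[~sle, 'score'].median():.2f}")
print(f"Mann-Whitney SLE vs HC: U={mw.statistic:.0f}, p={mw.p:.2e}")
print(table["stratum"].value_counts().to_string())
print("\nAn IFN-H patient sits in the top score quartile of the SLE group; the")
print("Mann-Whitney p shows the latent interferon activity separates the groups.")
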