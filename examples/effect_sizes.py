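"""Recover an injected signaling effect with the fixed-effects model.

A standardized shift (delta = 1.5) is injected into pSTAT1 of CD4 T cells
under IFN-alpha stimulation for the IFN-H stratum. Per-sample population
medians are modelled with Marker ~ Group, the Group coefficient is divided
by the response SD, and p-values are Benjamini-Hochberg adjusted. Only
cells with FDR < 0.05 enter the dotmap table.
"""

from ifncyto import effects as fx, synth, validation

tables, truth = synth.generate_cytof_events(
    n_samples_per_group=25, cells_per_sample=2000,
    effects={("CD4_T", "pSTAT1", "IFNa"): 1.5}, stimulations=("IFNa",), seed=3)
summaries, _ = validation.gate_and_summarize(tables)
res = fx.run_effects(summaries, ("IFN-H", "IFN-L"), stat="median", sd_mode="within")
print(res[["population", "marker", "effect", "p", "q"]].round(3).to_string(index=False))

dotmap, forest = fx.build_dotmap_table(res, fdr_cut=0.05)
print("\ndotmap rows at FDR < 0.05:")
print(dotmap.round(3).to_string(index=False))
print("\nThe CD4_T/pSTAT1 effect should be near the injected 1.5 (sampling noise")
print("of about +-0.3 at 25 samples/group); all other cells carry no effect.")
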