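"""Recovery and calibration experiments on synthetic study conditions.

These functions wire the generators to the analysis stages and measure how
well known ground truth is recovered: injected signaling effect sizes,
false-discovery control on exchangeable nulls, quartile stratification of a
latent interferon activity, and guided-gating accuracy on well-separated
mixtures. They are the package's own evidence that the machinery does what
it claims on data whose truth is known; they say nothing about features of
real cohorts the generators do not model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cyto, effects as fx, ifnscore, synth


def gate_and_summarize(tables, gates=None, min_cells=cyto.MIN_CELLS_DEFAULT):
    gates = gates or synth.truth_gates()
    markers = sorted({m for g in gates for m, _ in g.constraints})
    proc = [cyto.zero_threshold(cyto.arcsinh_transform(t)) for t in tables]
    pooled = pd.concat([t.data[markers] for t in proc])
    cuts = {m: cyto.derive_marker_threshold(pooled[m].to_numpy())[0]
            for m in markers}
    summaries = pd.concat(
        [cyto.summarize(t, cyto.assign_populations(t, gates, cuts), gates,
                        min_cells=min_cells) for t in proc],
        ignore_index=True)
    return summaries, cuts


def recover_effect(delta: float = 1.0, n_samples_per_group: int = 25,
                   cells_per_sample: int = 5000, population: str = "CD4_T",
                   marker: str = "pSTAT1", stimulation: str = "IFNa",
                   seed: int = 0, sd_mode: str = "within") -> float:
    """Inject one standardized signaling shift and recover it end to end.

    Generates a two-stratum cohort with a single injected effect, runs the
    full gate-summarize-model pipeline, and returns the estimated effect
    size for the affected (population, marker, stimulation) cell. The
    generator standardizes the injected shift against the between-sample
    (within-group) SD, so recovery uses ``sd_mode="within"``.
    """
    tables, _ = synth.generate_cytof_events(
        n_samples_per_group, cells_per_sample=cells_per_sample,
        effects={(population, marker, stimulation): delta},
        stimulations=(stimulation,), seed=seed)
    summaries, _ = gate_and_summarize(tables)
    res = fx.run_effects(summaries, ("IFN-H", "IFN-L"), stat="median",
                         sd_mode=sd_mode)
    row = res[(res["population"] == population) & (res["marker"] == marker)]
    return float(row["effect"].iloc[0])


def effect_bias_sweep(deltas=(0.5, 1.0, 2.0), n_reps: int = 100,
                      n_samples_per_group: int = 25, cells_per_sample: int = 600,
                      seed: int = 0) -> dict[float, float]:
    """Mean recovered effect per injected delta over seeded replicates."""
    out = {}
    for k, delta in enumerate(deltas):
        vals = [recover_effect(delta, n_samples_per_group, cells_per_sample,
                               seed=seed + 100_000 * (k + 1) + r)
                for r in range(n_reps)]
        out[float(delta)] = float(np.mean(vals))
    return out


def fdr_null_run(n_reps: int = 300, n_per_group: int = 10, n_populations: int = 20,
                 n_markers: int = 10, q_cut: float = 0.05, seed: int = 0
                 ) -> tuple[float, np.ndarray]:
    """Empirical FDR and pooled p-values of the effects model on pure nulls.

    Each replicate draws exchangeable per-sample summaries with no group
    effect (so every discovery is false) and fits the full effect-size
    model with BH adjustment. Returns ``(mean over replicates of
    V / max(R, 1), p-values pooled over replicates)``.
    """
    fdps, pvals = [], []
    for r in range(n_reps):
        df = synth.generate_null_summaries(n_per_group, n_populations,
                                           n_markers, seed=seed + r)
        res = fx.run_effects(df, ("IFN-H", "IFN-L"))
        n_disc = int((res["q"] < q_cut).sum())
        fdps.append(n_disc / max(n_disc, 1))
        pvals.append(res["p"].to_numpy())
    return float(np.mean(fdps)), np.concatenate(pvals)


def stratification_recovery(n_sle: int = 81, n_hc: int = 31, seed: int = 0
                            ) -> dict[str, float]:
    """Score-based IFN-H/IFN-L quartile strata vs latent-activity quartiles.

    Returns the recovery fraction (share of true upper/lower-quartile
    samples assigned to the matching stratum), the stratum sizes, and the
    Mann-Whitney p for SLE-vs-HC score separation.
    """
    ctm, truth = synth.generate_qpcr_cohort(n_sle, n_hc, seed=seed)
    expr = ifnscore.normalize_to_housekeeping(ifnscore.collapse_replicates(ctm))
    table = ifnscore.stratify_quartiles(
        ifnscore.compute_ifn_score(expr, groups=truth.groups))
    sle = table["group"] == "SLE"
    truth_strata = truth.true_strata.reindex(table.index)
    match = {}
    for stratum in ("IFN-H", "IFN-L"):
        true_set = truth_strata[sle] == stratum
        assigned = table.loc[sle, "stratum"] == stratum
        match[stratum] = float((assigned & true_set).sum() / max(true_set.sum(), 1))
    from . import stats
    mw = stats.mann_whitney(table.loc[sle, "score"], table.loc[~sle, "score"])
    n_h = int((truth_strata[sle] == "IFN-H").sum())
    n_l = int((truth_strata[sle] == "IFN-L").sum())
    pooled = (match["IFN-H"] * n_h + match["IFN-L"] * n_l) / max(n_h + n_l, 1)
    return {"recovery_pooled": float(pooled),
            "recovery_high": match["IFN-H"], "recovery_low": match["IFN-L"],
            "n_high": int((table["stratum"] == "IFN-H").sum()),
            "n_low": int((table["stratum"] == "IFN-L").sum()),
            "mw_p": mw.p,
            "median_score_sle": float(table.loc[sle, "score"].median()),
            "median_score_hc": float(table.loc[~sle, "score"].median())}


def gating_recovery(n_reps: int = 200, cells_per_sample: int = 1000,
                    fractions=(0.7, 0.3), seed: int = 0) -> dict[str, float]:
    """Per-cell gating accuracy and abundance calibration on 2-part mixtures.

    Each replicate generates one sample per stratum from a well-separated
    two-population mixture, derives the marker cut, gates, and checks
    (a) per-cell label agreement with the generator's truth and (b) whether
    each gated abundance falls inside the 99% binomial interval of its
    generating fraction. Returns the minimum agreement and the fraction of
    replicates with all abundances inside their intervals.
    """
    pops = [synth.PopulationSpec("A", fractions[0], {"CD3": "high"}),
            synth.PopulationSpec("B", fractions[1], {"CD3": "low"})]
    gates = synth.truth_gates(pops)
    agree, covered = [], []
    for r in range(n_reps):
        tables, truth = synth.generate_cytof_events(
            1, populations=pops, cells_per_sample=cells_per_sample,
            functional_markers=("pSTAT1",), seed=seed + r)
        summaries, cuts = gate_and_summarize(tables, gates=gates, min_cells=1)
        ok = True
        for t in tables:
            tt = cyto.zero_threshold(cyto.arcsinh_transform(t))
            labels = cyto.leaf_labels(cyto.assign_populations(tt, gates, cuts), gates)
            agree.append(float(
                (labels.values == truth.cell_labels[(t.sample_id, t.stimulation)]).mean()))
            ab = summaries[(summaries["sample"] == t.sample_id)
                           & (summaries["stat"] == "abundance")]
            for pop, p in zip(("A", "B"), fractions):
                lo, hi = sps.binom.interval(0.99, cells_per_sample, p)
                got = float(ab.loc[ab["population"] == pop, "value"].iloc[0])
                if not (lo / cells_per_sample <= got <= hi / cells_per_sample):
                    ok = False
        covered.append(ok)
    return {"min_agreement": float(np.min(agree)),
            "mean_agreement": float(np.mean(agree)),
            "coverage": float(np.mean(covered))}
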