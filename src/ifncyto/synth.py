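"""Seeded synthetic cohorts: qPCR Ct matrices, CyTOF event tables, MFI arrays.

Every generator is a pure function of (parameters, seed) and returns its
output together with a :class:`SyntheticTruth` recording the ground truth a
recovery test needs: the latent interferon activity behind the qPCR panel,
the population mixture and per-cell labels behind the cytometry events, the
injected standardized signaling shifts, and the reactive antigens behind
the arrays.

Model sketch
------------
* qPCR: a single latent IFN-activation factor per sample; SLE activities
  come from a right-shifted two-component mixture (a high-activity
  subgroup exists), healthy controls sit near zero. Signature-gene
  expression is multiplicative in the activity — Ct(g, s) =
  base_g - loading_g * activity_s + noise — because Ct is a log2-scale
  readout. Housekeeping assays are activity-independent.
* CyTOF: cells are drawn from a population mixture; each population's
  defining lineage markers come from well-separated "high" vs "low"
  components on the arcsinh scale (raw counts are the sinh-back-transform,
  i.e. zero-inflated lognormal-like on the raw scale). Functional
  (phospho) markers have a per-sample random effect; an injected effect
  (population, marker, stimulation, delta) shifts the affected group's
  per-sample median by delta times the between-sample (within-group) SD.
* Arrays: log-normal MFI; reactive antigens are elevated in the designated
  group by a stated log-fold; a configurable fraction of entries is marked
  undetected.

Each artifact draws from its own RNG stream derived from the master seed by
stable hashing of the artifact name, so adding a generator never perturbs
existing fixtures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cyto import EventTable
from .errors import ConfigError
from .serology import MFIMatrix

HOUSEKEEPING = ("GAPDH", "ACTB", "B2M")
N_SIGNATURE_GENES = 44


def artifact_rng(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one named artifact under a master seed."""
    h = hashlib.sha256(f"{name}|{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big") & 0x7FFFFFFF)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated artifact."""

    seed: int
    latent_ifn_activity: pd.Series | None = None          # per sample
    true_strata: pd.Series | None = None                  # IFN-H/IFN-L/mid/HC
    population_fractions: pd.DataFrame | None = None      # sample x population (realized)
    cell_labels: dict = field(default_factory=dict)       # (sample, stim) -> array
    injected_effects: dict = field(default_factory=dict)  # (pop, marker, stim) -> delta
    reactive_antigens: dict = field(default_factory=dict) # antigen -> log-fold
    groups: pd.Series | None = None

    def to_json_dict(self) -> dict:
        out = {"seed": self.seed,
               "injected_effects": {"|".join(k): v for k, v in self.injected_effects.items()},
               "reactive_antigens": dict(self.reactive_antigens)}
        if self.latent_ifn_activity is not None:
            out["latent_ifn_activity"] = self.latent_ifn_activity.to_dict()
        if self.true_strata is not None:
            out["true_strata"] = self.true_strata.to_dict()
        if self.groups is not None:
            out["groups"] = self.groups.to_dict()
        if self.population_fractions is not None:
            out["population_fractions"] = {s: row.to_dict()
                                           for s, row in self.population_fractions.iterrows()}
        return out


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrParams:
    """Distribution settings for the qPCR cohort generator.

    SLE latent activity is the mixture
    (1 - high_fraction) * N(base_shift, base_sd) +
    high_fraction * N(base_shift + latent_shift, high_sd); healthy controls
    draw from N(0, hc_sd). Units of activity are log2-expression SDs of a
    unit-loading gene.
    """

    latent_shift: float = 2.5
    high_fraction: float = 0.25
    base_shift: float = 0.5
    base_sd: float = 0.4
    high_sd: float = 0.6
    hc_sd: float = 0.4
    loading_low: float = 1.0
    loading_high: float = 2.0
    baseline_ct_low: float = 26.0
    baseline_ct_high: float = 30.0
    hk_ct_low: float = 18.0
    hk_ct_high: float = 22.0
    assay_noise_sd: float = 0.15   # cycles, per (sample, assay)
    replicate_noise_sd: float = 0.15  # cycles, per replicate well
    ct_min: float = 10.0
    ct_max: float = 40.0


def generate_qpcr_cohort(n_sle: int, n_hc: int, n_genes: int = N_SIGNATURE_GENES,
                         params: QpcrParams | None = None, seed: int = 0):
    """Synthetic duplicate-well Ct matrix driven by one latent IFN factor.

    Returns ``(CtMatrix, SyntheticTruth)``; the matrix carries
    ``n_sle + n_hc`` samples x ``n_genes + 3`` assays x 2 replicates.
    """
    from .ifnscore import CtMatrix  # local import avoids a cycle

    if n_sle < 2 or n_hc < 2 or n_genes < 2:
        raise ConfigError("need n_sle, n_hc >= 2 and n_genes >= 2")
    p = params or QpcrParams()
    rng = artifact_rng(seed, "qpcr")

    samples = [f"SLE{i+1:03d}" for i in range(n_sle)] + [f"HC{i+1:03d}" for i in range(n_hc)]
    groups = pd.Series(["SLE"] * n_sle + ["HC"] * n_hc, index=samples, name="group")

    is_high = rng.random(n_sle) < p.high_fraction
    act_sle = np.where(is_high,
                       rng.normal(p.base_shift + p.latent_shift, p.high_sd, n_sle),
                       rng.normal(p.base_shift, p.base_sd, n_sle))
    act_hc = rng.normal(0.0, p.hc_sd, n_hc)
    activity = pd.Series(np.concatenate([act_sle, act_hc]), index=samples,
                         name="latent_ifn_activity")

    genes = [f"IFI{j+1:03d}" for j in range(n_genes)]
    assays = genes + list(HOUSEKEEPING)
    loadings = rng.uniform(p.loading_low, p.loading_high, n_genes)
    base_ct = rng.uniform(p.baseline_ct_low, p.baseline_ct_high, n_genes)
    hk_ct = rng.uniform(p.hk_ct_low, p.hk_ct_high, len(HOUSEKEEPING))

    n = len(samples)
    mean_ct = np.empty((n, len(assays)))
    mean_ct[:, :n_genes] = base_ct[None, :] - loadings[None, :] * activity.values[:, None]
    mean_ct[:, n_genes:] = hk_ct[None, :]
    mean_ct = mean_ct + rng.normal(0, p.assay_noise_sd, mean_ct.shape)
    ct = mean_ct[:, :, None] + rng.normal(0, p.replicate_noise_sd, (n, len(assays), 2))
    ct = np.clip(ct, p.ct_min, p.ct_max)

    strata = pd.Series("HC", index=samples, dtype=object)
    q1, q3 = np.quantile(act_sle, [0.25, 0.75])
    strata.iloc[:n_sle] = np.where(act_sle >= q3, "IFN-H",
                                   np.where(act_sle <= q1, "IFN-L", "mid"))
    truth = SyntheticTruth(seed=seed, latent_ifn_activity=activity,
                           true_strata=strata, groups=groups)
    return CtMatrix(samples, assays, ct, HOUSEKEEPING), truth


# ---------------------------------------------------------------------------
# CyTOF


@dataclass(frozen=True)
class PopulationSpec:
    """A synthetic population: mixture fraction + high/low lineage marker states."""

    name: str
    fraction: float
    markers: dict  # marker -> "high" | "low"


def default_population_specs() -> list[PopulationSpec]:
    """Two well-separated T-cell subsets plus a CD3- remainder."""
    return [
        PopulationSpec("CD4_T", 0.45, {"CD3": "high", "CD4": "high", "CD8": "low"}),
        PopulationSpec("CD8_T", 0.25, {"CD3": "high", "CD4": "low", "CD8": "high"}),
        PopulationSpec("non_T", 0.30, {"CD3": "low", "CD4": "low", "CD8": "low"}),
    ]


@dataclass(frozen=True)
class CytofParams:
    """Distribution settings for event generation (arcsinh-scale units)."""

    high_mean: float = 3.0
    high_sd: float = 0.35
    low_mean: float = 0.15
    low_sd: float = 0.10
    functional_baseline: float = 1.0
    functional_cell_sd: float = 0.5    # cell-to-cell spread within a sample
    functional_sample_sd: float = 0.25 # between-sample (within-group) SD
    stimulation_bump: float = 0.5      # shift of functional markers when stimulated
    cofactor: float = 5.0


def generate_cytof_events(n_samples_per_group: int,
                          populations: list[PopulationSpec] | None = None,
                          cells_per_sample: int = 5000,
                          effects: dict | None = None,
                          stimulations=("US",),
                          functional_markers=("pSTAT1", "pSTAT3", "pSTAT5"),
                          group_labels=("IFN-H", "IFN-L"),
                          params: CytofParams | None = None,
                          seed: int = 0):
    """Raw-count event tables for two groups of samples under stimulations.

    ``effects`` maps (population, marker, stimulation) -> delta: under that
    stimulation the first group's per-sample median of the marker inside
    that population is shifted by delta x the between-sample SD. Raw ion
    counts are ``cofactor * sinh(v)`` of the arcsinh-scale draws (clipped
    at 0), so the stated arcsinh transform recovers the generative scale.

    Returns ``(tables, truth)`` where ``tables`` is a list of raw
    :class:`~ifncyto.cyto.EventTable` (one per sample x stimulation).
    """
    pops = populations or default_population_specs()
    p = params or CytofParams()
    effects = dict(effects or {})
    fracs = np.array([q.fraction for q in pops], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ConfigError(f"population fractions must sum to 1, got {fracs.sum()}")
    lineage = sorted({m for q in pops for m in q.markers})
    channels = lineage + list(functional_markers)
    for (pop, marker, stim) in effects:
        if marker not in channels:
            raise ConfigError(f"effect marker {marker!r} not in channel list")
        if pop not in [q.name for q in pops]:
            raise ConfigError(f"effect population {pop!r} not defined")
        if stim not in stimulations:
            raise ConfigError(f"effect stimulation {stim!r} not in stimulations")

    rng = artifact_rng(seed, "cytof")
    roles = {m: "lineage" for m in lineage} | {m: "functional" for m in functional_markers}

    samples = [(f"{g}_{i+1:03d}", g) for g in group_labels
               for i in range(n_samples_per_group)]
    frac_rows = {}
    tables, cell_labels = [], {}
    # per-sample functional random effects are stimulation-independent
    sample_fx = {sid: rng.normal(0, p.functional_sample_sd, len(functional_markers))
                 for sid, _ in samples}
    for sid, grp in samples:
        counts = rng.multinomial(cells_per_sample, fracs)
        frac_rows[sid] = counts / cells_per_sample
        labels = np.repeat([q.name for q in pops], counts)
        perm = rng.permutation(cells_per_sample)
        labels = labels[perm]
        for stim in stimulations:
            cols = {}
            for m in lineage:
                v = np.empty(cells_per_sample)
                for q, cnt in zip(pops, counts):
                    sel = labels == q.name
                    if q.markers.get(m, "low") == "high":
                        v[sel] = rng.normal(p.high_mean, p.high_sd, sel.sum())
                    else:
                        v[sel] = rng.normal(p.low_mean, p.low_sd, sel.sum())
                cols[m] = v
            for j, m in enumerate(functional_markers):
                mu = p.functional_baseline + (p.stimulation_bump if stim != "US" else 0.0)
                v = rng.normal(mu + sample_fx[sid][j], p.functional_cell_sd,
                               cells_per_sample)
                for (pop, marker, estim), delta in effects.items():
                    if marker == m and estim == stim and grp == group_labels[0]:
                        v[labels == pop] += delta * p.functional_sample_sd
                cols[m] = v
            df = pd.DataFrame(cols, columns=channels)
            raw = df.copy()
            for c in channels:
                raw[c] = p.cofactor * np.sinh(np.maximum(df[c], 0.0))
            tables.append(EventTable(sid, stim, raw, dict(roles), "raw",
                                     {"group": grp, "stratum": grp, "batch": "study1"}))
            cell_labels[(sid, stim)] = labels.copy()

    truth = SyntheticTruth(
        seed=seed,
        population_fractions=pd.DataFrame.from_dict(
            frac_rows, orient="index", columns=[q.name for q in pops]),
        cell_labels=cell_labels, injected_effects=effects,
        groups=pd.Series({sid: g for sid, g in samples}, name="group"))
    return tables, truth


def truth_gates(populations: list[PopulationSpec] | None = None):
    """Gate definitions matching the generator's high/low marker states."""
    from .cyto import GateDefinition

    pops = populations or default_population_specs()
    return [GateDefinition(q.name,
                           tuple((m, "+" if s == "high" else "-")
                                 for m, s in sorted(q.markers.items())))
            for q in pops]


# ---------------------------------------------------------------------------
# antigen arrays


def generate_array_data(n_per_group: int, antigens, reactive: dict | None = None,
                        noise_sd: float = 0.4, undetected_frac: float = 0.0,
                        group_labels=("HC", "SLE"), baseline_log_mfi: float = np.log(3000.0),
                        seed: int = 0):
    """Log-normal MFI matrix with antigen-specific elevations in one group.

    ``reactive`` maps antigen -> natural-log fold elevation applied to the
    second group label. ``undetected_frac`` of entries is flagged
    undetected (masked; preprocessing sets them to MFI 1).
    """
    reactive = dict(reactive or {})
    antigens = list(antigens)
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    unknown = [a for a in reactive if a not in antigens]
    if unknown:
        raise ConfigError(f"reactive antigen(s) not in antigen list: {unknown}")
    if not (0 <= undetected_frac < 1):
        raise ConfigError("undetected_frac must be in [0, 1)")

    rng = artifact_rng(seed, "arrays")
    samples = [f"{g}_{i+1:03d}" for g in group_labels for i in range(n_per_group)]
    groups = pd.Series([g for g in group_labels for _ in range(n_per_group)],
                       index=samples, name="group")
    mu = np.full((len(samples), len(antigens)), baseline_log_mfi)
    for j, a in enumerate(antigens):
        if a in reactive:
            mu[groups.values == group_labels[1], j] += reactive[a]
    log_mfi = rng.normal(mu, noise_sd)
    mfi = pd.DataFrame(np.exp(log_mfi), index=samples, columns=antigens)
    undet = pd.DataFrame(rng.random(mfi.shape) < undetected_frac,
                         index=samples, columns=antigens)
    truth = SyntheticTruth(seed=seed, reactive_antigens=reactive, groups=groups)
    return MFIMatrix(mfi.mask(undet), groups, "IgG", undet), truth


# ---------------------------------------------------------------------------
# summary-level null (for FDR calibration of the effects model)


def generate_null_summaries(n_per_group: int, n_populations: int, n_markers: int,
                            group_labels=("IFN-H", "IFN-L"), seed: int = 0) -> pd.DataFrame:
    """Exchangeable-null per-sample summaries feeding the effects model.

    One standard-normal response per (sample, population, marker) with no
    group effect; the tidy schema matches :func:`ifncyto.cyto.summarize`.
    """
    rng = artifact_rng(seed, "null_summaries")
    rows = []
    for g in group_labels:
        for i in range(n_per_group):
            sid = f"{g}_{i+1:03d}"
            vals = rng.normal(0, 1, (n_populations, n_markers))
            for pi in range(n_populations):
                for mi in range(n_markers):
                    rows.append(dict(sample=sid, stimulation="US",
                                     population=f"pop{pi:02d}", marker=f"mk{mi:02d}",
                                     stat="median", value=vals[pi, mi], group=g,
                                     stratum=g, batch="study1", n_cells=1000,
                                     low_count=False))
    return pd.DataFrame(rows)
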