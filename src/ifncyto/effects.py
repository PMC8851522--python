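"""Fixed-effects effect-size regression over per-sample population summaries.

For each (population, marker[, stimulation]) cell the model
``response ~ Group + Treatment + Batch`` is fit by ordinary least squares on
one row per sample (per-sample medians/abundances, never per-cell values —
per-cell fits would pseudo-replicate). The effect size is the Group
regression coefficient divided by the standard deviation of the response
(``sd_mode="pooled"``: sample SD over all rows in the fit, the default;
``"within"``: pooled within-group SD, the Cohen's-d convention). P-values
are Benjamini-Hochberg adjusted within each stimulation family, and tables
filtered at FDR < 0.05 feed dotmap/forest outputs.

Covariates with a single observed level are dropped automatically, so
single-stimulation and single-batch analyses fit ``response ~ Group``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import DataError, FitError

FDR_CUT_DEFAULT = 0.05


@dataclass(frozen=True)
class FitResult:
    coefficient: float
    se: float
    p: float
    degenerate: bool = False


def fit_effect_model(frame: pd.DataFrame, contrast: tuple[str, str],
                     response: str = "value", group: str = "group",
                     covariates: tuple[str, ...] = ("stimulation", "batch")) -> FitResult:
    """OLS fit of ``response ~ Group (+ covariates)``; Group contrast coefficient.

    ``contrast = (level_of_interest, reference)``: the returned coefficient
    is the mean shift of the first level relative to the second, adjusted
    for the covariates. Covariates with one observed level are dropped.
    """
    sub = frame[frame[group].isin(contrast)].copy()
    counts = sub[group].value_counts()
    if any(counts.get(lev, 0) < 3 for lev in contrast):
        raise DataError(f"need >= 3 samples per group level, got {counts.to_dict()}")
    if "sample" in sub.columns and sub["sample"].duplicated().any():
        raise DataError("duplicated sample within a fit")

    y = sub[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return FitResult(0.0, np.nan, np.nan, degenerate=True)

    X = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
    X["group"] = (sub[group] == contrast[0]).astype(float)
    for cov in covariates:
        if cov in sub.columns and sub[cov].nunique(dropna=True) > 1:
            dummies = pd.get_dummies(sub[cov].astype(str), prefix=cov,
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitError(f"rank-deficient design; columns {list(X.columns)}")
    fit = sm.OLS(y, X.to_numpy()).fit()
    j = list(X.columns).index("group")
    return FitResult(float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j]))


def effect_size(coefficient: float, values, sd_mode: str = "pooled",
                groups=None) -> float:
    """Standardized effect: regression coefficient / SD of the response.

    ``sd_mode="pooled"`` uses the sample SD (ddof=1) of all responses in
    the fit; ``"within"`` pools the within-group SDs (requires ``groups``).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("effect_size requires >= 2 response values")
    sd = response_sd(v, sd_mode, groups)
    if sd == 0:
        raise DataError("zero response variance: effect size degenerate")
    return float(coefficient / sd)


def response_sd(values, sd_mode: str = "pooled", groups=None) -> float:
    v = np.asarray(values, dtype=float)
    if sd_mode == "pooled":
        return float(np.std(v, ddof=1))
    if sd_mode == "within":
        if groups is None:
            raise ValueError("sd_mode='within' requires group labels")
        g = np.asarray(groups)
        ss, df = 0.0, 0
        for lev in pd.unique(g):
            x = v[g == lev]
            if x.size > 1:
                ss += float(np.sum((x - x.mean()) ** 2))
                df += x.size - 1
        if df == 0:
            return 0.0
        return float(np.sqrt(ss / df))
    raise ValueError(f"unknown sd_mode {sd_mode!r}")


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_effects(summaries: pd.DataFrame, contrast: tuple[str, str],
                group: str = "group", per_stimulation: bool = True,
                sd_mode: str = "pooled", stat: str | None = None,
                drop_low_count: bool = True) -> pd.DataFrame:
    """Fit every (population, marker[, stimulation]) cell and BH-adjust.

    ``summaries`` is the tidy frame from :func:`ifncyto.cyto.summarize`
    (columns: sample, stimulation, population, marker, stat, value, group,
    batch, low_count). ``stat`` filters to one summary statistic
    ("median" for signaling, "abundance" for subset frequencies); by
    default both are analyzed. The BH family is all tests within one
    stimulation (``per_stimulation=True``) or the whole run.
    """
    df = summaries.copy()
    if drop_low_count and "low_count" in df.columns:
        df = df[~df["low_count"]]
    if stat is not None:
        df = df[df["stat"] == stat]
    df = df[df[group].isin(contrast)]
    if df.empty:
        raise DataError("no rows left to model after filtering")

    stim_keys = ["stimulation"] if per_stimulation else []
    covs = () if per_stimulation else ("stimulation",)
    rows = []
    for key, cell in df.groupby(stim_keys + ["population", "marker", "stat"], sort=True):
        key = dict(zip(stim_keys + ["population", "marker", "stat"], key))
        try:
            fit = fit_effect_model(cell, contrast, covariates=covs + ("batch",))
        except (DataError, FitError):
            continue
        if fit.degenerate or cell["value"].nunique() == 1:
            continue
        sd = response_sd(cell["value"], sd_mode, cell[group])
        if sd == 0:
            continue
        rows.append(key | dict(
            coefficient=fit.coefficient, sd_response=sd,
            effect=fit.coefficient / sd, se_effect=fit.se / sd, p=fit.p,
            n=len(cell)))
    if not rows:
        raise DataError("no estimable (population, marker) cells")
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    fam = out.groupby("stimulation") if per_stimulation else [(None, out)]
    for _, idx in ((k, g.index) for k, g in fam):
        out.loc[idx, "q"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    out["direction"] = np.where(out["effect"] >= 0, "positive", "negative")
    return out


def build_dotmap_table(results: pd.DataFrame,
                       fdr_cut: float = FDR_CUT_DEFAULT) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dotmap + forest tables from effect-size results, filtered at q < fdr_cut.

    Dotmap rows carry (population, marker, stimulation, effect, -log10(q),
    direction); the forest table adds the 95% interval effect +/- 1.96 se.
    Positive effects render "red", negative "blue". An empty result after
    filtering is allowed.
    """
    if results.empty:
        raise DataError("results table is empty")
    kept = results[results["q"] < fdr_cut].copy()
    kept["neg_log10_q"] = -np.log10(np.maximum(kept["q"], 1e-300))
    kept["color"] = np.where(kept["effect"] >= 0, "red", "blue")
    cols = ["population", "marker", "stimulation", "effect", "neg_log10_q",
            "direction", "color", "q"]
    dotmap = kept[[c for c in cols if c in kept.columns]].reset_index(drop=True)
    forest = kept.assign(ci_low=kept["effect"] - 1.96 * kept["se_effect"],
                         ci_high=kept["effect"] + 1.96 * kept["se_effect"])
    fcols = ["population", "marker", "stimulation", "effect", "ci_low", "ci_high", "q"]
    return dotmap, forest[[c for c in fcols if c in forest.columns]].reset_index(drop=True)


def render_dotmap(dotmap: pd.DataFrame, path) -> None:
    """Basic matplotlib render of a dotmap table (size = |effect|, color = sign)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if dotmap.empty:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no cells at FDR cut", ha="center")
        ax.axis("off")
    else:
        pops = sorted(dotmap["population"].unique())
        marks = sorted(dotmap["marker"].unique())
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(marks), 1 + 0.4 * len(pops)))
        for _, r in dotmap.iterrows():
            ax.scatter(marks.index(r["marker"]), pops.index(r["population"]),
                       s=40 * abs(r["effect"]) + 5,
                       c="tab:red" if r["effect"] >= 0 else "tab:blue",
                       alpha=min(1.0, 0.3 + 0.1 * r["neg_log10_q"]))
        ax.set_xticks(range(len(marks)), marks, rotation=90)
        ax.set_yticks(range(len(pops)), pops)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
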