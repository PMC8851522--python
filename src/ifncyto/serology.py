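"""Autoantigen-array analysis: SAM permutation q-values, imputation, clustering.

MFI matrices (samples x antigens, mean net fluorescence of six replicate
features upstream) are preprocessed — undetected features set to MFI 1,
antigens whose maximum IgG MFI is below 1,000 flagged non-reactive and
excluded — then screened with a SAM (significance analysis of microarrays)
procedure built on Wilcoxon rank statistics: the observed standardized
statistic per antigen is compared against its expected order statistic over
group-label permutations, and a delta-threshold sweep converts the
permutation null into per-antigen q-values (FDR estimates). Supporting
utilities provide k-nearest-neighbor replacement of missing values,
average-linkage Euclidean hierarchical clustering for heatmap ordering, and
the ELISA detection-limit rule (2x the SD of the blanks).

The default statistic is the two-sample Wilcoxon rank-sum (standardized,
tie-corrected); the signed-rank variant is available for paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .errors import DataError

NONREACTIVE_CUT = 1000.0
Q_CALL_DEFAULT = 0.001   # "FDR of 0" stringency
EXHAUSTIVE_MAX = 20000   # enumerate label assignments up to this many


@dataclass
class MFIMatrix:
    """Samples x antigens mean-fluorescence matrix with group labels."""

    mfi: pd.DataFrame                 # samples x antigens
    groups: pd.Series                 # per-sample labels, aligned with mfi.index
    isotype: str = "IgG"
    undetected: pd.DataFrame | None = None  # boolean, same shape

    def __post_init__(self):
        self.groups = pd.Series(self.groups).reindex(self.mfi.index)
        if self.undetected is None:
            self.undetected = self.mfi.isna()
        self.undetected = self.undetected.reindex_like(self.mfi).fillna(False).astype(bool)

    @property
    def samples(self) -> list:
        return list(self.mfi.index)

    @property
    def antigens(self) -> list:
        return list(self.mfi.columns)


def preprocess_mfi(m: MFIMatrix, nonreactive_cut: float = NONREACTIVE_CUT
                   ) -> tuple[MFIMatrix, pd.Series]:
    """Set undetected features to MFI 1 and flag non-reactive antigens.

    An antigen is non-reactive when its maximum (IgG) MFI across samples is
    strictly below ``nonreactive_cut``; non-reactive antigens are excluded
    from SAM by default. Returns the cleaned matrix and a per-antigen
    boolean ``reactive`` Series.
    """
    vals = m.mfi.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise DataError("negative MFI value")
    mfi = m.mfi.mask(m.undetected | m.mfi.isna(), 1.0)
    reactive = mfi.max(axis=0) >= nonreactive_cut
    reactive.name = "reactive"
    return replace(m, mfi=mfi, undetected=m.undetected.copy()), reactive


# ---------------------------------------------------------------------------
# rank statistics


def _rank_sum_z(X: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Standardized (tie-corrected) Wilcoxon rank-sum per row of X.

    X is antigens x samples; idx2 indexes the second group. Positive values
    mean group 2 ranks higher.
    """
    n = X.shape[1]
    n2 = idx2.size
    ranks = rankdata(X, axis=1)
    W = ranks[:, idx2].sum(axis=1)
    expect = n2 * (n + 1) / 2.0
    n1 = n - n2
    # tie-robust variance: n1*n2/(n*(n-1)) * (sum r^2 - n*(n+1)^2/4)
    var = n1 * n2 / (n * (n - 1.0)) * ((ranks ** 2).sum(axis=1) - n * (n + 1.0) ** 2 / 4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (W - expect) / np.sqrt(var), 0.0)
    return z


def _signed_rank_z(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Standardized Wilcoxon signed-rank per row for paired differences.

    X holds per-row paired differences (antigens x pairs); ``signs`` is a
    +/-1 vector flipping each pair (the permutation unit for paired data).
    """
    d = X * signs
    absd = np.abs(d)
    ranks = rankdata(absd, axis=1)
    ranks = np.where(absd == 0, 0.0, ranks)  # zero differences drop out
    stat = (np.sign(d) * ranks).sum(axis=1)
    var = (ranks ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, stat / np.sqrt(var), 0.0)


# ---------------------------------------------------------------------------
# SAM delta sweep


def _delta_cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float
                   ) -> tuple[float, float]:
    """Tusher-style asymmetric cutoffs for one delta.

    cut_up is the smallest observed order statistic whose excess over its
    expected value reaches delta; cut_low the analogue on the low side.
    """
    diff = d_sorted - dbar
    up = np.where(diff >= delta)[0]
    lo = np.where(-diff >= delta)[0]
    cut_up = float(d_sorted[up.min()]) if up.size else np.inf
    cut_low = float(d_sorted[lo.max()]) if lo.size else -np.inf
    if cut_low >= cut_up:  # crossing curves at tiny delta: everything is called
        return float(d_sorted.min()), float(d_sorted.max())
    return cut_up, cut_low


def _sample_assignments(n: int, n2: int, n_perm: int, seed: int) -> list[np.ndarray]:
    """Up to n_perm DISTINCT group-label assignments, uniformly without replacement.

    Sampling distinct assignments makes the Monte-Carlo estimator converge
    to (and, once every assignment is covered, coincide with) the
    exhaustive computation. When the assignment space is small enough it is
    enumerated and subsampled directly; otherwise rejection sampling is
    used (collisions are negligible in large spaces).
    """
    rng = np.random.default_rng(seed)
    n_distinct = comb(n, n2)
    if n_distinct <= n_perm:
        return [np.array(c) for c in combinations(range(n), n2)]
    if n_distinct <= max(4 * n_perm, 200000):
        allc = list(combinations(range(n), n2))
        pick = rng.choice(n_distinct, size=n_perm, replace=False)
        return [np.array(allc[i]) for i in sorted(pick)]
    seen, perms = set(), []
    while len(perms) < n_perm:
        c = tuple(np.sort(rng.choice(n, size=n2, replace=False)))
        if c not in seen:
            seen.add(c)
            perms.append(np.array(c))
    return perms


def sam_rank(m: MFIMatrix, groups=None, n_perm="exhaustive", seed: int = 0,
             stat: str = "rank_sum", q_call: float = Q_CALL_DEFAULT,
             exhaustive_max: int = EXHAUSTIVE_MAX, pi0: float = 1.0,
             false_summary: str = "mean",
             reactive: pd.Series | None = None) -> pd.DataFrame:
    """SAM with Wilcoxon rank statistics and permutation q-values.

    Per antigen the observed standardized statistic ``d`` is compared with
    the mean order statistic over permutations of the group labels
    (exhaustive enumeration of the distinct label assignments when their
    count is at most ``exhaustive_max`` or ``n_perm="exhaustive"``;
    otherwise ``n_perm`` distinct assignments sampled uniformly without
    replacement under ``seed``, which reduces to the exhaustive set when
    ``n_perm`` covers the space). For each delta in the
    sweep, antigens beyond the asymmetric cutoffs are called and the FDR is
    estimated as pi0 x (average false calls across permutations) / (observed
    calls); the per-antigen q is the smallest such FDR at which the antigen
    is called. ``false_summary="median"`` switches the false-call summary
    to the median across permutations.

    Returns a DataFrame indexed by antigen with columns ``observed_stat``,
    ``expected_stat``, ``q``, ``called`` (at ``q_call``), ``n_permutations``.
    """
    groups = pd.Series(groups).reindex(m.mfi.index) if groups is not None else m.groups
    if groups.isna().any():
        raise DataError("missing group label for some samples")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise DataError(f"sam_rank requires exactly 2 group levels, got {levels}")
    counts = groups.value_counts()
    if counts.min() < 3:
        raise DataError(f"need >= 3 samples per group, got {counts.to_dict()}")

    cols = m.antigens if reactive is None else [a for a in m.antigens if reactive[a]]
    if not cols:
        raise DataError("no reactive antigens to test")
    X = m.mfi[cols].to_numpy(dtype=float).T  # antigens x samples
    n = X.shape[1]
    idx2_obs = np.where((groups == levels[1]).to_numpy())[0]
    n2 = idx2_obs.size

    if stat == "rank_sum":
        statfun = lambda idx2: _rank_sum_z(X, idx2)
    elif stat == "signed_rank":
        raise DataError("signed_rank requires paired input; use sam_signed_rank")
    else:
        raise ValueError(f"unknown stat {stat!r}")

    d_obs = statfun(idx2_obs)

    n_distinct = comb(n, n2)
    if n_perm == "exhaustive":
        if n_distinct > exhaustive_max:
            raise DataError(f"{n_distinct} label assignments exceed exhaustive_max="
                            f"{exhaustive_max}; pass an integer n_perm")
        perms = [np.array(c) for c in combinations(range(n), n2)]
    else:
        perms = _sample_assignments(n, n2, int(n_perm), seed)

    perm_stats = np.vstack([statfun(idx2) for idx2 in perms])  # B x m
    perm_sorted = np.sort(perm_stats, axis=1)
    dbar = perm_sorted.mean(axis=0)

    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    deltas = np.unique(np.abs(d_sorted - dbar))
    q = np.full(len(cols), 1.0)
    for delta in deltas:
        cut_up, cut_low = _delta_cutoffs(d_sorted, dbar, float(delta))
        called = (d_obs >= cut_up) | (d_obs <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        false = ((perm_stats >= cut_up) | (perm_stats <= cut_low)).sum(axis=1)
        agg = np.median if false_summary == "median" else np.mean
        fdr = min(1.0, pi0 * float(agg(false)) / n_called)
        q[called] = np.minimum(q[called], fdr)

    expected = np.empty_like(dbar)
    expected[order] = dbar
    out = pd.DataFrame({"observed_stat": d_obs, "expected_stat": expected,
                        "q": q, "called": q < q_call,
                        "n_permutations": len(perms)},
                       index=pd.Index(cols, name="antigen"))
    return out


def sam_signed_rank(diffs: pd.DataFrame, n_perm="exhaustive", seed: int = 0,
                    q_call: float = Q_CALL_DEFAULT,
                    exhaustive_max: int = EXHAUSTIVE_MAX,
                    pi0: float = 1.0) -> pd.DataFrame:
    """SAM for paired designs: signed-rank statistic, sign-flip permutations.

    ``diffs`` holds per-pair differences (pairs x antigens). The null is
    generated by flipping the sign of each pair; exhaustive when 2**n_pairs
    is at most ``exhaustive_max``. Same delta-sweep q-value construction as
    :func:`sam_rank`.
    """
    X = diffs.to_numpy(dtype=float).T  # antigens x pairs
    n = X.shape[1]
    if n < 3:
        raise DataError("need >= 3 pairs")
    d_obs = _signed_rank_z(X, np.ones(n))

    n_distinct = 2 ** n
    if n_perm == "exhaustive":
        if n_distinct > exhaustive_max:
            raise DataError(f"{n_distinct} sign patterns exceed exhaustive_max; "
                            "pass an integer n_perm")
        signsets = [np.array([1 if (b >> i) & 1 == 0 else -1 for i in range(n)])
                    for b in range(n_distinct)]
    else:
        rng = np.random.default_rng(seed)
        if n_distinct <= max(4 * int(n_perm), 200000):
            pick = rng.choice(n_distinct, size=min(int(n_perm), n_distinct),
                              replace=False)
            signsets = [np.array([1 if (b >> i) & 1 == 0 else -1 for i in range(n)])
                        for b in sorted(pick)]
        else:
            seen, signsets = set(), []
            while len(signsets) < int(n_perm):
                s = tuple(rng.choice([-1, 1], size=n))
                if s not in seen:
                    seen.add(s)
                    signsets.append(np.array(s))

    perm_stats = np.vstack([_signed_rank_z(X, s) for s in signsets])
    perm_sorted = np.sort(perm_stats, axis=1)
    dbar = perm_sorted.mean(axis=0)
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    q = np.full(X.shape[0], 1.0)
    for delta in np.unique(np.abs(d_sorted - dbar)):
        cut_up, cut_low = _delta_cutoffs(d_sorted, dbar, float(delta))
        called = (d_obs >= cut_up) | (d_obs <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        false = ((perm_stats >= cut_up) | (perm_stats <= cut_low)).sum(axis=1)
        q[called] = np.minimum(q[called], min(1.0, pi0 * float(np.mean(false)) / n_called))

    expected = np.empty_like(dbar)
    expected[order] = dbar
    return pd.DataFrame({"observed_stat": d_obs, "expected_stat": expected,
                         "q": q, "called": q < q_call,
                         "n_permutations": len(signsets)},
                        index=pd.Index(diffs.columns, name="antigen"))


# ---------------------------------------------------------------------------
# imputation and clustering


def knn_impute(m: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Replace missing entries by the mean of the k nearest samples' values.

    Distance between samples is Euclidean over the antigens observed in
    both; neighbors must have the target antigen observed. Observed entries
    are returned unchanged.
    """
    X = m.to_numpy(dtype=float)
    n, p = X.shape
    miss = ~np.isfinite(X)
    if miss.all(axis=0).any():
        bad = [m.columns[j] for j in np.where(miss.all(axis=0))[0]]
        raise DataError(f"all-missing antigen(s), cannot impute: {bad}")
    if miss.all(axis=1).any():
        bad = [m.index[i] for i in np.where(miss.all(axis=1))[0]]
        raise DataError(f"sample(s) with no observed values: {bad}")
    if not miss.any():
        return m.copy()

    # pairwise Euclidean over mutually observed antigens
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~miss[i] & ~miss[j]
            if shared.any():
                d = float(np.sqrt(np.sum((X[i, shared] - X[j, shared]) ** 2)))
                dist[i, j] = dist[j, i] = d

    out = X.copy()
    for i, j in zip(*np.where(miss)):
        donors = np.where(~miss[:, j])[0]
        order = donors[np.lexsort((donors, dist[i, donors]))]  # distance, then index
        order = order[np.isfinite(dist[i, order])]
        if order.size == 0:
            raise DataError(f"no usable neighbor for ({m.index[i]}, {m.columns[j]})")
        out[i, j] = X[order[:k], j].mean()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def hcluster_average(m: pd.DataFrame, axis: str = "samples"
                     ) -> tuple[np.ndarray, list]:
    """Average-linkage Euclidean hierarchical clustering; returns (Z, leaf order).

    ``axis="samples"`` clusters rows, ``"antigens"`` clusters columns. The
    matrix must be complete — impute first. Leaf order is the dendrogram's
    left-to-right traversal; names are returned, not positions.
    """
    if axis == "antigens":
        m = m.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'antigens', got {axis!r}")
    X = m.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DataError("clustering requires >= 2 items")
    if not np.isfinite(X).all():
        raise DataError("matrix contains NaN: run knn_impute first")
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    leaves = [m.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaves


# ---------------------------------------------------------------------------
# ELISA utilities


def elisa_detection_limit(blanks) -> float:
    """Detection limit = 2x the sample standard deviation of the blanks."""
    b = np.asarray(blanks, dtype=float)
    if b.size < 2:
        raise DataError("detection limit requires >= 2 blank measurements")
    return float(2.0 * np.std(b, ddof=1))


def background_subtract(counts, bsa) -> np.ndarray:
    """Net ELISA counts: average antigen counts minus the BSA background."""
    return np.asarray(counts, dtype=float) - np.mean(np.asarray(bsa, dtype=float))
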