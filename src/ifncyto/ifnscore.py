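"""Consensus interferon (IFN) signature scoring from qPCR Ct matrices.

The score follows the cumulative-signature construction: duplicate Ct
reactions are averaged, Ct values are normalized to the housekeeping genes
(GAPDH, ACTB, B2M), relative expression is 2**(-dCt), each transcript is
normalized to its highest value across samples, and the per-sample score is
the sum of those per-transcript values (so the score lives in
``[0, n_panel_genes]``). SLE patients are stratified into IFN-H (upper
quartile) and IFN-L (lower quartile) strata on the score.

Housekeeping normalization subtracts the arithmetic mean of the
housekeeping Ct values: Ct is a log2-scale quantity, so the mean on the Ct
scale is the geometric mean on the linear expression scale — the standard
delta-Ct convention. A literal geometric mean of the Ct numbers is available
via ``hk_mean="geometric"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats
from .errors import DataError, SchemaError

HOUSEKEEPING_DEFAULT = ("GAPDH", "ACTB", "B2M")

#: Strings in a Ct CSV treated as "no amplification" and masked.
UNDETERMINED_TOKENS = {"", "undetermined", "undet", "na", "nan", "n/a"}

_REP_SUFFIX = re.compile(r"^(?P<gene>.+?)_(?:rep)?(?P<rep>\d+)$")


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values with replicate structure.

    ``ct`` has shape (n_samples, n_assays, n_replicates); entries where
    ``undetermined`` is True carry no meaningful Ct (reaction did not cross
    threshold, or cell was blank).
    """

    samples: list[str]
    assays: list[str]
    ct: np.ndarray
    housekeeping: tuple[str, ...] = HOUSEKEEPING_DEFAULT
    undetermined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.ndim == 2:
            self.ct = self.ct[:, :, None]
        if self.undetermined is None:
            self.undetermined = ~np.isfinite(self.ct)
        self.undetermined = np.asarray(self.undetermined, dtype=bool)
        if self.undetermined.shape != self.ct.shape:
            raise SchemaError("undetermined mask shape must match ct")
        missing = [g for g in self.housekeeping if g not in self.assays]
        if missing:
            raise SchemaError(f"housekeeping gene(s) absent from assays: {missing}")
        if len(set(self.samples)) != len(self.samples):
            raise SchemaError("duplicate sample ids in CtMatrix")

    @property
    def signature_assays(self) -> list[str]:
        return [a for a in self.assays if a not in self.housekeeping]

    @property
    def n_replicates(self) -> int:
        return self.ct.shape[2]


def read_ct(path, housekeeping=HOUSEKEEPING_DEFAULT) -> CtMatrix:
    """Read a Ct CSV (sample rows x assay columns) into a CtMatrix.

    Replicates are encoded as column suffixes ``GENE_1``/``GENE_2`` (or
    ``GENE_rep1``); a bare ``GENE`` column is a single replicate. Cells
    reading "Undetermined" (or blank) are masked, not parsed as numbers.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise SchemaError(f"duplicate sample ids in {path}")

    pairs: dict[str, dict[int, pd.Series]] = {}
    for col in df.columns:
        m = _REP_SUFFIX.match(col)
        gene, rep = (m.group("gene"), int(m.group("rep"))) if m else (col, 1)
        pairs.setdefault(gene, {})[rep] = df[col]
    assays = list(pairs)
    for hk in housekeeping:
        if hk not in assays:
            raise SchemaError(f"housekeeping gene {hk!r} missing from {path}")

    n_rep = max(len(v) for v in pairs.values())
    ct = np.full((len(samples), len(assays), n_rep), np.nan)
    mask = np.ones_like(ct, dtype=bool)
    for j, gene in enumerate(assays):
        for k, (_, col) in enumerate(sorted(pairs[gene].items())):
            for i, raw in enumerate(col):
                token = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
                if token.lower() in UNDETERMINED_TOKENS:
                    continue
                ct[i, j, k] = float(token)
                mask[i, j, k] = False
    return CtMatrix(samples, assays, ct, tuple(housekeeping), mask)


def collapse_replicates(m: CtMatrix) -> CtMatrix:
    """Average unmasked replicate Ct values; all-masked entries stay masked."""
    valid = ~m.undetermined
    n_valid = valid.sum(axis=2)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0,
                        np.where(valid, m.ct, 0.0).sum(axis=2) / np.maximum(n_valid, 1),
                        np.nan)
    return CtMatrix(list(m.samples), list(m.assays), mean[:, :, None],
                    m.housekeeping, (n_valid == 0)[:, :, None])


@dataclass
class ExpressionMatrix:
    """Relative expression 2**(-dCt), samples x genes, unitless and >= 0."""

    samples: list[str]
    genes: list[str]
    expr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.samples, columns=self.genes)


def normalize_to_housekeeping(m: CtMatrix, hk_mean: str = "ct_mean") -> ExpressionMatrix:
    """Housekeeping-normalize Ct and convert to relative expression.

    dCt(gene, sample) = Ct(gene, sample) - hk(sample), where hk is the
    arithmetic mean of the housekeeping Ct values (``hk_mean="ct_mean"``,
    the geometric mean on the linear scale) or the literal geometric mean of
    the Ct numbers (``"geometric"``). expr = 2**(-dCt). Masked signature
    entries become expression 0 (below detection).
    """
    if m.n_replicates != 1:
        m = collapse_replicates(m)
    ct = m.ct[:, :, 0]
    mask = m.undetermined[:, :, 0]
    hk_idx = [m.assays.index(g) for g in m.housekeeping]
    if mask[:, hk_idx].any():
        bad = [m.samples[i] for i in np.where(mask[:, hk_idx].any(axis=1))[0]]
        raise DataError(f"undetermined housekeeping Ct for sample(s): {bad}")
    hk_ct = ct[:, hk_idx]
    if hk_mean == "ct_mean":
        ref = hk_ct.mean(axis=1)
    elif hk_mean == "geometric":
        ref = np.exp(np.log(hk_ct).mean(axis=1))
    else:
        raise ValueError(f"unknown hk_mean {hk_mean!r}")
    genes = m.signature_assays
    gidx = [m.assays.index(g) for g in genes]
    dct = ct[:, gidx] - ref[:, None]
    expr = np.where(mask[:, gidx], 0.0, np.power(2.0, -dct))
    return ExpressionMatrix(list(m.samples), genes, expr)


def compute_ifn_score(e: ExpressionMatrix, panel=None, groups=None) -> pd.DataFrame:
    """Cumulative IFN score: sum over panel genes of max-normalized expression.

    Each transcript is divided by its highest value across all samples, so
    each per-gene term lies in [0, 1] and the score in [0, len(panel)].
    Returns a table (index = sample) with columns ``score``, ``group``
    (from ``groups`` mapping, default "SLE"), and ``stratum`` (all "n/a"
    until :func:`stratify_quartiles`).
    """
    panel = list(panel) if panel is not None else list(e.genes)
    missing = [g for g in panel if g not in e.genes]
    if missing:
        raise SchemaError(f"panel gene(s) not in expression matrix: {missing}")
    idx = [e.genes.index(g) for g in panel]
    sub = e.expr[:, idx]
    gmax = sub.max(axis=0)
    zero = [panel[j] for j in np.where(gmax <= 0)[0]]
    if zero:
        raise DataError(f"all-zero expression for gene(s) {zero}: max-normalization undefined")
    score = (sub / gmax).sum(axis=1)
    group = pd.Series({s: "SLE" for s in e.samples} if groups is None else dict(groups))
    tab = pd.DataFrame({"score": score, "group": group.reindex(e.samples).values,
                        "stratum": "n/a"}, index=pd.Index(e.samples, name="sample"))
    return tab


def stratify_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Assign IFN-H / IFN-L / mid strata within the SLE group by score quartiles.

    Q1 and Q3 are linear-interpolation quantiles of the SLE scores;
    score >= Q3 -> IFN-H, score <= Q1 -> IFN-L, else mid. Healthy controls
    keep stratum "n/a". If all SLE scores are equal the quartile bounds
    degenerate and every SLE sample is assigned "mid".
    """
    out = table.copy()
    sle = out["group"] == "SLE"
    scores = out.loc[sle, "score"].to_numpy(dtype=float)
    if scores.size < 4:
        raise DataError(f"stratification requires >= 4 SLE samples, got {scores.size}")
    if np.unique(scores).size == 1:
        out.loc[sle, "stratum"] = "mid"
        return out
    q1, q3 = np.quantile(scores, [0.25, 0.75])  # linear interpolation
    strat = np.where(scores >= q3, "IFN-H", np.where(scores <= q1, "IFN-L", "mid"))
    out.loc[sle, "stratum"] = strat
    out.loc[~sle, "stratum"] = "n/a"
    return out


def correlate_scores(a, b) -> stats.TestResult:
    """Spearman rho between two per-sample score vectors (paired)."""
    return stats.spearman(a, b)
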