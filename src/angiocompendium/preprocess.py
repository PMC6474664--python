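"""Paired-sample preprocessing and differential-expression selection.

Input expression values are assumed to be log2-scale intensities already
summarized to gene (or probe-set) level.  The module provides quantile
normalization across samples, a paired two-sided Wilcoxon signed-rank test
(exact by enumeration for small replicate counts, normal approximation with
continuity and tie corrections above), strict-threshold selection of
differentially expressed (DE) genes, and collapsing of replicate probe IDs
to one row per gene by p-value averaging.
"""

from __future__ import annotations

import functools
import re
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_THRESHOLD",
    "EXACT_LIMIT",
    "ExpressionSet",
    "quantile_normalize",
    "wilcoxon_signed_rank",
    "select_de",
    "collapse_replicates",
]

#: Significance cutoff for DE selection; genes pass strictly below it.
DEFAULT_THRESHOLD = 0.003

#: Largest number of non-zero paired differences handled by exact enumeration.
EXACT_LIMIT = 25

_COLUMN_RE = re.compile(r"^(?P<treatment>.+)_(?P<arm>ctrl|trt)_(?P<rep>\d+)$")


@dataclass
class ExpressionSet:
    """Paired treated/control replicate expression for one treatment.

    ``control`` and ``treated`` are genes x replicates arrays in identical
    gene order; replicate *i* of the treated arm is paired with replicate
    *i* of the control arm.  Gene identifiers are upper-cased on
    construction so that they join cleanly with knowledge-base files.
    """

    gene_ids: list[str]
    control: np.ndarray
    treated: np.ndarray
    treatment: str

    def __post_init__(self) -> None:
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        self.treated = np.atleast_2d(np.asarray(self.treated, dtype=float))
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        if self.control.shape != self.treated.shape:
            raise ValueError(
                "control and treated matrices must have identical shape, got "
                f"{self.control.shape} vs {self.treated.shape}"
            )
        if self.control.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.control.shape[0]} rows"
            )
        if np.isnan(self.control).any() or np.isnan(self.treated).any():
            raise ValueError("expression matrices contain missing values")

    @property
    def n_genes(self) -> int:
        return self.control.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.control.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for i in range(self.n_replicates):
            cols[f"{self.treatment}_ctrl_{i + 1}"] = self.control[:, i]
        for i in range(self.n_replicates):
            cols[f"{self.treatment}_trt_{i + 1}"] = self.treated[:, i]
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene"))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, treatment: str | None = None) -> "ExpressionSet":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.isna().any().any():
            raise ValueError(f"{path}: expression matrix contains missing values")
        ctrl: dict[int, str] = {}
        trt: dict[int, str] = {}
        inferred: set[str] = set()
        for col in frame.columns:
            m = _COLUMN_RE.match(col)
            if m is None:
                raise ValueError(f"{path}: unrecognized column name {col!r}")
            inferred.add(m["treatment"])
            (ctrl if m["arm"] == "ctrl" else trt)[int(m["rep"])] = col
        if treatment is None:
            if len(inferred) != 1:
                raise ValueError(
                    f"{path}: ambiguous treatment names {sorted(inferred)}"
                )
            treatment = inferred.pop()
        if sorted(ctrl) != sorted(trt):
            raise ValueError(f"{path}: unpaired replicate columns")
        order = sorted(ctrl)
        return cls(
            gene_ids=list(frame.index),
            control=frame[[ctrl[i] for i in order]].to_numpy(),
            treated=frame[[trt[i] for i in order]].to_numpy(),
            treatment=treatment,
        )


def quantile_normalize(matrix):
    """Force every sample (column) onto the common mean-quantile distribution.

    The reference distribution is the row-wise mean of the column-sorted
    input; each value is replaced by the reference value at its within-column
    rank (average ranks for ties, interpolating the two flanking reference
    values at half-ranks).  Row and column order are preserved.  Accepts and
    returns either a DataFrame or an ndarray.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values")
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = stats.rankdata(arr, axis=0)  # average ranks, 1-based
    lo = np.floor(ranks).astype(int) - 1
    hi = np.ceil(ranks).astype(int) - 1
    out = 0.5 * (reference[lo] + reference[hi])
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@functools.lru_cache(maxsize=1024)
def _signrank_p_table(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Two-sided exact p for every achievable doubled rank-sum.

    ``doubled_ranks`` are 2x the (average) ranks of |differences| so that
    tied half-ranks become integers.  Entry ``w2`` of the returned table is
    min(1, 2*min(P(W2 <= w2), P(W2 >= w2))) under the null that each
    difference is independently positive or negative with probability 1/2.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    n_assignments = counts.sum()  # 2**n, exact in float64 for n <= EXACT_LIMIT
    cdf = np.cumsum(counts)
    sf = np.cumsum(counts[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf) / n_assignments)


def wilcoxon_signed_rank(treated, control) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking (the classical exclusion
    rule); ties among |differences| receive average ranks.  Exact by
    enumeration of all sign assignments for up to ``EXACT_LIMIT`` non-zero
    differences, otherwise a normal approximation with continuity and tie
    corrections.  Returns 1.0 when every difference is zero.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("treated and control must be equal-length 1-D vectors")
    d = t - c
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    if n <= EXACT_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(int)
        w2 = int(doubled[d > 0].sum())
        return float(_signrank_p_table(tuple(sorted(doubled)))[w2])
    w = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    variance = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48.0
    )
    if variance <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(variance)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def select_de(expr: ExpressionSet, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-gene paired DE table with strict-threshold significance flags.

    Returns a DataFrame indexed by gene with columns ``p_value``,
    ``log2_fold_change`` (mean treated - control), ``direction`` (sign of
    the fold change) and ``significant`` (p strictly below ``threshold``).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    diffs = expr.treated - expr.control
    lfc = diffs.mean(axis=1)
    pvals = np.fromiter(
        (
            wilcoxon_signed_rank(expr.treated[i], expr.control[i])
            for i in range(expr.n_genes)
        ),
        dtype=float,
        count=expr.n_genes,
    )
    table = pd.DataFrame(
        {
            "p_value": pvals,
            "log2_fold_change": lfc,
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": pvals < threshold,
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    table.attrs["treatment"] = expr.treatment
    table.attrs["threshold"] = float(threshold)
    return table


def collapse_replicates(
    table: pd.DataFrame,
    id_map: Mapping[str, str] | Callable[[str], str],
    resignify: bool = False,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Collapse replicate probe rows to one row per gene.

    The collapsed p-value is the arithmetic mean of member p-values; the
    log2 fold change is the member mean and sets the direction.  With the
    default ``resignify=False`` (select-then-collapse: selection already
    happened at probe level) a gene is significant if any member was; with
    ``resignify=True`` the significance flag is recomputed as mean-p <
    ``threshold`` (collapse-then-select).  Members with conflicting
    directions are kept and trigger a warning.

    ``id_map`` must cover every row of ``table`` (probe -> gene); a missing
    probe raises ``KeyError``.
    """
    if callable(id_map):
        genes = [str(id_map(p)).upper() for p in table.index]
    else:
        missing = [p for p in table.index if p not in id_map]
        if missing:
            raise KeyError(f"id_map does not cover probes: {missing[:10]}")
        genes = [str(id_map[p]).upper() for p in table.index]

    if resignify and threshold is None:
        threshold = table.attrs.get("threshold", DEFAULT_THRESHOLD)

    work = table.assign(_gene=genes)
    grouped = work.groupby("_gene", sort=True)
    p_mean = grouped["p_value"].mean()
    lfc_mean = grouped["log2_fold_change"].mean()
    conflicted = grouped["direction"].nunique() > 1
    if conflicted.any():
        names = list(conflicted.index[conflicted])
        warnings.warn(
            "conflicting probe directions collapsed for genes: "
            + ", ".join(names[:20])
            + ("..." if len(names) > 20 else ""),
            stacklevel=2,
        )
    if resignify:
        significant = p_mean < threshold
    else:
        significant = grouped["significant"].any()
    collapsed = pd.DataFrame(
        {
            "p_value": p_mean,
            "log2_fold_change": lfc_mean,
            "direction": np.where(lfc_mean > 0, "up", "down"),
            "significant": significant,
        }
    )
    collapsed.index.name = "gene"
    collapsed.attrs.update(table.attrs)
    return collapsed
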