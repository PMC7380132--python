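"""Agreement statistics between classification schemes and contingency tests.

Cohen's kappa measures chance-corrected agreement between two labelings of
the same samples: kappa = (p_o - p_e) / (1 - p_e), with observed agreement
p_o = trace/n and chance agreement p_e = sum_i row_i * col_i / n^2. Per-class
accuracy reads row-wise fractions off the same confusion table. Group-wise
subtype distributions (e.g. Mes vs non-Mes across stage groups) are compared
with the two-sided Fisher exact test under the point-probability rule: the
two-sided p sums the hypergeometric probabilities, over all tables with the
observed margins, of tables no more probable than the observed one. Two-sided
Fisher has competing definitions; the point-probability convention is the one
mainstream statistical software uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ConfusionTable", "cross_tabulate", "cohens_kappa",
           "per_class_accuracy", "fisher_exact_2x2", "subtype_by_group_test"]


@dataclass(frozen=True)
class ConfusionTable:
    """k x m cross-tabulation of two label vectors (rows: reference)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match label lists")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if counts.sum() < 1:
            raise ValueError("confusion table is empty (n = 0)")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def is_square(self) -> bool:
        return self.counts.shape[0] == self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def cross_tabulate(
    labels_a: pd.Series,
    labels_b: pd.Series,
    *,
    exclude: set[str] | frozenset[str] = frozenset({"unclassified"}),
) -> ConfusionTable:
    """Cross-tabulate two per-sample label vectors joined on sample id.

    Samples carrying an excluded label (default: "unclassified") in either
    vector are removed before counting, mirroring the standard practice of
    dropping samples that did not cluster into any subtype. Label order is
    sorted for determinism.
    """
    a, b = labels_a.align(labels_b, join="inner")
    if len(a) == 0:
        raise ValueError("label vectors share no sample ids")
    keep = ~(a.isin(exclude) | b.isin(exclude))
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d sample(s) with label in %s", n_excluded, sorted(exclude))
    a, b = a[keep].astype(str), b[keep].astype(str)
    if len(a) == 0:
        raise ValueError("no samples remain after exclusions")
    rows = tuple(sorted(a.unique()))
    cols = tuple(sorted(b.unique()))
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    for x, y in zip(a, b):
        counts[ri[x], ci[y]] += 1
    return ConfusionTable(rows, cols, counts)


def cohens_kappa(table: ConfusionTable) -> float:
    """Cohen's kappa from a square confusion table.

    Degenerate case: when chance agreement p_e equals 1 (all mass in a single
    row/column pair), kappa is defined as 1.0 if the observed agreement is
    also perfect, and is an error otherwise (0/0 with genuine disagreement).
    """
    if not table.is_square:
        raise ValueError("Cohen's kappa requires a square table")
    counts = table.counts.astype(float)
    n = counts.sum()
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if np.isclose(p_e, 1.0):
        if np.isclose(p_o, 1.0):
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but observed is not")
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_accuracy(table: ConfusionTable) -> pd.Series:
    """Row-wise accuracy: diagonal count over row total, NaN for empty rows."""
    if not table.is_square:
        raise ValueError("per-class accuracy requires a square table")
    counts = table.counts.astype(float)
    row_totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(row_totals > 0, np.diag(counts) / row_totals, np.nan)
    return pd.Series(acc, index=list(table.row_labels), name="accuracy")


def fisher_exact_2x2(table: ConfusionTable | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule).

    A table with any zero margin carries no information about association and
    returns p = 1.0.
    """
    counts = table.counts if isinstance(table, ConfusionTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {counts.shape}")
    if (counts < 0).any() or counts.dtype.kind not in "iu":
        counts = np.asarray(counts)
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(np.int64)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        logger.info("zero margin in 2x2 table; returning p = 1.0")
        return 1.0
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(min(p, 1.0))


def subtype_by_group_test(
    calls: pd.Series,
    annotations: pd.DataFrame,
    grouping: str,
    *,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Mes-vs-non-Mes counts per group and pairwise two-sided Fisher tests.

    ``calls`` is a boolean per-sample Mes indicator indexed by sample id.
    For each requested pair of groups (default: all pairs in sorted order),
    the 2x2 table [groups x (Mes, non-Mes)] is tested. Raw p-values are
    reported together with a Benjamini-Hochberg-adjusted column; the
    adjustment is informational and never gates output. Empty groups are
    excluded with a log entry. With fewer than two groups, the count table is
    returned with no tests.
    """
    if grouping not in annotations.columns:
        raise KeyError(f"grouping column {grouping!r} not in annotations")
    joined = annotations[[grouping]].join(calls.rename("is_mes"), how="inner")
    joined = joined.dropna(subset=[grouping])
    tab = (
        joined.groupby(grouping, sort=True)["is_mes"]
        .agg(n="size", n_mes="sum")
        .reset_index()
    )
    tab = tab[tab["n"] > 0]
    groups = tab[grouping].tolist()
    counts = {g: (int(m), int(n - m))
              for g, n, m in zip(tab[grouping], tab["n"], tab["n_mes"])}
    if pairs is None:
        pairs = list(combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in counts:
                raise KeyError(f"group {g!r} absent (or empty) in column {grouping!r}")
        table = np.array([counts[g1], counts[g2]], dtype=np.int64)
        frac1 = counts[g1][0] / sum(counts[g1])
        frac2 = counts[g2][0] / sum(counts[g2])
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "n_mes_a": counts[g1][0],
                "n_nonmes_a": counts[g1][1],
                "n_mes_b": counts[g2][0],
                "n_nonmes_b": counts[g2][1],
                "fraction_mes_a": frac1,
                "fraction_mes_b": frac2,
                "direction": "a>b" if frac1 > frac2 else ("a<b" if frac1 < frac2 else "a=b"),
                "p_fisher": fisher_exact_2x2(table),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["p_bh"] = multipletests(result["p_fisher"], method="fdr_bh")[1]
    result.attrs["group_counts"] = tab
    return result
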