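"""Association of signature scores with annotated cell-type content.

Consumes the tabular output of digital image analysis (per-sample fibroblast,
epithelial cancer cell and immune cell quantities — counts or areas) and
correlates signature scores with cell-type percentages. The percent basis is
the three annotated classes only, not total cells: percent_i = 100 q_i / sum q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CellContentRecord", "cell_percents", "correlate_score_content",
           "stratified_association", "content_table_to_percents"]

CELL_CLASSES = ("fibroblast", "cancer", "immune")


@dataclass(frozen=True)
class CellContentRecord:
    """Raw per-class quantities for one sample, with derived percents."""

    sample_id: str
    fibroblast: float
    cancer: float
    immune: float

    def __post_init__(self) -> None:
        for name in CELL_CLASSES:
            if getattr(self, name) < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative {name} quantity"
                )
        if self.total == 0:
            raise ValueError(f"sample {self.sample_id!r}: all cell quantities are zero")

    @property
    def total(self) -> float:
        return self.fibroblast + self.cancer + self.immune

    @property
    def percents(self) -> tuple[float, float, float]:
        return cell_percents(self.fibroblast, self.cancer, self.immune)


def cell_percents(
    fibroblast: float, cancer: float, immune: float
) -> tuple[float, float, float]:
    """Percent of each class among the three annotated classes."""
    total = fibroblast + cancer + immune
    if total <= 0:
        raise ValueError("cell quantities sum to zero; percents undefined")
    return tuple(100.0 * q / total for q in (fibroblast, cancer, immune))


def content_table_to_percents(content: pd.DataFrame) -> pd.DataFrame:
    """Convert a table of raw class quantities to percents per sample.

    Expects columns fibroblast / cancer / immune indexed by sample id; returns
    fibroblast_pct / cancer_pct / immune_pct.
    """
    missing = [c for c in CELL_CLASSES if c not in content.columns]
    if missing:
        raise KeyError(f"content table lacks column(s): {missing}")
    q = content[list(CELL_CLASSES)].astype(float)
    if (q < 0).any().any():
        raise ValueError("negative cell quantities")
    totals = q.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero cell quantities for sample(s): {zero}")
    pct = q.div(totals, axis=0) * 100.0
    pct.columns = [f"{c}_pct" for c in CELL_CLASSES]
    return pct


def correlate_score_content(
    scores: pd.Series,
    percents: pd.Series,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlate a per-sample score with a cell-class percentage.

    Joins on sample id, drops pairs with either value missing (counted in the
    log), and returns (r, two-sided p, n). Requires >= 3 complete pairs and
    non-constant vectors.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    x, y = scores.align(percents, join="inner")
    complete = x.notna() & y.notna()
    dropped = int((~complete).sum()) + (len(scores) - len(x)) + (len(percents) - len(y))
    if dropped:
        logger.info("dropped %d sample(s) missing a score or a percent", dropped)
    x, y = x[complete].astype(float), y[complete].astype(float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, have {n}")
    if x.nunique() == 1 or y.nunique() == 1:
        raise ValueError("correlation undefined: one input vector is constant")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), n


def stratified_association(
    scores: pd.Series,
    percents: pd.Series,
    annotations: pd.DataFrame,
    stratum_column: str,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-stratum score-vs-content correlations.

    One row per stratum value with r, p, n and a ``testable`` flag; strata
    with fewer than 3 complete pairs (or constant inputs) are reported as
    untestable rather than raising.
    """
    if stratum_column not in annotations.columns:
        raise KeyError(f"stratum column {stratum_column!r} not in annotations")
    rows = []
    strata = sorted(annotations[stratum_column].dropna().unique())
    for stratum in strata:
        ids = annotations.index[annotations[stratum_column] == stratum]
        s = scores.reindex(ids).dropna()
        try:
            r, p, n = correlate_score_content(s, percents, method)
            rows.append({"stratum": stratum, "r": r, "p": p, "n": n, "testable": True})
        except ValueError:
            rows.append({"stratum": stratum, "r": np.nan, "p": np.nan,
                         "n": len(s), "testable": False})
    return pd.DataFrame(rows)
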