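"""Median-threshold mesenchymal (Mes) subtype classification.

The classifier binarizes each gene of a mesenchymal signature (typically the
15-gene CAF/ECM panel) against its median expression in a reference
population: a sample scores 1 for a gene when its expression strictly exceeds
the gene's threshold, else 0. The Mes score is the fraction of signature
genes scoring 1, so it lies on the lattice {0, 1/k, ..., 1}; a sample is
called Mes only when the score is exactly 1 (every gene above threshold),
unless a relaxed cutoff is requested explicitly.

Because both thresholding and the strict comparison depend on ranks only,
every call is invariant under any strictly increasing per-gene transform
applied consistently to the matrix and the reference (e.g. log2(x+1)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, GeneSignature, intersect_signature

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSet", "MesCall", "compute_thresholds", "score_samples",
           "classify_cohort", "calls_to_frame"]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-gene median thresholds on the scale of the source matrix."""

    thresholds: dict[str, float]
    reference_description: str = "all samples"

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("threshold set is empty")
        for g, t in self.thresholds.items():
            if not math.isfinite(t):
                raise ValueError(f"non-finite threshold for gene {g!r}: {t}")

    @property
    def genes(self) -> list[str]:
        return list(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class MesCall:
    """Per-sample binary gene scores, normalized Mes score and call."""

    sample_id: str
    gene_scores: dict[str, int]
    mes_score: float
    is_mes: bool
    n_genes_used: int
    missing_genes: tuple[str, ...] = field(default=())


def compute_thresholds(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    reference: str | list[str] = "all",
) -> ThresholdSet:
    """Per-gene median thresholds over a reference sample set.

    ``reference`` is either the string ``"all"`` or an explicit list of sample
    ids (e.g. the primary tumors of a matched cohort); it is never inferred.
    Medians over an even number of samples are the mean of the two central
    order statistics. Signature genes absent from the matrix are dropped
    before thresholding; zero present genes is an error.
    """
    present, missing = intersect_signature(signature, matrix)
    if present is None:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if missing:
        logger.warning("signature %r: %d gene(s) missing from matrix: %s",
                       signature.name, len(missing), missing)
    if reference == "all":
        ref_ids = matrix.sample_ids
        desc = "all samples"
    else:
        ref_ids = list(reference)
        if not ref_ids:
            raise ValueError("reference sample set is empty")
        absent = [s for s in ref_ids if s not in matrix.data.columns]
        if absent:
            raise KeyError(f"reference sample id(s) not in matrix: {absent}")
        desc = f"{len(ref_ids)} reference samples"
    sub = matrix.data.loc[list(present.genes), ref_ids]
    medians = sub.median(axis=1)
    return ThresholdSet(dict(zip(present.genes, medians.astype(float))), desc)


def score_samples(
    matrix: ExpressionMatrix,
    thresholds: ThresholdSet,
    *,
    mes_cutoff: float = 1.0,
) -> list[MesCall]:
    """Score every sample of a matrix against a threshold set.

    A gene scores 1 when expression strictly exceeds its threshold; ties at
    the threshold score 0. ``mes_score`` is the fraction of available genes
    scoring 1 and ``is_mes`` requires ``mes_score >= mes_cutoff`` (default 1.0:
    all genes above threshold). Threshold genes absent from the matrix are
    recorded per call and the score renormalized over the remainder; fewer
    than half the genes available makes the classification unreliable and is
    an error.
    """
    genes = thresholds.genes
    present = [g for g in genes if g in matrix.data.index]
    missing = tuple(g for g in genes if g not in matrix.data.index)
    min_needed = math.ceil(len(genes) / 2)
    if len(present) < min_needed:
        raise ValueError(
            f"only {len(present)} of {len(genes)} threshold genes present; "
            f"need at least {min_needed} for a reliable classification"
        )
    if missing:
        logger.warning("scoring with %d/%d genes; missing: %s",
                       len(present), len(genes), list(missing))
    t = np.array([thresholds.thresholds[g] for g in present])
    block = matrix.data.loc[present]  # genes x samples
    binary = (block.to_numpy() > t[:, None]).astype(int)
    calls = []
    for j, sid in enumerate(matrix.sample_ids):
        gene_scores = dict(zip(present, binary[:, j].tolist()))
        score = binary[:, j].sum() / len(present)
        calls.append(
            MesCall(
                sample_id=sid,
                gene_scores=gene_scores,
                mes_score=float(score),
                is_mes=bool(score >= mes_cutoff),
                n_genes_used=len(present),
                missing_genes=missing,
            )
        )
    return calls


def calls_to_frame(calls: list[MesCall]) -> pd.DataFrame:
    """Tabulate calls: sample_id index, mes_score / is_mes / bookkeeping."""
    return pd.DataFrame(
        {
            "mes_score": [c.mes_score for c in calls],
            "is_mes": [c.is_mes for c in calls],
            "n_genes_used": [c.n_genes_used for c in calls],
            "missing_genes": [",".join(c.missing_genes) for c in calls],
        },
        index=pd.Index([c.sample_id for c in calls], name="sample_id"),
    )


def classify_cohort(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    reference: str | list[str] = "all",
    annotations: pd.DataFrame | None = None,
    groupby: list[str] | None = None,
    *,
    mes_cutoff: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Classify a cohort and summarize Mes fractions by annotation strata.

    Returns ``(calls, summary)``: per-sample calls as a DataFrame, and — when
    annotations and grouping columns are supplied — a summary with one row per
    group (sorted lexicographically for determinism) carrying ``n``, ``n_mes``
    and ``fraction_mes``. Groups with zero samples simply do not appear.
    """
    thresholds = compute_thresholds(matrix, signature, reference)
    calls = calls_to_frame(score_samples(matrix, thresholds, mes_cutoff=mes_cutoff))
    if annotations is None or not groupby:
        return calls, None
    missing_cols = [c for c in groupby if c not in annotations.columns]
    if missing_cols:
        raise KeyError(f"grouping column(s) not in annotations: {missing_cols}")
    joined = calls.join(annotations[groupby], how="inner")
    if len(joined) < len(calls):
        logger.warning("%d sample(s) lack annotations and were dropped from the summary",
                       len(calls) - len(joined))
    grouped = joined.groupby(groupby, sort=True)["is_mes"]
    summary = grouped.agg(n="size", n_mes="sum").reset_index()
    summary["fraction_mes"] = summary["n_mes"] / summary["n"]
    return calls, summary
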