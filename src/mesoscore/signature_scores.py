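"""Gene-wise standardization, composite signature z-scores and the stromal
contrast score.

A signature z-score for a sample is the unweighted mean, over the signature's
genes, of gene-wise standardized expression (each gene centered and scaled
across samples of the data set). Standardization is always computed within a
single data set, never across merged cohorts.

The stromal contrast score compares two stromal signatures — one derived from
the stroma of omental metastases, one from the stroma of primary ovarian
tumors — as a signed combination: positive weight on the omental-metastasis
signature, negative on the primary signature. Higher values indicate
metastasis-like stroma. Because z-scores cross zero, the signed combination is
computed as a difference by default; a literal per-sample quotient is
available behind ``mode="quotient"`` for sensitivity analysis only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, GeneSignature, intersect_signature

logger = logging.getLogger(__name__)

__all__ = ["ZMatrix", "ztransform", "signature_zscore", "stromal_contrast",
           "mes15_zscore", "contrast_by_group"]


@dataclass
class ZMatrix:
    """Gene-wise standardized expression (mean 0, sd 1 per retained gene)."""

    data: pd.DataFrame  # genes x samples, standardized
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def ztransform(matrix: ExpressionMatrix, *, ddof: int = 1) -> ZMatrix:
    """Standardize each gene across samples: z = (x - mean) / sd.

    Uses the sample standard deviation (n-1 denominator) by default. Genes
    with zero variance carry no ranking information and cannot be scaled;
    they are dropped and listed in ``dropped_genes``. Requires >= 2 samples.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-transformation requires at least 2 samples")
    values = matrix.data
    sd = values.std(axis=1, ddof=ddof)
    zero_var = sd == 0.0
    dropped = values.index[zero_var].tolist()
    if dropped:
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped)
    kept = values.loc[~zero_var]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[~zero_var], axis=0)
    return ZMatrix(z, dropped)


def _present_genes(z: ZMatrix, sig: GeneSignature) -> list[str]:
    available = set(z.data.index)
    present = [g for g in sig.genes if g in available]
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} is present in the z-matrix"
        )
    n_missing = len(sig.genes) - len(present)
    if n_missing:
        logger.warning("signature %r: scoring on %d/%d genes",
                       sig.name, len(present), len(sig.genes))
    return present


def signature_zscore(z: ZMatrix, sig: GeneSignature) -> pd.Series:
    """Per-sample signature z-score: unweighted mean of the signature genes'
    z-values in that sample. Absent genes are dropped (with a warning)."""
    present = _present_genes(z, sig)
    scores = z.data.loc[present].mean(axis=0)
    scores.name = sig.name
    return scores


def mes15_zscore(z: ZMatrix, mes15: GeneSignature) -> pd.Series:
    """Mes 15-gene z-score: :func:`signature_zscore` retained as a named
    output for the mesenchymal panel."""
    scores = signature_zscore(z, mes15)
    scores.name = "mes15_zscore"
    return scores


def stromal_contrast(
    z: ZMatrix,
    omental_sig: GeneSignature,
    primary_sig: GeneSignature,
    *,
    mode: str = "difference",
) -> pd.Series:
    """Signed omental-vs-primary stromal contrast per sample.

    ``difference`` (default): omental signature z-score minus primary
    signature z-score. Antisymmetric under swapping the signatures, mean zero
    over the data set (both components are means of mean-zero rows).
    ``quotient``: literal per-sample ratio, unstable near zero denominators —
    sensitivity analysis only.
    """
    omental = signature_zscore(z, omental_sig)
    primary = signature_zscore(z, primary_sig)
    if mode == "difference":
        contrast = omental - primary
    elif mode == "quotient":
        contrast = omental / primary
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    contrast.name = "stromal_contrast"
    return contrast


def contrast_by_group(
    contrast: pd.Series,
    annotations: pd.DataFrame,
    groupby: str | list[str],
) -> pd.DataFrame:
    """Group means of a per-sample score by annotation strata (n, mean, sd)."""
    if isinstance(groupby, str):
        groupby = [groupby]
    missing = [c for c in groupby if c not in annotations.columns]
    if missing:
        raise KeyError(f"grouping column(s) not in annotations: {missing}")
    joined = annotations[groupby].join(contrast.rename("score"), how="inner")
    out = (
        joined.groupby(groupby, sort=True)["score"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    return out
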