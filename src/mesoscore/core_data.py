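"""Data model and I/O for expression matrices, sample annotations and gene sets.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
normalized expression values (log-like or linear scale; the scale is recorded
in free-form metadata, never guessed). Sample annotations travel as a pandas
DataFrame indexed by sample id, with controlled-vocabulary columns for stage,
presumed primary site, collection site, tumor role and original molecular
subtype. Gene sets are read from GMT files into :class:`GeneSignature`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "intersect_signature",
    "read_annotations",
    "route_label",
    "stage_group",
    "normalize_site",
    "validate_cell_fractions",
    "SITE_SYNONYMS",
    "PERITONEAL_SITES",
]


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Site-string normalization table. Real cohorts spell collection sites many
#: ways ("Omentum", "omental", "OMENTUM"); keys are matched lower-case. The
#: table is a plain module-level dict so applications can extend it.
SITE_SYNONYMS: dict[str, str] = {
    "ovary": "ovary",
    "ovarian": "ovary",
    "omentum": "omentum",
    "omental": "omentum",
    "peritoneum": "peritoneum",
    "peritoneal": "peritoneum",
    "colon": "colon",
    "intestine": "colon",
    "bowel": "colon",
    "lymph node": "lymph_node",
    "lymph_node": "lymph_node",
    "lymphnode": "lymph_node",
    "uterus": "uterus",
    "fallopian tube": "fallopian_tube",
    "fallopian_tube": "fallopian_tube",
    "abdominal wall": "abdominal_wall",
    "abdominal_wall": "abdominal_wall",
    "diaphragm": "diaphragm",
}

#: Collection sites counted as "peritoneal" when deriving route labels
#: (ovary x omentum/peritoneum/colon -> ov-per, etc.).
PERITONEAL_SITES: frozenset[str] = frozenset(
    {"omentum", "peritoneum", "colon", "abdominal_wall", "diaphragm"}
)

VALID_STAGES = {"I", "II", "III", "IV", "unknown"}
VALID_PRIMARY_SITES = {"ovary", "peritoneum", "other", "unknown"}
VALID_TUMOR_ROLES = {"primary", "metastatic", "recurrent", "unknown"}
VALID_SUBTYPES = {
    "Immunoreactive",
    "Mesenchymal",
    "Proliferative",
    "Differentiated",
    "unclassified",
}

SIGNATURE_ROLES = ("mes15", "mes100", "primary_stroma", "omental_stroma", "other")


def normalize_site(raw: str) -> str:
    """Map a free-text site string onto the controlled vocabulary.

    Unknown strings are lower-cased with spaces replaced by underscores so
    they remain usable as grouping keys rather than raising.
    """
    key = str(raw).strip().lower()
    return SITE_SYNONYMS.get(key, key.replace(" ", "_"))


def stage_group(stage: str) -> str:
    """Collapse FIGO stage to the I-II / III-IV dichotomy."""
    if stage in ("I", "II"):
        return "I-II"
    if stage in ("III", "IV"):
        return "III-IV"
    return "unknown"


def route_label(primary_site: str, collection_site: str) -> str:
    """Dissemination-route label from presumed origin x collection site.

    ``ov-ov``  tumor of ovarian origin collected from the ovary,
    ``ov-per`` ovarian origin collected from a peritoneal site,
    ``per-ov`` peritoneal (PPC) origin collected from the ovary,
    ``per-per`` peritoneal origin collected from a peritoneal site.
    Any combination outside this vocabulary maps to ``other``.
    """
    origin = normalize_site(primary_site)
    site = normalize_site(collection_site)
    if origin == "ovary":
        if site == "ovary":
            return "ov-ov"
        if site in PERITONEAL_SITES:
            return "ov-per"
    elif origin == "peritoneum":
        if site == "ovary":
            return "per-ov"
        if site in PERITONEAL_SITES:
            return "per-per"
    return "other"


def validate_cell_fractions(
    fibroblast: float, cancer: float, immune: float, *, tol: float = 1e-6
) -> None:
    """Check a (fibroblast, cancer, immune) percentage triple sums to 100."""
    for name, v in (("fibroblast", fibroblast), ("cancer", cancer), ("immune", immune)):
        if v < 0:
            raise ValueError(f"cell fraction {name!r} is negative: {v}")
    total = fibroblast + cancer + immune
    if abs(total - 100.0) > tol:
        raise ValueError(f"cell fractions sum to {total}, expected 100 within {tol}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples.

    Parameters
    ----------
    data
        DataFrame with gene symbols as the index and sample ids as columns.
        Values must be finite floats on a consistent scale.
    metadata
        Free-form provenance (platform, transform applied, scale).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"sample ids not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], dict(self.metadata))


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list with a role in the analysis."""

    name: str
    genes: tuple[str, ...]
    role: str = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.role not in SIGNATURE_ROLES:
            raise ValueError(
                f"signature role {self.role!r} not in {SIGNATURE_ROLES}"
            )

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Expression I/O
# ---------------------------------------------------------------------------

_DUP_POLICIES = ("max-mean", "first", "mean")


def _collapse_duplicates(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if not dup_genes:
        return df
    logger.warning(
        "collapsing %d duplicated gene symbol(s) by policy %r: %s",
        len(dup_genes), policy, dup_genes,
    )
    if policy == "first":
        return df[~df.index.duplicated(keep="first")]
    if policy == "mean":
        return df.groupby(level=0, sort=False).mean()
    if policy == "max-mean":
        # keep, per symbol, the row with the highest mean expression
        order = df.index.drop_duplicates()
        rows = []
        for g in order:
            block = df.loc[[g]]
            rows.append(block.iloc[int(np.argmax(block.mean(axis=1).to_numpy()))])
        out = pd.DataFrame(rows)
        out.index = order
        return out
    raise ValueError(f"unknown duplicate policy {policy!r}; choose from {_DUP_POLICIES}")


def read_expression(
    path: str | Path,
    *,
    sep: str | None = None,
    duplicate_policy: str = "max-mean",
    drop_missing: bool = False,
    transposed: bool = False,
    metadata: Mapping | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV expression table.

    The first column holds gene ids, the first row sample ids. Files with
    samples in rows must be declared via ``transposed=True``; orientation is
    never guessed. Duplicate gene rows are collapsed by ``duplicate_policy``
    (default keeps the row with the highest mean). Missing values are rejected
    unless ``drop_missing=True``, which drops affected gene rows.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if not transposed and len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if transposed:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")

    # detection pass: locate non-numeric cells without losing precision
    probe = df.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & df.notna()
    if bad.any().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[gi, si]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if probe.isna().any().any():
        if not drop_missing:
            na_rows = probe.index[probe.isna().any(axis=1)].tolist()
            raise ValueError(
                f"{path}: missing values in gene row(s) {na_rows}; "
                "pass drop_missing=True to drop them"
            )
        n_before = df.shape[0]
        df = df.loc[probe.notna().all(axis=1)]
        logger.warning("%s: dropped %d gene row(s) with missing values",
                       path, n_before - df.shape[0])
    # conversion pass: astype(float) is correctly rounded, so decimal text
    # written by write_expression round-trips bit-identically
    numeric = df.astype(float)

    numeric = _collapse_duplicates(numeric, duplicate_policy)
    meta = dict(metadata or {})
    meta.setdefault("source", str(path))
    return ExpressionMatrix(numeric, meta)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes-in-rows, tab-delimited, UTF-8 expression table.

    Values round-trip exactly through :func:`read_expression` for any finite
    float64 input (full shortest-repr formatting).
    """
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def _infer_role(name: str) -> str:
    key = name.strip().lower()
    for role in SIGNATURE_ROLES[:-1]:
        if key == role or key.replace("-", "_") == role:
            return role
    return "other"


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene signatures from a GMT file (name, description, genes...).

    Duplicate genes within a set are deduplicated (order-preserving) with a
    warning. Empty files yield an empty list. A signature whose name matches
    a known role (mes15, mes100, primary_stroma, omental_stroma) is tagged
    with that role.
    """
    signatures: list[GeneSignature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s:%d: signature %r lists %d duplicate gene(s); deduplicated",
                    path, lineno, name, len(genes) - len(unique),
                )
            signatures.append(
                GeneSignature(name, tuple(unique), _infer_role(name), description)
            )
    return signatures


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Write signatures to GMT (tab-delimited, UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or sig.role, *sig.genes]))
            fh.write("\n")


def intersect_signature(
    sig: GeneSignature, matrix: ExpressionMatrix
) -> tuple[GeneSignature | None, list[str]]:
    """Split a signature into genes present in / missing from a matrix.

    Real cohorts routinely lack a transcript or two of a published signature;
    the convention is to drop absent genes and proceed on the remainder.
    Returns ``(present, missing)`` where ``present`` preserves signature order
    and is ``None`` when the intersection is empty (a valid, reportable
    outcome, not an error).
    """
    available = set(matrix.gene_ids)
    present = tuple(g for g in sig.genes if g in available)
    missing = [g for g in sig.genes if g not in available]
    if not present:
        return None, missing
    return GeneSignature(sig.name, present, sig.role, sig.description), missing


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "stage",
    "primary_site",
    "collection_site",
    "tumor_role",
    "original_subtype",
)


def read_annotations(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a sample annotation table and derive stage_group and route.

    Expects a ``sample_id`` column plus any of stage, primary_site,
    collection_site, tumor_role, original_subtype, and optional
    fibroblast_pct / cancer_pct / immune_pct columns (which must sum to 100
    per sample when all three are present). Site strings are normalized
    through :data:`SITE_SYNONYMS`.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: annotation table lacks a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df = df.set_index("sample_id")
    return derive_annotation_columns(df)


def derive_annotation_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize sites and add stage_group / route columns in place."""
    df = df.copy()
    for col in ("primary_site", "collection_site"):
        if col in df.columns:
            df[col] = df[col].fillna("unknown").map(normalize_site)
    if "stage" in df.columns:
        df["stage"] = df["stage"].fillna("unknown")
        bad = set(df["stage"]) - VALID_STAGES
        if bad:
            raise ValueError(f"invalid stage value(s): {sorted(bad)}")
        df["stage_group"] = df["stage"].map(stage_group)
    if {"primary_site", "collection_site"} <= set(df.columns):
        df["route"] = [
            route_label(p, c)
            for p, c in zip(df["primary_site"], df["collection_site"])
        ]
    pct_cols = ["fibroblast_pct", "cancer_pct", "immune_pct"]
    if all(c in df.columns for c in pct_cols):
        pct = df[pct_cols].astype(float)
        has_all = pct.notna().all(axis=1)
        for sid, row in pct[has_all].iterrows():
            validate_cell_fractions(*row.to_list())
        df[pct_cols] = pct
    return df
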