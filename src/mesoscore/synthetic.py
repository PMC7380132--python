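"""Synthetic bulk tumor expression cohorts as cell-type mixtures.

Bulk tumor expression is modeled as a convex mixture of cell-class archetype
profiles — stroma (fibroblasts), epithelial cancer cells and immune cells —
with the key biological structure that the stromal archetype differs by tumor
location: fibroblasts in upper-abdominal/omental metastases express the
mesenchymal (Mes) gene panel and the omental-metastasis stromal signature at
elevated levels, while fibroblasts in true primary ovarian tumors express the
primary-tumor stromal signature instead. Cohorts are organized in
route x stage strata (ov-ov, ov-per, per-ov, per-per crossed with FIGO
stage I-II / III-IV) so that every downstream statistic — the median-threshold
Mes classifier, signature z-scores, stromal contrast, subtype-by-group tests
and score-vs-cell-content correlations — can be checked against known ground
truth without any external data.

Per sample: cell fractions ~ Dirichlet; expression(gene) =
sum_class fraction x archetype mean, times multiplicative lognormal noise.
All randomness flows from a single integer seed through a named generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, GeneSignature, write_expression, write_gmt

logger = logging.getLogger(__name__)

__all__ = [
    "ArchetypeProfiles", "GroupDesign", "CohortDesign", "SyntheticCohort",
    "default_signatures", "default_gene_universe", "default_design",
    "generate_archetypes", "generate_cohort", "write_fixture_bundle",
    "simulate_default_cohort",
]

CELL_CLASSES = ("primary_stroma", "metastatic_stroma", "cancer_epithelium", "immune")

# Synthetic stand-in for the 15-gene mesenchymal panel: the six stromal/ECM
# genes commonly named as exemplars of the mesenchymal HGSC subtype plus nine
# canonical cancer-associated-fibroblast / matrix genes. The true published
# panel lives in supplementary material we do not redistribute; for every
# computation here only the list's length and its stromal provenance matter.
MES15_GENES = (
    "COL11A1", "POSTN", "LOX", "VCAN", "TNC", "THBS2",
    "FAP", "FN1", "COL5A1", "COL5A2", "INHBA", "SPARC",
    "TIMP3", "CTSK", "DCN",
)

# Synthetic placeholder symbols for the two 21-gene stromal signatures
# (primary ovarian tumor stroma vs omental metastasis stroma); the published
# lists are external data consumed as GMT in real analyses.
PRIMARY_STROMA_GENES = tuple(f"PSTR{i:02d}" for i in range(1, 22))
OMENTAL_STROMA_GENES = tuple(f"OMST{i:02d}" for i in range(1, 22))


def default_signatures() -> dict[str, GeneSignature]:
    """The generator's built-in signatures (synthetic stand-ins, see above)."""
    return {
        "mes15": GeneSignature("mes15", MES15_GENES, "mes15",
                               "synthetic stand-in mesenchymal 15-gene panel"),
        "primary_stroma": GeneSignature(
            "primary_stroma", PRIMARY_STROMA_GENES, "primary_stroma",
            "synthetic stand-in primary-tumor stromal signature"),
        "omental_stroma": GeneSignature(
            "omental_stroma", OMENTAL_STROMA_GENES, "omental_stroma",
            "synthetic stand-in omental-metastasis stromal signature"),
    }


def default_gene_universe(n_background: int = 150) -> tuple[str, ...]:
    """All signature genes plus unstructured background genes."""
    background = tuple(f"BG{i:04d}" for i in range(1, n_background + 1))
    return MES15_GENES + PRIMARY_STROMA_GENES + OMENTAL_STROMA_GENES + background


@dataclass
class ArchetypeProfiles:
    """Mean expression per gene per cell class (linear scale).

    Baselines are drawn once per gene (log-uniform) and shared across classes;
    location-dependent biology enters as multiplicative fold effects on the
    signature genes: the Mes panel and the omental stromal signature are
    elevated in metastatic stroma, the primary stromal signature in primary
    stroma. Sharing baselines makes the fold ratios exact by construction.
    """

    means: pd.DataFrame  # genes x CELL_CLASSES
    mes15_fold: float
    omental_fold: float
    primary_fold: float

    def __post_init__(self) -> None:
        if (self.means.to_numpy() <= 0).any():
            raise ValueError("archetype means must be positive")
        missing = [c for c in CELL_CLASSES if c not in self.means.columns]
        if missing:
            raise ValueError(f"archetype table lacks class(es): {missing}")

    def check_mes_elevation(self, mes_genes: tuple[str, ...],
                            min_fold: float | None = None) -> None:
        """Assert the Mes panel is elevated in metastatic stroma relative to
        cancer epithelium by at least the configured fold."""
        fold = self.mes15_fold if min_fold is None else min_fold
        ratio = (self.means.loc[list(mes_genes), "metastatic_stroma"]
                 / self.means.loc[list(mes_genes), "cancer_epithelium"])
        bad = ratio[ratio < fold]
        if len(bad):
            raise ValueError(
                f"Mes genes below the {fold}x stromal elevation: {bad.index.tolist()}"
            )


def generate_archetypes(
    gene_universe: tuple[str, ...] | list[str] | None = None,
    signatures: dict[str, GeneSignature] | None = None,
    *,
    seed: int = 0,
    mes15_fold: float = 8.0,
    omental_fold: float = 6.0,
    primary_fold: float = 6.0,
    baseline_range: tuple[float, float] = (16.0, 1024.0),
) -> ArchetypeProfiles:
    """Draw archetype mean profiles; deterministic for a fixed seed.

    Baseline means are log-uniform over ``baseline_range``. Every signature
    gene must belong to the gene universe.
    """
    signatures = signatures or default_signatures()
    if gene_universe is None:
        gene_universe = default_gene_universe()
    genes = list(gene_universe)
    universe = set(genes)
    for sig in signatures.values():
        absent = [g for g in sig.genes if g not in universe]
        if absent:
            raise ValueError(
                f"signature {sig.name!r} gene(s) absent from universe: {absent}"
            )
    rng = np.random.default_rng(seed)
    lo, hi = np.log(baseline_range[0]), np.log(baseline_range[1])
    baseline = np.exp(rng.uniform(lo, hi, size=len(genes)))
    means = pd.DataFrame(
        {cls: baseline.copy() for cls in CELL_CLASSES}, index=genes
    )
    mes = list(signatures["mes15"].genes)
    omental = list(signatures["omental_stroma"].genes)
    primary = list(signatures["primary_stroma"].genes)
    means.loc[mes, "metastatic_stroma"] *= mes15_fold
    means.loc[omental, "metastatic_stroma"] *= omental_fold
    means.loc[primary, "primary_stroma"] *= primary_fold
    profiles = ArchetypeProfiles(means, mes15_fold, omental_fold, primary_fold)
    if mes15_fold >= 1.0:
        profiles.check_mes_elevation(tuple(mes))
    return profiles


@dataclass(frozen=True)
class GroupDesign:
    """One route x stage stratum of the cohort design.

    ``stroma`` is "primary", "metastatic", or a float in [0, 1]: the fraction
    of the stratum's samples carrying metastatic stroma (rounded to a count,
    assignment shuffled deterministically).
    """

    route: str
    stage_group: str
    n: int
    stroma: str | float = "primary"
    dirichlet: tuple[float, float, float] = (4.0, 6.0, 1.5)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if any(a <= 0 for a in self.dirichlet):
            raise ValueError("Dirichlet concentrations must be > 0")
        if isinstance(self.stroma, str):
            if self.stroma not in ("primary", "metastatic"):
                raise ValueError(f"unknown stroma identity {self.stroma!r}")
        elif not 0.0 <= float(self.stroma) <= 1.0:
            raise ValueError("stroma mixture weight must lie in [0, 1]")

    @property
    def metastatic_fraction(self) -> float:
        if self.stroma == "primary":
            return 0.0
        if self.stroma == "metastatic":
            return 1.0
        return float(self.stroma)


@dataclass(frozen=True)
class CohortDesign:
    """Full cohort design: strata, noise level, seed and truth convention."""

    groups: tuple[GroupDesign, ...]
    noise_sigma: float = 0.15
    seed: int = 0
    mes_fibroblast_floor: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.groups:
            raise ValueError("design has no groups")

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)

    def to_dict(self) -> dict:
        return {
            "groups": [asdict(g) for g in self.groups],
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "mes_fibroblast_floor": self.mes_fibroblast_floor,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        groups = tuple(
            GroupDesign(
                route=g["route"],
                stage_group=g["stage_group"],
                n=int(g["n"]),
                stroma=g.get("stroma", "primary"),
                dirichlet=tuple(g.get("dirichlet", (4.0, 6.0, 1.5))),
            )
            for g in d["groups"]
        )
        return cls(
            groups=groups,
            noise_sigma=float(d.get("noise_sigma", 0.15)),
            seed=int(d.get("seed", 0)),
            mes_fibroblast_floor=float(d.get("mes_fibroblast_floor", 0.2)),
        )


#: Dirichlet concentrations for (fibroblast, cancer, immune): metastatic-site
#: strata are fibroblast-rich, pelvis-confined strata epithelium-rich.
_MET_DIRICHLET = (5.0, 4.0, 1.0)
_PRIMARY_DIRICHLET = (3.0, 6.0, 1.0)


def default_design(seed: int = 0, *, scale: float = 1.0) -> CohortDesign:
    """The default 200-sample cohort emulating a site/stage-structured study.

    Pelvis-confined ov-ov stage I-II tumors carry primary stroma only; ov-ov
    stage III-IV tumors are a 25% metastatic-stroma mixture (occult metastases
    seeded back to the ovary); peritoneal-site strata carry metastatic stroma.
    ``scale`` multiplies all group sizes (for smaller property-test cohorts).
    """
    def sz(n: int) -> int:
        return max(1, round(n * scale))

    return CohortDesign(
        groups=(
            GroupDesign("ov-ov", "I-II", sz(40), "primary", _PRIMARY_DIRICHLET),
            GroupDesign("ov-ov", "III-IV", sz(80), 0.25, _MET_DIRICHLET),
            GroupDesign("ov-per", "III-IV", sz(50), "metastatic", _MET_DIRICHLET),
            GroupDesign("per-per", "III-IV", sz(30), "metastatic", _MET_DIRICHLET),
        ),
        noise_sigma=0.15,
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    """Generated matrix, annotations, and ground truth for recovery testing."""

    matrix: ExpressionMatrix
    annotations: pd.DataFrame
    truth: pd.DataFrame
    design: CohortDesign
    signatures: dict[str, GeneSignature]


_ROUTE_SITES = {
    "ov-ov": ("ovary", "ovary"),
    "ov-per": ("ovary", "omentum"),
    "per-ov": ("peritoneum", "ovary"),
    "per-per": ("peritoneum", "peritoneum"),
}

_STAGE_OF_GROUP = {"I-II": "II", "III-IV": "III"}

_NON_MES_SUBTYPES = ("Immunoreactive", "Proliferative", "Differentiated")


def generate_cohort(
    archetypes: ArchetypeProfiles,
    design: CohortDesign,
    signatures: dict[str, GeneSignature] | None = None,
) -> SyntheticCohort:
    """Generate a cohort from archetypes and a design; deterministic per seed.

    Ground-truth "intended Mes" couples stroma identity with a fibroblast
    fraction floor: a sample is intended Mes iff its stroma is metastatic AND
    its fibroblast fraction is at least ``design.mes_fibroblast_floor`` (the
    signal is carried by fibroblasts, so a nearly stroma-free sample cannot
    express it in bulk). The ``original_subtype`` annotation is set to
    Mesenchymal for intended-Mes samples and drawn among the three other
    subtypes otherwise, providing a reference labeling for concordance tests.
    """
    signatures = signatures or default_signatures()
    if design.total_n == 0:
        raise ValueError("design generates zero samples")
    rng = np.random.default_rng(design.seed)
    genes = list(archetypes.means.index)
    columns: list[np.ndarray] = []
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []
    sample_ids: list[str] = []
    counter = 0
    means = archetypes.means
    for group in design.groups:
        if group.n == 0:
            continue
        n_met = int(round(group.metastatic_fraction * group.n))
        stroma_ids = np.array(
            ["metastatic_stroma"] * n_met + ["primary_stroma"] * (group.n - n_met)
        )
        rng.shuffle(stroma_ids)
        fractions = rng.dirichlet(group.dirichlet, size=group.n)
        primary_site, collection_site = _ROUTE_SITES[group.route]
        tumor_role = "primary" if group.route == "ov-ov" else "metastatic"
        for i in range(group.n):
            counter += 1
            sid = f"S{counter:04d}"
            f_fib, f_can, f_imm = fractions[i]
            stroma = stroma_ids[i]
            profile = (
                f_fib * means[stroma].to_numpy()
                + f_can * means["cancer_epithelium"].to_numpy()
                + f_imm * means["immune"].to_numpy()
            )
            if design.noise_sigma > 0:
                profile = profile * rng.lognormal(
                    0.0, design.noise_sigma, size=len(genes)
                )
            intended_mes = (
                stroma == "metastatic_stroma"
                and f_fib >= design.mes_fibroblast_floor
            )
            subtype = (
                "Mesenchymal" if intended_mes
                else str(rng.choice(_NON_MES_SUBTYPES))
            )
            columns.append(profile)
            sample_ids.append(sid)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "stage": _STAGE_OF_GROUP[group.stage_group],
                    "stage_group": group.stage_group,
                    "primary_site": primary_site,
                    "collection_site": collection_site,
                    "route": group.route,
                    "tumor_role": tumor_role,
                    "original_subtype": subtype,
                    "fibroblast_pct": 100.0 * f_fib,
                    "cancer_pct": 100.0 * f_can,
                    "immune_pct": 100.0 * f_imm,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "fibroblast_fraction": f_fib,
                    "cancer_fraction": f_can,
                    "immune_fraction": f_imm,
                    "stroma_identity": stroma,
                    "intended_mes": intended_mes,
                }
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids),
        {"scale": "linear", "generator": "mesoscore.synthetic",
         "seed": design.seed, "config_hash": design.config_hash()},
    )
    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return SyntheticCohort(matrix, annotations, truth, design, signatures)


def simulate_default_cohort(seed: int = 0) -> SyntheticCohort:
    """Archetypes + default design in one call (the standard study cohort)."""
    design = default_design(seed=seed)
    archetypes = generate_archetypes(seed=seed)
    return generate_cohort(archetypes, design)


def write_fixture_bundle(
    cohort: SyntheticCohort,
    directory: str | Path,
    *,
    cells_per_sample: int = 2000,
    force: bool = False,
) -> dict[str, Path]:
    """Write a cohort to disk as a reproducible TSV/GMT fixture bundle.

    Emits matrix.tsv, annotations.tsv, content.tsv (cell counts: fractions
    times ``cells_per_sample``), truth.tsv, signatures.gmt and manifest.json
    (seed plus a config hash that changes iff the design changes). Two runs
    with the same seed and design produce byte-identical files. Refuses a
    non-empty existing directory unless ``force=True``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass force=True to overwrite"
        )
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}" for name in
             ("matrix.tsv", "annotations.tsv", "content.tsv",
              "truth.tsv", "signatures.gmt", "manifest.json")}
    write_expression(cohort.matrix, paths["matrix.tsv"])
    cohort.annotations.to_csv(paths["annotations.tsv"], sep="\t",
                              index_label="sample_id", encoding="utf-8")
    content = pd.DataFrame(
        {
            "fibroblast": cohort.truth["fibroblast_fraction"] * cells_per_sample,
            "cancer": cohort.truth["cancer_fraction"] * cells_per_sample,
            "immune": cohort.truth["immune_fraction"] * cells_per_sample,
        }
    ).round(0).astype(int)
    content.to_csv(paths["content.tsv"], sep="\t", index_label="sample_id",
                   encoding="utf-8")
    cohort.truth.to_csv(paths["truth.tsv"], sep="\t", index_label="sample_id",
                        encoding="utf-8")
    write_gmt(cohort.signatures.values(), paths["signatures.gmt"])
    manifest = {
        "seed": cohort.design.seed,
        "config_hash": cohort.design.config_hash(),
        "n_samples": cohort.matrix.n_samples,
        "n_genes": cohort.matrix.n_genes,
        "cells_per_sample": cells_per_sample,
        "design": cohort.design.to_dict(),
    }
    paths["manifest.json"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
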