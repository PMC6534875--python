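"""Synthetic labeled compendia, signature stand-ins and benchmark inputs.

Everything graded or tested against "known truth" in this package runs on
data generated here: a compendium of purified immune-cell libraries with
planted marker genes, side tables emulating cancer-cell-line and bulk-tumor
expression summaries, a gene-set compendium, external validation cohorts,
and a synthetic signature matrix with the published row/column bookkeeping
(170 genes, 10 cell types, containing both curated blacklists).

The generator's emissions emulate the structure of the real resources —
log-normal between-library variability, cell-specific markers with large
fold changes, housekeeping genes with cell-type-dependent mRNA content,
and a tumor profile disjoint from the immune markers — not their exact
gene content, which is not reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .signature import (
    CELL_TYPES,
    CURATED_BLACKLIST,
    TUMOR_BLACKLIST,
    LabeledCompendium,
    SignatureMatrix,
)

__all__ = [
    "FixtureBundle",
    "make_compendium",
    "make_synthetic_til10",
    "make_gene_sets",
    "make_ccle_summary",
    "make_tcga_summary",
    "make_alias_map",
    "make_fixtures",
    "default_scaling_factors",
]

TUMOR_LABEL = "Tumor"

MARKERS_PER_TYPE = 13
#: the reference compendium averages ~5 libraries per cell type (51 datasets,
#: 10 types); 4 keeps leave-one-out rebuilds meaningful (3 libraries remain)
LIBRARIES_PER_TYPE = 4
N_BACKGROUND = 400
N_HOUSEKEEPING = 20
N_TUMOR_MARKERS = 12

#: per-type mRNA content used to plant the PSMB2 housekeeping gene, scaled
#: around 50 TPM; myeloid cells carry more mRNA than granulocytes
MRNA_CONTENT = {
    "B.cells": 1.0,
    "Macrophages.M1": 1.4,
    "Macrophages.M2": 1.4,
    "Monocytes": 1.2,
    "Neutrophils": 0.4,
    "NK.cells": 1.0,
    "T.cells.CD4": 0.9,
    "T.cells.CD8": 0.9,
    "Tregs": 0.9,
    "Dendritic.cells": 1.3,
    TUMOR_LABEL: 2.0,
}

_TYPE_CODE = {
    "B.cells": "B",
    "Macrophages.M1": "M1",
    "Macrophages.M2": "M2",
    "Monocytes": "MO",
    "Neutrophils": "NE",
    "NK.cells": "NK",
    "T.cells.CD4": "C4",
    "T.cells.CD8": "C8",
    "Tregs": "TR",
    "Dendritic.cells": "DC",
}


def marker_names(cell_type: str, n: int = MARKERS_PER_TYPE) -> list[str]:
    code = _TYPE_CODE[cell_type]
    return [f"MK{code}{i:02d}" for i in range(1, n + 1)]


def planted_markers() -> dict[str, str]:
    """Ground-truth marker ownership planted in the compendium."""
    return {g: t for t in CELL_TYPES for g in marker_names(t)}


# ---------------------------------------------------------------------------
# compendium
# ---------------------------------------------------------------------------

def _library_noise(rng: np.random.Generator, base: np.ndarray, sigma: float) -> np.ndarray:
    return base * rng.lognormal(mean=0.0, sigma=sigma, size=base.shape)


def make_compendium(
    seed: int = 0,
    libraries_per_type: int = LIBRARIES_PER_TYPE,
    noise_sigma: float = 0.15,
    dataset_tag: str = "synthA",
) -> LabeledCompendium:
    """Synthetic TPM compendium: 10 immune types x 3 libraries + 1 tumor.

    Planted content, per gene class:

    * markers (13 per type): ~60-250 TPM in the owner type, ~0.1-0.6
      elsewhere (detected but low);
    * decoys: cell-specific genes that downstream filters must remove —
      ``DECOY_CCLE*`` (tumor cell-line expressed), ``DECOY_TCGA*`` (near
      absent in bulk tumors), ``DECOY_HI*`` (exceeding 700 TPM),
      ``DECOY_GS*`` (listed in another type's gene set);
    * PSMB2 and housekeeping genes: flat across types, PSMB2 scaled by the
      per-type mRNA content so that scaling factors can be derived from it;
    * tumor markers: expressed only in the tumor library;
    * background genes: shared log-normal baseline.

    Between-library variability is log-normal with ``noise_sigma``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    genes: list[str] = []
    base_by_type: dict[str, list[float]] = {t: [] for t in list(CELL_TYPES) + [TUMOR_LABEL]}

    def add_gene(name: str, levels: dict[str, float], default: float) -> None:
        genes.append(name)
        for t in base_by_type:
            base_by_type[t].append(levels.get(t, default))

    def specific_levels(owner: str, on: float) -> dict[str, float]:
        # off-type leakage differs between cell types, as in real data;
        # without that spread a 3-bin quantizer has no low/medium structure
        levels = {
            t: float(rng.lognormal(np.log(0.3), 1.0)) for t in base_by_type
        }
        levels[owner] = on
        return levels

    for cell_type in CELL_TYPES:
        for g in marker_names(cell_type):
            add_gene(g, specific_levels(cell_type, float(rng.uniform(60, 250))), 0.0)

    # decoys: specific in the compendium, removed by the side-table filters
    for i, cell_type in enumerate(CELL_TYPES[:4]):
        add_gene(f"DECOY_CCLE{i}", specific_levels(cell_type, 120.0), 0.0)
        add_gene(f"DECOY_TCGA{i}", specific_levels(cell_type, 90.0), 0.0)
        add_gene(f"DECOY_GS{i}", specific_levels(cell_type, 150.0), 0.0)
    for i, cell_type in enumerate(CELL_TYPES[4:8]):
        add_gene(f"DECOY_HI{i}", specific_levels(cell_type, 3000.0), 0.0)

    psmb2_levels = {t: 50.0 * MRNA_CONTENT[t] for t in base_by_type}
    add_gene("PSMB2", psmb2_levels, 50.0)
    for i in range(N_HOUSEKEEPING):
        add_gene(f"HK{i:03d}", {}, float(rng.uniform(20, 200)))
    for i in range(N_TUMOR_MARKERS):
        add_gene(f"TUM{i:02d}", {TUMOR_LABEL: float(rng.uniform(100, 400))}, 0.05)
    for i in range(N_BACKGROUND):
        add_gene(f"BG{i:03d}", {}, float(rng.lognormal(2.0, 1.2)))

    # rescale the background so each type's baseline sums to ~10^6: planted
    # marker levels then survive TPM renormalization roughly unchanged
    bg_idx = [k for k, g in enumerate(genes) if g.startswith("BG")]
    for t, base in base_by_type.items():
        arr = np.asarray(base)
        bg_mass = arr[bg_idx].sum()
        rest = arr.sum() - bg_mass
        scale = (1e6 - rest) / bg_mass
        for k in bg_idx:
            base[k] *= scale

    columns, labels, datasets = {}, {}, {}
    for cell_type in CELL_TYPES:
        base = np.array(base_by_type[cell_type])
        for k in range(libraries_per_type):
            lib = f"{_TYPE_CODE[cell_type]}_lib{k}"
            columns[lib] = _library_noise(rng, base, noise_sigma)
            labels[lib] = cell_type
            datasets[lib] = dataset_tag
    tumor_lib = "TUMOR_lib0"
    columns[tumor_lib] = _library_noise(
        rng, np.array(base_by_type[TUMOR_LABEL]), noise_sigma
    )
    labels[tumor_lib] = TUMOR_LABEL
    datasets[tumor_lib] = dataset_tag

    values = pd.DataFrame(columns, index=genes)
    values = values * (1e6 / values.sum(axis=0))
    return LabeledCompendium(values=values, labels=labels, datasets=datasets)


def type_profiles(compendium: LabeledCompendium) -> pd.DataFrame:
    """Median TPM profile per cell type (plus tumor) of a compendium.

    Profiles are renormalized to sum to 10^6 (medians of normalized
    libraries do not sum exactly), so linear mixtures of profiles are
    valid TPM columns themselves.
    """
    cols = {}
    for cell_type in list(CELL_TYPES) + [TUMOR_LABEL]:
        libs = compendium.libraries_of(cell_type)
        if libs:
            med = compendium.values[libs].median(axis=1)
            cols[cell_type] = med * (1e6 / med.sum())
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# side tables for the external filters
# ---------------------------------------------------------------------------

def make_ccle_summary(seed: int = 0, n_lines: int = 5) -> pd.DataFrame:
    """Per-gene median log2 expression across synthetic cancer cell lines.

    Immune markers are low (< 7) in the lines; ``DECOY_CCLE*`` genes exceed
    7 in every line, which the tumor-expression filter must catch.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCC1E]))
    compendium = make_compendium(seed)
    genes = compendium.values.index
    lines = [f"line{i}" for i in range(n_lines)]
    table = pd.DataFrame(
        rng.uniform(0.0, 5.0, size=(len(genes), n_lines)), index=genes, columns=lines
    )
    decoys = [g for g in genes if g.startswith("DECOY_CCLE")]
    table.loc[decoys] = rng.uniform(8.0, 12.0, size=(len(decoys), n_lines))
    return table


def make_tcga_summary(seed: int = 0) -> pd.Series:
    """Per-gene mean TPM across synthetic bulk tumors.

    All genes provide deconvolution support (>= 1 TPM) except the
    ``DECOY_TCGA*`` genes, planted below 1 TPM.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7C6A]))
    compendium = make_compendium(seed)
    genes = compendium.values.index
    means = pd.Series(rng.uniform(2.0, 60.0, size=len(genes)), index=genes)
    for g in genes:
        if g.startswith("DECOY_TCGA"):
            means[g] = rng.uniform(0.05, 0.5)
    return means


def make_gene_sets(seed: int = 0) -> list[tuple[str, str, list[str]]]:
    """Gene-set compendium tagged by cell type.

    Each type's set lists its own planted markers (harmless); a cross-type
    confuser set lists the ``DECOY_GS*`` genes under a different type, and
    a CD4-tagged set lists a Treg marker to exercise the CD4 exemption.
    """
    sets: list[tuple[str, str, list[str]]] = [
        (f"{t}_set", t, marker_names(t)) for t in CELL_TYPES
    ]
    confusers = [f"DECOY_GS{i}" for i in range(4)]
    sets.append(("nk_extra", "NK.cells", confusers))
    sets.append(("cd4_population", "T.cells.CD4", [marker_names("Tregs")[0]]))
    return sets


def make_alias_map(seed: int = 0) -> dict[str, str]:
    """Outdated-symbol aliases for the re-annotation step."""
    markers = planted_markers()
    some = sorted(markers)[:5]
    return {f"OLD_{g}": g for g in some}


def make_external_datasets(
    seed: int = 0, n_datasets: int = 2
) -> dict[str, LabeledCompendium]:
    """Independent labeled cohorts for the restricted-expression filter."""
    return {
        f"ext{k}": make_compendium(
            seed=seed + 1000 + k, noise_sigma=0.25, dataset_tag=f"ext{k}"
        )
        for k in range(n_datasets)
    }


# ---------------------------------------------------------------------------
# synthetic signature stand-in
# ---------------------------------------------------------------------------

def make_synthetic_til10(seed: int = 0) -> SignatureMatrix:
    """Synthetic 170-gene, 10-type signature with the published bookkeeping.

    This is a stand-in for the published signature matrix (which ships as a
    supplementary spreadsheet and is not bundled): 138 synthetic specific
    markers plus the 17 curated variable-expression genes and the 15
    additional tumor-associated genes, 170 rows in all.  Curated genes are
    planted with moderate, near-uniform expression across all cell types —
    the documented reason for their removal — so that dropping them yields
    a better-conditioned (lower condition number) matrix, as reported for
    the real signature.  All values are TPM-scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7110]))
    tumor_extra = [g for g in TUMOR_BLACKLIST if g not in CURATED_BLACKLIST]
    n_specific = 170 - len(CURATED_BLACKLIST) - len(tumor_extra)
    specific = [f"SIG{i:03d}" for i in range(1, n_specific + 1)]

    # the T-cell family shares much of its transcriptome: markers of one
    # member leak into the others, which is what makes Treg/CD4 separation
    # ill-conditioned in the real signature
    t_family = ("T.cells.CD4", "T.cells.CD8", "Tregs")
    rows, owners = {}, {}
    owner_cycle = list(CELL_TYPES)
    for i, gene in enumerate(specific + tumor_extra):
        owner = owner_cycle[i % len(owner_cycle)]
        on = rng.lognormal(np.log(80.0), 0.6)
        off = rng.lognormal(np.log(0.6), 0.8, size=len(CELL_TYPES))
        row = pd.Series(off, index=list(CELL_TYPES))
        row[owner] = on
        if owner in t_family:
            for relative in t_family:
                if relative != owner:
                    row[relative] = on * rng.uniform(0.25, 0.55)
        rows[gene] = row
        owners[gene] = owner
    for gene in CURATED_BLACKLIST:
        level = rng.uniform(30.0, 90.0)
        row = pd.Series(
            level * rng.lognormal(0.0, 0.35, size=len(CELL_TYPES)),
            index=list(CELL_TYPES),
        )
        rows[gene] = row
        owners[gene] = row.idxmax()
    values = pd.DataFrame(rows).T.loc[list(rows)]
    return SignatureMatrix(values=values, owners=owners)


@lru_cache(maxsize=1)
def _default_scaling() -> "ScalingFactors":
    from .deconvolution import ScalingFactors

    compendium = make_compendium(seed=0)
    factors = ScalingFactors.from_housekeeping(compendium, gene="PSMB2")
    immune = {c: v for c, v in factors.factors.items() if c in CELL_TYPES}
    # normalize so the median factor is 1 (factors are content ratios)
    med = float(np.median(list(immune.values())))
    return ScalingFactors({c: v / med for c, v in immune.items()})


def default_scaling_factors():
    """Default per-type mRNA scaling factors.

    Derived once, deterministically, as the median PSMB2 expression per
    cell type of the bundled synthetic compendium, normalized to median 1.
    Supply your own :class:`~quantiseq.deconvolution.ScalingFactors` for
    real data.
    """
    return _default_scaling()


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Everything needed to run the pipeline end to end on synthetic data."""

    compendium: LabeledCompendium
    profiles: pd.DataFrame
    signature: SignatureMatrix
    ccle_summary: pd.DataFrame
    tcga_summary: pd.Series
    gene_sets: list[tuple[str, str, list[str]]]
    alias_map: dict[str, str]
    external: dict[str, LabeledCompendium]
    markers: dict[str, str] = field(default_factory=planted_markers)


def make_fixtures(seed: int = 0) -> FixtureBundle:
    """Deterministic bundle of all synthetic inputs for one seed."""
    compendium = make_compendium(seed)
    return FixtureBundle(
        compendium=compendium,
        profiles=type_profiles(compendium),
        signature=make_synthetic_til10(seed),
        ccle_summary=make_ccle_summary(seed),
        tcga_summary=make_tcga_summary(seed),
        gene_sets=make_gene_sets(seed),
        alias_map=make_alias_map(seed),
        external=make_external_datasets(seed),
    )
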