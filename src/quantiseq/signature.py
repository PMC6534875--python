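"""Construction and curation of cell-type signature matrices.

A signature matrix holds median TPM-normalized expression profiles of marker
genes for ten immune cell types.  Marker genes are selected from a labeled
compendium of purified-cell libraries through a chain of filters: detection,
quantized cell-specific expression, absence in tumors, cross-type gene-set
specificity, bounded expression range, correlation with true mixture
fractions, and restricted expression in external cohorts.  Curated
blacklists shrink the matrix for RNA-seq (default) and tumor input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CELL_TYPES",
    "CURATED_BLACKLIST",
    "TUMOR_BLACKLIST",
    "LabeledCompendium",
    "SignatureMatrix",
    "FilterReport",
    "quantize_expression",
    "select_cell_specific_genes",
    "filter_tumor_expression",
    "filter_specificity",
    "filter_range",
    "filter_fraction_correlation",
    "filter_restricted_expression",
    "build_signature_profiles",
    "build_signature",
    "apply_gene_blacklists",
    "condition_number",
    "read_signature_matrix",
    "read_gene_list",
]

#: canonical cell-type column order of the TIL10-style signature
CELL_TYPES = (
    "B.cells",
    "Macrophages.M1",
    "Macrophages.M2",
    "Monocytes",
    "Neutrophils",
    "NK.cells",
    "T.cells.CD4",
    "T.cells.CD8",
    "Tregs",
    "Dendritic.cells",
)

#: curated genes with variable expression, dropped by default for RNA-seq
CURATED_BLACKLIST = (
    "CD36", "CSTA", "NRGN", "C5AR2", "CEP19", "CYP4F3", "DOCK5", "HAL",
    "LRRK2", "LY96", "NINJ2", "PPP1R3B", "TECPR2", "TLR1", "TLR4",
    "TMEM154", "CD248",
)

#: genes over-expressed in bulk tumors, additionally dropped in tumor mode
TUMOR_BLACKLIST = (
    "NUPR1", "CD36", "CSTA", "HPGD", "CFB", "ECM1", "FCGBP", "PLTP",
    "FXYD6", "HOPX", "SERPING1", "ENPP2", "GATM", "PDPN", "ADAM6",
    "FCRLA", "SLC1A3",
)

#: default marker-selection thresholds
MAX_RANGE_TPM = 700.0          # genes exceeding this in any library are dropped
MIN_FRACTION_CORR = 0.6        # Pearson r with true fractions
MIN_RESTRICTED_RATIO = 2.0     # median over datasets of in/out expression ratio
MIN_TREG_VS_CD4_RATIO = 1.0    # extra Treg-vs-CD4 restricted-expression pass
TOP_RANKED_PER_TYPE = 30
MIN_DETECTED_LIBRARIES = 2


@dataclass
class LabeledCompendium:
    """TPM-normalized expression of purified libraries with cell-type labels.

    ``labels`` maps library id -> cell type (one of :data:`CELL_TYPES` or
    ``"Tumor"``); ``datasets`` optionally maps library id -> study of origin.
    """

    values: pd.DataFrame
    labels: dict[str, str]
    datasets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.labels)
        if missing:
            raise ValueError(f"libraries without a cell-type label: {sorted(missing)}")

    def libraries_of(self, cell_type: str) -> list[str]:
        return [l for l in self.values.columns if self.labels[l] == cell_type]

    @property
    def immune_libraries(self) -> list[str]:
        return [l for l in self.values.columns if self.labels[l] in CELL_TYPES]


@dataclass
class SignatureMatrix:
    """Signature genes x cell types, median TPM profiles with marker owners."""

    values: pd.DataFrame
    owners: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "GENE"
        out.to_csv(path, sep="\t")


@dataclass
class FilterReport:
    """Per-gene trace of the marker-selection pipeline."""

    candidates: dict[str, str]                    # gene -> owner at entry
    flags: pd.DataFrame                           # gene x criterion booleans
    restricted_ratios: pd.DataFrame | None = None # gene x dataset R_gd
    fraction_corr: pd.Series | None = None        # gene -> r with owner fraction

    def selected(self) -> list[str]:
        return list(self.flags.index[self.flags.all(axis=1)])


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    owners = dict(values.idxmax(axis=1)) if values.shape[1] else {}
    return SignatureMatrix(values=values.astype(float), owners=owners)


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    lines = Path(path).read_text().split()
    return tuple(dict.fromkeys(lines))


# ---------------------------------------------------------------------------
# quantization and cell-specific selection
# ---------------------------------------------------------------------------

def _best_two_thresholds(sorted_vals: np.ndarray) -> tuple[int, int]:
    """Exhaustive split of a sorted vector into 3 bins minimizing within-bin SSE.

    Returns (i, j): bins are [0:i), [i:j), [j:n).  Ties take the first
    (lexicographically smallest) split, which keeps the result deterministic.
    """
    n = len(sorted_vals)
    c1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    c2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def sse(a: int, b: int) -> float:  # segment [a:b)
        if b <= a:
            return 0.0
        s = c1[b] - c1[a]
        q = c2[b] - c2[a]
        return q - s * s / (b - a)

    best = (np.inf, 1, 2)
    for i in range(1, n - 1):
        left = sse(0, i)
        for j in range(i + 1, n):
            total = left + sse(i, j) + sse(j, n)
            if total < best[0] - 1e-12:
                best = (total, i, j)
    return best[1], best[2]


def quantize_expression(compendium: LabeledCompendium) -> pd.DataFrame:
    """Assign each (gene, library) a bin in {0: low, 1: medium, 2: high}.

    Per gene, expression is taken on log2(x+1) scale and the two bin
    thresholds are found by exhaustive within-bin-variance minimization.
    Bins are monotone in expression by construction; genes with (near-)
    constant expression across libraries are all "low".
    """
    log_vals = np.log2(compendium.values.to_numpy(dtype=float) + 1.0)
    n_genes, n_libs = log_vals.shape
    bins = np.zeros((n_genes, n_libs), dtype=np.int8)
    for g in range(n_genes):
        row = log_vals[g]
        if np.ptp(row) < 1e-12 or n_libs < 3:
            continue
        order = np.argsort(row, kind="mergesort")
        i, j = _best_two_thresholds(row[order])
        ranks = np.empty(n_libs, dtype=np.int64)
        ranks[order] = np.arange(n_libs)
        gene_bins = np.where(ranks < i, 0, np.where(ranks < j, 1, 2))
        # equal values must share a bin: push ties up to the higher bin
        for level in (2, 1):
            members = row[gene_bins == level]
            if members.size:
                gene_bins[row >= members.min()] = np.maximum(
                    gene_bins[row >= members.min()], level
                )
        bins[g] = gene_bins
    return pd.DataFrame(bins, index=compendium.values.index,
                        columns=compendium.values.columns)


def _detection_prefilter(compendium: LabeledCompendium) -> pd.Index:
    detected = (compendium.values[compendium.immune_libraries] > 0).sum(axis=1)
    return compendium.values.index[detected >= MIN_DETECTED_LIBRARIES]


def select_cell_specific_genes(
    bins: pd.DataFrame, compendium: LabeledCompendium
) -> dict[str, str]:
    """Candidate markers: high in every library of one type, low/medium elsewhere.

    Returns gene -> owner cell type.  The two-sided requirement makes
    ownership unique by construction (a gene high in all libraries of two
    types violates the "low or medium in all other libraries" clause for
    both), which is asserted.
    """
    keep = _detection_prefilter(compendium)
    bins = bins.loc[bins.index.intersection(keep)]
    owners: dict[str, str] = {}
    arr = bins.to_numpy()
    cols = list(bins.columns)
    for cell_type in CELL_TYPES:
        in_idx = [cols.index(l) for l in compendium.libraries_of(cell_type)]
        if not in_idx:
            continue
        out_idx = [k for k in range(len(cols)) if k not in in_idx]
        mask = (arr[:, in_idx] == 2).all(axis=1)
        if out_idx:
            mask &= (arr[:, out_idx] <= 1).all(axis=1)
        for gene in bins.index[mask]:
            assert gene not in owners, f"gene {gene} owned by two cell types"
            owners[gene] = cell_type
    return owners


# ---------------------------------------------------------------------------
# external filters
# ---------------------------------------------------------------------------

def filter_tumor_expression(
    genes: dict[str, str],
    ccle_summary: pd.DataFrame | None = None,
    tcga_summary: pd.Series | None = None,
) -> dict[str, str]:
    """Drop genes expressed in tumors or useless for bulk deconvolution.

    ``ccle_summary``: per-gene, per-cell-line median log2 expression; a gene
    is dropped when it exceeds 7 in *all* provided cancer lines.
    ``tcga_summary``: per-gene mean TPM over bulk tumors; a gene is dropped
    when its mean is below 1 TPM.  Genes missing from a summary are retained
    with a warning.
    """
    out = dict(genes)
    missing: list[str] = []
    if ccle_summary is not None:
        for gene in list(out):
            if gene not in ccle_summary.index:
                missing.append(gene)
                continue
            if (ccle_summary.loc[gene] > 7.0).all():
                del out[gene]
    if tcga_summary is not None:
        for gene in list(out):
            if gene not in tcga_summary.index:
                missing.append(gene)
                continue
            if tcga_summary.loc[gene] < 1.0:
                del out[gene]
    if missing:
        warnings.warn(
            f"{len(set(missing))} candidate gene(s) absent from tumor summaries; retained"
        )
    return out


def filter_specificity(
    genes: dict[str, str], gene_sets: list[tuple[str, str, list[str]]]
) -> dict[str, str]:
    """Drop genes listed in a gene set specific for another cell type.

    ``gene_sets`` entries are (set name, cell-type tag, member genes).
    Sets tagged for CD4 T cells are not used against Treg candidates, since
    bona fide Treg markers (e.g. FOXP3) appear in CD4 population sets.
    """
    out = dict(genes)
    for _name, tag, members in gene_sets:
        member_set = set(members)
        for gene in list(out):
            owner = out.get(gene)
            if owner is None or tag == owner:
                continue
            if owner == "Tregs" and tag == "T.cells.CD4":
                continue
            if gene in member_set:
                del out[gene]
    return out


def filter_range(genes: dict[str, str], compendium: LabeledCompendium) -> dict[str, str]:
    """Drop genes whose expression strictly exceeds 700 TPM in any library."""
    peaks = compendium.values.max(axis=1)
    return {g: c for g, c in genes.items()
            if g not in peaks.index or peaks[g] <= MAX_RANGE_TPM}


def filter_fraction_correlation(
    genes: dict[str, str],
    mixtures: pd.DataFrame,
    true_fractions: pd.DataFrame,
) -> tuple[dict[str, str], pd.Series]:
    """Keep genes whose expression correlates (r >= 0.6) with the owner fraction.

    ``mixtures``: genes x simulated mixtures; ``true_fractions``: mixtures x
    cell types.  Genes with zero expression variance across mixtures are
    removed with a warning.
    """
    out: dict[str, str] = {}
    corr = {}
    degenerate = 0
    for gene, owner in genes.items():
        if gene not in mixtures.index or owner not in true_fractions.columns:
            continue
        x = mixtures.loc[gene].to_numpy(dtype=float)
        y = true_fractions[owner].to_numpy(dtype=float)
        if np.ptp(x) < 1e-12:
            degenerate += 1
            continue
        r = stats.pearsonr(x, y).statistic
        corr[gene] = r
        if r >= MIN_FRACTION_CORR:
            out[gene] = owner
    if degenerate:
        warnings.warn(f"{degenerate} candidate gene(s) constant across mixtures; removed")
    return out, pd.Series(corr, dtype=float)


def _restricted_ratio(
    values: pd.DataFrame, in_libs: list[str], out_libs: list[str], gene: str
) -> float:
    num = float(values.loc[gene, in_libs].median())
    den = float(values.loc[gene, out_libs].median()) if out_libs else 0.0
    if den <= 0:
        return np.inf
    return num / den


def filter_restricted_expression(
    genes: dict[str, str],
    external: dict[str, LabeledCompendium],
    treg_vs_cd4: dict[str, LabeledCompendium] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Rank candidates by restricted expression in external cohorts.

    For each external dataset d the ratio R_gd = median(in-type) /
    median(out-of-type) is computed; per cell type the top 30 genes ranked
    by median_d(R_gd), among those with a median >= 2, survive.  For Treg
    candidates, CD4 libraries are excluded from the out-group, and an extra
    Treg-vs-CD4 pass (threshold 1) runs on ``treg_vs_cd4`` datasets.
    A zero out-group median makes the ratio +infinity.  Ties at the top-30
    boundary break by gene symbol for determinism.
    """
    ratio_rows: dict[str, dict[str, float]] = {g: {} for g in genes}
    for name, data in external.items():
        for gene, owner in genes.items():
            if gene not in data.values.index:
                continue
            in_libs = data.libraries_of(owner)
            if not in_libs:
                continue
            out_libs = [l for l in data.values.columns if data.labels[l] != owner]
            if owner == "Tregs":
                out_libs = [l for l in out_libs if data.labels[l] != "T.cells.CD4"]
            ratio_rows[gene][name] = _restricted_ratio(data.values, in_libs, out_libs, gene)
    ratios = pd.DataFrame.from_dict(ratio_rows, orient="index")
    med = ratios.median(axis=1, skipna=True)

    out: dict[str, str] = {}
    for cell_type in CELL_TYPES:
        members = sorted(g for g, c in genes.items() if c == cell_type)
        scored = [(g, med.get(g, np.nan)) for g in members]
        passed = [(g, r) for g, r in scored if np.isfinite(r) or r == np.inf]
        passed = [(g, r) for g, r in passed if r >= MIN_RESTRICTED_RATIO]
        # sort by descending ratio, then symbol, keep the top 30
        passed.sort(key=lambda t: (-t[1], t[0]))
        for g, _r in passed[:TOP_RANKED_PER_TYPE]:
            out[g] = cell_type

    if treg_vs_cd4:
        for gene in [g for g, c in out.items() if c == "Tregs"]:
            per_dataset = []
            for data in treg_vs_cd4.values():
                if gene not in data.values.index:
                    continue
                in_libs = data.libraries_of("Tregs")
                cd4_libs = data.libraries_of("T.cells.CD4")
                if in_libs and cd4_libs:
                    per_dataset.append(
                        _restricted_ratio(data.values, in_libs, cd4_libs, gene)
                    )
            if per_dataset and np.median(per_dataset) < MIN_TREG_VS_CD4_RATIO:
                del out[gene]
    return out, ratios


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_signature_profiles(
    compendium: LabeledCompendium, genes: dict[str, str]
) -> SignatureMatrix:
    """Median expression per (selected gene, cell type) over that type's libraries."""
    present = [t for t in CELL_TYPES if compendium.libraries_of(t)]
    gene_order = sorted(genes)
    profiles = pd.DataFrame(index=gene_order, columns=present, dtype=float)
    for cell_type in present:
        libs = compendium.libraries_of(cell_type)
        profiles[cell_type] = compendium.values.loc[gene_order, libs].median(axis=1)
    return SignatureMatrix(values=profiles, owners={g: genes[g] for g in gene_order})


def build_signature(
    compendium: LabeledCompendium,
    *,
    ccle_summary: pd.DataFrame | None = None,
    tcga_summary: pd.Series | None = None,
    gene_sets: list[tuple[str, str, list[str]]] | None = None,
    mixtures: pd.DataFrame | None = None,
    true_fractions: pd.DataFrame | None = None,
    external: dict[str, LabeledCompendium] | None = None,
    treg_vs_cd4: dict[str, LabeledCompendium] | None = None,
) -> tuple[SignatureMatrix, FilterReport]:
    """Run the full marker-selection chain and assemble median profiles.

    Filters whose side data is not supplied are skipped, which is what the
    leave-K-out validation design uses (only the compendium-intrinsic
    filters vary with the left-out libraries).
    """
    bins = quantize_expression(compendium)
    candidates = select_cell_specific_genes(bins, compendium)
    flags = pd.DataFrame(index=sorted(candidates), dtype=bool)

    genes = dict(candidates)

    def record(name: str, survivors: dict[str, str]) -> None:
        flags[name] = [g in survivors for g in flags.index]

    if ccle_summary is not None or tcga_summary is not None:
        genes = filter_tumor_expression(genes, ccle_summary, tcga_summary)
        record("tumor_expression", genes)
    if gene_sets is not None:
        genes = filter_specificity(genes, gene_sets)
        record("specificity", genes)
    genes = filter_range(genes, compendium)
    record("range", genes)
    fraction_corr = None
    if mixtures is not None and true_fractions is not None:
        genes, fraction_corr = filter_fraction_correlation(genes, mixtures, true_fractions)
        record("fraction_correlation", genes)
    ratios = None
    if external:
        genes, ratios = filter_restricted_expression(genes, external, treg_vs_cd4)
        record("restricted_expression", genes)

    signature = build_signature_profiles(compendium, genes)
    report = FilterReport(
        candidates=candidates,
        flags=flags,
        restricted_ratios=ratios,
        fraction_corr=fraction_corr,
    )
    return signature, report


def apply_gene_blacklists(
    signature: SignatureMatrix,
    rmgenes: str | Path | None = "default",
    tumor: bool = False,
) -> SignatureMatrix:
    """Remove curated and/or tumor-associated genes from a signature.

    ``rmgenes``: ``"default"`` removes the curated variable-expression list,
    ``"none"``/``None`` leaves the matrix unchanged, any other value is read
    as a path to a one-symbol-per-line file.  ``tumor=True`` additionally
    removes the tumor-associated list.  Absent genes are silently skipped.
    """
    drop: set[str] = set()
    if rmgenes == "default":
        drop |= set(CURATED_BLACKLIST)
    elif rmgenes in (None, "none"):
        pass
    else:
        drop |= set(read_gene_list(rmgenes))
    if tumor:
        drop |= set(TUMOR_BLACKLIST)
    keep = [g for g in signature.values.index if g not in drop]
    return SignatureMatrix(
        values=signature.values.loc[keep],
        owners={g: c for g, c in signature.owners.items() if g in keep},
    )


def condition_number(signature: SignatureMatrix) -> float:
    """Ratio of extreme singular values of the linear-scale signature.

    Lower values indicate a better-posed deconvolution; rank-deficient
    matrices report +infinity with a warning.
    """
    arr = signature.values.to_numpy(dtype=float)
    if arr.shape[0] < arr.shape[1]:
        raise ValueError("signature needs at least as many genes as cell types")
    s = np.linalg.svd(arr, compute_uv=False)
    if s[-1] <= s[0] * np.finfo(float).eps * max(arr.shape):
        warnings.warn("rank-deficient signature matrix; condition number infinite")
        return np.inf
    return float(s[0] / s[-1])
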