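"""Reading, annotation and normalization of bulk expression matrices.

Expression values are handled as genes x samples tables.  RNA-seq input is
expected as TPM (or any within-sample abundance that can be rescaled to TPM);
microarray input is unlogged when necessary, quantile-normalized, collapsed
from probes to gene symbols, and then put on the same TPM-like scale so that
a single deconvolution code path serves both platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_alias_map",
    "read_expression_matrix",
    "reannotate_and_collapse",
    "renormalize_tpm",
    "quantile_normalize",
    "collapse_probes",
    "prepare_microarray",
]

#: scale to which every sample column is renormalized (transcripts per million)
TPM_SCALE = 1e6

#: microarray intensities on a linear scale always exceed this; a matrix whose
#: maximum is below it is assumed to be log2-transformed
LOG2_DETECTION_MAX = 50.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with platform/scale bookkeeping.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, index = gene (or probe) identifiers,
        columns = sample labels.
    platform : str
        ``"rnaseq"`` or ``"microarray"``.
    scale : str
        ``"linear"`` or ``"log2-suspected"`` (microarray heuristics only).
    """

    values: pd.DataFrame
    platform: str = "rnaseq"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.platform not in ("rnaseq", "microarray"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.scale not in ("linear", "log2-suspected"):
            raise ValueError(f"unknown scale tag {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path, gene_col: str = "GENE") -> None:
        out = self.values.copy()
        out.index.name = gene_col
        out.to_csv(path, sep="\t")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping old gene symbols to approved symbols."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"alias map {path} must have two tab-separated columns")
    table = table.dropna()
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def read_expression_matrix(path: str | Path, platform: str = "rnaseq") -> ExpressionMatrix:
    """Parse a TSV expression matrix (first column gene symbols, header samples).

    Microarray matrices whose maximum value is below ``LOG2_DETECTION_MAX``
    are tagged as log2-scale so that :func:`prepare_microarray` unlogs them.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index.name = None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() | raw.isna()
    if bad.any().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise ValueError(f"{path}: non-numeric value for gene {g!r} in sample {s!r}")
    values = numeric.astype(float)
    values.index = values.index.astype(str)
    scale = "linear"
    if platform == "microarray" and float(values.to_numpy().max()) < LOG2_DETECTION_MAX:
        scale = "log2-suspected"
    return ExpressionMatrix(values=values, platform=platform, scale=scale)


def reannotate_and_collapse(
    matrix: ExpressionMatrix, aliases: dict[str, str] | None = None
) -> ExpressionMatrix:
    """Map symbols through an alias table and median-collapse duplicates.

    Symbols absent from the alias map pass through unchanged.  Rows that end
    up sharing a symbol are replaced by their per-sample median (midpoint
    convention for even counts, i.e. the ordinary median).
    """
    values = matrix.values
    if aliases:
        values = values.rename(index=lambda g: aliases.get(g, g))
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).median()
    return replace(matrix, values=values)


def renormalize_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so expression sums to 10^6 (TPM convention).

    Idempotent; raises for any all-zero sample column (naming the sample).
    """
    values = matrix.values
    if (values.to_numpy() < 0).any():
        raise ValueError("negative expression values; unlog the data first")
    sums = values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero expression: {list(zero.index)}")
    return replace(matrix, values=values * (TPM_SCALE / sums), scale="linear")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map each sample's order statistics onto the mean sorted profile.

    The reference distribution is the across-sample mean of the sorted
    columns; tied values within a sample receive the average of the
    reference values they span, so within-sample rank order is preserved.
    """
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values across ties
        series = pd.Series(ranked).groupby(pd.Series(col)).transform("mean")
        out[:, j] = series.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(values: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    """Keep, per gene symbol, the probe with the highest mean across samples."""
    missing = sorted(set(probe_map) - set(values.index))
    if missing:
        warnings.warn(f"probe map names {len(missing)} absent probe(s); ignored")
    mapped = values.loc[[p for p in values.index if p in probe_map]].copy()
    symbols = pd.Series({p: probe_map[p] for p in mapped.index})
    means = mapped.mean(axis=1)
    keep = means.groupby(symbols).idxmax()
    collapsed = mapped.loc[keep.to_numpy()]
    collapsed.index = keep.index.astype(str)
    unmapped = values.loc[[p for p in values.index if p not in probe_map]]
    return pd.concat([collapsed, unmapped]).sort_index()


def prepare_microarray(
    matrix: ExpressionMatrix, probe_map: dict[str, str] | None = None
) -> ExpressionMatrix:
    """Unlog (if needed), quantile-normalize, collapse probes, renormalize.

    Produces a linear, TPM-like matrix directly comparable with RNA-seq
    input to the deconvolution stage.
    """
    if matrix.platform != "microarray":
        raise ValueError("prepare_microarray expects a microarray matrix")
    values = matrix.values
    if matrix.scale == "log2-suspected":
        values = np.power(2.0, values)
    values = quantile_normalize(values)
    if probe_map:
        values = collapse_probes(values, probe_map)
    prepared = ExpressionMatrix(values=values, platform="microarray", scale="linear")
    return renormalize_tpm(prepared)
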