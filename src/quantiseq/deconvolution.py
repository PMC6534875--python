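"""Constrained least-squares deconvolution of immune cell fractions.

Each bulk sample m is modeled as m = S F over the signature genes shared by
mixture and signature (G*), with F >= 0 and sum(F) <= 1.  The slack of the
sum constraint is reported as the "Other" (uncharacterized, e.g. tumor)
fraction.  Two post-regression corrections follow the method: a heuristic
re-fit for regulatory T cells, whose signature is nearly collinear with
non-regulatory CD4 T cells, and a rescaling of the fractions by per-type
mRNA content so that estimates represent cell fractions rather than mRNA
fractions.

The module exposes both a functional surface (:func:`deconvolute`) and a
statsmodels-style model object (:class:`DeconvolutionModel`) whose
:meth:`~DeconvolutionModel.fit` returns a :class:`DeconvolutionResults`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .io import ExpressionMatrix, prepare_microarray, reannotate_and_collapse, renormalize_tpm
from .signature import SignatureMatrix, apply_gene_blacklists

__all__ = [
    "OTHER_LABEL",
    "TREG_REFIT_THRESHOLD",
    "ScalingFactors",
    "FractionTable",
    "DensityTable",
    "solve_constrained_lsq",
    "apply_treg_heuristic",
    "normalize_mrna_content",
    "estimate_other_fraction",
    "deconvolute",
    "scale_to_densities",
    "DeconvolutionModel",
    "DeconvolutionResults",
]

OTHER_LABEL = "Other"

#: below this raw Treg fraction the CD4-free re-fit is triggered
TREG_REFIT_THRESHOLD = 0.02

#: fewer shared signature genes than this is an error, under 80% a warning
MIN_SHARED_GENES = 10
WARN_SHARED_FRACTION = 0.8

_SUM_TOL = 1e-9


@dataclass
class ScalingFactors:
    """Per-cell-type mRNA content proxies n_c (all positive).

    The reference recipe derives them as the median expression of the PSMB2
    housekeeping gene across each cell type's libraries.
    """

    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = {c: v for c, v in self.factors.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive mRNA scaling factors: {bad}")

    def vector(self, cell_types: list[str]) -> np.ndarray:
        missing = [c for c in cell_types if c not in self.factors]
        if missing:
            raise KeyError(f"no mRNA scaling factor for {missing}")
        return np.array([self.factors[c] for c in cell_types], dtype=float)

    @classmethod
    def unit(cls, cell_types: list[str]) -> "ScalingFactors":
        return cls({c: 1.0 for c in cell_types})

    @classmethod
    def from_housekeeping(
        cls, compendium, gene: str = "PSMB2"
    ) -> "ScalingFactors":
        """Median housekeeping-gene expression per cell type of a compendium."""
        factors = {}
        for cell_type in set(compendium.labels.values()):
            libs = compendium.libraries_of(cell_type)
            if libs and gene in compendium.values.index:
                factors[cell_type] = float(compendium.values.loc[gene, libs].median())
        return cls({c: v for c, v in factors.items() if v > 0})


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _simplex_face_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact minimizer of ||Ax-b||^2 s.t. x >= 0, sum(x) = 1.

    Enumerates the faces of the simplex (subsets of coordinates clamped to
    zero); on each face the equality-constrained minimizer solves a KKT
    system, and the best feasible one is the global optimum of the convex
    program.  Exact and deterministic for the small cell-type counts used
    here (C <= ~12).
    """
    n = A.shape[1]
    AtA = A.T @ A
    Atb = A.T @ b
    best_x, best_obj = None, np.inf
    for size in range(1, n + 1):
        for free in itertools.combinations(range(n), size):
            idx = list(free)
            k = len(idx)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = AtA[np.ix_(idx, idx)]
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.concatenate([Atb[idx], [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            x_free = sol[:k]
            if (x_free < -1e-10).any():
                continue
            x = np.zeros(n)
            x[idx] = np.clip(x_free, 0.0, None)
            obj = float(np.sum((A @ x - b) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_x = obj, x
    assert best_x is not None
    return best_x


def solve_constrained_lsq(S: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Minimize ||S F - m||^2 subject to F >= 0 and sum(F) <= 1.

    The non-negative solution (scipy NNLS) is optimal whenever its sum does
    not exceed 1 (the sum constraint is then inactive); otherwise the
    optimum lies on the sum(F)=1 face and is found exactly by face
    enumeration.  Deterministic, no random initialization.
    """
    S = np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    if S.shape[0] != m.shape[0]:
        raise ValueError("signature and mixture gene dimensions differ")
    if not np.all(m >= 0):
        raise ValueError("mixture column contains negative values")
    F, _ = scipy.optimize.nnls(S, m)
    if F.sum() <= 1.0 + _SUM_TOL:
        return F
    return _simplex_face_solve(S, m)


# ---------------------------------------------------------------------------
# post-regression corrections
# ---------------------------------------------------------------------------

def apply_treg_heuristic(
    S: pd.DataFrame,
    m: np.ndarray,
    fractions: pd.Series,
    cd4_label: str = "T.cells.CD4",
    treg_label: str = "Tregs",
) -> pd.Series:
    """Counteract regulatory-T-cell dropout caused by CD4 collinearity.

    If the raw Treg fraction is below :data:`TREG_REFIT_THRESHOLD`, the
    system is re-solved without the CD4 column; the final Treg fraction is
    the mean of the two fits and CD4 is reduced by it (floored at 0).  The
    adjusted fractions are then rescaled so their sum matches the
    pre-adjustment total, keeping the absolute-fraction semantics intact.
    """
    if cd4_label not in S.columns or treg_label not in S.columns:
        warnings.warn("CD4/Treg columns missing; Treg heuristic skipped")
        return fractions
    f1_reg = float(fractions[treg_label])
    if f1_reg >= TREG_REFIT_THRESHOLD:
        return fractions
    reduced = S.drop(columns=[cd4_label])
    refit = solve_constrained_lsq(reduced.to_numpy(), m)
    f2_reg = float(refit[list(reduced.columns).index(treg_label)])
    f_reg = (f1_reg + f2_reg) / 2.0
    f_cd4 = max(float(fractions[cd4_label]) - f_reg, 0.0)
    adjusted = fractions.copy()
    adjusted[treg_label] = f_reg
    adjusted[cd4_label] = f_cd4
    total_before = float(fractions.sum())
    total_after = float(adjusted.sum())
    if total_after > 0:
        adjusted *= total_before / total_after
    return adjusted


def normalize_mrna_content(fractions: pd.Series, factors: ScalingFactors) -> pd.Series:
    """Convert mRNA fractions to cell fractions via per-type mRNA content.

    F'_c = F_c / n_c, then F''_c = F'_c * f / f' with f = sum(F) and
    f' = sum(F'), so the total immune fraction is preserved.
    """
    n = factors.vector(list(fractions.index))
    f_prime = fractions.to_numpy() / n
    f = float(fractions.sum())
    fp = float(f_prime.sum())
    if fp <= 0:
        return pd.Series(0.0, index=fractions.index)
    return pd.Series(f_prime * (f / fp), index=fractions.index)


def estimate_other_fraction(fractions: pd.Series) -> float:
    """Uncharacterized-cell fraction: the slack 1 - sum(F''), clipped at 0."""
    return max(1.0 - float(fractions.sum()), 0.0)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

@dataclass
class FractionTable:
    """Samples x (cell types + Other) absolute fractions, with raw audit trail."""

    fractions: pd.DataFrame                 # corrected F'' plus Other column
    raw: pd.DataFrame | None = None         # F straight from the regression

    def __post_init__(self) -> None:
        if OTHER_LABEL not in self.fractions.columns:
            raise ValueError("fraction table lacks an Other column")
        arr = self.fractions.to_numpy()
        if (arr < -1e-9).any():
            raise ValueError("negative fractions")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("fractions and Other must sum to 1 per sample")

    @property
    def cell_types(self) -> list[str]:
        return [c for c in self.fractions.columns if c != OTHER_LABEL]

    def to_tsv(self, path: str | Path) -> None:
        out = self.fractions.copy()
        out.index.name = "Sample"
        out.to_csv(path, sep="\t")


@dataclass
class DensityTable:
    """Cell densities (cells/mm^2) = fractions x per-sample total density."""

    densities: pd.DataFrame
    total_density: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.densities.copy()
        out.index.name = "Sample"
        out.to_csv(path, sep="\t")


def scale_to_densities(table: FractionTable, total_cells: pd.Series) -> DensityTable:
    """Multiply fractions by per-sample total cell density (cells/mm^2).

    Samples without a density are excluded with a warning.
    """
    if (total_cells < 0).any():
        raise ValueError("total cell densities must be non-negative")
    shared = [s for s in table.fractions.index if s in total_cells.index]
    missing = [s for s in table.fractions.index if s not in total_cells.index]
    if missing:
        warnings.warn(f"no total density for sample(s) {missing}; excluded")
    dens = table.fractions.loc[shared].mul(total_cells.loc[shared], axis=0)
    return DensityTable(densities=dens, total_density=total_cells.loc[shared])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DeconvolutionModel:
    """Constrained least-squares mixture model M = S F for bulk samples.

    Parameters
    ----------
    mixture : ExpressionMatrix or pandas.DataFrame
        Bulk expression, genes x samples.  Prepared according to platform
        (gene re-annotation, TPM renormalization; quantile normalization
        first when ``arrays=True``).
    signature : SignatureMatrix
        Reference profiles, signature genes x cell types.
    tumor : bool
        Drop tumor-associated signature genes before fitting.
    arrays : bool
        Treat the mixture as microarray data (quantile-normalize; the
        full signature is kept by default for arrays).
    rmgenes : str or None
        ``"default"``, ``"none"`` or a path to a custom blacklist; when
        left as ``"auto"`` the platform default applies (default list for
        RNA-seq, none for arrays).
    mrna_scale : bool
        Apply mRNA-content correction (disable when true fractions are
        mRNA fractions, as in read-level simulations).
    scaling : ScalingFactors, optional
        Per-type mRNA content; defaults to the bundled synthetic-compendium
        housekeeping profile when scaling is enabled.
    """

    def __init__(
        self,
        mixture: ExpressionMatrix | pd.DataFrame,
        signature: SignatureMatrix,
        *,
        tumor: bool = False,
        arrays: bool = False,
        rmgenes: str | None = "auto",
        mrna_scale: bool = True,
        scaling: ScalingFactors | None = None,
        aliases: dict[str, str] | None = None,
        prepare: bool = True,
    ) -> None:
        if isinstance(mixture, pd.DataFrame):
            mixture = ExpressionMatrix(
                values=mixture, platform="microarray" if arrays else "rnaseq"
            )
        if rmgenes == "auto":
            rmgenes = "none" if arrays else "default"
        self.signature = apply_gene_blacklists(signature, rmgenes=rmgenes, tumor=tumor)
        if prepare:
            mixture = reannotate_and_collapse(mixture, aliases)
            if arrays:
                mixture = prepare_microarray(mixture)
            else:
                mixture = renormalize_tpm(mixture)
        self.mixture = mixture
        self.mrna_scale = mrna_scale
        if scaling is None and mrna_scale:
            from .synthetic import default_scaling_factors

            scaling = default_scaling_factors()
        self.scaling = scaling

        self.shared_genes = [
            g for g in self.signature.values.index if g in self.mixture.values.index
        ]
        n_types = self.signature.values.shape[1]
        if len(self.shared_genes) < max(MIN_SHARED_GENES, n_types):
            raise ValueError(
                "insufficient signature coverage: "
                f"{len(self.shared_genes)} shared genes for {n_types} cell types"
            )
        self.coverage = len(self.shared_genes) / self.signature.values.shape[0]
        if self.coverage < WARN_SHARED_FRACTION:
            warnings.warn(
                f"only {len(self.shared_genes)}/{self.signature.values.shape[0]} "
                "signature genes present in the mixture"
            )

    @classmethod
    def from_files(
        cls, mixture_path: str | Path, signature_path: str | Path, **kwargs
    ) -> "DeconvolutionModel":
        from .signature import read_signature_matrix
        from .io import read_expression_matrix

        platform = "microarray" if kwargs.get("arrays") else "rnaseq"
        mixture = read_expression_matrix(mixture_path, platform=platform)
        signature = read_signature_matrix(signature_path)
        return cls(mixture, signature, **kwargs)

    def fit(self) -> "DeconvolutionResults":
        S = self.signature.values.loc[self.shared_genes]
        cell_types = list(S.columns)
        raw_rows, corrected_rows, failures = {}, {}, {}
        for sample in self.mixture.values.columns:
            m = self.mixture.values.loc[self.shared_genes, sample].to_numpy(dtype=float)
            try:
                F = pd.Series(solve_constrained_lsq(S.to_numpy(), m), index=cell_types)
                adjusted = apply_treg_heuristic(S, m, F)
                if self.mrna_scale and self.scaling is not None:
                    corrected = normalize_mrna_content(adjusted, self.scaling)
                else:
                    corrected = adjusted
                raw_rows[sample] = F
                row = corrected.copy()
                row[OTHER_LABEL] = estimate_other_fraction(corrected)
                corrected_rows[sample] = row
            except Exception as exc:  # keep going over remaining samples
                failures[sample] = str(exc)
                warnings.warn(f"sample {sample!r} failed: {exc}")
        if not corrected_rows:
            raise RuntimeError(f"all samples failed: {failures}")
        fractions = pd.DataFrame(corrected_rows).T.loc[list(corrected_rows)]
        raw = pd.DataFrame(raw_rows).T.loc[list(raw_rows)]
        table = FractionTable(fractions=fractions, raw=raw)
        return DeconvolutionResults(model=self, table=table, failures=failures)


@dataclass
class DeconvolutionResults:
    """Estimated absolute cell fractions with audit and reporting helpers."""

    model: DeconvolutionModel
    table: FractionTable
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def fractions(self) -> pd.DataFrame:
        return self.table.fractions

    @property
    def raw_fractions(self) -> pd.DataFrame | None:
        return self.table.raw

    def residuals(self) -> pd.Series:
        """Root-mean-square regression residual per sample (raw fit, TPM units)."""
        S = self.model.signature.values.loc[self.model.shared_genes]
        out = {}
        for sample, row in self.table.raw.iterrows():
            m = self.model.mixture.values.loc[self.model.shared_genes, sample]
            resid = S.to_numpy() @ row.to_numpy() - m.to_numpy(dtype=float)
            out[sample] = float(np.sqrt(np.mean(resid**2)))
        return pd.Series(out, name="rms_residual")

    def scale_to_densities(self, total_cells: pd.Series) -> DensityTable:
        return scale_to_densities(self.table, total_cells)

    def summary(self) -> str:
        frac = self.table.fractions
        lines = [
            "Constrained least-squares deconvolution",
            "=" * 55,
            f"samples: {frac.shape[0]}    cell types: {len(self.table.cell_types)}",
            f"signature genes used: {len(self.model.shared_genes)} "
            f"({self.model.coverage:.0%} of signature)",
            f"mRNA-content scaling: {'on' if self.model.mrna_scale else 'off'}",
            "",
            "mean fractions across samples:",
        ]
        for cell_type, value in frac.mean(axis=0).items():
            lines.append(f"  {cell_type:<18s} {value:8.4f}")
        if self.failures:
            lines += ["", f"failed samples: {sorted(self.failures)}"]
        return "\n".join(lines)

    def plot_fractions(self, ax=None):
        """Stacked-bar plot of per-sample fraction composition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        self.table.fractions.plot(kind="bar", stacked=True, ax=ax, width=0.9)
        ax.set_ylabel("cell fraction")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
        return ax


def deconvolute(
    mixture: ExpressionMatrix | pd.DataFrame,
    signature: SignatureMatrix,
    **options,
) -> FractionTable:
    """One-call deconvolution: build the model, fit, return the FractionTable."""
    return DeconvolutionModel(mixture, signature, **options).fit().table
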