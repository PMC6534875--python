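"""Aggregate immune scores and benchmarking metrics from fraction tables.

The deconvolution-based immunoscore dichotomizes CD3 (= CD8 + CD4 + Treg)
and CD8 T-cell fractions at their cohort medians; the TB score does the
same with B-cell and CD8 fractions.  Samples high on both markers are
"Hi-Hi", samples at or below both medians are "Lo-Lo", mixed samples are
left unclassified (and excluded from two-group comparisons).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LYMPHOCYTE_TYPES",
    "lymphocyte_fraction",
    "immunoscore_classes",
    "tb_score_classes",
    "metrics",
]

LYMPHOCYTE_TYPES = ("B.cells", "NK.cells", "T.cells.CD4", "T.cells.CD8", "Tregs")
CD3_COMPONENTS = ("T.cells.CD8", "T.cells.CD4", "Tregs")

HI_HI = "Hi-Hi"
LO_LO = "Lo-Lo"
UNCLASSIFIED = "unclassified"


def _require(frame: pd.DataFrame, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise KeyError(f"fraction table lacks column(s) {missing}")


def _fractions_frame(fractions) -> pd.DataFrame:
    # accept FractionTable-like objects or plain DataFrames
    return fractions.fractions if hasattr(fractions, "fractions") else fractions


def lymphocyte_fraction(fractions) -> pd.Series:
    """Total lymphocytes: B + NK + CD4 + CD8 + Treg fractions per sample."""
    frame = _fractions_frame(fractions)
    _require(frame, LYMPHOCYTE_TYPES)
    return frame[list(LYMPHOCYTE_TYPES)].sum(axis=1).rename("lymphocytes")


def _dichotomize(
    frame: pd.DataFrame,
    marker_a: pd.Series,
    marker_b: pd.Series,
    groups: pd.Series | None,
) -> pd.Series:
    def classify(a: pd.Series, b: pd.Series) -> pd.Series:
        med_a, med_b = a.median(), b.median()
        if a.nunique() == 1 and b.nunique() == 1:
            warnings.warn("all samples identical; everyone classified Lo-Lo")
        out = pd.Series(UNCLASSIFIED, index=a.index)
        out[(a > med_a) & (b > med_b)] = HI_HI
        out[(a <= med_a) & (b <= med_b)] = LO_LO
        return out

    if groups is None:
        return classify(marker_a, marker_b)
    pieces = []
    for _, idx in groups.groupby(groups).groups.items():
        pieces.append(classify(marker_a.loc[idx], marker_b.loc[idx]))
    return pd.concat(pieces).loc[frame.index]


def immunoscore_classes(fractions, groups: pd.Series | None = None) -> pd.DataFrame:
    """Immunoscore classes from median-dichotomized CD3 and CD8 fractions.

    ``groups`` (e.g. cancer type per sample) makes medians group-wise.
    Returns a table with the two marker fractions and the class label.
    """
    frame = _fractions_frame(fractions)
    _require(frame, CD3_COMPONENTS)
    if frame.shape[0] < 2:
        raise ValueError("at least two samples are required for dichotomization")
    cd3 = frame[list(CD3_COMPONENTS)].sum(axis=1)
    cd8 = frame["T.cells.CD8"]
    label = _dichotomize(frame, cd3, cd8, groups)
    return pd.DataFrame(
        {"CD3": cd3, "CD8": cd8, "immunoscore_class": label}, index=frame.index
    )


def tb_score_classes(fractions, groups: pd.Series | None = None) -> pd.DataFrame:
    """TB-score classes from median-dichotomized B-cell and CD8 fractions."""
    frame = _fractions_frame(fractions)
    _require(frame, ("B.cells", "T.cells.CD8"))
    if frame.shape[0] < 2:
        raise ValueError("at least two samples are required for dichotomization")
    b = frame["B.cells"]
    cd8 = frame["T.cells.CD8"]
    label = _dichotomize(frame, b, cd8, groups)
    return pd.DataFrame({"B": b, "CD8": cd8, "tb_class": label}, index=frame.index)


def metrics(estimated, true) -> pd.Series:
    """Pearson r and RMSE = sqrt(mean((est - true)^2)) between two vectors.

    Pearson r is reported as NaN when either vector is constant.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError("metrics expects two equal-length vectors")
    if est.size < 2:
        raise ValueError("metrics needs at least two observations")
    rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
    if np.ptp(est) == 0 or np.ptp(tru) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(est, tru).statistic)
    return pd.Series({"pearson_r": r, "rmse": rmse})
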