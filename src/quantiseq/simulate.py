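"""In-silico bulk mixtures with known composition for benchmarking.

Mixtures emulate the read-mixing design of the validation study at the
expression level: the expected profile is the fraction-weighted sum of
per-cell-type TPM profiles plus a tumor profile, and finite sequencing
depth is emulated by multinomial resampling of that profile at the target
number of read pairs.  True fractions are therefore mRNA fractions, and
deconvolution of simulated data is assessed without mRNA-content scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import metrics
from .signature import CELL_TYPES, LabeledCompendium, build_signature

__all__ = [
    "TUMOR_LABEL",
    "SimulationDesign",
    "MixtureTruth",
    "simulate_fractions",
    "simulate_mixture",
    "generate_design",
    "simulate_dataset",
    "leave_k_out_validate",
]

TUMOR_LABEL = "Tumor"

DEFAULT_N_MIXTURES = 100
DEFAULT_PURITIES = tuple(round(p / 10, 1) for p in range(11))      # 0:10:100%
DEFAULT_DEPTHS = (1e6, 2e6, 5e6, 1e7, 2e7, 5e7, 1e8)               # read pairs
DEFAULT_BASE_DEPTH = 1e6
DEFAULT_ANCHOR_PURITY = 0.6


@dataclass
class MixtureTruth:
    """Known composition of one simulated mixture (fractions sum to 1)."""

    fractions: pd.Series          # immune cell types + Tumor
    purity: float
    depth: float

    def __post_init__(self) -> None:
        total = float(self.fractions.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"truth fractions sum to {total}, expected 1")


@dataclass
class SimulationDesign:
    """Enumerated grid of (mixture, purity, depth) datasets.

    The purity sweep runs at the base depth; the depth sweep runs at one
    anchor purity, with the base depth counted once (in the purity sweep),
    so the total is n_mixtures * (len(purities) + len(depths) - 1).
    """

    n_mixtures: int = DEFAULT_N_MIXTURES
    purities: tuple[float, ...] = DEFAULT_PURITIES
    depths: tuple[float, ...] = DEFAULT_DEPTHS
    base_depth: float = DEFAULT_BASE_DEPTH
    anchor_purity: float = DEFAULT_ANCHOR_PURITY
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p < 0 or p > 1 for p in self.purities):
            raise ValueError("purities must lie in [0, 1]")
        if any(d <= 0 for d in self.depths) or self.base_depth <= 0:
            raise ValueError("depths must be positive")
        if self.anchor_purity not in self.purities:
            raise ValueError(
                f"anchor purity {self.anchor_purity} not in the purity grid"
            )
        if self.base_depth not in self.depths:
            raise ValueError("base depth must be part of the depth grid")

    def enumerate(self) -> list[tuple[int, float, float]]:
        """All (mixture index, purity, depth) datasets of the design."""
        out = [
            (i, purity, self.base_depth)
            for purity in self.purities
            for i in range(self.n_mixtures)
        ]
        out += [
            (i, self.anchor_purity, depth)
            for depth in self.depths
            if depth != self.base_depth
            for i in range(self.n_mixtures)
        ]
        return out

    @property
    def size(self) -> int:
        return self.n_mixtures * (len(self.purities) + len(self.depths) - 1)


def generate_design(
    n_mixtures: int = DEFAULT_N_MIXTURES,
    purities: tuple[float, ...] = DEFAULT_PURITIES,
    depths: tuple[float, ...] = DEFAULT_DEPTHS,
    anchor_purity: float = DEFAULT_ANCHOR_PURITY,
    base_depth: float = DEFAULT_BASE_DEPTH,
    seed: int = 0,
) -> SimulationDesign:
    """Validated simulation design; the reference grids give 1700 datasets."""
    return SimulationDesign(
        n_mixtures=n_mixtures,
        purities=tuple(purities),
        depths=tuple(depths),
        base_depth=base_depth,
        anchor_purity=anchor_purity,
        seed=seed,
    )


def simulate_fractions(
    rng: np.random.Generator,
    purity: float,
    cell_types: tuple[str, ...] = CELL_TYPES,
) -> MixtureTruth:
    """Draw immune fractions uniform on [0,1], renormalized to sum to 1-purity.

    The tumor fraction equals the purity; renormalization makes the vector
    a composition, and by symmetry each immune type has expected fraction
    (1 - purity) / n_types.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must lie in [0, 1]")
    draws = rng.uniform(0.0, 1.0, size=len(cell_types))
    if purity >= 1.0 or draws.sum() == 0:
        immune = np.zeros(len(cell_types))
    else:
        immune = draws / draws.sum() * (1.0 - purity)
    fractions = pd.Series(immune, index=list(cell_types))
    fractions[TUMOR_LABEL] = purity
    return MixtureTruth(fractions=fractions, purity=purity, depth=np.nan)


def simulate_mixture(
    profiles: pd.DataFrame,
    truth: MixtureTruth,
    depth: float | None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Compose a bulk TPM column from per-type profiles at a sequencing depth.

    The expected profile is sum_c truth_c * profile_c.  Finite ``depth``
    resamples gene counts from a multinomial with that many read pairs and
    converts back to TPM; ``depth=None`` (infinite) returns the exact
    linear mixture.
    """
    missing = [c for c in truth.fractions.index if c not in profiles.columns]
    if missing:
        raise KeyError(f"profiles missing for {missing}")
    expected = profiles[list(truth.fractions.index)].to_numpy(dtype=float) @ (
        truth.fractions.to_numpy(dtype=float)
    )
    expected = pd.Series(expected, index=profiles.index)
    if depth is None or np.isinf(depth):
        return expected
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if rng is None:
        raise ValueError("finite-depth simulation needs a random generator")
    p = expected.to_numpy() / expected.to_numpy().sum()
    counts = rng.multinomial(int(depth), p)
    return pd.Series(counts / counts.sum() * 1e6, index=profiles.index)


def simulate_dataset(
    profiles: pd.DataFrame,
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate all mixtures of a design; bit-reproducible given the seed.

    Returns (mixtures: genes x datasets, truth: datasets x fractions+meta).
    One RNG stream per mixture index is spawned from the design seed, so
    the same mixture index reuses the same immune composition across
    purities and depths, as in the reference design.
    """
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(design.n_mixtures)
    base_draws = [
        np.random.default_rng(children[i]).uniform(0.0, 1.0, size=len(CELL_TYPES))
        for i in range(design.n_mixtures)
    ]
    noise_rng = np.random.default_rng(master.spawn(1)[0])

    columns, truth_rows = {}, {}
    for i, purity, depth in design.enumerate():
        draws = base_draws[i]
        immune = (
            draws / draws.sum() * (1.0 - purity)
            if purity < 1.0 and draws.sum() > 0
            else np.zeros(len(CELL_TYPES))
        )
        fractions = pd.Series(immune, index=list(CELL_TYPES))
        fractions[TUMOR_LABEL] = purity
        truth = MixtureTruth(fractions=fractions, purity=purity, depth=depth)
        name = f"mix{i:03d}_p{int(round(purity * 100)):03d}_d{depth:.0e}"
        columns[name] = simulate_mixture(profiles, truth, depth, noise_rng)
        truth_rows[name] = pd.concat(
            [fractions, pd.Series({"purity": purity, "depth": depth})]
        )
    mixtures = pd.DataFrame(columns)
    truth_table = pd.DataFrame(truth_rows).T
    return mixtures, truth_table


def leave_k_out_validate(
    compendium: LabeledCompendium,
    n_mixtures: int = 100,
    purity: float = DEFAULT_ANCHOR_PURITY,
    depth: float | None = DEFAULT_BASE_DEPTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-K-out benchmark: per-type Pearson r and RMSE against truth.

    For each simulated mixture, one library per cell type is drawn to
    compose the mixture, and the signature is rebuilt from the remaining
    libraries only, so mixture and signature never share data.
    Deconvolution runs without mRNA scaling (truth = mRNA fractions).
    Returns a cell-type-indexed table with columns ``pearson_r``, ``rmse``
    and an ``overall`` row across all (type, mixture) pairs.
    """
    from .deconvolution import DeconvolutionModel

    rng = np.random.default_rng(seed)
    estimates, truths = [], []
    for i in range(n_mixtures):
        chosen = {
            t: compendium.libraries_of(t)[rng.integers(len(compendium.libraries_of(t)))]
            for t in CELL_TYPES
        }
        tumor_libs = compendium.libraries_of(TUMOR_LABEL)
        chosen[TUMOR_LABEL] = tumor_libs[rng.integers(len(tumor_libs))] if tumor_libs else None

        mix_profiles = pd.DataFrame(
            {t: compendium.values[l] for t, l in chosen.items() if l is not None}
        )
        truth = simulate_fractions(rng, purity)
        if TUMOR_LABEL not in mix_profiles.columns:
            truth.fractions = truth.fractions.drop(TUMOR_LABEL) / (1.0 - purity)
        m = simulate_mixture(mix_profiles, truth, depth, rng)

        held_out = LabeledCompendium(
            values=compendium.values.drop(
                columns=[l for l in chosen.values() if l is not None]
            ),
            labels={
                l: c
                for l, c in compendium.labels.items()
                if l not in set(chosen.values())
            },
            datasets=compendium.datasets,
        )
        signature, _ = build_signature(held_out)
        model = DeconvolutionModel(
            m.to_frame(name=f"mix{i:03d}"),
            signature,
            mrna_scale=False,
            rmgenes="none",
            prepare=True,
        )
        result = model.fit()
        estimates.append(result.fractions.iloc[0][list(CELL_TYPES)])
        truths.append(truth.fractions[list(CELL_TYPES)])

    est = pd.DataFrame(estimates).reset_index(drop=True)
    tru = pd.DataFrame(truths).reset_index(drop=True)
    rows = {}
    for cell_type in CELL_TYPES:
        rows[cell_type] = metrics(est[cell_type], tru[cell_type])
    rows["overall"] = metrics(
        est.to_numpy().ravel(), tru.to_numpy().ravel()
    )
    table = pd.DataFrame(rows).T
    table.index.name = "cell_type"
    return table
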