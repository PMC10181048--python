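"""Synthetic genotype x trait matrices with controlled statistical structure.

Traits are drawn from a multivariate normal with a requested inter-trait
correlation matrix, then shifted and scaled to per-trait means and
standard deviations. Optionally one genotype (the "planted winner") is
overwritten with the directed extremum of every trait pushed three
standard deviations further, so it dominates the table and must come out
ranked first — a recovery check for the whole scoring chain.

``barley_like_config`` mimics a warm-region barley trial: six traits with
means near the trial grand means (DHE 101.8 d, DMA 135.7 d, GFP 32.5 d,
PLH 84.6 cm, TKW 38.4 g, YLD 3750 kg/ha), spreads comparable to the
observed genotype means, and a correlation pattern with heading and
maturity tightly coupled, grain-filling period favoring late maturity and
early heading, and yield positively tied to grain fill and kernel weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BENEFIT, COST, DirectionSpec, TraitMatrix, _as_direction

__all__ = ["TraitSpec", "SimulationConfig", "simulate_traits", "barley_like_config"]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: name, orientation, target moments, units."""

    name: str
    direction: str
    mean: float
    sd: float
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _as_direction(self.direction))
        if self.sd <= 0:
            raise ValueError(f"trait {self.name!r}: sd must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic trial.

    ``correlation`` is the m x m inter-trait correlation matrix (identity
    if omitted); it must be symmetric positive semi-definite with a unit
    diagonal. ``planted_winner`` overwrites the first genotype with the
    directed extremum of every trait plus a 3-sd margin. ``round_days``
    rounds traits whose units are days to whole days (off by default:
    SIIG is scale-free, so rounding only loses information).
    """

    n_genotypes: int
    traits: tuple[TraitSpec, ...]
    correlation: np.ndarray | None = None
    planted_winner: bool = False
    round_days: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        object.__setattr__(self, "traits", tuple(self.traits))
        m = len(self.traits)
        if m < 1:
            raise ValueError("need at least one trait")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (m, m):
                raise ValueError(f"correlation matrix must be {m} x {m}")
            if not np.allclose(C, C.T, atol=1e-12):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-12):
                raise ValueError("correlation matrix must have unit diagonal")
            eigmin = np.linalg.eigvalsh(C).min()
            if eigmin < -1e-10:
                raise ValueError(
                    f"correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {eigmin:.3g})"
                )
            object.__setattr__(self, "correlation", C)

    def direction_spec(self) -> DirectionSpec:
        return DirectionSpec({t.name: t.direction for t in self.traits})


def simulate_traits(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TraitMatrix:
    """Draw a TraitMatrix according to *config*.

    Randomness comes from ``rng`` if given, else from the config's seed;
    the same seed always yields the same matrix.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = len(config.traits)
    C = config.correlation if config.correlation is not None else np.eye(m)
    # eigen-based factor tolerates exactly singular correlation matrices
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((config.n_genotypes, m)) @ L.T
    means = np.array([t.mean for t in config.traits])
    sds = np.array([t.sd for t in config.traits])
    X = means + Z * sds

    if config.planted_winner:
        row = np.empty(m)
        for j, t in enumerate(config.traits):
            col = X[:, j]
            if t.direction == BENEFIT:
                row[j] = col.max() + 3.0 * t.sd
            else:
                row[j] = col.min() - 3.0 * t.sd
        X[0] = row

    if config.round_days:
        for j, t in enumerate(config.traits):
            if t.units == "days":
                X[:, j] = np.round(X[:, j])

    ids = [f"G{i + 1}" for i in range(config.n_genotypes)]
    return TraitMatrix.from_arrays(ids, [t.name for t in config.traits], X)


#: Inter-trait correlation pattern for the barley-like preset; order
#: DHE, DMA, GFP, PLH, TKW, YLD. DHE and DMA move together; GFP, being
#: the maturity-heading gap, runs against DHE and with DMA; yield gains
#: from a longer grain fill and heavier kernels.
_BARLEY_CORR = np.array(
    [
        #  DHE    DMA    GFP    PLH    TKW    YLD
        [1.00, 0.70, -0.40, 0.10, 0.00, -0.20],  # DHE
        [0.70, 1.00, 0.35, 0.10, 0.00, 0.10],  # DMA
        [-0.40, 0.35, 1.00, 0.00, 0.10, 0.35],  # GFP
        [0.10, 0.10, 0.00, 1.00, 0.10, 0.00],  # PLH
        [0.00, 0.00, 0.10, 0.10, 1.00, 0.25],  # TKW
        [-0.20, 0.10, 0.35, 0.00, 0.25, 1.00],  # YLD
    ]
)


def barley_like_config(
    n_genotypes: int = 111,
    planted_winner: bool = False,
    seed: int | None = None,
) -> SimulationConfig:
    """A six-trait configuration emulating a warm-region barley trial."""
    traits = (
        TraitSpec("DHE", COST, mean=101.8, sd=2.6, units="days"),
        TraitSpec("DMA", COST, mean=135.7, sd=2.0, units="days"),
        TraitSpec("GFP", BENEFIT, mean=32.5, sd=1.8, units="days"),
        TraitSpec("PLH", COST, mean=84.6, sd=6.2, units="cm"),
        TraitSpec("TKW", BENEFIT, mean=38.4, sd=3.3, units="g"),
        TraitSpec("YLD", BENEFIT, mean=3750.0, sd=470.0, units="kg/ha"),
    )
    return SimulationConfig(
        n_genotypes=n_genotypes,
        traits=traits,
        correlation=_BARLEY_CORR,
        planted_winner=planted_winner,
        seed=seed,
    )
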