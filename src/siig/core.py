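"""Core computation chain for the Selection Index of Ideal Genotype (SIIG).

SIIG ranks genotypes by closeness to a trait-wise ideal profile. Starting
from a genotype x trait matrix ``D`` with entries ``x_ij``, each trait
column is vector-normalized::

    r_ij = x_ij / sqrt(sum_i x_ij**2)

so that every column has unit Euclidean norm and the index becomes
independent of trait units and scales. For each trait the ideal value
``r_j+`` is the directed extremum across genotypes (maximum for benefit
traits such as grain yield, minimum for cost traits such as days to
maturity) and the non-ideal value ``r_j-`` is the opposite extremum.
Euclidean distances of each genotype's normalized profile to the ideal
(``d_i+``) and non-ideal (``d_i-``) profiles yield the closeness score

    SIIG_i = d_i- / (d_i+ + d_i-)   in [0, 1],

with 1 meaning the genotype attains the ideal on every trait and 0 the
anti-ideal. Genotypes are ranked by descending SIIG.

The index needs no trait weights and no variance-component estimation,
which makes it usable in early generations of a breeding program where
only plot means are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "TraitMatrix",
    "DirectionSpec",
    "NormalizedMatrix",
    "IdealProfiles",
    "DistanceResult",
    "SIIGResult",
    "WARM_BARLEY",
    "normalize",
    "ideal_profiles",
    "distances",
    "siig_scores",
    "compute_siig",
    "derive_gfp",
]

BENEFIT = "benefit"
COST = "cost"

#: Synonyms accepted wherever a trait orientation is written down.
_DIRECTION_SYNONYMS = {
    "benefit": BENEFIT,
    "max": BENEFIT,
    "maximize": BENEFIT,
    "cost": COST,
    "min": COST,
    "minimize": COST,
}


def _as_direction(value: str) -> str:
    try:
        return _DIRECTION_SYNONYMS[str(value).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown trait direction {value!r}; expected one of "
            f"{sorted(_DIRECTION_SYNONYMS)}"
        ) from None


@dataclass(frozen=True)
class TraitMatrix:
    """Raw genotype x trait matrix ``D``.

    ``data`` holds one row per genotype (index = genotype IDs, strings)
    and one numeric column per trait, in the trait's own units (days, cm,
    g, kg/ha, ...). Construction validates the structural invariants:
    at least two genotypes, at least one trait, unique labels on both
    axes, and no missing or non-finite cells.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2:
            raise ValueError("a trait matrix needs at least 2 genotypes")
        if df.shape[1] < 1:
            raise ValueError("a trait matrix needs at least 1 trait")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genotype IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate trait names: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("trait values must be numeric")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite trait value at genotype "
                f"{df.index[i]!r}, trait {df.columns[j]!r}"
            )
        if (values < 0).any():
            warnings.warn(
                "trait matrix contains negative values; SIIG is defined "
                "but the ideal/non-ideal orientation may not be meaningful",
                stacklevel=3,
            )

    @classmethod
    def from_arrays(
        cls,
        genotype_ids: Sequence[str],
        trait_names: Sequence[str],
        values: np.ndarray | Sequence[Sequence[float]],
    ) -> "TraitMatrix":
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index([str(g) for g in genotype_ids], name="genotype"),
            columns=list(trait_names),
        )
        return cls(df)

    @property
    def genotype_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_traits(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DirectionSpec:
    """Per-trait orientation: benefit (larger is better) or cost (smaller).

    The orientation is the researcher's call, not a property of the data:
    e.g. in warm, terminal-drought-prone environments early maturity makes
    days to maturity a cost trait, while a longer grain-filling period is
    a benefit.
    """

    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {str(k): _as_direction(v) for k, v in self.directions.items()}
        object.__setattr__(self, "directions", canon)

    def __getitem__(self, trait: str) -> str:
        return self.directions[trait]

    def __contains__(self, trait: str) -> bool:
        return trait in self.directions

    def benefit_mask(self, trait_names: Iterable[str]) -> np.ndarray:
        """Boolean mask (True = benefit) aligned with *trait_names*.

        Raises if any trait lacks a direction; warns about directions for
        traits absent from the matrix rather than failing.
        """
        trait_names = list(trait_names)
        missing = [t for t in trait_names if t not in self.directions]
        if missing:
            raise KeyError(f"no direction declared for trait(s): {missing}")
        extra = sorted(set(self.directions) - set(trait_names))
        if extra:
            warnings.warn(
                f"directions declared for traits not in the matrix: {extra}",
                stacklevel=2,
            )
        return np.array([self.directions[t] == BENEFIT for t in trait_names])


#: Default orientation for the six barley traits in warm, short-season
#: environments: select for dwarfism (PLH cost), early heading/maturity
#: (DHE, DMA cost), a long grain-filling period and high kernel weight
#: and yield (GFP, TKW, YLD benefit).
WARM_BARLEY = DirectionSpec(
    {
        "DHE": COST,
        "DMA": COST,
        "GFP": BENEFIT,
        "PLH": COST,
        "TKW": BENEFIT,
        "YLD": BENEFIT,
    }
)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Unit-norm columns ``r_ij``; same axes as the source TraitMatrix."""

    data: pd.DataFrame

    @property
    def genotype_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class IdealProfiles:
    """Per-trait ideal (``r_j+``) and non-ideal (``r_j-``) normalized values."""

    r_plus: pd.Series
    r_minus: pd.Series


@dataclass(frozen=True)
class DistanceResult:
    """Euclidean distances of each genotype to the ideal and non-ideal profiles."""

    d_plus: pd.Series
    d_minus: pd.Series


@dataclass(frozen=True)
class SIIGResult:
    """Per-genotype SIIG scores with ranks and audit distances.

    ``table`` has columns ``d_plus``, ``d_minus``, ``siig`` and ``rank``
    (1 = best), indexed by genotype ID in the input order.
    """

    table: pd.DataFrame

    @property
    def genotype_ids(self) -> list[str]:
        return [str(g) for g in self.table.index]

    @property
    def siig(self) -> pd.Series:
        return self.table["siig"]

    @property
    def rank(self) -> pd.Series:
        return self.table["rank"]

    def top(self, k: int = 10) -> pd.DataFrame:
        """The *k* best genotypes by rank."""
        return self.table.nsmallest(k, "rank")


def normalize(matrix: TraitMatrix) -> NormalizedMatrix:
    """Vector-normalize each trait column to unit Euclidean norm.

    r_ij = x_ij / sqrt(sum_i x_ij**2). Division by the column norm makes
    every column unit-free, so traits measured in days, cm, g and kg/ha
    become commensurable. A column that is identically zero has no norm
    and is rejected.
    """
    X = matrix.values
    norms = np.sqrt((X**2).sum(axis=0))
    zero = norms == 0.0
    if zero.any():
        traits = [matrix.trait_names[j] for j in np.flatnonzero(zero)]
        raise ValueError(f"cannot normalize all-zero trait column(s): {traits}")
    return NormalizedMatrix(matrix.data / norms)


def ideal_profiles(
    normalized: NormalizedMatrix, directions: DirectionSpec
) -> IdealProfiles:
    """Extract the ideal and non-ideal genotype profile per trait.

    Benefit traits take the column maximum as ideal and minimum as
    non-ideal; cost traits the reverse.
    """
    benefit = directions.benefit_mask(normalized.trait_names)
    hi = normalized.data.max(axis=0)
    lo = normalized.data.min(axis=0)
    r_plus = hi.where(pd.Series(benefit, index=hi.index), lo)
    r_minus = lo.where(pd.Series(benefit, index=lo.index), hi)
    return IdealProfiles(r_plus=r_plus, r_minus=r_minus)


def distances(normalized: NormalizedMatrix, profiles: IdealProfiles) -> DistanceResult:
    """Euclidean distance of every genotype row to r+ and r-."""
    traits = normalized.trait_names
    if list(profiles.r_plus.index) != traits or list(profiles.r_minus.index) != traits:
        raise ValueError(
            "trait axes of the normalized matrix and the ideal profiles disagree"
        )
    R = normalized.values
    d_plus = np.sqrt(((R - profiles.r_plus.to_numpy()) ** 2).sum(axis=1))
    d_minus = np.sqrt(((R - profiles.r_minus.to_numpy()) ** 2).sum(axis=1))
    idx = normalized.data.index
    return DistanceResult(
        d_plus=pd.Series(d_plus, index=idx, name="d_plus"),
        d_minus=pd.Series(d_minus, index=idx, name="d_minus"),
    )


def _rank_descending(values: np.ndarray, method: str) -> np.ndarray:
    if method == "ordinal":
        # stable: ties keep input order
        order = np.argsort(-values, kind="stable")
        ranks = np.empty(len(values), dtype=float)
        ranks[order] = np.arange(1, len(values) + 1)
        return ranks
    if method == "average":
        return rankdata(-values, method="average")
    raise ValueError(f"unknown rank method {method!r}; use 'ordinal' or 'average'")


def siig_scores(dist: DistanceResult, rank_method: str = "ordinal") -> SIIGResult:
    """Closeness score SIIG_i = d_i- / (d_i+ + d_i-) with ranks.

    A genotype with d+ = d- = 0 is possible only when all genotypes are
    identical on every trait; such a genotype is simultaneously ideal and
    non-ideal and is scored 0.5 with a warning rather than erroring.

    ``rank_method='ordinal'`` (default) breaks ties by input order so
    ranks are a permutation of 1..n; ``'average'`` assigns mid-ranks for
    correlation work.
    """
    d_plus = dist.d_plus.to_numpy(dtype=float)
    d_minus = dist.d_minus.to_numpy(dtype=float)
    total = d_plus + d_minus
    degenerate = total == 0.0
    if degenerate.any():
        warnings.warn(
            "d+ + d- = 0 for some genotypes (all genotypes identical on "
            "every trait?); assigning SIIG = 0.5",
            stacklevel=2,
        )
    siig = np.where(degenerate, 0.5, d_minus / np.where(degenerate, 1.0, total))
    ranks = _rank_descending(siig, rank_method)
    table = pd.DataFrame(
        {
            "d_plus": d_plus,
            "d_minus": d_minus,
            "siig": siig,
            "rank": ranks if rank_method == "average" else ranks.astype(int),
        },
        index=dist.d_plus.index,
    )
    return SIIGResult(table)


def compute_siig(
    matrix: TraitMatrix,
    directions: DirectionSpec,
    rank_method: str = "ordinal",
) -> SIIGResult:
    """Full pipeline: normalize, locate ideal profiles, distances, score, rank."""
    normalized = normalize(matrix)
    profiles = ideal_profiles(normalized, directions)
    dist = distances(normalized, profiles)
    return siig_scores(dist, rank_method=rank_method)


def derive_gfp(
    dhe: Sequence[float] | pd.Series,
    dma: Sequence[float] | pd.Series,
    genotype_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Grain-filling period in days: GFP = DMA - DHE.

    Heading marks the start of grain fill and physiological maturity its
    end, so maturity must not precede heading; a negative difference is
    reported as an error naming the genotype.
    """
    dhe_arr = np.asarray(dhe, dtype=float)
    dma_arr = np.asarray(dma, dtype=float)
    if dhe_arr.shape != dma_arr.shape:
        raise ValueError("DHE and DMA vectors must have the same length")
    if genotype_ids is None:
        if isinstance(dhe, pd.Series):
            genotype_ids = [str(g) for g in dhe.index]
        else:
            genotype_ids = [str(i + 1) for i in range(len(dhe_arr))]
    gfp = dma_arr - dhe_arr
    neg = gfp < 0
    if neg.any():
        bad = [genotype_ids[i] for i in np.flatnonzero(neg)]
        raise ValueError(
            f"maturity precedes heading (negative GFP) for genotype(s): {bad}"
        )
    return pd.Series(gfp, index=pd.Index(genotype_ids, name="genotype"), name="GFP")
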