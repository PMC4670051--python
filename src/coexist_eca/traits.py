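"""Species trait vectors: baselines, single-trait variants, random sampling.

A species is a vector of 12 ecophysiological traits controlling carbon
uptake (photosynthetic capacity, stomatal behaviour, light capture),
carbon use (growth efficiency, allocation, turnover) and nitrogen economy
(uptake, stoichiometry, retranslocation).  Baseline values are means for
temperate C3 grassland species; the sensitivity designs vary each trait by
±50% around its baseline, either one at a time or jointly at random.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitVector",
    "TraitRanges",
    "VARYING_TRAITS",
    "HELD_CONSTANT_TRAITS",
    "base_traits",
    "single_trait_variants",
    "sample_traits",
    "default_ranges",
    "trait_arrays",
    "traits_to_frame",
    "frame_to_traits",
    "read_traits_csv",
    "write_traits_csv",
]

#: Traits varied by ±50% in the sensitivity designs.
VARYING_TRAITS: tuple[str, ...] = (
    "vcmax_per_n",
    "g1",
    "Y",
    "sla",
    "af",
    "sr",
    "kr",
    "rho",
    "lam",
)

#: Traits held at baseline in every generated species set.
HELD_CONSTANT_TRAITS: tuple[str, ...] = ("jmax_ratio", "ks")

_BASELINE = {
    "vcmax_per_n": 52.0,  # umol CO2 g-1 N s-1
    "jmax_ratio": 1.86,  # Jmax/Vcmax, dimensionless
    "g1": 3.7,  # kPa^0.5
    "Y": 0.5,  # carbon use efficiency, dimensionless
    "ks": 0.6,  # m2 ground m-2 leaf
    "sla": 14.0,  # m2 leaf kg-1 DM
    "af": 0.4,  # fraction of C to foliage
    "sr": 0.75,  # root turnover, yr-1
    "kr": 0.0239,  # m2 ground g-1 C
    "rho": 0.6,  # root-to-leaf N:C ratio
    "lam": 0.5,  # N retranslocation fraction
}


@dataclass(frozen=True)
class TraitVector:
    """One species: a point in the 12-dimensional trait space.

    Root allocation is derived (``ar = 1 - af``), never stored.
    """

    vcmax_per_n: float
    jmax_ratio: float
    g1: float
    Y: float
    ks: float
    sla: float
    af: float
    sr: float
    kr: float
    rho: float
    lam: float
    species_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.af < 1.0:
            raise ValueError(f"af must be in (0, 1), got {self.af}")
        if not 0.0 <= self.lam < 1.0:
            raise ValueError(f"lam must be in [0, 1), got {self.lam}")
        if not 0.0 < self.Y < 1.0:
            raise ValueError(f"Y must be in (0, 1), got {self.Y}")
        for name in ("vcmax_per_n", "jmax_ratio", "g1", "ks", "sla", "sr", "kr", "rho"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

    @property
    def ar(self) -> float:
        """Fraction of C allocated to roots (= 1 - af)."""
        return 1.0 - self.af

    def replace(self, **changes) -> "TraitVector":
        return dataclasses.replace(self, **changes)


TRAIT_FIELDS: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(TraitVector) if f.name != "species_id"
)


@dataclass(frozen=True)
class TraitRanges:
    """Per-trait uniform sampling bounds (±50% of baseline for varying traits)."""

    low: dict[str, float]
    high: dict[str, float]

    def __post_init__(self) -> None:
        for name in TRAIT_FIELDS:
            if name not in self.low or name not in self.high:
                raise ValueError(f"missing bounds for trait {name!r}")
            if self.low[name] > self.high[name]:
                raise ValueError(f"low > high for trait {name!r}")


def base_traits() -> TraitVector:
    """Baseline species: mean trait values of the focal grassland flora."""
    return TraitVector(species_id="base", **_BASELINE)


def default_ranges(base: TraitVector | None = None) -> TraitRanges:
    """±50% bounds around baseline for varying traits; degenerate for held ones."""
    base = base or base_traits()
    low, high = {}, {}
    for name in TRAIT_FIELDS:
        b = getattr(base, name)
        if name in VARYING_TRAITS:
            low[name], high[name] = 0.5 * b, 1.5 * b
        else:
            low[name] = high[name] = b
    return TraitRanges(low=low, high=high)


def single_trait_variants(base: TraitVector | None = None) -> list[TraitVector]:
    """The 18 one-trait-at-a-time variants: each varying trait at 1.5x and 0.5x.

    Labels are ``"+<trait>"`` (1.5x baseline) and ``"-<trait>"`` (0.5x).
    """
    base = base or base_traits()
    variants = []
    for name in VARYING_TRAITS:
        b = getattr(base, name)
        variants.append(base.replace(**{name: 1.5 * b}, species_id=f"+{name}"))
        variants.append(base.replace(**{name: 0.5 * b}, species_id=f"-{name}"))
    return variants


def sample_traits(
    n: int,
    seed: int | np.random.Generator,
    ranges: TraitRanges | None = None,
    sampler: Callable[[np.random.Generator, TraitRanges, int], dict] | None = None,
) -> list[TraitVector]:
    """Draw ``n`` random species, each varying trait i.i.d. uniform in its range.

    Traits are sampled independently.  ``sampler`` is a hook for user-supplied
    joint samplers (signature ``(rng, ranges, n) -> {trait: array}``); the
    default independent-uniform sampler is used when it is None.

    Parameters
    ----------
    n : number of species (>= 1).
    seed : integer seed or a Generator (for stream control).
    ranges : sampling bounds; defaults to ±50% around baseline.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranges = ranges or default_ranges()
    if sampler is None:
        draws = {
            name: rng.uniform(ranges.low[name], ranges.high[name], size=n)
            for name in TRAIT_FIELDS
        }
    else:
        draws = sampler(rng, ranges, n)
    width = len(str(n - 1)) if n > 1 else 1
    return [
        TraitVector(
            species_id=f"sp{i:0{width}d}",
            **{name: float(draws[name][i]) for name in TRAIT_FIELDS},
        )
        for i in range(n)
    ]


def trait_arrays(species: Sequence[TraitVector]) -> dict[str, np.ndarray]:
    """Column-wise view of a species list for vectorised model evaluation."""
    out: dict[str, np.ndarray] = {
        name: np.array([getattr(s, name) for s in species], dtype=float)
        for name in TRAIT_FIELDS
    }
    out["species_id"] = np.array([s.species_id for s in species], dtype=object)
    return out


# ---------------------------------------------------------------------------
# CSV interface: one species per row, columns named exactly as the fields.

def traits_to_frame(species: Iterable[TraitVector]) -> pd.DataFrame:
    rows = [
        {"species_id": s.species_id, **{f: getattr(s, f) for f in TRAIT_FIELDS}}
        for s in species
    ]
    return pd.DataFrame(rows, columns=("species_id", *TRAIT_FIELDS))


def frame_to_traits(frame: pd.DataFrame) -> list[TraitVector]:
    missing = set(TRAIT_FIELDS) - set(frame.columns)
    if missing:
        raise ValueError(f"trait table is missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            TraitVector(
                species_id=str(row.get("species_id", "")),
                **{f: float(row[f]) for f in TRAIT_FIELDS},
            )
        )
    return out


def write_traits_csv(species: Sequence[TraitVector], path) -> None:
    traits_to_frame(species).to_csv(path, index=False)


def read_traits_csv(path) -> list[TraitVector]:
    return frame_to_traits(pd.read_csv(path))
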