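"""Resource-use (Tilman) competition from monoculture R* and I* values.

Under resource-use theory a species that, in monoculture, depletes both
limiting resources (soil nitrogen supply, R*; light at the soil surface,
I*) to lower residual levels than a competitor excludes that competitor;
if each species depletes a different resource further, the pair coexists
on the two-resource trade-off.  Pairwise outcomes therefore come entirely
from each species' monoculture equilibrium, so all-pairs tournaments over
thousands of species need one equilibrium solve per species, never per
pair.

An equivalent trait-space formulation brackets the monoculture NPP ratio
of the pair between a light bound (``af*SLA*ks`` products) and a nutrient
bound (``(1-af)*kr/sr`` products): coexistence holds exactly when the NPP
ratio falls between the two bounds.  The bounds here are derived by taking
logs of the R* and I* expressions, which makes the equivalence exact by
construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .production import Equilibrium
from .traits import TraitVector

__all__ = [
    "Outcome",
    "PairOutcome",
    "TournamentResult",
    "pair_outcome",
    "coexistence_bounds",
    "tournament",
    "ability_delta",
    "REL_TIE_TOL",
]

#: Relative tolerance under which R* or I* values are treated as equal.
#: Equality in either coordinate breaks both strict inequalities, so ties
#: yield coexistence (and self-competition is a coexistence).
REL_TIE_TOL = 1e-9


class Outcome(enum.Enum):
    A_WINS = "A_WINS"
    B_WINS = "B_WINS"
    COEXIST = "COEXIST"


@dataclass(frozen=True)
class PairOutcome:
    outcome: Outcome
    a_id: str
    b_id: str

    def swapped(self) -> "PairOutcome":
        mapping = {
            Outcome.A_WINS: Outcome.B_WINS,
            Outcome.B_WINS: Outcome.A_WINS,
            Outcome.COEXIST: Outcome.COEXIST,
        }
        return PairOutcome(mapping[self.outcome], self.b_id, self.a_id)


@dataclass(frozen=True)
class TournamentResult:
    """All-pairs outcome counts; ability = wins + 0.5 * coexists (points)."""

    species_ids: tuple[str, ...]
    wins: np.ndarray
    losses: np.ndarray
    coexists: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def ability(self) -> np.ndarray:
        return self.wins + 0.5 * self.coexists

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.species_ids,
                "wins": self.wins,
                "losses": self.losses,
                "coexists": self.coexists,
                "ability": self.ability,
            }
        )


def _strictly_less(x: float, y: float) -> bool:
    return (y - x) > REL_TIE_TOL * max(abs(x), abs(y))


def pair_outcome(eq_a: Equilibrium, eq_b: Equilibrium) -> PairOutcome:
    """Outcome of pairwise competition from the two monoculture equilibria.

    A wins when both its R* and I* are strictly lower than B's; B wins in
    the mirror case; any other configuration (a resource trade-off, or a
    tie in either coordinate) is coexistence.
    """
    for eq in (eq_a, eq_b):
        if not eq.converged:
            raise ValueError(f"equilibrium for {eq.species_id!r} did not converge")
    a_r_lt = _strictly_less(eq_a.r_star, eq_b.r_star)
    b_r_lt = _strictly_less(eq_b.r_star, eq_a.r_star)
    a_i_lt = _strictly_less(eq_a.i_star, eq_b.i_star)
    b_i_lt = _strictly_less(eq_b.i_star, eq_a.i_star)
    if a_r_lt and a_i_lt:
        out = Outcome.A_WINS
    elif b_r_lt and b_i_lt:
        out = Outcome.B_WINS
    else:
        out = Outcome.COEXIST
    return PairOutcome(out, eq_a.species_id, eq_b.species_id)


def coexistence_bounds(
    traits_a: TraitVector,
    traits_b: TraitVector,
    npp_a: float,
    npp_b: float,
) -> bool:
    """True iff the pair coexists, from traits and monoculture NPPs alone.

    Taking logs of R*_A = R*_B gives the nutrient bound on NPP_B/NPP_A,
    ``(kr_A (1-af_A)/sr_A) / (kr_B (1-af_B)/sr_B)``; logs of I*_A = I*_B
    give the light bound ``(af_A SLA_A ks_A) / (af_B SLA_B ks_B)``.  The
    pair coexists exactly when the NPP ratio lies between the two bounds
    (boundary cases are ties, hence coexistence).
    """
    if npp_a <= 0.0 or npp_b <= 0.0:
        raise ValueError("monoculture NPPs must be strictly positive")
    ratio = npp_b / npp_a
    light_bound = (traits_a.af * traits_a.sla * traits_a.ks) / (
        traits_b.af * traits_b.sla * traits_b.ks
    )
    nutrient_bound = (traits_a.kr * (1.0 - traits_a.af) / traits_a.sr) / (
        traits_b.kr * (1.0 - traits_b.af) / traits_b.sr
    )
    lo, hi = min(light_bound, nutrient_bound), max(light_bound, nutrient_bound)
    # Strict exclusion requires the ratio strictly outside [lo, hi]; the
    # same relative tolerance as the R*/I* tie rule applies at the edges.
    below = (lo - ratio) > REL_TIE_TOL * max(ratio, lo)
    above = (ratio - hi) > REL_TIE_TOL * max(ratio, hi)
    return not (below or above)


def tournament(equilibria: list[Equilibrium]) -> TournamentResult:
    """All-pairs resource-use tournament over converged equilibria.

    Every unordered pair contributes exactly one point: 1 to a winner, or
    0.5 to each member of a coexisting pair.
    """
    if len(equilibria) < 2:
        raise ValueError("a tournament needs at least 2 species")
    bad = [e.species_id for e in equilibria if not e.converged]
    if bad:
        raise ValueError(f"unconverged equilibria for species {bad}")
    r = np.array([e.r_star for e in equilibria])
    i = np.array([e.i_star for e in equilibria])
    ids = tuple(e.species_id for e in equilibria)

    def lt(x):  # strict pairwise less-than with relative tie tolerance
        diff = x[None, :] - x[:, None]
        scale = np.maximum(np.abs(x[None, :]), np.abs(x[:, None]))
        return diff > REL_TIE_TOL * scale

    r_lt, i_lt = lt(r), lt(i)
    win = r_lt & i_lt
    lose = win.T
    np.fill_diagonal(win, False)
    coex = ~(win | lose)
    np.fill_diagonal(coex, False)
    return TournamentResult(
        species_ids=ids,
        wins=win.sum(axis=1),
        losses=lose.sum(axis=1),
        coexists=coex.sum(axis=1),
    )


def ability_delta(
    result_ambient: TournamentResult, result_elevated: TournamentResult
) -> pd.DataFrame:
    """Per-species change in ability and outcome counts, elevated - ambient."""
    if result_ambient.species_ids != result_elevated.species_ids:
        raise ValueError("tournaments cover different species sets")
    return pd.DataFrame(
        {
            "species_id": result_ambient.species_ids,
            "ability_ambient": result_ambient.ability,
            "ability_elevated": result_elevated.ability,
            "ability_delta": result_elevated.ability - result_ambient.ability,
            "wins_delta": result_elevated.wins - result_ambient.wins,
            "losses_delta": result_elevated.losses - result_ambient.losses,
            "coexists_delta": result_elevated.coexists - result_ambient.coexists,
        }
    )
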