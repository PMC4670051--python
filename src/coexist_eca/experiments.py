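"""Study designs: single-trait and random-species competition experiments.

Three reproducible pipelines, each run at ambient (360 ppm) and elevated
(550 ppm) CO2:

* ``run_single_trait_study`` — the 18 one-trait-at-a-time variants:
  all-pairs resource-use tournament (ability = wins + 0.5 coexists) and
  all-pairs resource-capture mixtures (per-species mean biomass share),
  plus the nine high-vs-low capture pairs with NPPs, dominance ratios and
  CO2 enhancement (E/A) ratios.
* ``run_random_use_study`` — n random species, all-pairs resource-use
  tournament per CO2 level; per-species win/loss/coexist counts and their
  ambient-to-elevated deltas; winner/loser trait means over decisive pairs
  (trait importance); Spearman correlations of traits with ambient NPP,
  ambient ability, and the ability change under elevated CO2.
* ``run_random_capture_study`` — random species pairs simulated as
  mixtures; winner-share distributions per level, winner-change counts,
  trait importance (winner = biomass share > 0.5), and a cross-theory
  comparison against the resource-use outcomes for the same pairs.

Mixture runs use a long protocol (default 120 years) so that slow
competitive-exclusion transients reach equilibrium; monoculture
equilibria come from the analytic annual-balance solver.  Default sizes
(2000 species / 500 pairs) keep a full desk run in minutes; both scale up
by argument.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .forcing import AnnualForcing, default_forcing
from .production import (
    DEFAULT_CONSTANTS,
    Equilibrium,
    ModelConstants,
    equilibria_to_frame,
    solve_equilibria,
)
from .resource_capture import MixtureResult, mixtures_to_frame, simulate_mixtures
from .resource_use import Outcome, TournamentResult, ability_delta, tournament
from .traits import (
    VARYING_TRAITS,
    TraitVector,
    sample_traits,
    single_trait_variants,
    traits_to_frame,
)

__all__ = [
    "ImportanceRecord",
    "CorrelationRecord",
    "SingleTraitStudy",
    "RandomUseStudy",
    "RandomCaptureStudy",
    "run_single_trait_study",
    "run_random_use_study",
    "run_random_capture_study",
    "trait_importance",
    "spearman_rho",
    "histogram_frame",
    "MIXTURE_YEARS",
]

logger = logging.getLogger(__name__)

#: Mixture-run length (years) used by the studies: long enough that slow
#: exclusion transients equilibrate under the default forcing.
MIXTURE_YEARS = 120

AMBIENT_ELEVATED = (360.0, 550.0)


@dataclass(frozen=True)
class ImportanceRecord:
    """Winner-vs-loser contrast of one trait, normalised by its overall mean."""

    trait: str
    mean_winning: float
    mean_losing: float
    mean_overall: float
    importance: float  # (mean_winning - mean_losing) / mean_overall


@dataclass(frozen=True)
class CorrelationRecord:
    trait: str
    spearman_rho: float


# ---------------------------------------------------------------------------
# Statistics helpers

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho)


def trait_importance(
    winner_traits: pd.DataFrame,
    loser_traits: pd.DataFrame,
    winner_weights: np.ndarray | None = None,
    loser_weights: np.ndarray | None = None,
    traits: Sequence[str] = VARYING_TRAITS,
) -> list[ImportanceRecord]:
    """Per-trait winner/loser mean contrast over decisive competitions.

    ``importance = (mean_winning - mean_losing) / mean_overall`` where the
    overall mean pools winners and losers.  Optional weights let callers
    pass per-species decisive-win and decisive-loss counts instead of
    expanding one row per pair.  Records are ordered by descending
    absolute importance.
    """
    if len(winner_traits) == 0 or len(loser_traits) == 0:
        raise ValueError("winner and loser groups must be nonempty")
    ww = np.ones(len(winner_traits)) if winner_weights is None else np.asarray(winner_weights, float)
    lw = np.ones(len(loser_traits)) if loser_weights is None else np.asarray(loser_weights, float)
    if ww.sum() <= 0 or lw.sum() <= 0:
        raise ValueError("weights must have positive total")
    records = []
    for name in traits:
        wv = winner_traits[name].to_numpy(dtype=float)
        lv = loser_traits[name].to_numpy(dtype=float)
        mean_w = float(np.average(wv, weights=ww))
        mean_l = float(np.average(lv, weights=lw))
        mean_all = float(
            np.average(np.concatenate([wv, lv]), weights=np.concatenate([ww, lw]))
        )
        records.append(
            ImportanceRecord(
                trait=name,
                mean_winning=mean_w,
                mean_losing=mean_l,
                mean_overall=mean_all,
                importance=(mean_w - mean_l) / mean_all,
            )
        )
    records.sort(key=lambda r: abs(r.importance), reverse=True)
    return records


def importance_frame(records: list[ImportanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def histogram_frame(values: np.ndarray, bins) -> pd.DataFrame:
    """Binned counts as a machine-checkable table (bin edges + counts)."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# Single-trait study

@dataclass
class SingleTraitStudy:
    equilibria: dict[float, list[Equilibrium]]
    tournaments: dict[float, TournamentResult]
    use_ranking: pd.DataFrame  # resource-use ability per variant per CO2 level
    capture_ranking: pd.DataFrame  # mean biomass share per variant per level
    capture_pairs: pd.DataFrame  # the 9 high-vs-low pairs with E/A ratios


def _unordered_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def run_single_trait_study(
    forcing: AnnualForcing | None = None,
    ca_levels: tuple[float, float] = AMBIENT_ELEVATED,
    mixture_years: int = MIXTURE_YEARS,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> SingleTraitStudy:
    """Pairwise competition among species differing in one trait value."""
    forcing = forcing or default_forcing()
    variants = single_trait_variants()
    ids = [v.species_id for v in variants]
    n = len(variants)
    pair_idx = _unordered_pairs(n)

    equilibria: dict[float, list[Equilibrium]] = {}
    tournaments: dict[float, TournamentResult] = {}
    use_cols: dict[str, np.ndarray] = {}
    cap_cols: dict[str, np.ndarray] = {}
    pair_rows = []

    for ca in ca_levels:
        t0 = time.perf_counter()
        eqs = solve_equilibria(variants, forcing, ca, constants)
        equilibria[ca] = eqs
        tournaments[ca] = tournament(eqs)
        use_cols[f"ability_{ca:g}"] = tournaments[ca].ability
        logger.info("single-trait resource use @ %g ppm: %.2fs", ca, time.perf_counter() - t0)

        t0 = time.perf_counter()
        mixtures = simulate_mixtures(
            [(variants[i], variants[j]) for i, j in pair_idx],
            forcing, ca, years=mixture_years, constants=constants,
        )
        # Per-variant mean biomass share over its 17 pairings (extinct
        # opponents give the survivor share 1.0, the extinct species 0.0).
        share_sum = np.zeros(n)
        for (i, j), res in zip(pair_idx, mixtures):
            total = res.biomass_i + res.biomass_j
            share_sum[i] += res.biomass_i / total
            share_sum[j] += res.biomass_j / total
        cap_cols[f"mean_share_{ca:g}"] = share_sum / (n - 1)
        logger.info("single-trait capture @ %g ppm: %.2fs", ca, time.perf_counter() - t0)

        # The nine high-vs-low pairs of the same trait.
        for k, name in enumerate(VARYING_TRAITS):
            res = next(
                r for (i, j), r in zip(pair_idx, mixtures)
                if {ids[i], ids[j]} == {f"+{name}", f"-{name}"}
            )
            hi_first = res.id_i == f"+{name}"
            npp_hi = res.npp_i if hi_first else res.npp_j
            npp_lo = res.npp_j if hi_first else res.npp_i
            pair_rows.append(
                {
                    "trait": name,
                    "ca": ca,
                    "npp_high": npp_hi,
                    "npp_low": npp_lo,
                    "winner_id": res.winner_id,
                    "dominance_ratio": res.dominance_ratio,
                    "npp_share_winner": res.npp_share_winner,
                    "coexist": res.coexist,
                }
            )

    use_ranking = pd.DataFrame({"species_id": ids, **use_cols}).sort_values(
        f"ability_{ca_levels[0]:g}", ascending=False, ignore_index=True
    )
    capture_ranking = pd.DataFrame({"species_id": ids, **cap_cols}).sort_values(
        f"mean_share_{ca_levels[0]:g}", ascending=False, ignore_index=True
    )

    pairs = pd.DataFrame(pair_rows)
    amb, elev = ca_levels
    wide = pairs.pivot(index="trait", columns="ca")
    ea = pd.DataFrame(
        {
            "ea_ratio_high": wide[("npp_high", elev)] / wide[("npp_high", amb)],
            "ea_ratio_low": wide[("npp_low", elev)] / wide[("npp_low", amb)],
        }
    ).reset_index()
    capture_pairs = pairs.merge(ea, on="trait")

    return SingleTraitStudy(
        equilibria=equilibria,
        tournaments=tournaments,
        use_ranking=use_ranking,
        capture_ranking=capture_ranking,
        capture_pairs=capture_pairs,
    )


# ---------------------------------------------------------------------------
# Random-species resource-use study

@dataclass
class RandomUseStudy:
    species: list[TraitVector]
    equilibria: dict[float, list[Equilibrium]]
    tournaments: dict[float, TournamentResult]
    deltas: pd.DataFrame  # per-species ability/outcome-count deltas
    importance: pd.DataFrame  # winner/loser trait contrast, ambient decisive pairs
    correlations: pd.DataFrame  # Spearman rho per trait and response
    histograms: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_random_use_study(
    n: int = 2000,
    seed: int = 0,
    forcing: AnnualForcing | None = None,
    ca_levels: tuple[float, float] = AMBIENT_ELEVATED,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> RandomUseStudy:
    """All-pairs resource-use competition among n random species."""
    if n < 2:
        raise ValueError("need at least 2 species")
    forcing = forcing or default_forcing()
    species = sample_traits(n, seed)
    tframe = traits_to_frame(species)

    equilibria: dict[float, list[Equilibrium]] = {}
    tournaments: dict[float, TournamentResult] = {}
    for ca in ca_levels:
        t0 = time.perf_counter()
        equilibria[ca] = solve_equilibria(species, forcing, ca, constants)
        tournaments[ca] = tournament(equilibria[ca])
        logger.info("random-use n=%d @ %g ppm: %.2fs", n, ca, time.perf_counter() - t0)

    amb, elev = ca_levels
    deltas = ability_delta(tournaments[amb], tournaments[elev])

    # Trait importance over decisive ambient pairs: each decisive pair
    # contributes its winner to the winning group and its loser to the
    # losing group, implemented with win/loss counts as weights.
    t_amb = tournaments[amb]
    importance = importance_frame(
        trait_importance(
            tframe, tframe,
            winner_weights=t_amb.wins.astype(float),
            loser_weights=t_amb.losses.astype(float),
        )
    )

    npp_amb = np.array([e.npp_star for e in equilibria[amb]])
    responses = {
        "ambient_npp": npp_amb,
        "ambient_ability": t_amb.ability,
        "ability_delta": deltas["ability_delta"].to_numpy(),
    }
    corr_rows = []
    for name in VARYING_TRAITS:
        x = tframe[name].to_numpy(dtype=float)
        for resp_name, resp in responses.items():
            corr_rows.append(
                {"trait": name, "response": resp_name, "spearman_rho": spearman_rho(x, resp)}
            )
    correlations = pd.DataFrame(corr_rows)

    histograms = {}
    bins = np.linspace(0, n - 1, 41)
    for ca, label in ((amb, "ambient"), (elev, "elevated")):
        t = tournaments[ca]
        for what in ("wins", "losses", "coexists"):
            histograms[f"{what}_{label}"] = histogram_frame(getattr(t, what), bins)
    delta_bins = 41
    for what in ("wins_delta", "losses_delta", "coexists_delta"):
        histograms[what] = histogram_frame(deltas[what].to_numpy(), delta_bins)

    return RandomUseStudy(
        species=species,
        equilibria=equilibria,
        tournaments=tournaments,
        deltas=deltas,
        importance=importance,
        correlations=correlations,
        histograms=histograms,
    )


# ---------------------------------------------------------------------------
# Random-pairs resource-capture study

@dataclass
class RandomCaptureStudy:
    pairs: list[tuple[TraitVector, TraitVector]]
    results: dict[float, list[MixtureResult]]
    table: pd.DataFrame  # per-pair shares at both levels + winner-change flag
    winner_change_fraction: float
    importance: pd.DataFrame
    cross_theory: pd.DataFrame  # capture share vs resource-use outcome per species
    histograms: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_random_capture_study(
    n_pairs: int = 500,
    seed: int = 0,
    forcing: AnnualForcing | None = None,
    ca_levels: tuple[float, float] = AMBIENT_ELEVATED,
    mixture_years: int = MIXTURE_YEARS,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> RandomCaptureStudy:
    """Two-species capture competition in n random pairs at both CO2 levels.

    Two independent random species sets are drawn and paired index-wise;
    the winner is the species with the larger ambient equilibrium biomass.
    """
    if n_pairs < 1:
        raise ValueError("need at least 1 pair")
    forcing = forcing or default_forcing()
    rng = np.random.default_rng(seed)
    set_a = sample_traits(n_pairs, rng)
    set_b = sample_traits(n_pairs, rng)
    set_b = [t.replace(species_id=t.species_id + "b") for t in set_b]
    pairs = list(zip(set_a, set_b))

    results: dict[float, list[MixtureResult]] = {}
    for ca in ca_levels:
        t0 = time.perf_counter()
        results[ca] = simulate_mixtures(pairs, forcing, ca, years=mixture_years, constants=constants)
        logger.info("random-capture %d pairs @ %g ppm: %.2fs", n_pairs, ca, time.perf_counter() - t0)

    amb, elev = ca_levels
    rows = []
    for res_a, res_e in zip(results[amb], results[elev]):
        share_i_amb = res_a.biomass_i / (res_a.biomass_i + res_a.biomass_j)
        share_i_elev = res_e.biomass_i / (res_e.biomass_i + res_e.biomass_j)
        winner_is_i = share_i_amb >= 0.5
        w_amb = share_i_amb if winner_is_i else 1.0 - share_i_amb
        w_elev = share_i_elev if winner_is_i else 1.0 - share_i_elev
        rows.append(
            {
                "id_i": res_a.id_i,
                "id_j": res_a.id_j,
                "share_i_ambient": share_i_amb,
                "share_i_elevated": share_i_elev,
                "winner_id_ambient": res_a.id_i if winner_is_i else res_a.id_j,
                "winner_share_ambient": w_amb,
                "winner_share_elevated": w_elev,
                "share_change": w_elev - w_amb,
                "winner_changed": w_elev < 0.5,
            }
        )
    table = pd.DataFrame(rows)
    winner_change_fraction = float(table["winner_changed"].mean())

    # Trait importance: ambient winners (share > 0.5) vs losers.
    fa = traits_to_frame(set_a)
    fb = traits_to_frame(set_b)
    winner_is_i = table["share_i_ambient"].to_numpy() > 0.5
    winners = pd.concat([fa[winner_is_i], fb[~winner_is_i]], ignore_index=True)
    losers = pd.concat([fa[~winner_is_i], fb[winner_is_i]], ignore_index=True)
    importance = importance_frame(trait_importance(winners, losers))

    # Cross-theory: resource-use outcome for the same pairs, from the
    # monoculture equilibria of all 2n species at ambient CO2.
    eq_a = solve_equilibria(set_a, forcing, amb, constants)
    eq_b = solve_equilibria(set_b, forcing, amb, constants)
    from .resource_use import pair_outcome  # local import avoids cycle at module load

    cross_rows = []
    for ea, eb, row in zip(eq_a, eq_b, rows):
        out = pair_outcome(ea, eb).outcome
        for species_label, share, use_out in (
            (ea.species_id, row["share_i_ambient"], out),
            (eb.species_id, 1.0 - row["share_i_ambient"], _swap_outcome(out)),
        ):
            cross_rows.append(
                {
                    "species_id": species_label,
                    "capture_share_ambient": share,
                    "use_outcome": use_out.value,
                }
            )
    cross_theory = pd.DataFrame(cross_rows)

    # Shares of the ambient winner: can fall below 0.5 at elevated CO2 when
    # the dominant species changes, so the bins span the full unit interval.
    share_bins = np.linspace(0.0, 1.0, 51)
    histograms = {
        "winner_share_ambient": histogram_frame(table["winner_share_ambient"].to_numpy(), share_bins),
        "winner_share_elevated": histogram_frame(table["winner_share_elevated"].to_numpy(), share_bins),
        "share_change": histogram_frame(table["share_change"].to_numpy(), 25),
    }

    return RandomCaptureStudy(
        pairs=pairs,
        results=results,
        table=table,
        winner_change_fraction=winner_change_fraction,
        importance=importance,
        cross_theory=cross_theory,
        histograms=histograms,
    )


def _swap_outcome(out: Outcome) -> Outcome:
    if out is Outcome.A_WINS:
        return Outcome.B_WINS
    if out is Outcome.B_WINS:
        return Outcome.A_WINS
    return Outcome.COEXIST
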