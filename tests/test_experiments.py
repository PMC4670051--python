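"""Study pipelines, summary statistics, determinism, forcing robustness."""

import numpy as np
import pandas as pd
import pytest

from coexist_eca.experiments import (
    histogram_frame,
    run_random_use_study,
    run_single_trait_study,
    spearman_rho,
    trait_importance,
)
from coexist_eca.forcing import generate_forcing
from coexist_eca.production import solve_equilibria
from coexist_eca.resource_use import tournament
from coexist_eca.traits import sample_traits

AMBIENT, ELEVATED = 360.0, 550.0


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 6, 8, 10]) == pytest.approx(1.0)
        assert spearman_rho(x, [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_values_use_average_ranks(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 20.0, 20.0, 30.0, 40.0]

        def brute_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.sort(v)
            return np.array([np.mean(np.nonzero(order == vi)[0] + 1) for vi in v])

        rx, ry = brute_ranks(x), brute_ranks(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestTraitImportance:
    def test_arithmetic(self):
        w = pd.DataFrame({"Y": [6.0, 6.0]})
        l = pd.DataFrame({"Y": [4.0, 4.0]})
        rec = trait_importance(w, l, traits=("Y",))[0]
        assert rec.importance == pytest.approx(0.4)
        assert rec.mean_overall == pytest.approx(5.0)

    def test_identical_groups_have_zero_importance(self):
        frame = pd.DataFrame({"Y": [0.4, 0.6], "af": [0.3, 0.5]})
        for rec in trait_importance(frame, frame, traits=("Y", "af")):
            assert rec.importance == pytest.approx(0.0)

    def test_weighted_equals_expanded(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"Y": rng.uniform(0.25, 0.75, 6)})
        w = rng.integers(0, 5, 6)
        l = rng.integers(0, 5, 6)
        w[0] = l[1] = 1  # ensure positive totals
        weighted = trait_importance(frame, frame, w, l, traits=("Y",))[0]
        expanded = trait_importance(
            frame.loc[frame.index.repeat(w)], frame.loc[frame.index.repeat(l)],
            traits=("Y",),
        )[0]
        assert weighted.importance == pytest.approx(expanded.importance, rel=1e-12)

    def test_empty_group_rejected(self):
        frame = pd.DataFrame({"Y": [0.5]})
        with pytest.raises(ValueError):
            trait_importance(frame, frame.iloc[:0])

    def test_sorted_by_absolute_importance(self, use_study_500):
        imp = use_study_500.importance["importance"].to_numpy()
        assert (np.abs(imp)[:-1] >= np.abs(imp)[1:] - 1e-12).all()


def test_histogram_frame_counts_everything():
    frame = histogram_frame(np.arange(100), bins=10)
    assert frame["count"].sum() == 100
    assert (frame["bin_left"] < frame["bin_right"]).all()


@pytest.fixture(scope="module")
def study(forcing):
    return run_single_trait_study(forcing)


class TestSingleTraitStudy:

    def test_competition_becomes_more_even_under_elevated_co2(self, study):
        """Dominance ratios fall at 550 ppm wherever ambient competition
        was not already complete exclusion."""
        pairs = study.capture_pairs.pivot(index="trait", columns="ca", values="dominance_ratio")
        undecided = pairs[360.0] < 0.995
        assert undecided.sum() >= 6
        assert (pairs.loc[undecided, 550.0] <= pairs.loc[undecided, 360.0]).all()

    def test_ambient_loser_is_more_co2_responsive_but_never_overtakes(self, study):
        amb = study.capture_pairs[study.capture_pairs["ca"] == 360.0]
        for _, row in amb.iterrows():
            hi_wins = row["winner_id"].startswith("+")
            ea_hi, ea_lo = row["ea_ratio_high"], row["ea_ratio_low"]
            if np.isfinite(ea_hi) and np.isfinite(ea_lo):
                if hi_wins:
                    assert ea_lo >= ea_hi
                else:
                    assert ea_hi >= ea_lo
        elev = study.capture_pairs[study.capture_pairs["ca"] == 550.0]
        merged = amb.merge(elev, on="trait", suffixes=("_a", "_e"))
        assert (merged["winner_id_a"] == merged["winner_id_e"]).all()

    def test_rankings_cover_all_18_variants(self, study):
        assert len(study.use_ranking) == 18
        assert len(study.capture_ranking) == 18
        assert study.use_ranking["ability_360"].sum() == pytest.approx(153.0)

    def test_capture_ranking_led_by_high_af_and_high_y(self, study):
        top2 = set(study.capture_ranking["species_id"].head(2))
        assert top2 == {"+af", "+Y"}
        bottom2 = set(study.capture_ranking["species_id"].tail(2))
        assert bottom2 == {"-af", "-Y"}


class TestRandomStudies:
    def test_same_seed_reproduces_study_exactly(self, forcing):
        a = run_random_use_study(n=40, seed=5, forcing=forcing)
        b = run_random_use_study(n=40, seed=5, forcing=forcing)
        assert np.array_equal(a.tournaments[AMBIENT].ability, b.tournaments[AMBIENT].ability)
        assert a.deltas.equals(b.deltas)
        assert a.correlations.equals(b.correlations)

    def test_total_points_conserved_at_both_levels(self, use_study_500):
        for t in use_study_500.tournaments.values():
            n = t.n_species
            assert t.ability.sum() == pytest.approx(n * (n - 1) / 2)

    def test_winner_share_histograms_cover_all_pairs(self, capture_study_500):
        for name in ("winner_share_ambient", "winner_share_elevated"):
            assert capture_study_500.histograms[name]["count"].sum() == 500

    def test_cross_theory_winners_have_majority_biomass_share(self, capture_study_500):
        """Resource-use winners almost always hold > 0.5 of mixture biomass."""
        cross = capture_study_500.cross_theory
        winners = cross[cross["use_outcome"] == "A_WINS"]
        assert len(winners) > 100
        agree = (winners["capture_share_ambient"] > 0.5).mean()
        assert agree > 0.9


class TestForcingRobustness:
    """Directional conclusions survive ±20% changes in the default forcing."""

    @pytest.mark.parametrize("scale", [0.8, 1.2])
    def test_directions_insensitive_to_ipar(self, scale):
        import scipy.stats

        forcing = generate_forcing(annual_ipar_target=2500.0 * scale)
        species = sample_traits(80, 23)
        eq_a = solve_equilibria(species, forcing, AMBIENT)
        eq_e = solve_equilibria(species, forcing, ELEVATED)
        coex_a = tournament(eq_a).coexists.sum()
        coex_e = tournament(eq_e).coexists.sum()
        assert coex_e > coex_a
        na = np.array([e.npp_star for e in eq_a])
        ne = np.array([e.npp_star for e in eq_e])
        viable = na > 1.0
        assert (ne[viable] > na[viable]).all()
        rho = scipy.stats.spearmanr(ne[viable] / na[viable], na[viable]).statistic
        assert rho < 0.0

    @pytest.mark.parametrize("dtemp", [-2.4, 2.4])
    def test_directions_insensitive_to_temperature(self, dtemp):
        forcing = generate_forcing(mean_temp=12.0 + dtemp)
        species = sample_traits(80, 23)
        coex = {
            ca: tournament(solve_equilibria(species, forcing, ca)).coexists.sum()
            for ca in (AMBIENT, ELEVATED)
        }
        assert coex[ELEVATED] > coex[AMBIENT]


def test_cli_runs_and_writes_tables(tmp_path):
    from click.testing import CliRunner

    from coexist_eca.cli import main

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("n_species: 12\nseed: 1\n")
    out = tmp_path / "out"
    runner = CliRunner()
    result = runner.invoke(
        main, ["random-use", "--config", str(cfg), "--out", str(out)]
    )
    assert result.exit_code == 0, result.output
    assert (out / "tournament_360.csv").exists()
    assert (out / "trait_correlations.csv").exists()
    assert (out / "manifest.json").exists()
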