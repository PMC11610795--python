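"""Consistency/refinement harnesses, LOOCV bands and TAC statistics."""

import numpy as np
import pytest

from tacmix import (
    DiscreteMeasure,
    NoiseModel,
    PopulationSpec,
    consistency_study,
    discrepancy_D,
    generate_population,
    loocv_study,
    refinement_studies,
    tac_statistics,
)


class TestTacStatistics:
    def test_triangle_curve(self):
        s = tac_statistics([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert s.peak_value == 1.0
        assert s.peak_time == 1.0
        assert s.auc == pytest.approx(1.0)

    def test_constant_curve_first_peak_convention(self):
        s = tac_statistics([0.0, 1.0, 2.0, 3.0], [0.4] * 4)
        assert s.peak_value == 0.4
        assert s.peak_time == 0.0  # first index attaining the maximum
        assert s.auc == pytest.approx(1.2)

    def test_scaling_linearity(self):
        t = np.linspace(0, 5, 30)
        y = np.sin(t) ** 2
        s1, s2 = tac_statistics(t, y), tac_statistics(t, 2 * y)
        assert s2.peak_value == pytest.approx(2 * s1.peak_value)
        assert s2.auc == pytest.approx(2 * s1.auc)
        assert s2.peak_time == s1.peak_time

    def test_trapezoid_refinement_converges_quadratically(self):
        exact = 2.0  # integral of sin on [0, pi] is 2
        errs = []
        for n in (8, 16, 32):
            t = np.linspace(0, np.pi, n + 1)
            errs.append(abs(tac_statistics(t, np.sin(t)).auc - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.1)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            tac_statistics([0.0], [1.0])
        with pytest.raises(ValueError):
            tac_statistics([0.0, 0.0], [1.0, 2.0])


class TestConsistencyStudy:
    def test_single_atom_truth_matches_closed_form(self, default_grid, noise, shared_cache):
        """With the truth a grid atom and tiny noise the fit concentrates on the
        generating node, so D is the analytic single-atom value (near zero)."""
        j = default_grid.nearest_index((0.5, 0.55))
        truth = DiscreteMeasure.atom(default_grid, j)
        spec = PopulationSpec(m=2, truth=truth, sigma2=1e-6, N_sim=32, seed=13)
        res = consistency_study(spec, [1, 2], default_grid, 32, noise, cache=shared_cache)
        analytic = discrepancy_D(DiscreteMeasure.atom(default_grid, j), truth)
        assert analytic == 0.0
        for _, D in res.rows:
            assert D <= 0.1 * discrepancy_D(DiscreteMeasure.uniform(default_grid), truth)

    def test_seeded_determinism(self, default_grid, noise, shared_cache):
        spec = PopulationSpec(m=3, sigma2=1e-6, N_sim=16, seed=21)
        r1 = consistency_study(spec, [1, 3], default_grid, 16, noise, cache=shared_cache)
        r2 = consistency_study(spec, [1, 3], default_grid, 16, noise, cache=shared_cache)
        assert r1.rows == r2.rows

    def test_nested_panels_share_prefix(self, default_grid, noise, shared_cache):
        """D at m is computed on the first m episodes of one panel, so a
        single-m run equals the corresponding row of a ladder run."""
        spec = PopulationSpec(m=3, sigma2=1e-6, N_sim=16, seed=22)
        ladder = consistency_study(spec, [1, 3], default_grid, 16, noise, cache=shared_cache)
        single = consistency_study(spec, [3], default_grid, 16, noise, cache=shared_cache)
        assert ladder.rows[1] == single.rows[0]


class TestRefinementStudies:
    def test_tables_and_single_entry_consistency(self, default_grid, noise, shared_cache):
        spec = PopulationSpec(m=4, sigma2=1e-6, N_sim=16, seed=31)
        tM, tN = refinement_studies(spec, M_list=[25, 100], N_list=[8, 16],
                                    fixed_grid=default_grid, fixed_N=16,
                                    noise=noise, cache=shared_cache)
        assert tM.kind == "M" and [r[0] for r in tM.rows] == [25, 100]
        assert tN.kind == "N" and [r[0] for r in tN.rows] == [8, 16]
        # single-entry N ladder agrees with a direct consistency run: Dbar_N = D / N
        direct = consistency_study(spec, [4], default_grid, 16, noise, cache=shared_cache)
        assert tN.rows[1][1] == pytest.approx(direct.rows[0][1] / 16, rel=1e-12)

    def test_non_square_grid_size_rejected(self, default_grid, noise):
        spec = PopulationSpec(m=2, N_sim=8, seed=1)
        with pytest.raises(ValueError):
            refinement_studies(spec, [30], [], default_grid, 8, noise)


@pytest.fixture(scope="module")
def two_atom_panel(default_grid):
    ja = default_grid.nearest_index((0.3, 0.4))
    jb = default_grid.nearest_index((0.6, 0.75))
    truth = DiscreteMeasure.atoms(default_grid, [ja, jb], [0.5, 0.5])
    spec = PopulationSpec(m=5, truth=truth, sigma2=1e-6, N_sim=32, seed=41)
    episodes, _ = generate_population(spec)
    return episodes


class TestLoocv:
    def test_bands_are_ordered(self, two_atom_panel, default_grid, noise, shared_cache):
        res = loocv_study(two_atom_panel, default_grid, 32, noise,
                          n_draws=20, seed=1, cache=shared_cache)
        for rec in res.episodes:
            assert np.all(rec.lower <= rec.estimated + 1e-12)
            assert np.all(rec.estimated <= rec.upper + 1e-12)
            for lo, hi in rec.stat_intervals.values():
                assert lo <= hi

    def test_two_draw_band_is_min_max(self, two_atom_panel, default_grid, noise, shared_cache):
        """With 2 samples, linear-interpolation percentiles at 2.5/97.5 are
        within the sample range and the band has positive width where the
        curves differ."""
        res = loocv_study(two_atom_panel, default_grid, 32, noise, n_draws=2,
                          seed=3, cache=shared_cache, predictive_sigma2=0.0)
        rec = res.episodes[0]
        assert np.all(rec.lower <= rec.upper)

    def test_degenerate_measure_flagged_zero_width(self, default_grid, noise, shared_cache):
        """All episodes from one atom: the fitted measure collapses, draws are
        identical noise-free curves, the band has width 0 and the mean equals
        the curve."""
        j = default_grid.nearest_index((0.5, 0.55))
        truth = DiscreteMeasure.atom(default_grid, j)
        spec = PopulationSpec(m=3, truth=truth, sigma2=1e-6, N_sim=32, seed=43)
        episodes, _ = generate_population(spec)
        res = loocv_study(episodes, default_grid, 32, noise, n_draws=10,
                          seed=5, cache=shared_cache, predictive_sigma2=0.0)
        for rec in res.episodes:
            assert rec.degenerate
            np.testing.assert_allclose(rec.lower, rec.upper, atol=1e-15)
            np.testing.assert_allclose(rec.estimated, rec.lower, atol=1e-15)

    def test_requires_two_episodes_and_two_draws(self, two_atom_panel, default_grid, noise):
        with pytest.raises(ValueError):
            loocv_study(two_atom_panel[:1], default_grid, 32, noise)
        with pytest.raises(ValueError):
            loocv_study(two_atom_panel, default_grid, 32, noise, n_draws=1)

    def test_held_out_generating_node_dominates_row(self, default_grid, noise, shared_cache):
        """Sanity link: for a noise-free episode generated at a grid node, that
        node maximizes the episode's log-density row."""
        from tacmix import build_log_density_matrix

        j = default_grid.nearest_index((0.45, 0.6))
        truth = DiscreteMeasure.atom(default_grid, j)
        spec = PopulationSpec(m=1, truth=truth, sigma2=0.0, N_sim=32, seed=44)
        episodes, _ = generate_population(spec)
        L = build_log_density_matrix(episodes, default_grid, 32, noise, cache=shared_cache)
        assert int(np.argmax(L.values[0])) == j
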