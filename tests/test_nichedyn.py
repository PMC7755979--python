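import numpy as np
import pytest

import cytoniche as cn
from cytoniche.nichedyn import NicheSummary

from test_nichestats import toy_grid


class TestDynamicsIndices:
    @pytest.mark.parametrize("p", [50, 75, 95])
    def test_identical_grids(self, nested_pair, p):
        _, g_low, _ = nested_pair
        entry = cn.dynamics_indices(g_low, g_low, p)
        assert (entry.expansion, entry.unfilling) == (0.0, 0.0)
        assert (entry.stability_e, entry.stability_n) == (1.0, 1.0)

    def test_nested_niches_show_unfilling_not_expansion(self, nested_pair):
        _, g_low, g_high = nested_pair
        for p in (75, 95):
            entry = cn.dynamics_indices(g_low, g_high, p)
            assert entry.expansion == 0.0
            assert entry.unfilling > 0.0
            assert entry.expansion + entry.stability_e == pytest.approx(1.0, abs=1e-9)
            assert entry.unfilling + entry.stability_n == pytest.approx(1.0, abs=1e-9)

    def test_marginal_environment_trimming_is_monotone(self, nested_pair):
        # shrinking the analysis region (95 -> 75) trims marginal
        # non-overlap, so unfilling cannot grow
        _, g_low, g_high = nested_pair
        u75 = cn.dynamics_indices(g_low, g_high, 75).unfilling
        u95 = cn.dynamics_indices(g_low, g_high, 95).unfilling
        assert u75 <= u95

    def test_disjoint_supports_within_region(self):
        g1 = toy_grid(np.array([[0.6, 0.4], [0.0, 0.0]]))
        g2 = toy_grid(np.array([[0.0, 0.0], [0.3, 0.7]]))
        entry = cn.dynamics_indices(g1, g2, 95)
        assert entry.expansion == 1.0
        assert entry.unfilling == 1.0

    def test_value_mode_agrees_on_identical_grids(self, nested_pair):
        _, g_low, _ = nested_pair
        entry = cn.dynamics_indices(g_low, g_low, 75, quantile_mode="value")
        assert (entry.expansion, entry.unfilling) == (0.0, 0.0)

    def test_empty_region_errors(self):
        env1 = np.array([[1.0, 0.0], [0.0, 0.0]])
        env2 = np.array([[0.0, 0.0], [0.0, 1.0]])
        g1 = toy_grid(np.array([[1.0, 0.0], [0.0, 0.0]]), env=env1)
        g2 = toy_grid(np.array([[0.0, 0.0], [0.0, 1.0]]), env=env2)
        with pytest.raises(ValueError, match="region"):
            cn.dynamics_indices(g1, g2, 75)


class TestOptimumBreadth:
    def test_single_occupied_cell_is_a_point_mass(self):
        z = np.zeros((4, 4))
        z[2, 1] = 1.0
        g = toy_grid(z)
        summary = cn.optimum_breadth(g, n_cells=10, reps=50, seed=0)
        assert np.all(summary.optimum_samples[:, 0] == 2.0)
        assert np.all(summary.optimum_samples[:, 1] == 1.0)
        assert np.all(summary.breadth_samples == 0.0)

    def test_two_cell_closed_form(self):
        # equal mass on cells at axis-1 scores -1 and +1: optimum draws are
        # centred at 0 with SE 2*sqrt(0.25/100) = 0.1, and the unbiased
        # sample variance has expectation 1
        z = np.array([[0.5], [0.5]])
        g = toy_grid(z)
        g.x_centers = np.array([-1.0, 1.0])
        summary = cn.optimum_breadth(g, n_cells=100, reps=1000, seed=1)
        assert abs(summary.optimum_samples[:, 0].mean()) < 4 * 0.1 / np.sqrt(1000) * 10
        assert summary.optimum_samples[:, 0].std() == pytest.approx(0.1, rel=0.15)
        assert summary.breadth_samples[:, 0].mean() == pytest.approx(1.0, abs=0.01)

    def test_deterministic_under_seed(self, nested_pair):
        _, g_low, _ = nested_pair
        a = cn.optimum_breadth(g_low, reps=50, seed=4)
        b = cn.optimum_breadth(g_low, reps=50, seed=4)
        assert np.array_equal(a.optimum_samples, b.optimum_samples)
        assert np.array_equal(a.breadth_samples, b.breadth_samples)

    def test_uniform_and_weighted_modes_differ(self, nested_pair):
        _, g_low, _ = nested_pair
        w = cn.optimum_breadth(g_low, reps=100, seed=5, weighted=True)
        u = cn.optimum_breadth(g_low, reps=100, seed=5, weighted=False)
        # weighted draws concentrate where z is large, so breadth shrinks
        assert w.breadth_samples.mean() < u.breadth_samples.mean()

    def test_guards(self, nested_pair):
        _, g_low, _ = nested_pair
        with pytest.raises(ValueError):
            cn.optimum_breadth(g_low, reps=0)
        with pytest.raises(ValueError):
            cn.optimum_breadth(g_low, n_cells=0)


class TestCompareSummaries:
    def _summary(self, center, reps=100):
        samples = np.full((reps, 2), float(center))
        return NicheSummary("t", samples, np.abs(samples), reps, 10, 0)

    def test_identical_not_different(self):
        a = self._summary(1.0)
        assert cn.compare_summaries(a, a, axis=0) == "not_different"

    def test_disjoint_intervals_differ(self):
        assert cn.compare_summaries(self._summary(0.0), self._summary(2.0), 0) == "different"

    def test_matches_interval_overlap_oracle(self, nested_pair):
        _, g_low, g_high = nested_pair
        a = cn.optimum_breadth(g_low, reps=300, seed=6)
        b = cn.optimum_breadth(g_high, reps=300, seed=7)
        for axis in (0, 1):
            lo_a, hi_a = a.optimum_interval(axis)
            lo_b, hi_b = b.optimum_interval(axis)
            oracle = "different" if hi_a < lo_b or hi_b < lo_a else "not_different"
            assert cn.compare_summaries(a, b, axis) == oracle

    def test_mismatched_reps_error(self):
        with pytest.raises(ValueError):
            cn.compare_summaries(self._summary(0, 100), self._summary(0, 50), 0)
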