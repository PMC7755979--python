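import numpy as np
import pandas as pd
import pytest

import cytoniche as cn
from cytoniche.envspace import build_space, fit_pca_env

from conftest import whitened


def frame_with_exact_correlation(corr, n=400, seed=0):
    """Data whose *sample* correlation matrix equals ``corr`` exactly."""
    corr = np.asarray(corr, dtype=float)
    x = whitened(n, corr.shape[0], seed=seed)
    y = x @ np.linalg.cholesky(corr).T
    return pd.DataFrame(y, columns=[f"v{i+1}" for i in range(corr.shape[0])])


class TestFilterCorrelated:
    def test_duplicate_variable_collapses(self):
        frame = frame_with_exact_correlation(np.eye(2))
        frame["v2"] = frame["v1"]
        assert cn.filter_correlated(frame) == ["v1"]

    def test_below_threshold_all_retained(self):
        frame = frame_with_exact_correlation([[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1]])
        assert cn.filter_correlated(frame) == ["v1", "v2", "v3"]

    def test_greedy_drops_the_hub_variable(self):
        # v1 correlates strongly with both others; dropping it resolves
        # every excess correlation in one step
        frame = frame_with_exact_correlation(
            [[1, 0.80, 0.75], [0.80, 1, 0.50], [0.75, 0.50, 1]]
        )
        assert cn.filter_correlated(frame) == ["v2", "v3"]

    def test_constant_variable_dropped_with_warning(self):
        frame = frame_with_exact_correlation(np.eye(2))
        frame["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            kept = cn.filter_correlated(frame)
        assert kept == ["v1", "v2"]


class TestFitPcaEnv:
    def test_two_variable_closed_form(self):
        # eigenvalues of a 2x2 correlation matrix are 1 +/- r
        frame = frame_with_exact_correlation([[1, 0.6], [0.6, 1]])
        model = fit_pca_env(frame)
        assert model.explained[0] == pytest.approx((1 + 0.6) / 2, abs=1e-12)
        assert model.explained[1] == pytest.approx((1 - 0.6) / 2, abs=1e-12)

    def test_explained_fractions_are_a_partition(self):
        frame = frame_with_exact_correlation(np.eye(4) * 0.4 + 0.6)
        model = fit_pca_env(frame)
        assert model.explained[0] >= model.explained[1]
        assert model.explained.sum() <= 1.0 + 1e-12

    def test_loadings_orthonormal_with_positive_peaks(self):
        frame = frame_with_exact_correlation([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1]])
        model = fit_pca_env(frame)
        assert np.allclose(model.loadings @ model.loadings.T, np.eye(2), atol=1e-10)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_single_informative_variable_degenerates_gracefully(self):
        frame = pd.DataFrame({"v1": np.linspace(0, 1, 50), "v2": 3.0})
        with pytest.warns(UserWarning):
            model = fit_pca_env(frame)
        assert model.explained[0] == 1.0
        assert model.explained[1] == 0.0

    def test_all_constant_errors(self):
        frame = pd.DataFrame({"v1": np.ones(30), "v2": np.zeros(30)})
        with pytest.raises(ValueError, match="constant"):
            fit_pca_env(frame)


def uniform_background(n=2000, seed=0, lo=-3.0, hi=3.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(lo, hi, size=(n, 2)), columns=["v1", "v2"])


class TestNicheGrid:
    def test_occupancy_is_normalized(self, small_survey):
        _, env, _, groups = small_survey
        occ, bg = groups["4x"]
        grid = cn.build_niche_grid(occ, bg, env.var_names, R=60, cytotype="4x")
        assert grid.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert (grid.z >= 0).all()
        assert (grid.occ_density >= 0).all()

    def test_point_mass_concentrates(self):
        bg = uniform_background()
        occ = pd.DataFrame({"v1": np.zeros(20), "v2": np.zeros(20)})
        grid = cn.build_niche_grid(occ, bg, ["v1", "v2"], R=80)
        cells = grid.cell_scores()
        z = grid.z.ravel()
        radius = 4 * max(grid.bandwidths)
        near = np.linalg.norm(cells, axis=1) < radius
        assert z[near].sum() > 0.95

    def test_occurrences_equal_background_make_flat_occupancy(self):
        # ratio-of-densities identity: same sample in numerator and
        # denominator gives z constant over the available support
        bg = uniform_background(n=3000)
        grid = cn.build_niche_grid(bg, bg, ["v1", "v2"], R=60)
        dense = grid.env_density > 0.2 * grid.env_density.max()
        vals = grid.z[dense]
        assert vals.max() / vals.min() < 1.5

    def test_site_order_invariance(self, small_survey):
        _, env, _, groups = small_survey
        occ, bg = groups["4x"]
        g1 = cn.build_niche_grid(occ, bg, env.var_names, R=50)
        g2 = cn.build_niche_grid(
            occ.sample(frac=1, random_state=2),
            bg.sample(frac=1, random_state=3),
            env.var_names,
            R=50,
        )
        assert np.allclose(g1.z, g2.z, atol=1e-12)

    def test_uncorrected_reduces_to_occurrence_density(self):
        bg = uniform_background()
        rng = np.random.default_rng(5)
        occ = pd.DataFrame(rng.normal(0, 0.5, size=(100, 2)), columns=["v1", "v2"])
        grid = cn.build_niche_grid(occ, bg, ["v1", "v2"], R=60, corrected=False)
        avail = grid.env_density >= 1e-6 * grid.env_density.max()
        expect = np.where(avail, grid.occ_density, 0.0)
        expect /= expect.sum()
        assert np.allclose(grid.z, expect, atol=1e-12)

    def test_requires_five_occurrences(self):
        bg = uniform_background()
        occ = pd.DataFrame({"v1": [0, 0, 0], "v2": [0, 0, 0]})
        with pytest.raises(ValueError):
            cn.build_niche_grid(occ, bg, ["v1", "v2"])

    def test_resolution_stability_of_overlap(self, small_survey):
        _, env, _, groups = small_survey
        occ4, bg4 = groups["4x"]
        occ5, bg5 = groups["5x"]
        ds = {}
        for R in (100, 200):
            space = build_space(
                {"4x": bg4[env.var_names], "5x": bg5[env.var_names]},
                env.var_names,
                R=R,
            )
            g4 = space.occupancy(space.model.transform(occ4), "4x")
            g5 = space.occupancy(space.model.transform(occ5), "5x")
            ds[R] = cn.schoener_d(g4, g5)
        assert abs(ds[100] - ds[200]) < 0.02

    def test_netcdf_and_csv_round_trip(self, small_survey, tmp_path):
        _, env, _, groups = small_survey
        occ, bg = groups["4x"]
        grid = cn.build_niche_grid(occ, bg, env.var_names, R=30)
        nc = tmp_path / "grid.nc"
        grid.save(nc)
        import xarray as xr

        ds = xr.open_dataset(nc, engine="scipy")
        assert np.allclose(ds["z"].values, grid.z)
        csv = tmp_path / "grid.csv"
        grid.save(csv)
        back = pd.read_csv(csv)
        assert len(back) == 30 * 30
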