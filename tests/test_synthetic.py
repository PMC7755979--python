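import numpy as np
import pandas as pd
import pytest

import cytoniche as cn
from cytoniche.cytometry import call_table


def two_var_model(r=0.9, n_sites=10_000):
    """Loadings realizing an implied correlation r between two variables."""
    return cn.LatentEnvModel(
        n_sites=n_sites,
        gradient_loadings={"v1": (1.0, 0.0), "v2": (r, 0.0)},
        noise_sd=np.array([0.0, np.sqrt(1.0 - r**2)]),
        lattice_extent_km=500.0,
    )


class TestGenerateEnvSites:
    def test_noise_free_identity_loadings_reproduce_latents(self):
        model = cn.LatentEnvModel(
            n_sites=400,
            gradient_loadings={"v1": (1.0, 0.0), "v2": (0.0, 1.0)},
            noise_sd=0.0,
        )
        env = cn.generate_env_sites(model, seed=5)
        assert np.allclose(env.frame["v1"], env.frame["g1"])
        assert np.allclose(env.frame["v2"], env.frame["g2"])

    def test_deterministic_under_seed(self):
        model = cn.LatentEnvModel(n_sites=500)
        a = cn.generate_env_sites(model, seed=9).frame
        b = cn.generate_env_sites(model, seed=9).frame
        pd.testing.assert_frame_equal(a, b)
        c = cn.generate_env_sites(model, seed=10).frame
        assert not a.equals(c)

    def test_sample_correlation_matches_construction(self):
        env = cn.generate_env_sites(two_var_model(0.9), seed=3)
        r = np.corrcoef(env.frame["v1"], env.frame["v2"])[0, 1]
        assert abs(r - 0.9) < 0.03

    def test_full_correlation_matrix_within_monte_carlo_error(self):
        model = cn.LatentEnvModel(n_sites=8000)
        env = cn.generate_env_sites(model, seed=4)
        sample = env.frame[model.var_names].corr().to_numpy()
        implied = model.implied_correlation()
        assert np.abs(sample - implied).max() < 0.06

    def test_latent_gradients_are_unit_variance(self):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=5000), seed=2)
        assert env.frame["g1"].std(ddof=0) == pytest.approx(1.0, abs=0.01)
        assert env.frame["g2"].std(ddof=0) == pytest.approx(1.0, abs=0.01)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            cn.LatentEnvModel(gradient_loadings={"v1": (1.0, 0.0)})
        with pytest.raises(ValueError):
            cn.LatentEnvModel(noise_sd=-0.1)


class TestSampleOccurrences:
    def test_point_mass_limit_concentrates_at_optimum(self):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=8000), seed=6)
        spec = cn.NicheSpec("5x", (0.0, 0.0), (0.05, 0.05), 1.0)
        occ = cn.sample_occurrences(env, [spec], seed=7)
        dist = np.hypot(occ.frame["g1"], occ.frame["g2"])
        assert dist.max() < 0.35  # everything within a few envelope SDs

    def test_acceptance_sampler_is_unbiased(self):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=12000), seed=8)
        spec = cn.NicheSpec("4x", (0.3, -0.2), (0.5, 0.5), 0.2)
        occ = cn.sample_occurrences(env, [spec], seed=9)
        n = len(occ.frame)
        se = 0.5 / np.sqrt(n)
        assert abs(occ.frame["g1"].mean() - 0.3) < 3 * se
        assert abs(occ.frame["g2"].mean() - (-0.2)) < 3 * se

    def test_equal_specs_give_equal_optima_within_error(self):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=12000), seed=10)
        specs = [
            cn.NicheSpec("4x", (0.0, 0.0), (0.6, 0.6), 0.15),
            cn.NicheSpec("5x", (0.0, 0.0), (0.6, 0.6), 0.15),
        ]
        occ = cn.sample_occurrences(env, specs, seed=11)
        a = occ.frame[occ.frame.cytotype == "4x"][["g1", "g2"]].mean()
        b = occ.frame[occ.frame.cytotype == "5x"][["g1", "g2"]].mean()
        n1 = (occ.frame.cytotype == "4x").sum()
        n2 = (occ.frame.cytotype == "5x").sum()
        se = 0.6 * np.sqrt(1 / n1 + 1 / n2)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 2 * se

    def test_too_few_occurrences_advises_more_sites(self):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=200), seed=1)
        spec = cn.NicheSpec("7x", (0.0, 0.0), (0.3, 0.3), 0.001)
        with pytest.raises(ValueError, match="n_sites"):
            cn.sample_occurrences(env, [spec], seed=2)


class TestSamplePopulationTable:
    def _occ(self, n_specs=2, seed=12):
        env = cn.generate_env_sites(cn.LatentEnvModel(n_sites=4000), seed=seed)
        specs = [
            cn.NicheSpec(c, (0.0, 0.0), (9.0, 9.0), 0.9)
            for c in ["4x", "5x", "6x"][:n_specs]
        ]
        return cn.sample_occurrences(env, specs, seed=seed + 1)

    def test_zero_rate_means_all_uniform(self):
        pops = cn.sample_population_table(
            self._occ(), cn.MixtureSpec(base_mixing_rate=0.0), seed=13
        )
        assert all(not p.is_mixed for p in pops)

    def test_single_cytotype_never_mixes(self):
        pops = cn.sample_population_table(
            self._occ(n_specs=1), cn.MixtureSpec(base_mixing_rate=1.0), seed=14
        )
        assert all(not p.is_mixed for p in pops)

    def test_full_overlap_mixing_rate_recovered(self):
        # both envelopes cover the whole lattice, so every population sits in
        # a contact zone and mixes with the nominal probability
        pops = cn.sample_population_table(
            self._occ(), cn.MixtureSpec(base_mixing_rate=0.5), seed=15
        )
        assert len(pops) > 2000
        frac = sum(p.is_mixed for p in pops) / len(pops)
        assert abs(frac - 0.5) < 0.03

    def test_individual_counts_have_survey_shape(self):
        pops = cn.sample_population_table(self._occ(), cn.MixtureSpec(), seed=16)
        sizes = np.array([p.n_individuals for p in pops])
        assert sizes.min() >= 2
        assert 9 < sizes.mean() < 17  # mean ~13, strongly right-skewed
        assert sizes.std() > sizes.mean() * 0.7


class TestSampleRF:
    def _pops(self):
        return [
            cn.PopulationRecord(f"p{i}", 0, 0, "r", {c: 30})
            for i, c in enumerate(["3x", "4x", "5x", "6x", "7x", "8x"])
        ]

    def test_zero_sd_reproduces_means_and_perfect_calls(self):
        sd0 = {c: 0.0 for c in ["3x", "4x", "5x", "6x", "7x", "8x"]}
        rf = cn.sample_rf(self._pops(), sd_per_ploidy=sd0, cv_fail_fraction=0.0, seed=17)
        calls = call_table(rf)
        merged = rf.merge(calls, on="sample_id")
        assert (merged["status"] == "called").all()
        assert (merged["ploidy"] == merged["true_ploidy"]).all()

    def test_default_means_increase_with_ploidy(self):
        sd0 = {c: 0.0 for c in ["3x", "4x", "5x", "6x", "7x", "8x"]}
        rf = cn.sample_rf(self._pops(), sd_per_ploidy=sd0, seed=18)
        means = rf.groupby("true_ploidy")["rf"].mean()
        ordered = means.loc[["3x", "4x", "5x", "6x", "7x", "8x"]]
        assert (ordered.diff().dropna() > 0).all()

    def test_overlapping_envelopes_yield_ambiguous_calls(self):
        pops = [cn.PopulationRecord("p", 0, 0, "r", {"4x": 300, "5x": 300})]
        rf = cn.sample_rf(pops, cv_fail_fraction=0.0, seed=19)
        calls = call_table(rf)
        assert (calls["status"] == "ambiguous").sum() > 0

    def test_call_accuracy_degrades_with_sd(self):
        accs = []
        for sd in (0.0, 0.05, 0.15):
            rf = cn.sample_rf(
                self._pops(),
                sd_per_ploidy={c: sd for c in ["3x", "4x", "5x", "6x", "7x", "8x"]},
                cv_fail_fraction=0.0,
                seed=20,
            )
            merged = rf.merge(call_table(rf), on="sample_id")
            called = merged[merged["status"] == "called"]
            accs.append((called["ploidy"] == called["true_ploidy"]).mean())
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]

    def test_missing_calibration_row_names_the_ploidy(self):
        pops = [cn.PopulationRecord("p", 0, 0, "r", {"3x": 2})]
        with pytest.raises(KeyError, match="3x"):
            cn.sample_rf(pops, stain="DAPI", seed=21)

    def test_cv_failure_fraction_controls_gate(self):
        rf = cn.sample_rf(self._pops(), cv_fail_fraction=0.3, seed=22)
        frac = (rf["cv_percent"] >= 5.0).mean()
        assert abs(frac - 0.3) < 0.1

    def test_deterministic_under_seed(self):
        a = cn.sample_rf(self._pops(), seed=23)
        b = cn.sample_rf(self._pops(), seed=23)
        pd.testing.assert_frame_equal(a, b)
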