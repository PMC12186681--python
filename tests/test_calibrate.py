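"""Growth-law simulation, the normalized-SSE cost, and swarm fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cellecon as ce
from cellecon import calibrate as cal


@pytest.fixture(scope="module")
def truth():
    return ce.default_parameters()


@pytest.fixture(scope="module")
def noiseless_ds(truth):
    return cal.synth_growth_law_dataset(truth, phi_grid=[0.3, 0.5, 1.0],
                                        kcm_grid=[0.0], noise_sd=0.0,
                                        seed=1, source="DB")


class TestNormalizedSse:
    def test_perfect_fit_is_zero(self):
        assert cal.normalized_sse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_zero_prediction_scores_one(self):
        assert cal.normalized_sse([0.0, 0.0, 0.0], [3.0, 1.0, 2.0]) == 1.0

    def test_hand_value(self):
        assert cal.normalized_sse([2.0, 2.0], [1.0, 1.0]) == 1.0

    def test_all_zero_observation_rejected(self):
        with pytest.raises(ValueError):
            cal.normalized_sse([1.0], [0.0])

    @given(scale=st.floats(1e-3, 1e3),
           vals=st.lists(st.floats(0.1, 10), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, vals):
        exp = np.asarray(vals)
        sim = exp * 1.3 + 0.1
        assert cal.normalized_sse(sim * scale, exp * scale) == pytest.approx(
            cal.normalized_sse(sim, exp), rel=1e-9)


class TestGrowthLawCurves:
    def test_one_row_per_condition(self, truth):
        ds = cal.growth_law_curves(truth, phi_grid=[0.5], kcm_grid=[0.0])
        assert len(ds.table) == 1
        assert set(cal.OBSERVABLES) <= set(ds.table.columns)

    def test_nutrient_quality_raises_growth(self, noiseless_ds):
        tab = noiseless_ds.table
        assert tab["lambda"].is_monotonic_increasing

    def test_translation_inhibition_lowers_growth_raises_ribosomes(self, truth):
        ds = cal.growth_law_curves(truth, phi_grid=[1.0],
                                   kcm_grid=[0.0, 0.3, 0.8])
        lam = ds.table["lambda"].to_numpy()
        phi_R = ds.table["phi_R"].to_numpy()
        assert np.all(np.diff(lam) < 0)
        assert np.all(np.diff(phi_R) > 0)


class TestFitCost:
    def test_perfect_parameters_have_zero_cost(self, truth, noiseless_ds):
        assert cal.fit_cost(truth, [noiseless_ds]) == pytest.approx(0.0, abs=1e-12)

    def test_weights_recovered_from_scaled_observations(self, truth, noiseless_ds):
        # observations set to half the simulated values give sigma = 1 for
        # every series: cost = 10+1+1+1 (DB) + 5+5 (Scott) = 23
        half_db = cal.GrowthLawDataset(
            "DB", noiseless_ds.table.assign(
                **{c: noiseless_ds.table[c] / 2 for c in cal.OBSERVABLES}))
        half_scott = cal.GrowthLawDataset(
            "Scott", half_db.table.drop(columns=["gamma", "theta"]))
        assert cal.fit_cost(truth, [half_db, half_scott]) == pytest.approx(23.0,
                                                                           rel=1e-9)

    def test_db_lambda_dominates_cost(self, truth, noiseless_ds):
        # perturb only the lambda column: the DB weight is 10
        tab = noiseless_ds.table.copy()
        tab["lambda"] /= 2.0            # sigma = 1 for lambda, 0 for the rest
        ds = cal.GrowthLawDataset("DB", tab)
        assert cal.fit_cost(truth, [ds]) == pytest.approx(10.0, rel=1e-9)

    def test_missing_series_contributes_zero(self, truth, noiseless_ds):
        tab = noiseless_ds.table.drop(columns=["theta"])
        ds = cal.GrowthLawDataset("DB", tab)
        assert cal.fit_cost(truth, [ds]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("param,factor", [("gamma_max", 1.2),
                                              ("gamma_max", 0.8),
                                              ("K_gamma", 1.2),
                                              ("kappa_theta", 0.8)])
    def test_parameter_perturbations_increase_cost(self, truth, noiseless_ds,
                                                   param, factor):
        perturbed = truth.with_(**{param: getattr(truth, param) * factor})
        assert cal.fit_cost(perturbed, [noiseless_ds]) > 1e-4


class TestSyntheticData:
    def test_zero_noise_equals_simulation(self, truth, noiseless_ds):
        sim = cal.growth_law_curves(truth, phi_grid=[0.3, 0.5, 1.0],
                                    kcm_grid=[0.0])
        for obs in cal.OBSERVABLES:
            assert np.allclose(noiseless_ds.table[obs], sim.table[obs])

    def test_seed_reproducibility(self, truth):
        a = cal.synth_growth_law_dataset(truth, [0.5, 1.0], noise_sd=0.1, seed=9)
        b = cal.synth_growth_law_dataset(truth, [0.5, 1.0], noise_sd=0.1, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_noise_magnitude(self, truth):
        # relative deviations of a 5%-noise table have sd in [0.03, 0.07]
        # (25 phi x 2 k_cm conditions x 4 observables = 200 points)
        phi = np.linspace(0.3, 1.0, 25)
        kcm = [0.0, 0.3]
        clean = cal.growth_law_curves(truth, phi_grid=phi, kcm_grid=kcm)
        noisy = cal.synth_growth_law_dataset(truth, phi_grid=phi,
                                             kcm_grid=kcm, noise_sd=0.05,
                                             seed=11)
        devs = []
        for obs in cal.OBSERVABLES:
            devs.extend(np.asarray(noisy.table[obs]) / np.asarray(clean.table[obs]) - 1)
        assert len(devs) >= 200
        sd = float(np.std(devs))
        assert 0.03 <= sd <= 0.07

    def test_table_round_trip(self, truth, tmp_path, noiseless_ds):
        path = tmp_path / "laws.csv"
        cal.write_growth_law_table([noiseless_ds], path)
        back = cal.read_growth_law_table(path)
        assert len(back) == 1 and back[0].source == "DB"
        pd.testing.assert_frame_equal(
            back[0].table, noiseless_ds.table.reset_index(drop=True),
            check_exact=False, rtol=1e-12)


class TestParticleSwarm:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            cal.FitConfig(free_params=("a",), bounds=())
        with pytest.raises(ValueError):
            cal.FitConfig(free_params=("a",), bounds=((2.0, 1.0),))
        cfg = cal.FitConfig(free_params=("gamma_max",), bounds=((1.0, 2.0),))
        assert cfg.n_particles == 500 and cfg.n_generations == 500

    def test_recovery_and_determinism(self, truth, noiseless_ds):
        cfg = cal.FitConfig(free_params=("gamma_max",),
                            bounds=((3.6e4, 1.44e5),),
                            n_particles=8, n_generations=8, seed=5)
        fit1 = cal.fit_parameters([noiseless_ds], cfg, truth)
        fit2 = cal.fit_parameters([noiseless_ds], cfg, truth)
        assert fit1.best_values == fit2.best_values
        assert fit1.best_cost == fit2.best_cost
        assert fit1.best_values["gamma_max"] == pytest.approx(truth.gamma_max,
                                                              rel=0.10)
        trace = fit1.cost_trace
        assert np.all(np.diff(trace) <= 1e-15)
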