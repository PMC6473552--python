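"""Trial simulation engine: data generation, least squares, operating characteristics."""

import numpy as np
import pytest

import stratdesign as sd
from stratdesign import presets
from stratdesign.simulate import RankDeficientError


class TestBiomarkerSimulation:
    def test_degenerate_prevalences(self, rng):
        assert np.all(sd.simulate_biomarkers(50, (0.0, 0.0), rng) == 0)
        assert np.all(sd.simulate_biomarkers(50, (1.0, 1.0), rng) == 1)

    def test_double_positive_frequency(self, rng):
        n = 50_000
        profiles = sd.simulate_biomarkers(n, (0.3, 0.3), rng)
        freq = np.mean(profiles.sum(axis=1) == 2)
        assert abs(freq - 0.09) < 3 * np.sqrt(0.09 * 0.91 / n)


class TestAssignAndRespond:
    def test_noiseless_responses_equal_cell_means(self, full_spec, rng):
        theta = presets.theta_confirmatory()
        profiles = sd.simulate_biomarkers(200, (0.5, 0.5), rng)
        table = sd.assign_and_respond(profiles, sd.fixed_scheme("rct", 2, 2),
                                      theta, sigma2=0.0, rng=rng)
        X = full_spec.design_matrix(table)
        np.testing.assert_allclose(table["y"], X @ theta, atol=1e-12)

    def test_linked_scheme_never_crosses_linkage(self, rng):
        profiles = np.tile([0, 1], (500, 1))
        table = sd.assign_and_respond(profiles, sd.fixed_scheme("linked", 2, 2),
                                      presets.theta_confirmatory(), 1.0, rng)
        assert not ((table["x1"] == 0) & (table["x2"] == 1)
                    & (table["arm"] == 1)).any()

    def test_unenrolled_profiles_are_dropped(self, rng):
        scheme = sd.RandomizationScheme(2, 2, {(0, 0): [1 / 3] * 3})
        profiles = np.array([[0, 0], [1, 1], [0, 0], [0, 1]])
        table = sd.assign_and_respond(profiles, scheme,
                                      presets.theta_confirmatory(), 1.0, rng)
        assert len(table) == 2
        assert set(table["id"]) == {0, 2}

    def test_subgroup_mean_approaches_model_mean(self, full_spec, rng):
        theta = presets.theta_confirmatory()
        profiles = np.tile([1, 0], (40_000, 1))
        table = sd.assign_and_respond(profiles, sd.fixed_scheme("rct", 2, 2),
                                      theta, 1.15, rng)
        sub = table[table["arm"] == 1]
        expected = theta @ full_spec.feature_row((1, 0), 1)
        assert sub["y"].mean() == pytest.approx(
            expected, abs=3 * np.sqrt(1.15 / len(sub)))


class TestPhase2Simulation:
    def test_expected_subgroup_size(self, rng):
        table = sd.simulate_phase2(40_000, (0.3, 0.3),
                                   presets.theta_phase2(), 1.15, rng)
        frac = ((table["x1"] == 0) & (table["x2"] == 0)).mean()
        assert frac == pytest.approx(0.49, abs=0.01)

    def test_noiseless_zero_theta_gives_zero_response(self, rng):
        table = sd.simulate_phase2(100, (0.3, 0.3), np.zeros(9), 0.0, rng)
        assert np.all(table["y"] == 0.0)

    def test_large_sample_recovers_parameters(self, full_spec, rng):
        theta = presets.theta_phase2()
        table = sd.simulate_phase2(100_000, (0.3, 0.3), theta, 1.15, rng)
        theta_hat, _, sigma2_hat = sd.fit_least_squares(table, full_spec)
        np.testing.assert_allclose(theta_hat, theta, atol=0.06)
        assert sigma2_hat == pytest.approx(1.15, abs=0.03)


class TestLeastSquares:
    def test_noiseless_fit_is_exact(self, full_spec, rng):
        theta = presets.theta_confirmatory()
        profiles = sd.simulate_biomarkers(500, (0.5, 0.5), rng)
        table = sd.assign_and_respond(profiles, sd.fixed_scheme("rct", 2, 2),
                                      theta, 0.0, rng)
        theta_hat, cov, sigma2_hat = sd.fit_least_squares(table, full_spec)
        np.testing.assert_allclose(theta_hat, theta, atol=1e-8)
        assert sigma2_hat == pytest.approx(0.0, abs=1e-12)

    def test_confidence_interval_coverage(self, full_spec):
        theta = presets.theta_confirmatory()
        hits = np.zeros(9)
        reps = 300
        rng = np.random.default_rng(4)
        for _ in range(reps):
            profiles = sd.simulate_biomarkers(1000, (0.3, 0.3), rng)
            table = sd.assign_and_respond(
                profiles, sd.fixed_scheme("rct", 2, 2), theta, 1.15, rng)
            est, cov, _ = sd.fit_least_squares(table, full_spec)
            se = np.sqrt(np.diag(cov))
            hits += (np.abs(est - theta) <= 1.96 * se)
        coverage = hits / reps
        assert np.all(np.abs(coverage - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps))

    def test_rank_deficiency_detected(self, full_spec, rng):
        scheme = sd.RandomizationScheme(2, 2, {(0, 0): [0.5, 0.5, 0.0]})
        profiles = np.zeros((100, 2), dtype=int)
        table = sd.assign_and_respond(profiles, scheme,
                                      presets.theta_confirmatory(), 1.0, rng)
        with pytest.raises(RankDeficientError):
            sd.fit_least_squares(table, full_spec)

    def test_reduced_model_estimates_combined_effect(self, full_spec,
                                                     first_illustration,
                                                     solved_design, rng):
        """Under the optimal design, beta2' is consistent for beta2+delta22."""
        reduced = first_illustration["reduced"]
        theta = presets.theta_confirmatory()
        profiles = sd.simulate_biomarkers(40_000, (0.3, 0.3), rng)
        table = sd.assign_and_respond(profiles, solved_design.scheme, theta,
                                      1.15, rng)
        est, _, _ = sd.fit_least_squares(table, reduced)
        target = theta[full_spec.index_of("beta2")] \
            + theta[full_spec.index_of("delta22")]
        assert est[reduced.index_of("beta2'")] == pytest.approx(target,
                                                                abs=0.05)


class TestAnalyticPower:
    def test_zero_effect_gives_alpha_exactly(self, full_spec, catalogue):
        scheme = sd.fixed_scheme("rct", 2, 2)
        power = sd.analytic_power(scheme, 1000, (0.3, 0.3), np.zeros(9), 1.15,
                                  catalogue[0], full_spec, alpha=0.05)
        assert power == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_effect_size(self, full_spec, catalogue):
        scheme = sd.fixed_scheme("rct", 2, 2)
        powers = []
        for beta1 in (-0.4, -0.2, -0.1):
            theta = full_spec.theta_from_labels({"beta1": beta1})
            powers.append(sd.analytic_power(scheme, 1000, (0.3, 0.3), theta,
                                            1.15, catalogue[0], full_spec))
        assert powers[0] > powers[1] > powers[2]

    def test_non_estimable_contrast_raises(self, full_spec, catalogue):
        scheme = sd.RandomizationScheme(2, 2, {(0, 0): [0.5, 0.5, 0.0]})
        with pytest.raises(RankDeficientError):
            sd.analytic_power(scheme, 1000, (0.3, 0.3), np.zeros(9), 1.15,
                              catalogue[4], full_spec)


class TestConfirmatoryTrial:
    def test_encr_is_sum_of_powers(self, theta_confirmatory):
        trial = sd.ConfirmatoryTrial(sd.fixed_scheme("rct", 2, 2),
                                     theta_confirmatory, 1.15, 1000, (0.3, 0.3))
        res = trial.simulate(10, 10, seed=0)
        assert res.encr == pytest.approx(sum(res.power.values()), abs=1e-15)
        assert set(res.power) == {1, 2, 7, 8}
        assert set(res.type1) == {3, 4, 5, 6}

    def test_fixed_seed_is_bit_reproducible(self, theta_confirmatory):
        trial = sd.ConfirmatoryTrial(sd.fixed_scheme("linked", 2, 2),
                                     theta_confirmatory, 1.15, 1000, (0.3, 0.3))
        a = trial.simulate(5, 5, seed=42)
        b = trial.simulate(5, 5, seed=42)
        np.testing.assert_array_equal(a.rejection_rate, b.rejection_rate)

    def test_type1_error_at_nominal_level(self):
        trial = sd.ConfirmatoryTrial(sd.fixed_scheme("rct", 2, 2), np.zeros(9),
                                     1.15, 1000, (0.3, 0.3), alpha=0.05)
        res = trial.simulate(50, 100, seed=7)
        reps = res.n_fitted
        tol = 3 * np.sqrt(0.05 * 0.95 / reps) + 0.005
        assert np.all(np.abs(res.rejection_rate - 0.05) < tol)
        assert res.encr == 0.0

    def test_simulated_power_matches_analytic_oracle(self, full_spec,
                                                     catalogue,
                                                     theta_confirmatory):
        scheme = sd.fixed_scheme("linked", 2, 2)
        trial = sd.ConfirmatoryTrial(scheme, theta_confirmatory, 1.15, 1000,
                                     (0.3, 0.3))
        res = trial.simulate(100, 100, seed=11)
        analytic = [sd.analytic_power(scheme, 1000, (0.3, 0.3),
                                      theta_confirmatory, 1.15, c, full_spec)
                    for c in catalogue]
        np.testing.assert_allclose(res.rejection_rate, analytic, atol=0.02)

    def test_doubling_n_never_hurts_power(self, theta_confirmatory):
        small = sd.ConfirmatoryTrial(sd.fixed_scheme("rct", 2, 2),
                                     theta_confirmatory, 1.15, 500, (0.3, 0.3))
        large = sd.ConfirmatoryTrial(sd.fixed_scheme("rct", 2, 2),
                                     theta_confirmatory, 1.15, 1000, (0.3, 0.3))
        rs = small.simulate(40, 40, seed=3)
        rl = large.simulate(40, 40, seed=3)
        for r, p_small in rs.power.items():
            assert rl.power[r] >= p_small - 0.04

    def test_matches_patient_level_statsmodels_fit(self, full_spec, catalogue,
                                                   theta_confirmatory):
        """Cross-validate the sufficient-statistic engine against an explicit
        patient-level OLS path on the same operating characteristics."""
        import statsmodels.api as sm
        from scipy import stats as sps

        rng = np.random.default_rng(13)
        scheme = sd.fixed_scheme("rct", 2, 2)
        C = np.vstack([c.vector(full_spec) for c in catalogue])
        z = sps.norm.ppf(0.95)
        reps = 600
        rej = np.zeros(8)
        for _ in range(reps):
            profiles = sd.simulate_biomarkers(1000, (0.3, 0.3), rng)
            table = sd.assign_and_respond(profiles, scheme,
                                          theta_confirmatory, 1.15, rng)
            X = full_spec.design_matrix(table)
            fit = sm.OLS(table["y"].to_numpy(), X).fit()
            se = np.sqrt(np.einsum("rp,pq,rq->r", C, fit.cov_params(), C))
            rej += (C @ fit.params) / se < -z
        trial = sd.ConfirmatoryTrial(scheme, theta_confirmatory, 1.15, 1000,
                                     (0.3, 0.3))
        res = trial.simulate(30, 100, seed=17)
        ref = rej / reps
        se_mc = np.sqrt(res.rejection_rate * (1 - res.rejection_rate) / reps
                        + ref * (1 - ref) / reps) + 1e-3
        tol = np.maximum(4 * se_mc, 0.02)
        assert np.all(np.abs(res.rejection_rate - ref) < tol), (
            res.rejection_rate, ref)
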