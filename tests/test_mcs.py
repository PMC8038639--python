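"""Monte Carlo engine: moment matching, simulation, curves, exceedance."""

import math

import numpy as np
import pytest

from totorisk import (
    DomainError,
    ExposureModel,
    MCSResult,
    UnsupportedElementError,
    cumulative_curve,
    exceedance_check,
    fit_lognormal_moments,
    run_mcs,
)

SEED = 20210408

# closed-form mean of 1/BW for the log-normal matched to (74, 10) kg
E_INV_BW = math.exp(-4.2950167 + 0.1345242**2 / 2)


class TestFitLognormalMoments:
    @pytest.mark.parametrize(
        "mean, sd, mu, sigma",
        [
            (74, 10, 4.295017, 0.134524),
            (0.100, 0.030, -2.345674, 0.293560),
        ],
    )
    def test_hand_solved_parameters(self, mean, sd, mu, sigma):
        spec = fit_lognormal_moments(mean, sd)
        assert spec.mu == pytest.approx(mu, abs=5e-6)
        assert spec.sigma == pytest.approx(sigma, abs=5e-6)

    @pytest.mark.parametrize("mean, sd", [(74, 10), (0.100, 0.030), (3.0, 2.9)])
    def test_round_trip_reproduces_moments_analytically(self, mean, sd):
        spec = fit_lognormal_moments(mean, sd)
        implied_mean = math.exp(spec.mu + spec.sigma**2 / 2)
        implied_sd = implied_mean * math.sqrt(math.expm1(spec.sigma**2))
        assert implied_mean == pytest.approx(mean, rel=1e-12)
        assert implied_sd == pytest.approx(sd, rel=1e-12)

    def test_zero_sd_is_a_point_mass(self):
        spec = fit_lognormal_moments(5.0, 0.0)
        draws = spec.draw(np.random.default_rng(0), 100)
        assert np.all(draws == 5.0)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(DomainError):
            fit_lognormal_moments(0.0, 1.0)


class TestRunMcs:
    def test_degenerate_distributions_reproduce_deterministic_hi(self, element_table):
        exp = ExposureModel(cr_sd=0.0, bw_sd=0.0)
        result = run_mcs(17.78, exp, element_table["Zn"], n_iter=100, seed=SEED)
        expected = 17.78 * 0.100 / (74 * 0.30)
        assert np.allclose(result.hi_samples, expected)

    def test_seed_reproducibility_bit_identical(self, exposure, element_table):
        a = run_mcs(1.0, exposure, element_table["Cu"], n_iter=500, seed=SEED)
        b = run_mcs(1.0, exposure, element_table["Cu"], n_iter=500, seed=SEED)
        assert np.array_equal(a.hi_samples, b.hi_samples)
        assert np.array_equal(a.cr_draws, b.cr_draws)

    def test_input_draws_match_target_moments(self, exposure, element_table):
        result = run_mcs(1.0, exposure, element_table["Zn"], n_iter=10_000, seed=SEED)
        for draws, mean, sd, sigma in [
            (result.cr_draws, 0.100, 0.030, 0.293560),
            (result.bw_draws, 74.0, 10.0, 0.134524),
        ]:
            se_mean = sd / math.sqrt(draws.size)
            assert np.mean(draws) == pytest.approx(mean, abs=3 * se_mean)
            # se of the sample sd, accounting for the log-normal's kurtosis:
            # Var(s) ~ sd^2 (gamma2 + 2) / (4n), gamma2 the excess kurtosis
            w = sigma**2
            gamma2 = math.exp(4 * w) + 2 * math.exp(3 * w) + 3 * math.exp(2 * w) - 6
            se_sd = sd * math.sqrt((gamma2 + 2) / (4 * draws.size))
            assert np.std(draws, ddof=1) == pytest.approx(sd, abs=4 * se_sd)

    def test_hi_recomputes_exactly_from_stored_draws(self, exposure, element_table):
        zn = element_table["Zn"]
        result = run_mcs(2.5, exposure, zn, n_iter=1000, seed=SEED)
        recomputed = result.c_draws * result.cr_draws / (result.bw_draws * zn.rfd)
        assert np.array_equal(result.hi_samples, recomputed)

    def test_mean_hi_matches_closed_form(self, exposure, element_table):
        # E[HI] = C * E[CR] * E[1/BW] / RfD for independent inputs
        result = run_mcs(1.0, exposure, element_table["Zn"], n_iter=100_000, seed=SEED)
        expected = 1.0 * 0.100 * E_INV_BW / 0.30
        # E[1/BW] = exp(sigma^2)/mean = 0.0137603, so E[HI] = 0.0045868
        assert expected == pytest.approx(0.0045868, abs=2e-6)
        assert result.mean == pytest.approx(expected, rel=0.01)

    def test_jensen_mean_hi_exceeds_plug_in(self, exposure, element_table):
        result = run_mcs(1.0, exposure, element_table["Fe"], n_iter=50_000, seed=SEED)
        plug_in = 1.0 * exposure.cr_mean / (exposure.bw_mean * 0.7)
        assert result.mean >= plug_in

    def test_probabilistic_to_deterministic_ratio(self, exposure, element_table):
        """Mean MCS hazard over the point-value hazard: cr_mean*E[1/BW]/(cr_det/bw_det)."""
        result = run_mcs(1.0, exposure, element_table["Cu"], n_iter=100_000, seed=SEED)
        deterministic = 1.0 * exposure.cr_det / (exposure.bw_det * 0.40)
        analytic = exposure.cr_mean * E_INV_BW / (exposure.cr_det / exposure.bw_det)
        assert analytic == pytest.approx(0.783, abs=5e-4)
        assert result.mean / deterministic == pytest.approx(analytic, rel=0.01)

    def test_all_draws_positive_and_percentiles_ordered(self, exposure, element_table):
        result = run_mcs(17.78, exposure, element_table["Zn"], n_iter=5000, seed=SEED)
        assert np.all(result.hi_samples > 0)
        median = float(np.median(result.hi_samples))
        assert result.p5 <= median <= result.p95

    def test_lead_rejected(self, exposure, element_table):
        with pytest.raises(UnsupportedElementError, match="RfD"):
            run_mcs(1.0, exposure, element_table["Pb"], n_iter=10, seed=SEED)

    def test_bad_iteration_count_rejected(self, exposure, element_table):
        with pytest.raises(DomainError):
            run_mcs(1.0, exposure, element_table["Zn"], n_iter=0, seed=SEED)

    def test_distributed_concentration_accepted(self, exposure, element_table):
        spec = fit_lognormal_moments(2.0, 0.5)
        result = run_mcs(spec, exposure, element_table["Cu"], n_iter=20_000, seed=SEED)
        assert np.std(result.c_draws) > 0
        assert np.mean(result.c_draws) == pytest.approx(2.0, rel=0.02)


def _result_from_samples(samples):
    samples = np.asarray(samples, dtype=float)
    ones = np.ones_like(samples)
    return MCSResult("Zn", samples.size, 0, samples, ones, ones, ones)


class TestCumulativeCurve:
    def test_median_of_four_points(self):
        curve = cumulative_curve(_result_from_samples([1, 2, 3, 4]), n_points=7)
        value = np.interp(2.5, curve[:, 0], curve[:, 1])
        assert value == pytest.approx(0.5, abs=0.1)
        at_25 = curve[np.searchsorted(curve[:, 0], 2.5)][1]
        assert at_25 == pytest.approx(0.5)

    def test_last_point_reaches_probability_one(self):
        curve = cumulative_curve(_result_from_samples([0.1, 0.7, 0.3]), n_points=5)
        assert curve[-1, 1] == 1.0

    def test_monotone_non_decreasing(self, exposure, element_table):
        result = run_mcs(17.78, exposure, element_table["Zn"], n_iter=2000, seed=SEED)
        curve = cumulative_curve(result)
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert np.all(np.diff(curve[:, 0]) > 0)

    def test_consistent_with_p95(self, exposure, element_table):
        result = run_mcs(17.78, exposure, element_table["Zn"], n_iter=10_000, seed=SEED)
        curve = cumulative_curve(result, n_points=2000)
        prob_at_p95 = float(np.interp(result.p95, curve[:, 0], curve[:, 1]))
        assert prob_at_p95 == pytest.approx(0.95, abs=0.005)

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            cumulative_curve(_result_from_samples([1, 2]), n_points=1)


class TestExceedance:
    def test_all_below_threshold(self):
        check = exceedance_check(_result_from_samples([0.1, 0.2, 0.3]))
        assert check.below_threshold and check.exceedance_prob == 0.0

    def test_half_above_threshold(self):
        check = exceedance_check(_result_from_samples([0.5, 0.6, 1.5, 1.6]))
        assert not check.below_threshold
        assert check.exceedance_prob == 0.5
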