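"""Quantal statistics: interval fits, Poisson tests, cooperativity,
time-course and facilitation-decay fits, occupancy traces."""

import numpy as np
import pytest
from scipy import stats

from vesikin import NO_STIMULUS, Pulse, StimulusProtocol, equilibrate, simulate
from vesikin.analysis import (fit_cooperativity, fit_facilitation_decay,
                              fit_interval_distribution,
                              fit_release_time_course, mepp_frequency,
                              occupancy_fractions, poisson_test)


class TestIntervalFit:
    def test_recovers_known_time_constant(self, rng):
        # parameter recovery: tau-hat within 3 sampling SEs of truth
        tau_true = 1.61
        times = np.cumsum(rng.exponential(tau_true, size=500))
        fit = fit_interval_distribution(times, bin_width=0.5)
        assert abs(fit.tau - tau_true) < 3 * tau_true / np.sqrt(500)
        assert fit.tau_se == pytest.approx(fit.tau / np.sqrt(fit.n_T))

    def test_model_bin_counts_sum_close_to_total(self, rng):
        times = np.cumsum(rng.exponential(1.0, size=2000))
        fit = fit_interval_distribution(times, bin_width=0.1)
        assert fit.model.sum() == pytest.approx(fit.n_T, rel=0.01)

    def test_degenerate_equal_intervals_flagged(self):
        fit = fit_interval_distribution(np.arange(30) * 2.0)
        assert fit.degenerate

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_interval_distribution(np.arange(10.0))


class TestPoissonTest:
    def test_hand_computed_chi_square(self):
        # 250 trials, observed classes {0:135, 1:92, 2:20, 3:3}
        counts = np.repeat([0, 1, 2, 3], [135, 92, 20, 3])
        qs = poisson_test(counts)
        m = (92 + 2 * 20 + 3 * 3) / 250
        assert qs.m == pytest.approx(m) and m == pytest.approx(0.564)
        # brute-force oracle with the same pooling convention
        pk = stats.poisson.pmf([0, 1, 2, 3], m)
        pk[-1] += stats.poisson.sf(3, m)
        expected = 250 * pk
        obs = np.array([135.0, 92, 20, 3])
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert qs.chi2 == pytest.approx(chi2)
        assert qs.p == pytest.approx(stats.chi2.sf(chi2, len(expected) - 2))

    def test_null_counts_rarely_rejected(self, rng):
        # counts truly Poisson -> p uniform; median over replicates ~ 0.5
        ps = []
        for _ in range(60):
            qs = poisson_test(rng.poisson(1.0, size=250))
            ps.append(qs.p)
        assert np.median(ps) > 0.2
        assert np.mean(np.array(ps) > 0.05) > 0.8

    def test_all_failures_degenerate(self):
        qs = poisson_test(np.zeros(100, dtype=int))
        assert qs.degenerate and np.isnan(qs.p)

    def test_expected_classes_pooled_above_threshold(self, rng):
        qs = poisson_test(rng.poisson(0.3, size=300))
        assert (qs.expected >= 1.0).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            poisson_test(np.ones(20, dtype=int))


class TestCooperativityFit:
    def test_exact_fourth_order_data_recovered(self):
        tau_e = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.5]) * 1e-3
        k, K = 2.0e12, 0.9e-3
        m = k * (tau_e / (1 + tau_e / K)) ** 4
        fit = fit_cooperativity(tau_e, m, order=4)
        assert fit.r_squared > 0.99999
        assert fit.K == pytest.approx(K, rel=1e-3)

    def test_flat_response_has_zero_r_squared(self):
        tau_e = np.linspace(0.1e-3, 1e-3, 8)
        fit = fit_cooperativity(tau_e, np.full(8, 5.0), order=3)
        assert fit.r_squared < 0.5

    def test_rejects_bad_order_or_few_points(self):
        with pytest.raises(ValueError):
            fit_cooperativity(np.ones(8), np.ones(8), order=2)
        with pytest.raises(ValueError):
            fit_cooperativity(np.ones(3), np.ones(3), order=3)


class TestReleaseTimeCourseFit:
    def test_pure_single_exponential_gives_zero_A(self):
        u = np.linspace(0.1, 4, 20)
        fit = fit_release_time_course(u, np.exp(-u))
        assert abs(fit.A) < 1e-6

    def test_two_exponential_recovery(self):
        u = np.linspace(0.05, 5, 40)
        y = 1.5 * np.exp(-u) - 0.5 * np.exp(-u / 0.3)
        fit = fit_release_time_course(u, y)
        assert fit.A == pytest.approx(0.5, abs=1e-6)
        assert fit.x == pytest.approx(0.3, abs=1e-4)

    def test_second_exponential_only_shapes_early_times(self):
        u = np.linspace(0.05, 5, 200)
        y = 1.5 * np.exp(-u) - 0.5 * np.exp(-u / 0.3)
        # relative deviation from the late-time single-exponential branch
        dev = np.abs(y - 1.5 * np.exp(-u)) / (1.5 * np.exp(-u))
        assert dev[u < 1].max() > 100 * dev[u > 3].max()


class TestFacilitationDecayFit:
    def test_recovers_well_separated_constants(self):
        t = np.array([10, 20, 30, 50, 80, 120, 180, 250, 350, 500]) * 1e-3
        ratio = 1 + 2.0 * np.exp(-t / 0.030) + 0.5 * np.exp(-t / 0.170)
        fit = fit_facilitation_decay(t, ratio)
        assert fit.tau_fast == pytest.approx(0.030, rel=0.02)
        assert fit.tau_slow == pytest.approx(0.170, rel=0.02)
        assert fit.tau_fast < fit.tau_slow
        assert not fit.single_exponential

    def test_flat_curve_has_negligible_amplitudes(self):
        t = np.linspace(0.03, 0.5, 8)
        fit = fit_facilitation_decay(t, np.ones(8))
        assert fit.B_fast + fit.B_slow < 0.05

    def test_single_exponential_data_flagged(self):
        t = np.linspace(0.03, 0.5, 12)
        fit = fit_facilitation_decay(t, 1 + 2.5 * np.exp(-t / 0.077))
        assert fit.single_exponential
        assert fit.r_squared > 0.9999


class TestOccupancyAndFrequency:
    def test_fractions_sum_to_one_and_start_docked_heavy(self, frog4):
        state = equilibrate(frog4, 10_000, 60)
        proto = StimulusProtocol((Pulse(0.2, 500.0, 1.3e-3),))
        log, _ = simulate(frog4, proto, 0.5, 61, state)
        grid = np.linspace(0.0, 0.5, 101)
        df = occupancy_fractions(log, grid)
        sums = df[list(frog4.states)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert df["D"].iloc[0] == pytest.approx(0.98, abs=0.005)

    def test_fused_pool_spikes_after_pulse_then_recycles(self, frog4):
        state = equilibrate(frog4, 10_000, 62)
        proto = StimulusProtocol((Pulse(0.05, 500.0, 1.3e-3),))
        log, _ = simulate(frog4, proto, 3.0, 63, state)
        df = occupancy_fractions(log, np.array([0.04, 0.08, 3.0]))
        f = df["F"].to_numpy()
        assert f[1] > 10 * f[0]       # spike right after the pulse
        assert f[2] < f[1] / 5        # decays away at rate rho

    def test_mepp_frequency_counts_per_duration(self, frog4):
        state = equilibrate(frog4, 10_000, 64)
        log, _ = simulate(frog4, NO_STIMULUS, 30.0, 65, state, record="fusions")
        freq = mepp_frequency(log)
        assert freq["count_rate"] == pytest.approx(freq["n_events"] / 30.0)

    def test_spontaneous_intervals_are_exponential(self, cat4):
        # KS against the fitted exponential at alpha = 0.01
        state = equilibrate(cat4, 10_000, 66)
        log, _ = simulate(cat4, NO_STIMULUS, 400.0, 67, state, record="fusions")
        intervals = np.diff(log.fusion_times)
        d, p = stats.kstest(intervals, "expon", args=(0, intervals.mean()))
        assert p > 0.01
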