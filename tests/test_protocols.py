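"""Protocol runners: windows, calibration, facilitation/depression and
scheme-variant behaviour."""

import numpy as np
import pytest

from vesikin import RateParams, build_scheme
from vesikin.analysis import mepp_frequency, poisson_test
from vesikin.meanfield import expected_release, steady_state
from vesikin.protocols import (ResponseWindow, calibrate_amplitude,
                               calibrate_peak_facilitation, count_in_windows,
                               response_windows, run_impulse_series,
                               run_lag_sweep, run_param_sweep,
                               run_spontaneous, run_train_test)
from vesikin.stimulus import train_with_test


class TestWindows:
    def test_width_is_ten_tau_e_capped_at_next_onset(self):
        proto = train_with_test(3, 0.03, 0.25, 500.0, 5e-3)  # 10*tau_e > ipi
        wins = response_windows(proto)
        assert wins[0].width == pytest.approx(0.03)
        assert wins[-1].width == pytest.approx(0.05)

    def test_counting_is_pure_function_of_event_times(self):
        wins = [ResponseWindow(0.0, 0.013), ResponseWindow(0.03, 0.013)]
        times = np.array([0.001, 0.012, 0.0131, 0.031, 0.05])
        counts, asyn = count_in_windows(times, wins)
        assert counts.tolist() == [2, 1]
        assert asyn == 2


class TestSpontaneous:
    def test_cat_interval_constant_near_inverse_flux(self, cat4):
        log = run_spontaneous(cat4, 10_000, 300.0, seed=101)
        freq = mepp_frequency(log)
        flux = steady_state(cat4, 10_000).fusion_flux
        assert freq["count_rate"] == pytest.approx(flux, rel=0.25)

    def test_frog_releases_faster_than_cat(self, frog4, cat4):
        f_log = run_spontaneous(frog4, 10_000, 200.0, seed=102)
        c_log = run_spontaneous(cat4, 10_000, 200.0, seed=103)
        assert (mepp_frequency(f_log)["count_rate"]
                > mepp_frequency(c_log)["count_rate"])


class TestCalibration:
    def test_target_zero_gives_zero_amplitude(self, frog4):
        cal = calibrate_amplitude(frog4, 10_000, 1.3e-3, 0.0)
        assert cal.I_e == 0.0

    def test_release_fraction_monotone_in_amplitude(self, frog4):
        # the property that justifies bisection, via the exact expectation
        from vesikin.stimulus import Pulse, StimulusProtocol
        fracs = [expected_release(
            frog4, StimulusProtocol((Pulse(0.0, ie, 1.3e-3),)), 13e-3, 10_000)
            for ie in (0.0, 100.0, 300.0, 700.0, 2000.0)]
        assert (np.diff(fracs) > 0).all()

    def test_three_percent_anchor_hits_target(self, frog4):
        cal = calibrate_amplitude(frog4, 10_000, 1.3e-3, 0.03)
        assert cal.achieved == pytest.approx(0.03, rel=0.021)
        assert 300 < cal.I_e < 900

    def test_ssa_calibration_agrees_with_meanfield(self, frog4):
        mf = calibrate_amplitude(frog4, 10_000, 1.3e-3, 0.03)
        ssa = calibrate_amplitude(frog4, 10_000, 1.3e-3, 0.03, method="ssa",
                                  seed=999, n_trials=60, rel_tol=0.05)
        assert ssa.I_e == pytest.approx(mf.I_e, rel=0.15)

    def test_unattainable_target_raises(self, frog4):
        with pytest.raises(ValueError):
            calibrate_amplitude(frog4, 10_000, 1e-9, 0.99)

    def test_peak_facilitation_anchor(self, frog4):
        cal = calibrate_peak_facilitation(frog4, 10_000, 1.5e-3, 2.5)
        assert cal.achieved == pytest.approx(2.5, rel=0.021)


class TestImpulseSeries:
    def test_small_amplitude_yields_mostly_failures(self, frog4):
        cal = calibrate_amplitude(frog4, 10_000, 0.05e-3, 2e-5)  # m ~ 0.2
        res = run_impulse_series(frog4, 10_000, 150, 5.0, cal.I_e, 0.05e-3,
                                 seed=201)
        counts = res.counts[:, 0]
        assert (counts == 0).mean() > 0.6
        assert len(np.unique(counts)) <= 3

    def test_zero_amplitude_counts_match_spontaneous_rate(self, frog4):
        res = run_impulse_series(frog4, 10_000, 200, 5.0, 0.0, 0.15e-3, seed=202)
        # expected in-window count = flux * width, essentially zero classes
        flux = steady_state(frog4, 10_000).fusion_flux
        expect = flux * res.windows[0].width
        assert res.counts.mean() == pytest.approx(expect, abs=0.01)

    def test_poisson_agreement_at_low_probability(self, frog4):
        cal = calibrate_amplitude(frog4, 10_000, 0.15e-3, 1e-4)
        res = run_impulse_series(frog4, 10_000, 250, 5.0, cal.I_e, 0.15e-3,
                                 seed=203)
        qs = poisson_test(res.counts[:, 0])
        assert qs.p > 0.05
        assert 2 <= len(qs.classes) <= 8


@pytest.fixture(scope="module")
def mm(frog4):
    cal = calibrate_amplitude(frog4, 10_000, 1.3e-3, 0.03)
    res = run_train_test(frog4, 10_000, seed=301, n_runs=200,
                         I_e=cal.I_e, tau_e=1.3e-3, test_lag=0.25)
    return cal, res


class TestTrainTest:
    def test_facilitation_then_depression(self, frog4, mm):
        cal, res = mm
        m = res.mean_counts
        assert m[0] < m[1] < m[2]            # facilitation over the train
        # depression on the test pulse: exact in expectation; SSA consistent
        proto = res.protocol
        t_test = proto.pulses[-1].t_s
        mf_test = expected_release(frog4, proto, t_test + 0.013, 10_000,
                                   t_from=t_test)
        mf_first = expected_release(frog4, proto, 0.013, 10_000)
        assert mf_test < mf_first
        se = res.counts[:, -1].std(ddof=1) / np.sqrt(res.n_trials)
        assert abs(m[-1] - mf_test) < 3 * se

    def test_chelator_override_abolishes_pulse3_facilitation(self, frog4, mm):
        cal, res = mm
        chel = run_train_test(frog4, 10_000, seed=302, n_runs=200,
                              I_e=cal.I_e, tau_e=1.3e-3, test_lag=0.25,
                              overrides={2: (None, 0.3e-3)})
        norm = chel.mean_counts / chel.mean_counts[0]
        assert norm[2] < 1.2                  # back toward baseline
        assert res.mean_counts[2] / res.mean_counts[0] > 2.5
        # depression relief on the test pulse
        assert chel.mean_counts[-1] > res.mean_counts[-1]

    def test_asynchronous_release_present_after_train(self, frog4, mm):
        cal, _ = mm
        res = run_train_test(frog4, 10_000, seed=303, n_runs=50, I_e=cal.I_e,
                             tau_e=1.3e-3, test_lag=None, tail=0.1)
        assert res.asynchronous.mean() > 1.0

    def test_zero_amplitude_ratio_is_unity(self, frog4):
        sweep = run_lag_sweep(frog4, 10_000, [0.1], 0.0, 1.5e-3,
                              n_runs=40, seed=304)
        # unstimulated "protocol": counts are spontaneous, ratio ~ 1
        assert sweep.mean_test[0] == pytest.approx(sweep.mean_first[0], abs=0.3)


class TestLagSweepAndVariants:
    def test_fast_recycling_eliminates_depression(self, frog_params):
        s10 = build_scheme(4, frog_params.with_rho(10.0))
        base = build_scheme(4, frog_params)
        cal = calibrate_peak_facilitation(base, 10_000, 1.5e-3, 2.5)
        sweep = run_lag_sweep(s10, 10_000, [0.03, 0.12, 0.45], cal.I_e,
                              1.5e-3, n_runs=60, seed=401)
        assert sweep.ratio[0] > 2.0                   # enhanced facilitation
        assert (sweep.ratio > 1.0 - 3 * sweep.ratio_se).all()  # no depression

    def test_slow_recycling_sustains_depression(self, frog_params):
        s01 = build_scheme(4, frog_params.with_rho(0.1))
        base = build_scheme(4, frog_params)
        cal = calibrate_peak_facilitation(base, 10_000, 1.5e-3, 2.5)
        sweep = run_lag_sweep(s01, 10_000, [0.45], cal.I_e, 1.5e-3,
                              n_runs=80, seed=402)
        assert sweep.ratio[0] < 0.85

    def test_three_state_chain_shows_depression_without_facilitation(self, frog_params, frog4):
        # the 3-state chain is fed the amplitude calibrated for the 4-state
        # frog experiment; its large resting primed pool then over-releases
        # and depletion dominates at every lag
        s3 = build_scheme(3, frog_params)
        cal = calibrate_peak_facilitation(frog4, 10_000, 1.5e-3, 2.5)
        sweep = run_lag_sweep(s3, 10_000, [0.03, 0.09, 0.25], cal.I_e,
                              1.5e-3, n_runs=60, seed=403)
        assert (sweep.ratio < 1.0 + 3 * sweep.ratio_se).all()  # never facilitates
        assert sweep.ratio[0] < 0.9                            # depressed early
        assert sweep.mean_first[0] > 1000                      # over-release

    def test_longer_transient_releases_more(self, frog4):
        # m(tau_e) non-decreasing at fixed amplitude (exact expectation)
        from vesikin.stimulus import Pulse, StimulusProtocol
        ms = [expected_release(frog4,
                               StimulusProtocol((Pulse(0.0, 500.0, te),)),
                               10 * te, 10_000)
              for te in (0.1e-3, 0.5e-3, 1.0e-3, 1.5e-3)]
        assert (np.diff(ms) > 0).all()


class TestParamSweep:
    def test_mepp_frequency_increases_with_alpha(self, frog_params):
        def obs(scheme, seed):
            return steady_state(scheme, 10_000).fusion_flux

        df = run_param_sweep(frog_params, 4, {"alpha": [0.1, 0.3, 0.9]},
                             obs, seed=501)
        assert df["value"].is_monotonic_increasing

    def test_small_lambda1_extends_quantal_class_range(self, frog_params, frog4):
        # lambda1 = 5 inflates the resting preprimed pool: the same
        # amplitude that gives m ~ 1 at lambda = 50 now discharges several
        # times more quanta per impulse, stretching the class range
        cal = calibrate_amplitude(frog4, 10_000, 0.15e-3, 1e-4)
        lam5 = RateParams(alpha=0.3, lambda1=5.0, lambda2=50.0, rho=1.0)
        s5 = build_scheme(4, lam5)
        res = run_impulse_series(s5, 10_000, 250, 5.0, cal.I_e, 0.15e-3,
                                 seed=502)
        qs = poisson_test(res.counts[:, 0])
        assert qs.m > 3.0                      # vs ~1 at lambda = 50
        assert res.counts.max() >= 10          # extended class range
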