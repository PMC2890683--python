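"""Estimation-chain tests: apparent T2, coronary-sinus OEF, rest calibration,
hyperemic OEF inversion, and the end-to-end round trip."""

import numpy as np
import pytest

from myooef import (
    CalibrationError,
    FitError,
    ModelViolationError,
    NoSolutionError,
    SignalSeries,
    SimulationConfig,
    TissueState,
    calibrate_rest,
    cs_signal,
    fit_apparent_t2,
    fit_cs_oef,
    fit_stress_oef,
    simulate_phantom,
    simulate_session,
    voxel_signal,
)
from myooef.fitting import stress_forward_t2


def _with_noise(series, sigma_abs, seed, **kw):
    rng = np.random.default_rng(seed)
    noisy = np.clip(series.intensity + rng.normal(0, sigma_abs, len(series)), 1e-9, None)
    return SignalSeries(te_ms=series.te_ms, intensity=noisy, **kw)


class TestApparentT2:
    def test_noise_free_monoexponential_recovered(self, protocol):
        ph = simulate_phantom(43.5, protocol)
        fit = fit_apparent_t2(ph)
        assert fit.t2_apparent == pytest.approx(43.5, rel=1e-6)
        assert fit.s0_hat == pytest.approx(1000.0, rel=1e-6)

    def test_two_point_closed_form_exact(self):
        series = SignalSeries(
            te_ms=np.array([24.0, 48.0]),
            intensity=np.array([100.0, 100.0 / np.e]),
        )
        fit = fit_apparent_t2(series)
        assert fit.t2_apparent == 24.0  # dTE / ln(S1/S2), bitwise
        assert fit.residual_norm == 0.0

    def test_noisy_recovery_within_two_ms(self, protocol):
        # 1% of S0 Gaussian noise on 5 echoes, true T2 = 40 ms; tolerance from
        # the Monte-Carlo spread of the monoexponential fit (median ~1 ms)
        errs = [
            abs(fit_apparent_t2(simulate_phantom(40.0, protocol, 0.01, seed)).t2_apparent - 40.0)
            for seed in range(25)
        ]
        assert np.median(errs) < 2.0

    def test_non_decaying_series_raises(self, protocol):
        flat = SignalSeries(
            te_ms=np.array(protocol.te_list), intensity=np.full(5, 100.0)
        )
        with pytest.raises(FitError):
            fit_apparent_t2(flat)
        rising = SignalSeries(te_ms=np.array([24.0, 48.0]), intensity=np.array([1.0, 2.0]))
        with pytest.raises(FitError):
            fit_apparent_t2(rising)


class TestCsOef:
    @pytest.mark.parametrize("oef_true", [0.73, 0.0, 1.0, 0.31])
    def test_noise_free_round_trip(self, protocol, table, oef_true):
        sig = cs_signal(oef_true, protocol, 500.0, table) if oef_true > 0 else \
            cs_signal(0.0, protocol, 500.0, table)
        est = fit_cs_oef(sig, protocol, table)
        assert est.oef_hat == pytest.approx(oef_true, abs=1e-6)
        assert est.source == "coronary_sinus"

    def test_boundary_solution_flagged(self, protocol, table):
        est = fit_cs_oef(cs_signal(0.0, protocol, 500.0, table), protocol, table)
        assert est.diagnostics["at_boundary"]

    def test_noisy_mean_unbiased_within_003(self, protocol, table):
        # 2% of S0 noise, 200 seeded replicates at OEF = 0.7: the mean estimate
        # stays within 0.03 of truth (single-replicate spread is ~0.07)
        clean = cs_signal(0.7, protocol, 1000.0, table)
        ests = [
            fit_cs_oef(_with_noise(clean, 20.0, seed, label="cs"), protocol, table).oef_hat
            for seed in range(200)
        ]
        assert abs(np.mean(ests) - 0.7) < 0.03


class TestRestCalibration:
    def test_noise_free_round_trip_recovers_r20t_r21t(self, myo_rest_clean, protocol, table):
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        assert cal.r20t_hat == pytest.approx(24.5, rel=1e-3)
        assert cal.r21t_hat == pytest.approx(1.06e5, rel=1e-3)
        assert cal.fit_r_squared > 0.999999
        assert cal.warnings == ()

    def test_degenerate_diffusion_term(self, protocol, table):
        state = TissueState(oef=0.73, mbv=0.06, r20t=24.5, r21t=0.0)
        sig = voxel_signal(state, protocol, 1000.0, table)
        cal = calibrate_rest(sig, 0.73, 0.06, protocol, table)
        assert cal.r20t_hat == pytest.approx(24.5, rel=1e-4)
        assert abs(cal.r21t_hat) < 1e-3 * 1.06e5

    def test_apparent_mode_available_but_biased(self, myo_rest_clean, protocol, table):
        cal = calibrate_rest(
            myo_rest_clean, 0.73, 0.06, protocol, table, s0_mode="apparent"
        )
        # intercept still close; the smoothed representation mostly distorts the slope
        assert cal.r20t_hat == pytest.approx(24.5, rel=5e-3)

    def test_noisy_median_r20t_within_5pct(self, protocol, table):
        # 1% of S0 noise, 100 seeded replicates: median R20t within 5% of truth
        r20s = []
        for seed in range(100):
            b = simulate_session(SimulationConfig(seed=seed, noise_sigma=0.01))
            cal = calibrate_rest(b.myo_rest, 0.73, 0.06, protocol, table)
            r20s.append(cal.r20t_hat)
        assert abs(np.median(r20s) / 24.5 - 1) < 0.05

    def test_blood_term_exceeding_signal_fails_loudly(self, protocol, table):
        # absurd MBV makes the blood term larger than the total signal at
        # every echo -> calibration error naming the TE
        sig = voxel_signal(
            TissueState(oef=0.73, mbv=0.06, r20t=24.5, r21t=1.06e5),
            protocol, 1000.0, table,
        )
        shrunk = SignalSeries(te_ms=sig.te_ms, intensity=sig.intensity * 0.2)
        with pytest.raises(CalibrationError, match="TE"):
            calibrate_rest(shrunk, 0.73, 0.9, protocol, table, s0_mode="apparent")


class TestStressOef:
    def test_noise_free_round_trip(self, myo_rest_clean, myo_stress_clean, protocol, table):
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        est = fit_stress_oef(myo_stress_clean, cal, 0.10, protocol, table)
        assert est.oef_hat == pytest.approx(0.37, abs=1e-4)

    def test_boundary_truth_recovered(self, myo_rest_clean, protocol, table):
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        state = TissueState(oef=1.0, mbv=0.10, r20t=cal.r20t_hat, r21t=max(cal.r21t_hat, 0))
        sig = voxel_signal(state, protocol, 1000.0, table, condition="stress")
        est = fit_stress_oef(sig, cal, 0.10, protocol, table)
        assert est.oef_hat == pytest.approx(1.0, abs=1e-4)

    def test_forward_map_monotone_decreasing(self, myo_rest_clean, protocol, table):
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        grid = np.linspace(0, 1, 11)
        t2s = [stress_forward_t2(g, cal, 0.10, protocol, table) for g in grid]
        assert np.all(np.diff(t2s) < 0)

    def test_larger_measured_t2_gives_smaller_oef(self, myo_rest_clean, protocol, table):
        # the BOLD direction: hyperemic T2 rises as extraction falls
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        ests = []
        for oef_true in (0.6, 0.4, 0.2):
            state = TissueState(oef=oef_true, mbv=0.10, r20t=24.5, r21t=1.06e5)
            sig = voxel_signal(state, protocol, 1000.0, table, condition="stress")
            t2 = fit_apparent_t2(sig).t2_apparent
            est = fit_stress_oef(sig, cal, 0.10, protocol, table)
            ests.append((t2, est.oef_hat))
        t2s, oefs = zip(*ests)
        assert np.all(np.diff(t2s) > 0) and np.all(np.diff(oefs) < 0)

    def test_unattainable_t2_reports_interval(self, myo_rest_clean, protocol, table):
        cal = calibrate_rest(myo_rest_clean, 0.73, 0.06, protocol, table)
        # a series decaying far too slowly for any OEF in [0, 1]
        slow = SignalSeries(
            te_ms=np.array([24.0, 36.0, 48.0, 60.0, 72.0]),
            intensity=1000.0 * np.exp(-np.array([24, 36, 48, 60, 72]) / 90.0),
            condition="stress",
        )
        with pytest.raises(NoSolutionError) as exc:
            fit_stress_oef(slow, cal, 0.10, protocol, table)
        lo, hi = exc.value.attainable
        assert lo < hi < 90.0


class TestEndToEndRoundTrip:
    def test_full_chain_noise_free(self, clean_session, protocol, table):
        b = clean_session
        oef_rest = fit_cs_oef(b.cs_rest, protocol, table)
        cal = calibrate_rest(
            b.myo_rest, oef_rest.oef_hat, b.truth["mbv_rest"], protocol, table
        )
        est = fit_stress_oef(b.myo_stress, cal, b.truth["mbv_stress"], protocol, table)
        assert oef_rest.oef_hat == pytest.approx(b.truth["oef_rest"], abs=1e-6)
        assert cal.r20t_hat == pytest.approx(b.truth["r20t"], rel=1e-3)
        assert cal.r21t_hat == pytest.approx(b.truth["r21t"], rel=1e-3)
        assert est.oef_hat == pytest.approx(b.truth["oef_stress"], abs=1e-4)
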