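"""Mitochondrial calibration, content, CRC, influx and respirometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioquant import synthetic as syn
from cardioquant.io import Event, Trace
from cardioquant.mito import (
    Calibration,
    crc_analysis,
    fluorescence_at,
    free_calcium,
    influx_rate,
    mito_ca_content,
    respirometry,
)


class TestFreeCalcium:
    def test_fmin_maps_to_zero(self):
        cal = Calibration(fmax=900.0, fmin=100.0)
        assert free_calcium(100.0, cal) == 0.0

    def test_midpoint_returns_kd(self):
        # at F = (Fmin+Fmax)/2 the ratio (F-Fmin)/(Fmax-F) is 1, so the
        # equation returns exactly Kd = 335 nmol/L
        cal = Calibration(fmax=900.0, fmin=100.0)
        assert free_calcium(500.0, cal) == pytest.approx(335.0)

    def test_direct_arithmetic(self):
        cal = Calibration(fmax=900.0, fmin=0.0)
        assert free_calcium(600.0, cal) == pytest.approx(2.0 * 335.0)

    def test_saturation_errors(self):
        cal = Calibration(fmax=900.0, fmin=100.0)
        with pytest.raises(ValueError, match="saturated"):
            free_calcium(900.0, cal)

    def test_below_fmin_clamp_or_error(self):
        cal = Calibration(fmax=900.0, fmin=100.0)
        with pytest.raises(ValueError, match="below fmin"):
            free_calcium(50.0, cal)
        with pytest.warns(UserWarning):
            assert free_calcium(50.0, cal, clamp_below_fmin=True) == 0.0

    def test_monotone_in_fluorescence(self):
        cal = Calibration(fmax=900.0, fmin=100.0)
        f = np.linspace(100.0, 899.0, 200)
        ca = free_calcium(f, cal)
        assert np.all(np.diff(ca) > 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ca=st.floats(0.0, 1e5), kd=st.floats(1.0, 1e4),
           fmin=st.floats(0.0, 100.0), span=st.floats(1.0, 1e4))
    def test_roundtrip_inverse(self, ca, kd, fmin, span):
        cal = Calibration(fmax=fmin + span, fmin=fmin, kd=kd)
        back = free_calcium(fluorescence_at(ca, cal), cal)
        assert back == pytest.approx(ca, rel=1e-9, abs=1e-9)

    def test_invalid_calibration(self):
        with pytest.raises(ValueError):
            Calibration(fmax=100.0, fmin=100.0)
        with pytest.raises(ValueError):
            Calibration(fmax=200.0, fmin=100.0, kd=0.0)


def _content_trace(ca_baseline=100.0, ca_released=500.0,
                   fmax=1000.0, fmin=100.0):
    cal = Calibration(fmax=fmax, fmin=fmin)
    t = np.arange(0.0, 400.0, 1.0)
    v = np.empty_like(t)
    v[t < 100.0] = fluorescence_at(ca_baseline, cal)
    v[(t >= 100.0) & (t < 200.0)] = fluorescence_at(ca_released, cal)
    v[(t >= 200.0) & (t < 300.0)] = fmax
    v[t >= 300.0] = fmin
    events = [Event(100.0, "FCCP"), Event(200.0, "CaCl2_max"),
              Event(300.0, "EGTA_min")]
    return Trace(t, v, events)


class TestMitoCaContent:
    def test_constructed_release_per_mg(self):
        trace = _content_trace(ca_baseline=100.0, ca_released=500.0)
        res = mito_ca_content(trace, protein_mg=0.2)
        assert res.content_per_mg == pytest.approx(
            (res.free_ca_released_nM - res.free_ca_baseline_nM) / 0.2)
        # plateau-read calibration reproduces the configured free Ca2+
        assert res.free_ca_baseline_nM == pytest.approx(100.0, rel=0.02)
        assert res.free_ca_released_nM == pytest.approx(500.0, rel=0.02)

    def test_no_release_gives_zero_content(self):
        trace = _content_trace(ca_baseline=200.0, ca_released=200.0)
        res = mito_ca_content(trace, protein_mg=1.0)
        assert res.content_per_mg == pytest.approx(0.0, abs=1e-9)

    def test_doubling_protein_halves_content(self):
        trace = _content_trace()
        a = mito_ca_content(trace, protein_mg=0.1)
        b = mito_ca_content(trace, protein_mg=0.2)
        assert a.content_per_mg == pytest.approx(2.0 * b.content_per_mg)

    def test_missing_additions_listed(self):
        trace = _content_trace()
        trace.events = [e for e in trace.events if e.label != "EGTA_min"]
        with pytest.raises(ValueError, match="EGTA_min"):
            mito_ca_content(trace, protein_mg=1.0)


class TestCrc:
    def test_generator_release_index_minus_one(self):
        trace, truth = syn.simulate_crc_trace(release_at_pulse=7,
                                              noise_sd=0.0)
        res = crc_analysis(trace, protein_mg=1.0)
        assert res.pulses_tolerated == 6
        assert not res.censored
        assert res.mptp_time_s is not None

    def test_all_recover_is_censored(self):
        trace, _ = syn.simulate_crc_trace(release_at_pulse=None,
                                          n_pulses=10, noise_sd=0.0)
        res = crc_analysis(trace, protein_mg=1.0)
        assert res.censored
        assert res.pulses_tolerated == 10
        assert res.cumulative_ca == pytest.approx(100.0)

    def test_cumulative_arithmetic(self):
        trace, _ = syn.simulate_crc_trace(release_at_pulse=7,
                                          pulse_amount_uM=10.0,
                                          noise_sd=0.0)
        res = crc_analysis(trace, protein_mg=1.0)
        assert res.cumulative_ca == pytest.approx(60.0)

    def test_affine_invariance(self):
        trace, _ = syn.simulate_crc_trace(release_at_pulse=5, noise_sd=1.0,
                                          seed=3)
        scaled = Trace(trace.time, 3.5 * trace.value + 200.0, trace.events)
        a = crc_analysis(trace, protein_mg=1.0)
        b = crc_analysis(scaled, protein_mg=1.0)
        assert a.pulses_tolerated == b.pulses_tolerated
        assert a.censored == b.censored

    def test_no_pulses_errors(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError, match="no pulse"):
            crc_analysis(Trace(t, np.ones_like(t)), pulse_amount=10.0)


class TestInfluxRate:
    @pytest.mark.parametrize("window", [(60.0, 80.0), (60.0, 100.0),
                                        (65.0, 95.0)])
    def test_exact_on_pure_quadratic_any_window(self, window):
        trace, _ = syn.simulate_influx_trace(curvature=0.5,
                                             initial_rate=50.0,
                                             noise_sd=0.0)
        rate, r2 = influx_rate(trace, window)
        # |b| at the window start: the derivative changes with the
        # re-zeroed origin, 2*a*(t0-60) less than at energization
        t0 = window[0]
        expected = abs(-50.0 + 2.0 * 0.5 * (t0 - 60.0))
        assert rate == pytest.approx(expected, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_signal_zero_rate(self):
        t = np.arange(0.0, 100.0, 0.5)
        trace = Trace(t, np.full_like(t, 123.0))
        rate, _ = influx_rate(trace, (10.0, 50.0))
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_median_under_10pct(self):
        errs = []
        for seed in range(30):
            trace, _ = syn.simulate_influx_trace(noise_sd=5.0, seed=seed)
            rate, _ = influx_rate(trace, (60.0, 100.0))
            errs.append(abs(rate - 50.0) / 50.0)
        assert np.median(errs) < 0.10

    def test_short_window_errors(self):
        trace, _ = syn.simulate_influx_trace(noise_sd=0.0)
        with pytest.raises(ValueError, match="5 samples"):
            influx_rate(trace, (60.0, 61.0))


class TestRespirometry:
    def test_constructed_respiratory_control(self):
        trace, _ = syn.simulate_o2_trace(flux_routine=20.0,
                                         flux_state3=100.0,
                                         flux_uncoupled=120.0,
                                         noise_sd=0.0)
        rr = respirometry(trace, protein_mg=1.0)
        assert rr.respiratory_control == pytest.approx(5.0, rel=1e-9)
        assert rr.routine == pytest.approx(20.0, rel=1e-9)
        assert rr.uncoupled == pytest.approx(120.0, rel=1e-9)

    def test_equal_fluxes_give_rc_one(self):
        trace, _ = syn.simulate_o2_trace(flux_routine=50.0,
                                         flux_state3=50.0,
                                         flux_uncoupled=50.0,
                                         noise_sd=0.0)
        rr = respirometry(trace)
        assert rr.respiratory_control == pytest.approx(1.0, rel=1e-9)

    def test_noisy_flux_recovery_within_5pct(self):
        trace, _ = syn.simulate_o2_trace(noise_sd=20.0, seed=1)
        rr = respirometry(trace)
        assert rr.routine == pytest.approx(20.0, rel=0.05)
        assert rr.state3 == pytest.approx(100.0, rel=0.05)
        assert rr.uncoupled == pytest.approx(120.0, rel=0.05)

    def test_per_mg_scaling(self):
        trace, _ = syn.simulate_o2_trace(noise_sd=0.0)
        a = respirometry(trace, protein_mg=0.5)
        b = respirometry(trace, protein_mg=1.0)
        assert a.state3 == pytest.approx(2.0 * b.state3)
        assert a.respiratory_control == pytest.approx(b.respiratory_control)
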