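"""Generator construction guarantees: exact ground truth, determinism."""

import numpy as np
import pytest

from cardioquant import synthetic as syn


class TestDeterminism:
    @pytest.mark.parametrize("gen,kwargs", [
        (syn.simulate_transient_train, {"pacing_hz": 1, "n_beats": 3,
                                        "noise_sd": 1.0}),
        (syn.simulate_shortening_train, {"pacing_hz": 1, "n_beats": 3,
                                         "noise_sd": 0.2}),
        (syn.simulate_crc_trace, {"noise_sd": 1.0}),
        (syn.simulate_influx_trace, {"noise_sd": 2.0}),
        (syn.simulate_o2_trace, {"noise_sd": 5.0}),
    ])
    def test_same_seed_bit_identical_traces(self, gen, kwargs):
        a, _ = gen(seed=42, **kwargs)
        b, _ = gen(seed=42, **kwargs)
        assert np.array_equal(a.value, b.value)

    def test_linescan_same_seed_identical_event_list(self):
        a, ta = syn.simulate_linescan(seed=7)
        b, tb = syn.simulate_linescan(seed=7)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(ta["centers_um"], tb["centers_um"])
        assert np.array_equal(ta["centers_ms"], tb["centers_ms"])

    def test_changing_seed_changes_noise_not_truth(self):
        _, ta = syn.simulate_transient_train(1, 3, noise_sd=1.0, seed=1)
        _, tb = syn.simulate_transient_train(1, 3, noise_sd=1.0, seed=2)
        for key in ("tau_ms", "amplitude_dff0", "ttp_ms", "f0"):
            assert ta[key] == tb[key]

    def test_assay_streams_are_independent(self):
        # same global seed, different assays: distinct noise streams
        a, _ = syn.simulate_transient_train(1, 1, noise_sd=1.0, seed=5)
        b, _ = syn.simulate_shortening_train(1, 1, noise_sd=1.0, seed=5)
        n = min(a.value.size, b.value.size)
        assert not np.array_equal(a.value[:n] - a.value[:n].round(),
                                  b.value[:n] - b.value[:n].round())


class TestTransientTrain:
    def test_noiseless_peak_is_exact(self):
        trace, truth = syn.simulate_transient_train(
            0.5, 3, f0=1.0, amplitude_dff0=1.0, noise_sd=0.0)
        dff0 = (trace.value - 1.0) / 1.0
        assert dff0.max() == pytest.approx(1.0, abs=1e-12)

    def test_stimulus_events_match_truth(self):
        trace, truth = syn.simulate_transient_train(2.0, 4, tau_ms=100.0,
                                                    noise_sd=0.0)
        np.testing.assert_allclose(trace.event_times("stimulus"),
                                   truth["stimulus_times_ms"])

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            syn.simulate_transient_train(1, 3, amplitude_dff0=-1.0)
        with pytest.raises(ValueError):
            syn.simulate_transient_train(1, 3, tau_ms=0.0)
        with pytest.raises(ValueError):
            syn.simulate_transient_train(1, 3, f0=0.0)

    def test_overlapping_beats_warn(self):
        with pytest.warns(UserWarning, match="overlap"):
            syn.simulate_transient_train(5.0, 3, ttp_ms=50, tau_ms=200)


class TestShorteningTrain:
    def test_noiseless_minimum_exact(self):
        trace, _ = syn.simulate_shortening_train(
            0.5, 3, resting_length_um=100.0, max_shortening_pct=10.0,
            noise_sd=0.0)
        assert trace.value.min() == pytest.approx(90.0, abs=1e-9)

    def test_zero_beats_flat_trace_no_events(self):
        trace, truth = syn.simulate_shortening_train(
            0.5, 0, resting_length_um=100.0, noise_sd=0.0)
        assert trace.events == []
        np.testing.assert_allclose(trace.value, 100.0)

    def test_invalid_shortening_pct(self):
        with pytest.raises(ValueError):
            syn.simulate_shortening_train(1, 3, max_shortening_pct=120.0)


class TestLineScan:
    def test_zero_rate_gives_baseline_plus_noise(self):
        scan, truth = syn.simulate_linescan(
            spark_rate_per_100um_s=0.0, f0=1000.0, noise_sd=10.0, seed=1)
        assert truth["n_sparks"] == 0
        assert abs(scan.intensity.mean() - 1000.0) < 1.0

    def test_planted_count_frequency_arithmetic(self):
        scan, truth = syn.simulate_linescan(
            length_um=50.0, duration_s=2.0, n_sparks=5, seed=0)
        assert truth["true_frequency_per_100um_s"] == pytest.approx(
            5.0 / (0.5 * 2.0))

    def test_high_density_warns(self):
        with pytest.warns(UserWarning, match="event-covered"):
            syn.simulate_linescan(length_um=20.0, duration_s=0.5,
                                  n_sparks=200, spark_fwhm_um=5.0,
                                  spark_half_time_ms=100.0, seed=0)


class TestCrcTrace:
    def test_pulse_events_and_tolerated_truth(self):
        trace, truth = syn.simulate_crc_trace(release_at_pulse=7,
                                              noise_sd=0.0)
        assert len(trace.event_times("pulse")) == 7
        assert truth["pulses_tolerated"] == 6
        assert not truth["censored"]

    def test_censored_when_no_release(self):
        trace, truth = syn.simulate_crc_trace(release_at_pulse=None,
                                              n_pulses=10, noise_sd=0.0)
        assert truth["censored"]
        assert truth["pulses_tolerated"] == 10

    def test_cumulative_arithmetic(self):
        _, truth = syn.simulate_crc_trace(pulse_amount_uM=10.0,
                                          release_at_pulse=7)
        assert truth["pulses_tolerated"] * truth["pulse_amount_uM"] == 60.0

    def test_invalid_release_index(self):
        with pytest.raises(ValueError):
            syn.simulate_crc_trace(release_at_pulse=0)


class TestInfluxTrace:
    def test_quadratic_is_exact_in_window(self):
        trace, truth = syn.simulate_influx_trace(
            curvature=0.5, initial_rate=50.0, baseline_f=1000.0,
            energize_time_s=60.0, window_s=40.0, noise_sd=0.0)
        i0 = trace.index_at(60.0)
        tp = trace.time[i0:] - 60.0
        expected = 1000.0 - 50.0 * tp + 0.5 * tp**2
        in_win = tp <= 40.0
        np.testing.assert_allclose(trace.value[i0:][in_win],
                                   expected[in_win], rtol=1e-12)


class TestO2Trace:
    def test_segment_slopes_match_fluxes(self):
        trace, truth = syn.simulate_o2_trace(
            flux_routine=20.0, flux_state3=100.0, flux_uncoupled=120.0,
            noise_sd=0.0)
        for label, flux in (("substrate", 20.0), ("ADP", 100.0),
                            ("FCCP", 120.0)):
            t0 = trace.event_times(label)[0]
            i0 = trace.index_at(t0) + 2
            slope = (trace.value[i0 + 10] - trace.value[i0]) / (
                trace.time[i0 + 10] - trace.time[i0])
            assert slope == pytest.approx(-flux, rel=1e-9)
        assert truth["respiratory_control"] == pytest.approx(5.0)


class TestPvOcclusion:
    def test_steady_state_truth_identities(self):
        _, truth = syn.simulate_pv_occlusion(edv_ul=50.0, esv_ul=20.0,
                                             hr_bpm=600.0)
        assert truth["sv_ul"] == 30.0
        assert truth["ef_pct"] == 60.0
        assert truth["co_ul_min"] == 18000.0

    def test_es_ed_points_lie_on_configured_lines(self):
        _, truth = syn.simulate_pv_occlusion(espvr_slope=2.0,
                                             edpvr_slope=0.25, v0_ul=1.5)
        for v, p in truth["es_points"]:
            assert p == pytest.approx(2.0 * (v - 1.5), rel=1e-12)
        for v, p in truth["ed_points"]:
            assert p == pytest.approx(0.25 * (v - 1.5), rel=1e-12)

    def test_signals_are_continuous(self):
        series, _ = syn.simulate_pv_occlusion()
        assert np.max(np.abs(np.diff(series.volume))) < 1.5
        assert np.max(np.abs(np.diff(series.pressure))) < 5.0

    def test_excessive_occlusion_raises(self):
        with pytest.raises(ValueError, match="v0"):
            syn.simulate_pv_occlusion(n_beats_occlusion=40,
                                      preload_step_ul=2.0)


class TestHistology:
    def test_fractions_exact_up_to_rounding(self):
        _, truth = syn.simulate_histology(frac_blue=0.3, frac_red=0.6)
        assert truth["frac_blue"] == pytest.approx(0.3, abs=1e-4)
        assert truth["frac_red"] == pytest.approx(0.6, abs=1e-4)
        assert truth["fibrotic_index"] == pytest.approx(0.5, abs=1e-3)

    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError):
            syn.simulate_histology(frac_blue=0.7, frac_red=0.6)

    def test_cell_image_truth_areas_are_analytic(self):
        _, truth = syn.simulate_cell_image(
            cells=[{"cx": 50, "cy": 50, "a": 10.0, "b": 12.5}])
        assert truth["areas_um2"][0] == pytest.approx(np.pi * 10.0 * 12.5)


class TestQpcr:
    def test_zero_fold_change_gives_fold_one(self):
        table, truth = syn.simulate_qpcr(
            log2_fold_changes={"CTRL": 0.0, "X": 0.0}, ct_sd=0.0)
        assert truth["fold_changes"]["X"] == 1.0

    def test_log2_fold_one_is_exactly_two_noiseless(self):
        table, truth = syn.simulate_qpcr(
            log2_fold_changes={"CTRL": 0.0, "X": 1.0}, ct_sd=0.0)
        sub = table[(table["group"] == "X") & (table["gene"] != "Gapdh")]
        hk = table[(table["group"] == "X") & (table["gene"] == "Gapdh")]
        dct = sub["ct"].to_numpy() - hk["ct"].to_numpy()
        assert np.allclose(2.0 ** -(dct - 3.0), 2.0)

    def test_every_sample_has_housekeeping(self):
        table, _ = syn.simulate_qpcr()
        hk = set(table[table["gene"] == "Gapdh"]["sample"])
        assert set(table["sample"]) == hk
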