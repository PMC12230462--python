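"""Synthetic data generators with known ground truth.

Every input modality the analysis modules consume can be generated here
with configurable true parameters and additive Gaussian noise, so each
downstream stage is testable by parameter recovery without any external
recordings.  Each generator returns ``(data, truth)`` where ``truth`` is
a JSON-serializable dict of the parameters actually used (including the
exact planted event lists where applicable).

Reproducibility: one global integer seed is split into independent
per-assay streams via :class:`numpy.random.SeedSequence`, so re-running
a single assay reproduces it bit-identically regardless of what else
was generated.

Deliberate simplifications (no biophysical ODE models, no
photobleaching or motion artifacts): signal shapes are the minimal
smooth forms consistent with the quantities the analyzers measure —
half-sine rises, mono-exponential decays, separable Gaussian sparks,
piecewise-linear O2 depletion, a time-varying-elastance PV loop.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import Event, LineScan, PvSeries, Trace

__all__ = [
    "simulate_transient_train",
    "simulate_shortening_train",
    "simulate_linescan",
    "simulate_crc_trace",
    "simulate_influx_trace",
    "simulate_o2_trace",
    "simulate_pv_occlusion",
    "simulate_histology",
    "simulate_cell_image",
    "simulate_qpcr",
]

# Stable stream ids so a fixed global seed reproduces each assay
# independently of generation order.
_STREAMS = {
    "transient": 1,
    "shortening": 2,
    "linescan": 3,
    "crc": 4,
    "influx": 5,
    "o2": 6,
    "pv": 7,
    "histology": 8,
    "cells": 9,
    "qpcr": 10,
}


def _rng(seed: int, assay: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[assay],))
    )


# ---------------------------------------------------------------------------
# Ca2+ transients and cell shortening
# ---------------------------------------------------------------------------

def _beat_waveform(t_ms: np.ndarray, ttp_ms: float, tau_ms: float) -> np.ndarray:
    """Unit-amplitude beat: half-sine rise over ttp, exp decay with tau.

    Defined for t >= 0 relative to the stimulus; 0 before the stimulus.
    """
    w = np.zeros_like(t_ms)
    rise = (t_ms >= 0) & (t_ms < ttp_ms)
    w[rise] = np.sin(0.5 * np.pi * t_ms[rise] / ttp_ms)
    fall = t_ms >= ttp_ms
    w[fall] = np.exp(-(t_ms[fall] - ttp_ms) / tau_ms)
    return w


def simulate_transient_train(
    pacing_hz: float = 1.0,
    n_beats: int = 10,
    f0: float = 100.0,
    amplitude_dff0: float = 1.0,
    ttp_ms: float = 50.0,
    tau_ms: float = 200.0,
    sampling_interval_ms: float = 1.0,
    noise_sd: float = 0.0,
    lead_in_ms: float = 300.0,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """Paced Ca2+ fluorescence transient train.

    Each beat rises from baseline ``f0`` to ``f0*(1+amplitude_dff0)``
    along a half-sine over ``ttp_ms``, then decays mono-exponentially
    with time constant ``tau_ms`` toward ``f0``.  Beats are piecewise:
    each pacing interval carries only its own beat (the recommended
    pacing period > ttp + 3*tau keeps the residual tail negligible
    anyway).  Stimulus times are annotated as events.
    """
    if amplitude_dff0 <= 0 or tau_ms <= 0 or ttp_ms <= 0:
        raise ValueError("amplitude, ttp and tau must be positive")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    period_ms = 1000.0 / pacing_hz
    if n_beats > 0 and period_ms <= ttp_ms + 3.0 * tau_ms:
        warnings.warn(
            "pacing period <= ttp + 3*tau: beats overlap, baseline recovery "
            "is incomplete", stacklevel=2,
        )
    duration = lead_in_ms + max(n_beats, 1) * period_ms
    t = np.arange(0.0, duration, sampling_interval_ms)
    stim_times = lead_in_ms + period_ms * np.arange(n_beats)
    value = np.full_like(t, f0)
    for s in stim_times:
        in_beat = (t >= s) & (t < s + period_ms)
        value[in_beat] += amplitude_dff0 * f0 * _beat_waveform(
            t[in_beat] - s, ttp_ms, tau_ms
        )
    rng = _rng(seed, "transient")
    value = value + rng.normal(0.0, noise_sd, size=t.shape)
    events = [Event(float(s), "stimulus") for s in stim_times]
    truth = {
        "assay": "transient",
        "pacing_hz": pacing_hz,
        "n_beats": n_beats,
        "f0": f0,
        "amplitude_dff0": amplitude_dff0,
        "ttp_ms": ttp_ms,
        # time to peak as analyzers measure it: from the 10%-amplitude
        # onset of the half-sine rise, not from the stimulus
        "ttp_from_onset_ms": float(
            ttp_ms * (1.0 - 2.0 * np.arcsin(0.1) / np.pi)
        ),
        "tau_ms": tau_ms,
        "t50_ms": float(np.log(2.0) * tau_ms),
        "stimulus_times_ms": stim_times,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(t, value, events), truth


def simulate_shortening_train(
    pacing_hz: float = 1.0,
    n_beats: int = 10,
    resting_length_um: float = 120.0,
    max_shortening_pct: float = 10.0,
    ttps_ms: float = 80.0,
    tthr_ms: float = 150.0,
    sampling_interval_ms: float = 1.0,
    noise_sd: float = 0.0,
    lead_in_ms: float = 300.0,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """Paced cell-length train.

    Each beat dips from ``resting_length_um`` by
    ``max_shortening_pct/100 * resting_length_um``: a half-sine
    contraction reaching the minimum ``ttps_ms`` after the stimulus,
    then an exponential relaxation that crosses 50% length recovery
    exactly ``tthr_ms`` after the minimum.  Zero beats yields a flat
    trace at resting length with no events.
    """
    if not (0 < max_shortening_pct < 100):
        raise ValueError("max_shortening_pct must be in (0, 100)")
    if ttps_ms <= 0 or tthr_ms <= 0 or resting_length_um <= 0:
        raise ValueError("resting length, ttps and tthr must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    period_ms = 1000.0 / pacing_hz
    depth = max_shortening_pct / 100.0 * resting_length_um
    duration = lead_in_ms + max(n_beats, 1) * period_ms
    t = np.arange(0.0, duration, sampling_interval_ms)
    stim_times = lead_in_ms + period_ms * np.arange(n_beats)
    value = np.full_like(t, resting_length_um)
    # relaxation: depth*exp(-ln2 * dt/tthr) crosses depth/2 at dt = tthr
    lam = np.log(2.0) / tthr_ms
    for s in stim_times:
        in_beat = (t >= s) & (t < s + period_ms)
        tb = t[in_beat] - s
        dip = np.where(
            tb < ttps_ms,
            depth * np.sin(0.5 * np.pi * tb / ttps_ms),
            depth * np.exp(-lam * (tb - ttps_ms)),
        )
        value[in_beat] -= dip
    rng = _rng(seed, "shortening")
    value = value + rng.normal(0.0, noise_sd, size=t.shape)
    events = [Event(float(s), "stimulus") for s in stim_times]
    truth = {
        "assay": "shortening",
        "pacing_hz": pacing_hz,
        "n_beats": n_beats,
        "resting_length_um": resting_length_um,
        "max_shortening_pct": max_shortening_pct,
        "max_shortening_um": depth,
        "ttps_ms": ttps_ms,
        "ttps_from_onset_ms": float(
            ttps_ms * (1.0 - 2.0 * np.arcsin(0.1) / np.pi)
        ),
        "tthr_ms": tthr_ms,
        "stimulus_times_ms": stim_times,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(t, value, events), truth


# ---------------------------------------------------------------------------
# Line-scan Ca2+ sparks
# ---------------------------------------------------------------------------

def simulate_linescan(
    length_um: float = 50.0,
    pixel_um: float = 0.1,
    duration_s: float = 2.0,
    line_period_ms: float = 2.0,
    spark_rate_per_100um_s: float = 2.0,
    spark_amp_dff0: float = 1.0,
    spark_fwhm_um: float = 2.0,
    spark_half_time_ms: float = 20.0,
    f0: float = 1000.0,
    noise_sd: float = 50.0,
    n_sparks: int | None = None,
    seed: int = 0,
) -> tuple[LineScan, dict]:
    """Confocal line scan with Poisson-planted Ca2+ sparks.

    Sparks are separable: a Gaussian in space (FWHM ``spark_fwhm_um``)
    times an instantaneous-rise / exponential-fall kernel in time (half
    time ``spark_half_time_ms``), superposed multiplicatively on the
    baseline ``f0`` (amplitude in dF/F0 units) with additive Gaussian
    noise (in raw fluorescence units).  ``n_sparks`` overrides the
    Poisson draw with an exact planted count.  The true event list is
    returned in the ground truth.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed, "linescan")
    nx = int(round(length_um / pixel_um))
    nt = int(round(duration_s * 1000.0 / line_period_ms))
    x_um = (np.arange(nx) + 0.5) * pixel_um
    t_ms = (np.arange(nt) + 0.5) * line_period_ms

    expected = spark_rate_per_100um_s * (length_um / 100.0) * duration_s
    k = int(rng.poisson(expected)) if n_sparks is None else int(n_sparks)
    centers_x = rng.uniform(0.0, length_um, size=k)
    centers_t = rng.uniform(0.0, duration_s * 1000.0, size=k)
    order = np.argsort(centers_t)
    centers_x, centers_t = centers_x[order], centers_t[order]

    sigma_um = spark_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    dff0 = np.zeros((nx, nt))
    for cx, ct in zip(centers_x, centers_t):
        sp = np.exp(-0.5 * ((x_um - cx) / sigma_um) ** 2)
        tp = np.where(
            t_ms >= ct,
            np.exp(-np.log(2.0) * (t_ms - ct) / spark_half_time_ms),
            0.0,
        )
        dff0 += spark_amp_dff0 * np.outer(sp, tp)
    covered = np.mean(dff0 > 0.05 * spark_amp_dff0) if k else 0.0
    if covered > 0.5:
        warnings.warn(
            "more than 50% of pixels are event-covered; spark detection "
            "validity is compromised at this density", stacklevel=2,
        )
    img = f0 * (1.0 + dff0) + rng.normal(0.0, noise_sd, size=(nx, nt))
    scan = LineScan(img, pixel_um, line_period_ms, cell_extent_um=length_um)
    truth = {
        "assay": "linescan",
        "n_sparks": k,
        "centers_um": centers_x,
        "centers_ms": centers_t,
        "spark_amp_dff0": spark_amp_dff0,
        "spark_fwhm_um": spark_fwhm_um,
        "spark_half_time_ms": spark_half_time_ms,
        "spark_rate_per_100um_s": spark_rate_per_100um_s,
        "true_frequency_per_100um_s": k / (length_um / 100.0) / duration_s,
        "f0": f0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return scan, truth


# ---------------------------------------------------------------------------
# Mitochondrial fluorometry
# ---------------------------------------------------------------------------

def simulate_crc_trace(
    pulse_amount_uM: float = 10.0,
    pulse_interval_s: float = 180.0,
    n_pulses: int = 10,
    release_at_pulse: int | None = 7,
    uptake_tau_s: float = 30.0,
    release_rate_per_s: float = 2.0,
    baseline_f: float = 100.0,
    f_per_uM: float = 10.0,
    sampling_interval_s: float = 1.0,
    noise_sd: float = 0.0,
    lead_in_s: float = 60.0,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """Ca2+ retention capacity trace (extramitochondrial Ca2+ indicator).

    Ca2+ pulses of ``pulse_amount_uM`` are added every
    ``pulse_interval_s``: each produces a fluorescence step of
    ``pulse_amount_uM * f_per_uM`` followed by exponential re-uptake
    toward baseline (tau ``uptake_tau_s``).  At 1-based pulse index
    ``release_at_pulse`` the pore opens: no re-uptake, and the signal
    rises monotonically (``release_rate_per_s`` F-units/s).  ``None``
    means every pulse recovers (a censored experiment).
    """
    if release_at_pulse is not None and release_at_pulse <= 0:
        raise ValueError("release_at_pulse must be a positive 1-based index")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_eff = n_pulses if release_at_pulse is None else min(n_pulses, release_at_pulse)
    duration = lead_in_s + n_eff * pulse_interval_s + pulse_interval_s
    t = np.arange(0.0, duration, sampling_interval_s)
    value = np.full_like(t, baseline_f)
    step = pulse_amount_uM * f_per_uM
    pulse_times = lead_in_s + pulse_interval_s * np.arange(n_eff)
    for i, pt in enumerate(pulse_times, start=1):
        after = t >= pt
        if release_at_pulse is not None and i == release_at_pulse:
            value[after] += step + release_rate_per_s * (t[after] - pt)
        else:
            value[after] += step * np.exp(-(t[after] - pt) / uptake_tau_s)
    rng = _rng(seed, "crc")
    value = value + rng.normal(0.0, noise_sd, size=t.shape)
    events = [
        Event(float(pt), "pulse", pulse_amount_uM) for pt in pulse_times
    ]
    truth = {
        "assay": "crc",
        "pulse_amount_uM": pulse_amount_uM,
        "pulse_interval_s": pulse_interval_s,
        "n_pulses_added": n_eff,
        "release_at_pulse": release_at_pulse,
        "pulses_tolerated": (
            n_eff if release_at_pulse is None or release_at_pulse > n_eff
            else release_at_pulse - 1
        ),
        "censored": release_at_pulse is None or release_at_pulse > n_eff,
        "uptake_tau_s": uptake_tau_s,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(t, value, events), truth


def simulate_influx_trace(
    bolus_uM: float = 40.0,
    energize_time_s: float = 60.0,
    initial_rate: float = 50.0,
    curvature: float = 0.5,
    baseline_f: float = 1000.0,
    window_s: float = 40.0,
    sampling_interval_s: float = 0.5,
    noise_sd: float = 0.0,
    lead_in_s: float = 30.0,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """Mitochondrial Ca2+ influx (uptake) trace.

    A Ca2+ bolus raises the indicator signal to ``baseline_f``; after
    the energizing substrate addition at ``energize_time_s`` the signal
    decays as ``F(t') = c + b t' + a t'^2`` with ``b = -initial_rate``
    and ``a = curvature`` over the analysis window, then holds.  The
    true initial uptake rate is ``|b|`` in F-units/s.
    """
    if initial_rate < 0:
        raise ValueError("initial_rate must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    duration = energize_time_s + window_s + 10.0
    t = np.arange(0.0, duration, sampling_interval_s)
    pre_bolus = baseline_f - bolus_uM * 10.0
    value = np.full_like(t, max(pre_bolus, 0.0))
    bolus_time = lead_in_s
    value[t >= bolus_time] = baseline_f
    tp = t - energize_time_s
    in_win = (tp >= 0) & (tp <= window_s)
    a, b, c = curvature, -initial_rate, baseline_f
    quad = c + b * tp + a * tp**2
    value[in_win] = quad[in_win]
    end_val = c + b * window_s + a * window_s**2
    value[tp > window_s] = end_val
    rng = _rng(seed, "influx")
    value = value + rng.normal(0.0, noise_sd, size=t.shape)
    events = [
        Event(float(bolus_time), "bolus", bolus_uM),
        Event(float(energize_time_s), "succinate"),
    ]
    truth = {
        "assay": "influx",
        "bolus_uM": bolus_uM,
        "energize_time_s": energize_time_s,
        "initial_rate": initial_rate,
        "curvature": curvature,
        "window_s": window_s,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(t, value, events), truth


def simulate_o2_trace(
    flux_routine: float = 20.0,
    flux_state3: float = 100.0,
    flux_uncoupled: float = 120.0,
    segment_s: float = 120.0,
    o2_start: float = 30000.0,
    sampling_interval_s: float = 1.0,
    noise_sd: float = 0.0,
    lead_in_s: float = 60.0,
    seed: int = 0,
) -> tuple[Trace, dict]:
    """High-resolution respirometry O2 concentration trace.

    Piecewise linear: flat before substrate, then segments whose
    negative slope equals the configured flux after each sequential
    addition — substrate (+rotenone) -> routine, ADP -> state 3,
    FCCP -> uncoupled.  Addition events mark the segment boundaries.
    O2 concentration and fluxes are in consistent instrument units
    (signal and signal/s); the respiratory control ratio is unitless
    either way.
    """
    for fx in (flux_routine, flux_state3, flux_uncoupled):
        if fx < 0:
            raise ValueError("fluxes must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t_sub = lead_in_s
    t_adp = t_sub + segment_s
    t_fccp = t_adp + segment_s
    duration = t_fccp + segment_s
    t = np.arange(0.0, duration, sampling_interval_s)
    value = np.full_like(t, o2_start)
    boundaries = [(t_sub, flux_routine), (t_adp, flux_state3), (t_fccp, flux_uncoupled)]
    level = o2_start
    prev_t = t_sub
    for i, (tb, flux) in enumerate(boundaries):
        t_end = boundaries[i + 1][0] if i + 1 < len(boundaries) else duration
        seg = (t >= tb) & (t < t_end)
        value[seg] = level - flux * (t[seg] - tb)
        level = level - flux * (t_end - tb)
        prev_t = t_end
    rng = _rng(seed, "o2")
    value = value + rng.normal(0.0, noise_sd, size=t.shape)
    events = [
        Event(float(t_sub), "substrate"),
        Event(float(t_adp), "ADP", 200.0),
        Event(float(t_fccp), "FCCP", 0.08),
    ]
    truth = {
        "assay": "o2",
        "flux_routine": flux_routine,
        "flux_state3": flux_state3,
        "flux_uncoupled": flux_uncoupled,
        "respiratory_control": (
            flux_state3 / flux_routine if flux_routine > 0 else float("nan")
        ),
        "segment_s": segment_s,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(t, value, events), truth


# ---------------------------------------------------------------------------
# Pressure-volume loops
# ---------------------------------------------------------------------------

def simulate_pv_occlusion(
    n_beats_steady: int = 5,
    n_beats_occlusion: int = 15,
    edv_ul: float = 50.0,
    esv_ul: float = 20.0,
    hr_bpm: float = 600.0,
    espvr_slope: float = 2.0,
    edpvr_slope: float = 0.25,
    v0_ul: float = 1.5,
    preload_step_ul: float = 1.2,
    sampling_interval_ms: float = 0.5,
    pressure_noise_sd: float = 0.0,
    volume_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PvSeries, dict]:
    """LV pressure-volume series: steady state then vena-cava occlusion.

    Each cycle follows a time-varying elastance model,
    ``P(t) = [Eed + e(t) (Ees - Eed)] (V(t) - V0)`` with activation
    ``e(t) = sin^2(pi t / T)`` peaking exactly when volume is minimal,
    so end-systolic points lie on ``P = Ees (V - V0)`` and end-diastolic
    points on ``P = Eed (V - V0)`` by construction.  During occlusion
    both EDV and ESV fall by ``preload_step_ul`` per beat — applied as a
    continuous ramp within each beat (filling is impeded gradually, and
    the recorded signals stay continuous) — sweeping the end-systolic
    and end-diastolic points down their respective lines.
    """
    if esv_ul >= edv_ul:
        raise ValueError("esv must be smaller than edv")
    if v0_ul >= esv_ul:
        raise ValueError("v0 must be below esv")
    period_ms = 60000.0 / hr_bpm
    n_per = int(round(period_ms / sampling_interval_ms))
    n_total = n_beats_steady + n_beats_occlusion
    min_drop = n_beats_occlusion * preload_step_ul
    if esv_ul - min_drop <= v0_ul:
        raise ValueError("occlusion would drive ESV at or below v0; reduce "
                         "n_beats_occlusion or preload_step_ul")
    sv = edv_ul - esv_ul
    phase = (np.arange(n_per) + 0.5) / n_per
    shape = np.sin(np.pi * phase) ** 2      # 0 at ED, 1 at ES
    time, pressure, volume = [], [], []
    ed_points, es_points = [], []
    for b in range(n_total):
        drop_start = preload_step_ul * max(0, b - n_beats_steady)
        drop_end = preload_step_ul * max(0, b + 1 - n_beats_steady)
        # preload falls linearly within the beat so V and P are
        # continuous across beat boundaries
        edv_b = edv_ul - (drop_start + (drop_end - drop_start) * phase)
        esv_b = esv_ul - (drop_start + (drop_end - drop_start) * phase)
        v = edv_b - (edv_b - esv_b) * shape
        elast = edpvr_slope + shape * (espvr_slope - edpvr_slope)
        p = elast * (v - v0_ul)
        t0 = b * period_ms
        time.append(t0 + phase * period_ms)
        pressure.append(p)
        volume.append(v)
        edv_at_start = edv_ul - drop_start
        esv_at_mid = esv_ul - 0.5 * (drop_start + drop_end)
        ed_points.append((edv_at_start,
                          edpvr_slope * (edv_at_start - v0_ul)))
        es_points.append((esv_at_mid, espvr_slope * (esv_at_mid - v0_ul)))
    time = np.concatenate(time)
    pressure = np.concatenate(pressure)
    volume = np.concatenate(volume)
    rng = _rng(seed, "pv")
    pressure = pressure + rng.normal(0.0, pressure_noise_sd, size=pressure.shape)
    volume = volume + rng.normal(0.0, volume_noise_sd, size=volume.shape)
    volume = np.maximum(volume, 1e-6)
    occl_time = n_beats_steady * period_ms
    events = [Event(float(occl_time), "occlusion_start")]
    truth = {
        "assay": "pv",
        "edv_ul": edv_ul,
        "esv_ul": esv_ul,
        "sv_ul": sv,
        "ef_pct": 100.0 * sv / edv_ul,
        "hr_bpm": hr_bpm,
        "co_ul_min": sv * hr_bpm,
        "espvr_slope": espvr_slope,
        "edpvr_slope": edpvr_slope,
        "v0_ul": v0_ul,
        "preload_step_ul": preload_step_ul,
        "n_beats_steady": n_beats_steady,
        "n_beats_occlusion": n_beats_occlusion,
        "ed_points": ed_points,
        "es_points": es_points,
        "noise_sd_pressure": pressure_noise_sd,
        "seed": seed,
    }
    return PvSeries(time, pressure, volume, events), truth


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

# Pure-hue palette used for generated micrographs (8-bit RGB).
PALETTE = {
    "blue": (40, 60, 200),         # collagen / fibrotic stain
    "red": (200, 40, 50),          # muscle stain
    "background": (245, 245, 245), # unstained / lumen
    "positive": (140, 90, 40),     # DAB brown
}


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  scale_px: float) -> np.ndarray:
    """Gaussian-filtered white noise: a spatially clustered random field."""
    from scipy.ndimage import gaussian_filter

    field = rng.normal(size=shape)
    return gaussian_filter(field, sigma=scale_px)


def simulate_histology(
    width: int = 256,
    height: int = 256,
    frac_blue: float = 0.3,
    frac_red: float = 0.6,
    um_per_px: float = 1.0,
    blob_scale_px: float = 8.0,
    hue_jitter_deg: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Two-color trichrome-like texture with exact class fractions.

    Pixels are partitioned into blue (fibrotic), red (muscle) and
    background classes by rank-thresholding a smoothed random field, so
    the class pixel counts match the requested fractions exactly (up to
    integer rounding) while remaining spatially clustered.
    ``hue_jitter_deg`` perturbs each pixel's hue to emulate stain
    variability.
    """
    if frac_blue < 0 or frac_red < 0 or frac_blue + frac_red > 1.0 + 1e-12:
        raise ValueError("fractions must be non-negative and sum to <= 1")
    rng = _rng(seed, "histology")
    n = width * height
    field = _smooth_field((height, width), rng, blob_scale_px).ravel()
    order = np.argsort(field, kind="stable")
    n_blue = int(round(frac_blue * n))
    n_red = int(round(frac_red * n))
    labels = np.full(n, 0, dtype=np.uint8)  # 0 background, 1 blue, 2 red
    labels[order[:n_blue]] = 1
    labels[order[n_blue:n_blue + n_red]] = 2
    labels = labels.reshape(height, width)
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[labels == 0] = PALETTE["background"]
    img[labels == 1] = PALETTE["blue"]
    img[labels == 2] = PALETTE["red"]
    if hue_jitter_deg > 0:
        from skimage.color import hsv2rgb, rgb2hsv

        hsv = rgb2hsv(img.astype(float) / 255.0)
        jitter = rng.uniform(-hue_jitter_deg, hue_jitter_deg,
                             size=hsv.shape[:2]) / 360.0
        hsv[..., 0] = np.mod(hsv[..., 0] + jitter, 1.0)
        img = np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    truth = {
        "assay": "histology",
        "frac_blue": n_blue / n,
        "frac_red": n_red / n,
        "frac_background": (n - n_blue - n_red) / n,
        "fibrotic_index": (n_blue / n_red) if n_red else float("nan"),
        "um_per_px": um_per_px,
        "hue_jitter_deg": hue_jitter_deg,
        "seed": seed,
    }
    return img, truth


def simulate_cell_image(
    cells: list[dict] | None = None,
    width: int = 256,
    height: int = 256,
    um_per_px: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Eosin-like micrograph of elliptical myocyte cross sections.

    ``cells`` is a list of dicts with keys ``cx, cy`` (px), ``a, b``
    (semi-axes, um) and optional ``angle`` (deg).  Cells are drawn as
    filled red ellipses with a small dark nucleus at the center on a
    white background; true analytic areas pi*a*b (um^2) are returned.
    """
    rng = _rng(seed, "cells")
    if cells is None:
        cells = [
            {"cx": 64, "cy": 64, "a": 10.0, "b": 12.5},
            {"cx": 180, "cy": 70, "a": 12.0, "b": 9.0},
            {"cx": 90, "cy": 180, "a": 8.0, "b": 8.0},
            {"cx": 190, "cy": 185, "a": 11.0, "b": 14.0},
        ]
    img = np.full((height, width, 3), 245, dtype=np.uint8)
    yy, xx = np.mgrid[0:height, 0:width]
    areas = []
    for c in cells:
        a_px = c["a"] / um_per_px
        b_px = c["b"] / um_per_px
        theta = np.deg2rad(c.get("angle", 0.0))
        dx, dy = xx - c["cx"], yy - c["cy"]
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
        img[inside] = PALETTE["red"]
        nucleus = (u / (0.25 * a_px)) ** 2 + (v / (0.25 * b_px)) ** 2 <= 1.0
        img[nucleus] = (60, 40, 90)
        areas.append(np.pi * c["a"] * c["b"])
    if noise_sd > 0:
        img = np.clip(
            img.astype(float) + rng.normal(0.0, noise_sd, size=img.shape),
            0, 255,
        ).astype(np.uint8)
    truth = {
        "assay": "cells",
        "areas_um2": areas,
        "n_cells": len(cells),
        "um_per_px": um_per_px,
        "seed": seed,
    }
    return img, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    n_per_group: int = 8,
    log2_fold_changes: dict[str, float] | None = None,
    control_group: str = "CTRL",
    dct_control_mean: float = 3.0,
    hk_ct_mean: float = 18.0,
    ct_sd: float = 0.0,
    gene: str = "Nppb",
    housekeeping: str = "Gapdh",
    seed: int = 0,
):
    """Ct table for one target gene and a housekeeping gene.

    Group mean ΔCt is ``dct_control_mean - log2_fold_change(group)``
    (the control's entry is forced to 0), so the expected group fold
    change under 2^−ΔΔCt equals ``2**log2_fold_change`` exactly when
    ``ct_sd = 0``.  Ct noise is independent Gaussian per well.
    """
    import pandas as pd

    if log2_fold_changes is None:
        log2_fold_changes = {control_group: 0.0, "HF": 1.5, "HF+CBD": 0.5}
    log2_fold_changes = dict(log2_fold_changes)
    log2_fold_changes[control_group] = 0.0
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")
    rng = _rng(seed, "qpcr")
    rows = []
    for group, l2fc in log2_fold_changes.items():
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            hk_ct = hk_ct_mean + rng.normal(0.0, ct_sd)
            tgt_ct = hk_ct_mean + dct_control_mean - l2fc + rng.normal(0.0, ct_sd)
            rows.append((sample, group, housekeeping, hk_ct))
            rows.append((sample, group, gene, tgt_ct))
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    truth = {
        "assay": "qpcr",
        "log2_fold_changes": log2_fold_changes,
        "fold_changes": {g: float(2.0**v) for g, v in log2_fold_changes.items()},
        "control_group": control_group,
        "dct_control_mean": dct_control_mean,
        "ct_sd": ct_sd,
        "gene": gene,
        "housekeeping": housekeeping,
        "n_per_group": n_per_group,
        "seed": seed,
    }
    return table, truth
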