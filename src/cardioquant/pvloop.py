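"""Pressure-volume loop hemodynamics.

Steady-state indices (stroke volume, ejection fraction, cardiac
output) come from individual cardiac cycles delimited at end-diastole
(volume maxima); load-independent indices come from a transient
preload reduction (vena-cava occlusion), during which the end-systolic
and end-diastolic points of successive beats sweep out the ESPVR and
EDPVR lines whose slopes are fitted by ordinary least squares.

The end-systolic point of a cycle is not uniquely defined by raw data;
two conventions are implemented:

* ``"elastance"`` (default): the sample maximizing P/(V - V0), with V0
  estimated by a two-pass fit (first pass uses the max-pressure
  convention to get a provisional ESPVR intercept, second pass
  re-picks the points);
* ``"max_pressure"``: the sample of maximal pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .io import PvSeries

__all__ = [
    "CardiacCycle",
    "Hemodynamics",
    "PvrFit",
    "detect_cycles",
    "steady_state_cycles",
    "occlusion_cycles",
    "steady_state_hemodynamics",
    "espvr_fit",
    "edpvr_fit",
]

SMOOTH_SAMPLES = 10        # moving-average width for boundary detection
EDV_DROP_FRACTION = 0.05   # occlusion onset when EDV drops >5% of running median


@dataclass
class CardiacCycle:
    start: int
    end: int                 # exclusive
    edv: float
    esv: float
    edp: float
    esp: float
    esv_index: int
    period_ms: float

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return 100.0 * self.sv / self.edv


@dataclass
class Hemodynamics:
    sv_ul: float
    ef_pct: float
    co_ul_min: float
    hr_bpm: float
    n_cycles: int


@dataclass
class PvrFit:
    slope: float             # mmHg/uL
    v0_ul: float             # volume-axis intercept
    r2: float
    n_points: int


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def detect_cycles(series: PvSeries, es_convention: str = "elastance",
                  smooth_samples: int = SMOOTH_SAMPLES) -> list[CardiacCycle]:
    """Delimit cardiac cycles at end-diastolic volume maxima.

    The volume signal is smoothed by a short moving average before peak
    picking (catheter noise); per-cycle pressures and volumes are then
    read from a local-quadratic (Savitzky-Golay) fit of the raw
    samples, which is exact for smooth signals and roughly halves
    sample noise at the landmarks.
    """
    v = series.volume
    vs = _moving_average(v, smooth_samples)
    prominence = 0.1 * float(np.ptp(vs))
    if prominence <= 0:
        raise ValueError("constant volume signal: no cardiac cycles")
    peaks, _ = find_peaks(vs, prominence=prominence)
    # find_peaks cannot flag the series edges; a recording that starts or
    # ends at end-diastole contributes a boundary cycle
    if peaks.size:
        if (vs[0] >= vs[: peaks[0]].max() - 1e-12
                and vs[0] >= vs[peaks[0]] - 0.5 * prominence):
            peaks = np.concatenate(([0], peaks))
        if (peaks[-1] < v.size - 2
                and vs[-1] >= vs[peaks[-1] + 1:].max() - 1e-12
                and vs[-1] >= vs[peaks[-1]] - 0.5 * prominence):
            peaks = np.concatenate((peaks, [v.size - 1]))
    if peaks.size < 2:
        raise ValueError("fewer than 2 end-diastolic volume maxima found")
    win = min(15, max(5, 2 * (v.size // 50) + 1))
    p_sg = savgol_filter(series.pressure, win, 2, mode="interp")
    v_sg = savgol_filter(v, win, 2, mode="interp")
    # refine each boundary to the local-fit volume maximum near the
    # moving-average peak (the moving average shifts peaks slightly)
    w = max(smooth_samples, 1)
    refined = []
    for pk in peaks:
        a = max(pk - w, 0)
        b = min(pk + w + 1, v.size)
        refined.append(a + int(np.argmax(v_sg[a:b])))
    peaks = np.unique(refined)
    cycles: list[CardiacCycle] = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        i_esv = a + int(np.argmin(v_sg[a:b]))
        cycles.append(CardiacCycle(
            start=int(a), end=int(b),
            edv=float(v_sg[a]), esv=float(v_sg[i_esv]),
            edp=float(p_sg[a]), esp=float(p_sg[i_esv]),
            esv_index=int(i_esv),
            period_ms=float(series.time[b] - series.time[a]),
        ))
    _assign_es_points(cycles, series, es_convention, p_sg, v_sg)
    return cycles


def _assign_es_points(cycles: list[CardiacCycle], series: PvSeries,
                      convention: str, p_sg: np.ndarray,
                      v_sg: np.ndarray) -> None:
    """Set each cycle's (esp, esv) per the chosen end-systolic convention."""
    if convention == "max_pressure":
        for c in cycles:
            i = c.start + int(np.argmax(p_sg[c.start:c.end]))
            c.esv_index = i
            c.esp = float(p_sg[i])
            c.esv = float(v_sg[i])
        return
    if convention != "elastance":
        raise ValueError("es_convention must be 'elastance' or 'max_pressure'")
    # pass 1: provisional v0 from max-pressure points
    pts = []
    for c in cycles:
        i = c.start + int(np.argmax(p_sg[c.start:c.end]))
        pts.append((v_sg[i], p_sg[i]))
    pts = np.asarray(pts)
    if pts.shape[0] >= 3 and np.ptp(pts[:, 0]) > 0:
        slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
        v0_est = -intercept / slope if slope > 0 else float(np.min(v_sg)) - 1.0
    else:
        v0_est = float(np.min(v_sg)) - 1.0
    v0_est = min(v0_est, float(np.min(v_sg)) - 1e-6)
    # pass 2: maximize the elastance ratio P/(V - v0_est)
    for c in cycles:
        ratio = p_sg[c.start:c.end] / (v_sg[c.start:c.end] - v0_est)
        i = c.start + int(np.argmax(ratio))
        c.esv_index = i
        c.esp = float(p_sg[i])
        c.esv = float(v_sg[i])


def steady_state_cycles(cycles: list[CardiacCycle], series: PvSeries,
                        ) -> list[CardiacCycle]:
    """Cycles before the occlusion: event marker or a >5% EDV drop."""
    occl = [e.time for e in series.events if e.label == "occlusion_start"]
    if occl:
        t_occl = min(occl)
        # classify by cycle midpoint so the beat straddling the marker is
        # attributed to the occlusion phase it mostly occupies
        return [
            c for c in cycles
            if 0.5 * (series.time[c.start] + series.time[c.end - 1]) < t_occl
        ]
    out = []
    for i, c in enumerate(cycles):
        med = np.median([x.edv for x in cycles[: i + 1]])
        if c.edv < (1.0 - EDV_DROP_FRACTION) * med:
            break
        out.append(c)
    return out


def occlusion_cycles(cycles: list[CardiacCycle], series: PvSeries,
                     ) -> list[CardiacCycle]:
    ss = steady_state_cycles(cycles, series)
    return cycles[len(ss):]


def steady_state_hemodynamics(cycles: list[CardiacCycle]) -> Hemodynamics:
    """SV/EF/CO/HR averaged over the supplied (pre-occlusion) cycles."""
    if not cycles:
        raise ValueError("no steady-state cycles")
    sv = float(np.mean([c.sv for c in cycles]))
    ef = float(np.mean([c.ef for c in cycles]))
    period_ms = float(np.mean([c.period_ms for c in cycles]))
    hr = 60000.0 / period_ms
    return Hemodynamics(sv_ul=sv, ef_pct=ef, co_ul_min=sv * hr, hr_bpm=hr,
                        n_cycles=len(cycles))


def _linear_fit(v: np.ndarray, p: np.ndarray, n_min: int = 3) -> PvrFit:
    if v.size < n_min:
        raise ValueError(f"need at least {n_min} beats for the fit")
    slope, intercept = np.polyfit(v, p, 1)
    pred = slope * v + intercept
    ss_res = float(np.sum((p - pred) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    v0 = -intercept / slope if slope != 0 else float("nan")
    return PvrFit(slope=float(slope), v0_ul=float(v0),
                  r2=float(np.clip(r2, 0.0, 1.0)), n_points=int(v.size))


def _check_decreasing_preload(cycles: list[CardiacCycle]) -> None:
    edv = np.array([c.edv for c in cycles])
    if edv.size >= 2 and not np.all(np.diff(edv) < 0):
        if edv[-1] >= edv[0]:
            warnings.warn("preload is not decreasing across the claimed "
                          "occlusion beats", stacklevel=3)


def espvr_fit(cycles: list[CardiacCycle]) -> PvrFit:
    """OLS line through the end-systolic (V, P) points of occlusion beats."""
    _check_decreasing_preload(cycles)
    v = np.array([c.esv for c in cycles])
    p = np.array([c.esp for c in cycles])
    return _linear_fit(v, p)


def edpvr_fit(cycles: list[CardiacCycle]) -> PvrFit:
    """OLS line through the end-diastolic (V, P) points of occlusion beats."""
    _check_decreasing_preload(cycles)
    v = np.array([c.edv for c in cycles])
    p = np.array([c.edp for c in cycles])
    return _linear_fit(v, p)
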