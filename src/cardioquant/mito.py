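"""Mitochondrial fluorometric and respirometric assays.

Covers four quantifications on isolated mitochondria / permeabilized
cells:

* free-Ca2+ calibration of an indicator via
  ``[Ca2+] = Kd * (F - Fmin) / (Fmax - F)`` (Fluo-4: Kd = 335 nmol/L);
* mitochondrial Ca2+ content: the free-Ca2+ rise after FCCP
  depolarization releases the matrix Ca2+, normalized per mg protein;
* Ca2+ retention capacity (CRC): repeated 10 umol/L Ca2+ pulses until
  permeability-transition-pore (mPTP) opening, detected as the first
  pulse with no re-uptake followed by a sustained fluorescence rise;
* Ca2+ influx rate: |first-derivative| at the start of a second-order
  polynomial fit to the post-energization fluorescence decay;
* respirometry: per-segment O2 slopes (routine / state 3 / uncoupled)
  and the respiratory control ratio state3 / routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Trace

__all__ = [
    "Calibration",
    "MitoCaResult",
    "CrcResult",
    "RespRates",
    "free_calcium",
    "fluorescence_at",
    "mito_ca_content",
    "crc_analysis",
    "influx_rate",
    "respirometry",
]

FLUO4_KD_NM = 335.0               # Ca2+/Fluo-4 dissociation constant, nmol/L
PLATEAU_WINDOW_S = 10.0           # median window for plateau estimates
RECOVERY_FRACTION = 0.5           # re-uptake criterion for CRC pulses


@dataclass(frozen=True)
class Calibration:
    """Indicator calibration: Kd plus saturating / zero-Ca2+ fluorescence."""

    fmax: float
    fmin: float
    kd: float = FLUO4_KD_NM

    def __post_init__(self):
        if self.fmax <= self.fmin:
            raise ValueError("fmax must exceed fmin")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass
class MitoCaResult:
    free_ca_baseline_nM: float
    free_ca_released_nM: float
    content_per_mg: float          # nmol/L free Ca2+ released per mg protein
    protein_mg: float
    calibration: Calibration


@dataclass
class CrcResult:
    pulses_tolerated: int
    cumulative_ca: float           # pulse-amount units per mg
    mptp_time_s: float | None      # None when censored
    censored: bool
    n_pulses: int
    pulse_amount: float
    protein_mg: float


@dataclass
class RespRates:
    routine: float
    state3: float
    uncoupled: float
    respiratory_control: float
    protein_mg: float


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def free_calcium(f: float | np.ndarray, cal: Calibration,
                 clamp_below_fmin: bool = False) -> float | np.ndarray:
    """Free [Ca2+] (nmol/L) from indicator fluorescence.

    ``[Ca2+] = Kd (F - Fmin) / (Fmax - F)``; strictly increasing on
    [Fmin, Fmax).  F at or above Fmax is saturated (error).  F below
    Fmin is an error unless ``clamp_below_fmin``, which clamps to 0
    with a warning.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f >= cal.fmax):
        raise ValueError("fluorescence at or above fmax: indicator saturated")
    if np.any(f < cal.fmin):
        if not clamp_below_fmin:
            raise ValueError("fluorescence below fmin")
        warnings.warn("fluorescence below fmin clamped to fmin", stacklevel=2)
        f = np.maximum(f, cal.fmin)
    ca = cal.kd * (f - cal.fmin) / (cal.fmax - f)
    return float(ca) if ca.ndim == 0 else ca


def fluorescence_at(ca_nM: float | np.ndarray, cal: Calibration,
                    ) -> float | np.ndarray:
    """Inverse of :func:`free_calcium`: F = (Fmin*Kd + Ca*Fmax)/(Kd + Ca)."""
    ca = np.asarray(ca_nM, dtype=float)
    f = (cal.fmin * cal.kd + ca * cal.fmax) / (cal.kd + ca)
    return float(f) if f.ndim == 0 else f


# ---------------------------------------------------------------------------
# Plateau helpers
# ---------------------------------------------------------------------------

def _plateau_before(trace: Trace, t_end: float,
                    window_s: float = PLATEAU_WINDOW_S) -> float:
    """Median signal over the final ``window_s`` before ``t_end``.

    A median is robust to the mixing spike right at an addition instant.
    """
    i0 = trace.index_at(t_end - window_s)
    i1 = trace.index_at(t_end)
    if i1 <= i0:
        raise ValueError("empty plateau window")
    return float(np.median(trace.value[i0:i1]))


def _addition_time(trace: Trace, label: str) -> float:
    times = trace.event_times(label)
    if times.size == 0:
        raise ValueError(f"required addition '{label}' not found on trace")
    return float(times[0])


# ---------------------------------------------------------------------------
# Mitochondrial Ca2+ content
# ---------------------------------------------------------------------------

def mito_ca_content(trace: Trace, protein_mg: float,
                    kd: float = FLUO4_KD_NM,
                    plateau_window_s: float = PLATEAU_WINDOW_S,
                    ) -> MitoCaResult:
    """Matrix Ca2+ content from an FCCP-release fluorometry trace.

    F0 is the plateau before FCCP; F the plateau after FCCP (before the
    next addition); Fmax/Fmin come from the post-CaCl2 / post-EGTA
    calibration plateaus.  Content is the calibrated free-Ca2+ rise
    (released minus baseline) divided by protein mass, so a no-release
    trace reports zero.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    missing = [lab for lab in ("FCCP", "CaCl2_max", "EGTA_min")
               if trace.event_times(lab).size == 0]
    if missing:
        raise ValueError(f"missing required additions: {missing}")
    t_fccp = _addition_time(trace, "FCCP")
    t_camax = _addition_time(trace, "CaCl2_max")
    t_egta = _addition_time(trace, "EGTA_min")

    def _next_after(t: float) -> float:
        later = [e.time for e in trace.events if e.time > t + 1e-9]
        return min(later) if later else float(trace.time[-1])

    f0 = _plateau_before(trace, t_fccp, plateau_window_s)
    f_rel = _plateau_before(trace, _next_after(t_fccp), plateau_window_s)
    fmax = _plateau_before(trace, _next_after(t_camax), plateau_window_s)
    fmin = _plateau_before(trace, _next_after(t_egta), plateau_window_s)
    cal = Calibration(fmax=fmax, fmin=fmin, kd=kd)
    ca0 = free_calcium(f0, cal, clamp_below_fmin=True)
    ca_rel = free_calcium(f_rel, cal, clamp_below_fmin=True)
    return MitoCaResult(
        free_ca_baseline_nM=ca0,
        free_ca_released_nM=ca_rel,
        content_per_mg=(ca_rel - ca0) / protein_mg,
        protein_mg=protein_mg,
        calibration=cal,
    )


# ---------------------------------------------------------------------------
# Ca2+ retention capacity
# ---------------------------------------------------------------------------

def crc_analysis(trace: Trace, pulse_amount: float | None = None,
                 protein_mg: float = 1.0,
                 recovery_fraction: float = RECOVERY_FRACTION,
                 ) -> CrcResult:
    """Count Ca2+ pulses tolerated before mPTP opening.

    For each pulse, the peak (max shortly after the addition) is
    compared with the pre-pulse baseline; the pulse *recovers* when the
    signal returns by at least ``recovery_fraction`` of the excursion
    before the next pulse (or trace end).  mPTP opening is the first
    pulse with no recovery and a non-falling late trend (the massive,
    sustained Ca2+ release); pulses_tolerated counts the pulses before
    it.  If every pulse recovers the result is censored.

    All criteria are ratios of fluorescence differences, so the result
    is invariant to affine rescaling of the signal.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    pulses = [e for e in trace.events if e.label == "pulse"]
    if not pulses:
        raise ValueError("no pulse additions on trace")
    times = [p.time for p in pulses]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("pulse additions are not time-ordered")
    if pulse_amount is None:
        amounts = {p.amount for p in pulses if p.amount is not None}
        if len(amounts) != 1:
            raise ValueError("pulse_amount not given and pulse amounts "
                             "missing or non-uniform")
        pulse_amount = amounts.pop()

    mptp_time: float | None = None
    tolerated = 0
    for i, pt in enumerate(times):
        t_next = times[i + 1] if i + 1 < len(times) else float(trace.time[-1])
        i_pre0 = trace.index_at(max(pt - 5 * trace.dt, trace.time[0]))
        i_pulse = trace.index_at(pt)
        baseline = float(np.median(trace.value[i_pre0:max(i_pulse, i_pre0 + 1)]))
        i_end = trace.index_at(t_next)
        seg = trace.value[i_pulse:i_end]
        if seg.size < 3:
            break
        peak_rel = int(np.argmax(seg[: max(3, seg.size // 4)]))
        peak = float(seg[peak_rel])
        excursion = peak - baseline
        if excursion <= 0:
            tolerated += 1
            continue
        post = seg[peak_rel:]
        recovered = float(np.min(post)) <= peak - recovery_fraction * excursion
        if recovered:
            tolerated += 1
            continue
        # no recovery: sustained rise = late level at or above the peak
        tail = post[-max(3, post.size // 5):]
        sustained = float(np.median(tail)) >= peak - 0.1 * excursion
        if sustained:
            mptp_time = pt
            break
        tolerated += 1  # slow drift but not a release event
    censored = mptp_time is None
    return CrcResult(
        pulses_tolerated=tolerated,
        cumulative_ca=tolerated * pulse_amount / protein_mg,
        mptp_time_s=mptp_time,
        censored=censored,
        n_pulses=len(pulses),
        pulse_amount=pulse_amount,
        protein_mg=protein_mg,
    )


# ---------------------------------------------------------------------------
# Ca2+ influx rate
# ---------------------------------------------------------------------------

def influx_rate(trace: Trace, window: tuple[float, float],
                evaluate_at: str = "start") -> tuple[float, float]:
    """Initial Ca2+ uptake rate from a quadratic fit to the decay.

    Fits ``F(t') = a t'^2 + b t' + c`` by least squares on the window
    (t' re-zeroed at the window start) and returns ``(rate, r2)`` where
    rate is the absolute derivative ``|b|`` at the window start (or
    ``|2 a T/2 + b|`` at mid-window with ``evaluate_at='mid'``).
    """
    t0, t1 = window
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 - i0 < 5:
        raise ValueError("need at least 5 samples in the fit window")
    t = trace.time[i0:i1] - trace.time[i0]
    y = trace.value[i0:i1]
    if np.ptp(t) <= 0:
        raise ValueError("degenerate fit window")
    coeffs = np.polyfit(t, y, 2)
    a, b, c = coeffs
    pred = np.polyval(coeffs, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if evaluate_at == "start":
        rate = abs(b)
    elif evaluate_at == "mid":
        rate = abs(2.0 * a * (t[-1] / 2.0) + b)
    else:
        raise ValueError("evaluate_at must be 'start' or 'mid'")
    return float(rate), r2


# ---------------------------------------------------------------------------
# Respirometry
# ---------------------------------------------------------------------------

def _trimmed_robust_slope(t: np.ndarray, y: np.ndarray,
                          trim_frac: float = 0.10) -> float:
    """Theil-Sen slope over the segment interior (10% trimmed each end).

    Addition/mixing artifacts contaminate segment edges; the trim plus
    a rank-based slope keeps single spikes from biasing the flux.
    """
    from scipy.stats import theilslopes

    n = t.size
    k = int(np.floor(trim_frac * n))
    sl = slice(k, n - k) if n - 2 * k >= 3 else slice(None)
    return float(theilslopes(y[sl], t[sl])[0])


def respirometry(trace: Trace, protein_mg: float = 1.0,
                 positive_slope_tol: float = 1e-6) -> RespRates:
    """Segmented O2 fluxes and the respiratory control ratio.

    Segments are delimited by the substrate, ADP and FCCP additions:
    substrate->ADP is routine respiration, ADP->FCCP state 3
    (phosphorylating), FCCP->end uncoupled.  Flux = -slope of the O2
    concentration per segment, normalized per mg protein.  Respiratory
    control = state3 / routine (no state-4/oligomycin step in this
    protocol).
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    t_sub = _addition_time(trace, "substrate")
    t_adp = _addition_time(trace, "ADP")
    t_fccp = _addition_time(trace, "FCCP")
    if not (t_sub < t_adp < t_fccp):
        raise ValueError("additions must be ordered substrate < ADP < FCCP")
    bounds = [(t_sub, t_adp), (t_adp, t_fccp), (t_fccp, float(trace.time[-1]))]
    fluxes = []
    for ta, tb in bounds:
        i0, i1 = trace.index_at(ta), trace.index_at(tb)
        if i1 - i0 < 5:
            raise ValueError("segment too short for a slope fit")
        slope = _trimmed_robust_slope(trace.time[i0:i1], trace.value[i0:i1])
        if slope > positive_slope_tol * max(1.0, abs(np.ptp(trace.value))):
            warnings.warn("positive O2 slope in a respiration segment "
                          "(re-oxygenation artifact?)", stacklevel=2)
        fluxes.append(max(-slope, 0.0) / protein_mg)
    routine, state3, uncoupled = fluxes
    rc = state3 / routine if routine > 0 else float("inf")
    return RespRates(routine=routine, state3=state3, uncoupled=uncoupled,
                     respiratory_control=rc, protein_mg=protein_mg)
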