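# cardioquant

Quantification pipeline for the assays used in cardiomyocyte and
whole-heart phenotyping of heart-failure models: intracellular Ca²⁺
handling and contractility, Ca²⁺ sparks, mitochondrial Ca²⁺ and
respiration, histopathology indices, pressure–volume hemodynamics,
qPCR relative expression, and the group-statistics layer that ties
them together.

It is written for labs that currently scatter these measurements
across MATLAB scripts, ImageJ plugins and spreadsheet formulas:
each stage is a tested, reusable Python function, and every input
modality has a synthetic generator with known ground truth so the
whole pipeline is verifiable by parameter recovery — no recordings
required.

## What it computes

**Ca²⁺ transients and cell shortening** (`cardioquant.transients`) —
per-beat features on paced recordings: amplitude as the maximal
ΔF/F₀ (F₀ = mean pre-stimulus fluorescence), time to peak from the
10 %-amplitude onset, T₅₀ of decay (interpolated half-amplitude
crossing after the peak), decay τ from a least-squares fit of
A·e^(−t/τ) + C to the decay phase; maximal shortening, TTPS and TTHR
for cell-length traces; batch tables with per-cell medians across
beats at 0.5/1/2 Hz pacing.

**Ca²⁺ sparks** (`cardioquant.sparks`) — detection on confocal line
scans (0.1 µm pixels) normalized row-wise to ΔF/F₀: two-pass
thresholding (candidates at mean + k·SD, k = 3.8 by default, extension
at mean + 2·SD), minimum-extent filtering, watershed splitting of
overlapping events; spark frequency in events·(100 µm)⁻¹·s⁻¹ and
amplitudes.

**Mitochondrial assays** (`cardioquant.mito`) — indicator calibration
[Ca²⁺] = K_d·(F − F_min)/(F_max − F) with K_d = 335 nmol/L for
Ca²⁺/Fluo-4; matrix Ca²⁺ content from FCCP-release traces per mg
protein; Ca²⁺ retention capacity with mPTP-opening detection (first
pulse with no re-uptake and a sustained rise); Ca²⁺ influx rate as
|dF/dt| of a second-order polynomial fit to the post-energization
decay; respirometry segment slopes (routine / state 3 / uncoupled) and
respiratory control = state 3 / routine.

**Histology** (`cardioquant.histology`) — hue/saturation pixel
classification for the Masson fibrotic index (%blue / %red), myocyte
cross-sectional areas (pixel counts × scale², border cells excluded,
≥ 20-cells inclusion rule), TUNEL/DAB positive-pixel fraction over
tissue pixels, and mean intensity for ΔΨm images.

**PV loops** (`cardioquant.pvloop`) — cycle detection at end-diastolic
volume maxima; SV = EDV − ESV, EF = 100·SV/EDV, CO = SV·HR from the
steady state; ESPVR and EDPVR slopes by least squares through the
end-systolic / end-diastolic points of vena-cava-occlusion beats.

**Statistics** (`cardioquant.stats`) — 2^(−ΔΔCt) relative expression
(Livak), percent-of-control normalization, and group comparisons:
unpaired t-test for two groups, one-/two-way ANOVA with Tukey HSD, or
Kruskal–Wallis with Dunn's post hoc, selected automatically via a
Shapiro–Wilk screen.

**Synthetic data** (`cardioquant.synthetic`) — generators for every
modality above with configurable true parameters, noise and a shared
seed-split RNG; each returns the data plus a JSON-serializable ground
truth.

## Worked example

```python
import numpy as np
from cardioquant import synthetic as syn, transients as tr, mito, pvloop as pv

# paced Ca2+ transient train with known kinetics, 2% photometric noise
trace, truth = syn.simulate_transient_train(
    pacing_hz=1.0, n_beats=10, f0=100.0, amplitude_dff0=1.2,
    ttp_ms=50.0, tau_ms=180.0, noise_sd=2.0, seed=3)
rows = []
for seg in tr.segment_beats(trace):
    f0 = tr.baseline_f0(seg, trace)
    f = tr.transient_features(seg, trace, f0)
    if f.usable:
        rows.append((f.amplitude, f.time_to_peak, f.t50_decay, f.tau))
med = np.median(np.array(rows), axis=0)
print(f"amplitude dF/F0: {med[0]:.3f}")   # 1.175  (true 1.2)
print(f"T50 decay      : {med[2]:.1f} ms")  # 124.5  (ln2*tau = 124.8)
print(f"tau            : {med[3]:.1f} ms")  # 179.8  (true 180)

# Fluo-4 calibration: midpoint fluorescence returns Kd exactly
cal = mito.Calibration(fmax=900.0, fmin=100.0)
print(mito.free_calcium(500.0, cal))      # 335.0 nmol/L

# PV loops: steady state + occlusion-derived chamber properties
series, _ = syn.simulate_pv_occlusion(pressure_noise_sd=1.0, seed=3)
cycles = pv.detect_cycles(series)
hd = pv.steady_state_hemodynamics(pv.steady_state_cycles(cycles, series))
occ = pv.occlusion_cycles(cycles, series)
print(f"SV {hd.sv_ul:.1f} uL  EF {hd.ef_pct:.1f} %  CO {hd.co_ul_min:.0f} uL/min")
# SV 29.8 uL  EF 59.5 %  CO 17871 uL/min   (true 30 / 60 / 18000)
print(f"ESPVR {pv.espvr_fit(occ).slope:.2f}  EDPVR {pv.edpvr_fit(occ).slope:.3f}")
# ESPVR 2.00  EDPVR 0.276 mmHg/uL          (true 2.0 / 0.25)
```

The amplitude reads 1.175 rather than 1.2 because the beat train at
1 Hz leaves a small decay tail under the next beat's baseline window —
exactly the bias a real paced recording carries; slower pacing removes
it.

A command-line interface mirrors the library
(`cardioquant simulate|transients|sparks|mito|pvloop|histology|stats`,
see `cardioquant --help`).

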