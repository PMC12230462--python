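# Methods

This note documents the models, estimators, default parameters and
known limitations behind each `cardioquant` module, and what the
synthetic generators do and do not emulate.

## Ca²⁺ transients and cell shortening

Per-beat features are extracted from uniformly sampled traces split at
pacing stimuli (explicit events, or reconstructed from the pacing
frequency and the detected first onset; the first onset is located by
extrapolating the initial suprathreshold rise back to baseline).

* **F₀ / resting length** — arithmetic mean over a window before the
  stimulus (default 200 ms). The window must contain samples and yield
  a positive value.
* **Amplitude** — max of (F − F₀)/F₀ over the beat. On noisy beats the
  raw maximum is biased upward by the extreme of the noise, so the peak
  is read from a short local-quadratic (Savitzky–Golay, 11-sample)
  denoised view; noiseless recordings (baseline SD ≤ 10⁻⁶ in
  normalized units) use the raw samples so constructed signals are
  recovered exactly.
* **Onset** — the last interpolated upward crossing of 10 % of the
  beat amplitude before the peak (`onset_frac` configurable). Time to
  peak is onset → peak. Onset is not universally standardized; the 10 %
  convention is stated with every result this package produces.
* **T₅₀ of decay / TTHR** — first linearly interpolated crossing of
  half amplitude after the peak (half recovery after the minimum for
  shortening). The first crossing of a raw noisy signal is
  systematically early (the noise reaches the threshold before the
  mean does), so crossings on noisy beats are read from a wider
  (75-sample) Savitzky–Golay view. Both windows are module constants;
  at a 1 kHz sampling rate they are well below the kinetics they
  measure (τ ≥ 100 ms), and the quadratic filter is exact on locally
  quadratic signal shapes.
* **τ** — nonlinear least squares of A·e^(−t/τ) + C on the raw decay
  (peak → beat end), log-linear initialization, τ > 0 bound. The offset
  C absorbs baselines that do not return exactly to F₀. A
  non-convergent fit reports τ as absent with a diagnostic flag.
* **Usability floor** — a beat is flagged unusable when its amplitude
  is below 5× the baseline noise SD (estimated from the F₀ window);
  this prevents fitting pure noise.
* **Batch aggregation** — per-cell **median** across beats, robust to a
  single arrhythmic beat. Whether source recordings should be averaged
  or represented by one beat is a lab convention; the per-beat long
  table is emitted alongside so either can be recomputed.

## Ca²⁺ sparks

Line scans (space × time, 0.1 µm pixels by convention) are normalized
per spatial row by the temporal 20th percentile — a baseline estimator
robust to sparse bright events — then reduced to ΔF/F₀.

Detection is a two-pass threshold in the tradition of automated spark
analyzers: candidate pixels above mean + k·SD (k = 3.8 default; the SD
is a median/MAD estimate, insensitive to the sparks themselves),
extended to connected regions above mean + 2·SD. Guards against shot
noise and artifacts:

* a region must contain ≥ 2 candidate pixels and span ≥ 3 pixels ×
  2 lines;
* temporal gaps up to 15 lines in the extension mask are closed, so a
  decaying tail that noise pushes briefly below threshold reconnects
  to its event instead of re-triggering as a new one;
* regions with multiple local maxima (located on a lightly Gaussian-
  denoised view, σ = 1.5 px × 1 line) are split by marker watershed
  only when the valley between maxima drops below 70 % of the lower
  peak; ties are resolved in favor of the earlier event.

Event position is the intensity-weighted spatial centroid (the spatial
kernel is symmetric, so this is unbiased); event time is the peak
line, because the canonical spark is a fast rise with a slow fall and
a temporal centroid would lag the release onset by tens of
milliseconds. Amplitude is the raw ΔF/F₀ at the denoised peak
location; spatial FWHM and temporal FDHM are interpolated half-max
widths through the peak and are reported absent when the event is
clipped by the image border. Frequency = events / (cell extent /
100 µm) / scan seconds.

The detection criterion k is configuration, not a constant of nature;
all outputs carry the k they were computed with.

## Mitochondrial assays

* **Calibration** — [Ca²⁺] = K_d (F − F_min)/(F_max − F); K_d defaults
  to 335 nmol/L (Ca²⁺/Fluo-4). F ≥ F_max is a saturation error; F <
  F_min errors or clamps to zero with a warning, per configuration.
  The implementation and its algebraic inverse round-trip to 10⁻⁹
  relative.
* **Content** — plateaus are medians of the final 10 s before the next
  addition (robust to mixing spikes at the addition instant). F_max and
  F_min come from the post-CaCl₂ / post-EGTA plateaus of the same
  trace. Content per mg = (free Ca²⁺ after FCCP − before FCCP) /
  protein mass. Baseline subtraction is a deliberate choice — the
  qualitative protocol does not state it — made so that a trace with no
  FCCP-induced release reports zero content.
* **CRC** — per pulse, the excursion is peak (max over the first
  quarter of the inter-pulse interval) minus the pre-pulse baseline;
  the pulse *recovers* if the signal returns by ≥ 50 % of the
  excursion before the next pulse. mPTP opening is the first pulse
  with no recovery **and** a late level at or near the peak (the
  sustained, massive release); slow drift without a sustained rise is
  not called an opening. All criteria are ratios of fluorescence
  differences, making the analysis invariant to affine rescaling of
  the signal. A trace where every pulse recovers is reported censored.
* **Influx rate** — least-squares quadratic F(t) = a·t² + b·t + c on a
  user window re-zeroed at its start; the rate is |b| (the derivative
  magnitude at the window start, where uptake is maximal right after
  energization; mid-window evaluation is a config option). R² is
  reported with the rate.
* **Respirometry** — segments are delimited by the substrate, ADP and
  FCCP additions (routine, state 3, uncoupled respectively). Per
  segment the flux is −slope from a Theil–Sen fit over the interior
  (10 % trimmed at each end; addition artifacts live at segment
  edges), normalized per mg. Respiratory control = state 3 / routine,
  because the emulated protocol has no state-4/oligomycin step; the
  ratio definition is configurable where such a segment exists.

## Histology

Pixel classification is done in HSV space: blue = hue 180–260°,
red = hue < 20° or > 340°, both requiring saturation > 0.15; all else
is background. The thresholds are configuration and are serialized
with every result. The fibrotic index is %blue / %red of all pixels,
flagged undefined when no red pixels exist. Myocyte areas are pixel
counts × (µm/px)², border-touching cells excluded, with the ≥ 20
cells-per-image inclusion rule surfaced as a flag rather than a hard
error. Automatic segmentation (red-channel classification, hole
filling, distance-transform watershed) is provided for convenience,
but manually drawn masks — the faithful equivalent of interactive cell
selection — are accepted directly. Positive-pixel fractions (TUNEL/DAB,
default hue 10–50°) use tissue pixels as the denominator, excluding
white/luminal pixels (value ≥ 0.92 and unsaturated).

## Pressure–volume analysis

Cycles are delimited at end-diastolic volume maxima found on a
10-sample moving average (series edges that start or end at
end-diastole are included); landmark pressures and volumes are then
read from a Savitzky–Golay local-quadratic fit of the raw samples —
exact for smooth signals and roughly halving per-sample noise, which
matters most for the small EDP range swept during an occlusion.

The end-systolic point of a cycle is convention-dependent; both common
choices are implemented: the default maximizes P/(V − V₀) with V₀
estimated by a two-pass fit (max-pressure points → provisional ESPVR
intercept → re-pick), and a simpler max-pressure convention is
selectable. Results should state the convention used; the two give
systematically different ESPVR slopes.

Steady-state SV/EF/HR are per-cycle values averaged over the
pre-occlusion window (occlusion marker event, else a > 5 % EDV drop
from the running median; the beat straddling the marker is assigned by
its midpoint). ESPVR and EDPVR are ordinary least squares through the
end-systolic / end-diastolic points of ≥ 3 occlusion beats; EDPVR is
fitted linearly (a single slope is the reported quantity; exponential
stiffness models are out of scope). A non-decreasing preload across
the claimed occlusion emits a warning.

## Statistics

ΔΔCt follows Livak: ΔCt = Ct_target − Ct_housekeeping per sample,
centered on the arithmetic mean ΔCt of the control group (equivalently
the control group's geometric-mean fold is exactly 1), fold = 2^(−ΔΔCt).
Per-plate calibrator samples are out of scope.

`compare_groups` reproduces the standard decision tree: two groups →
unpaired t-test; more → one-way ANOVA + Tukey HSD, or Kruskal–Wallis +
Dunn when any group fails a Shapiro–Wilk normality screen at α = 0.05
(`design="auto"`; every path can be forced). Two-factor designs use a
type-II ANOVA (statsmodels OLS) with Tukey HSD on the group factor
within each level of the second factor. Dunn's test is implemented
in-package (pairwise z statistics on pooled mean ranks with tie
correction) with Holm adjustment by default, Bonferroni optional.
Groups with zero variance everywhere short-circuit to a flagged
degenerate result (identical means → statistic 0, p = 1).

The two-way path treats repeated factors (e.g. pacing frequency within
cell) as independent — a known limitation; a mixed-effects model is
out of scope.

## Synthetic generators

The generators produce the minimal smooth signal families consistent
with what the analyzers measure, each with exact, serialized ground
truth:

* transients: half-sine rise over TTP (smooth, monotone, unambiguous
  peak) then mono-exponential decay; shortening uses the same rise and
  an exponential relaxation that crosses half recovery exactly at
  TTHR. Ground truth carries both the stimulus-referenced and the
  10 %-onset-referenced rise times.
* line scans: sparks as separable Gaussians in space ×
  instantaneous-rise/exponential-fall kernels in time (canonical spark
  morphology), Poisson-planted, on a flat baseline with white Gaussian
  noise.
* CRC: fluorescence steps with exponential re-uptake; the release
  pulse rises linearly without recovery. Influx: exact quadratic decay
  after energization. O₂: piecewise linear with configured segment
  slopes.
* PV loops: a time-varying elastance model P = [E_ed + e(t)(E_es −
  E_ed)](V − V₀) with e(t) = sin²(πt/T) peaking at minimal volume, so
  end-systolic and end-diastolic points lie exactly on the configured
  ESPVR/EDPVR lines; during occlusion the preload falls as a
  continuous within-beat ramp (1.2 µL/beat over 15 beats by default)
  so the recorded signals remain continuous, as catheter data are.
* histology: rank-thresholded smoothed noise fields give spatially
  clustered textures with exact class fractions; cell images are
  analytic ellipses. qPCR: Gaussian Ct values whose group means encode
  the configured log₂ fold changes exactly.

Default conditions mirror the emulated experiments: 0.5/1/2 Hz pacing,
0.1 µm line-scan pixels at 1–2 ms line periods, 10 µmol/L Ca²⁺ pulses
every 180 s, a 40 µmol/L bolus for influx, 600 bpm murine PV loops of
50/20 µL EDV/ESV, K_d = 335 nmol/L. Noise defaults are stated per
generator and sized to realistic photometric/catheter noise (e.g. 2 %
of baseline fluorescence; 2 mmHg pressure SD in the noisy PV
condition).

What the generators do **not** emulate — and hence what passing
recovery tests cannot certify on real data: biophysical Ca²⁺ dynamics
(no ODE cell models, no SR load dependence), photobleaching, motion
and focus drift, spark-in-wave morphology, stain variability beyond
hue jitter, catheter volume-calibration error, and qPCR efficiency
differences between genes. The pipeline's estimators are validated
for bias and noise behavior, not for robustness to artifacts it never
sees.

## Verification problem sizes

The recovery studies run at sizes chosen to make medians stable while
keeping the whole suite fast on a laptop: ~200 beats across the 3 × 3
τ/amplitude grid, 50 line scans of 50 µm × 2 s for detection
performance plus 50 spark-free scans for the false-positive check, 50
randomized CRC traces, 100 seeds for influx and PV noise recovery,
1000 null simulations for the ANOVA type-I rate and 200 for power.
`scripts/acceptance.py` recomputes all of them from a single `--seed`.
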