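# Methods

This note defines every computation the package performs, the default
parameter values with units, and the reasoning behind the design choices
that were ours to make.

## Signal model and notation

A recording yields, per ROI, a raw fluorescence trace F(t) sampled at
frame rate *f*ₛ (default 30.0 Hz). The pipeline computes

- a smoothed trace S(t) = SG(F; w, p) — Savitzky–Golay filter,
- a baseline F₀(t) — sliding-window percentile of S(t),
- ΔF/F₀(t) = (S(t) − F₀(t)) / F₀(t),

then detects Ca²⁺ events on ΔF/F₀ and classifies each cell as active or
inactive.

## Smoothing

Savitzky–Golay, window **w = 301 frames** (10.03 s at 30 Hz), polynomial
order **p = 3**, with polynomial edge fitting (`scipy.signal.savgol_filter`,
`mode="interp"`). For traces shorter than 301 samples the window shrinks to
the largest odd width ≤ the trace length (with a warning); the filter
reproduces any cubic exactly, which the test suite asserts to 1e-8.

## Baseline and ΔF/F₀

F₀(t) is the **10th percentile** of S over a centred sliding window of
`max(1, round(fₛ / f_c))` frames with cutoff **f_c = 1/15 Hz**, i.e. 450
frames (15 s) at 30 Hz. Windows are **truncated at the trace edges** (no
padding): the window at sample i covers `[i − (W−1)//2, i + W//2]`
intersected with the trace. Percentile interpolation is numpy's linear
rule; the implementation is a numba sorted-window filter that the tests
verify bit-exactly against a per-window `np.percentile` loop. An
alternative `baseline_mode="percentile+butterworth"` low-pass-filters the
running percentile instead. F₀ ≤ 0 anywhere is an error, since ΔF/F₀ would
be undefined.

Consequences asserted in the tests: a constant trace gives ΔF/F₀ ≡ 0;
adding a constant shifts F₀ by that constant; scaling the trace leaves
ΔF/F₀ unchanged.

## Event detection

Events are peaks of ΔF/F₀ satisfying, in MATLAB `findpeaks` semantics:

- **MinPeakHeight 0.2** — absolute peak height ≥ 0.2 ΔF/F₀;
- **MinPeakWidth 15 frames** (0.5 s at 30 Hz) — width measured at half the
  peak's *prominence*;
- **MinPeakDistance 30 frames** (1 s) — peaks are visited tallest first
  (ties: earlier peak first) and any remaining peak strictly closer than
  30 frames to an accepted peak is discarded;
- a plateau's peak index is its middle sample, rounded down.

Candidate maxima, prominences and widths come from `scipy.signal`; the
filters and suppression are implemented here. The acceptance suite checks
exact agreement with an independent pure-Python enumerator on 1,000 random
traces, and one-sided boundary cases (height 0.19/0.21, width 14/16,
distance 29/31).

## Active-cell classification

A cell is **active** iff all three hold (strict inequalities):

1. skewness(ΔF/F₀) > 1.0 — biased g₁ (`scipy.stats.skew`, `bias=True`);
2. SD(ΔF/F₀) > 0.04 — sample SD with `ddof=1`;
3. ≥ 1 detected event.

Per-cell frequency is events/min over the recording; mean amplitude is the
mean detected peak height, reported as *undefined* (None), not zero, for
cells with no events. An organoid summary reports the active-cell rate
(% of ROIs active) and pools per-cell frequencies/amplitudes over active
cells (optionally over all cells with ≥ 1 event). Groups are compared on
per-organoid values: Student's t (two-tailed, pooled variance) for two
groups; one-way ANOVA with Dunnett (vs a named control) or Tukey HSD
post-hoc for more, significance at p < 0.05.

## Motion correction

Per-frame rigid shifts are estimated by FFT cross-correlation of the
mean-subtracted frame against a reference (mean frame, first frame, or a
chosen index), with the correlation peak searched within ±`max_shift`
pixels (default 20) and optional parabolic sub-pixel refinement. A
zero-variance frame gets shift (0, 0) and a flag. Correction applies the
negated shift; integer shifts are applied exactly, fractional ones by
linear interpolation; exposed pixels are filled with 0. Sign convention:
shift (dy, dx) means the frame content moved down/right by that amount.

## Synthetic generator

Each cell's clean trace is F(t) = B(t)·(1 + Σᵢ aᵢ·k(t − tᵢ)) + ε with

- B(t) = baseline·(1 + drift·sin(2πt/T)) — baseline 100 a.u., 5% drift
  over the recording duration T;
- k(τ) = (1 − e^(−τ/τ_r))·e^(−τ/τ_d), peak-normalised so that the
  programmed amplitude aᵢ equals the true ΔF/F₀ peak of an isolated event
  (the multiplicative form makes amplitudes baseline-independent);
- event times tᵢ ~ Poisson with rate 2 events/min for active cells (0 for
  inactive), amplitudes aᵢ ~ N(0.6, 0.1) clipped at 0.1;
- ε white Gaussian noise, SD 2.0 a.u.

Defaults: 3600 frames (120 s at 30 Hz), 64×64 movies, 8 cells of ROI
radius 4 on background 20 a.u., active fraction 0.5 (n_active =
⌊n·fraction⌋, at least 1 when the fraction is positive). Movies paint
disk ROIs with the clean trace value, apply integer rigid shifts (frame 0
unshifted), then add pixel noise. `GroundTruth` carries labels, event
times/amplitudes, shifts, ROI pixels and clean traces.

`sample_cohort_configs` draws per-organoid active fractions from
N(mean, 0.02) clipped to [0, 1]. Real organoid cohorts show large
inter-organoid spread in active-cell rate; without some between-organoid
variability a simulated group can be degenerate (zero variance) and the
t-test undefined.

### Kinetics choice

The default kinetics are **τ_r = 1.5 s, τ_d = 6 s** — slow synchronized
network events, not single-cell indicator kinetics. This is deliberate:
the pipeline's prescribed 10-s smoothing window attenuates a fast
transient (0.05 s rise / 0.5 s decay) to ~14% of its amplitude, so no
generator using fast kinetics could exercise amplitude recovery through
this pipeline. With the slow kinetics the filter gain on an isolated event
is ≈ 0.99, and the smoothing window itself implies the recordings it was
designed for contain events on this timescale.

## Measured recovery performance

On defaults (2 events/min, amplitude 0.6, 120-s traces):

- **Event count**: ~85.5% of realized ground-truth events are detected
  (81–87% across independent 60-cell seed blocks). The dominant loss is
  *event merging*: the 10-s smoothing window cannot resolve two events
  closer than ~5 s, and at 2 events/min ~28% of events have such a
  neighbour. A smaller share is lost at trace edges (peaks falling beyond
  the end, or inside the truncated-baseline edge region). This is a
  property of the prescribed smoothing width at this event rate, not of
  the implementation; the 15% recovery band in the acceptance suite is
  therefore met only marginally.
- **Amplitude**: mean detected height within ~7% of the programmed 0.6
  (percentile-baseline and filter interaction slightly attenuate peaks;
  detection also censors the smallest events).
- **Classification**: ≥ 95% per-cell accuracy on 50-cell organoids; mean
  recovered active-cell rate within 3 percentage points of programmed.
- **Registration**: exact integer-shift recovery noise-free; ≥ 95% of
  frames within 1 px at 5% noise.
- **Cohort contrast**: programmed active fractions 0.10 vs 0.03 (10
  organoids/group, 50 cells) yield p < 0.05 in ≥ 90% of replicate draws.

Recovery is always measured against the *realized* ground truth, not the
programmed Poisson expectation: the generator's own sampling fluctuation
(SD ≈ 5% of the total event count at these sizes) is not pipeline error.

## Limitations

- The smoothing/baseline parameters target slow network events; fast
  single-cell transients are strongly attenuated and largely undetectable
  under these settings.
- Motion correction is rigid and per-frame; non-rigid deformation is out
  of scope.
- Seeded region growing is a simple stand-in for interactive ROI tools;
  it assumes roughly disk-shaped, well-separated cells.
- Statistics treat organoids as independent units; no mixed-effects
  modelling of within-organoid correlation.
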