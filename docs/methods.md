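# Methods

This note documents the signal models, estimators and numerical choices
behind `vitalband`, and what the synthetic-data validation does and does
not establish about real recordings.

## Heart rate from PPG

The photoplethysmogram (PPG) is treated as a steady reflectance level (DC)
plus a pulsatile component (AC) at the pulse frequency. Heart rate is
estimated spectrally:

1. mean-subtract the window (no taper — a window function would rescale the
   amplitudes of the analytic worked examples, and the spectral *argmax* is
   what matters here, not sidelobe suppression);
2. zero-pad and FFT to a single-sided amplitude spectrum with grid spacing
   ≤ 0.002 Hz (default). A 40-s window has 0.025 Hz native resolution,
   i.e. 1.5 bpm granularity; padding interpolates the spectrum finely
   enough to read off sub-bpm peak positions such as 1.342 Hz;
3. take the argmax inside the closed physiological band 0.5–3.5 Hz
   (30–210 bpm) and convert: bpm = 60 × f_peak. Band edges are inclusive
   and amplitude ties resolve toward the lower frequency so the estimator
   is deterministic.

Long recordings are analyzed in consecutive non-overlapping 40-s windows
(half-open, trailing partial window dropped), with window estimates
averaged over 5-min spans — the protocol used when comparing against
reference pulse oximetry that reports 5-min averages. Whether the 40-s
windows overlap was an open choice; non-overlapping windows keep estimates
independent and bookkeeping trivial.

## SpO2 from the modulation ratio

Per consecutive 10-s interval and per wavelength, DC is the interval mean
and AC is the mean height of detected pulse peaks above DC. Peak detection
uses `scipy.signal.find_peaks` with a minimum spacing of 0.25 s (caps the
pulse rate at 240 bpm, above the analysis band) and a prominence of at
least 10% of the interval's maximum deviation from DC. These two detector
thresholds are design choices fixed by the closed-form sinusoid test
(amplitude recovered within 2%); no detector parameters are inherent to
the ratio-of-ratios method itself. Intervals with no detectable peaks are
flagged and excluded from downstream averaging rather than contributing a
zero.

The modulation ratio R = (AC_red/DC_red)/(AC_ir/DC_ir) feeds the linear
empirical map SpO2 = 110 − 25R. The map exceeds 100% for R < 0.4, so the
reported value is clamped to [0, 100] with the unclamped value retained
alongside. R is invariant to any per-wavelength rescaling of the signal,
which is what makes the ratio usable across LED drive currents and skin
tones — a property the test suite asserts directly.

## Calibration and bias correction

Two correction schemes, chosen per metric:

* **Linear calibration** (heart rate): ordinary least squares predicting
  the reference from the device reading, so a new device value maps
  directly to an adjusted estimate. Reported with R² (squared sample
  correlation) and a 95% prediction interval for a single future
  observation, with half-width t_{n−1,0.025} · s · √(1 + 1/n) — constant
  in x. Here `s` is the sample standard deviation of the original
  (reference) data set and the t quantile uses n−1 degrees of freedom.
  That convention differs from the textbook regression prediction interval
  (residual standard error, n−2 df, leverage term); it is implemented as
  stated because it is the contract this interval is defined by, and the
  conventional residual standard error is computed and exposed as
  `s_resid_` so both are auditable.
* **Bias correction** (SpO2, skin temperature): an additive shift equal to
  mean(reference) − mean(device). After correction the device mean equals
  the reference mean to floating point; the shift leaves variance
  untouched. Skin temperature plus a fixed offset serves as a core-body
  temperature estimate — valid exactly to the extent that skin tracks core
  with a stable offset, which is a modeling assumption, not a physiological
  law; the offset is therefore a parameter, not a constant.

Agreement after correction is checked with a paired two-sided test
(Wilcoxon signed-rank by default, paired t as an alternative), thin
wrappers over scipy. All-zero differences are degenerate: the t route
returns p = 1, the Wilcoxon route raises, since its statistic is undefined.

## Activity classification

Each 30-s tri-axial window reduces to six features: per-axis minima and
maxima in mg, exact and unsmoothed. Classification into the five-level
intensity scale (1 sitting → 5 sprinting) uses a support vector machine:
features are z-scored with training-split statistics (axis ranges differ
by ~3×, so unscaled margins would be dominated by the widest axis), then a
linear-kernel one-vs-one multiclass SVM with C = 1 — the classic default
multiclass SVM configuration; nothing in the problem suggested a
nonlinear kernel, and six features with well-separated class extremes are
linearly separable by construction. Training uses a stratified 70/30
split with an explicit seed: with ~50 windows over 5 classes, an
unstratified split too easily leaves a class unrepresented on one side.

Prediction is computed from the stored hyperplane weights by one-vs-one
voting (ties broken by summed margins, then the lower level), which makes
fitted models serializable as plain JSON — weights, intercepts, scaler
statistics, class labels — instead of pickles. Tests assert the vote
reproduces `sklearn.svm.SVC.predict` on the fixture corpus.

## GSR

The 10-bit ADC code is mapped linearly onto 1–16 μS, endpoints exact. The
sensor's true transfer function (op-amp plus adjustable potentiometer) is
device-specific and not modeled; the linear map is declared as the
package's convention and isolated in one function so it can be swapped.
Note the printed sensor resolution of 0.1 μS is coarser than the
~0.0147 μS/count a linear 10-bit map implies; the discrepancy is inherited
from the hardware description and left as-is. The analysis quantity is the
deviation from an individual baseline — conductance minus the mean over a
baseline window — optionally smoothed with a centered moving average
(edge-padded so length and scale are preserved; width ≤ 1 sample is the
identity).

## Synthetic data

The generators define the validation conditions; their defaults are the
study conditions the analysis chain is meant to operate under.

* **PPG** (50 Hz, 40 s default): per beat, a primary systolic Gaussian
  bump (σ = 0.15 beat periods) plus a secondary diastolic bump at 0.45
  periods delay (σ = 0.20, relative amplitude 0.3 by default), repeated
  periodically and superposed on DC; optional additive white Gaussian
  noise, independent per wavelength. The two-bump shape reproduces the
  classic two-peak reflectance morphology while keeping the spectral
  fundamental strictly dominant over its harmonics (verified by the
  spectral round-trip tests). The pulse train is normalized so that the
  *mean detected-peak height above the signal mean* is one; under that
  convention perfusion × DC is exactly the AC that the peak-averaging
  extractor measures, and the ground-truth modulation ratio is exactly
  perfusion_red / perfusion_ir regardless of morphology. Default
  perfusions 0.01 (red) / 0.02 (IR) place the pipeline at R = 0.5, the
  97.5% saturation operating point; equal perfusions give R = 1, the 85%
  point.
* **Accelerometry** (10 Hz, 30 s): per axis, uniform samples inside the
  reference range for the requested level, with the two endpoints planted
  explicitly so that jitter-free windows reproduce the printed per-axis
  extremes *exactly* rather than almost surely. `jitter_frac` moves each
  endpoint uniformly by up to that fraction of the axis range; the
  validation corpus uses 10 windows per level at 2% jitter (the corpus
  size matches the 50-dataset training protocol; its per-level
  composition is the package's choice).
* **Temperature / GSR** (1 Hz, 300 s): skin = 32.48 °C baseline + optional
  Gaussian random-walk drift; latent core truth = skin + 4.14 °C by
  default (an offset parameter, not an asserted physiological constant).
  GSR = 2 μS baseline with a trapezoidal +3 μS rise inside an exercise
  interval (5-s linear ramps), quantized to ADC codes.

All randomness flows from one explicit seed per spec via
`numpy.random.default_rng`; no global RNG state. Zero noise/jitter makes
every generator fully deterministic.

What passing these tests shows: the estimators invert the stated signal
models exactly or to stated tolerance, the bookkeeping (windows, splits,
confusion counts) is correct, and the end-to-end chain is deterministic.
What they do not show: robustness to motion artifacts, baseline wander,
contact-pressure changes, arrhythmia, or any morphology beyond additive
Gaussian noise on a periodic two-bump pulse — real-device performance
claims require real recordings.

## Degenerate inputs and numerical conventions

* Constant signal → zero spectrum; constant interval → flagged AC.
* AC_ir = 0 or flagged interval → `UndefinedRatioError`, never a silent 0.
* Constant device series → calibration rejected (slope undefined);
  bias correction still valid.
* All windows are half-open [start, end) in seconds; trailing partial
  windows are dropped, so a 299-s log yields ⌊299/40⌋ = 7 heart-rate rows.
* Device-log round-trips are bit-exact: floats are written with shortest
  round-trip repr and re-parsed with numpy's exact parser.
* Session reports are pure functions of (log, config, models); identical
  inputs give byte-identical JSON, with a config hash recorded in the
  provenance block.

## Problem sizes

Validation runs use 40–300 s signals at the native rates (50 Hz PPG,
10 Hz accelerometry, 1 Hz temperature/GSR), a 50-window classification
corpus, and 100 replicates for the slope-recovery property — sizes chosen
to exercise every code path at the study's own sampling rates while
keeping the whole suite fast on a laptop.
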