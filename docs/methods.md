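# Methods

## Synthetic forward model

The generator emulates fiber-probe Raman acquisitions on the six tissue
classes found around a vertebra.  Its defaults are the study conditions
every benchmark and test runs under.

**Spectral axis.** 400–2000 cm⁻¹ at 1.75 cm⁻¹ spacing → 915 bins.  The
instrument being emulated resolves ≈1.8 cm⁻¹ and yields more than 900
bins; 1.75 cm⁻¹ is the coarsest spacing satisfying both.

**Band model.** Each tissue's noiseless emission is a sum of Gaussian
bands taken from a machine-readable band-assignment table (center or
center range, vibrational mode, biomolecular assignment, ordinal 0–4
"star" score per tissue).  Choices:

- *Peak shape*: Gaussian, FWHM 12 cm⁻¹ for every band.  Tissue Raman
  bands are narrow (< 50 cm⁻¹) and approximately symmetric; a single
  default width is the simplest defensible choice and is a per-band field.
- *Star-to-amplitude map*: linear — a band contributes
  `stars × amplitude_per_star` times a unit-area Gaussian.  The star
  scores are ordinal; linearity is the minimal assumption and
  `amplitude_per_star` (default 1600 integrated counts) is a config knob
  chosen so a four-star band peaks near 500 counts, a realistic
  photon-counting scale for ~1 s integrations.
- *Center ranges* ("959–965") collapse to their midpoint; the range
  expresses biological variability, not a different line shape.
- *Zero-star entries contribute nothing.*  Consequence: synthetic bone is
  a single mineral line with no organic signal at all, which is stronger
  than real bone (≈40 % organic phase).  See "Limitations".
- *Cartilage vs ligament*: the band-assignment table pools both into one
  "connective" column.  To make them separable — as they are in real
  data — the generator applies two documented multiplicative tweaks:
  cartilage's 1448–1451 cm⁻¹ band is scaled to 0.35 (it is weak in real
  cartilage) and ligament's 959–965 cm⁻¹ mineral band to 0.25 (mineral
  deposits occur in articular cartilage, not ligament).  Both live in
  `GeneratorConfig.connective_tweaks`.

**Instrument terms.** A broad autofluorescence baseline (wide Gaussian
bump, FWHM 900 cm⁻¹, amplitude 1500 counts plus a 20 % constant floor —
roughly 3× the tallest Raman peak, so baseline removal is genuinely
exercised), optional per-bin multiplicative instrument response, Poisson
shot noise on the photon signal, Gaussian dark counts (mean 100, sd 5)
added per accumulation with an independently drawn laser-off dark frame
stored alongside, three accumulations per site, and a per-spectrum
log-amplitude jitter of 10 % (`class_jitter`) emulating coupling and
exposure variability.

**Datasets and trajectories.** The ex vivo geometry is a balanced
six-class dataset, default 27 spectra/class = 162, with site metadata
cycling over three synthetic animals.  Drilling trajectories are 1 mm
depth steps through a layer plan; `interface` steps emit a convex mixture
(default 0.5) of the neighbouring layers' profiles, emulating physical
tissue mixing in the drilling cavity; the epidural layer uses the fat
profile; the breach depth is the first spinal-cord step.  The default
in vivo plans are four trajectories of 12, 12, 12 and 8 steps (44 spectra)
with breaches at 9, 9, 9 and 7 mm.

**Randomness.** Every public generator takes one integer seed; internal
streams are spawned via `numpy` `SeedSequence`, so identical seeds give
bitwise-identical datasets and different seeds share no streams.

## Preprocessing chain

Applied in a fixed, provenance-recorded order: (1) dark subtraction,
(2) response correction (elementwise division), (3) Savitzky–Golay
smoothing, order 3, window 11, mirror padding, applied per accumulation,
(4) accumulation averaging, (5) baseline removal, (6) SNV.

Smoothing precedes averaging, matching the instrument-software
convention of smoothing each exposure as it arrives, although
the two commute only approximately under odd edge modes.  SNV uses the
population (divide-by-n) standard deviation: unambiguous and idempotent;
a sample-sd variant would be a one-line change.  Saturated or non-finite
inputs are rejected, not repaired.

**Baseline estimator.** A bubble (rolling-circle) morphological
algorithm: grow the largest circle that fits under the spectrum on an
interval (in axis-normalized coordinates), raise it until it touches,
split the interval at the touch point, recurse while intervals are wider
than `min_bubble_width` (default 100 cm⁻¹ — far above the 12 cm⁻¹ band
width, far below the ≥500 cm⁻¹ baseline scale).  An endpoint touch
shrinks the interval by one sample so recursion always progresses.  The
spectrum is mirror-padded by one bubble width so the envelope does not
droop at the edges, and the envelope's touch-point scallops are evened
with a quadratic Savitzky–Golay pass (window ≈ 1.4 bubble widths) before
clipping to the input.  The Raman part is defined as the exact residual:
`raman + baseline` reconstructs the input bit-for-bit, and the baseline
never exceeds the input.  Any estimator meeting this contract
(e.g. a library rolling ball) would be interchangeable.

On the noiseless decomposition test (12 cm⁻¹ peaks on a 600 cm⁻¹
background) the recovered peak component correlates with truth at
r ≈ 0.998 and a lone narrow peak keeps > 95 % of its area.

## Classification models

Feature selection is a liblinear L1-penalized linear SVM (squared hinge);
for the six-class task the one-vs-rest coefficient rows are pooled and a
bin is retained if any row is nonzero, reported with its largest
coefficient magnitude.  Classification is an L2-penalized linear SVM on
the retained bins only.  The grid is 10 log-spaced C1 values in
[0.005, 0.05] × 10 log-spaced C2 in [0.1, 5].  For each C1, features are
selected independently within each of five stratified CV folds; a C1
whose selection is empty or reaches 20 bins on any fold is discarded
(feature budget).  The winning pair minimizes summed validation
misclassifications (= FP + FN for the binary tasks, total off-diagonal
for six classes), tie-breaking toward fewer features, then smaller C2,
then smaller C1.  The final model refits selection and classifier on the
full 60 % partition and calibrates a per-class Platt sigmoid on
out-of-fold decision values; multiclass probabilities are normalized
per-class sigmoids.  The 60/40 split is stratified with largest-remainder
allocation totalling ⌈0.6 n⌉, so 162 balanced spectra split 98/64.

Probability orientation for the binary tasks is 1 = spinal cord / soft
tissue, 0 = bone; plotting utilities can flip to the bar-chart convention
(1 = bone) via `probability_profile(report, orientation="bone")`.

Breach detection applies the full preprocessing chain to each depth step
and reports the shallowest depth whose calibrated soft probability
exceeds 0.5.  No smoothing across depths: classification is
per-measurement, and the ROC-optimal threshold is available as an
alternative to 0.5.

## Problem sizes used by the benchmark study

The repeated-seed study (`ramanspine.benchmark.run_protocol`, also run by
`scripts/acceptance.py`) uses ten independently seeded datasets of 162
spectra, the full 10×10 grid with fivefold CV for each of the three
tasks, and four drilling trajectories (44 spectra) per seed — about two
minutes on one CPU in total.

## What passing tests do and do not show

The generator produces linearly separable classes by construction once
noise and baseline are removed: band positions are exact, amplitude
jitter is global per spectrum, and noise is uncorrelated across bins.
Perfect hold-out accuracies on synthetic data therefore validate the
*pipeline* — that preprocessing preserves the discriminative band
structure and that selection, tuning, and calibration are implemented
correctly, with the hold-out untouched during training — not the
real-world difficulty of the task.  Real tissue adds band-position
variability, correlated biochemical composition across sites, bleeding
and water films, and probe-coupling effects that this generator does not
model.

A known consequence of the band model: because synthetic bone carries
*no* organic bands, the absence of protein/lipid signal identifies bone
as perfectly as the presence of the 961 cm⁻¹ mineral peak does.  The L1
stage therefore reliably *selects* a mineral-band bin for the binary
tasks, but the bin with the largest raw coefficient magnitude is usually
an amide or C–O/C–N band: SNV gives the mineral bin roughly ten times the
dynamic range of other bins, so a small coefficient suffices for it, and
raw coefficient magnitude is a scale-dependent importance measure.  In
real bone spectra the organic bands are present (bone is ≈40 % organic),
which removes the absence-of-signal shortcut and makes the mineral peak
the dominant selected feature.  This discrepancy is intrinsic to the
zero-star-means-zero band model and is reported as-is rather than patched
with post-hoc generator components.

## Numerical notes

- All SVM fits run liblinear with tight tolerances (1e-5 selection,
  1e-6 classification) and high iteration caps; fits are deterministic
  given the data, so reproducibility reduces to seeding the generator,
  the splitter, and the fold shuffler.
- Degenerate inputs fail loudly: constant spectra cannot be SNV-scaled,
  constant decision scores cannot be calibrated, single-class inputs
  cannot be fit, and a grid whose every C1 violates the feature budget is
  a configuration error.
- ROC curves sweep all distinct score thresholds plus one above the
  maximum, store (sensitivity, specificity) pairs, and use trapezoidal
  AUC; the operating point minimizes Euclidean distance to the ideal
  corner with ties resolved toward higher sensitivity.
- Confusion matrices are oriented rows = predicted, columns = true, and
  every rendered matrix is labeled with that orientation.
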