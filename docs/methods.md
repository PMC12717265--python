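# Methods

`vapredict` predicts monocular far-distance visual acuity (VA, in logMAR)
from a subject's ocular wavefront aberrations by two routes: a *functional*
route that simulates what the subject sees and scores a virtual chart test,
and a *tabular* route that regresses measured VA directly on Zernike
coefficients, age and amplitude of accommodation with gradient-boosted
trees. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic test bed does and does not show.

## Optical model

The eye's monochromatic wavefront error over a circular pupil is expanded
in Zernike polynomials with OSA/ANSI single indexing and unit-variance
normalization (`sqrt(2(n+1))` for m != 0, `sqrt(n+1)` for m = 0); index
j = 0..35 covers radial orders up to 7. Coefficients are in micrometres
for a standardized 3 mm pupil (radius 1.5 mm), the scale clinical
aberrometers report.

The complex pupil function is `P = A(r) exp(i 2 pi W / lambda)` inside the
aperture, where `A(r) = 10^(-rho_sc r^2 / 2)` models the Stiles–Crawford
apodization (default `rho_sc = 0.05 mm^-2`, the usual literature value).
The default simulation wavelength is 555 nm (photopic peak): although
Hartmann–Shack devices measure in the near infrared, the optotypes are
simulated for visible viewing. Both are configurable.

The incoherent point-spread function is the squared magnitude of the
zero-padded pupil's FFT, normalized to unit sum. The pupil disc is
inscribed with a one-sample margin so its sampled aperture is exactly
invariant under 90-degree index rotations about the centre sample; this
makes the pure-defocus PSF symmetric on the grid to machine precision,
which the tests exploit. Defaults: 256 samples across the pupil, 3x
zero-padding. The PSF's natural angular sampling
(`lambda / (N dx)` per pixel) generally does not land on the optotype
canvas scale, so the kernel is bilinearly resampled onto the canvas's
pixels-per-degree, cropped to the smallest centred window holding all but
1e-9 of its mass, and renormalized.

Coefficient manipulations mirror clinical conditions:

- **correction** zeroes the three second-order terms (j = 3, 4, 5),
  emulating best spectacle correction;
- **defocus conditions** zero both astigmatism terms and set
  `c_2^0 = d r^2 / (4 sqrt 3)` for a trial-lens power `d` (D), measured
  relative to the corrected state, because clinical defocus curves start
  from best correction. Positive `d` (myopic wavefront defocus) gives a
  positive coefficient; the conversion is linear in `d`, quadratic in `r`;
- **spherical equivalent** is `SE = S + C/2`;
- the **vergence correction** for a chart at distance `d` metres is
  `-1/d` D (-0.25 D at the standard 4 m lane).

## Neural stage

Post-optical processing is modelled by a radially symmetric neural
transfer function NTF = SCSF / MOTF:

- SCSF(f) = `psi sech[(f/(phi f0))^p] - a sech[f/(phi f1)]` with the
  published fit psi = 373.08, f0 = 4.1726 cpd, f1 = 1.3625 cpd,
  a = 0.8493, p = 0.7786, phi = 1. With these numbers the subtracted
  low-frequency lobe is ~440x smaller than the gain, so the function is
  maximal at zero frequency rather than showing the band-pass peak of a
  raw contrast sensitivity curve; that is a property of the published
  parameter set, which this package evaluates verbatim.
- MOTF combines four exponential terms, two divided by `1 + AF/7`, where
  `AF = 1 + (age/70)^4` is an age factor. The expression is printed as a
  four-term sum whose weight pairs (0.426 + 0.574, 0.123 + 0.877) each sum
  to one, which strongly suggests a product of two bracketed factors was
  intended; both forms are implemented, the printed sum being the default
  for fidelity and the product a config switch. Because the NTF used for
  filtering is normalized to unit gain at zero frequency, the choice
  affects only the filter's shape, never the overall image level. Two of
  the exponents (e^-37f, e^-360f) decay so fast that those terms matter
  only below ~0.1 cpd; they are evaluated verbatim.

Filtering multiplies the image's spectrum by the DC-normalized NTF at each
pixel's radial frequency in cycles/degree, so the spatial mean is
preserved exactly before clipping; the mid-frequency contrast boost can
overshoot the [0, 1] intensity range, and the result is clipped back so
images stay displayable and trainable.

Retinal sampling is modelled as a band-limit at the Nyquist frequency of
the photoreceptor mosaic, default 120 samples/degree (foveal cone
spacing), applied in the Fourier domain with a raised-cosine edge over 10%
of the cutoff; it can be disabled. Neural noise is i.i.d. zero-mean
Gaussian with variance 0.01 on the [0, 1] intensity scale, clipped to
[0, 1], deterministic under a seed.

## Optotypes and the simulation pipeline

Letters come from the ten-letter Sloan alphabet on the classic 5x5 grid
(stroke = 1/5 of height) as programmatic geometric glyphs — no font file
is vendored; the geometric contract (height, stroke, shape topology) is
what the pipeline relies on. Sizing follows the logMAR convention: a
0.0 logMAR letter subtends 5 arcmin. The canvas is 224 x 224 pixels
spanning 1 degree (224 px/deg) — chosen so the largest protocol letter
(1.0 logMAR, 50 arcmin, 187 px) fits with margin; the angular field of the
canvas is an open design choice and is configurable. Rendering is binary
(ink 0.0 on background 1.0) and deterministic.

PSF convolution is linear with background-value padding (background 1.0),
so no periodic ghosts enter the canvas; with a unit-sum kernel and a
centred letter, mean intensity is conserved to well below 1e-6.

The full pipeline per presentation: render -> PSF convolution -> retinal
band-limit -> NTF filter -> Gaussian noise. Intermediates are retrievable
for debugging, and a PSF kernel can be precomputed per eye to amortize the
optical stage across letters.

## Recognition

Two recognizers share one contract (image -> recognized/unrecognized):

- A minimal CNN — 3x3 convolution with 8 filters, batch normalization,
  ReLU, 2x2/stride-2 max-pooling, a fully connected layer onto 2 classes,
  softmax with cross-entropy — implemented directly on numpy with Adam
  (learning rate 1e-3, the usual default; batches of 32, 10 epochs,
  70/15/15 splits). Initialization is seeded He-style; training is
  reproducible under a fixed seed. Ties at probability 0.5 go to
  "unrecognized" (the protocol-safe direction).
- A training-free Pearson-correlation template matcher against the ten
  noise-free letter templates at the same size and scale; a constant image
  is unrecognized by convention.

Confusion matrices are reported with axis-explicit names — row fractions
(per predicted class) and column fractions (per target class) — because
the conventional labels "sensitivity"/"precision" attach to different
axes in different reporting traditions; the axis-explicit numbers are
unambiguous.

## VA scoring protocol

Five letters per line, starting at 1.0 logMAR, stepping down 0.1 while at
least one letter is recognized, stopping at a fully-missed line or after
the floor line (-0.3). Final VA = last attempted line's logMAR + 0.02 per
error, with errors accumulated over **all** attempted lines; under this
reading a clean run that ends on a fully-missed line scores exactly the
previous line's value, matching letter-by-letter chart scoring. The
alternative (count only the terminal line) is available behind a flag.
Line levels are generated with exact two-decimal arithmetic so labels
never drift.

## Tabular dataset and boosting

Each eye contributes an uncorrected row and a corrected row; each
dominant eye adds nine defocus rows (-3.00 to +1.00 D in 0.50 D steps
over the corrected baseline). Rows with missing VA are dropped. The AA
gate encodes that accommodation can only compensate negative (trial-lens)
defocus: AA enters defocus rows only when the lens power is negative, is
zero for corrected rows, and for uncorrected rows gates on the sign of the
eye's spherical equivalent (an extension of the same physiology to the
as-measured state; flagged as this package's choice). The train/test
split is seeded uniform with the test set taking floor(0.2 n) rows.

LSBoost is written from scratch: F0 = mean(y), then CART trees fitted to
residuals, each entering with shrinkage nu. The CART split search is an
exhaustive scan over (feature, threshold) midpoints using prefix sums,
with growth stopped by depth, `min_leaf` or zero gain — verified against
a brute-force oracle on small datasets. Hyperparameters are not pinned by
any protocol, so defaults are conventional: 300 stages, nu = 0.1,
max depth 4, min leaf 5, all configurable and recorded in the model
metadata. XGBoost is wrapped behind the same surface (same defaults,
`n_jobs = 1` for determinism) and doubles as a cross-implementation
sanity check in tests; it is never used to implement LSBoost.

Feature subsets: the leading 5, 9 or 14 OSA coefficients (z1..zk) or all
36 (z0..z35), plus age and optionally the gated AA.

Metrics: MSE, RMSE, MAE, R^2, and the max, min, mode and median of the
absolute errors. The mode is computed after rounding to the 0.02-logMAR
letter quantum (errors are near-discrete multiples of it), ties broken
toward the smaller value — a declared rule, not an inferred one. The
optional outlier screen removes errors above 3 x std of the error sample
in a single pass (population std, no iterative re-estimation) and reports
both counts. Stratified analyses use six inclusive age bins (30-40,
41-44, 45-50, 51-55, 56-60, 61-65; float ages floored to years) and SE
groups (myopic < -0.5 D, emmetropic [-0.5, 0.5], hyperopic > 0.5 D), the
latter restricted to uncorrected rows since only those reflect an eye's
real refractive state.

## Synthetic cohort

The generator emulates the eligibility window of a healthy-adult
refraction study — ages uniform on 30–65 years, SE ~ N(-1.0, 2.0^2) D
clipped to [-7, +4], AA mean `max(0, 18.5 - 0.3 age)` D with 1.0 D
jitter truncated at zero (a Hofstetter-like decline), cylinder
`-|N(0, 0.75^2)|` D split into the two astigmatism coefficients at a
random axis, defocus `c_2^0` derived from SE, and higher-order
coefficients ~ N(0, 0.03^2) um.

Latent VA per condition follows a declared blur rule: the condition's
total defocus (SE for uncorrected, the trial-lens power once corrected)
is rescued by accommodation when negative, and
`VA = -0.1 + 0.18 (|residual| + 0.5 |cyl|) + 0.004 max(0, age - 50)`,
clipped to [-0.3, 1.1], plus N(0, 0.02) measurement noise. The simulated
observer converts latent VA to letter responses with
`P(recognized) = 0.1 + 0.9 logistic((presented - latent)/0.05)` — a 10%
guess floor and a 0.05-logMAR psychometric slope. A configurable number
of VA cells (default 11 on the 135-subject cohort) is blanked at random
to exercise the missing-data path.

All generative constants are fixture parameters chosen for clinical
plausibility and declared in `GeneratorConfig`; they are not estimates of
any real population. Consequently, passing tests demonstrate that the
machinery is correct and self-consistent — that the boosting stack
recovers a known blur rule, that the protocol tracks a known latent VA —
not that the models attain any particular accuracy on real eyes. Real
data differ in ways the generator does not emulate: correlated
higher-order aberrations, response errors beyond the guess floor,
pupil-size variation, and learning/fatigue effects.

## Problem sizes and budgets

Default test and acceptance runs use the study-scale cohort (135 subjects
/ 270 eyes / 1744 observations) for counting and splitting checks, a
500-subject cohort for the boosting-recovery property, 200 random small
datasets for the CART oracle, and a 200-image separable fixture (sharp
versus heavily defocused letters) for recognizer training — sizes chosen
to exercise every code path at desk scale.

## Known limitations

- The NTF is population-average; no per-subject calibration is attempted.
- No crowding/contour interaction, chromatic aberration, scatter, or
  pupil-size rescaling of coefficients.
- The Sloan glyphs are geometric approximations; stroke topology is
  faithful but fine typographic detail is not.
- The CNN is intentionally tiny and trained on synthetic labels here;
  its confusion-matrix performance on real clinical responses depends on
  the deposited clinical dataset, which this package treats as an
  optional external benchmark, not a bundled artifact.
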