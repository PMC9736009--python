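# Methods

## The measurement and its model

A honey (or honey/syrup) sample on a microscope slide is trans-illuminated
with broadband light; a tunable bandpass filter sweeps the visible range and
a camera records one image per centre wavelength, giving a hypercube of
intensities `(n_bands, rows, cols)`.  The default wavelength grid is 311
bands, 420–730 nm at 1 nm steps; all band arithmetic in the package is in
nanometres, never band indices, so fitted coefficients are portable across
grids.

Transmittance at a wavelength is the ratio of transmitted to incident power,

    tau(lambda) = P(lambda) / W(lambda),

where `W` comes from a white-reference acquisition (illumination alone)
processed through the identical spatial path as the sample.  The measured
per-band signal is modelled as the deterministic transmittance plus additive
spatial white readout noise, `rho = tau + eta`, with `eta` independent across
pixels and bands.

## Synthetic acquisitions

No public archive of raw cubes exists for this instrument class, so the
package generates cube pairs with the statistical structure the analysis
assumes.  The generator is a pure function of (configuration, seed).

* **Endmembers.**  Each pure material (two honeys, three syrups by default)
  gets a transmittance spectrum `exp(-A(lambda))` where the absorbance `A`
  is a seeded baseline (uniform 0.1–0.8) plus 3–6 broad Gaussian bumps
  (centres anywhere on the grid, widths 40–120 nm, heights 0.2–1.2).  The
  construction keeps values in (0, 1], yields gently curving spectra a short
  sinusoid expansion can represent, and the whole library is redrawn (up to a
  bounded retry count) until every material pair differs by at least the
  `separation` parameter (default 0.15) somewhere on the grid, so classes
  are distinguishable by construction.
* **Mixtures.**  The bench recipe mixes honey and syrup to a fixed total
  mass (23 g default) at honey mass fractions 100/90/80/70/60 %.  Mixture
  spectra are linear in transmittance by mass fraction by default;
  a Beer–Lambert mode (linear in absorbance) is provided since physics
  favours it — for these gently varying spectra the two differ little.
* **Illumination.**  Koehler alignment is emulated by its effect: a smooth
  multiplicative field `1 - falloff * (r/r_max)^2` (default falloff 0.15)
  times a broad positive lamp spectrum of order one.  The white cube is this
  product plus noise; the sample cube multiplies in the mixture
  transmittance before noise.  Dividing the noiseless cubes recovers the
  mixture spectrum to machine precision.
* **Noise.**  `sigma_read` (default 0.002 intensity units, the low-noise
  regime) scales i.i.d. Gaussian noise per pixel per band; an optional
  per-band vector modulates it.  Negative post-noise intensities are clipped
  to zero (vanishingly rare at default noise).

What the generator does **not** emulate: optical point-spread and defocus,
the filter's finite bandwidth, pixel-correlated (fixed-pattern) noise,
scattering particles and bubbles, and the full biochemical variability of
real honey.  Passing tests therefore demonstrate that the *pipeline
machinery* — calibration, compression, classification, metrics — behaves as
specified under its stated statistical assumptions, not that real adulterated
honey is classified at the reported rates.

## Preprocessing

A rectangular region of interest (0-based, half-open, extents forced to
multiples of the neighborhood size) is tiled into non-overlapping 4×4
neighborhoods; each tile's pixels are averaged into one spectral curve, and
sample curves are divided by white-reference curves tile-by-tile.  The order
is fixed as average-then-divide: the tile mean estimates transmitted power,
and it differs from divide-then-average whenever illumination varies inside
a tile.  Transmittance values above 1 (possible under noise) are flagged,
never clipped, so noise statistics stay unbiased.  A seeded subsample
without replacement caps each class at `n_per_class` curves (default 100).

## Sum-of-sines compression

Each curve is approximated by

    tau_hat(lambda) = sum_{n=1}^{N} a_n sin(b_n lambda + c_n),  N = 8,

so 311 samples collapse to 24 coefficients (~13× reduction).  Fits are
canonicalized — `a_n >= 0`, `b_n >= 0` (zero allowed), `c_n` in (-pi, pi],
terms sorted by ascending frequency — collapsing the symmetry family
`a sin(b L + c) = -a sin(b L + c ± pi)` to a unique representative.  The
coefficient vector is interleaved `(a1, b1, c1, ..., a8, b8, c8)`.

**Starting points.**  Two deterministic initializations are tried, then
seeded jitters of the second (5 starts total by default):

1. *Half-Fourier linear start.*  Frequencies fixed at quarter-wave harmonics
   of the grid window, the lowest slot a near-DC term that absorbs the
   curve's mean; amplitudes and phases solved by ridge-regularised linear
   least squares (ridge 1e-4 of the mean Gram eigenvalue).  The low-frequency
   sine/cosine columns are nearly collinear over a finite window; without the
   ridge the solver returns huge mutually cancelling amplitudes whose
   null-space component varies wildly between near-identical curves.  For
   smooth transmittance spectra this start is already near the optimum.
2. *Spectral-peak start.*  Frequencies from the largest magnitude bins of
   the mean-removed curve's discrete Fourier transform (adjacent bins
   suppressed), amplitudes and phases from the bin values.  This start wins
   for genuinely oscillatory inputs.

Starts are attempted in order and skipped once one reaches RMSE < 0.005
(half the 1 %-of-full-scale quality target), since jitter cannot meaningfully
improve such a fit.

**Optimizer.**  A package-local Levenberg–Marquardt (damped Gauss–Newton
with Marquardt diagonal scaling and Nielsen's gain-ratio damping update,
analytic Jacobian, own Cholesky solve).  Two properties motivated owning
this solver rather than delegating:

* *Bit-reproducibility.*  Vectorised transcendental kernels choose SIMD code
  paths by buffer alignment, giving ULP-level run-to-run differences that a
  chaotic descent amplifies into materially different (equal-quality)
  coefficient vectors.  All evaluations here run on explicitly 64-byte-
  aligned, reused buffers, and all remaining operations are exactly rounded,
  so identical inputs give bit-identical fits regardless of heap or library
  state.  Identical curves therefore produce identical feature rows and
  pipeline reruns are byte-identical.
* *Feature stability.*  The cost surface has flat valleys (a near-zero
  amplitude leaves its frequency and phase free).  Iterating far below the
  measurement noise does not improve the fit but drifts coefficients along
  those valleys, degrading their comparability across curves — measured as a
  drop of cross-validated accuracy from 100 % to ~78 % on an otherwise
  identical run.  The optimizer therefore runs in 100-evaluation segments
  and stops, keeping the pre-drift iterate, once a segment improves RMSE by
  less than 0.1 % relatively.  Stopping that way (or via the cost-decrease /
  step-size / gradient tolerances, default 1e-10) sets `converged=True`;
  exhausting the overall budget while still improving leaves
  `converged=False` with the best-so-far fit — never an exception.

The per-curve RMSE (transmittance units; ×100 gives percent of full scale)
is recorded alongside the coefficients.  On default synthetic curves the
maximum RMSE across 100 curves is ≈ 0.07 %, comfortably below the 1 %
benchmark for this compression.

## Classification

One classifier per honey×syrup combination (default; a joint mode pools
combinations) over the four adulterated classes (90/80/70/60 % honey), 100
feature rows each, with stratified 10-fold cross-validation.  Families:

* **LDA** — pooled full-covariance Gaussian discriminant, priors from
  training frequencies.  The pooled covariance is regularised by a 1e-6
  shrinkage toward the scaled identity (the closest supported form of a
  small diagonal ridge) so it is always invertible.
* **Quadratic SVM** — soft-margin SVM, degree-2 polynomial kernel, C = 1,
  `coef0 = 1`, one-vs-one multiclass voting.  The kernel scale is set
  automatically per training fold as the median pairwise distance of the
  standardized training features (`gamma = 1/median²`).
* **NN** — one fully connected hidden layer of 100 ReLU units, softmax
  output, cross-entropy loss, full-batch L-BFGS, L2 penalty 1e-4, iteration
  cap 1000, seeded initialization.

Amplitude, frequency and phase columns live on wildly different scales, so
every family z-scores features with training-fold statistics only; nothing
fitted ever sees its test fold (verified by a label-corruption test).

## Metrics

Multiclass predictions are tallied into a confusion matrix with fixed class
order, reduced one-vs-rest to per-class (TP, FP, FN, TN), and reported as
precision, recall, specificity and F1 in percent, plus unweighted macro
averages and overall accuracy = 100·trace/total (for balanced classes this
equals the mean per-class recall exactly).  A zero denominator yields 0 with
a degeneracy flag rather than an error.  Report tables round at one decimal,
half away from zero; underlying values keep full precision.

## Problem sizes

Default cubes are 64×64×311 (desk scale; the sensor-size 1200×1920 is
configurable), giving 256 curves per class before subsampling to 100.  The
default-scale reproduction in the test suite runs 2 honeys × 3 syrups × 4
levels × 100 curves (2 400 fits) and cross-validates the SVM per
combination; the acceptance script fits 100 curves drawn across all thirty
honey–syrup–fraction conditions from 8×8 cubes.

## Known limitations

* The sinusoid expansion has no constant term; the mean is carried by a
  near-DC component, whose amplitude/phase trade-off is one of the flat
  valleys discussed above.
* Coefficients are only meaningful comparatively when produced by the same
  initialization policy; mixing feature matrices from different `n_terms`
  or policies is unsupported.
* The per-combination classifier layout matches the benchmark design;
  the joint mode is provided but has no published reference behaviour.
* Phase coefficients wrap on (-pi, pi]; curves whose phase sits near the
  boundary can split into two clusters in feature space.  The z-scored
  kernels tolerate this at default conditions.
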