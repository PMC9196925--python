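# Methods

## Problem and scope

Multispectral autofluorescence lifetime imaging (maFLIM) dermoscopy records,
at every pixel of a lesion image, a fluorescence decay in each of three
emission bands (390, 452 and ~500 nm, targeting collagen, NADH and FAD).
Malignant transformation alters both the spectral balance and the temporal
dynamics of these endogenous fluorophores, so per-lesion summaries of the
decay parameters can feed a classifier that separates benign from malignant
pigmented lesions. This package implements the full analysis chain —
preprocessing, time-domain biexponential features, frequency-domain phasor
features, and QDA classification with patient-level cross-validation — and,
because the clinical image data are not publicly available, a synthetic-data
generator that emulates the statistical structure of such a study so the
chain is testable end to end.

## Forward model and synthetic data

Each pixel's measured decay is modelled as the convolution of the
instrument response function (IRF) with a biexponential fluorescence
impulse response (FIR)

    h(t) = a_f exp(-t/tau_f) + (1 - a_f) exp(-t/tau_s),   0 <= a_f <= 1,
    0 < tau_f <= tau_s,

scaled by a per-channel intensity. The IRF is a unit-area Gaussian pulse
(FWHM 1 ns by default), the standard surrogate for a measured excitation
reflection. The generator evaluates the convolution *analytically* — the
Gaussian ⊛ exponential product is an exponentially-modified Gaussian,
computed via `erfcx` for overflow safety — and samples it on the 0.4 ns
acquisition grid (149 samples per channel, 2.5 GHz digitiser). Sampling the
continuous convolution, rather than convolving discretely on the grid,
matters for the frequency-domain path: the ratio of the DFTs of sampled
continuous signals recovers the continuous frequency response essentially
exactly (the Gaussian spectrum suppresses aliasing below 1e-9), whereas a
rectangle-rule discrete convolution leaves sampled-exponential phasors
visibly inside the universal semicircle (deviation ~0.03 at the 9th
harmonic for tau = 3 ns). A trapezoid-rule discrete convolution remains
available for IRFs known only through their samples.

Per-channel IRF arrival times are staggered by one sample
(4.0 / 4.4 / 4.8 ns) by default, reflecting unequal detection path delays.
This is not cosmetic: the phasor path concatenates the three channels, and
for bitwise-identical per-channel IRFs the concatenated spectrum is exactly
zero at every harmonic not divisible by three (3-fold segment symmetry),
which would make the frequency-domain division ill-posed. The code detects
and reports that degeneracy.

A scene is two regions — a centred disc covering 30% of the field of view
(the lesion) and its surround — each with its own per-channel
(a_f, tau_f, tau_s, intensity). Defaults sit in the range reported for skin
autofluorophores: sub-ns fast lifetimes, slow lifetimes of 3.5–5 ns,
fast-component weights 0.6–0.75, channel intensities of a few hundred
counts. A constant baseline offset (100 counts) keeps the pre-pulse
baseline clear of the ADC floor so that noise statistics survive clipping;
Gaussian noise is injected per pixel at a configurable peak SNR (default
25 dB, comfortably above the 15 dB masking threshold), with Poisson noise
as an option. Optional artifacts: railed (saturated) pixels and dark
"hair" stripes.

Cohorts follow the clinical study layout: 30 patients, 60 lesions, 41
benign / 19 malignant, each patient single-diagnosis, with per-patient
lesion counts matching the published distribution (2x5 + 15 patients for
the benign lesions; 2x3, 5x1 and 6 patients sharing 8 for the malignant
ones). Malignant lesions receive additive shifts of the lesion-region
parameters — by default on exactly the parameters the clinical analysis
found most discriminant (tau_fast and alpha_fast at 452 nm, tau_slow and
alpha_fast at 390 nm, alpha_fast at 500 nm). Per-patient random offsets are
applied identically to both regions of all of a patient's lesions, so the
region-difference features isolate the class effect while absolute
parameter levels vary across patients.

What the generator does *not* emulate: real skin texture, melanin
absorption, spatially varying decay parameters within a region, detector
afterpulsing, or instrument drift. Passing tests therefore demonstrate the
correctness and statistical sanity of the analysis chain, not clinical
performance.

## Preprocessing

Per pixel: (1) baseline removal by a joint least-squares line through the
first and last five time points of each channel (the joint fit was chosen
over two independent end fits; it is idempotent and exact for linear
baselines); (2) 5x5 spatial box averaging, with border pixels averaged over
their in-bounds neighbours only; (3) masking of pixels that saturate the
ADC in any channel (tested on the raw cube, where the railed signature is
intact) or whose SNR falls below 15 dB. The SNR estimator is
20*log10(peak / sigma) on the channel with the largest peak, where sigma is
the standard deviation of the signal-free samples at both trace ends (6
pre-pulse + 10 fully-decayed tail samples) and the peak is taken after a
3-sample smoothing so it is not dominated by the noise maximum; the
estimator tracks the generator's injected SNR within ~0.5 dB over 20–30 dB.
(4) Channels are tail-padded with zeros to the longest channel length
M = 149 and concatenated in band order into a 447-sample vector; (5)
K-means (k = 2, 10 restarts, fixed seed, Euclidean distance on the raw
concatenated decays) splits the valid pixels into region-1/region-2.
Region numbering is arbitrary; every downstream feature is invariant to it.

## Time-domain features

Each valid pixel and channel is fit by nonlinear least-squares iterative
reconvolution of the biexponential FIR, with the amplitude scale projected
out in closed form (variable projection), initialisation (0.5, 1 ns, 5 ns),
box bounds a_f in [0,1], lifetimes in [0.02, 25] ns, and post-fit
canonicalisation tau_f <= tau_s. Two fitters share the model kernel: a
per-decay scipy `least_squares` reference (supporting 1–3 exponential
components, used for the model-order check) and a batched
Levenberg–Marquardt fitter vectorised over pixels (numeric Jacobians,
per-pixel damping, active-set freezing of converged pixels) that makes
whole-cohort fitting tractable on one CPU; a test pins the two to each
other. When the IRF is parametric the kernel reconvolves analytically
(exact); with raw IRF samples it falls back to a trapezoid-rule discrete
reconvolution, which carries a few-percent discretisation bias for
lifetimes comparable to the 0.4 ns sample spacing — documented, tested at
its honest accuracy, and not used by the default pipeline. Noiseless
recovery over the grid a_f in {0.3..0.9}, tau_f in [0.3, 2] ns,
tau_s in [2.5, 8] ns is exact to ~1e-10 relative.

Derived per-pixel maps: the intensity-weighted average lifetime
tau_avg = (a_f tau_f^2 + (1-a_f) tau_s^2) / (a_f tau_f + (1-a_f) tau_s)
(equal to the FIR's normalised first moment; verified against numerical
quadrature), the absolute intensity I = s (a_f tau_f + (1-a_f) tau_s)
(the FIR time integral in closed form), the per-pixel channel-normalised
intensities, and the three normalised-intensity ratios. Non-converged
pixels are flagged and excluded from all region statistics.

A *global* feature is the absolute difference of the two region medians of
a pixel map — label-free (invariant to region renumbering) and robust to
patient-level offsets. The time-domain pools are the 6 intensity features
(3 normalised intensities + 3 ratios) and the 12 biexponential features
(a_fast, tau_fast, tau_slow, tau_avg per channel).

## Phasor features

Instead of per-pixel iterative fitting, the instrument response is removed
by one division in the frequency domain: P(w) = Y(w) U(0) / (U(w) Y(0)),
where Y and U are the 447-point DFTs of the concatenated decay and IRF.
The DFT length is exactly 3M (no power-of-two padding) so the harmonic
bins fall on k * f_s / (3M); the first nine harmonics (resolution
f_s/(3M) = 5.59 MHz, nominally printed as the 5.6 MHz grid up to 50.4 MHz)
cover the ~60 MHz fluorescence bandwidth. Feature names use the nominal
5.6 k MHz labels while the computation uses the exact bin frequencies.
Each pixel yields a phasor point (G, S) = (Re P, Im P) per harmonic;
monoexponential decays land on the universal semicircle
(G - 1/2)^2 + S^2 = 1/4 (verified to ~1e-7), and the phasor lifetime
S/(wG) matches the time-domain fit within far less than 1%.

Per harmonic, a bivariate Gaussian is fit to each region's point cloud by
sample moments (mean and 1/n covariance — the maximum-likelihood fit,
applied to the raw points rather than a binned histogram). Four features
compare the two regions: *distance* |mu1 - mu2|; *spread*
|det(Sigma1) - det(Sigma2)| (the covariance determinant being the cloud's
spread measure; a Frobenius-norm alternative is available behind a
keyword); *angle*, the acute angle between leading eigenvectors (degrees,
0–90); *symmetry* |s1 - s2| with s_i the major/minor eigenvalue ratio
(>= 1, removing axis-labelling ambiguity). Point-like clouds (covariances
at float-rounding scale) define angle = symmetry = 0; a rank-deficient
(line) cloud has no axis ratio and flags symmetry as NaN, excluded
downstream. 9 harmonics x 4 features = 36 phasor features. On the same
image the phasor pool is orders of magnitude faster to extract than the
biexponential pool (asserted as an ordering only).

## Classification

Lesion-level records (patient ID, diagnosis, features) are classified by
QDA: class-conditional Gaussians with unbiased covariance estimates,
empirical class priors (equal priors behind a keyword), a ridge of
1e-6 x mean diagonal added when a class covariance is near-singular, and a
0.5 posterior threshold with malignant as the positive class. The posterior
is computed from Cholesky factorisations and matches both the direct
density formula (to 1e-10) and scikit-learn's QDA.

Feature selection is greedy sequential forward search (SFS) maximising the
ROC AUC of the QDA on the fold's training patients (resubstitution; an
inner-LOPO scoring mode is available), with exact ties resolved toward the
pool's canonical order. SFS runs independently inside every fold of a
leave-one-patient-out cross-validation, so the left-out patient's lesions
never inform selection or training. The SFS feature count is swept from 1
to floor(sqrt(n_lesions)) = 7 (capped at the pool size) and the count with
the best aggregate F-score is kept, ties preferring higher sensitivity,
then fewer features. Features chosen in at least 50% of folds form the
pool's `fselected` set.

Ensembles average the pool-specific QDA posteriors with non-negative
weights summing to one. Weights are optimised per outer fold on a 0.1-step
simplex grid (11 vectors for two pools, 66 for three): an inner LOPO loop
over the training patients produces held-out posteriors per pool, each
grid vector is scored by the distance of its (1 - specificity,
sensitivity) operating point from the ideal (0, 1), and ties return the
lexicographically smallest vector. The pool QDAs are then retrained on all
training patients and the left-out lesions classified by the weighted
posterior.

No multiple-testing correction is applied anywhere (none is part of the
procedure being implemented).

## Validation experiments and problem sizes

The repository's standing experiments (analysis/05, the acceptance script,
and the acceptance tests) use desk-scale problem sizes chosen so the whole
chain runs in minutes on one CPU while leaving the procedure untouched:
32x32-pixel images (the clinical instrument's 140x140 grid is supported),
the full 30-patient / 60-lesion cohort layout, 100-point noiseless recovery
grids, and 20 label permutations for the null.

* Strong-effect recovery: with the large malignant shifts, low
  inter-patient spread and 35 dB SNR, the biexponential-pool LOPO-CV sweeps
  to 100% accuracy — the pipeline recovers a class effect it should
  trivially see.
* Permutation null: with zero class effect the features carry no label
  information. Mean LOPO-CV accuracy over 20 patient-label permutations
  sits at ~45–50%, i.e. at or slightly below coin-flip chance and far below
  the 68.3% majority base rate. This is expected, not a bug: SFS inside
  each fold picks the feature with the largest spurious training
  separation, which anti-generalises on held-out patients under the null,
  overwhelming the empirical-prior pull toward the majority class. The
  meaningful assertions are that the null never *beats* the base rate
  (leakage check) and that the strong-effect accuracy exceeds the entire
  null distribution.

## Numerical choices and degenerate inputs

* Fit convergence: relative parameter step < 1e-8 or iteration cap;
  non-converged pixels are excluded from medians, never imputed.
* tau_f = tau_s fixtures are accepted (the fit degenerates gracefully;
  tau_avg remains well-determined and is the asserted quantity).
* All-zero decays: SNR is -inf, the pixel is masked.
* Zero-sum concatenated signals are flagged NaN by the unit-sum
  normalisation (which is otherwise a no-op for the phasor, since the DC
  division already normalises).
* K-means degeneracy (all valid pixels in one cluster, e.g. a featureless
  image) raises with a diagnostic rather than returning an empty region.
* Exact SFS/AUC ties and weight-grid ties resolve deterministically
  (canonical feature order; lexicographically smallest weight vector), so
  every pipeline run is bit-reproducible given its seed.

## Known limitations

* The synthetic cohort is far easier than clinical data (piecewise-constant
  regions, Gaussian noise, exactly biexponential decays), so classification
  metrics on it say nothing about clinical accuracy; only the worked-example
  metric recomputations connect to the published clinical numbers.
* The sampled-IRF (non-parametric) reconvolution path has a few-percent
  lifetime bias at dt = 0.4 ns for sub-ns components.
* Phasor features at harmonics not divisible by three are noise-amplified
  under the default staggered-IRF geometry (the segment-symmetry
  suppression); spatial averaging mitigates but does not remove this.
* The 50% selection-frequency rule and the 0.1 weight grid are inherited
  procedure constants, not tuned quantities.
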