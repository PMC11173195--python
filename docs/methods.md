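# Methods

This note documents the models, conventions and numerical choices behind
`socialmap`, and what the synthetic-data tests do and do not establish
about real data.

## The experimental design being emulated

36 personality-trait concepts in a 2×2 factorial (affect × social
desirability, 9 concepts per cell) are presented auditorily, once per run,
in an event-related design: 0.25 s fixation, 0.5 s blank, 3.5 s audio
definition, 2.0 s mental simulation.  Event onsets refer to **audio onset**
and event duration to the 3.5 s stimulus; the jittered intertrial interval
runs from audio offset to the next trial's audio onset and follows a
pseudo-exponential distribution over 6–8 s (mass halving per 0.5 s step:
50%, 25%, 12.5%, 6.25%, with the residual 6.25% assigned to the final 8 s
bin so the distribution sums to one).  Under this convention 36 trials fit
comfortably inside a 537-volume run at TR 0.85 s, matching the acquisition
being emulated; had the ITI been measured from the end of the simulation
period instead, a full run would not fit, which is why the stimulus-offset
reading is the one implemented.  `draw_itis` offers a *sampled* mode
(i.i.d. draws) and a *deterministic* mode (largest-remainder allocation of
exact counts, shuffled), the latter giving exact proportions whenever the
trial count divides the probability denominators.

## BOLD synthesis

Signal is baseline + Σ events (HRF-convolved boxcar × concept pattern) +
linear drift + i.i.d. Gaussian noise, with optional volume-wise Gaussian
smoothing last.  The HRF is the canonical double gamma (peak 6 s,
undershoot 16 s, peak:undershoot ratio 6:1, unit dispersions), normalized
to unit peak.  Regressors are built on a grid `oversample` (default 10)
times finer than the TR and sampled at volume onsets; `oversample=1`
reduces exactly to discrete convolution at TR resolution, which is what the
unit-test oracle computes.

Ground truth is a `SignalSpec`: a list of regions, each with one amplitude
vector per concept (36 × n_roi_voxels), so any labeling of the concepts is
recoverable.  The default spec implants

- an *affect* region whose concept patterns are ±v (high/low affect) plus
  concept-specific jitter (relative SD 0.25) — class patterns are fixed per
  subject and shared across runs, since cross-run decoding presumes stable
  patterns;
- a *desirability* region, likewise, at a spatially distinct location;
- optionally an *RSA* region whose 36 patterns are a random linear
  projection of the sentence-embedding matrix, so that local
  representational geometry matches the embedding RDM, and the
  feature-to-voxel mapping is shared by all subjects built from the same
  spec (the premise of the encoding analysis).

Defaults: 24³ grid at 2.4 mm (tests mostly use 12³) with an ellipsoidal
brain mask; baseline 100; `effect_scale` and `noise_sd` in the same
arbitrary signal units.  "Moderate effect" in the recovery tests means
effect scale 3 against noise SD 1 — chosen once as a regime where a single
subject's searchlight shows a clear but not saturated advantage.

What the generator does **not** emulate: physiological noise, motion,
spatial autocorrelation of noise, field inhomogeneity, intersubject
anatomical variability (all synthetic subjects share one grid).  Passing
recovery tests therefore demonstrate the correctness of the analysis code
and its calibration under well-behaved noise, not robustness to scanner
artifacts.

## Data preparation

Order of operations: trim the first 10 volumes (onsets re-referenced by
−10·TR) → drop voxels whose variance is ≤ tolerance in *any* run → per
voxel, remove the least-squares line and scale the residual to unit
variance (a single combined linear model; the residual mean is zero by
construction, so detrend-then-scale and a two-pass z-score+detrend
coincide) → stack runs → one example per trial by averaging all volumes
whose acquisition midpoint (i+0.5)·TR falls in [onset+5.5, onset+10.5).
The half-open midpoint rule is this package's convention; only the window
bounds are inherited from the protocol being emulated.  Trials whose window
extends past the run end are dropped with a warning; voxels with no
post-detrend variance are zeroed and flagged.

## Searchlight decoding

Spheres are defined by center-to-center mm distance through the affine
(handles anisotropic grids); at the default 4 mm radius on a 2.4 mm grid a
sphere holds 19 voxels.  Per sphere: features standardized on the training
set only; linear SVM (margin penalty C=1) wrapped in sigmoid probability
calibration with an internal CV of min(3, smallest-class-count) folds —
the calibration settings are this package's choice, as is pairing the
dummy classifier seed-for-seed and fold-for-fold with the real classifier.
The dummy emits label-independent uniform random probabilities, so its AUC
distribution is centered on 0.5 and the difference map is centered on zero
under the null.

Three cross-validation schemes are first-class: the 100× stratified 80/20
shuffle reproduced from the original protocol (deliberately ignoring run
structure), and two leakage-safe alternatives — leave-one-run-out and
leave-two-concepts-out (one held-out concept per class, 18×18 = 324
candidate folds, subsampled reproducibly via `max_folds`).  Note that with
concept-specific pattern jitter, schemes that keep the same concepts in
train and test (stratified, leave-one-run-out) can decode partly through
concept identity; leave-two-concepts-out is the scheme that certifies
generalization to unseen concepts.

Reproducibility: each sphere's sub-seed is derived from the master seed and
the center's flat grid index via `SeedSequence`, so results are invariant
to traversal order and parallelism.

## Group inference

Observed statistic: TFCE of the group mean map (E = 0.5, H = 2,
dh = max/100, 26-connectivity — the standard published parameterization;
the variance-normalized t-map variant is available but off by default,
since difference-from-chance maps are fed directly).  Null: max TFCE over
the mask under random per-subject sign flips; corrected
p = (1 + #{perm max ≥ observed}) / (1 + n_perm), so p is never 0 and never
below 1/(1+n_perm).  This yields weak family-wise error control by the
max-statistic argument; the suite verifies ≈5% empirical FWER on
zero-signal experiments (20 replicates × 10 subjects × 200 permutations —
a deliberately scaled-down version of the 10 000-permutation production
setting, sized so the whole calibration runs on a desktop in about a
minute).  Because a sign-flip null has only 2^n distinct patterns, at
least ~6 subjects are needed before p < 0.05 is attainable at all.  The
desirability-vs-affect contrast is implemented as paired differences over
the same subjects.

## RSA and noise ceilings

RDMs are 1 − Pearson over rows; vectorization uses the strict upper
triangle; Spearman uses average ranks for ties; Fisher z = arctanh with
|rho| clipped at 1 − 1e−7.  The chance map is the mean z over concept-row
shuffles (default 100) — the aggregator is this package's choice.  Noise
ceilings per sphere: lower = mean over subjects of Spearman(subject RDM,
mean RDM of the others); upper = the same against the mean including the
subject.  Lower ≤ upper is not a theorem for rank correlation, but
violations beyond noise indicate mismatched inputs and are warned about.

## Encoding-based RSA

Ridge regression maps sentence features to voxels, trained on all subjects
but one; the L2 penalty is selected from {0.01, 0.1, 1, 10, 100, 1000} by
an inner leave-one-subject-out loop scored by mean per-voxel Pearson
correlation between predicted and held-out values (the grid and the scoring
criterion are this package's choices).  Features are standardized on the
training stack.  Voxels are split into 20 equal contiguous chunks fit
independently; ridge is separable across targets, so chunked and unchunked
predictions agree to numerical precision (tested), and chunking exists
purely to bound the weight-matrix memory at the full 16 128-feature scale.
The held-out subject's data never enters standardization, penalty
selection, or fitting — audited by a test that corrupts the held-out data
and asserts an unchanged encoder.

## Language-model features

The extraction contract is: per-token hidden states of one layer (default
8, width 768), right-padded with zeros to 21 tokens, flattened to 16 128
elements.  Zero-padding (rather than truncation or repetition) is this
package's convention for shorter sentences.  The default backend is a
deterministic stub (hash-seeded Gaussian states) so the package builds and
tests without model downloads; a HuggingFace backend with identical
interface is available when `transformers` is installed.  Feature-space
decoding holds out one item per class (324 folds), scores the pair by the
SVM decision function, and tests significance by label shuffling with the
(1+k)/(1+n) p convention.

## Behavioral statistics

Paired t with d_z = t/√n; pooled-variance two-sample t with Cohen's d.
The JZS Bayes factor integrates the likelihood ratio over the
inverse-gamma(1/2, r²/2) mixing prior implied by a Cauchy(0, r) prior on
standardized effect size (default r = √2/2), by adaptive quadrature on
[0, ∞) with a relative-error guard of 1e−4; the natural log is returned,
which reproduces the published values (ln BF10 = 14.35 at t = 8.026,
46.69 at t = 30.382, n = 30) — a base-10 reading would give ≈6.2 and
≈20.3 and is therefore ruled out.  Two-sample Bayes factors use effective
N = n₁n₂/(n₁+n₂) with ν = n₁+n₂−2.  Test–retest reliability is ICC2
(two-way random effects, absolute agreement, single measure) with the
F-based 95% CI, computed via pingouin; the variant is fixed because the
emulated analysis names none.

The ratings generator draws a shared true score per subject × concept ×
dimension (cell mean + Gaussian between-subject offset) and adds
independent session noise, clipping to [0, 100] and logging the clip count;
its pre-clipping test–retest reliability is
(cell-mean spread + between_sd²) / (that + noise_sd²), which the ICC
estimator recovers within ±0.05 in the suite.

## Problem sizes in the test suite

Tests run on 12³ (or smaller) grids, 2–4 runs, 2–6 subjects, tens of
permutations/shuffles, with searchlights evaluated at implant and control
centers rather than every voxel.  These sizes were chosen so the whole
battery — including the FWER calibration and the three recovery analyses —
completes on a single desktop core in a few minutes while keeping every
statistical check adequately powered; production-scale settings (whole-brain
centers, 100 repetitions, 10 000 permutations) remain the library defaults.

## Known limitations

- The stratified 80/20 scheme reproduces a protocol that ignores run
  structure; its absolute decoding levels on data with concept-stable
  patterns partly reflect concept identity, not only class information.
- The noise model is white Gaussian; TFCE's spatial sensitivity profile on
  smooth noise is exercised only via the optional smoothing path.
- The two-sample ratings-difference analysis with its specific pairing
  structure is not modeled; the generic tests are provided instead.
- The real-transformer backend is interface-tested only; numerical parity
  with any specific pretrained model is out of scope.
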