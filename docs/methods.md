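# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Data model and conventions

A spectrum is a real vector on a strictly descending chemical-shift
axis. Index `i` of an `n`-point spectrum maps to
`ppm_high − i·(ppm_high − ppm_low)/(n − 1)`, endpoints inclusive. The
canonical single-voxel format is 512 points on [7.2; −2.8] ppm (so the
step is 10/511 ≈ 0.0196 ppm); HRMAS defaults to [4.5; 0.5] ppm at
whatever length the file carries. jMRUI exports do not state a ppm
origin: the spectral width is inferred from the header as
`(1000/SamplingInterval_ms) / (TransmitterFrequency·10⁻⁶)` ppm (the
sampling interval is taken to be in milliseconds) and the axis is
centred on a configurable reference, by default 4.7 ppm — the water
resonance — at the centre point. The inferred range is logged at parse
time so users can verify both assumptions.

The region of interest is a closed interval `[ppm_low, ppm_high]`:
every axis point inside it, both ends included, becomes a feature.
On the canonical axis the default [4.5; 0.5] ppm region contains 205
channels. When two spectra per case are concatenated (e.g. two echo
times), each case's row is the ROI of the first spectrum followed by
the ROI of the second; features are tagged `DS1`/`DS2` and cases are
matched across the two datasets by exact identifier equality, with
unmatched cases dropped under a warning. Spectra of different lengths
within one matrix are an error — no resampling or interpolation is
attempted.

## Feature selection and extraction

**CFS merit.** A subset S of k features scores
`merit(S) = k·r̄cf / sqrt(k + k(k−1)·r̄ff)`, with `r̄cf` the mean
feature–class correlation over S and `r̄ff` the mean absolute pairwise
feature–feature correlation. The class is nominal and intensities are
continuous, so the feature–class correlation of a column x is estimated
as the prior-weighted mean over classes c of |Pearson(x, 1{y=c})| —
deterministic, symmetric under label permutation, and zero (with a
warning, not an error) for constant columns, which therefore are never
selected. Whether the original subset evaluator discretised intensities
first is not recoverable; this estimator was chosen for determinism and
testability and is the single switch point if a discretised variant is
ever wanted.

**Search.** Hill climbing, forward (start empty, add the
merit-maximising feature) or backward (start full, drop the feature
whose removal most improves merit), stopping at the first move that
fails to *strictly* increase merit; ties break to the lowest feature
index. Strict improvement prevents cycling, with one consequence worth
knowing: backward search cannot drop a perfectly redundant duplicate,
because removing it leaves merit unchanged rather than increased. The
terminal merit still equals the exhaustive optimum on such instances
(verified against a brute-force subset search in the tests); forward
search selects exactly one copy.

**PCA.** Eigendecomposition of the covariance matrix of the
mean-centred matrix (not the correlation matrix: spectral channels
share units; standardisation is available behind a flag). Components
are ranked by eigenvalue, and the retained count is the minimal k whose
cumulative variance fraction reaches the target, default 0.95. Each
component's largest-magnitude loading is made positive so serialised
models are reproducible. The back-transform filter (project onto the
retained components, return to feature space) acts as an
attribute-noise filter; with PCA selected in the training pipeline the
classifier is trained on the filtered matrix, keeping ppm-labelled
features throughout.

## Fisher LDA with spherical-Gaussian posteriors

For C classes (2–4), the within-class scatter `Sw` pools squared
deviations from class means and the between-class scatter `Sb` weights
squared deviations of class means from the grand mean by class size.
The canonical variates are the top C−1 eigenvectors of `pinv(Sw)·Sb`,
columns ordered by descending discriminant eigenvalue and sign-fixed so
each column's largest-magnitude loading is positive. Cases are
projected as `Z = X·W` with no centring, so the stored weights fully
determine the report coordinates.

Fisher's criterion carries no probability model, so posteriors come
from one spherical Gaussian per class in canonical space: centre at the
projected class mean, and a single standard deviation common to all
classes — the pooled root-mean-square distance of projected training
cases from their class mean, over all n cases and all d = C−1
dimensions, `σ = sqrt(Σᵢ‖zᵢ−μ_{yᵢ}‖²/(n·d))`. A per-dimension or
per-class σ would also be defensible; the single scalar is the most
literal "spherical, common to all" reading and is flagged here for
users comparing against other implementations. Posteriors
`p(c|z) ∝ π_c·exp(−‖z−μ_c‖²/2σ²)` are computed with log-sum-exp, so
rows sum to one to ≤1e−12 for any finite input. Priors default to
training class frequencies; `uniform` is provided because super-classes
are often very unequal in size. Prediction is the maximum posterior,
ties to the lowest class index.

**Degenerate inputs.** Coincident class means raise an error (nothing
to separate). When `n_features ≥ n_cases − C` the within scatter is
singular; the Moore–Penrose pseudo-inverse is used (deterministic and
parameter-free) under a warning. Note that `pinv` maps null-space
directions of `Sw` to zero, so in heavily under-determined problems the
fallback does *not* exploit the zero-within-scatter directions and
training data need not be perfectly separated — feature selection
before fitting is the intended regime. If the projected data collapse
exactly onto the class means, σ is floored at √eps to keep the
Gaussians proper.

**Boundaries.** With equal spherical covariances the equal-posterior
locus of a class pair is a point (C=2) or a straight line (C=3). The
two-class threshold is the midpoint of the projected means shifted by
`σ²·ln(π₂/π₁)/(μ₂−μ₁)`. For three classes the intersection point
solves the 2×2 linear system of two pairwise equalities, and each
boundary is represented by an outer endpoint on its locus, on the side
away from the third class mean, placed at 1.2× the extent of the
training projections (a display convention; the tie condition
|Δposterior| ≤ 1e−9 holds at every stored point). Collinear class
means make the lines parallel: the intersection is omitted with a
warning and one point per locus is still returned. Four-class models
project into three dimensions and no boundaries are computed.

## Evaluation

All resampling schemes refit **only** the classifier, on the
already-fixed feature columns; feature selection is never re-run inside
a resample. The estimates are therefore slightly optimistic and should
be read as classifier — not pipeline — error.

* Confusion matrix: `counts[p, a]` counts cases of actual class `a`
  predicted as `p` (rows = predicted, columns = actual).
* K-fold: stratified by class via shuffled round-robin assignment; a
  partition whose training split misses a class is re-drawn (up to 100
  attempts). With K = n the partition degenerates to the identity
  (case i alone in fold i, no randomness), which makes K = n coincide
  exactly, replicate for replicate, with leave-one-out.
* Bootstrap (default N = 1000): each replicate draws n cases with
  replacement, refits, and scores the out-of-bag cases (`eval_on='full'`
  scores the whole original set instead — both readings exist in
  practice; out-of-bag is the default as the standard choice for LDA
  error estimation). Replicates with an empty class or an empty
  out-of-bag set are redrawn and counted. The expected out-of-bag
  fraction is `(1−1/n)ⁿ → e⁻¹ ≈ 0.368`, which the tests verify.
  Per-class numbers are recalls (fraction of that class's test cases
  predicted correctly). Accuracies are percentages; spreads are sample
  (n−1) standard deviations.
* ROC: one-vs-rest per class, scored by that class's posterior.
  Thresholds sweep the unique scores in descending order with tied
  scores forming a single step — the convention under which the
  trapezoid AUC equals the Mann–Whitney concordant-pair fraction
  exactly (asserted to 1e−12 in the tests). Resampling refits during
  folds relax the per-class minimum to one training case; the public
  `fit` requires two.

Every stochastic routine takes an explicit seed and reproduces its
per-replicate results bit-for-bit from (method, seed, N or K).

## Synthetic data

The generator emulates what the classifier assumes about MRS data: a
spectrum is a sum of Gaussian or Lorentzian resonance lines at fixed
chemical shifts plus i.i.d. Gaussian point noise, with per-case peak
amplitudes drawn lognormally (exact requested mean and sd; positive by
construction) to mimic metabolite-concentration variation. One global
seed drives a per-(class, case) seed sequence, so enlarging a dataset
never changes existing cases. It does **not** emulate chemical-shift
drift, lineshape distortion, baseline roll, residual water or eddy
currents — so passing tests demonstrate the correctness of the
statistics on well-behaved data, not robustness to real-world
artefacts.

The packaged scenario models three super-classes of a short-TE
brain-tumour study at 512 points on [7.2; −2.8] ppm, 20 cases per
class: a common backbone (choline 3.21, creatine 3.03, NAA 2.02 ppm)
plus one discriminative marker per class (alanine 1.47 for low-grade
meningeal, mobile lipids 1.29 for aggressive, myo-inositol 3.55 for
low-grade glial), with the marker's amplitude mean 10 noise-sd above
the other classes' (12 vs 2, noise sd 1.0, amplitude sd 1.0, FWHM
0.06 ppm). These are realistic relative intensities for averaged
short-TE spectra; with this separation the construction is separable
to near-certainty per case. The "Bayes ceiling" reported by the
acceptance script is the accuracy of an oracle classifier that scores
each case against the true noise-free class templates under an
independent-Gaussian approximation per channel (amplitude variance
propagated through each peak's profile); it is exact up to treating
the lognormal amplitude scatter as Gaussian, and sits at ~100% for the
packaged scenario.

## Problem sizes

The default test and acceptance runs use the packaged scenario (60
cases × 205 ROI channels), 20-seed repetitions for the recovery
property, N = 1000 bootstrap replicates and ≤12-feature exhaustive
oracles — sizes chosen so every oracle comparison is exact and the
whole suite runs in seconds while exercising the same code paths as a
full-scale study (e.g. 217-case, 188-channel problems behave
identically, only slower).

## Known limitations

* Only Fisher LDA is provided; no quadratic, regularised or kernel
  discriminants, and at most four classes.
* CFS correlations are computed on raw intensities; no discretisation
  variant is implemented.
* The pseudo-inverse fallback for singular within-scatter does not
  exploit null-space directions (see above); select features first.
* No spectral alignment or resampling: concatenation and matrix
  assembly require equal resolutions.
* The `.dat` class-identifier token is accepted as text (numeric or
  not) and stored verbatim.
* XML `Parameters` metadata are round-tripped verbatim as opaque
  key-value pairs; no schema is enforced on their contents.
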