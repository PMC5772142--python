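# Methods

This note documents the statistical model behind each `streamconn` stage,
the conventions and defaults that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where
the procedure was genuinely open.

## First-level GLM

The temporal model is the conventional one for block-design fMRI:

- Task regressors are square waves over block durations convolved with
  the canonical double-gamma haemodynamic response (peak ~6 s, undershoot
  ~16 s, peak:undershoot ratio 6) and its temporal derivative, built with
  nilearn's `compute_regressor` at 16× microtime oversampling.
- Drift is removed with a discrete-cosine basis containing every cosine
  with period longer than the high-pass cutoff (default 128 s). The drift
  projection is a residual-forming (hence idempotent) projection applied
  identically to data and design; the DCT columns are exactly zero-mean,
  so the model constant is unaffected.
- Temporal autocorrelation is modelled as first-order autoregressive with
  a single coefficient pooled over voxels, estimated from the lag-1
  autocovariance of the OLS residuals, then removed by prewhitening
  (first row scaled by √(1−ρ²), subsequent rows yₜ − ρyₜ₋₁) before the
  final fit. Pooling is a deliberate simplification over per-voxel ML: at
  the simulated noise levels it is unbiased to within 0.05 (verified by
  Monte-Carlo in the test suite) and keeps every fit deterministic.
- Contrast t maps use t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) with dof =
  n − rank(X) − (number of drift functions). A voxel with exactly zero
  residual variance is reported as signed infinity and logged.

Seed localization takes the t-map maximum within a spherical search
region (default radius 15 mm — the published restricted search areas are
not specified numerically, so the extent is configurable). Ties are
broken by the lexicographically smallest voxel index, which is stable
across platforms. Only the main HRF columns enter the localizer
contrasts; the derivative columns absorb latency misfit but are not
contrasted.

Multi-echo combination weights each echo per voxel by TE·tSNR estimated
from the first 30 volumes, normalized to unit sum and applied to the
whole run. Zero-variance voxels in the estimation window fall back to
TE-proportional weights (logged, not fatal).

## ROI geometry

Spheres are sets of voxels whose centres lie within the radius of the
centre coordinate in **world millimetres**, boundary inclusive. This
convention is what makes a 4 mm sphere on a 2 mm isotropic grid contain
exactly 33 voxels (offsets with i²+j²+k² ≤ 4: 1+6+12+8+6), and it handles
anisotropic grids correctly. Voxel indices are 0-based; world coordinates
are RAS+ mm. Target-table x magnitudes are resolved to left = −x,
right = +x. Target spheres are not clipped to a grey-matter mask (the
source procedure is silent; clipping is configurable).

## Seed-based connectivity

The seed timeseries is the first eigenvariate — the leading left-singular
vector of the per-voxel demeaned time × voxel matrix — with the sign
fixed so the mean voxel loading is positive and the amplitude scaled to
the standard deviation of the ROI mean timeseries. These two conventions
make the output unique and deterministic.

Each voxel's seed coupling is the seed-regressor coefficient in a GLM
that also contains the 15-column nuisance set: 6 rigid-body motion
parameters, their backward temporal differences (first row zero), and
the mean signals of white-matter, CSF and out-of-brain compartment masks
(plain means; the masks are inputs). High-pass and AR(1) handling are
identical to the localizer GLM. In the noiseless case the seed β is
provably invariant to adding any linear combination of nuisance columns
to the data; the suite checks this to 1e−6.

Stream strength is the voxel-count-weighted mean β over all voxels of
all parcels of a stream (per-parcel means are also exported). Negative
βs are *not* zeroed for stream strength — zero-masking is a fingerprint
convention only. Group ANOVAs are repeated-measures (statsmodels
`AnovaRM`), requiring a balanced within-subject layout; follow-up 2×2
interaction tests are Bonferroni-corrected over the number of seed pairs.
A motion-screening helper excludes subjects whose translation parameters
exceed 3 mm.

Whole-brain group inference is nonparametric: a one-sample (or
paired-difference) t map across subjects, clusters formed from contiguous
voxels (26-connectivity) above the one-sided t threshold for p < 0.001,
and cluster-mass family-wise error assessed against the maximum-cluster-
mass distribution under per-subject sign flips (default 1000). This
replaces random-field theory deliberately: it is assumption-light, exact
under exchangeability, and its 5% FWE calibration is itself verified in
the test suite (200 null group analyses). Group maps are computed on
smoothed maps (6 mm FWHM default); ROI and fingerprint stages use
unsmoothed βs.

## Fingerprint matching

A fingerprint is the ordered vector of mean βs over the 13 packaged
target ROIs, zero-masked per subject before group averaging. Two
group-mean fingerprints are compared by the city-block distance after a
joint min-max normalization over the combined 26 arm values, mapping the
weakest connection of either profile to 0 and the strongest to 1.

The permutation null swaps each subject's pair of region labels
independently (exchangeability of paired labels), recomputes both group
means, **renormalizes the permuted pair**, and recomputes the distance —
renormalizing inside the loop is what keeps the test unbiased by the
observed range. Monte-Carlo p-values use the add-one formula
p = (1 + #{null ≥ obs}) / (1 + n_perm), so p is never zero and the
minimum attainable value is 1/(n_perm+1). With n ≤ 20 subjects an exact
mode enumerates all 2ⁿ swap assignments (identity included, so
p = #{null ≥ obs}/2ⁿ > 0). The default 5000 permutations reproduce the
standard operating point; the null is vectorized so exhaustive/MC
agreement can be tested cheaply.

Per-arm attribution fits a logistic regression of the region label on
the arm value across the stacked per-subject observations and reports the
Wald p of the slope, uncorrected (these are descriptive follow-ups).
Perfect separation is flagged (`separated=True`) and reported at the
boundary value p = 0 rather than raising.

## Stream classification

Training items are the whole-brain connectivity patterns of the 22
stream parcels (13 dorsal, 9 ventral), computed per subject with exactly
the seed-GLM procedure above (parcel eigenvariate as seed) and flattened
on a shared in-brain voxel set. Queries are classified by majority vote
of the k nearest items under the city-block metric; a tied vote at even
k falls back to the label of the single nearest item, and equal distances
are ordered by training-item index, making every outcome deterministic.
k is swept from 2 to 8 (one less than the ventral class size). The
13:9 class imbalance is left as-is, matching the design it emulates; its
consequence (shuffled-label dorsal probability → 13/22) is documented by
a property test. Outcomes (dorsal = 1) are compared with a Friedman test
blocking on subject × k, with midrank ties; two-treatment follow-ups
reduce to the sign-test-style χ² on discordant blocks and are
Bonferroni-corrected.

## Tract strength

Connection strength from streamline counts is
value = log₁₀((count + 1)/total), averaged over the rows contributing to
a (subject, seed, hemisphere, stream) cell. The +1 pseudo-count keeps
zero-count cells finite, division by the seed's total streamlines removes
per-seed tracking yield, and log base 10 makes the values read as path
probabilities (−3 ⇒ one path in 1000). The exact normalization and log
base of the emulated procedure are unstated, so this choice is isolated
behind one function with configurable pseudo-count and base. The
statistic is strictly increasing in count, strictly decreasing in total,
and the seed × stream interaction conclusion is invariant to rescaling
all totals by a common factor (exactly so without the pseudo-count,
verified to ~5% with it). The diffusion seeding rule — the 20 white-matter
boundary voxels nearest each seed coordinate — is provided as a geometry
helper; tracking itself is out of scope and the module consumes count
tables.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants exactly the structure the analyses are designed to
detect. Voxel timeseries are linear combinations of two latent
unit-variance AR(1) "network" signals (dorsal and ventral,
autocorrelation 0.3 by default) plus AR(1) Gaussian noise; spherical
seed sites carry graded loadings (EBA-like 0.8/0.4, LOC-like 0.6/0.6,
FBA-like 0.4/0.8 by default), and parcels of a toy dorsal/ventral
parcellation load 0.7 on their stream's latent. Motion parameters are
random walks injected as additive confounds; white-matter, CSF and
out-of-brain compartments carry shared nuisance signals so that nuisance
regression has something real to remove. Localizer runs add
HRF-convolved block responses at the seed sites (16 s blocks, 8 s rest,
amplitude 3 against unit noise). Path counts are multinomial draws over
{dorsal, ventral, lost} with per-subject lognormal rate jitter
(σ = 0.2) and default rates in which every seed reaches ventral more
often but the dorsal:ventral ratio is graded. Every generator draws from
a `SeedSequence` spawned as (kind, subject), so runs are individually
reproducible and order-independent.

Default desk-scale sizes: 8 subjects, 24×28×24 grid at 2 mm, 200 rest
volumes at TR 2 s, 150 localizer volumes, 5000 streamlines per seed.
Statistical checks that need more data use 16 subjects or 500 volumes,
chosen to match the sampling regimes the analyses target.

What the generator does **not** emulate: MR physics (susceptibility,
distortion, slice timing), spatial misregistration, anatomical realism of
parcel geometry, spatially correlated noise, non-Gaussian artefacts, and
distance-dependent tractography bias. Passing tests therefore certify
the statistical machinery — calibration, recovery, determinism — under
the stated generative model, not robustness to acquisition artefacts in
real data.

## Numerical conventions and degenerate inputs

- Rank-deficient designs raise with the names of the suspect columns
  (QR diagnostic) rather than silently pseudo-inverting.
- An ROI resolving to zero voxels raises a `DegenerateMaskError` naming
  the region.
- An all-constant ROI has no eigenvariate and raises.
- A fingerprint pair with all arms equal has no normalization and raises
  for the observed statistic; inside the permutation loop such a
  degenerate pair is scored as distance 0 (the profiles are identical).
- A repeated-measures table with no within-subject variance reports
  F = 0, p = 1 for every effect instead of a 0/0 round-off artefact.
- Friedman comparisons with fully tied blocks likewise report χ² = 0,
  p = 1.

## Known limitations

- Atlas-to-individual registration, surface processing, realignment and
  normalization are consumed as given, not implemented.
- The pooled-AR(1) + prewhitening scheme understates autocorrelation
  heterogeneity across tissue types; a per-voxel option is the natural
  extension.
- Cluster inference is one-sided per contrast direction; testing both
  directions requires two calls.
- The fingerprint test's observed statistic uses group-mean fingerprints
  (the emulated text permits per-subject variants; group-mean is the
  default here).
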