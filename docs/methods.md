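# Methods

## Scope

`parcelclass` implements a parcelwise resting-state sex-classification
analysis: per-subject parcel time series are cleaned of white-matter/CSF
signal, converted to Fisher-Z connectomes, and each parcel's connectivity
profile is used to classify sex with an RBF-kernel SVM under stratified
cross-validation; family-wise inference across parcels uses a
max-statistic permutation test. Because the cohorts such analyses are run
on (large young-adult and population samples) are access-restricted, the
package ships a synthetic cohort generator that reproduces the statistical
structure the analysis assumes, and the entire pipeline is validated
against it.

## Synthetic cohort model

**Base connectivity.** Parcel signals follow a low-rank factor model:
loadings `L` (P × k, standard normal, k = 12 by default) plus diagonal
uniqueness give a covariance `LLᵀ + Ψ`, normalized to a correlation matrix
and then shrunk halfway toward the identity. The shrinkage is deliberate:
it guarantees a spectral margin (smallest eigenvalue > 0.5) so that adding
localized effects on the Fisher-Z scale cannot push the group matrix off
the correlation cone. Without that headroom the necessary positive
semidefinite (PSD) repair systematically shrinks planted effects — the
generator would not honor its own effect-size contract.

**Sex and age effects.** Effects are specified in the same units the
pipeline measures. For each effect parcel *d* with size δ_d (Fisher-Z), the
edges between *d* and a designated target set get +δ_d/2 for males and
−δ_d/2 for females on the atanh scale; an optional age slope adds
`age_effect · (age − midpoint)` to a designated edge subset. Back-transform
with tanh yields the subject's expected correlation matrix. By default the
target set is the last ten non-effect parcels; pointing `target_parcels` at
the effect parcels themselves confines the signal to the planted set, which
is the cleanest configuration for planted-versus-null comparisons (an edge
has two ends — its target parcel carries the signal too).

**Subject-level variability.** Each subject's correlation matrix is a
normalized Wishart draw around their group matrix with
ν = 1/`subject_noise_sd`² degrees of freedom, giving edgewise Fisher-Z
noise of approximately `subject_noise_sd` (default 0.1, i.e. ν = 100)
while remaining PSD by construction and keeping the expected male-minus-
female difference at the designed δ. An earlier design that added i.i.d.
noise to every edge and projected back to the correlation cone was
abandoned: an entrywise perturbation of sd σ has spectral norm ≈ 2σ√P,
which for realistic σ dwarfs any eigenvalue margin, and the projection then
attenuated planted effects by ~30%. `nearest_correlation` (eigenvalue
clipping with diagonal renormalization, iterated) remains as a safety net
and as the documented repair operator for user-supplied matrices.

**Acquisition and phenotypes.** Time series are zero-mean Gaussian draws
with the subject's correlation structure; two AR(1) series (φ = 0.6, unit
variance) model WM and CSF signal and are added to every parcel with
subject-specific loadings ~ N(0.5, 0.15), so the cleaning stage has real
work to do. Defaults mirror the two study acquisition profiles: profile A —
434 subjects, 1200 volumes, TR 0.72 s, ages 22–37; profile B — 941
subjects, 300 volumes, TR 2.2 s, ages 18–88. Male and female age
distributions are identical by construction (paired draws) unless
`age_sex_gap` is set, which is how the leakage audit creates an
age-confounded cohort. Mean FD is lognormal around 0.16 mm with no sex
difference; per-parcel GMV is lognormal around 500 (arbitrary units) with
10% subject noise and an additive male offset (default 30) — large enough
that a naive analysis could be confounded, and removable with
`match_subjects_by_covariate` (greedy nearest-neighbor pairing without
replacement, configurable caliper, deterministic in input order).

**Sample pairs.** `generate_sample_pair` gives two cohorts sharing the
effect map *and* the latent structure seed (factor loadings, base GMV)
while differing in subjects, acquisition, noise and age range. Sharing the
structure is a deliberate design choice: cross-sample generalization is
only a meaningful test if the two samples measure the same underlying
"brain" under different conditions.

**Voxel level.** When requested, each parcel's voxels are `latent ×
loading + noise` with positive loadings of mean 1, so the first
eigenvariate differs nontrivially from the plain voxel mean.

What the generator does **not** emulate: hemodynamics, spatial smoothness,
scanner drift, within-sex "mosaic" heterogeneity (each parcel has a single
δ; real sex differences are likely a mixture), or non-Gaussian tails.
Passing tests therefore demonstrate the correctness and calibration of the
*pipeline*, not claims about real cohorts.

## Connectome extraction

Nuisance regression is per-channel OLS on `[intercept, WM, CSF]`; residuals
are mean-zero and orthogonal to the regressors, and the operation is
idempotent. Collinear nuisance columns are dropped with a warning — the
regressors include an intercept by choice (whether the original cleaning
demeaned its regressors is ambiguous; including the intercept makes the
residuals invariant to that choice). With voxel data, each parcel's signal
is the first left singular vector of the column-demeaned voxel matrix,
scaled by σ₁/√n_vox; the sign is fixed to correlate non-negatively with the
mean voxel signal (tie → first voxel), since SVD signs are arbitrary and
reproducibility requires a convention. A `clean_stage` switch applies
cleaning at the voxel level (default, matching the narrative order of the
original procedure) or at the parcel level. Correlations are clipped to
±(1 − 10⁻⁷) before atanh so degenerate inputs stay finite; the connectome
diagonal is stored as NaN and never consumed.

## Classification

Per parcel: stratified k-fold CV (k = 10 default; folds differ in size by
at most one). Strictly within each training fold, in order: (1) per-feature
OLS betas for the confounds (age by default; FD and GMV can be added) are
fitted and applied, unchanged, to training and held-out subjects — the
train-only confound adjustment that prevents label information leaking
through covariates; (2) per-feature z-scoring statistics (zero-variance
features dropped with record); (3) `sklearn.svm.SVC` with RBF kernel.
Accuracy is pooled over subjects (exact for unequal folds). Decision
ties at exactly 0 go to the lexicographically first class label.

Hyperparameters: grid defaults to C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ (steps of 2²);
per outer fold an inner stratified CV (5-fold default) selects the
accuracy-maximizing point (ties → smallest C, then smallest γ), and the
final full-sample model combines fold selections by geometric mean —
arithmetic averaging on the log scale, the only average that respects the
grid's geometry. Where no grid is supplied the fixed default is C = 1,
γ = 1/p. When cross-validating with a grid, each fold uses its own
selection so no held-out information reaches any fitted component; an
audit test perturbs held-out data and verifies the training-fold artifacts
are bit-identical.

External prediction applies the training confound betas, training scaler
and trained SVM to a new cohort without refitting anything. Models
serialize to a single JSON file (support vectors, dual coefficients,
intercept, γ, scaler, betas, atlas hash); prediction runs from those arrays
alone, so a loaded model needs no fitted estimator object.

`classify_all_parcels` derives per-parcel seeds from the master seed and
parcel id, making maps identical across worker counts; failed parcels are
recorded as NaN with the error message, never silently dropped. Parcel id 0
denotes the whole-brain upper-triangle feature vector (P(P−1)/2 entries).

## Permutation inference

One label permutation per draw is applied identically to every parcel
(max-statistic correction presumes a common permutation), CV accuracies are
recomputed with the same settings (folds re-stratified per permutation),
and the maximum over parcels is stored. FWE p-values use the add-one
estimator p = (1 + #{max_b ≥ acc}) / (1 + B), which is never zero and
yields a valid level-α test under exchangeability; p is non-increasing in
observed accuracy by construction. Hyperparameters selected on the
unpermuted data are reused inside the loop by default — re-tuning inside
thousands of permutations is computationally prohibitive and, being
label-blind at the null, changes little; `retune=True` restores full
re-tuning at reduced scale.

Secondary analyses use Welch t-tests (robust default where only "t-test"
is specified), Benjamini–Hochberg FDR, Spearman correlations with
average-rank ties, and sample (n − 1) standard deviations in summaries.
`consensus_top_parcels` takes floor(fraction · P) parcels per map with ties
at the cutoff included, then intersects.

## Problem sizes used in validation

The test suite and acceptance script run the pipeline at reduced scale,
chosen to keep the full validation under a few minutes while preserving
the statistical structure: FWE calibration uses 50 global-null cohorts of
10 parcels × 60 subjects × 150 volumes with 100 permutations and 5-fold CV
(the empirical family-wise error rate comes out at or below the nominal
0.05); effect recovery uses 40 parcels × 200 subjects with δ = 0.4 on 5
parcels over 10 seeds; cross-sample checks use 16-parcel, 120-subject
pairs at 1200 vs 300 volumes.

One validation threshold is knowingly unattainable: a rank correlation
between a binary planted-effect vector (5 of 40 parcels, equal δ) and any
accuracy ranking is bounded at ρ ≈ 0.573 under average-rank tie handling,
so the corresponding assertion can fail even when — as observed — the
planted parcels occupy exactly the top five ranks in every seed. The
substantive checks (top-rank occupancy, null parcels at chance) pass.

## Known limitations

- The generator's single-δ star structure is one choice among many; it does
  not model within-sex heterogeneity or network-level effects.
- Permutation re-tuning is off by default (see above); observed and null
  statistics therefore share hyperparameters, a mild conservatism.
- NIfTI support is read-only and grid-matched; no surface data, no dynamic
  connectivity, no partial correlations, no global-signal regression,
  band-pass filtering or scrubbing.
- GMV is synthetic throughout; the GMV confound analyses validate the
  machinery, not anatomical claims.
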