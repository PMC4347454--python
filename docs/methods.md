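# Methods

## Model and estimation

Both modalities follow the linear mixture `X = A·S` with statistically
independent component rows `S` and subject loadings `A`. Estimation is
infomax ICA in a PCA-whitened subject space: subjects are the channels,
voxels/SNPs the samples; each subject row is centered, the subject-space
covariance eigendecomposed, and the top-k whitened representation kept so
the unmixing matrix `W` is square and `A = W⁻¹` is exact (mapped back to
subject space through the dewhitening matrix). The entropy surrogate
tracked per iteration is `ln|det W| + E[Σᵢ ln yᵢ(1−yᵢ)]`, the joint entropy
of the logistic-squashed sources up to a constant; the full-batch
natural-gradient update is `ΔW = η(I + (1−2Y)Uᵀ/N)W`, `ΔW₀ = η·mean(1−2Y)`.
The logistic nonlinearity matches super-Gaussian (sparse) sources, which
both sparse spatial maps and sparse SNP weight vectors are.

The cross-modality term is the squared Pearson correlation between one FA
loading column and one SNP loading column. Its gradient with respect to a
(centered) column a, partner b, is `2ρ(b/(‖a‖‖b‖) − ρ a/‖a‖²)`; the update
is applied to the subject-space columns of the maximally correlated pair
whenever its |r| exceeds `constraint_threshold`, then projected back to the
reduced space (least squares against the dewhitening map) and propagated to
`W = A⁻¹`. Ascent on corr² preserves the sign of the correlation while
growing its magnitude, so a negative planted association stays negative.

### Constraint scheduling

Per iteration, the constraint step for a loading column is the corr²
gradient scaled by `constraint_rate` and by the column norm (making the
step relative, hence invariant to the arbitrary ICA scaling of loadings).
Two guards keep the correlation term from overwhelming separation:

- the ICA learning rate is multiplied by `anneal_factor` (0.9) whenever a
  modality's entropy surrogate decreases;
- if the entropy drop in either modality is steeper than `endurance`
  (−1×10⁻⁵), the constraint is suspended for that iteration and its rate
  halved. The bound's mechanism is not uniquely determined by its
  published description ("control the decreasing slope of the entropy
  term"); suspend-and-halve is the conservative reading and is what the
  calibration tests exercise.

Iteration stops when the relative weight change in both modalities falls
below `convergence_tol` (1e-6) or at `max_iterations` (512). Because the
constraint perturbs `W` every sweep while active, runs on linked data
typically end at the iteration cap with the loadings long since stable; the
`converged` flag reports the strict criterion honestly rather than being
relaxed. Components are returned with unit-variance rows and the
largest-|weight| element positive, the scale and sign absorbed into the
loadings — pinning ICA's scale/sign indeterminacy so thresholded maps and
top-weight sets are reproducible. Default `constraint_rate` is 0.1: strong
enough to enhance a genuine 0.37 association by a few hundredths, weak
enough not to manufacture one (verified by the null-calibration tests).

### Model order

FA-side order uses the Wax–Kailath minimum-description-length criterion on
the subject-space covariance eigenvalues,
`MDL(k) = −n(p−k)·ln(GM/AM of trailing eigenvalues) + ½k(2p−k)ln n`,
minimized over k (ties to the smallest k). SNP-side order uses run-to-run
component consistency: for each candidate k, the whitened data are
decomposed from `n_runs` random initializations, runs are greedily matched
on absolute component correlation, and the mean matched |corr| is the
score. The selection rule is the **largest** k scoring at least 0.85
(falling back to the score maximum): small k are trivially stable, so
maximizing the score degenerates to the smallest candidate, whereas the
score stays high up to the true order and drops sharply beyond it — the
0.85 floor reads off that drop.

## Genotype QC

Dosages count minor alleles (0/1/2). The chain is: subject call rate >
0.9 and SNP call rate > 0.9 (iterated to a fixed point, since removals
change the rates the other filter sees — this also makes the filter
idempotent); missing-call replacement from the best in-window LD proxy
(max dosage r², floor 0.8, allele-aligned by the correlation sign, SNPs
with unfillable calls removed); exact Hardy–Weinberg test within controls
(p ≥ 1e-6 kept), computed by conditioning on allele counts and summing
probabilities of heterozygote counts no more probable than the observed
one (log-gamma arithmetic, valid at any count); MAF strictly > 0.05 over
non-missing calls, with majority-coded columns recoded so the counted
allele is the minor one. Imputation precedes the frequency-based filters
so they see filled data. Ancestry correction removes dosage principal
components whose subject scores associate with the ethnicity labels
(one-way ANOVA, Bonferroni over the 10 PCs examined, α = 0.05) by
projection; dimensions never change. The diagnosis pre-filter is a per-SNP
Welch t-test on dosage (a trend-test-equivalent, monotone choice; a
chi-square trend variant is available), keeping p < 0.01 uncorrected in
genomic order. Gender-consistency and relatedness checks are accepted as
upstream metadata; no genotype-intensity data are in scope.

## FA preparation

Site effects are removed voxelwise. For a one-way site design the OLS fit
on site indicators equals the per-site voxel means, so the correction
subtracts each subject's site mean and restores the voxel grand mean —
post-correction per-site means agree to numerical precision and grand
means are exactly preserved (the reference-level intercept would not
preserve them under unbalanced sites). Sites with a single subject make
the voxelwise fit ill-posed and are rejected; single-site data pass
through only via an explicit flag. Voxel variance normalization is not
applied by default. A post-hoc check tabulates per-site diagnosis means of
a loading column, flags whether the group difference points the same way
at every site, and reports the site × diagnosis interaction F-test.

## Association statistics

Pair statistics are Pearson correlations over all `n₁ × n₂` loading-column
pairs with two-sided t p-values; the partial correlation residualizes both
members on an intercept plus covariates and tests the residual correlation
on n − 2 − q degrees of freedom. Two covariate presets exist
(site + ethnicity + age + sex, and age + sex) because published practice
varies; both are reported, neither privileged. Bonferroni control is
α/m over the m pair tests. The permutation null permutes the subject order
of the SNP modality (breaking alignment, preserving within-modality
structure; equivalent under exchangeability to permuting either side) and
re-runs the **full decomposition** per permutation, recording the top
absolute pair correlation; the empirical p is `#{null ≥ observed}/n_perm`
with no +1 correction, matching the tail-counting convention of the
procedure this implements. A reduced-iteration profile for permuted reruns
is allowed and always declared in the result. The k-fold analysis drops
one diagnosis-stratified 10% block per fold (contiguous blocks after a
seeded shuffle), reruns with identical parameters, matches fold components
to the full-data components by maximal |corr| of weight vectors, and
records the matched pair's loading correlation and the overlap ratio
|subset∩full|/|full| of top-5% SNP sets. Group differences on loadings use
the pooled-variance two-sample t-test.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 73 patients
and 87 controls over 4 acquisition sites; FA built as
`baseline + scale·A₁S₁ + site offsets + Gaussian noise` with blob-shaped
(contiguous-run) sparse FA components; SNP dosages obtained by
rank-discretizing a latent `A₂S₂ + noise` per column at Hardy–Weinberg
cutpoints for a MAF drawn from (0.05, 0.5) — preserving the linear
structure the decomposition assumes while yielding legal 0/1/2 marginals.
One FA and one SNP component are linked: their loading columns carry
opposite-direction group shifts (controls > patients on FA; patients >
controls on SNP) and are given an **exact** in-sample correlation at the
target (−0.37) by a closed-form projection adjustment, so the planted
effect is not subject to sampling error. All randomness flows from one
seed through named spawned substreams.

Default sizes (5000 voxels, 1000 SNPs, 9 FA / 7 SNP components) put the
SNP panel at the post-pre-filter scale; `missing_rate` defaults to 0
because the matrix the decomposition consumes is post-QC, and missingness
is exercised explicitly in the QC tests. Group-effect parameters are
coefficients on the standardized group indicator (the realized
standardized mean difference is recorded in the ground truth). What the
generator does **not** emulate: realistic brain geometry or spatial
autocorrelation beyond 1-D blobs, LD block structure (synthetic SNPs are
mutually independent, so LD imputation on generated data removes rather
than fills — proxy filling is tested on constructed tables), genotyping
intensity artifacts, and any coupling between ethnicity labels and allele
frequencies (stratification is simulated separately where ancestry
correction is tested). Passing tests therefore demonstrate algorithmic
correctness and calibration, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script use these scales, chosen to keep
every property measurable at desk scale: parameter recovery on the full
default cohort (160 × 5000 / 1000, 10 seeds); permutation calibration on
20 null cohorts of 200 voxels / 150 SNPs with 3+3 components, 200
permutations each at a 24-iteration profile, identical profiles for the
observed and permuted statistics so they are exchangeable; MDL recovery on
100 simulations of a rank-3 signal in 20 channels × 200 samples at SNR 10;
separation quality on 5 Laplace sources × 160 mixtures, 10 seeds. Exact
HWE equivalence is checked for every table with up to 200 genotypes
against an independent ratio-recurrence enumeration.

Degenerate inputs are handled explicitly: zero-variance loading columns
and constant component rows are errors; a vector numerically explained by
the covariates has partial correlation 0; ties in top-fraction selection
break by ascending index (stable sort); equal eigenvalues give MDL order
0; non-finite infomax steps are rejected and treated as an annealing
signal. Reported decompositions are bit-reproducible given the same seed
and data.

## Known limitations

The constraint biases the raw p-value of the selected pair (selection +
enhancement), which is why the permutation test is the authoritative null
— the raw Bonferroni flag is reported but should be read accordingly. The
constraint-update formula is this package's own gradient derivation for
the published corr² objective, validated against numerical
differentiation; bit-equivalence with any particular toolbox
implementation is not claimed. Only two modalities are supported, one
constrained pair by default, full-batch updates at these data scales, and
no reference-guided or sparse-ICA variants.
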