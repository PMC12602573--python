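# Methods notes

This note documents the models, numerical choices and known limits of
`cbmeta`'s two engines and of the synthetic-data generators that back the
test suite. Everything quantitative stated here is computed by the tests or
by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Coordinate-based engine (ALE)

### Model and assumptions

A reported activation focus is treated not as a point but as the center of
an isotropic 3-D Gaussian expressing spatial uncertainty. Two uncertainty
sources are combined in quadrature: a between-template component (differences
among spatial-normalization pipelines) and a between-subject component that
shrinks with the square root of the sample size, so larger experiments get
tighter kernels. Defaults follow the published empirical calibration,
expressed as mean Euclidean displacements of 5.7 mm (template) and 11.6 mm
(subject); both are config values (`cbmeta.kernels`). For n = 20 the
combined FWHM is ≈ 9.2 mm. The kernel is discretized by the midpoint rule
(density at the voxel center × voxel volume) and truncated at 3.5 σ, where
its mass is ≈ 1 to better than 1%.

Per experiment, foci are snapped to their nearest voxel and aggregated by
the voxelwise **maximum** over kernels — a focus cloud from one experiment
cannot count as independent evidence — yielding the modeled-activation (MA)
map. An additive aggregation is available behind a flag for comparison with
the older formulation. Across experiments the union
`ALE = 1 − ∏(1 − MA_i)` measures convergence. Experiments from the same
participant sample must be merged before analysis (`cbmeta.io` does this on
read, pooling foci), otherwise the union treats them as independent.

### The analytic null

The voxelwise null is the distribution of the union when one in-mask voxel
is drawn at random from each MA map. Since
`1 − ALE = ∏(1 − MA_i)`, the statistic is additive on the scale
`L = −log(1 − ALE)`; the null is therefore computed by histogramming each
map's in-mask L-values on a lattice of width 1e-5 and convolving the
histograms (FFT). This is exactly the sequential union-combination of
per-map histograms, reformulated so each combination is a convolution; on
the small MA values that occur in practice L ≈ ALE, so the lattice width is
effectively 1e-5 on the ALE axis as well. Tail probabilities are inclusive
(`P(ALE ≥ a)`), so ALE = 0 maps to p = 1 exactly; values above the support
receive the smallest representable tail and are logged.

Two discretization facts matter for validation. First, because foci snap to
voxels, MA values — and hence the union — carry large atoms; a Monte-Carlo
oracle must bin each map's contribution on the same lattice *before*
summing, or whole atoms land one bin away from the analytic mass and the
comparison fails at several binomial SEs even when both computations are
correct. The test-suite oracle does exactly this and agrees with the
analytic null within 3 binomial SEs at tails from 0.1 down to 1e-4 with 10⁶
draws. Second, the cluster-forming threshold is converted from p to an ALE
cutoff at the lower edge of the first bin whose tail falls below p.

### Cluster-level FWE

Observed clusters are formed from voxels with analytic p below the
cluster-forming threshold (default 0.001) under 26-connectivity
(configurable: 6/18/26). The null for cluster size simulates datasets of
uniformly placed in-mask foci matching the observed dataset's number of
experiments and per-experiment n and foci counts; each simulated ALE map is
thresholded at the observed analysis' ALE cutoff (the simulated datasets
have identical properties, so their analytic null is the observed one), and
the maximum cluster size is recorded. A cluster is significant when its
size exceeds the (1 − α) quantile of that max-size null — max-statistic
FWE control across clusters; `alpha=1` reports everything. Because the
max-size null is a property of the generative configuration, not of a
particular dataset, `cluster_fwe` accepts a precomputed null so calibration
experiments with many replicate datasets can share one batch of
simulations. Under pure noise (20 experiments × 10 foci, 500 shared
simulations, 200 replicates) the measured family-wise rate at α = 0.05 sits
in the 0.02–0.09 band.

### Conjunctions, contrasts, contributions

Conjunction is the minimum statistic over cluster-corrected maps: a voxel
survives only when significant in all inputs, with connected components
below an extent threshold (default 25 voxels) removed as incidental
overlap. Contrasts compare the voxelwise difference of *unthresholded* ALE
maps to a null built by re-splitting the pooled experiments into groups of
the original sizes (default 25,000 permutations; desk default 2,000). The
per-voxel posterior probability is the proportion of permuted differences
strictly below the observed one — ties count against the observed
difference, the conservative choice — thresholded at > 0.95, inclusively
masked by the corresponding main effect, and extent-filtered. The
permutation stream is oriented canonically by the (size, sorted-ids) key of
the two sets, so swapping the arguments swaps the outputs exactly under the
same seed. Contribution analysis sums the union ALE over a cluster's voxels
("summarized ALE"; a mean would give identical percentages) and recomputes
it leaving each experiment out; an experiment contributes when removal
strictly decreases the sum.

### Numerical/degenerate-input choices

Empty suprathreshold sets yield empty cluster tables, not errors. Foci
outside the grid bounding box are skipped with a warning; an analysis pool
below 17 experiments triggers a stability warning (configurable floor).
One seed drives a whole analysis; permutations and simulations draw from
that stream in a fixed order, so reruns are bit-identical.

## Behavioral engine (effect sizes + RVE)

### Effect sizes

Interference costs are repeated-measures standardized mean differences with
the small-sample correction (formulas in the README). Sign convention:
incongruent slower ⇒ positive g, enforced by construction. Condition
spreads reported as standard errors are converted by SD = SE·√n under an
explicit flag — never inferred from magnitude. The between-condition
correlation is recovered from a paired t (SD_diff = |Δm|·√n/t) or a
reported SD of differences; derived r outside (−0.999, 0.999) is clamped
with a warning. The imputed aggregate correlation is an intercept-only
correlated-effects RVE fit on the raw r scale with large-sample variances
(1−r²)²/(n−1), honoring study clustering; a Fisher-z variant exists behind
a flag (`impute_r_fisher_z`) because "mean correlation" is ambiguous — on
realistic inputs the two differ in the third decimal. The three
r-assignment strategies (observed+imputed, observed+floor 0.6, all-imputed)
are all first-class and run side by side in the pipeline.

### Correlated-effects RVE

The working model is intraclass within studies: sampling covariance
v̄_j[(1−ρ)I + ρJ] plus a common between-study effect τ²J, with v̄_j the
study's mean effect-size variance. Estimation steps:

1. Preliminary weights u_j = 1/(k_j v̄_j); WLS fit; QE = Σ u e².
2. τ̂² is the exact method-of-moments solution of
   E[QE] = tr(A V₀) + τ² tr(A J_block), A = (I−H)'U(I−H), truncated at 0.
   ρ (default 0.8) enters only here; with one effect size per study the
   estimator reduces algebraically to DerSimonian–Laird (verified against
   statsmodels in the tests).
3. Final weights w_j = 1/(k_j(v̄_j + τ̂²)); within a study all effect sizes
   share one weight, the study's total weight ∝ 1/(v̄_j + τ̂²).
4. CR2-type sandwich: per-study adjustment matrices A_j solve
   A_j G_j A_j = Φ_j (symmetric Riccati solution via eigendecompositions)
   with G_j the j-th diagonal block of (I−H)Φ(I−H)', making the variance
   estimator exactly unbiased when the truth equals the working model —
   the defining CR2 criterion. Saturated clusters (zero residuals by
   construction) fall back to the identity adjustment.
5. Satterthwaite dfs per coefficient from the model-implied covariance of
   the sandwich; coefficients with df < 4 are flagged unreliable. The
   omnibus test for multi-level moderators is the approximate Hotelling
   T² with Zhang-style df, standardized by the model-implied covariance so
   the single-coefficient case collapses exactly to t² with the same df.

Equal-variance reductions (equal k and v̄ across studies) make all weights
equal regardless of τ̂², so the intercept is the plain mean and is invariant
to ρ to machine precision; on general data ρ moves the intercept only
through τ̂², by ~1e-6 in practice — the basis of the ρ-sensitivity table.
The r-sensitivity grid refits the intercept-only model on the subset with
observed correlations, replacing them by each fixed grid value; point
estimates stay within a few hundredths while the per-effect-size variance
scales with (1−r).

Bias testing regresses g on SE(g) with the same CE machinery (slope ⇒
funnel asymmetry). Influence diagnostics deliberately fit an
independence-assuming random-effects model with REML τ² (bounded scalar
optimization of the restricted likelihood) and compute externally
standardized deleted residuals and Cook's distances per case; flags use
|residual| > 3 or D > 4/n — conventional cutoffs, stated as such. The
pipeline refits the headline model with flagged cases removed.

Hierarchical (lab-level) dependence beyond study clustering is not modeled:
the dominant dependence in this literature is multiple effect sizes per
study, which the CE scheme targets.

## Synthetic-data generators

`gen_foci_dataset` draws, per experiment, each active truth center with its
report probability, scattered by an isotropic Gaussian and
rejection-resampled at the mask boundary, plus a fixed number of uniform
in-mask noise foci (fixed, not resampled, to mirror the identical-properties
matching of the FWE null). Moderator levels are assigned cyclically from
the configured level → active-centers map. All foci land exactly on in-mask
voxel centers or are rejected.

`gen_behavioral_dataset` works at the summary-statistic level (only
summaries enter the analysis): true effects θ = μ_g + moderator shift +
study component + experiment component with total SD τ and within-study
correlation ρ_within; observed mean differences are drawn with sampling SD
SD_diff/√n; condition SDs follow the chi-square sampling law **with a
shared component weighted r²**, because both SDs come from the same
subjects — drawing them independently inflates the implied SD of
differences at high r and biases recovered g low by several percent, which
is a property of the estimator on unrealistic inputs, not of the method.
Observed correlations are drawn on the Fisher-z scale with SE 1/√(n−3) and
reported for a configurable fraction of experiments. Defaults mirror a
typical interference literature: 68 study clusters, effect sizes per study
1–4 (pin `n_es_total=164` for the canonical shape), μ_g = 0.64, τ = 0.2,
r = 0.91, ρ_within = 0.8, n per experiment 15–60, RT scale 700 ± 120 ms.

What passing tests show — and what they do not: the generators produce
Gaussian study/effect hierarchies, symmetric noise, exactly coded
moderators and foci with stationary isotropic scatter. Real literatures
have skewed RT distributions, coding ambiguity, correlated moderators,
selective reporting, and foci whose scatter follows anatomy. Calibration
and recovery results here validate the *machinery* (formulas, weighting,
permutation logic, error control), not robustness to those field
realities; the bias regression and influence diagnostics exist precisely
because real data violate the clean model.

## Problem sizes and defaults

Simulation-backed checks run on a compact ellipsoid grid (30×36×30 voxels
at 4 mm, ≈10k in-mask voxels) with desk-scale counts: 300–500 simulated
datasets for FWE nulls, 1,000 permutations for contrasts, 200 replicates
for calibration and coverage — sizes chosen so the whole verification
battery runs in minutes on one CPU while leaving Monte-Carlo error well
inside the asserted tolerances. Production analyses on a 2 mm MNI152 grid
(the nilearn-bundled whole-brain mask is the default for real tables)
should use the full-scale settings (`paper_scale=True`: 10,000 simulated
datasets, 25,000 permutations).

## Known limitations

* Peak extraction from statistical images is out of scope; inputs are
  coordinate tables only.
* No anatomical labeling of clusters, surface rendering, or
  meta-analytic connectivity modeling.
* Heterogeneity indices (I², Q) are deliberately not reported for RVE
  fits, where they are not trustworthy point estimates.
* The analytic null samples uniformly over the whole mask; restricting to
  nonzero-MA voxels would shift tails slightly. The choice is documented
  and consistent between the null and its oracle.
* Whether the aggregate imputed correlation should live on the r or
  Fisher-z scale is genuinely ambiguous; raw-r is the default, the
  alternative is one call away.
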