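# cbmeta

Coordinate-based and behavioral meta-analysis of task-interference
(Stroop-type) studies: an Activation Likelihood Estimation (ALE) engine for
pooling reported activation peaks across fMRI experiments, and a
robust-variance-estimation (RVE) engine for pooling repeated-measures
reaction-time effect sizes across the same literature.

It is written for cognitive-neuroscience meta-analysts who have (a) tables
of activation foci (study, sample size, MNI/Talairach x/y/z, moderator
codes) and (b) tables of per-experiment RT summaries (n, condition means
and SDs/SEs, optionally the between-condition correlation), and who want the
complete analysis menu — subgroup main effects, conjunctions, contrasts,
contribution tables, moderator meta-regressions, bias and outlier checks,
sensitivity grids — from a single reproducible pipeline. A synthetic-data
module generates both table types with known ground truth, so every stage is
testable and calibratable without any external download.

## The statistics

**ALE.** Each reported focus becomes a 3-D Gaussian probability kernel whose
width combines between-template and between-subject spatial uncertainty,
the latter shrinking with sample size:
FWHM(n) = sqrt(FWHM_template² + FWHM_subject²/n). Per experiment, voxelwise
aggregation over foci takes the maximum, giving a modeled-activation (MA)
map; across experiments the union

    ALE = 1 − ∏ᵢ (1 − MAᵢ)

scores convergence at each voxel. Voxelwise p-values come from the analytic
null that samples one voxel at random per MA map and takes the same union
(computed exactly by convolution on the −log(1−ALE) axis). Clusters formed
at p < 0.001 are tested at cluster-level FWE p < 0.05 against the maximum
cluster size in simulated datasets of randomly placed foci with identical
properties (number of experiments, per-experiment n and foci count).
Conjunctions use the minimum statistic over corrected maps with a 25-voxel
extent rule; contrasts compare the observed ALE difference against 25,000
label-exchange permutations of the pooled experiments, thresholded at
posterior probability > 0.95 and masked by the respective main effect.
Leave-one-experiment-out contribution tables quantify which experiments
drive each significant cluster.

**Effect sizes and RVE.** The behavioral interference cost is the
repeated-measures standardized mean difference with small-sample correction
(Hedges g): with between-condition correlation r,

    SD_diff = sqrt(sd_I² + sd_C² − 2 r sd_I sd_C),  SD_within = SD_diff / sqrt(2(1−r)),
    d = (m_I − m_C) / SD_within,  Var_d = (1/n + d²/2n)·2(1−r),
    J = 1 − 3/(4(n−1)−1),  g = J·d,  Var_g = J²·Var_d.

Because r is rarely reported, it is recovered from paired t statistics or
SDs of differences where possible, and otherwise imputed from an
intercept-only RVE aggregate of the observed coefficients; analyses run
under three r-assignment strategies (observed+imputed, observed+floor 0.6,
all-imputed). Studies contribute several effect sizes, so inference uses
correlated-effects RVE: weights w = 1/(k_j(v̄_j + τ²)) per study j with k_j
effect sizes and mean variance v̄_j, a method-of-moments τ² (the assumed
within-study correlation ρ, default 0.8, enters only there), a CR2-adjusted
cluster-robust sandwich, Satterthwaite degrees of freedom, and HTZ-style
omnibus F tests for multi-level moderators. Bias is probed by meta-regression
of g on its SE (a dependent-effects funnel-asymmetry test) and outliers by
case-deletion diagnostics under an independence random-effects model.

## Worked example

```python
import numpy as np
from cbmeta import (FociSimConfig, TruthCenter, BehavSimConfig,
                    gen_foci_dataset, gen_behavioral_dataset,
                    cluster_fwe, build_es_table, fit_rve)
from cbmeta.io import ellipsoid_grid
from cbmeta.effect_size import records_from_frame, es_table_to_frame

# --- coordinate side: 20 experiments reporting one true center + noise foci
grid = ellipsoid_grid()
cfg = FociSimConfig(n_experiments=20,
                    truth_centers=[TruthCenter(0, 0, 0, 1.0, 5.0)],
                    n_noise_foci=8, seed=42)
experiments, truth = gen_foci_dataset(cfg, grid)
result = cluster_fwe(experiments, n_sim=300, seed=1, min_experiments=2)
print(result.cluster_table[result.cluster_table.significant])

# --- behavioral side: 68 studies, 164 effect sizes, nested dependence
table, truth = gen_behavioral_dataset(
    BehavSimConfig(n_studies=68, n_es_total=164, seed=7))
es = build_es_table(records_from_frame(table), strategy="observed_plus_imputed")
frame = es_table_to_frame(es)
fit = fit_rve(frame["g"].to_numpy(), frame["var_g"].to_numpy(),
              frame["study_id"].to_numpy())
print(fit.report())
```

Output:

```
 cluster_id  size  peak_ale  peak_x  peak_y  peak_z  p_fwe  significant
          3    49  0.316197    -2.0    -2.0    -2.0    0.0         True

CE-weighted RVE fit: 164 effect sizes in 68 studies; tau^2 = 0.0533, rho = 0.8
     coef  estimate  robust_se       t      df      p  ci_low  ci_high  df_unreliable
intercept    0.6274     0.0267 23.5114 66.8509 0.0000  0.5741   0.6806  False
```

The single significant cluster sits at (−2, −2, −2) mm — within one voxel of
the simulated truth center at the origin — and survives FWE correction
(no random dataset among 300 produced a cluster that large). The RVE
intercept 0.63 (robust SE 0.027, 95% CI 0.57–0.68, Satterthwaite df ≈ 67)
recovers the generating mean effect of 0.64 from the dependent,
study-nested effect sizes.

The full menu (subgroup ALEs, conjunctions, contrasts, contribution tables,
moderator meta-regressions, bias/outlier/sensitivity analyses) runs from a
YAML config through the CLI:

```bash
cbmeta all --config analysis.yaml --seed 7 --out results_dir
cbmeta behavior --config analysis.yaml --strategy all_imputed
```

Real coordinate/behavioral tables drop in via `coordinate_table:` /
`behavioral_table:` config keys (CSV schemas in `cbmeta.io`); without them
the bundled synthetic generators supply the inputs.

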