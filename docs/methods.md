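# Methods

This document describes the statistical machinery, the synthetic-data
model, and the design decisions behind `strucov`.

## ROI registry

The canonical `bilateral7` scheme has 75 names: 7 bilateral subcortical
structures (thalamus, caudate, putamen, pallidum, hippocampus, amygdala,
accumbens), 68 cortical regions (34 per hemisphere, Desikan-style
names), and `icv`. A `lateralized14` variant keeps left/right
subcortical volumes separate; `strucov.io.lateralized_to_bilateral` sums
homologous structures. FreeSurfer `aseg.stats` / `aparc.stats` files map
onto the registry via `strucov.roi.freesurfer_label_map`.

Pair families and their sizes:

| family                 | bilateral | lateralized |
|------------------------|-----------|-------------|
| intra-subcortical      | 21        | 91          |
| subcortico-cortical    | 476       | 952         |
| cortico-cortical       | 2278      | 2278        |

## Core statistics (`stats_core`)

**Partial Spearman.** Every variable (including covariates) is converted
to mid-ranks; covariates are removed from both sides by least-squares
(QR) residualization; the statistic is the Pearson correlation of the
residuals, tested with a t statistic on `n − 2 − k` degrees of freedom.
With no covariates this reduces exactly to the classical tie-corrected
Spearman correlation.

**z-score products.** Columns are z-scored with `ddof = 1`; for a pair
(X, Y) the per-subject coupling measure is `z_X · z_Y`, and
`(1/(n−1)) Σ z_X z_Y` reconstructs the Pearson correlation exactly. The
per-subject products are what gets correlated with severity in the
continuous analysis. A sign caveat is attached to every coupling output:
a large product means the subject is concordantly extreme on both
regions, so its correlation with severity cannot be read directly as
"more/less covariance" without inspecting the group-level structure.

**Olkin–Pratt adjustment.** Sample correlations feeding group contrasts
are adjusted by `r · (1 + (1 − r²)/(2(n − 3)))`, clamped to [−1, 1],
requiring `n ≥ 5`.

**BH-FDR.** A stable-sort step-up procedure that also returns the
realized (data-dependent) p-threshold — the largest p-value rejected, or
0.0 when nothing is rejected. The subcortical analysis applies it to one
pooled family of 504 tests (7 + 21 + 476); cortical regional (68) and
cortico-cortical (2278) tests form separate families.

## Group analysis (`group_analysis`)

The severity score is median-split. All subjects tied at the median go
en bloc to one side — the side minimizing `|n_low − n_high|`, with ties
broken toward the low group. Within each group the inter-regional
correlation matrix is computed and Olkin–Pratt-adjusted; the statistic
per pair is `r_high − r_low` (each group must have ≥ 5 subjects).

Inference uses a constrained permutation: each surrogate "low" group
takes half of the original low group and half of the original high group
(odd remainders assigned by a fair coin), preserving group sizes while
partially breaking the severity–covariance link. Iteration `it` of a run
with seed `s` uses `np.random.default_rng([s, it])`, so results are
independent of chunking and reproducible. P-values are add-one:
`(1 + #{surrogate ≥ observed}) / (1 + B)`. Familywise correction uses
the max-|difference| statistic across the tested pair family.

## Continuous analysis (`continuous_analysis`)

Three test blocks share one partial-Spearman configuration (covariates:
age, IQ, ICV):

1. regional volume vs severity (7 subcortical tests);
2. intra-subcortical z-product coupling vs severity (21 tests);
3. subcortico-cortical coupling vs severity (476 tests).

These 504 p-values are pooled into a single BH family. The
`subscale_specificity_sweep` repeats the coupling analysis for each of
the five RBS-R subscales and reports per-family flag counts; degenerate
subscales yield an all-NaN row rather than an error.

## Synthetic cohort model (`synthetic_data`)

Per subject `i` and region `r`:

```
V_ri = μ_r · (ICV_i / mean ICV) · exp(ε_ri) + σ_r · a_r · w_i · f_i
w_i  = sqrt(λ0 + λ1 · IS_i / max IS)
```

with `ε_ri ~ N(0, cv_r²)` (so ICV acts as a genuine multiplicative
confounder), `σ_r = μ_r · cv_r`, loadings `a_r`, and standard-normal
factors `f`. Subscale scores are drawn from gamma distributions and
rounded; the gamma parameters are fixed-point-adjusted against the exact
lattice moments so the *rounded* scores hit the target means and SDs.
Severity (IS) enters only through `w_i`, so the planted effect is a
severity-dependent covariance, not a mean shift.

**Clique factors.** `coupled_pairs` must form a union of cliques over
disjoint ROI sets; each connected component receives its own
standard-normal factor `f`, and the planted effect size of a pair is the
product of its two loadings. The generator rejects (with `ConfigError`)
pair sets whose components are not complete cliques, because a single
shared factor cannot represent an incomplete component without also
inducing the missing pairs.

The default configuration plants five intra-subcortical pairs
(amygdala–pallidum, amygdala–accumbens, pallidum–accumbens,
caudate–thalamus, hippocampus–putamen) organized as three cliques, and
recruits 24 cortical partners (loading 0.85) into the two larger
cliques. The cortical recruitment is deliberate: the pooled BH threshold
is data-dependent, and a realistic planted signal includes
subcortico-cortical couplings, which in turn raise the realized
threshold and the power for the intra-subcortical pairs. A regional
volume effect (thalamus, slope −100 mm³ per IS point) is planted for the
volume tests.

**A structural ceiling.** Under this model the z-product of a coupled
pair behaves like `w² χ²`-distributed noise around its mean; even with
`λ1 → ∞` the Spearman correlation between the product and IS saturates
near 0.56. Power therefore comes from two levers only: the share of
variance the factor carries (controlled by `roi_cv` vs `icv_cv`) and the
endogenous BH threshold (controlled by how much true signal is planted).
The frozen defaults (`λ0 = 0.05, λ1 = 250, roi_cv = 0.15,
icv_cv = 0.08`) were calibrated once against those levers and not tuned
afterwards; `scripts/calibrate_effects.py` documents the procedure,
including a dedicated higher-n configuration used to demonstrate power
of the group permutation test, whose contrast statistic has its own
structural cap (≈ 0.4) at the default cohort size.

**Presets.** `planted-coupling` (defaults), `null` (λ1 = 0: coupling
exists but is unrelated to severity — the correct null for the
severity tests), `planted-volume` (volume slope only), `tiny` (n = 8).
`make_fixture_suite` writes all four as byte-stable TSVs with a
manifest; `float_precision="round_trip"` parsing makes TSV round trips
byte-identical.

## Reproducibility

All randomness flows through `np.random.default_rng` with explicit
seeds; the CLI derives stage seeds from the run seed by fixed offsets,
so enabling or disabling one stage never shifts another stage's results.
Manifests record inputs, seeds, stage status and realized thresholds.
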