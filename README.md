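# strucov

Structural-covariance analysis of regional brain volumes against a
behavioral severity score. The package implements, end to end:

- **Brain–behavior associations** — partial Spearman correlations between
  per-region gray-matter volumes and a Repetitive Behavior Scale subscale
  (Insistence on Sameness by default), covarying age, IQ and intracranial
  volume (ICV).
- **Group covariance comparison** — a median split of the severity score
  (tied scores assigned en bloc to whichever side best balances group
  sizes), pairwise inter-regional correlation differences adjusted by the
  Olkin–Pratt population estimator, and inference by a constrained
  Monte-Carlo permutation test with a max-statistic familywise correction.
- **Continuous coupling analysis** — per-subject z-score products as a
  subject-level coupling measure, correlated with severity via the same
  partial Spearman machinery, with Benjamini–Hochberg FDR applied to a
  pooled subcortical family (7 regional + 21 intra-subcortical + 476
  subcortico-cortical tests = 504) and to cortical families separately.
- **Synthetic cohorts** — a generator with planted, scoreable effects
  (severity-coupled covariance cliques and regional volume slopes) plus a
  reproducible text fixture suite.
- **CLI** — `strucov simulate / analyze / report`.

## CLI usage

```bash
# Generate a synthetic cohort with planted severity-coupled covariance
strucov simulate --preset planted-coupling --seed 4 --out-dir runs/sim

# Full analysis: behavior stats, median-split permutation test,
# continuous coupling with pooled FDR, optional subscale specificity sweep
strucov analyze --volumes runs/sim/volumes.tsv \
                --phenotypes runs/sim/phenotypes.tsv \
                --out-dir runs/ana --n-iterations 2000 --specificity

# Re-render the split heatmap from a saved results table
strucov report --split-results runs/ana/split_intra_subcortical.tsv \
               --out-dir runs/rep
```

Every run writes a `manifest.txt` recording inputs, seeds, per-stage
status (`stage.<name> = ok` / `failed: ...`) and key realized quantities
such as the data-dependent BH p-threshold.

Presets: `planted-coupling` (default), `null` (coupling present but
unrelated to severity), `planted-volume` (regional volume slope only),
`tiny` (n = 8 smoke cohort).

## Library usage

```python
from strucov.synthetic_data import GeneratorConfig, generate_cohort
from strucov.continuous_analysis import run_subcortical_analysis
from strucov.group_analysis import median_split, constrained_permutation_test
from strucov.roi import intra_subcortical_pairs

cohort, volumes, truth = generate_cohort(GeneratorConfig(seed=0))
pooled, threshold = run_subcortical_analysis(volumes, cohort)

split = median_split(cohort.subscale("insistence_on_sameness"))
perm = constrained_permutation_test(
    volumes, split, intra_subcortical_pairs(volumes.scheme),
    n_iterations=2000, seed=0)
```

Input formats: TSV phenotype/volume tables (see `strucov.io`) or
FreeSurfer `aseg.stats` / `aparc.stats` files
(`strucov.io.read_freesurfer_stats`), mapped onto a 75-name ROI registry
(7 bilateral subcortical, 68 cortical, ICV) with an optional lateralized
variant.

## Tests and acceptance report

```bash
pytest -q                       # full suite, a few minutes
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`scripts/acceptance.py` re-computes the headline quantities (pair
enumeration counts, z-product reconstruction error, oracle agreement
rates, permutation type-I rates under a null cohort, planted-effect
recovery and specificity across 25 seeds, empirical FDR of the pooled BH
pass) and writes them as JSON.

Effect sizes in the generator defaults were calibrated once and frozen;
`scripts/calibrate_effects.py` documents the procedure and the frozen
values. Methodological details and design rationale are in
`docs/methods.md`.
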