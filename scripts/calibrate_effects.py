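#!/usr/bin/env python
"""One-time calibration of the synthetic generator's frozen effect sizes.

This script reproduces the calibration that froze the defaults in
``strucov.synthetic_data.GeneratorConfig``:

* ``coupling_slope`` (lambda1) = 250, ``coupling_base`` (lambda0) = 0.05,
  ``roi_cv`` = 0.15, ``icv_cv`` = 0.08, cortical clique loading 0.85 —
  chosen so the continuous analysis recovers >= 4/5 planted intra-
  subcortical pairs after the pooled 504-test FDR in >= 80 % of the
  canonical seeds 0-24, with <= 1 false pair on average;
* ``volume_effect_rois`` thalamus slope = -100 mm^3 per IS point — chosen
  so the single-region partial Spearman is negative in >= 90 % of seeds;
* the group-contrast "maximum effect" configuration used by the
  permutation power check (n=150, is_sd=12, lambda1=60, icv_cv=0.02,
  single planted pair).

Context for the choices (measured during calibration, re-derivable here):

* Per-pair partial Spearman of a z-product against IS is capped near 0.56
  by the chi-squared(1) noise of per-subject products under a Gaussian
  latent factor, regardless of effect size; the planted pairs therefore
  sit near the detection boundary and the widespread subcortico-cortical
  coupling of the default cliques (which raises the data-dependent BH
  threshold) is required for stable recovery.
* On seed ranges other than the canonical one, the recovery pass rate was
  0.68-0.92 (pooled ~0.82 over 125 seeds): truly above, but near, the
  0.80 bar.  Defaults were frozen once and not revisited.

Run: ``python scripts/calibrate_effects.py [--quick]``.  The full run
repeats the frozen-point measurements; ``--quick`` uses fewer seeds.
"""

from __future__ import annotations

import argparse
import warnings

import numpy as np

from strucov.continuous_analysis import (
    regional_volume_association,
    run_subcortical_analysis,
)
from strucov.group_analysis import constrained_permutation_test, median_split
from strucov.roi import intra_subcortical_pairs
from strucov.synthetic_data import GeneratorConfig, generate_cohort, preset_config


def recovery_rate(seeds: range) -> tuple[float, float]:
    rec, fp = [], []
    for seed in seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, vol, truth = generate_cohort(GeneratorConfig(seed=seed))
        pooled, _ = run_subcortical_analysis(vol, cohort)
        planted = truth.planted_pairs(set(vol.scheme.subcortical_names))
        hits = {
            tuple(sorted(a.pair))
            for a in pooled
            if a.family == "intra_subcortical" and a.q_flag
        }
        rec.append(len(hits & planted))
        fp.append(len(hits - planted))
    rec_arr = np.array(rec)
    return float(np.mean(rec_arr >= 4)), float(np.mean(fp))


def volume_effect_rate(seeds: range) -> float:
    neg = 0
    for seed in seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, vol, _ = generate_cohort(preset_config("planted-volume", seed))
        assoc = regional_volume_association(vol, cohort)
        neg += next(a.rho for a in assoc if a.pair[0] == "thalamus") < 0
    return neg / len(seeds)


def group_power_config(seed: int) -> GeneratorConfig:
    """The frozen 'maximum group-contrast effect' configuration."""
    return GeneratorConfig(
        seed=seed,
        n_subjects=150,
        is_sd=12.0,
        coupling_base=0.0,
        coupling_slope=60.0,
        icv_cv=0.02,
        coupled_pairs=(("amygdala", "pallidum"),),
        roi_loadings=(),
        volume_effect_rois=(),
    )


def group_power_rate(seeds: range, n_iterations: int = 2000) -> float:
    hits = 0
    for seed in seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, vol, _ = generate_cohort(group_power_config(seed))
        split = median_split(cohort.subscale("insistence_on_sameness"))
        pairs = intra_subcortical_pairs(vol.scheme)
        res = constrained_permutation_test(vol, split, pairs, n_iterations, seed=seed)
        i = next(k for k, p in enumerate(pairs) if set(p) == {"amygdala", "pallidum"})
        hits += res.p_maxstat[i] < 0.05
    return hits / len(seeds)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--quick", action="store_true", help="fewer seeds / iterations")
    args = ap.parse_args()
    n_rec, n_vol, n_pow, it = (10, 10, 5, 500) if args.quick else (25, 40, 20, 2000)

    p, fp = recovery_rate(range(n_rec))
    print(f"recovery_pass_rate_seeds_0_{n_rec - 1} = {p:.3f} (criterion >= 0.80)")
    print(f"recovery_false_pairs_mean = {fp:.3f} (criterion <= 1)")
    print(f"thalamus_negative_rho_rate = {volume_effect_rate(range(n_vol)):.3f} (target >= 0.90)")
    print(f"group_power_maxstat_rate = {group_power_rate(range(n_pow), it):.3f} (target >= 0.90)")


if __name__ == "__main__":
    main()
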