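"""Median-split group comparison of structural covariance.

Subjects are split into low- and high-severity groups at the sample median of
a behavioral score, with all median-tied subjects assigned en bloc to the
side giving the most even group sizes.  Structural covariance (Pearson r of
ROI volumes across subjects) is computed per group, each group's r values are
transformed to approximately unbiased population estimates using that group's
own degrees of freedom, and the high-minus-low difference of adjusted r is
tested by a constrained Monte-Carlo procedure: each iteration reshuffles
subjects into two pseudo-groups containing an even (+-1) mixture of the
original low and high members, so the null distribution excludes relabelings
that nearly reproduce the observed groups.  Familywise correction uses the
permutation distribution of the maximum |difference| across all pairs in the
family (max-statistic correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .io import VolumeTable
from .stats_core import adjust_r_population


@dataclass(frozen=True)
class SplitAssignment:
    """Low/high labels from a median split with en-bloc tie handling."""

    labels: tuple[str, ...]
    median_value: float
    tie_block_side: Literal["low", "high"]
    n_low: int
    n_high: int

    @property
    def low_mask(self) -> np.ndarray:
        return np.array([lab == "low" for lab in self.labels])

    @property
    def high_mask(self) -> np.ndarray:
        return ~self.low_mask


@dataclass(frozen=True)
class GroupCovariance:
    """Per-pair Pearson r by group plus adjusted values and their difference."""

    pairs: tuple[tuple[str, str], ...]
    r_low: np.ndarray
    r_high: np.ndarray
    r_low_adj: np.ndarray
    r_high_adj: np.ndarray
    diff: np.ndarray  # adjusted high - adjusted low


@dataclass(frozen=True)
class GroupDifferenceResult:
    """Observed group covariance differences with Monte-Carlo p-values."""

    pairs: tuple[tuple[str, str], ...]
    r_low: np.ndarray
    r_high: np.ndarray
    r_low_adj: np.ndarray
    r_high_adj: np.ndarray
    diff: np.ndarray
    p_uncorrected: np.ndarray
    p_maxstat: np.ndarray
    n_iterations: int
    seed: int

    def to_dataframe(self, alpha: float = 0.05) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_x": [x for x, _ in self.pairs],
                "roi_y": [y for _, y in self.pairs],
                "r_low": self.r_low,
                "r_high": self.r_high,
                "r_low_adj": self.r_low_adj,
                "r_high_adj": self.r_high_adj,
                "diff": self.diff,
                "p_uncorrected": self.p_uncorrected,
                "p_maxstat": self.p_maxstat,
                "significant_corrected": self.p_maxstat < alpha,
            }
        )


def median_split(scores: np.ndarray) -> SplitAssignment:
    """Split subjects at the sample median of ``scores``.

    Subjects strictly below the median are low, strictly above are high, and
    the whole block of median-tied subjects goes to whichever side minimizes
    |n_low - n_high| (ties between the two placements break to low, so the
    rule is deterministic).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise DegenerateInputError("median split needs at least 4 subjects")
    if np.ptp(s) == 0:
        raise DegenerateInputError("all scores identical; no median split exists")
    med = float(np.median(s))
    below = s < med
    above = s > med
    tied = s == med
    n_tied = int(tied.sum())
    if n_tied == 0:
        side: Literal["low", "high"] = "low"
    else:
        imbalance_low = abs((below.sum() + n_tied) - above.sum())
        imbalance_high = abs(below.sum() - (above.sum() + n_tied))
        side = "low" if imbalance_low <= imbalance_high else "high"
    low = below | (tied if side == "low" else np.zeros_like(tied))
    labels = tuple("low" if flag else "high" for flag in low)
    n_low = int(low.sum())
    n_high = s.size - n_low
    if n_low == 0 or n_high == 0:
        raise DegenerateInputError("median split produced an empty group")
    return SplitAssignment(labels, med, side, n_low, n_high)


def _pair_pearson(arr: np.ndarray, xi: np.ndarray, yi: np.ndarray) -> np.ndarray:
    """Pearson r for index pairs of the columns of ``arr``."""
    c = np.corrcoef(arr, rowvar=False)
    return c[xi, yi]


def _pair_indices(
    volumes: VolumeTable, pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = sorted({c for pair in pairs for c in pair}, key=volumes.scheme.names.index)
    loc = {c: i for i, c in enumerate(cols)}
    xi = np.array([loc[x] for x, _ in pairs])
    yi = np.array([loc[y] for _, y in pairs])
    return volumes.matrix(cols), xi, yi


def group_covariance_difference(
    volumes: VolumeTable,
    split: SplitAssignment,
    pairs: list[tuple[str, str]],
) -> GroupCovariance:
    """Adjusted high-minus-low Pearson r difference per region pair."""
    if len(split.labels) != volumes.n:
        raise ValidationError("split and volume table cover different subjects")
    if min(split.n_low, split.n_high) < 5:
        raise DegenerateInputError("each group needs at least 5 subjects")
    arr, xi, yi = _pair_indices(volumes, pairs)
    low, high = split.low_mask, split.high_mask
    for mask, label in ((low, "low"), (high, "high")):
        if (arr[mask].std(axis=0, ddof=1) == 0).any():
            raise DegenerateInputError(f"constant ROI column within the {label} group")
    r_low = _pair_pearson(arr[low], xi, yi)
    r_high = _pair_pearson(arr[high], xi, yi)
    r_low_adj = adjust_r_population(r_low, split.n_low)
    r_high_adj = adjust_r_population(r_high, split.n_high)
    return GroupCovariance(
        tuple(pairs), r_low, r_high, r_low_adj, r_high_adj, r_high_adj - r_low_adj
    )


def _stratified_halves(
    idx: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split one stratum as evenly as possible; odd remainder by fair coin."""
    perm = rng.permutation(idx)
    cut = idx.size // 2
    if idx.size % 2 == 1 and rng.random() < 0.5:
        cut += 1
    return perm[:cut], perm[cut:]


def constrained_permutation_test(
    volumes: VolumeTable,
    split: SplitAssignment,
    pairs: list[tuple[str, str]],
    n_iterations: int = 10_000,
    seed: int = 0,
    alternative: Literal["two-sided", "greater"] = "two-sided",
    debug_checks: bool = False,
) -> GroupDifferenceResult:
    """Constrained Monte-Carlo test of the adjusted covariance difference.

    Each iteration splits the original low and high groups in half (odd
    strata assign their remainder by fair coin) and recombines the halves
    into two pseudo-groups, so every pseudo-group holds an even (+-1) mixture
    of original low and high members.  Adjusted r differences between the
    pseudo-groups form the null distribution.  ``p_uncorrected`` uses each
    pair's own null; ``p_maxstat`` uses the per-iteration maximum |difference|
    over all pairs in the family, giving familywise control.  Both use the
    add-one estimator (p = (1 + exceedances) / (1 + iterations)) so p is
    never 0.  All randomness derives from ``seed``; results are independent
    of any chunking of the iteration range.
    """
    if n_iterations < 100:
        raise ValidationError("n_iterations must be at least 100")
    if min(split.n_low, split.n_high) < 2:
        raise DegenerateInputError("stratified reshuffling needs >= 2 subjects per group")
    observed = group_covariance_difference(volumes, split, pairs)
    arr, xi, yi = _pair_indices(volumes, pairs)
    low_idx = np.flatnonzero(split.low_mask)
    high_idx = np.flatnonzero(split.high_mask)

    obs = observed.diff
    abs_obs = np.abs(obs)
    count = np.zeros(len(pairs), dtype=np.int64)
    count_max = np.zeros(len(pairs), dtype=np.int64)

    for it in range(n_iterations):
        rng = np.random.default_rng([seed, it])
        lo_a, lo_b = _stratified_halves(low_idx, rng)
        hi_a, hi_b = _stratified_halves(high_idx, rng)
        g1 = np.concatenate([lo_a, hi_a])
        g2 = np.concatenate([lo_b, hi_b])
        if debug_checks:
            for half, s in ((lo_a, low_idx.size), (hi_a, high_idx.size)):
                assert s // 2 <= half.size <= (s + 1) // 2
            assert g1.size + g2.size == volumes.n
        r1 = adjust_r_population(_pair_pearson(arr[g1], xi, yi), g1.size)
        r2 = adjust_r_population(_pair_pearson(arr[g2], xi, yi), g2.size)
        null = r2 - r1
        if alternative == "two-sided":
            stat = np.abs(null)
            count += stat >= abs_obs
            count_max += stat.max() >= abs_obs
        else:
            count += null >= obs
            count_max += null.max() >= obs

    p_unc = (1.0 + count) / (1.0 + n_iterations)
    p_max = (1.0 + count_max) / (1.0 + n_iterations)
    return GroupDifferenceResult(
        tuple(pairs),
        observed.r_low,
        observed.r_high,
        observed.r_low_adj,
        observed.r_high_adj,
        observed.diff,
        p_unc,
        p_max,
        n_iterations,
        seed,
    )
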