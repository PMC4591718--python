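"""Statistical primitives shared by every analysis stage.

Implements the per-subject decomposition of the Pearson correlation into
z-score products, rank-based partial correlation with nuisance covariates,
the small-sample (Olkin-Pratt) bias adjustment of r, Benjamini-Hochberg FDR,
and the nonparametric severity comparison across RBS-R subscales.

The z-product decomposition writes the Pearson correlation of two volume
series X, Y over N subjects as

    r = (1 / (N - 1)) * sum_i z_Xi * z_Yi

with z-scores computed using the sample (N - 1) standard deviation.  Each
summand z_Xi * z_Yi is a single subject's contribution to the inter-regional
association, and is the per-subject coupling statistic used throughout the
continuous analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError
from .io import SUBSCALES, CohortTable

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class PartialCorrResult:
    """A partial (rank) correlation: coefficient, two-sided p, n, covariate count."""

    rho: float
    p: float
    n: int
    k: int


@dataclass(frozen=True)
class ZProductMatrix:
    """Per-subject z-score products for a list of region pairs.

    ``values[i, j]`` is z_Xi * z_Yi for subject i and pair ``pair_index[j]``;
    summing a column and dividing by (n - 1) reconstructs that pair's Pearson r.
    """

    values: np.ndarray
    pair_index: tuple[tuple[str, str], ...]
    n: int

    def reconstruct_pearson(self) -> np.ndarray:
        return self.values.sum(axis=0) / (self.n - 1)


def zscore_columns(volumes: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Standardize each column to mean 0 and sample SD 1 (N - 1 denominator).

    Raises :class:`DegenerateInputError` naming the offending column if any
    column is constant.
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise DegenerateInputError("z-scoring needs at least 2 rows")
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        idx = int(np.flatnonzero(sd == 0)[0])
        name = volumes.columns[idx] if isinstance(volumes, pd.DataFrame) else idx
        raise DegenerateInputError(f"constant column {name!r} cannot be z-scored")
    z = (arr - arr.mean(axis=0)) / sd
    if isinstance(volumes, pd.DataFrame):
        return pd.DataFrame(z, index=volumes.index, columns=volumes.columns)
    return z.reshape(np.shape(volumes))


def zproduct_pairs(zmat: pd.DataFrame, pairs: list[tuple[str, str]]) -> ZProductMatrix:
    """Per-subject z-score products for each (X, Y) pair of columns of ``zmat``.

    ``zmat`` must already be standardized (see :func:`zscore_columns`); the
    reconstruction identity then holds exactly for every pair.
    """
    for x, y in pairs:
        if x == y:
            raise ValidationError(f"self-pair ({x!r}, {x!r}) is not a region pair")
    xi = [zmat.columns.get_loc(x) for x, _ in pairs]
    yi = [zmat.columns.get_loc(y) for _, y in pairs]
    z = zmat.to_numpy(dtype=float)
    values = z[:, xi] * z[:, yi]
    return ZProductMatrix(values, tuple((x, y) for x, y in pairs), z.shape[0])


def _rank(a: np.ndarray) -> np.ndarray:
    """Mid-rank transform, column-wise for 2-D input."""
    if a.ndim == 1:
        return stats.rankdata(a)
    return stats.rankdata(a, axis=0)


def partial_spearman_batch(
    x: np.ndarray,
    ys: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Spearman of ``x`` against each column of ``ys``.

    All variables (including covariates) are mid-rank transformed; the ranks
    of x and of each y column are residualized on an intercept plus covariate
    ranks by least squares, and the correlation of residuals is returned with
    a two-sided p-value from the t distribution on n - 2 - k degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if ys.ndim == 1:
        ys = ys[:, None]
    n = x.shape[0]
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates, float).T).T.shape[1]
    if n <= k + 2:
        raise DegenerateInputError(f"n={n} too small for k={k} covariates")
    if np.ptp(x) == 0:
        raise DegenerateInputError("behavioral variable is constant")
    const = np.ptp(ys, axis=0) == 0
    if const.any():
        raise DegenerateInputError(
            f"column {int(np.flatnonzero(const)[0])} of the outcome matrix is constant"
        )

    rx = _rank(x)
    ry = _rank(ys)
    if covariates is None:
        design = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack([np.ones(n), _rank(cov)])
    q, _ = np.linalg.qr(design)
    res_x = rx - q @ (q.T @ rx)
    res_y = ry - q @ (q.T @ ry)

    nx = np.linalg.norm(res_x)
    nys = np.linalg.norm(res_y, axis=0)
    if nx < 1e-12 or (nys < 1e-12).any():
        raise DegenerateInputError("variable lies in the span of the covariates")
    rho = np.clip((res_x @ res_y) / (nx * nys), -1.0, 1.0)

    df = n - 2 - k
    one_minus = np.clip(1.0 - rho**2, _TINY, None)
    t = rho * np.sqrt(df / one_minus)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _TINY, 1.0)
    return rho, p


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PartialCorrResult:
    """Spearman rank correlation of x and y, partialling ``covariates``.

    With no covariates this reduces to the classical (tie-corrected) Spearman
    correlation.
    """
    rho, p = partial_spearman_batch(np.asarray(x, float), np.asarray(y, float), covariates)
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates, float).T).T.shape[1]
    return PartialCorrResult(float(rho[0]), float(p[0]), len(np.asarray(x)), k)


def pearson_matrix(volumes: pd.DataFrame, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Pearson product-moment r for each (X, Y) column pair of ``volumes``."""
    cols = sorted({c for pair in pairs for c in pair}, key=list(volumes.columns).index)
    arr = volumes.loc[:, cols].to_numpy(dtype=float)
    if arr.shape[0] < 4:
        raise DegenerateInputError("Pearson matrix needs at least 4 subjects")
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        name = cols[int(np.flatnonzero(sd == 0)[0])]
        raise DegenerateInputError(f"constant column {name!r}")
    corr = np.corrcoef(arr, rowvar=False)
    loc = {c: i for i, c in enumerate(cols)}
    return np.array([corr[loc[x], loc[y]] for x, y in pairs])


def adjust_r_population(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Approximately unbiased population estimate of a Pearson correlation.

    Applies the Olkin-Pratt first-order correction
    ``r * (1 + (1 - r^2) / (2 * (n - 3)))`` and clamps to [-1, 1].  The
    correction uses the group's own degrees of freedom, so groups of unequal
    size become comparable before differencing.
    """
    if n < 5:
        raise DegenerateInputError(f"bias adjustment unstable for n={n} < 5")
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) > 1 + 1e-12).any():
        raise ValidationError("correlation outside [-1, 1]")
    arr = np.clip(arr, -1.0, 1.0)
    out = np.clip(arr * (1.0 + (1.0 - arr**2) / (2.0 * (n - 3))), -1.0, 1.0)
    return float(out) if np.isscalar(r) else out


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns per-test rejection flags and the realized p-value threshold (the
    largest p among rejected tests; 0.0 when nothing is rejected).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if not (0 < q < 1):
        raise ValidationError(f"FDR rate q={q} outside (0, 1)")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    crit = (np.arange(1, m + 1) / m) * q
    passed = np.flatnonzero(p[order] <= crit)
    if passed.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    cut = passed[-1]
    threshold = float(p[order][cut])
    return p <= threshold, threshold


@dataclass(frozen=True)
class SubscaleComparison:
    """Kruskal-Wallis across the five RBS-R subscales plus pairwise rank-sum
    tests of insistence-on-sameness against each other subscale.

    ``pairwise`` maps subscale name -> (rank-sum statistic of the IS sample,
    one-sided p for IS scoring higher).
    """

    h_statistic: float
    p_omnibus: float
    pairwise: dict[str, tuple[float, float]]


def compare_subscale_severity(cohort: CohortTable) -> SubscaleComparison:
    """Test whether insistence-on-sameness is endorsed more severely than the
    other four RBS-R subscales.

    Omnibus: Kruskal-Wallis H over the five score distributions.  Follow-up:
    Wilcoxon rank-sum (mid-rank ties, normal approximation) of IS versus each
    other subscale, one-sided for IS being greater.
    """
    samples = {name: cohort.subscale(name) for name in SUBSCALES}
    for name, s in samples.items():
        if np.ptp(s) == 0:
            warnings.warn(f"subscale {name!r} is constant across subjects", stacklevel=2)
    is_scores = samples["insistence_on_sameness"]
    try:
        h, p_omni = stats.kruskal(*samples.values())
    except ValueError:  # all observations identical across all groups
        h, p_omni = 0.0, 1.0
    pairwise: dict[str, tuple[float, float]] = {}
    n1 = len(is_scores)
    for name in SUBSCALES[1:]:
        u, p = stats.mannwhitneyu(
            is_scores, samples[name], alternative="greater", method="asymptotic"
        )
        w = float(u) + n1 * (n1 + 1) / 2.0  # rank sum of the IS sample
        pairwise[name] = (w, float(p))
    return SubscaleComparison(float(h), float(p_omni), pairwise)
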