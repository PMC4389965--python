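"""Cohort dichotomization by KDE minima and resampling association test.

A cohort is split into splitter-high and splitter-low patients at a
local minimum of the kernel density estimate of the splitter gene's log2
expression (with a <5%-of-maximal-density rule when several minima
exist).  The response gene is then compared between the high group and
10,000 equally sized random subsamples of the low group; the mean M and
standard deviation SD of the resampled mean differences give the
statistic Z = -M/SD, converted to a two-sided p-value with the standard
normal CDF.  Repression of the response gene in splitter-high patients
yields M < 0 and Z > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the density-minimum cutoff search."""

    cutoff: float | None
    grid_x: np.ndarray
    density: np.ndarray
    minima: list[float]
    max_density: float
    rule_applied: str  # 'single_minimum' | 'five_percent_rule' | 'none_found'


@dataclass(frozen=True)
class BootstrapResult:
    """Resampling comparison of the high group against the low group."""

    n_high: int
    n_low: int
    M: float
    SD: float
    Z: float
    p_two_sided: float
    n_iter: int
    seed: int | None
    degenerate: bool = False

    @property
    def pct_high(self) -> float:
        return pct_high(self.n_high, self.n_low)


def pct_high(n_high: int, n_low: int) -> float:
    """Percentage of splitter-high patients, rounded to one decimal for
    reporting."""
    if n_high + n_low == 0:
        raise ValueError("empty cohort")
    return round(100.0 * n_high / (n_high + n_low), 1)


def estimate_density(
    values: np.ndarray, bandwidth: str | float = "silverman", n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE on an even grid spanning [min - 3h, max + 3h].

    Returns (grid, density, bandwidth h).  Silverman's rule by default.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 observations")
    if np.std(values) == 0:
        raise ValueError("constant input: density is degenerate")
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, n_grid)
    return grid, kde(grid), h


def find_cutoff(
    grid_x: np.ndarray, density: np.ndarray, five_pct: float = 0.05
) -> CutoffResult:
    """Locate the dichotomization cutoff among interior density minima.

    Exactly one interior minimum: that is the cutoff.  Several: among
    minima with density < five_pct * max density, the one with the
    smallest x above the dominant (global) mode is chosen — the minimum
    closest to the low-expression distribution.  No interior minimum, or
    none qualifying: rule_applied = 'none_found' and cutoff is None.
    """
    d = np.asarray(density, dtype=float)
    x = np.asarray(grid_x, dtype=float)
    max_density = float(d.max())

    interior = np.flatnonzero((d[1:-1] < d[:-2]) & (d[1:-1] <= d[2:])) + 1
    minima = [float(x[i]) for i in interior]

    if len(interior) == 0:
        return CutoffResult(None, x, d, minima, max_density, "none_found")
    if len(interior) == 1:
        return CutoffResult(
            float(x[interior[0]]), x, d, minima, max_density, "single_minimum"
        )

    mode_x = float(x[np.argmax(d)])
    qualifying = [
        i for i in interior if d[i] < five_pct * max_density and x[i] > mode_x
    ]
    if not qualifying:
        return CutoffResult(None, x, d, minima, max_density, "none_found")
    best = min(qualifying, key=lambda i: x[i])
    return CutoffResult(
        float(x[best]), x, d, minima, max_density, "five_percent_rule"
    )


def dichotomize(
    cohort: pd.DataFrame, cutoff: float, splitter_col: str = "evi1_log2"
) -> pd.Series:
    """High/low labels: high iff splitter expression is strictly above
    the cutoff (boundary values go to the low group)."""
    return pd.Series(
        cohort[splitter_col].to_numpy() > cutoff,
        index=cohort.index,
        name="high",
    )


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, p = 2 * (1 - Phi(|z|))."""
    return float(2.0 * stats.norm.sf(abs(z)))


def bootstrap_association(
    cohort: pd.DataFrame,
    labels: pd.Series,
    n_iter: int = 10_000,
    seed: int | None = None,
    response_col: str = "ms4a3_log2",
    with_replacement: bool = False,
) -> BootstrapResult:
    """Compare response expression in the high group against ``n_iter``
    random, equally sized subsamples of the low group.

    Each iteration draws n_high low-group patients (without replacement
    by default) and records d_i = mean(response | high) - mean(response
    | sampled low).  M = mean(d_i), SD = sample standard deviation of
    d_i, Z = -M/SD, p = 2*(1 - Phi(|Z|)).  A degenerate run (SD = 0) is
    reported as Z = 0, p = 1 with the degenerate flag set.
    """
    labels = labels.astype(bool)
    response = cohort[response_col].to_numpy(dtype=float)
    high = response[labels.to_numpy()]
    low = response[~labels.to_numpy()]
    n_high, n_low = len(high), len(low)
    if n_high < 2:
        raise ValueError("need at least 2 high-group patients")
    if n_low < n_high:
        raise ValueError("low group smaller than high group")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")

    rng = np.random.default_rng(seed)
    mean_high = high.mean()
    if with_replacement:
        draws = rng.integers(0, n_low, size=(n_iter, n_high))
        sampled_means = low[draws].mean(axis=1)
    else:
        # vectorized sampling without replacement: first n_high positions
        # of an independent permutation per iteration
        keys = rng.random((n_iter, n_low))
        idx = np.argpartition(keys, n_high - 1, axis=1)[:, :n_high]
        sampled_means = low[idx].mean(axis=1)
    d = mean_high - sampled_means

    M = float(d.mean())
    SD = float(d.std(ddof=1)) if n_iter > 1 else 0.0
    if SD == 0.0:
        return BootstrapResult(
            n_high, n_low, M, SD, 0.0, 1.0, n_iter, seed, degenerate=True
        )
    Z = -M / SD
    return BootstrapResult(n_high, n_low, M, SD, Z, z_to_p(Z), n_iter, seed)


def associate(
    cohort: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int | None = None,
    bandwidth: str | float = "silverman",
    five_pct: float = 0.05,
    splitter_col: str = "evi1_log2",
    response_col: str = "ms4a3_log2",
) -> tuple[CutoffResult, BootstrapResult | None]:
    """Full cohort analysis: KDE -> cutoff -> dichotomize -> resampling
    test.  Returns (CutoffResult, BootstrapResult); the second is None
    when no cutoff was found or a group is too small."""
    grid, dens, _h = estimate_density(
        cohort[splitter_col].to_numpy(), bandwidth
    )
    cut = find_cutoff(grid, dens, five_pct)
    if cut.cutoff is None:
        return cut, None
    labels = dichotomize(cohort, cut.cutoff, splitter_col)
    n_high = int(labels.sum())
    n_low = int((~labels).sum())
    if n_high < 2 or n_low < n_high:
        return cut, None
    boot = bootstrap_association(
        cohort, labels, n_iter=n_iter, seed=seed, response_col=response_col
    )
    return cut, boot
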