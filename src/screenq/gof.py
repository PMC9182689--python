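"""Goodness-of-fit tests for the model's distributional predictions.

Two test families, both Kolmogorov–Smirnov style with discrete
reference laws:

* arrival Poissonness — are yearly diagnosis counts consistent with a
  homogeneous Poisson arrival process?  (Necessary, not sufficient,
  for the Markovian-arrivals assumption behind the product form.)
* queue length — does the empirical occupancy distribution of a queue
  match the predicted Poisson(rho) stationary marginal?

Classical KS p-values are conservative for discrete references, so by
default p-values come from a Monte-Carlo null: simulate the reference,
recompute the statistic, and report the exceedance fraction.  For the
arrival test the rate is re-estimated within each null replicate,
mirroring that the observed rate was itself estimated from the counts
under test.  Decisions across many subgroups are made at the
Bonferroni-adjusted 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "KsResult",
    "GofReport",
    "ks_poisson_counts",
    "ks_queue_length",
    "bonferroni",
    "gof_report",
]


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float
    n_obs: int
    method: str


@dataclass(frozen=True)
class GofReport:
    """Per-test statistics with Bonferroni-adjusted decisions."""

    table: pd.DataFrame  # label, family, statistic, p_value, p_adjusted, reject

    @property
    def n_rejections(self) -> int:
        return int(self.table["reject"].sum())


def _support_grid(rate: float, observed_max: int) -> np.ndarray:
    hi = max(int(observed_max), int(stats.poisson.ppf(1 - 1e-9, rate)) if rate > 0 else 0)
    return np.arange(hi + 1)


def _ks_stat_matrix(samples: np.ndarray, rates: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of each sample row to Poisson(rates[row]).

    The ECDF is accumulated through per-row histograms, which keeps
    memory linear in (rows x grid) even for tens of thousands of
    samples per row.
    """
    n_rows, n = samples.shape
    K = len(grid)
    hist = np.zeros((n_rows, K + 1))
    vals = np.minimum(samples.astype(np.int64), K)  # sentinel bin K: beyond grid
    np.add.at(hist, (np.repeat(np.arange(n_rows), n), vals.ravel()), 1.0)
    ecdf = np.cumsum(hist[:, :K], axis=1) / n
    ref = stats.poisson.cdf(grid[None, :], rates[:, None])
    return np.abs(ecdf - ref).max(axis=1)


def ks_poisson_counts(
    yearly_counts,
    rate: float | None = None,
    n_null: int = 2000,
    seed: int | None = None,
    method: str = "simulated",
) -> KsResult:
    """KS test of yearly arrival counts against Poisson(rate * 1 year).

    ``rate`` defaults to the empirical mean of the counts (the model's
    own estimator).  The simulated null re-estimates the rate per
    replicate so the plug-in bias is reflected in the reference
    distribution of the statistic.
    """
    counts = np.asarray(yearly_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 years of counts")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if rate is None:
        rate = float(counts.mean())
    if rate <= 0:
        raise ValueError("rate must be > 0")
    n = counts.size
    grid = _support_grid(rate, int(counts.max()))
    stat = float(
        _ks_stat_matrix(counts[None, :], np.array([rate]), grid)[0]
    )
    if method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(n) * stat))
        return KsResult(stat, min(1.0, p), n, method)
    rng = np.random.default_rng(seed)
    null_counts = rng.poisson(rate, size=(n_null, n)).astype(float)
    null_rates = null_counts.mean(axis=1).clip(min=1e-12)
    null_grid = _support_grid(rate, int(null_counts.max()))
    null_stats = _ks_stat_matrix(null_counts, null_rates, null_grid)
    p = (1.0 + np.count_nonzero(null_stats >= stat - 1e-15)) / (n_null + 1.0)
    return KsResult(stat, float(p), n, "simulated")


def ks_queue_length(
    empirical_counts,
    predicted_load: float,
    n_null: int = 2000,
    seed: int | None = None,
    method: str = "simulated",
) -> KsResult:
    """KS test of an empirical occupancy histogram against Poisson(rho).

    ``empirical_counts[k]`` is the number of samples in which the queue
    held exactly ``k`` agents.  The predicted load is an external model
    quantity (not fitted to these samples), so the null does not
    re-estimate it.
    """
    hist = np.asarray(empirical_counts, dtype=float)
    if hist.ndim != 1 or np.any(hist < 0):
        raise ValueError("empirical_counts must be a non-negative histogram")
    n = hist.sum()
    if n <= 0:
        raise ValueError("empty histogram")
    if not np.allclose(hist, np.round(hist)):
        raise ValueError("histogram entries must be integer sample counts")
    rho = float(predicted_load)
    if rho < 0:
        raise ValueError("predicted load must be >= 0")
    n = int(round(n))
    grid = _support_grid(rho, len(hist) - 1)
    ecdf = np.cumsum(np.pad(hist, (0, len(grid) - len(hist)))) / n
    ref = stats.poisson.cdf(grid, rho) if rho > 0 else np.ones_like(grid, dtype=float)
    stat = float(np.abs(ecdf - ref).max())
    if method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(n) * stat))
        return KsResult(stat, min(1.0, p), n, method)
    rng = np.random.default_rng(seed)
    null_samples = rng.poisson(rho, size=(n_null, n)).astype(float)
    null_grid = _support_grid(rho, int(null_samples.max()) if rho > 0 else 0)
    null_stats = _ks_stat_matrix(null_samples, np.full(n_null, rho), null_grid)
    p = (1.0 + np.count_nonzero(null_stats >= stat - 1e-15)) / (n_null + 1.0)
    return KsResult(stat, float(p), n, "simulated")


def bonferroni(p_values) -> np.ndarray:
    """Multiply each p-value by the number of tests, capped at one."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def gof_report(tests, alpha: float = 0.05) -> GofReport:
    """Assemble a report from ``(label, family, KsResult)`` triples."""
    labels = [t[0] for t in tests]
    families = [t[1] for t in tests]
    stats_ = [t[2].statistic for t in tests]
    raw = [t[2].p_value for t in tests]
    adj = bonferroni(raw)
    table = pd.DataFrame(
        {
            "label": labels,
            "family": families,
            "statistic": stats_,
            "p_value": raw,
            "p_adjusted": adj,
            "reject": adj < alpha,
        }
    )
    return GofReport(table=table)
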