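"""Exact equilibrium analysis of infinite-server networks.

Solving the traffic equations ``lambda = eta + lambda R`` (row-vector
convention) gives the aggregate arrival rate into each queue.  For an
open network of infinite-server queues with Poisson exogenous arrivals
the joint stationary law factorizes into independent Poisson marginals,

    P(N_1* = n_1, ..., N_J* = n_J) = prod_j exp(-rho_j) rho_j^{n_j} / n_j!

with loads ``rho_j = lambda_j / mu_j``.  This holds for *arbitrary*
service-time distributions with the given means (insensitivity), so the
analysis below only ever consumes service means.  Little's law then
yields the mean network sojourn time ``E(W*) = sum_j rho_j / eta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import QueueNetwork, require_valid

__all__ = [
    "TrafficSolution",
    "StationaryModel",
    "TrafficError",
    "solve_traffic",
    "stationary_model",
    "joint_pmf",
    "marginal_pmf",
    "marginal_tail",
    "expected_sojourn",
]

_RESID_RTOL = 1e-9


class TrafficError(RuntimeError):
    """No stationary traffic solution exists (I - R singular)."""


@dataclass(frozen=True)
class TrafficSolution:
    """Aggregate arrival rates and per-queue loads at equilibrium."""

    arrival_rates: np.ndarray  # lambda, per month
    loads: np.ndarray  # rho_j = lambda_j / mu_j


@dataclass(frozen=True)
class StationaryModel:
    """Product-of-Poissons stationary law with means ``loads``.

    Queues with ``rho_j = 0`` carry a degenerate Poisson(0) marginal
    (all mass at zero occupancy) rather than being an error: the
    no-screening network has an empty early-treatment queue.
    """

    loads: np.ndarray

    @property
    def n_queues(self) -> int:
        return len(self.loads)

    @property
    def means(self) -> np.ndarray:
        return np.asarray(self.loads)


def solve_traffic(net: QueueNetwork) -> TrafficSolution:
    """Solve ``lambda = eta (I - R)^{-1}`` for the aggregate rates.

    Direct factorization with a fixed-point fallback; the residual
    ``||lambda - eta - lambda R||`` must be below 1e-9 relative to
    ``||lambda||``.
    """
    require_valid(net)
    R = net.routing.entries
    eta = net.exogenous_rates
    J = len(eta)
    A = np.eye(J) - R
    try:
        lam = np.linalg.solve(A.T, eta)
    except np.linalg.LinAlgError:
        lam = _fixed_point(eta, R)
    resid = np.linalg.norm(lam - eta - lam @ R)
    if not np.isfinite(resid) or resid > _RESID_RTOL * max(1.0, np.linalg.norm(lam)):
        raise TrafficError("no stationary traffic solution")
    lam = np.where(np.abs(lam) < 1e-15, 0.0, lam)
    if np.any(lam < 0):
        raise TrafficError("no stationary traffic solution (negative rates)")
    rho = lam * net.service_means
    return TrafficSolution(arrival_rates=lam, loads=rho)


def _fixed_point(eta: np.ndarray, R: np.ndarray, max_iter: int = 100_000) -> np.ndarray:
    lam = eta.copy()
    for _ in range(max_iter):
        new = eta + lam @ R
        if np.linalg.norm(new - lam) <= 1e-12 * max(1.0, np.linalg.norm(new)):
            return new
        lam = new
    return lam


def stationary_model(net: QueueNetwork) -> StationaryModel:
    """Product-form stationary distribution of a valid network."""
    return StationaryModel(loads=solve_traffic(net).loads)


def joint_pmf(model: StationaryModel, counts) -> float:
    """P(N_1* = n_1, ..., N_J* = n_J) under the product form.

    Evaluated in log space to avoid underflow for large loads.
    """
    n = np.asarray(counts)
    if len(n) != model.n_queues:
        raise ValueError(f"counts length {len(n)} != {model.n_queues} queues")
    if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    rho = np.asarray(model.loads, dtype=float)
    logp = 0.0
    for rho_j, n_j in zip(rho, n):
        if rho_j == 0.0:
            if n_j != 0:
                return 0.0
            continue  # Poisson(0): point mass at 0
        logp += stats.poisson.logpmf(n_j, rho_j)
    return float(math.exp(logp))


def marginal_pmf(model: StationaryModel, queue: int, count: int) -> float:
    """P(N_j* = count) for one queue."""
    rho = float(model.loads[queue])
    if count < 0:
        raise ValueError("count must be >= 0")
    if rho == 0.0:
        return 1.0 if count == 0 else 0.0
    return float(stats.poisson.pmf(count, rho))


def marginal_tail(model: StationaryModel, queue: int, x: float) -> float:
    """Exceedance probability ``P(N_j* > x)`` for real ``x >= 0``.

    Equals ``1 - exp(-rho_j) * sum_{k=0}^{floor(x)} rho_j^k / k!``; the
    partial sum is evaluated through the regularized incomplete gamma
    function, which is exact for all loads.
    """
    if x < 0:
        raise ValueError("threshold x must be >= 0")
    rho = float(model.loads[queue])
    if rho == 0.0:
        return 0.0
    return float(stats.poisson.sf(math.floor(x), rho))


def expected_sojourn(net: QueueNetwork) -> float:
    """Mean time an agent spends in the network, in months.

    Little's law: ``E(W*) = E(N*) / eta = (1/eta) sum_j rho_j`` with
    ``eta`` the total exogenous arrival rate.
    """
    sol = solve_traffic(net)
    eta_total = float(net.exogenous_rates.sum())
    if eta_total <= 0:
        raise ValueError("no arrivals: total exogenous rate is zero")
    return float(sol.loads.sum() / eta_total)
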