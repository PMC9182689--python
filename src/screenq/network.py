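"""Open networks of infinite-server queues.

A network is described by a probabilistic routing matrix ``R`` (entry
``r_ij`` is the probability of moving to queue ``j`` on leaving queue
``i``; the residual mass ``r_i0 = 1 - sum_j r_ij`` exits the network),
a vector of exogenous Poisson arrival rates ``eta`` and one service-time
specification per queue.  Every queue has infinitely many servers, so
agents are served in parallel with independent durations; only the mean
of each service distribution matters for equilibrium quantities.

The internal time unit is months throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ServiceSpec",
    "RoutingMatrix",
    "QueueNetwork",
    "NetworkValidationError",
    "validate_network",
    "exit_probabilities",
]

#: residual tolerance for "every agent eventually exits" checks
_EXIT_TOL = 1e-10
#: relative tolerance between a declared mean and the analytic mean
_MEAN_RTOL = 1e-9

_FAMILIES = ("exponential", "lognormal", "deterministic", "uniform", "empirical", "mixture")


class NetworkValidationError(ValueError):
    """Raised when a structurally invalid network object is used."""


@dataclass(frozen=True)
class ServiceSpec:
    """Service-time distribution of a queue, supported on [0, inf).

    Parameters
    ----------
    family:
        One of ``exponential | lognormal | deterministic | uniform |
        empirical | mixture``.
    params:
        Family-specific parameters (see the constructors below).
    mean:
        The distribution mean ``1/mu`` in months.  For parametric
        families it must agree with the analytic mean of ``params``.
    """

    family: str
    params: tuple
    mean: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise NetworkValidationError(f"unknown service family {self.family!r}")
        if not (math.isfinite(self.mean) and self.mean > 0):
            raise NetworkValidationError("service mean must be finite and > 0")
        analytic = self._analytic_mean()
        if analytic is not None and not math.isclose(
            analytic, self.mean, rel_tol=_MEAN_RTOL
        ):
            raise NetworkValidationError(
                f"declared mean {self.mean} != analytic mean {analytic} "
                f"for family {self.family!r}"
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def exponential(cls, mean: float) -> "ServiceSpec":
        return cls("exponential", (float(mean),), float(mean))

    @classmethod
    def deterministic(cls, value: float) -> "ServiceSpec":
        return cls("deterministic", (float(value),), float(value))

    @classmethod
    def uniform(cls, low: float, high: float) -> "ServiceSpec":
        if not 0 <= low <= high:
            raise NetworkValidationError("uniform support must satisfy 0 <= low <= high")
        return cls("uniform", (float(low), float(high)), (low + high) / 2.0)

    @classmethod
    def lognormal(cls, mean: float, sigma_log: float) -> "ServiceSpec":
        """Lognormal with the given (linear-scale) mean and log-scale sd."""
        mu_log = math.log(mean) - 0.5 * sigma_log**2
        return cls("lognormal", (mu_log, float(sigma_log)), float(mean))

    @classmethod
    def from_log_params(cls, mu_log: float, sigma_log: float) -> "ServiceSpec":
        mean = math.exp(mu_log + 0.5 * sigma_log**2)
        return cls("lognormal", (float(mu_log), float(sigma_log)), mean)

    @classmethod
    def empirical(cls, samples: Sequence[float]) -> "ServiceSpec":
        """Empirical distribution of observed durations; mean = sample mean.

        The non-parametric analogue of the routing/means estimators: no
        family is assumed, the sample mean is the only quantity the
        equilibrium analysis consumes.
        """
        arr = tuple(float(s) for s in samples)
        if not arr or any(s < 0 or not math.isfinite(s) for s in arr):
            raise NetworkValidationError("empirical samples must be finite and >= 0")
        return cls("empirical", arr, sum(arr) / len(arr))

    @classmethod
    def mixture(cls, weights: Sequence[float], components: Sequence["ServiceSpec"]) -> "ServiceSpec":
        w = tuple(float(x) for x in weights)
        if len(w) != len(components) or not components:
            raise NetworkValidationError("mixture needs matching weights and components")
        if any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, rel_tol=1e-12):
            raise NetworkValidationError("mixture weights must be >= 0 and sum to 1")
        mean = sum(wi * c.mean for wi, c in zip(w, components))
        return cls("mixture", (w, tuple(components)), mean)

    # -- behaviour ----------------------------------------------------

    def _analytic_mean(self) -> float | None:
        if self.family == "exponential" or self.family == "deterministic":
            return self.params[0]
        if self.family == "uniform":
            return (self.params[0] + self.params[1]) / 2.0
        if self.family == "lognormal":
            mu_log, sigma_log = self.params
            return math.exp(mu_log + 0.5 * sigma_log**2)
        return None  # empirical / mixture store their mean directly

    def with_mean(self, mean: float) -> "ServiceSpec":
        """Same family/shape rescaled to a new mean (scale families only)."""
        scale = mean / self.mean
        if self.family == "exponential":
            return ServiceSpec.exponential(mean)
        if self.family == "deterministic":
            return ServiceSpec.deterministic(mean)
        if self.family == "uniform":
            lo, hi = self.params
            return ServiceSpec.uniform(lo * scale, hi * scale)
        if self.family == "lognormal":
            return ServiceSpec.lognormal(mean, self.params[1])
        if self.family == "empirical":
            return ServiceSpec.empirical(tuple(s * scale for s in self.params))
        raise NetworkValidationError(f"cannot rescale family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` service times (months)."""
        if self.family == "exponential":
            return rng.exponential(self.params[0], size)
        if self.family == "deterministic":
            return np.full(size, self.params[0])
        if self.family == "uniform":
            return rng.uniform(self.params[0], self.params[1], size)
        if self.family == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], size)
        if self.family == "empirical":
            return rng.choice(np.asarray(self.params), size=size, replace=True)
        # mixture
        weights, components = self.params
        idx = rng.choice(len(components), size=size, p=np.asarray(weights))
        out = np.empty(size)
        for k, comp in enumerate(components):
            mask = idx == k
            n = int(mask.sum())
            if n:
                out[mask] = comp.sample(rng, n)
        return out


@dataclass(frozen=True)
class RoutingMatrix:
    """J x J matrix of inter-queue routing probabilities."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise NetworkValidationError("routing matrix must be square")
        object.__setattr__(self, "entries", arr)

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    def violations(self) -> list[str]:
        """All structural problems; empty list means valid."""
        out: list[str] = []
        R = self.entries
        if np.any(~np.isfinite(R)):
            out.append("routing entries must be finite")
            return out
        bad = np.argwhere((R < 0) | (R > 1))
        for i, j in bad:
            out.append(f"queue {i}: entry r[{i},{j}]={R[i, j]:g} outside [0, 1]")
        sums = R.sum(axis=1)
        for i in np.nonzero(sums > 1 + 1e-12)[0]:
            out.append(f"queue {int(i)}: row sum > 1 ({sums[i]:g})")
        if not out:
            I = np.eye(self.size)
            try:
                inv = np.linalg.inv(I - R)
            except np.linalg.LinAlgError:
                out.append("no exit path / (I - R) singular")
            else:
                if (
                    np.max(np.abs((I - R) @ inv - I)) > _EXIT_TOL * max(1.0, np.abs(inv).max())
                    or np.min(inv) < -_EXIT_TOL
                ):
                    out.append("no exit path / (I - R) singular")
        return out


@dataclass(frozen=True)
class QueueNetwork:
    """An open infinite-server queuing network.

    ``exogenous_rates`` are Poisson arrival rates per month; ``services``
    give each queue's service-time law; ``labels`` are display names.
    """

    routing: RoutingMatrix
    exogenous_rates: np.ndarray
    services: tuple[ServiceSpec, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        eta = np.asarray(self.exogenous_rates, dtype=float).ravel()
        object.__setattr__(self, "exogenous_rates", eta)
        object.__setattr__(self, "services", tuple(self.services))
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"queue {i + 1}" for i in range(len(eta)))
            )
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_queues(self) -> int:
        return self.routing.size

    @property
    def service_means(self) -> np.ndarray:
        return np.array([s.mean for s in self.services])


def validate_network(net: QueueNetwork) -> list[str]:
    """Enumerate every violated invariant of ``net``; empty means valid.

    Validation reports rather than raises, so a caller can display all
    problems of a hand-written network file at once.
    """
    report = list(net.routing.violations())
    J = net.routing.size
    eta = net.exogenous_rates
    if len(eta) != J:
        report.append(f"exogenous_rates length {len(eta)} != J={J}")
    if len(net.services) != J:
        report.append(f"services length {len(net.services)} != J={J}")
    if np.any(~np.isfinite(eta)):
        report.append("exogenous rates must be finite")
    for i in np.nonzero(eta < 0)[0]:
        report.append(f"queue {int(i)}: exogenous rate {eta[i]:g} < 0")
    if np.all(eta <= 0):
        report.append("at least one exogenous rate must be positive")
    return report


def require_valid(net: QueueNetwork) -> None:
    report = validate_network(net)
    if report:
        raise NetworkValidationError("; ".join(report))


def exit_probabilities(routing: RoutingMatrix) -> np.ndarray:
    """Per-queue probability ``r_i0`` of leaving the network on departure."""
    bad = routing.violations()
    if bad:
        raise NetworkValidationError("; ".join(bad))
    return 1.0 - routing.entries.sum(axis=1)
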