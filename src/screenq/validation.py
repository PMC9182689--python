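"""End-to-end validation experiments.

Each function runs one of the package's standard self-checks — the
experiments that confront the exact product-form predictions with the
discrete-event simulator, the estimators with synthetic ground truth,
and the test statistics with their nominal error rates — and returns
plain numbers.  They are used by the test suite and by the
reproduction script.

Problem sizes are chosen so Monte-Carlo noise sits well inside each
check's tolerance on a single CPU: the stationary-marginal comparison
uses ~3x10^4 decorrelated occupancy samples per service family (the
total-variation noise floor for a Poisson(60) marginal is ~2.5/sqrt(m),
so smaller designs could not resolve a 0.02 band), and the Little's-law
check uses 3x10^5 agents (~3 standard errors inside its 1% band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .des import empirical_stationary, simulate_network
from .estimation import estimate_components
from .gof import ks_poisson_counts, ks_queue_length
from .network import QueueNetwork, RoutingMatrix, ServiceSpec
from .screening import ScreeningScenario, lifetime_gain
from .stationary import solve_traffic
from .synth import default_spec, generate_registry

__all__ = [
    "two_queue_reference_network",
    "screening_reference_network",
    "product_form_experiment",
    "littles_law_experiment",
    "recovery_experiment",
    "gof_type1_experiment",
    "gain_surface_experiment",
]


def two_queue_reference_network(family: str = "lognormal") -> QueueNetwork:
    """Diagnosis -> surgery tandem: 120 cases/yr, r12 = 0.4, means 6 / 12 mo."""
    makers = {
        "exponential": ServiceSpec.exponential,
        "deterministic": ServiceSpec.deterministic,
        "lognormal": lambda m: ServiceSpec.lognormal(m, 1.0),
    }
    make = makers[family]
    return QueueNetwork(
        routing=RoutingMatrix(np.array([[0.0, 0.4], [0.0, 0.0]])),
        exogenous_rates=np.array([120.0 / 12.0, 0.0]),
        services=(make(6.0), make(12.0)),
        labels=("diagnosed, awaiting surgery", "post-surgery"),
    )


def screening_reference_network() -> QueueNetwork:
    """Three-state screening model: 2y preclinical, 30% early-treated
    surviving 20y, 60% progressing with 1y survival, 10% undiagnosed
    death.  Mean sojourn is exactly 8.6 years."""
    R = np.array([[0.0, 0.3, 0.6], [0.0] * 3, [0.0] * 3])
    return QueueNetwork(
        routing=RoutingMatrix(R),
        exogenous_rates=np.array([10.0, 0.0, 0.0]),
        services=(
            ServiceSpec.exponential(24.0),
            ServiceSpec.exponential(240.0),
            ServiceSpec.exponential(12.0),
        ),
        labels=("undetected early disease", "early treatment", "late-stage disease"),
    )


@dataclass(frozen=True)
class ProductFormResult:
    family: str
    tv_distances: tuple  # per queue
    ks_p_values: tuple  # per queue, simulated null
    n_samples: int


def _tv_distance(pmf: np.ndarray, rho: float) -> float:
    k = np.arange(len(pmf))
    ref = stats.poisson.pmf(k, rho)
    return 0.5 * (np.abs(pmf - ref).sum() + (1.0 - ref.sum()))


def product_form_experiment(
    family: str,
    seed: int,
    n_samples: int = 30_000,
    spacing: float = 15.0,
    n_null: int = 500,
) -> ProductFormResult:
    """Empirical stationary marginals vs the predicted Poisson(rho_j).

    Simulates the two-queue reference model with every service drawn
    from ``family``, samples occupancy every ``spacing`` months after a
    60-month burn-in, and reports per-queue total-variation distances
    and simulated-null KS p-values against the product-form marginals.
    """
    net = two_queue_reference_network(family)
    burn_in = 60.0
    horizon = burn_in + n_samples * spacing
    sim = simulate_network(net, horizon, seed)
    emp = empirical_stationary(sim, burn_in=burn_in, spacing=spacing)
    sol = solve_traffic(net)
    tvs, ps = [], []
    rng = np.random.default_rng(seed + 1)
    for j in range(net.n_queues):
        tvs.append(float(_tv_distance(emp.pmfs[j], sol.loads[j])))
        res = ks_queue_length(
            emp.counts[j], sol.loads[j], n_null=n_null, seed=int(rng.integers(2**31))
        )
        ps.append(res.p_value)
    return ProductFormResult(
        family=family,
        tv_distances=tuple(tvs),
        ks_p_values=tuple(ps),
        n_samples=emp.n_samples,
    )


def littles_law_experiment(seed: int, n_agents: int = 300_000) -> dict:
    """Mean simulated sojourn vs (1/eta) sum_j rho_j on the screening net."""
    net = screening_reference_network()
    eta = float(net.exogenous_rates.sum())
    horizon = n_agents / eta
    sim = simulate_network(net, horizon, seed)
    sol = solve_traffic(net)
    exact = float(sol.loads.sum() / eta)
    simulated = float(sim.sojourns.mean())
    return {
        "exact_months": exact,
        "simulated_months": simulated,
        "rel_error": abs(simulated - exact) / exact,
        "n_agents": sim.n_agents,
    }


def recovery_experiment(seeds) -> dict:
    """Relative errors of (eta1, f, mean treated survival) vs synthetic truth."""
    errors = []
    for seed in seeds:
        spec = default_spec(seed=int(seed))
        registry, _ = generate_registry(spec)
        truth = spec.subgroups[0]
        comp = estimate_components(registry, truth.key)
        errors.append(
            [
                abs(comp.diagnosis_rate - truth.diagnosis_rate) / truth.diagnosis_rate,
                abs(comp.treated_fraction - truth.treated_fraction)
                / truth.treated_fraction,
                abs(comp.mean_treated_survival - truth.treated_survival.mean)
                / truth.treated_survival.mean,
            ]
        )
    errors = np.asarray(errors)
    return {
        "median_rel_error": float(np.median(errors)),
        "max_rel_error": float(errors.max()),
        "per_quantity_median": np.median(errors, axis=0).tolist(),
        "n_seeds": len(errors),
    }


def gof_type1_experiment(
    seed: int,
    rate: float = 200.0,
    n_years: int = 17,
    n_replicates: int = 500,
    n_null: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the arrival-Poissonness test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        counts = rng.poisson(rate, n_years)
        res = ks_poisson_counts(
            counts, n_null=n_null, seed=int(rng.integers(2**31))
        )
        rejections += res.p_value < alpha
    return {
        "type1_error": rejections / n_replicates,
        "n_replicates": n_replicates,
    }


def gain_surface_experiment(params, grid_size: int = 5) -> dict:
    """Gain over a detection x effectiveness grid; monotonicity + linearity."""
    grid = np.linspace(0.05, 1.0, grid_size)
    gains = np.array(
        [
            [
                lifetime_gain(
                    params, ScreeningScenario(detection_prob=d, effectiveness=e)
                )
                for e in grid
            ]
            for d in grid
        ]
    )
    monotone = bool(
        np.all(np.diff(gains, axis=0) >= -1e-12)
        and np.all(np.diff(gains, axis=1) >= -1e-12)
    )
    curvature = float(np.abs(np.diff(gains, n=2, axis=1)).max())
    return {"gains": gains, "monotone": monotone, "max_curvature_in_e": curvature}
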