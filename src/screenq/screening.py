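"""Screening and no-screening network constructors and benefit measures.

Each population subgroup gets a three-state network: undetected
early-stage disease (queue 1), screen-detected early treatment (queue
2), and late-stage symptomatic disease (queue 3).  New preclinical
cases arise at Poisson rate ``eta_1``; on leaving the early state a
case dies undiagnosed (``r10``), is caught by the screen and treated
early (``r12`` scaled by the screen's detection probability ``d``), or
progresses to the symptomatic stage (the remainder).  Early-treated
patients survive ``e * L`` on average — a fraction ``e`` (the screen's
"effectiveness") of the subgroup's conditional residual life
expectancy ``L``.  The no-screening counterfactual reroutes the
screen-detectable mass to progression, and the difference in mean
network sojourn (Little's law) is the expected residual-lifetime gain.

Times are months internally; gains are reported in years and per-screen
benefits in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import NetworkValidationError, QueueNetwork, RoutingMatrix, ServiceSpec
from .stationary import expected_sojourn, solve_traffic

__all__ = [
    "SubgroupKey",
    "SubgroupParams",
    "ScreeningScenario",
    "build_screening_network",
    "build_no_screening_network",
    "lifetime_gain",
    "per_screen_benefit",
    "apply_morbidity",
    "apply_mortality",
    "net_benefit_with_specificity",
]

MONTHS_PER_YEAR = 12.0
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True, order=True)
class SubgroupKey:
    """Population subgroup identified by clinically relevant covariates."""

    cancer_type: str
    sex: str
    ancestry: str
    age_band: str  # 5-year band label, e.g. "50-54"

    def __str__(self) -> str:
        return f"{self.cancer_type}/{self.sex}/{self.ancestry}/{self.age_band}"


@dataclass(frozen=True)
class SubgroupParams:
    """Estimated disease parameters for one subgroup.

    diagnosis_rate:
        New cases per *year* (eta_1).
    mean_early_sojourn:
        Mean months from disease initiation to leaving the preclinical
        state (1/mu_1).
    death_frac / screen_frac / progress_frac:
        Routing fractions r10 / r12 / r13 out of the early state; must
        sum to one.  ``screen_frac`` is the fraction detectable by a
        perfect screen.
    mean_late_survival:
        Mean months survived after symptomatic presentation (1/mu_3).
    treated_fraction:
        Fraction of symptomatic patients who start treatment before
        dying.
    mean_diag_to_treatment:
        Months between diagnosis and treatment initiation (tunable; not
        estimable from registry extracts).
    cond_life_expectancy:
        Residual life expectancy L in *years*, conditional on having
        reached the subgroup's age band.
    """

    diagnosis_rate: float
    mean_early_sojourn: float
    death_frac: float
    screen_frac: float
    progress_frac: float
    mean_late_survival: float
    treated_fraction: float
    mean_diag_to_treatment: float
    cond_life_expectancy: float
    key: SubgroupKey | None = None

    def __post_init__(self) -> None:
        r_sum = self.death_frac + self.screen_frac + self.progress_frac
        if abs(r_sum - 1.0) > 1e-12:
            raise ValueError(f"routing fractions sum to {r_sum}, expected 1")
        if min(self.death_frac, self.screen_frac, self.progress_frac) < 0:
            raise ValueError("routing fractions must be >= 0")
        if self.diagnosis_rate <= 0 or self.mean_early_sojourn <= 0:
            raise ValueError("diagnosis rate and early sojourn must be > 0")
        if self.mean_late_survival <= 0 or self.cond_life_expectancy <= 0:
            raise ValueError("survival means and life expectancy must be > 0")
        if not 0 <= self.treated_fraction <= 1:
            raise ValueError("treated_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ScreeningScenario:
    """Knobs of a hypothetical screening program.

    detection_prob:
        Probability ``d`` that a screen-detectable case is actually
        caught during its preclinical window.
    effectiveness:
        Fraction ``e`` of the conditional residual life expectancy
        attained on average by early-detected patients.
    qaly_factor:
        Quality-of-life weight in [0, 1] applied to treatment-affected
        survival time (1 = no morbidity).
    mortality_prob / mortality_survival:
        With probability ``p`` early treatment itself is fatal after
        ``mortality_survival`` months (default: point mass at one
        month).
    false_positive_rate / confirmatory_specificity / fp_survival_reduction:
        Specificity extension: a healthy screenee false-positives with
        the given rate, a confirmatory test removes a fraction
        ``confirmatory_specificity`` of those, and each treated false
        positive loses ``fp_survival_reduction * L`` years.
    """

    detection_prob: float
    effectiveness: float
    qaly_factor: float = 1.0
    mortality_prob: float = 0.0
    mortality_survival: float = 1.0  # months
    false_positive_rate: float = 0.0
    confirmatory_specificity: float = 0.9
    fp_survival_reduction: float = 0.0
    screens_per_person_year: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "detection_prob",
            "effectiveness",
            "qaly_factor",
            "mortality_prob",
            "false_positive_rate",
            "confirmatory_specificity",
            "fp_survival_reduction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mortality_survival <= 0:
            raise ValueError("mortality_survival must be > 0 months")
        if self.screens_per_person_year < 0:
            raise ValueError("screens_per_person_year must be >= 0")


def _early_treatment_service(params: SubgroupParams, scenario: ScreeningScenario) -> ServiceSpec:
    mean_months = scenario.effectiveness * params.cond_life_expectancy * MONTHS_PER_YEAR
    if mean_months <= 0:
        raise NetworkValidationError(
            "degenerate early-treatment survival: effectiveness * life expectancy is zero"
        )
    base = ServiceSpec.exponential(mean_months)
    if scenario.mortality_prob > 0:
        base = apply_mortality(
            base,
            scenario.mortality_prob,
            ServiceSpec.deterministic(scenario.mortality_survival),
        )
    return base


def build_screening_network(
    params: SubgroupParams, scenario: ScreeningScenario
) -> QueueNetwork:
    """Three-queue network of a subgroup under a screening program.

    Routing out of the early state: exit (death) with r10, early
    treatment with ``r12 * d``, progression with ``r13 + r12 * (1-d)``.
    """
    d = scenario.detection_prob
    r12_eff = params.screen_frac * d
    r13_eff = params.progress_frac + params.screen_frac * (1.0 - d)
    if r12_eff > 0:
        early_service = _early_treatment_service(params, scenario)
    else:
        # queue never visited; any positive mean keeps the spec valid
        early_service = _early_treatment_service(
            params, replace(scenario, effectiveness=max(scenario.effectiveness, 1e-9))
        )
    R = RoutingMatrix(
        np.array(
            [
                [0.0, r12_eff, r13_eff],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
    )
    eta = np.array([params.diagnosis_rate / MONTHS_PER_YEAR, 0.0, 0.0])
    services = (
        ServiceSpec.exponential(params.mean_early_sojourn),
        early_service,
        ServiceSpec.exponential(params.mean_late_survival),
    )
    return QueueNetwork(
        routing=R,
        exogenous_rates=eta,
        services=services,
        labels=("undetected early disease", "early treatment", "late-stage disease"),
    )


def build_no_screening_network(params: SubgroupParams) -> QueueNetwork:
    """Counterfactual without screening: detectable mass progresses.

    Identical to the screening network at detection probability zero —
    screen-detectable cases present symptomatically instead, so the
    early-treatment queue has no inflow.
    """
    scenario = ScreeningScenario(detection_prob=0.0, effectiveness=1.0)
    return build_screening_network(params, scenario)


def lifetime_gain(
    params: SubgroupParams,
    scenario: ScreeningScenario,
    per_detected: bool = False,
) -> float:
    """Expected residual-lifetime gain of screening, in years.

    The difference in mean network sojourn between the screening and
    no-screening networks.  With ``per_detected=True`` the gain is
    conditioned on being routed through early treatment (gain per
    positive case detected) rather than averaged over all cancer
    patients.
    """
    with_screen = expected_sojourn(build_screening_network(params, scenario))
    without = expected_sojourn(build_no_screening_network(params))
    gain_years = (with_screen - without) / MONTHS_PER_YEAR
    if per_detected:
        frac = params.screen_frac * scenario.detection_prob
        if frac == 0:
            return 0.0
        gain_years /= frac
    return gain_years


def per_screen_benefit(
    gain_years: float,
    params: SubgroupParams,
    population_size: int,
    screens_per_person_year: float = 1.0,
) -> float:
    """Benefit in *days* per screen administered.

    A screen of a random member of the subgroup finds an undetected
    early case with probability ``rho_1 / population_size`` where
    ``rho_1 = eta_1 * E(early sojourn)`` is the standing pool of
    undetected early disease.  ``screens_per_person_year`` is accepted
    for interface symmetry but cancels from the per-screen figure.
    """
    del screens_per_person_year
    if population_size <= 0:
        raise ValueError("population_size must be > 0")
    pool = params.diagnosis_rate * (params.mean_early_sojourn / MONTHS_PER_YEAR)
    return gain_years * DAYS_PER_YEAR * pool / population_size


def apply_morbidity(
    sojourn_years: float, qaly_factor: float, affected_fraction: float = 1.0
) -> float:
    """Quality-adjust a survival period for treatment morbidity.

    The affected fraction of the period is weighted by the QALY factor,
    the remainder passes through unweighted (temporary side effects
    reweight only the period in which they occur).
    """
    if not 0.0 <= qaly_factor <= 1.0:
        raise ValueError("qaly_factor must be in [0, 1]")
    if not 0.0 <= affected_fraction <= 1.0:
        raise ValueError("affected_fraction must be in [0, 1]")
    affected = sojourn_years * affected_fraction
    return affected * qaly_factor + (sojourn_years - affected)


def apply_mortality(
    service: ServiceSpec,
    p: float,
    early_death: ServiceSpec | None = None,
) -> ServiceSpec:
    """Mix a premature-death component into a service distribution.

    With probability ``p`` treatment is fatal and survival follows
    ``early_death`` (default: point mass at one month); with
    probability ``1 - p`` the original distribution applies.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mortality probability must be in [0, 1]")
    if p == 0.0:
        return service
    if early_death is None:
        early_death = ServiceSpec.deterministic(1.0)
    if p == 1.0:
        return early_death
    return ServiceSpec.mixture((p, 1.0 - p), (early_death, service))


def net_benefit_with_specificity(
    params: SubgroupParams,
    scenario: ScreeningScenario,
    healthy_population: int,
) -> float:
    """Net life-years gained per cohort-year once false positives count.

    The screening network is extended with a false-positive treatment
    queue fed by healthy screenees who fail both the screen and the
    confirmatory test.  Each treated false positive loses
    ``fp_survival_reduction * L`` years; the return value is
    true-positive gains minus those losses, per year of running the
    program, and can be negative when overtreatment dominates.
    """
    if healthy_population < 0:
        raise ValueError("healthy_population must be >= 0")
    gross = params.diagnosis_rate * lifetime_gain(params, scenario)
    fp_per_year = (
        healthy_population
        * scenario.screens_per_person_year
        * scenario.false_positive_rate
        * (1.0 - scenario.confirmatory_specificity)
    )
    loss_per_fp = scenario.fp_survival_reduction * params.cond_life_expectancy
    return gross - fp_per_year * loss_per_fp
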