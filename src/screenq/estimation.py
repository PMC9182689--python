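"""Parameter estimation from registry-style incidence/survival tables.

The equilibrium analysis makes no parametric assumptions about waiting
times, so there is no likelihood to maximize: rates are estimated by
empirical yearly averages, routing probabilities by empirical
proportions, and survival means by sample means after right-censoring
imputation.  Patients alive at the study cutoff carry only a lower
bound on survival; their times are imputed from the conditional
empirical survival distribution of observed deaths (a censored time
``t`` becomes the mean of deaths exceeding ``t``).

Subgroups with fewer than 100 records are excluded: empirical means on
smaller samples are too unstable to rank screening benefits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screening import SubgroupKey, SubgroupParams

__all__ = [
    "REGISTRY_COLUMNS",
    "LIFE_TABLE_COLUMNS",
    "AGE_BANDS_5YR",
    "LIFE_TABLE_BANDS",
    "EstimationConfig",
    "SubgroupComponents",
    "SubgroupExclusionError",
    "age_to_band",
    "age_to_life_band",
    "impute_censored",
    "conditional_life_expectancy",
    "estimate_components",
    "estimate_subgroup_params",
]

log = logging.getLogger(__name__)

REGISTRY_COLUMNS = [
    "patient_id",
    "cancer_type",
    "sex",
    "ancestry",
    "age_at_diagnosis",
    "diagnosis_year",
    "treated",
    "months_to_treatment",
    "survival_months",
    "vital_status",
]

LIFE_TABLE_COLUMNS = ["ancestry", "sex", "age_band", "expectancy_years"]

#: 5-year diagnosis-age bands, 25 through 84
AGE_BANDS_5YR = [f"{lo}-{lo + 4}" for lo in range(25, 85, 5)]

#: coarse life-table bands (conditional residual life expectancy)
LIFE_TABLE_BANDS = ["<=64", "65-74", "75+"]


class SubgroupExclusionError(ValueError):
    """Subgroup below the minimum sample size for reliable estimates."""


@dataclass(frozen=True)
class EstimationConfig:
    """Tunables of the estimation pipeline.

    ``mean_diag_to_treatment`` (months) is not estimable from registry
    extracts — it varies by institution — and is therefore a tunable.
    ``mean_early_sojourn`` (months) is the preclinical window from
    disease initiation to leaving the early state; registries anchored
    at diagnosis cannot estimate it, and the default reflects the long
    genetic-progression period of pancreatic-like disease (15 years).
    ``death_frac`` is the fraction dying before any possible diagnosis
    (left uncorrected by default; the effect is small outside the very
    oldest bands).
    """

    study_window: tuple[int, int] = (2000, 2016)
    min_subgroup_size: int = 100
    mean_diag_to_treatment: float = 1.0  # months
    mean_early_sojourn: float = 180.0  # months
    death_frac: float = 0.0
    screen_frac: float | None = None  # default: 1 - death_frac

    @property
    def n_years(self) -> int:
        return self.study_window[1] - self.study_window[0] + 1


@dataclass(frozen=True)
class SubgroupComponents:
    """Raw empirical estimates for one subgroup, before model assembly."""

    key: SubgroupKey
    n_records: int
    diagnosis_rate: float  # cases / year
    treated_fraction: float
    mean_treated_survival: float  # months from treatment start
    mean_untreated_survival: float  # months from diagnosis
    yearly_counts: np.ndarray  # diagnoses per calendar year of the window


def age_to_band(age: float) -> str:
    """5-year diagnosis-age band label for ``age`` in [25, 85)."""
    lo = int(age // 5) * 5
    if lo < 25 or lo > 80:
        raise ValueError(f"age {age} outside the modeled range 25-84")
    return f"{lo}-{lo + 4}"


def age_to_life_band(age: float) -> str:
    """Coarse life-table band containing ``age``."""
    if age < 25:
        raise ValueError(f"age {age} below the modeled range")
    if age <= 64:
        return "<=64"
    if age <= 74:
        return "65-74"
    return "75+"


def impute_censored(survivals) -> np.ndarray:
    """Impute right-censored survival times, in months.

    ``survivals`` is a sequence of ``(months, vital_status)`` pairs with
    status ``"dead"`` or ``"alive"``.  Observed deaths pass through;
    each censored time ``t`` is replaced by ``t + E(s - t | s > t)``
    over observed deaths ``s``, i.e. the mean of deaths exceeding ``t``.
    A censored time at or beyond every observed death has no qualifying
    deaths and passes through unchanged (with a logged warning) — the
    conditional-empirical rule is undefined there and keeping ``t`` is
    the conservative completion.
    """
    pairs = list(survivals)
    times = np.array([float(t) for t, _ in pairs])
    dead = np.array([status == "dead" for _, status in pairs])
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    out = times.copy()
    if dead.all() or not dead.any():
        if not dead.any() and len(pairs):
            log.warning("no observed deaths: censored times left unimputed")
        return out
    deaths = np.sort(times[dead])
    # suffix means: mean of deaths strictly greater than each censored time
    suffix_sum = np.concatenate([np.cumsum(deaths[::-1])[::-1], [0.0]])
    cens_idx = np.nonzero(~dead)[0]
    pos = np.searchsorted(deaths, times[cens_idx], side="right")
    n_above = len(deaths) - pos
    overflow = n_above == 0
    if overflow.any():
        log.warning(
            "%d censored time(s) exceed every observed death; left unimputed",
            int(overflow.sum()),
        )
    safe = ~overflow
    idx = cens_idx[safe]
    out[idx] = suffix_sum[pos[safe]] / n_above[safe]
    return out


def conditional_life_expectancy(
    life_table: pd.DataFrame, ancestry: str, sex: str, age: float
) -> float:
    """Residual life expectancy (years) given survival to ``age``.

    Piecewise-constant lookup over the coarse bands; the discontinuity
    at age 65 is a known artifact of the banding.
    """
    band = age_to_life_band(age)
    rows = life_table[
        (life_table["ancestry"] == ancestry)
        & (life_table["sex"] == sex)
        & (life_table["age_band"] == band)
    ]
    if rows.empty:
        raise KeyError(f"life table has no entry for ({ancestry}, {sex}, {band})")
    return float(rows["expectancy_years"].iloc[0])


def _subgroup_mask(registry: pd.DataFrame, key: SubgroupKey) -> pd.Series:
    bands = registry["age_at_diagnosis"].map(age_to_band)
    return (
        (registry["cancer_type"] == key.cancer_type)
        & (registry["sex"] == key.sex)
        & (registry["ancestry"] == key.ancestry)
        & (bands == key.age_band)
    )


def estimate_components(
    registry: pd.DataFrame, key: SubgroupKey, config: EstimationConfig | None = None
) -> SubgroupComponents:
    """Empirical rate/fraction/mean estimates for one subgroup.

    Deterministic given the registry and invariant to record order.
    Raises :class:`SubgroupExclusionError` below the minimum sample
    size.
    """
    config = config or EstimationConfig()
    sub = registry.loc[_subgroup_mask(registry, key)]
    n = len(sub)
    if n < config.min_subgroup_size:
        raise SubgroupExclusionError(
            f"excluded: insufficient sample for {key} "
            f"({n} < {config.min_subgroup_size})"
        )
    y0, y1 = config.study_window
    years = np.arange(y0, y1 + 1)
    counts = (
        sub["diagnosis_year"].value_counts().reindex(years, fill_value=0).to_numpy()
    )
    eta1 = counts.mean()

    by_year = sub.groupby("diagnosis_year")["treated"].mean()
    treated_fraction = float(by_year.mean())  # unweighted mean of per-year fractions

    treated = sub[sub["treated"]]
    if len(treated):
        imputed = impute_censored(
            list(zip(treated["survival_months"], treated["vital_status"]))
        )
        from_treatment = np.clip(
            imputed - treated["months_to_treatment"].to_numpy(float), 0.0, None
        )
        mean_treated = float(from_treatment.mean())
    else:
        mean_treated = float("nan")

    untreated = sub[~sub["treated"].astype(bool)]
    if len(untreated):
        imputed_u = impute_censored(
            list(zip(untreated["survival_months"], untreated["vital_status"]))
        )
        mean_untreated = float(imputed_u.mean())
    else:
        mean_untreated = float("nan")

    if key.age_band.split("-")[0] >= "75":
        log.warning(
            "subgroup %s: incidence may be underestimated by deaths before "
            "diagnosis in the oldest bands (not corrected)",
            key,
        )
    return SubgroupComponents(
        key=key,
        n_records=n,
        diagnosis_rate=float(eta1),
        treated_fraction=treated_fraction,
        mean_treated_survival=mean_treated,
        mean_untreated_survival=mean_untreated,
        yearly_counts=counts,
    )


def estimate_subgroup_params(
    registry: pd.DataFrame,
    key: SubgroupKey,
    life_table: pd.DataFrame,
    config: EstimationConfig | None = None,
) -> SubgroupParams:
    """Assemble :class:`SubgroupParams` for one subgroup.

    The late-stage mean survival (time from symptomatic presentation to
    death) composes the estimated pieces: treated patients wait the
    tunable diagnosis-to-treatment time then survive the treated mean,
    untreated patients survive the untreated mean, weighted by the
    treated fraction.  The conditional life expectancy is looked up at
    the midpoint of the subgroup's 5-year age band.
    """
    config = config or EstimationConfig()
    comp = estimate_components(registry, key, config)
    f = comp.treated_fraction
    w = config.mean_diag_to_treatment
    treated_part = 0.0 if np.isnan(comp.mean_treated_survival) else (
        w + comp.mean_treated_survival
    )
    untreated_part = 0.0 if np.isnan(comp.mean_untreated_survival) else (
        comp.mean_untreated_survival
    )
    mean_late = f * treated_part + (1.0 - f) * untreated_part
    if mean_late <= 0:
        mean_late = w  # degenerate subgroup: only instantaneous deaths observed

    lo, hi = (int(x) for x in key.age_band.split("-"))
    midpoint_age = (lo + hi) / 2.0
    L = conditional_life_expectancy(life_table, key.ancestry, key.sex, midpoint_age)

    r10 = config.death_frac
    r12 = (1.0 - r10) if config.screen_frac is None else config.screen_frac
    r13 = 1.0 - r10 - r12
    if r13 < 0:
        raise ValueError("death_frac + screen_frac exceed 1")
    return SubgroupParams(
        diagnosis_rate=comp.diagnosis_rate,
        mean_early_sojourn=config.mean_early_sojourn,
        death_frac=r10,
        screen_frac=r12,
        progress_frac=r13,
        mean_late_survival=mean_late,
        treated_fraction=f,
        mean_diag_to_treatment=w,
        cond_life_expectancy=L,
        key=key,
    )
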