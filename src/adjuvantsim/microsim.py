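"""Monthly-cycle microsimulation of post-lobectomy treatment outcomes.

Each simulated patient enters at the midpoint of their age category, just
after lobectomy, and transitions through monthly cycles until death from
lung cancer, death from other causes, or the month they turn 100.  Each
survived cycle accrues one month of survival weighted by a quality-of-life
utility determined by comorbidities and (decaying) treatment complications.

Treatment mechanics:

* the adjuvant-chemotherapy arm multiplies the monthly lung-cancer death
  probability by the treatment hazard ratio (0.83 at base case), uniformly
  for all profiles;
* during the first six cycles the chemotherapy arm's other-cause death
  probability is multiplied by the early-toxicity hazard ratio (2.41 at
  base case), after which it returns to background;
* complications are drawn once per type at treatment start and affect
  quality of life only (their mortality impact is carried by the toxicity
  hazard ratio); the utility decrement of 0.35 recovers linearly to zero
  over six months.

Random draws are made for every patient every cycle whether or not they are
still alive, so two arms simulated from the same seed consume identical
uniform streams (common random numbers): with all effect parameters at 1.0
the arms produce identical life histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import defaults
from .cohort import COMPLICATIONS, ChfLevel, CovariateVector, Stage
from .complications import ComplicationParams, complication_probabilities
from .survival import MonthlyRates

__all__ = ["ModelParams", "LifeHistory", "ArmOutcome", "CohortArrays",
           "monthly_utility", "simulate_patient", "simulate_cohort", "run_arm"]

ARMS = ("chemo", "observation")


@dataclass
class ModelParams:
    """All simulation inputs: hazards, effect sizes, disutilities, horizon."""

    treatment_hr_nsclc: float = defaults.TREATMENT_HR_NSCLC
    treatment_hr_nsclc_ci: tuple[float, float] = defaults.TREATMENT_HR_NSCLC_CI
    early_toxicity_hr: float = defaults.EARLY_TOXICITY_HR
    early_toxicity_hr_ci: tuple[float, float] = defaults.EARLY_TOXICITY_HR_CI
    toxicity_window_months: int = defaults.TOXICITY_WINDOW_MONTHS
    disutility_cad: float = defaults.DISUTILITY_CAD
    disutility_copd: float = defaults.DISUTILITY_COPD
    disutility_chf: float = defaults.DISUTILITY_CHF
    complication_disutility: float = defaults.COMPLICATION_DISUTILITY
    complication_recovery_months: int = defaults.COMPLICATION_RECOVERY_MONTHS
    baseline_utility: float = defaults.DEFAULT_BASELINE_UTILITY
    horizon_age_years: float = defaults.HORIZON_AGE_YEARS
    qaly_threshold: float = defaults.QALY_THRESHOLD
    discount_rate_annual: float = 0.0
    #: "multiplicative": p*HR capped at 1; "exact": 1-(1-p)**HR.
    hazard_scaling: str = "multiplicative"
    complications_enabled: bool = True
    complication_params: ComplicationParams = field(default_factory=ComplicationParams)
    #: Baseline monthly lung-cancer death probability by stage (observation).
    base_monthly_p_nsclc: dict[str, float] = field(
        default_factory=lambda: dict(defaults.BASE_MONTHLY_P_NSCLC))
    #: Reference-profile monthly other-cause death probability and its annual
    #: exponential growth with attained age.
    base_monthly_p_other: float = defaults.BASE_MONTHLY_P_OTHER
    other_cause_annual_growth: float = defaults.OTHER_CAUSE_ANNUAL_GROWTH
    #: Sub-hazard ratios applied to the reference other-cause curve per
    #: covariate (the registry competing-risks estimates).
    subhazard_ratios_other: dict[str, float] = field(
        default_factory=lambda: dict(defaults.SUBHAZARD_RATIOS_OTHER))
    #: Optional explicit per-stratum rates keyed by ``CovariateVector.label()``;
    #: overrides the reference-curve mechanism when present.
    monthly_rates_overrides: dict[str, MonthlyRates] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("treatment_hr_nsclc", "early_toxicity_hr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.toxicity_window_months < 0:
            raise ValueError("toxicity_window_months must be >= 0")
        for name in ("disutility_cad", "disutility_copd", "disutility_chf",
                     "complication_disutility"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.baseline_utility <= 1.0:
            raise ValueError("baseline_utility must be in (0, 1]")
        if self.hazard_scaling not in ("multiplicative", "exact"):
            raise ValueError("hazard_scaling must be 'multiplicative' or 'exact'")

    def horizon_months(self, covariates: CovariateVector) -> int:
        return int(round((self.horizon_age_years - covariates.entry_age) * 12))

    def monthly_rates_for(self, covariates: CovariateVector) -> MonthlyRates:
        """Baseline (observation-arm) rates for one profile.

        Default mechanism: a reference other-cause curve (66-69, male, no
        comorbidity) growing exponentially with attained age, scaled by the
        profile's sub-hazard ratios; a constant stage-specific lung-cancer
        hazard.  An explicit per-stratum override takes precedence.
        """
        label = covariates.label()
        horizon = self.horizon_months(covariates)
        if label in self.monthly_rates_overrides:
            return self.monthly_rates_overrides[label].extended(horizon)
        months = np.arange(1, horizon + 1)
        hr = 1.0
        dummies = covariates.dummies()
        for name, ratio in self.subhazard_ratios_other.items():
            hr *= ratio ** dummies.get(name, 0)
        growth = np.exp(self.other_cause_annual_growth * (months - 1) / 12.0)
        p_other = np.clip(self.base_monthly_p_other * hr * growth, 0.0, 0.5)
        p_nsclc = np.full(horizon,
                          self.base_monthly_p_nsclc[covariates.stage.value])
        return MonthlyRates(months, p_nsclc, p_other, stratum=label)

    def scale_probability(self, p: np.ndarray, hr: float) -> np.ndarray:
        if self.hazard_scaling == "exact":
            return 1.0 - (1.0 - p) ** hr
        return np.minimum(p * hr, 1.0)


@dataclass
class LifeHistory:
    """One simulated patient's trajectory."""

    months_survived: int
    death_cause: str  # "nsclc" | "other" | "alive_at_horizon"
    complication_flags: dict[str, bool]
    utilities: np.ndarray  # one weight per survived month
    qalys: float


@dataclass
class CohortArrays:
    """Vectorized outcomes for a simulated cohort (one arm)."""

    months_survived: np.ndarray
    death_cause: np.ndarray  # 0 alive at horizon, 1 nsclc, 2 other
    any_complication: np.ndarray
    qalys: np.ndarray

    @property
    def life_years(self) -> np.ndarray:
        return self.months_survived / 12.0


@dataclass
class ArmOutcome:
    """Aggregated outcomes for one arm."""

    arm: str
    n: int
    mean_qalys: float
    mean_life_years: float
    survival_at_60_months: float
    survival_at_120_months: float
    se_qalys: float
    se_life_years: float


def monthly_utility(covariates: CovariateVector,
                    months_since_complication: int | None,
                    params: ModelParams) -> float:
    """Quality-of-life weight for one cycle.

    Comorbidity disutilities are additive; a complication subtracts
    ``complication_disutility * (1 - m / recovery)`` for m cycles since the
    complication, reaching zero at the recovery horizon.  The result is
    floored at 0 (and capped at 1).
    """
    u = params.baseline_utility
    if covariates.cad:
        u -= params.disutility_cad
    if covariates.copd:
        u -= params.disutility_copd
    if covariates.chf != ChfLevel.NONE:
        u -= params.disutility_chf
    m = months_since_complication
    if m is not None and 0 <= m < params.complication_recovery_months:
        u -= params.complication_disutility * \
            (1.0 - m / params.complication_recovery_months)
    return float(min(max(u, 0.0), 1.0))


def _utility_paths(covariates: CovariateVector, params: ModelParams,
                   horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle utilities with and without a month-1 complication."""
    no_comp = np.array([monthly_utility(covariates, None, params)
                        for _ in range(horizon)])
    with_comp = np.array([monthly_utility(covariates, m - 1, params)
                          for m in range(1, horizon + 1)])
    if params.discount_rate_annual > 0:
        disc = (1.0 + params.discount_rate_annual) \
            ** (-(np.arange(horizon)) / 12.0)
        no_comp = no_comp * disc
        with_comp = with_comp * disc
    return no_comp, with_comp


def simulate_cohort(covariates: CovariateVector, arm: str, n: int,
                    params: ModelParams,
                    rng: np.random.Generator) -> CohortArrays:
    """Simulate ``n`` independent life histories of one profile in one arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if covariates.chf == ChfLevel.SEVERE:
        raise ValueError("severe CHF profiles are not lobectomy candidates "
                         "and cannot be simulated")
    params.validate()

    rates = params.monthly_rates_for(covariates)
    horizon = len(rates.months)
    p1 = rates.p_nsclc.copy()
    p2 = rates.p_other.copy()
    if arm == "chemo":
        p1 = params.scale_probability(p1, params.treatment_hr_nsclc)
        w = min(params.toxicity_window_months, horizon)
        p2 = p2.copy()
        p2[:w] = params.scale_probability(p2[:w], params.early_toxicity_hr)

    # complications: one draw per type at treatment start; uniforms are
    # consumed in both arms (and when complications are disabled) so paired
    # seeds stay synchronized
    u_comp = rng.random((len(COMPLICATIONS), n))
    if params.complications_enabled:
        probs = complication_probabilities(
            covariates, params.complication_params, arm)
        pvec = np.array([probs[c] for c in COMPLICATIONS])
    else:
        pvec = np.zeros(len(COMPLICATIONS))
    comp_flags = u_comp < pvec[:, None]
    any_comp = comp_flags.any(axis=0)

    u_no, u_with = _utility_paths(covariates, params, horizon)

    alive = np.ones(n, dtype=bool)
    cause = np.zeros(n, dtype=np.int8)
    months_survived = np.zeros(n, dtype=np.int32)
    qalys = np.zeros(n)

    for m in range(1, horizon + 1):
        u1 = rng.random(n)
        u2 = rng.random(n)
        die_ns = alive & (u1 < p1[m - 1])
        die_ot = alive & ~die_ns & (u2 < p2[m - 1])
        cause[die_ns] = 1
        cause[die_ot] = 2
        alive = alive & ~die_ns & ~die_ot
        if alive.any():
            months_survived[alive] += 1
            qalys[alive] += np.where(any_comp[alive],
                                     u_with[m - 1], u_no[m - 1]) / 12.0
        elif m < horizon:
            # nobody left alive; still consume the remaining uniforms so the
            # stream position is a function of the horizon only
            rng.random((horizon - m, 2, n))
            break

    return CohortArrays(months_survived=months_survived, death_cause=cause,
                        any_complication=any_comp, qalys=qalys)


def simulate_patient(covariates: CovariateVector, arm: str,
                     params: ModelParams,
                     rng: np.random.Generator) -> LifeHistory:
    """Simulate a single life history (the n=1 case of the cohort engine)."""
    # replicate the cohort path so a patient drawn with the same generator
    # state matches the corresponding cohort entry
    state = rng.bit_generator.state
    arrays = simulate_cohort(covariates, arm, 1, params, rng)
    rng_flags = np.random.default_rng()
    rng_flags.bit_generator.state = state
    u_comp = rng_flags.random((len(COMPLICATIONS), 1))[:, 0]
    if params.complications_enabled:
        probs = complication_probabilities(
            covariates, params.complication_params, arm)
    else:
        probs = {c: 0.0 for c in COMPLICATIONS}
    flags = {c: bool(u_comp[i] < probs[c])
             for i, c in enumerate(COMPLICATIONS)}

    horizon = params.horizon_months(covariates)
    u_no, u_with = _utility_paths(covariates, params, horizon)
    m = int(arrays.months_survived[0])
    utilities = (u_with if arrays.any_complication[0] else u_no)[:m]
    cause = {0: "alive_at_horizon", 1: "nsclc", 2: "other"}[int(arrays.death_cause[0])]
    return LifeHistory(months_survived=m, death_cause=cause,
                       complication_flags=flags, utilities=utilities,
                       qalys=float(arrays.qalys[0]))


def run_arm(covariates: CovariateVector, arm: str, n: int,
            params: ModelParams, seed) -> ArmOutcome:
    """Simulate an arm and aggregate.  ``seed`` may be an int or SeedSequence.

    Running both arms with the same seed pairs them through common random
    numbers.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    arrays = simulate_cohort(covariates, arm, n, params, rng)
    ly = arrays.life_years
    return ArmOutcome(
        arm=arm, n=n,
        mean_qalys=float(arrays.qalys.mean()),
        mean_life_years=float(ly.mean()),
        survival_at_60_months=float((arrays.months_survived >= 60).mean()),
        survival_at_120_months=float((arrays.months_survived >= 120).mean()),
        se_qalys=float(arrays.qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_life_years=float(ly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )
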