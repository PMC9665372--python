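"""Synthetic registry cohorts with known ground-truth effect sizes.

Stands in for the linked cancer-registry/claims extracts the estimation
stages were designed for.  Two cohort types are generated:

* a survival cohort in which death from non-lung-cancer causes follows a
  proportional subdistribution-hazards model (the generative form matching
  the Fine-Gray estimator, so fitted sub-hazard ratios are consistent for
  the configured truths), with lung-cancer death as the complementary cause
  and independent geometric-by-month right censoring;
* a chemotherapy complication cohort in which each of the seven
  hospitalization-level complications is an independent Bernoulli draw from
  a logistic model in the covariates.

The subdistribution CIF for other-cause death given covariates x is

    F_other(t; x) = 1 - (1 - p * (1 - exp(-t / tau)))**exp(x' beta)

with asymptote ``1 - (1-p)**exp(x'beta)``; event times are drawn by exact
inversion of this CIF.  Continuous times are rounded up to whole months to
match the monthly clock of the treatment simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .cohort import (
    COMPLICATIONS,
    COVARIATE_COLUMNS,
    AgeCategory,
    ChfLevel,
    Sex,
    Stage,
    design_matrix,
    frame_to_records,
)

__all__ = ["GeneratorConfig", "generate_survival_cohort",
           "generate_complication_cohort", "survival_frame",
           "complication_frame"]


@dataclass
class GeneratorConfig:
    """Ground truth and sampling plan for synthetic cohorts.

    Effect-size defaults are the published point estimates; covariate
    prevalences default to 30% for each binary comorbidity, uniform age
    categories, balanced sex and uniform stage (the source cohorts' joint
    covariate distribution is unpublished).
    """

    n: int = 10_000
    seed: int = 0
    true_subhazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(defaults.SUBHAZARD_RATIOS_OTHER))
    true_complication_odds_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in
                                 defaults.COMPLICATION_ODDS_RATIOS.items()})
    complication_intercepts: dict[str, float] = field(
        default_factory=lambda: {c: defaults.DEFAULT_COMPLICATION_INTERCEPT
                                 for c in COMPLICATIONS})
    baseline_cif_asymptote_other: float = 0.30
    baseline_time_scale_months: float = 60.0
    nsclc_time_scale_months: float = 40.0
    censoring_monthly_prob: float = 0.005
    age_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    prob_female: float = 0.5
    prob_copd: float = 0.3
    prob_cad: float = 0.3
    prob_chf_mild: float = 0.2
    prob_chf_severe: float = 0.1

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, v in self.true_subhazard_ratios.items():
            if v <= 0:
                raise ValueError(f"sub-hazard ratio {name} must be > 0")
        for comp, ors in self.true_complication_odds_ratios.items():
            for name, v in ors.items():
                if v <= 0:
                    raise ValueError(f"odds ratio {comp}:{name} must be > 0")
        if not 0.0 < self.baseline_cif_asymptote_other < 1.0:
            raise ValueError("baseline_cif_asymptote_other must be in (0,1)")
        if self.baseline_time_scale_months <= 0:
            raise ValueError("baseline_time_scale_months must be > 0")
        if not 0.0 <= self.censoring_monthly_prob < 1.0:
            raise ValueError("censoring_monthly_prob must be in [0,1)")
        if self.prob_chf_mild + self.prob_chf_severe >= 1.0:
            raise ValueError("CHF level probabilities must sum to < 1")
        if len(self.age_probs) != 4 or not math.isclose(sum(self.age_probs), 1.0):
            raise ValueError("age_probs must be 4 probabilities summing to 1")


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    cum = np.cumsum(cfg.age_probs)
    ages = np.searchsorted(cum, rng.random(n), side="right").clip(0, 3)
    age_cat = np.array([a.value for a in AgeCategory])[ages]
    sex = np.where(rng.random(n) < cfg.prob_female,
                   Sex.FEMALE.value, Sex.MALE.value)
    stage = np.array([s.value for s in Stage])[rng.integers(0, 4, size=n)]
    copd = rng.random(n) < cfg.prob_copd
    cad = rng.random(n) < cfg.prob_cad
    u = rng.random(n)
    chf = np.full(n, ChfLevel.NONE.value, dtype=object)
    chf[u < cfg.prob_chf_mild + cfg.prob_chf_severe] = ChfLevel.SEVERE.value
    chf[u < cfg.prob_chf_mild] = ChfLevel.MILD_MODERATE.value
    return pd.DataFrame({
        "age_category": age_cat, "sex": sex, "stage": stage,
        "copd": copd.astype(int), "cad": cad.astype(int), "chf": chf,
    })


def _linear_predictor(X: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """x' log(effect), with ``chf_any`` applying to either CHF level."""
    lp = np.zeros(len(X))
    for name, ratio in effects.items():
        if name == "chf_any":
            lp += math.log(ratio) * (X["chf_mild"].to_numpy()
                                     | X["chf_severe"].to_numpy())
        else:
            lp += math.log(ratio) * X[name].to_numpy()
    return lp


def survival_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a survival cohort as a cohort-dialect DataFrame."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    df = _draw_covariates(config, rng)
    X = design_matrix(df)

    p = config.baseline_cif_asymptote_other
    tau = config.baseline_time_scale_months
    eta = np.exp(_linear_predictor(X, config.true_subhazard_ratios))
    asymptote = 1.0 - (1.0 - p) ** eta

    u = rng.random(config.n)
    is_other = u < asymptote
    # exact inversion of the subdistribution CIF for the other-cause deaths
    inner = (1.0 - (1.0 - u) ** (1.0 / eta)) / p
    with np.errstate(divide="ignore", invalid="ignore"):
        t_other = -tau * np.log1p(-inner)
    t_nsclc = rng.exponential(config.nsclc_time_scale_months, size=config.n)
    t = np.where(is_other, t_other, t_nsclc)
    event_month = np.maximum(np.ceil(t), 1.0)

    u_cens = rng.random(config.n)
    q = config.censoring_monthly_prob
    if q > 0:
        cens_month = np.ceil(np.log(u_cens) / math.log1p(-q))
        cens_month = np.maximum(cens_month, 1.0)
    else:
        cens_month = np.full(config.n, np.inf)

    observed = event_month <= cens_month
    follow_up = np.where(observed, event_month, cens_month)
    event = np.where(observed, np.where(is_other, 2, 1), 0)

    df["follow_up_months"] = follow_up.astype(np.int64)
    df["event"] = event.astype(int)
    df["received_chemo"] = 0
    for c in COMPLICATIONS:
        df[c] = 0
    return df


def complication_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a chemotherapy-treated complication cohort as a DataFrame."""
    config.validate()
    missing = set(COMPLICATIONS) - set(config.complication_intercepts)
    if missing:
        raise ValueError(
            f"complication_intercepts missing for: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    df = _draw_covariates(config, rng)
    X = design_matrix(df)
    df["follow_up_months"] = 0
    df["event"] = 0
    df["received_chemo"] = 1
    for comp in COMPLICATIONS:
        lp = (config.complication_intercepts[comp]
              + _linear_predictor(
                  X, config.true_complication_odds_ratios.get(comp, {})))
        prob = 1.0 / (1.0 + np.exp(-lp))
        df[comp] = (rng.random(config.n) < prob).astype(int)
    return df


def generate_survival_cohort(config: GeneratorConfig):
    """Survival cohort as a list of :class:`RegistryRecord`."""
    return frame_to_records(survival_frame(config))


def generate_complication_cohort(config: GeneratorConfig):
    """Chemotherapy complication cohort as a list of :class:`RegistryRecord`."""
    return frame_to_records(complication_frame(config))
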