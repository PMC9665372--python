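"""Re-estimation of realized effect sizes from the engine's own output.

Input-consistency checks for the simulator: simulate paired arms, then
estimate the treatment effect the way a trial analyst would, and compare
with the configured input.  Two estimators are provided:

* the lung-cancer-death hazard ratio between arms, from a cause-specific
  proportional-hazards regression on the arm indicator (other-cause deaths
  censored);
* the other-cause discrete-hazard ratio between arms during the toxicity
  window, from pooled deaths per person-month at risk (the maximum-
  likelihood estimator for the engine's Bernoulli-cycle mechanism), with a
  Poisson-approximation Wald CI.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import CovariateVector
from .microsim import CohortArrays, ModelParams, simulate_cohort

__all__ = ["estimate_treatment_hr", "estimate_toxicity_hr"]


def _paired_arms(covariates: CovariateVector, params: ModelParams,
                 n_per_arm: int, seed) -> tuple[CohortArrays, CohortArrays]:
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    chemo = simulate_cohort(covariates, "chemo", n_per_arm, params,
                            np.random.default_rng(ss))
    obs = simulate_cohort(covariates, "observation", n_per_arm, params,
                          np.random.default_rng(ss))
    return chemo, obs


def estimate_treatment_hr(covariates: CovariateVector, params: ModelParams,
                          n_per_arm: int, seed) -> tuple[float, tuple[float, float]]:
    """Cause-specific lung-cancer-death HR (chemo vs observation) re-estimated
    from paired simulated cohorts.  Returns (hazard ratio, 95% CI)."""
    from lifelines import CoxPHFitter

    chemo, obs = _paired_arms(covariates, params, n_per_arm, seed)

    def frame(arr: CohortArrays, arm: int) -> pd.DataFrame:
        # death occurs in cycle months_survived + 1
        t = np.where(arr.death_cause > 0, arr.months_survived + 1,
                     arr.months_survived)
        return pd.DataFrame({"t": t, "e": (arr.death_cause == 1).astype(int),
                             "arm": arm})

    df = pd.concat([frame(chemo, 1), frame(obs, 0)], ignore_index=True)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    hr = float(np.exp(cph.params_["arm"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["arm"].to_numpy())
    return hr, (float(lo), float(hi))


def _window_hazard(arr: CohortArrays, lo: int, hi: int) -> tuple[int, int]:
    """Other-cause deaths and person-months at risk over cycles lo..hi."""
    deaths = person_months = 0
    for m in range(lo, hi + 1):
        person_months += int((arr.months_survived >= m - 1).sum())
        deaths += int(((arr.death_cause == 2)
                       & (arr.months_survived == m - 1)).sum())
    return deaths, person_months


def estimate_toxicity_hr(covariates: CovariateVector, params: ModelParams,
                         n_per_arm: int, seed,
                         ) -> tuple[float, tuple[float, float]]:
    """Months-1..window other-cause hazard ratio (chemo vs observation)
    re-estimated from paired cohorts with the lung-cancer hazard disabled.

    Returns (hazard ratio, 95% CI)."""
    isolated = replace(params, base_monthly_p_nsclc={
        s: 0.0 for s in params.base_monthly_p_nsclc})
    chemo, obs = _paired_arms(covariates, isolated, n_per_arm, seed)
    w = params.toxicity_window_months
    d1, e1 = _window_hazard(chemo, 1, w)
    d0, e0 = _window_hazard(obs, 1, w)
    if d0 == 0 or d1 == 0:
        raise ValueError("no other-cause deaths in the toxicity window; "
                         "increase n_per_arm or the baseline hazard")
    hr = (d1 / e1) / (d0 / e0)
    se_log = np.sqrt(1.0 / d1 + 1.0 / d0)
    ci = (float(hr * np.exp(-1.96 * se_log)), float(hr * np.exp(1.96 * se_log)))
    return float(hr), ci
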