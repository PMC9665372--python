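"""In-silico comparative trials of adjuvant chemotherapy vs. observation.

A trial simulates one patient stratum (age category x sex x stage x
comorbidity profile) under both strategies with common random numbers,
compares mean QALYs and 5-/10-year survival, and applies the decision rule:
adjuvant chemotherapy is the recommended strategy when it gains at least
0.25 QALYs (three quality-adjusted months) over observation.

The grid sweep covers 4 age categories x 2 sexes x 4 stages x 7 comorbidity
profiles (none, COPD, CAD, CHF, and the three distinct pairs) = 224 strata.
One-way sensitivity analysis reruns a stratum with the treatment-effect and
early-toxicity hazard ratios moved to each bound of their 95% CIs, all else
held at base case with the same seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import AgeCategory, ChfLevel, CovariateVector, Sex, Stage
from .microsim import ModelParams, simulate_cohort

__all__ = ["TrialResult", "SensitivityResult", "decide", "run_trial",
           "run_grid", "grid_strata", "grid_to_frame", "one_way_sensitivity",
           "COMORBIDITY_PROFILES"]

CHEMO = "adjuvant_chemotherapy"
OBSERVATION = "observation"

#: Comorbidity profiles swept by the grid: single conditions and the three
#: distinct pairs (CHF always mild/moderate in simulation).
COMORBIDITY_PROFILES = {
    "none": dict(copd=False, cad=False, chf=ChfLevel.NONE),
    "COPD": dict(copd=True, cad=False, chf=ChfLevel.NONE),
    "CAD": dict(copd=False, cad=True, chf=ChfLevel.NONE),
    "CHF": dict(copd=False, cad=False, chf=ChfLevel.MILD_MODERATE),
    "CAD+CHF": dict(copd=False, cad=True, chf=ChfLevel.MILD_MODERATE),
    "CAD+COPD": dict(copd=True, cad=True, chf=ChfLevel.NONE),
    "CHF+COPD": dict(copd=True, cad=False, chf=ChfLevel.MILD_MODERATE),
}


@dataclass
class TrialResult:
    """Outcome of one paired in-silico trial."""

    stratum: str
    covariates: CovariateVector
    delta_qalys: float
    delta_survival_5yr: float
    delta_survival_10yr: float
    decision: str
    mc_standard_error: float
    n_per_arm: int
    chemo_mean_qalys: float
    observation_mean_qalys: float


@dataclass
class SensitivityResult:
    """One entry of a one-way sensitivity sweep."""

    parameter: str
    value: float
    result: TrialResult


def decide(delta_qalys: float, threshold: float) -> str:
    """Treatment decision: chemotherapy iff the QALY gain meets the threshold.

    The rule is inclusive ("at least" the threshold favors treatment).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return CHEMO if delta_qalys >= threshold else OBSERVATION


def run_trial(covariates: CovariateVector, params: ModelParams,
              n_per_arm: int, seed) -> TrialResult:
    """Paired common-random-number trial for one stratum.

    ``seed`` may be an int or a SeedSequence; both arms are simulated from
    identical generator states so their uniform streams coincide.
    """
    if covariates.chf == ChfLevel.SEVERE:
        raise ValueError("severe CHF strata are excluded from simulation")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    chemo = simulate_cohort(covariates, "chemo", n_per_arm, params,
                            np.random.default_rng(ss))
    obs = simulate_cohort(covariates, "observation", n_per_arm, params,
                          np.random.default_rng(ss))
    diff = chemo.qalys - obs.qalys
    delta = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(n_per_arm)) if n_per_arm > 1 else 0.0
    return TrialResult(
        stratum=covariates.label(),
        covariates=covariates,
        delta_qalys=delta,
        delta_survival_5yr=float((chemo.months_survived >= 60).mean()
                                 - (obs.months_survived >= 60).mean()),
        delta_survival_10yr=float((chemo.months_survived >= 120).mean()
                                  - (obs.months_survived >= 120).mean()),
        decision=decide(delta, params.qaly_threshold),
        mc_standard_error=se,
        n_per_arm=n_per_arm,
        chemo_mean_qalys=float(chemo.qalys.mean()),
        observation_mean_qalys=float(obs.qalys.mean()),
    )


def grid_strata() -> list[CovariateVector]:
    """The full 4 x 2 x 4 x 7 = 224-stratum decision grid, in fixed order."""
    strata = []
    for age in AgeCategory:
        for sex in Sex:
            for stage in Stage:
                for profile in COMORBIDITY_PROFILES.values():
                    strata.append(CovariateVector(
                        age_category=age, sex=sex, stage=stage, **profile))
    return strata


def run_grid(params: ModelParams, n_per_arm: int, seed: int,
             ) -> list[TrialResult]:
    """Run the paired trial for every stratum of the decision grid."""
    params.validate()
    strata = grid_strata()
    children = np.random.SeedSequence(seed).spawn(len(strata))
    return [run_trial(cov, params, n_per_arm, child)
            for cov, child in zip(strata, children)]


def grid_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.covariates
        comorb = next(name for name, prof in COMORBIDITY_PROFILES.items()
                      if (prof["copd"], prof["cad"], prof["chf"])
                      == (c.copd, c.cad, c.chf))
        rows.append({
            "age_category": c.age_category.value, "sex": c.sex.value,
            "stage": c.stage.value, "comorbidity": comorb,
            "delta_qalys": r.delta_qalys,
            "delta_survival_5yr": r.delta_survival_5yr,
            "delta_survival_10yr": r.delta_survival_10yr,
            "mc_se": r.mc_standard_error, "decision": r.decision,
        })
    return pd.DataFrame(rows)


def one_way_sensitivity(covariates: CovariateVector, params: ModelParams,
                        n_per_arm: int, seed) -> list[SensitivityResult]:
    """One-way sweep over the 95% CI bounds of the two trial-derived HRs.

    Reruns the paired trial with the treatment-effect hazard ratio at each
    CI endpoint, then the early-toxicity hazard ratio at each endpoint,
    holding everything else (including seeds) at base case.  The base-case
    entry is reported first.
    """
    entries = [("base_case", None, params)]
    for lo_hi in params.treatment_hr_nsclc_ci:
        entries.append(("treatment_hr_nsclc", lo_hi,
                        replace(params, treatment_hr_nsclc=lo_hi)))
    for lo_hi in params.early_toxicity_hr_ci:
        entries.append(("early_toxicity_hr", lo_hi,
                        replace(params, early_toxicity_hr=lo_hi)))
    out = []
    for name, value, p in entries:
        res = run_trial(covariates, p, n_per_arm, seed)
        out.append(SensitivityResult(
            parameter=name,
            value=float(value) if value is not None else float("nan"),
            result=res))
    return out
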