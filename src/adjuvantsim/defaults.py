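"""Published effect-size defaults used throughout the package.

All values are point estimates (with 95% CIs where the simulator sweeps
them) from the source analyses the model is parameterized on: a pooled
randomized-trial analysis of adjuvant cisplatin (treatment efficacy and
early toxicity), registry-based competing-risks regression of non-lung-cancer
death (sub-hazard ratios), and logistic models of chemotherapy complications
requiring hospitalization. Non-significant complication effects enter as
odds ratio 1.0.
"""

from __future__ import annotations

from scipy.special import logit

#: Lung-cancer-death hazard ratio, adjuvant chemotherapy vs observation.
TREATMENT_HR_NSCLC = 0.83
TREATMENT_HR_NSCLC_CI = (0.76, 0.90)

#: Non-lung-cancer death hazard ratio in the first months after chemotherapy
#: (treatment toxicity), applied for ``TOXICITY_WINDOW_MONTHS`` cycles.
EARLY_TOXICITY_HR = 2.41
EARLY_TOXICITY_HR_CI = (1.64, 3.55)
TOXICITY_WINDOW_MONTHS = 6

#: Utility decrements by comorbidity (registry-linked health-survey estimates).
DISUTILITY_CAD = 0.018
DISUTILITY_COPD = 0.021
DISUTILITY_CHF = 0.069

#: Utility decrement for a major treatment complication, recovering linearly
#: to zero over six months.
COMPLICATION_DISUTILITY = 0.35
COMPLICATION_RECOVERY_MONTHS = 6

#: Decision rule: adjuvant chemotherapy is favored when it gains at least
#: 0.25 QALYs (three quality-adjusted months) over observation.
QALY_THRESHOLD = 0.25

#: Sub-hazard ratios for death from non-lung-cancer causes (reference:
#: age 66-69, male, no comorbidity), estimated on lobectomy patients who
#: did not receive adjuvant chemotherapy.
SUBHAZARD_RATIOS_OTHER = {
    "age_70_74": 1.17,
    "age_75_79": 1.33,
    "age_80_84": 1.62,
    "female": 0.78,
    "copd": 1.18,
    "cad": 1.25,
    "chf_mild": 1.49,
    "chf_severe": 1.88,
}

SUBHAZARD_CI_OTHER = {
    "age_70_74": (1.01, 1.37),
    "age_75_79": (1.14, 1.55),
    "age_80_84": (1.38, 1.92),
    "female": (0.70, 0.87),
    "copd": (1.06, 1.31),
    "cad": (1.11, 1.41),
    "chf_mild": (1.21, 1.83),
    "chf_severe": (1.48, 2.37),
}

#: Adjusted odds ratios for chemotherapy complications requiring
#: hospitalization.  Only significant effects are listed; everything else is
#: 1.0.  ``chf_any`` marks outcomes for which mild/moderate and severe CHF
#: were reported as a single pooled effect.
COMPLICATION_ODDS_RATIOS = {
    "serious_infection": {"copd": 1.80},
    "neutropenia": {},
    "nausea_vomiting": {"female": 2.33, "chf_any": 5.58},
    "anemia": {"copd": 1.41, "chf_mild": 2.08, "chf_severe": 2.81},
    "thrombocytopenia": {"copd": 2.39, "chf_any": 3.46},
    "neuropathy": {},
    "renal_failure": {},
}

#: Default per-complication baseline (reference-profile) log-odds.  The
#: source cohorts report adjusted odds ratios but not baseline rates; a 5%
#: reference-profile risk per complication type is a realistic order of
#: magnitude for hospitalization-level toxicity of platinum doublets.
DEFAULT_COMPLICATION_INTERCEPT = float(logit(0.05))

#: Relative risk of complications with vs. without adjuvant chemotherapy,
#: used to scale complication probabilities down in the observation arm.
#: Serious toxicity in the randomized trial informing this ratio was several
#: times more frequent under chemotherapy; the scalar is fully configurable.
DEFAULT_ANITA_RELATIVE_RISK = 5.0

#: Baseline (no-comorbidity, post-lobectomy) utility weight.  The source
#: analyses publish only decrements; 0.80 is a typical post-lobectomy utility
#: in the health-state-valuation literature.  Threshold-based treatment
#: comparisons are insensitive to this anchor; absolute QALYs are not.
DEFAULT_BASELINE_UTILITY = 0.80

HORIZON_AGE_YEARS = 100.0

#: Baseline monthly probability of lung-cancer death by stage (observation
#: arm, constant per cycle).  Chosen to give realistic 5-year cancer-specific
#: survival after lobectomy (~79%, 70%, 58%, 46% for IB-IIIA).
BASE_MONTHLY_P_NSCLC = {
    "IB": 0.004,
    "IIA": 0.006,
    "IIB": 0.009,
    "IIIA": 0.013,
}

#: Reference monthly probability of death from other causes for a 66-69
#: year-old man with no comorbidity (~2%/year), and the annual exponential
#: (Gompertz-like) growth rate of that hazard with attained age.
BASE_MONTHLY_P_OTHER = 0.0017
OTHER_CAUSE_ANNUAL_GROWTH = 0.09
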