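"""Monthly-cycle engine: utilities, hazards, QALY accounting, pairing."""

from dataclasses import replace

import numpy as np
import pytest

from adjuvantsim import (AgeCategory, ChfLevel, CovariateVector, ModelParams,
                         Sex, Stage, monthly_utility, run_arm,
                         simulate_cohort, simulate_patient)

STAGES = ["IB", "IIA", "IIB", "IIIA"]


def prof(**kw):
    base = dict(age_category=AgeCategory.AGE_66_69, sex=Sex.MALE,
                stage=Stage.IB)
    base.update(kw)
    return CovariateVector(**base)


def no_death_params(**kw):
    return replace(ModelParams(),
                   base_monthly_p_nsclc={s: 0.0 for s in STAGES},
                   base_monthly_p_other=0.0, complications_enabled=False,
                   **kw)


# ------------------------------------------------------------------- utilities

@pytest.mark.parametrize("covariates, months_since, expected", [
    (prof(), None, 0.80),                                    # baseline
    (prof(chf=ChfLevel.MILD_MODERATE), None, 0.80 - 0.069),  # CHF decrement
    (prof(cad=True, copd=True), None, 0.80 - 0.039),         # additive comorbidity
    (prof(), 3, 0.80 - 0.175),       # halfway through linear recovery
    (prof(), 0, 0.80 - 0.35),        # complication month
    (prof(), 6, 0.80),               # fully recovered
])
def test_monthly_utility_values(covariates, months_since, expected):
    assert monthly_utility(covariates, months_since,
                           ModelParams()) == pytest.approx(expected)


def test_utility_floors_at_zero():
    params = replace(ModelParams(), baseline_utility=0.30)
    u = monthly_utility(prof(chf=ChfLevel.MILD_MODERATE), 0, params)
    assert u == 0.0


# ---------------------------------------------------------------------- engine

def test_zero_hazards_survive_to_horizon_with_exact_qalys():
    params = no_death_params()
    out = run_arm(prof(), "observation", 50, params, seed=1)
    horizon = params.horizon_months(prof())  # (100 - 67.5) years * 12
    assert horizon == 390
    assert out.mean_life_years == pytest.approx(horizon / 12)
    assert out.mean_qalys == pytest.approx(horizon * 0.80 / 12)
    assert out.survival_at_60_months == 1.0 and out.survival_at_120_months == 1.0


def test_geometric_lifetime_closed_form():
    """Constant monthly death probability p: completed months are geometric
    with mean (1-p)/p."""
    p = 0.1
    params = replace(no_death_params(), base_monthly_p_other=p,
                     other_cause_annual_growth=0.0, subhazard_ratios_other={},
                     baseline_utility=1.0)
    n = 20_000
    arr = simulate_cohort(prof(), "observation", n, params,
                          np.random.default_rng(2))
    expected = (1 - p) / p
    sd = np.sqrt(1 - p) / p
    assert arr.months_survived.mean() == pytest.approx(
        expected, abs=4 * sd / np.sqrt(n))
    # utility 1.0: QALYs are exactly months/12
    assert np.allclose(arr.qalys, arr.months_survived / 12)


def test_toxicity_window_hazard_ratio_realized():
    """Chemotherapy arm's other-cause hazard is 2.41x observation during
    months 1-6 and equal afterwards."""
    params = replace(no_death_params(), base_monthly_p_other=0.02,
                     other_cause_annual_growth=0.0, subhazard_ratios_other={})
    n = 150_000
    ss = np.random.SeedSequence(3)
    ch = simulate_cohort(prof(), "chemo", n, params, np.random.default_rng(ss))
    ob = simulate_cohort(prof(), "observation", n, params,
                         np.random.default_rng(ss))

    def discrete_hazard(arr, lo, hi):
        deaths = person_months = 0
        for m in range(lo, hi + 1):
            at_risk = (arr.months_survived >= m - 1).sum()
            died = ((arr.death_cause == 2) & (arr.months_survived == m - 1)).sum()
            deaths += died
            person_months += at_risk
        return deaths / person_months

    early = discrete_hazard(ch, 1, 6) / discrete_hazard(ob, 1, 6)
    late = discrete_hazard(ch, 7, 18) / discrete_hazard(ob, 7, 18)
    assert early == pytest.approx(2.41, rel=0.05)
    assert late == pytest.approx(1.0, rel=0.05)


def test_exact_hazard_scaling_mode():
    params = replace(ModelParams(), hazard_scaling="exact")
    p = np.array([0.3])
    assert params.scale_probability(p, 2.0)[0] == pytest.approx(1 - 0.7 ** 2)
    assert ModelParams().scale_probability(p, 2.0)[0] == pytest.approx(0.6)


def test_run_arm_deterministic_given_seed():
    out1 = run_arm(prof(stage=Stage.IIIA), "chemo", 2000, ModelParams(), seed=9)
    out2 = run_arm(prof(stage=Stage.IIIA), "chemo", 2000, ModelParams(), seed=9)
    assert out1 == out2


def test_null_treatment_arms_identical_under_crn():
    """All effect parameters at 1 and complications off: the paired arms
    produce bitwise-identical life histories."""
    params = replace(ModelParams(), treatment_hr_nsclc=1.0,
                     early_toxicity_hr=1.0, complications_enabled=False)
    ss = np.random.SeedSequence(4)
    a = simulate_cohort(prof(stage=Stage.IIB), "chemo", 3000, params,
                        np.random.default_rng(ss))
    b = simulate_cohort(prof(stage=Stage.IIB), "observation", 3000, params,
                        np.random.default_rng(ss))
    assert np.array_equal(a.months_survived, b.months_survived)
    assert np.array_equal(a.death_cause, b.death_cause)
    assert np.array_equal(a.qalys, b.qalys)


def test_qalys_never_exceed_life_years():
    arr = simulate_cohort(prof(sex=Sex.FEMALE, copd=True, cad=True,
                               stage=Stage.IIIA), "chemo", 3000,
                          ModelParams(), np.random.default_rng(5))
    assert np.all(arr.qalys <= arr.life_years + 1e-12)
    lived = arr.months_survived > 0
    assert np.all(arr.qalys[lived] < arr.life_years[lived])  # disutility applies


def test_mean_qalys_monotone_in_effect_parameters():
    cov = prof(stage=Stage.IIIA)
    means = []
    for hr in (0.76, 0.90, 1.0):
        params = replace(ModelParams(), treatment_hr_nsclc=hr,
                         complications_enabled=False)
        means.append(run_arm(cov, "chemo", 20_000, params, seed=6).mean_qalys)
    assert means[0] >= means[1] >= means[2]

    means_tox = []
    for hr in (1.64, 3.55):
        params = replace(ModelParams(), early_toxicity_hr=hr,
                         complications_enabled=False)
        means_tox.append(run_arm(cov, "chemo", 20_000, params, seed=6).mean_qalys)
    assert means_tox[0] >= means_tox[1]


def test_simulate_patient_life_history_consistent():
    params = ModelParams()
    lh = simulate_patient(prof(stage=Stage.IIIA, copd=True), "chemo", params,
                          np.random.default_rng(7))
    assert len(lh.utilities) == lh.months_survived
    assert lh.qalys == pytest.approx(lh.utilities.sum() / 12)
    assert lh.death_cause in ("nsclc", "other", "alive_at_horizon")
    assert set(lh.complication_flags) == {
        "serious_infection", "neutropenia", "nausea_vomiting", "anemia",
        "thrombocytopenia", "neuropathy", "renal_failure"}


def test_severe_chf_rejected_by_simulator():
    with pytest.raises(ValueError, match="severe CHF"):
        simulate_cohort(prof(chf=ChfLevel.SEVERE), "chemo", 10, ModelParams(),
                        np.random.default_rng(0))


def test_survival_curve_converges_to_input_rates():
    """The simulated all-cause survival converges to the curve implied by
    the monthly transition probabilities."""
    params = replace(ModelParams(), complications_enabled=False,
                     treatment_hr_nsclc=1.0, early_toxicity_hr=1.0)
    cov = prof(stage=Stage.IIA)
    rates = params.monthly_rates_for(cov)
    truth = rates.accumulate().overall_survival

    def kolmogorov(n, seed):
        arr = simulate_cohort(cov, "observation", n, params,
                              np.random.default_rng(seed))
        emp = np.array([(arr.months_survived >= m).mean()
                        for m in range(len(truth))])
        return np.max(np.abs(emp - truth))

    assert kolmogorov(40_000, 8) < kolmogorov(1_000, 8) < 0.1
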