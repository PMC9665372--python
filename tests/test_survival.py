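"""Competing-risks estimation: Aalen-Johansen, monthly rates, Fine-Gray."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from adjuvantsim import (EstimationError, GeneratorConfig, aalen_johansen_cif,
                         fit_fine_gray, monthly_rates_from_cif, survival_frame)
from adjuvantsim.survival import finegray_fit_arrays
from conftest import reference_generator_kwargs


def toy_frame(times, events, **cols):
    n = len(times)
    base = dict(age_category="66-69", sex="male", stage="IB", copd=0, cad=0,
                chf="none", received_chemo=0)
    df = pd.DataFrame({"follow_up_months": times, "event": events})
    for k, v in base.items():
        df[k] = v
    for k, v in cols.items():
        df[k] = v
    return df


# ---------------------------------------------------------------- Aalen-Johansen

def test_aalen_johansen_hand_computed_steps():
    """3 patients: lung-cancer death at month 1, other death at month 2,
    censored at month 3."""
    cif = aalen_johansen_cif(toy_frame([1, 2, 3], [1, 2, 0]))
    assert cif.cif_nsclc[1] == pytest.approx(1 / 3)
    assert cif.cif_other[2] == pytest.approx(1 / 3)
    assert cif.overall_survival[2] == pytest.approx(1 / 3)
    cif.validate()


def test_aalen_johansen_no_events():
    cif = aalen_johansen_cif(toy_frame([5, 3, 8], [0, 0, 0]))
    assert np.all(cif.cif_nsclc == 0)
    assert np.all(cif.cif_other == 0)
    assert np.all(cif.overall_survival == 1)


def test_aalen_johansen_empty_cohort_rejected():
    with pytest.raises(EstimationError):
        aalen_johansen_cif(toy_frame([], []))


def test_cif_closure_without_censoring():
    """Complete follow-up: the two CIFs absorb all probability mass."""
    cfg = GeneratorConfig(n=3000, seed=4, censoring_monthly_prob=0.0)
    cif = aalen_johansen_cif(survival_frame(cfg))
    cif.validate()
    assert cif.cif_nsclc[-1] + cif.cif_other[-1] == pytest.approx(1.0, abs=1e-12)


def test_cif_closure_with_censoring():
    cfg = GeneratorConfig(n=3000, seed=6, censoring_monthly_prob=0.01)
    cif = aalen_johansen_cif(survival_frame(cfg))
    closure = cif.cif_nsclc + cif.cif_other + cif.overall_survival
    assert np.allclose(closure, 1.0, atol=1e-12)


# ---------------------------------------------------------------- monthly rates

def test_monthly_rates_hand_computed():
    cif = aalen_johansen_cif(toy_frame([1, 2, 3], [1, 2, 0]))
    rates = monthly_rates_from_cif(cif)
    assert rates.p_nsclc[0] == pytest.approx(1 / 3)   # month 1
    assert rates.p_other[1] == pytest.approx(1 / 2)   # month 2: (1/3)/(2/3)
    assert rates.p_other[0] == 0.0


def test_monthly_rates_zero_cif():
    cif = aalen_johansen_cif(toy_frame([4, 4], [0, 0]))
    rates = monthly_rates_from_cif(cif)
    assert np.all(rates.p_nsclc == 0) and np.all(rates.p_other == 0)


def test_rate_cif_round_trip_identity():
    """Re-accumulating monthly rates through the cycle recursion reproduces
    the input CIFs exactly at every grid point."""
    cfg = GeneratorConfig(n=2000, seed=12)
    cif = aalen_johansen_cif(survival_frame(cfg))
    back = monthly_rates_from_cif(cif).accumulate()
    assert np.allclose(back.cif_nsclc, cif.cif_nsclc, atol=1e-12)
    assert np.allclose(back.cif_other, cif.cif_other, atol=1e-12)
    assert np.allclose(back.overall_survival, cif.overall_survival, atol=1e-12)


# -------------------------------------------------------------------- Fine-Gray

def test_fine_gray_exchangeable_groups_give_null_effect():
    """Identical event/censoring patterns in both covariate groups: the
    sub-hazard ratio is exactly 1."""
    times = [1, 2, 3, 4, 5, 6, 7, 8] * 2
    events = [1, 2, 1, 0, 1, 2, 1, 0] * 2
    fit = fit_fine_gray(toy_frame(times, events, sex=["male"] * 8 + ["female"] * 8),
                        cause="other_death", covariate_names=("female",))
    assert fit.hazard_ratios["female"] == pytest.approx(1.0, abs=1e-6)


def _naive_subdistribution_loglik(beta, times, events, x):
    """Independent oracle: exact subdistribution partial likelihood for
    censoring-free data (competing-event subjects never leave risk sets)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        denom = 0.0
        for j in range(len(times)):
            in_risk = times[j] >= times[i] or events[j] == 2
            if in_risk:
                denom += np.exp(beta * x[j])
        ll += beta * x[i] - np.log(denom)
    return ll


def test_fine_gray_matches_brute_force_likelihood_grid():
    """6-record censoring-free toy data: the fitted coefficient equals the
    maximizer of the exact partial likelihood on a 1e-4 grid."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 2, 1, 1, 2, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
    grid = np.arange(-2.0, 2.0, 1e-4)
    lls = [_naive_subdistribution_loglik(b, times, events, x) for b in grid]
    oracle = grid[int(np.argmax(lls))]
    beta, _, _, _ = finegray_fit_arrays(times, events, x[:, None])
    assert beta[0] == pytest.approx(oracle, abs=1e-3)


def test_fine_gray_equals_cox_on_subdistribution_timescale():
    """Without censoring, Fine-Gray equals a proportional-hazards fit where
    competing-event subjects stay in every risk set."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(17)
    n = 300
    x = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)]).astype(float)
    eta = np.exp(0.4 * x[:, 0] - 0.2 * x[:, 1])
    u = rng.random(n)
    asym = 1 - 0.6 ** eta
    other = u < asym
    with np.errstate(invalid="ignore"):
        t = np.where(other, -20 * np.log1p(-(1 - (1 - u) ** (1 / eta)) / 0.4),
                     rng.exponential(15, n))
    events = np.where(other, 1, 2)

    beta, _, _, _ = finegray_fit_arrays(t, events, x)

    # oracle: competing subjects censored beyond the last event time
    t_mod = np.where(events == 2, t.max() + 1.0, t)
    df = pd.DataFrame({"t": t_mod, "e": (events == 1).astype(int),
                       "x0": x[:, 0], "x1": x[:, 1]})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    assert beta == pytest.approx(cph.params_.to_numpy(), abs=1e-4)


def test_fine_gray_matches_r_cmprsk():
    """Independent cross-check of the IPCW-weighted fit against cmprsk::crr
    on censored continuous-time data."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the cmprsk cross-check")
    rng = np.random.default_rng(5)
    n = 400
    x = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)]).astype(float)
    eta = np.exp(0.5 * x[:, 0] - 0.3 * x[:, 1])
    u = rng.random(n)
    asym = 1 - 0.6 ** eta
    other = u < asym
    with np.errstate(invalid="ignore"):
        t = np.where(other, -30 * np.log1p(-(1 - (1 - u) ** (1 / eta)) / 0.4),
                     rng.exponential(25, n))
    c = rng.exponential(80, n)
    events = np.where(t <= c, np.where(other, 1, 2), 0)
    time = np.minimum(t, c)

    beta, _, _, _ = finegray_fit_arrays(time, events, x)

    import tempfile, os
    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "fg.csv")
        pd.DataFrame({"time": time, "event": events,
                      "x1": x[:, 0], "x2": x[:, 1]}).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            library(cmprsk)
            d <- read.csv("{csv}")
            f <- crr(d$time, d$event, cbind(d$x1, d$x2),
                     failcode = 1, cencode = 0)
            cat(f$coef, sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
    r_beta = np.array([float(v) for v in out.stdout.split()])
    assert beta == pytest.approx(r_beta, abs=1e-4)


def test_fine_gray_recovers_generator_truths():
    """Large synthetic registry: fitted sub-hazard ratios recover the
    configured ground truth (published point estimates)."""
    cfg = GeneratorConfig(n=20_000, seed=7)
    fit = fit_fine_gray(survival_frame(cfg), cause="other_death")
    for name, truth in cfg.true_subhazard_ratios.items():
        est = fit.hazard_ratios[name]
        assert est == pytest.approx(truth, rel=0.10), name
    lo, hi = fit.ci95["female"]
    assert lo < 0.78 < hi


def test_fine_gray_ci_contains_point_estimate():
    cfg = GeneratorConfig(n=4000, seed=19)
    fit = fit_fine_gray(survival_frame(cfg), cause="other_death")
    for name, hr in fit.hazard_ratios.items():
        lo, hi = fit.ci95[name]
        assert lo < hr < hi


def test_fine_gray_errors():
    with pytest.raises(EstimationError):
        fit_fine_gray(toy_frame([1, 2, 3], [2, 2, 0]), cause="nsclc_death",
                      covariate_names=("female",))
    with pytest.raises(EstimationError, match="distinct"):
        fit_fine_gray(toy_frame([3, 3, 3], [1, 1, 0]), cause="nsclc_death",
                      covariate_names=("female",))
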