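"""Chemotherapy complication risk models.

Each of the seven hospitalization-level complications (serious infection,
neutropenia, nausea/vomiting, anemia, thrombocytopenia, neuropathy, renal
failure) gets an independent logistic model in age category, sex and
comorbidities, fitted on chemotherapy-treated patients.  The observation
arm's complication probabilities are the chemotherapy-arm probabilities
divided by the relative risk of complications with vs. without adjuvant
chemotherapy taken from randomized-trial data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import defaults
from .cohort import (
    COMPLICATIONS,
    COVARIATE_COLUMNS,
    ChfLevel,
    CovariateVector,
    design_matrix,
    records_to_frame,
)
from .survival import EstimationError

__all__ = ["ComplicationParams", "ComplicationFit", "fit_complication_model",
           "complication_probabilities"]


@dataclass
class ComplicationParams:
    """Per-complication logistic coefficients plus the between-arm relative risk.

    ``odds_ratios`` maps complication -> {covariate -> OR}; covariates not
    listed have OR 1.0.  A ``chf_any`` key applies the same OR to either CHF
    severity level (two outcomes were reported with pooled CHF effects).
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {c: defaults.DEFAULT_COMPLICATION_INTERCEPT
                                 for c in COMPLICATIONS})
    odds_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in
                                 defaults.COMPLICATION_ODDS_RATIOS.items()})
    anita_relative_risk: float = defaults.DEFAULT_ANITA_RELATIVE_RISK

    def validate(self) -> None:
        missing = set(COMPLICATIONS) - set(self.intercepts)
        if missing:
            raise ValueError(f"missing intercepts for: {sorted(missing)}")
        for comp, ors in self.odds_ratios.items():
            for name, v in ors.items():
                if v <= 0:
                    raise ValueError(f"odds ratio {comp}:{name} must be > 0")
        if self.anita_relative_risk < 1.0:
            raise ValueError("anita_relative_risk must be >= 1")


@dataclass
class ComplicationFit:
    """Fitted logistic model for one complication type."""

    complication: str
    intercept: float
    odds_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    standard_errors: dict[str, float]
    n_used: int
    n_cases: int

    def to_json(self) -> str:
        return json.dumps({
            "complication": self.complication,
            "intercept": self.intercept,
            "odds_ratios": self.odds_ratios,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "standard_errors": self.standard_errors,
            "n_used": self.n_used,
            "n_cases": self.n_cases,
        }, indent=2)


def fit_complication_model(records, complication: str,
                           covariate_names: tuple[str, ...] = COVARIATE_COLUMNS,
                           ) -> ComplicationFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs for one complication."""
    if complication not in COMPLICATIONS:
        raise ValueError(f"unknown complication {complication!r}")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    y = df[complication].to_numpy(dtype=float)
    if y.min() == y.max():
        raise EstimationError(
            f"{complication}: both outcome classes must be present")
    X = design_matrix(df, tuple(covariate_names))
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True)

    model = sm.Logit(y, Xc)
    try:
        res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise EstimationError(
            f"{complication}: logistic fit failed "
            f"(possible complete separation): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError(f"{complication}: logistic fit did not converge")
    if np.any(~np.isfinite(res.bse)) or np.max(np.abs(res.params)) > 15:
        raise EstimationError(
            f"{complication}: unstable estimates suggest complete separation")

    names = list(covariate_names)
    params = res.params[1:]
    bse = res.bse[1:]
    ci = res.conf_int()[1:]
    return ComplicationFit(
        complication=complication,
        intercept=float(res.params[0]),
        odds_ratios={k: float(np.exp(b)) for k, b in zip(names, params)},
        ci95={k: (float(np.exp(lo)), float(np.exp(hi)))
              for k, (lo, hi) in zip(names, ci)},
        standard_errors={k: float(s) for k, s in zip(names, bse)},
        n_used=len(df),
        n_cases=int(y.sum()),
    )


def _linear_predictor(cov: CovariateVector, intercept: float,
                      ors: dict[str, float]) -> float:
    dummies = cov.dummies()
    lp = intercept
    for name, ratio in ors.items():
        if name == "chf_any":
            lp += math.log(ratio) * int(cov.chf != ChfLevel.NONE)
        else:
            lp += math.log(ratio) * dummies[name]
    return lp


def complication_probabilities(covariates: CovariateVector,
                               params: ComplicationParams,
                               arm: str = "chemo") -> dict[str, float]:
    """Per-complication probabilities for one patient profile and arm.

    Chemotherapy arm: logistic(intercept + sum log-OR * indicator).
    Observation arm: the chemotherapy probability divided by the configured
    relative risk, clipped to [0, 1].
    """
    if arm not in ("chemo", "observation"):
        raise ValueError(f"unknown arm {arm!r}")
    params.validate()
    out = {}
    for comp in COMPLICATIONS:
        p = float(expit(_linear_predictor(
            covariates, params.intercepts[comp],
            params.odds_ratios.get(comp, {}))))
        if arm == "observation":
            p = min(max(p / params.anita_relative_risk, 0.0), 1.0)
        out[comp] = p
    return out
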