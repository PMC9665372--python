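"""Patient covariate profiles and registry-style cohort records.

A cohort is a table of one row per patient carrying the covariates used by
the mortality and complication models (age category, sex, AJCC 8th-edition
stage, COPD / CAD / CHF status), follow-up in whole months, the terminating
event (censoring, lung-cancer death, or death from other causes), and binary
flags for seven chemotherapy complications requiring hospitalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "AgeCategory",
    "Sex",
    "Stage",
    "ChfLevel",
    "CovariateVector",
    "RegistryRecord",
    "COMPLICATIONS",
    "COVARIATE_COLUMNS",
    "EVENT_CODES",
    "design_matrix",
    "records_to_frame",
    "frame_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
]


class AgeCategory(str, Enum):
    """Age at lobectomy, in the four Medicare-eligible bands the model uses."""

    AGE_66_69 = "66-69"
    AGE_70_74 = "70-74"
    AGE_75_79 = "75-79"
    AGE_80_84 = "80-84"

    @property
    def midpoint(self) -> float:
        lo, hi = (int(p) for p in self.value.split("-"))
        return (lo + hi) / 2.0


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Stage(str, Enum):
    """AJCC 8th-edition locoregional NSCLC stages eligible for lobectomy."""

    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    IIIA = "IIIA"


class ChfLevel(str, Enum):
    NONE = "none"
    MILD_MODERATE = "mild_moderate"
    SEVERE = "severe"


#: The seven chemotherapy complications requiring hospitalization tracked by
#: the model, in canonical column order.
COMPLICATIONS = (
    "serious_infection",
    "neutropenia",
    "nausea_vomiting",
    "anemia",
    "thrombocytopenia",
    "neuropathy",
    "renal_failure",
)

#: Dummy-coded covariate columns used by every regression in the package.
#: Reference levels: age 66-69, male, no COPD, no CAD, no CHF.
COVARIATE_COLUMNS = (
    "age_70_74",
    "age_75_79",
    "age_80_84",
    "female",
    "copd",
    "cad",
    "chf_mild",
    "chf_severe",
)

#: Event coding in the CSV dialect.
EVENT_CODES = {"censored": 0, "nsclc_death": 1, "other_death": 2}
EVENT_NAMES = {v: k for k, v in EVENT_CODES.items()}


@dataclass(frozen=True)
class CovariateVector:
    """One patient's risk profile.

    Severe CHF may appear in registry cohorts (it is modelled in the
    estimation stage) but is rejected by the treatment simulator: patients
    with severe CHF are not lobectomy candidates.
    """

    age_category: AgeCategory
    sex: Sex
    stage: Stage
    copd: bool = False
    cad: bool = False
    chf: ChfLevel = ChfLevel.NONE

    def dummies(self) -> dict[str, int]:
        """Dummy coding against the reference profile (66-69, male, healthy)."""
        return {
            "age_70_74": int(self.age_category == AgeCategory.AGE_70_74),
            "age_75_79": int(self.age_category == AgeCategory.AGE_75_79),
            "age_80_84": int(self.age_category == AgeCategory.AGE_80_84),
            "female": int(self.sex == Sex.FEMALE),
            "copd": int(self.copd),
            "cad": int(self.cad),
            "chf_mild": int(self.chf == ChfLevel.MILD_MODERATE),
            "chf_severe": int(self.chf == ChfLevel.SEVERE),
        }

    @property
    def entry_age(self) -> float:
        return self.age_category.midpoint

    def label(self) -> str:
        comorb = [c for c, has in
                  [("COPD", self.copd), ("CAD", self.cad),
                   ("CHF", self.chf != ChfLevel.NONE)] if has] or ["none"]
        return f"{self.age_category.value}/{self.sex.value}/{self.stage.value}/" \
               f"{'+'.join(comorb)}"


@dataclass
class RegistryRecord:
    """One patient's registry row: covariates, follow-up, event, complications."""

    covariates: CovariateVector
    follow_up_months: int
    event: str  # "censored" | "nsclc_death" | "other_death"
    received_chemo: bool = False
    complications: dict[str, bool] = field(
        default_factory=lambda: {c: False for c in COMPLICATIONS})

    def __post_init__(self) -> None:
        if self.follow_up_months < 0:
            raise ValueError("follow_up_months must be non-negative")
        if self.event not in EVENT_CODES:
            raise ValueError(f"unknown event {self.event!r}")


def records_to_frame(records: list[RegistryRecord]) -> pd.DataFrame:
    """Flatten records into the package's CSV dialect (one row per patient)."""
    rows = []
    for r in records:
        row = {
            "age_category": r.covariates.age_category.value,
            "sex": r.covariates.sex.value,
            "stage": r.covariates.stage.value,
            "copd": int(r.covariates.copd),
            "cad": int(r.covariates.cad),
            "chf": r.covariates.chf.value,
            "follow_up_months": r.follow_up_months,
            "event": EVENT_CODES[r.event],
            "received_chemo": int(r.received_chemo),
        }
        for c in COMPLICATIONS:
            row[c] = int(r.complications.get(c, False))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[RegistryRecord]:
    records = []
    for row in df.itertuples(index=False):
        cov = CovariateVector(
            age_category=AgeCategory(row.age_category),
            sex=Sex(row.sex),
            stage=Stage(row.stage),
            copd=bool(row.copd),
            cad=bool(row.cad),
            chf=ChfLevel(row.chf),
        )
        records.append(RegistryRecord(
            covariates=cov,
            follow_up_months=int(row.follow_up_months),
            event=EVENT_NAMES[int(row.event)],
            received_chemo=bool(row.received_chemo),
            complications={c: bool(getattr(row, c)) for c in COMPLICATIONS},
        ))
    return records


def design_matrix(df: pd.DataFrame,
                  columns: tuple[str, ...] = COVARIATE_COLUMNS) -> pd.DataFrame:
    """Dummy-coded covariate matrix from a cohort frame.

    Accepts either a frame already carrying dummy columns or the CSV dialect
    with categorical ``age_category`` / ``sex`` / ``chf`` columns.
    """
    out = pd.DataFrame(index=df.index)
    if "age_category" in df.columns:
        out["age_70_74"] = (df["age_category"] == AgeCategory.AGE_70_74.value).astype(int)
        out["age_75_79"] = (df["age_category"] == AgeCategory.AGE_75_79.value).astype(int)
        out["age_80_84"] = (df["age_category"] == AgeCategory.AGE_80_84.value).astype(int)
        out["female"] = (df["sex"] == Sex.FEMALE.value).astype(int)
        out["copd"] = df["copd"].astype(int)
        out["cad"] = df["cad"].astype(int)
        out["chf_mild"] = (df["chf"] == ChfLevel.MILD_MODERATE.value).astype(int)
        out["chf_severe"] = (df["chf"] == ChfLevel.SEVERE.value).astype(int)
    else:
        for c in columns:
            out[c] = df[c].astype(int)
    return out[list(columns)]


def write_cohort_csv(records_or_frame, path) -> None:
    df = (records_or_frame if isinstance(records_or_frame, pd.DataFrame)
          else records_to_frame(records_or_frame))
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"age_category", "sex", "stage", "copd", "cad", "chf",
                "follow_up_months", "event", "received_chemo"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
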