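import numpy as np
import pytest

from adjuvantsim import (AgeCategory, ChfLevel, CovariateVector, ModelParams,
                         Sex, Stage)


@pytest.fixture
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def reference_profile() -> CovariateVector:
    """Reference patient: 66-69, male, stage IB, no comorbidity."""
    return CovariateVector(AgeCategory.AGE_66_69, Sex.MALE, Stage.IB)


@pytest.fixture
def copd_iiia_profile() -> CovariateVector:
    return CovariateVector(AgeCategory.AGE_66_69, Sex.MALE, Stage.IIIA,
                           copd=True)


def reference_generator_kwargs() -> dict:
    """Generator settings forcing every patient to the reference profile."""
    return dict(age_probs=(1.0, 0.0, 0.0, 0.0), prob_female=0.0,
                prob_copd=0.0, prob_cad=0.0, prob_chf_mild=0.0,
                prob_chf_severe=0.0)
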