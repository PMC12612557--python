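import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crcsim
from crcsim.states import GROUPS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def white_men():
    return GROUPS[0]


@pytest.fixture(scope="session")
def black_men():
    return GROUPS[1]


@pytest.fixture(scope="session")
def zero_disease(white_men):
    """Disease parameters with every transition rate zero (life-table-only
    world)."""
    return crcsim.DiseaseParams(
        adenoma_onset=np.zeros(7),
        growth_dim_to_small=0.0,
        growth_small_to_large=0.0,
        large_to_preclinical=0.0,
        stage_progression=np.zeros(3),
        clinical_detection=np.zeros(4),
        crc_mortality=np.zeros(4),
        group=white_men.label,
    )


@pytest.fixture(scope="session")
def nominal_params(white_men):
    return crcsim.nominal_disease_params(white_men)


@pytest.fixture(scope="session")
def truth_white_men(white_men):
    return crcsim.make_truth(1, white_men)


@pytest.fixture(scope="session")
def small_outcomes(truth_white_men):
    """Six-strategy outcomes for a small seed-aligned cohort (shared by
    economics/CEA tests)."""
    sc = truth_white_men.scenario()
    return sc.outcomes(
        ("no_screening", "status_quo", "ctc_only", "colonoscopy_only",
         "fit_only", "mtsdna_only"), 4000, 11)
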