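"""Packaged base-case behavioral inputs.

Patient-level test characteristics and the status-quo adherence
schedules by race and gender, together with the uncertainty
distributions used for probabilistic sensitivity analysis.  These are
published point estimates; the natural-history transition rates, by
contrast, are free parameters recovered by calibration.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .screening import AdherenceProfile, Modality, TestPerformance
from .states import GROUPS, Group

# -- test characteristics (patient-level) -------------------------------------
# CTC sens for diminutive adenomas is 0 in the base case: colonoscopy referral
# is not recommended for lesions < 6 mm detected on CTC.

TEST_PERFORMANCE: Dict[Modality, TestPerformance] = {
    Modality.COLONOSCOPY: TestPerformance(0.75, 0.85, 0.95, 0.95, 0.86),
    Modality.CTC: TestPerformance(0.0, 0.786, 0.879, 0.961, 0.88),
    Modality.FIT: TestPerformance(0.076, 0.076, 0.238, 0.738, 0.964),
    Modality.MTSDNA: TestPerformance(0.172, 0.172, 0.424, 0.923, 0.898),
}

# Relative risks of initiating screening by modality pair (RCT-based).
RR_INITIAL = {
    "colonoscopy_vs_fit": 0.29,
    "fit_vs_colonoscopy": 3.45,
    "ctc_vs_colonoscopy": 1.80,
    "ctc_vs_fit": 0.53,
}

FOLLOWUP_ADHERENCE = {Modality.CTC: 0.977, Modality.FIT: 0.487, Modality.MTSDNA: 0.666}
SURVEILLANCE_ADHERENCE = (0.447, 0.546)  # (low risk, high risk)
REPEAT_OR_CTC_BLACK = 1.83

# -- status-quo adherence schedules by group -----------------------------------
# Columns are the origin modality: [colonoscopy, FIT].  Rows of `initial` are
# the age bands 45-49, 50-54, 55-59, 60-64, 65-69, 70-75; rows of `repeat` are
# <65 and >=65.

_STATUS_QUO_RAW = {
    "White men": {
        "pre45": [0.224, 0.087],
        "initial": [[0.081, 0.031], [0.042, 0.016], [0.024, 0.008],
                    [0.013, 0.004], [0.007, 0.002], [0.007, 0.002]],
        "repeat": [[0.239, 0.280], [0.565, 0.561]],
    },
    "Black men": {
        "pre45": [0.243, 0.090],
        "initial": [[0.063, 0.026], [0.032, 0.012], [0.021, 0.006],
                    [0.012, 0.004], [0.007, 0.002], [0.007, 0.002]],
        "repeat": [[0.202, 0.284], [0.647, 0.587]],
    },
    "White women": {
        "pre45": [0.239, 0.091],
        "initial": [[0.081, 0.035], [0.039, 0.016], [0.017, 0.007],
                    [0.008, 0.004], [0.004, 0.002], [0.004, 0.002]],
        "repeat": [[0.304, 0.322], [0.566, 0.616]],
    },
    "Black women": {
        "pre45": [0.202, 0.103],
        "initial": [[0.070, 0.020], [0.039, 0.009], [0.020, 0.004],
                    [0.011, 0.002], [0.006, 0.001], [0.006, 0.001]],
        "repeat": [[0.260, 0.339], [0.587, 0.641]],
    },
}


def status_quo_profile(group: Group) -> AdherenceProfile:
    """Status-quo adherence schedules for one demographic group."""
    try:
        raw = _STATUS_QUO_RAW[group.label]
    except KeyError:
        raise ValueError(f"unknown group {group.label!r}") from None
    return AdherenceProfile(
        pre45_screened=np.array(raw["pre45"]),
        initial=np.array(raw["initial"]),
        repeat=np.array(raw["repeat"]),
        switch=0.0,
        followup=dict(FOLLOWUP_ADHERENCE),
        surveillance=SURVEILLANCE_ADHERENCE,
        group=group.label,
    )


def status_quo_profiles() -> Dict[str, AdherenceProfile]:
    return {g.label: status_quo_profile(g) for g in GROUPS}


# -- PSA uncertainty distributions ---------------------------------------------
# Each entry: parameter path -> ("beta", alpha, beta) or ("pert", min, mode, max).
# Beta pairs and PERT triples are the published realistic (narrow) ranges.

PSA_DISTRIBUTIONS = {
    "performance.colonoscopy.sens_diminutive": ("beta", 229, 76),
    "performance.colonoscopy.sens_small": ("beta", 187, 33),
    "performance.colonoscopy.sens_large": ("beta", 559, 29),
    "performance.colonoscopy.sens_crc": ("beta", 559, 29),
    "performance.ctc.sens_diminutive": ("beta", 0.03, 3.01),
    "performance.ctc.sens_small": ("beta", 38, 10),
    "performance.ctc.sens_large": ("beta", 126, 17),
    "performance.ctc.sens_crc": ("beta", 126, 17),
    "performance.fit.sens_diminutive": ("beta", 218, 2645),
    "performance.fit.sens_small": ("beta", 218, 2645),
    "performance.fit.sens_large": ("beta", 169, 541),
    "performance.fit.sens_crc": ("beta", 46, 16),
    "performance.mtsdna.sens_diminutive": ("beta", 495, 2385),
    "performance.mtsdna.sens_small": ("beta", 495, 2385),
    "performance.mtsdna.sens_large": ("beta", 278, 378),
    "performance.mtsdna.sens_crc": ("beta", 51, 4),
    "multipliers.colonoscopy_vs_fit": ("beta", 112.99, 276.62),
    "multipliers.fit_vs_colonoscopy": ("pert", 2.94, 3.45, 4.0),
    "multipliers.ctc_vs_colonoscopy": ("pert", 1.46, 1.8, 2.35),
    "multipliers.ctc_vs_fit": ("beta", 89.64, 79.49),
    "followup.ctc": ("beta", 7.46, 0.18),
    "followup.fit": ("beta", 2076.84, 2187.72),
    "followup.mtsdna": ("beta", 2528.77, 1268.18),
    "surveillance.low_risk": ("beta", 8.81, 10.76),
    "surveillance.high_risk": ("beta", 30.39, 24.87),
}

# Wider one-way sensitivity ranges (low, high) for selected parameters.
OWSA_RANGES = {
    "multipliers.ctc_vs_colonoscopy": (1.46, 2.35),
    "multipliers.ctc_vs_fit": (0.46, 0.61),
    "followup.ctc": (0.80, 1.00),
    "followup.fit": (0.20, 1.00),
    "followup.mtsdna": (0.50, 1.00),
    "performance.ctc.sens_large": (0.821, 0.920),
    "performance.ctc.sens_crc": (0.821, 1.000),
    "surveillance.low_risk": (0.20, 0.70),
    "surveillance.high_risk": (0.40, 0.70),
    "repeat_or_ctc_black": (1.0, 2.5),
}
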