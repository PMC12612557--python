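"""Known-truth synthetic inputs for every pipeline stage.

The generator stands in for registry and survey data: it draws a truth
parameter set of plausible magnitude (a lifetime no-screening CRC risk
in the 6%–9% band, i.e. 60–90 cases per 1000), simulates calibration
targets at that truth, and re-exports the published behavioral defaults.
Target noise is independent multiplicative lognormal per target.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from ._rng import substream_seed
from .calibration import CalibrationTarget, SearchSpace
from .lifetable import make_life_table
from .params import DiseaseParams
from .scenario import Scenario, apply_calibration_params, summarize_for_targets
from .screening import STRATEGIES, AdherenceProfile
from .states import Group
from .tables import TEST_PERFORMANCE, status_quo_profiles

# Nominal (pre-calibration) natural-history rates.  Magnitudes follow the
# adenoma–carcinoma literature: onset rising with age, multi-year dwell in
# each adenoma size class, a ~3–5 year mean preclinical sojourn, and
# stage-graded excess mortality for ten years post-diagnosis.
_NOMINAL = {
    "adenoma_onset": np.array([0.0020, 0.0045, 0.0090, 0.0130, 0.0165, 0.0180, 0.0180]),
    "growth_dim_to_small": 0.060,
    "growth_small_to_large": 0.055,
    "large_to_preclinical": 0.060,
    "stage_progression": np.array([0.35, 0.45, 0.50]),
    "clinical_detection": np.array([0.12, 0.25, 0.45, 0.70]),
    "crc_mortality": np.array([0.010, 0.035, 0.090, 0.350]),
}

# Mild group contrasts: without screening the model should show lower CRC
# incidence for Black than White adults (the reversal under the status quo
# is then driven purely by adherence differences).
_GROUP_ONSET_MULT = {
    "White men": 1.00, "Black men": 0.80, "White women": 0.96, "Black women": 0.92,
}


def nominal_disease_params(group: Group) -> DiseaseParams:
    """Group-specific nominal natural-history parameters (the calibration
    base onto which free parameters are overlaid)."""
    mult = _GROUP_ONSET_MULT[group.label]
    return DiseaseParams(
        adenoma_onset=_NOMINAL["adenoma_onset"] * mult,
        growth_dim_to_small=_NOMINAL["growth_dim_to_small"],
        growth_small_to_large=_NOMINAL["growth_small_to_large"],
        large_to_preclinical=_NOMINAL["large_to_preclinical"],
        stage_progression=_NOMINAL["stage_progression"].copy(),
        clinical_detection=_NOMINAL["clinical_detection"].copy(),
        crc_mortality=_NOMINAL["crc_mortality"].copy(),
        other_cause_mortality=make_life_table(group.gender.value),
        group=group.label,
    )


def default_search_space() -> SearchSpace:
    """Bounds of the free calibrated parameters (all log-scaled)."""
    return SearchSpace(
        bounds={
            "onset_scale": (0.5, 2.0),
            "growth_dim_to_small": (0.02, 0.18),
            "growth_small_to_large": (0.02, 0.18),
            "large_to_preclinical": (0.02, 0.20),
            "detection_scale": (0.5, 2.0),
        },
        log_scale=("onset_scale", "growth_dim_to_small", "growth_small_to_large",
                   "large_to_preclinical", "detection_scale"),
    )


@dataclass
class TruthSpec:
    """A known-truth world: disease + adherence parameters and the noise
    level applied when targets are generated from them."""

    group: Group
    disease: DiseaseParams
    profile: AdherenceProfile
    truth_params: Dict[str, float] = field(default_factory=dict)
    target_noise: float = 0.05

    def scenario(self) -> Scenario:
        sc = Scenario.default(self.group, copy.deepcopy(self.disease))
        sc.profile = self.profile.copy()
        return sc

    def calibration_scenario(self) -> Scenario:
        """Scenario whose disease parameters are the *nominal* base the
        calibrator overlays candidates on (adherence is shared with the
        truth; the truth disease parameters are what must be recovered)."""
        sc = Scenario.default(self.group, nominal_disease_params(self.group))
        sc.profile = self.profile.copy()
        return sc


# Design band for the lifetime no-screening CRC risk of a generated truth,
# in cases per 1000 40-year-olds (6%-9%).
DESIGN_RISK_BAND = (60.0, 90.0)


def make_truth(seed: int, group: Group, target_noise: float = 0.05) -> TruthSpec:
    """Deterministic truth parameter set for one group.

    The free calibrated parameters are drawn from the central half of the
    search space (in unit coordinates), so truth is always interior to the
    bounds the calibrator searches.  Draws are rejection-sampled (with a
    deterministic sequence) until a pilot no-screening simulation puts the
    lifetime CRC risk inside DESIGN_RISK_BAND.
    """
    if not isinstance(group, Group):
        group = Group.parse(str(group))
    space = default_search_space()
    group_key = sum(group.label.encode())  # stable across processes
    rng = np.random.default_rng(substream_seed(seed, 101, group_key))
    base = nominal_disease_params(group)
    truth_params = None
    disease = None
    for _ in range(30):
        unit = 0.25 + 0.5 * rng.random(len(space.bounds))
        truth_params = space.from_unit(unit)
        disease = apply_calibration_params(base, truth_params)
        if DESIGN_RISK_BAND[0] <= _pilot_risk(disease, group, seed) <= DESIGN_RISK_BAND[1]:
            break
    profile = status_quo_profiles()[group.label]
    return TruthSpec(group=group, disease=disease, profile=profile,
                     truth_params=truth_params, target_noise=target_noise)


def _pilot_risk(disease: DiseaseParams, group: Group, seed: int, n: int = 10_000) -> float:
    """No-screening lifetime CRC cases per 1000 in a small pilot cohort."""
    from .natural_history import EventType, initialize_cohort, simulate_lifetime

    coh = initialize_cohort(n, group, 40, disease, substream_seed(seed, 909))
    led = simulate_lifetime(coh, disease)
    return 1000.0 * led.count(EventType.CRC_DIAGNOSIS) / n


# Default weights by target family: disease outcomes carry more weight than
# behavioral utilization summaries, which the candidate parameters do not move.
_FAMILY_WEIGHTS = (
    ("incidence_", 3.0), ("stage_", 1.0), ("adenoma_prev_", 2.0),
    ("polyp_share_", 1.0), ("ever_", 0.5), ("recent_", 0.5),
)


def _weight_for(name: str) -> float:
    for prefix, w in _FAMILY_WEIGHTS:
        if name.startswith(prefix):
            return w
    return 1.0


def make_targets(
    truth: TruthSpec, seed: int, n: int = 50_000, noise: float | None = None,
    summaries: Dict[str, float] | None = None,
) -> List[CalibrationTarget]:
    """Simulate large-cohort summaries at truth and add multiplicative
    lognormal noise at the stated relative SD.  Precomputed `summaries`
    skip the simulation (noise replicates over fixed summaries)."""
    sigma = truth.target_noise if noise is None else noise
    if summaries is None:
        summaries = summarize_for_targets(truth.scenario(), n=n,
                                          seed=substream_seed(seed, 7))
    rng = np.random.default_rng(substream_seed(seed, 11))
    targets = []
    for name in sorted(summaries):
        value = summaries[name]
        factor = float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)) if sigma > 0 else 1.0
        targets.append(CalibrationTarget(
            name=name, group=truth.group.label, age_band=_band_of(name),
            value=value * factor, weight=_weight_for(name), tolerance=3.0 * sigma,
        ))
    return targets


def _band_of(name: str) -> str:
    parts = name.rsplit("_", 2)
    if name.startswith("incidence_") and len(parts) == 3:
        return f"{parts[1]}-{parts[2]}"
    if name.startswith("adenoma_prev_"):
        return name.rsplit("_", 1)[1]
    return ""


def packaged_defaults():
    """The published base-case behavioral inputs: patient-level test
    characteristics, status-quo adherence schedules for all four groups,
    and the strategy-derivation rules."""
    return dict(TEST_PERFORMANCE), status_quo_profiles(), dict(STRATEGIES)


def scripted_ledger(events, n: int, start_age: int = 40, max_age: int = 100,
                    group: str = "White men", strategy: str = "scripted"):
    """Hand-written event ledger for economics tests.

    `events` is an iterable of (person_id, age, event, detail) tuples using
    :class:`crcsim.natural_history.EventType` values; every person must end
    in a death or alive_at_end entry for conservation to hold.
    """
    import pandas as pd

    from .natural_history import EventLedger

    frame = pd.DataFrame(events, columns=["person_id", "age", "event", "detail"])
    frame["event"] = frame["event"].map(lambda e: getattr(e, "value", e))
    return EventLedger(frame=frame, n=n, start_age=start_age, max_age=max_age,
                       group=group, strategy=strategy)
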