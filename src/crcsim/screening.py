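"""Screening modalities, test performance, and the three-component
real-world adherence model.

Adherence has three components per modality: *initial* screening
(first-ever uptake, an annual probability by age band), *repeat*
screening at the guideline interval (annual probability by <65 / >=65
band), and *switching* between colonoscopy and FIT at the next due date
under the status quo.  Single-modality strategies are derived from the
status-quo schedules: initial probabilities are scaled by relative-risk
multipliers specific to the person's original modality choice, and
repeat probabilities are taken from the named source modality, with an
odds-ratio uplift for CT colonography among Black adults.  Screening
stops after age 75.  Positive non-colonoscopy tests lead to diagnostic
colonoscopy with modality-specific follow-up adherence; people with an
adenoma history enter interval surveillance with tier-specific
attendance.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .states import AdenomaTier, Group, HealthState, Person, Race

SCREENING_START_AGE = 45
SCREENING_STOP_AGE = 75  # "All screening ended after age 75"

INITIAL_AGE_BANDS = ("45_49", "50_54", "55_59", "60_64", "65_69", "70_75")
REPEAT_AGE_BANDS = ("under_65", "65_plus")


class Modality(enum.IntEnum):
    COLONOSCOPY = 0
    CTC = 1
    FIT = 2
    MTSDNA = 3

    @property
    def interval(self) -> int:
        return _INTERVALS[self]

    @property
    def is_colonoscopy(self) -> bool:
        return self is Modality.COLONOSCOPY


# Guideline screening intervals in years.
_INTERVALS = {Modality.COLONOSCOPY: 10, Modality.CTC: 5, Modality.FIT: 1, Modality.MTSDNA: 3}

# Origin columns of the status-quo adherence tables.
ORIGIN_COLONOSCOPY = 0
ORIGIN_FIT = 1


def initial_age_band(age) -> np.ndarray:
    """Index into INITIAL_AGE_BANDS for ages 45..75."""
    return np.minimum((np.asarray(age) - 45) // 5, 5)


def repeat_age_band(age) -> int:
    return int(np.asarray(age) >= 65)


@dataclass
class TestPerformance:
    """Patient-level sensitivity by lesion class plus specificity."""

    __test__ = False  # not a pytest class, despite the name

    sens_diminutive: float
    sens_small: float
    sens_large: float
    sens_crc: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sens_diminutive", "sens_small", "sens_large", "sens_crc", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def sensitivity_for(self, state: HealthState) -> float:
        if state is HealthState.ADENOMA_DIMINUTIVE:
            return self.sens_diminutive
        if state is HealthState.ADENOMA_SMALL:
            return self.sens_small
        if state is HealthState.ADENOMA_LARGE:
            return self.sens_large
        if state.is_preclinical:
            return self.sens_crc
        raise ValueError(f"no sensitivity defined for state {state.name}")


@dataclass
class AdherenceProfile:
    """Status-quo or strategy-derived adherence schedules for one group.

    Arrays are indexed [age band, column] where the column is the status-quo
    origin modality (0 = colonoscopy, 1 = FIT).  For derived single-modality
    strategies the repeat columns coincide whenever the rule makes them so.
    """

    pre45_screened: np.ndarray      # (2,) fraction already initiated before 45, per origin
    initial: np.ndarray             # (6, 2) annual initial probability
    repeat: np.ndarray              # (2, 2) annual repeat probability
    switch: float = 0.0             # P(switch colonoscopy<->FIT at next due date), status quo
    followup: Dict[Modality, float] = field(
        default_factory=lambda: {Modality.CTC: 0.977, Modality.FIT: 0.487, Modality.MTSDNA: 0.666}
    )
    surveillance: Tuple[float, float] = (0.447, 0.546)   # (low-risk, high-risk) attendance
    surveillance_interval: Tuple[int, int] = (5, 3)      # years, (low-risk, high-risk)
    group: str = ""

    def __post_init__(self) -> None:
        self.pre45_screened = np.asarray(self.pre45_screened, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.repeat = np.asarray(self.repeat, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.initial.shape != (6, 2):
            raise ValueError(f"initial must be (6, 2), got {self.initial.shape}")
        if self.repeat.shape != (2, 2):
            raise ValueError(f"repeat must be (2, 2), got {self.repeat.shape}")
        if self.pre45_screened.shape != (2,):
            raise ValueError("pre45_screened must have one entry per origin modality")
        arrays = [self.pre45_screened, self.initial, self.repeat,
                  np.array(list(self.followup.values())), np.array(self.surveillance),
                  np.array([self.switch])]
        for arr in arrays:
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("adherence probabilities must lie in [0, 1]")
        if np.any(np.diff(self.initial, axis=0) > 1e-12):
            raise ValueError("initial probabilities must be non-increasing across age bands")

    def surveillance_attendance(self, tier: AdenomaTier) -> float:
        if tier is AdenomaTier.NONE:
            raise ValueError("surveillance requires an adenoma history tier")
        return self.surveillance[int(tier) - 1]

    def copy(self) -> "AdherenceProfile":
        return copy.deepcopy(self)

    # -- keyed text config mirroring the published panel structure -------------

    def to_flat_dict(self) -> dict:
        out: dict = {"group": self.group, "switch": float(self.switch)}
        for col, origin in enumerate(("colonoscopy", "fit")):
            out[f"pre45.{origin}"] = float(self.pre45_screened[col])
            for b, band in enumerate(INITIAL_AGE_BANDS):
                out[f"initial.{band}.{origin}"] = float(self.initial[b, col])
            for b, band in enumerate(REPEAT_AGE_BANDS):
                out[f"repeat.{band}.{origin}"] = float(self.repeat[b, col])
        for mod, p in self.followup.items():
            out[f"followup.{Modality(mod).name.lower()}"] = float(p)
        out["surveillance.low_risk"] = float(self.surveillance[0])
        out["surveillance.high_risk"] = float(self.surveillance[1])
        out["surveillance_interval.low_risk"] = int(self.surveillance_interval[0])
        out["surveillance_interval.high_risk"] = int(self.surveillance_interval[1])
        return out

    @classmethod
    def from_flat_dict(cls, d) -> "AdherenceProfile":
        origins = ("colonoscopy", "fit")
        return cls(
            pre45_screened=np.array([float(d[f"pre45.{o}"]) for o in origins]),
            initial=np.array([[float(d[f"initial.{band}.{o}"]) for o in origins]
                              for band in INITIAL_AGE_BANDS]),
            repeat=np.array([[float(d[f"repeat.{band}.{o}"]) for o in origins]
                             for band in REPEAT_AGE_BANDS]),
            switch=float(d.get("switch", 0.0)),
            followup={Modality[m.upper()]: float(d[f"followup.{m}"])
                      for m in ("ctc", "fit", "mtsdna")},
            surveillance=(float(d["surveillance.low_risk"]), float(d["surveillance.high_risk"])),
            surveillance_interval=(int(d.get("surveillance_interval.low_risk", 5)),
                                   int(d.get("surveillance_interval.high_risk", 3))),
            group=str(d.get("group", "")),
        )

    def save(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "AdherenceProfile":
        import yaml

        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class StrategyRule:
    """Named screening policy and its adherence-derivation rule."""

    name: str
    modality: Optional[Modality]                 # None for status quo / no screening
    initial_multiplier_from_colonoscopy: float = 1.0
    initial_multiplier_from_fit: float = 1.0
    repeat_source: str = "own"                   # 'own' | 'colonoscopy' | 'fit'
    repeat_odds_ratio_black: Optional[float] = None
    switching_allowed: bool = False
    screens: bool = True

    def __post_init__(self) -> None:
        if self.initial_multiplier_from_colonoscopy <= 0 or self.initial_multiplier_from_fit <= 0:
            raise ValueError("initial multipliers must be positive")


STRATEGIES: Dict[str, StrategyRule] = {
    "no_screening": StrategyRule("no_screening", None, screens=False),
    "status_quo": StrategyRule("status_quo", None, 1.0, 1.0, "own", None, switching_allowed=True),
    "ctc_only": StrategyRule("ctc_only", Modality.CTC, 1.80, 0.53, "colonoscopy", 1.83),
    "colonoscopy_only": StrategyRule("colonoscopy_only", Modality.COLONOSCOPY, 1.00, 0.29, "colonoscopy"),
    "fit_only": StrategyRule("fit_only", Modality.FIT, 3.45, 1.00, "fit"),
    "mtsdna_only": StrategyRule("mtsdna_only", Modality.MTSDNA, 3.45, 1.00, "fit"),
}


# -- adherence arithmetic ------------------------------------------------------


def apply_initial_multiplier(p: float, rr: float) -> float:
    """Scale an initial-screening probability by a relative risk, clipped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    return min(1.0, p * rr)


def apply_repeat_odds_ratio(p: float, odds_ratio: float) -> float:
    """Adjust a repeat-screening probability on the odds scale."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def derive_strategy_profile(
    status_quo: AdherenceProfile, rule: StrategyRule, group: Group
) -> AdherenceProfile:
    """Derive a single-modality strategy's adherence schedules from the
    status quo, per the strategy's multiplier and repeat rules."""
    if rule.name not in STRATEGIES:
        raise ValueError(f"unknown strategy rule {rule.name!r}")
    profile = status_quo.copy()
    profile.group = status_quo.group
    if rule.name in ("status_quo", "no_screening"):
        return profile

    mult = np.array([rule.initial_multiplier_from_colonoscopy, rule.initial_multiplier_from_fit])
    profile.initial = np.minimum(1.0, status_quo.initial * mult[None, :])

    if rule.repeat_source == "colonoscopy":
        base = status_quo.repeat[:, ORIGIN_COLONOSCOPY].copy()
    elif rule.repeat_source == "fit":
        base = status_quo.repeat[:, ORIGIN_FIT].copy()
    else:  # pragma: no cover - single-modality rules always name a source
        base = None
    if base is not None:
        if rule.repeat_odds_ratio_black is not None and group.race is Race.BLACK:
            base = np.array([apply_repeat_odds_ratio(p, rule.repeat_odds_ratio_black) for p in base])
        profile.repeat = np.column_stack([base, base])

    profile.switch = 0.0  # switching disabled outside the status quo
    return profile


# -- scalar per-person operations (the cohort engine vectorizes these) ---------


def annual_screening_decision(person, screening_state, profile: AdherenceProfile,
                              rule: StrategyRule, rng) -> str:
    """Routine-screening action for one person-year.

    Returns one of ``'none'``, ``'screen'``, ``'surveillance_colonoscopy'``.
    Diagnostic colonoscopy is triggered by a positive test, not here.
    """
    if not person.alive:
        raise ValueError("screening decision requires a living person")
    age = person.age
    if age < SCREENING_START_AGE or age > SCREENING_STOP_AGE or not rule.screens:
        return "none"
    if person.adenoma_history_tier is not AdenomaTier.NONE:
        if screening_state.surveillance_due is not None and age >= screening_state.surveillance_due:
            return surveillance_decision(person, profile, rng)
        return "none"
    if not screening_state.has_initiated:
        band = int(initial_age_band(age))
        p = profile.initial[band, screening_state.origin_column]
        return "screen" if rng.random() < p else "none"
    if screening_state.next_due is not None and age >= screening_state.next_due:
        col = screening_state.origin_column if rule.modality is not None \
            else int(screening_state.current_modality is Modality.FIT)
        p = profile.repeat[repeat_age_band(age), col]
        return "screen" if rng.random() < p else "none"
    return "none"


def run_test(modality: Modality, state: HealthState, perf: TestPerformance, rng) -> str:
    """One screening test on one person: 'negative', 'positive_lesion', or
    'positive_false' (no detectable lesion, imperfect specificity)."""
    if state.is_dead or state.is_clinical:
        raise ValueError(f"cannot screen a person in state {state.name}")
    if state is HealthState.NO_LESION:
        return "positive_false" if rng.random() < 1.0 - perf.specificity else "negative"
    sens = perf.sensitivity_for(state)
    return "positive_lesion" if rng.random() < sens else "negative"


def diagnostic_follow_up(modality: Modality, profile: AdherenceProfile, rng) -> bool:
    """Whether a positive non-colonoscopy test is followed by diagnostic
    colonoscopy in the same cycle."""
    if modality.is_colonoscopy:
        raise ValueError("colonoscopy needs no diagnostic follow-up")
    return bool(rng.random() < profile.followup[modality])


def surveillance_decision(person, profile: AdherenceProfile, rng) -> str:
    """Attendance draw at a surveillance due date."""
    tier = person.adenoma_history_tier
    p = profile.surveillance_attendance(tier)
    return "surveillance_colonoscopy" if rng.random() < p else "none"


def colonoscopy_resolution(person: Person, detected: bool, rng=None) -> Person:
    """Apply the consequences of a colonoscopy finding to one person.

    Detected adenomas are removed (polypectomy) and the surveillance tier
    floors at low risk for small and high risk for large adenomas; detected
    preclinical cancer is diagnosed at its current stage.
    """
    if not detected:
        return person
    state = person.state
    if state.is_adenoma:
        tier = person.adenoma_history_tier
        if state is HealthState.ADENOMA_SMALL:
            tier = max(tier, AdenomaTier.LOW_RISK)
        elif state is HealthState.ADENOMA_LARGE:
            tier = max(tier, AdenomaTier.HIGH_RISK)
        person.state = HealthState.NO_LESION
        person.adenoma_history_tier = AdenomaTier(tier)
    elif state.is_preclinical:
        person.state = HealthState(int(state) + 4)  # preclinical stage s -> clinical stage s
        person.years_since_diagnosis = 0
    return person


@dataclass
class PersonScreeningState:
    """Screening bookkeeping carried alongside a Person."""

    origin_modality: Modality = Modality.COLONOSCOPY
    has_initiated: bool = False
    next_due: Optional[int] = None
    current_modality: Optional[Modality] = None
    surveillance_due: Optional[int] = None

    def __post_init__(self) -> None:
        if self.current_modality is None:
            self.current_modality = self.origin_modality
        if not self.has_initiated and self.next_due is not None:
            raise ValueError("next_due is only defined after initiation")

    @property
    def origin_column(self) -> int:
        return ORIGIN_FIT if self.origin_modality is Modality.FIT else ORIGIN_COLONOSCOPY
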