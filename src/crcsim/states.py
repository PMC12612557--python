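"""Health states, demographic groups, and the per-person record.

The disease model follows the adenoma–carcinoma sequence: no lesion,
adenomas by size (diminutive 1–5 mm, small 6–9 mm, large >= 10 mm),
preclinical cancer by stage I–IV (present but undiagnosed, hence
screen-detectable), clinical cancer by stage I–IV (diagnosed), and two
absorbing death states (CRC death, other-cause death).  Exactly one
state per person per annual cycle; the machine tracks the single most
advanced lesion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class HealthState(enum.IntEnum):
    NO_LESION = 0
    ADENOMA_DIMINUTIVE = 1
    ADENOMA_SMALL = 2
    ADENOMA_LARGE = 3
    PRECLINICAL_CRC_I = 4
    PRECLINICAL_CRC_II = 5
    PRECLINICAL_CRC_III = 6
    PRECLINICAL_CRC_IV = 7
    CLINICAL_CRC_I = 8
    CLINICAL_CRC_II = 9
    CLINICAL_CRC_III = 10
    CLINICAL_CRC_IV = 11
    DEAD_CRC = 12
    DEAD_OTHER = 13

    @property
    def is_dead(self) -> bool:
        return self >= HealthState.DEAD_CRC

    @property
    def is_adenoma(self) -> bool:
        return HealthState.ADENOMA_DIMINUTIVE <= self <= HealthState.ADENOMA_LARGE

    @property
    def is_preclinical(self) -> bool:
        return HealthState.PRECLINICAL_CRC_I <= self <= HealthState.PRECLINICAL_CRC_IV

    @property
    def is_clinical(self) -> bool:
        return HealthState.CLINICAL_CRC_I <= self <= HealthState.CLINICAL_CRC_IV

    @property
    def stage(self) -> Optional[int]:
        """Cancer stage 1–4, or None for non-cancer states."""
        if self.is_preclinical:
            return int(self) - int(HealthState.PRECLINICAL_CRC_I) + 1
        if self.is_clinical:
            return int(self) - int(HealthState.CLINICAL_CRC_I) + 1
        return None


class AdenomaTier(enum.IntEnum):
    """Post-polypectomy surveillance risk tier.

    Monotone over a lifetime: once high-risk (history of a large adenoma),
    never downgraded.
    """

    NONE = 0
    LOW_RISK = 1   # history of small adenoma
    HIGH_RISK = 2  # history of large adenoma


class Race(str, enum.Enum):
    BLACK = "Black"
    WHITE = "White"


class Gender(str, enum.Enum):
    MEN = "men"
    WOMEN = "women"


@dataclass(frozen=True)
class Group:
    """Demographic group: race x gender stratum."""

    race: Race
    gender: Gender

    @property
    def label(self) -> str:
        return f"{self.race.value} {self.gender.value}"

    @classmethod
    def parse(cls, text: str) -> "Group":
        parts = text.strip().split()
        if len(parts) != 2:
            raise ValueError(f"unknown group {text!r}; expected e.g. 'White men'")
        race, gender = parts
        try:
            return cls(Race(race), Gender(gender))
        except ValueError as exc:
            raise ValueError(f"unknown group {text!r}") from exc


GROUPS = (
    Group(Race.WHITE, Gender.MEN),
    Group(Race.BLACK, Gender.MEN),
    Group(Race.WHITE, Gender.WOMEN),
    Group(Race.BLACK, Gender.WOMEN),
)


@dataclass
class Person:
    """Scalar view of one simulated individual (the cohort engine stores
    the same fields as parallel arrays)."""

    id: int
    age: int
    state: HealthState = HealthState.NO_LESION
    adenoma_history_tier: AdenomaTier = AdenomaTier.NONE
    years_since_diagnosis: Optional[int] = None

    @property
    def alive(self) -> bool:
        return not self.state.is_dead
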