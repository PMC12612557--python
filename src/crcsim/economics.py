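"""Lifetime costs and quality-adjusted life years from an event ledger.

Accounting conventions: a limited societal perspective (medical plus
patient/escort time costs, no productivity losses); all events are
booked at cycle start with no half-cycle correction; costs and QALYs are
discounted annually to the cohort start age; cancer care is costed in
three phases (initial year at diagnosis, continuing years in between,
terminal year before a CRC death).

The packaged cost and disutility values are synthetic placeholders of
realistic magnitude (the CTC procedure cost, $225, is the published 2024
CMS rate); they are editable config, not asserted estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .natural_history import EventLedger, EventType
from .screening import Modality


@dataclass
class DiscountSpec:
    rate: float = 0.03
    reference_age: int = 40

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.rate}")

    def factor(self, years_from_reference) -> np.ndarray:
        years = np.asarray(years_from_reference, dtype=float)
        if np.any(years < 0):
            raise ValueError("cannot discount events before the reference age")
        return (1.0 + self.rate) ** (-years)


def discount(amount: float, years_from_reference: float, spec: DiscountSpec) -> float:
    """Present value of `amount` accruing `years_from_reference` years out."""
    return float(amount * spec.factor(years_from_reference))


@dataclass
class CostSchedule:
    """Per-event costs in 2024 USD (procedure + bowel prep + patient and
    escort time folded into each per-test figure)."""

    screening: Dict[Modality, float] = field(default_factory=lambda: {
        Modality.COLONOSCOPY: 1520.0,   # procedure 1000 + prep 120 + patient & escort time 400
        Modality.CTC: 545.0,            # procedure 225 (2024 CMS rate) + prep 120 + time 200
        Modality.FIT: 47.0,             # test 24 + one hour patient time 23
        Modality.MTSDNA: 532.0,         # test 509 + one hour patient time 23
    })
    diagnostic_colonoscopy: float = 1620.0
    surveillance_colonoscopy: float = 1620.0
    complication: float = 9750.0
    # cancer-care phase costs are anchored so the discounted lifetime cost
    # per no-screening case is ~$100k, the magnitude published per-1000
    # cost/case tables imply
    cancer_initial: np.ndarray = field(default_factory=lambda: np.array([95000.0, 125000.0, 155000.0, 190000.0]))
    cancer_continuing: np.ndarray = field(default_factory=lambda: np.array([7500.0, 10000.0, 14000.0, 40000.0]))
    cancer_terminal: float = 135000.0

    def __post_init__(self) -> None:
        self.cancer_initial = np.asarray(self.cancer_initial, dtype=float)
        self.cancer_continuing = np.asarray(self.cancer_continuing, dtype=float)
        every = np.concatenate([
            np.array(list(self.screening.values())),
            [self.diagnostic_colonoscopy, self.surveillance_colonoscopy,
             self.complication, self.cancer_terminal],
            self.cancer_initial, self.cancer_continuing,
        ])
        if np.any(every < 0):
            raise ValueError("all costs must be non-negative")

    def to_flat_dict(self) -> dict:
        out = {f"screening.{m.name.lower()}": float(v) for m, v in self.screening.items()}
        out.update({
            "diagnostic_colonoscopy": float(self.diagnostic_colonoscopy),
            "surveillance_colonoscopy": float(self.surveillance_colonoscopy),
            "complication": float(self.complication),
            "cancer_terminal": float(self.cancer_terminal),
        })
        for i, s in enumerate(("I", "II", "III", "IV")):
            out[f"cancer_initial.{s}"] = float(self.cancer_initial[i])
            out[f"cancer_continuing.{s}"] = float(self.cancer_continuing[i])
        return out

    @classmethod
    def from_flat_dict(cls, d) -> "CostSchedule":
        stages = ("I", "II", "III", "IV")
        return cls(
            screening={m: float(d[f"screening.{m.name.lower()}"]) for m in Modality},
            diagnostic_colonoscopy=float(d["diagnostic_colonoscopy"]),
            surveillance_colonoscopy=float(d["surveillance_colonoscopy"]),
            complication=float(d["complication"]),
            cancer_initial=np.array([float(d[f"cancer_initial.{s}"]) for s in stages]),
            cancer_continuing=np.array([float(d[f"cancer_continuing.{s}"]) for s in stages]),
            cancer_terminal=float(d["cancer_terminal"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "CostSchedule":
        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class UtilitySchedule:
    """Baseline utility by age plus one-off and per-year disutility
    decrements (each one-off decrement is magnitude x duration, i.e. the
    QALY loss booked at the event age)."""

    baseline_knots: Dict[int, float] = field(default_factory=lambda: {0: 0.92, 60: 0.88, 70: 0.84, 80: 0.79})
    screening_disutility: Dict[Modality, float] = field(default_factory=lambda: {
        Modality.COLONOSCOPY: 0.0020, Modality.CTC: 0.0010,
        Modality.FIT: 0.0001, Modality.MTSDNA: 0.0001,
    })
    diagnostic_disutility: float = 0.0020
    surveillance_disutility: float = 0.0020
    complication_disutility: float = 0.0120
    cancer_care_decrement: np.ndarray = field(default_factory=lambda: np.array([0.06, 0.10, 0.18, 0.30]))

    def __post_init__(self) -> None:
        self.cancer_care_decrement = np.asarray(self.cancer_care_decrement, dtype=float)
        if any(not 0 <= u <= 1 for u in self.baseline_knots.values()):
            raise ValueError("baseline utilities must lie in [0, 1]")
        every = np.concatenate([
            np.array(list(self.screening_disutility.values())),
            [self.diagnostic_disutility, self.surveillance_disutility, self.complication_disutility],
            self.cancer_care_decrement,
        ])
        if np.any(every < 0):
            raise ValueError("disutility decrements must be >= 0")

    def baseline(self, ages) -> np.ndarray:
        ages = np.asarray(ages)
        knots = sorted(self.baseline_knots.items())
        out = np.full(ages.shape, knots[0][1], dtype=float)
        for age0, u in knots:
            out[ages >= age0] = u
        return out

    def to_flat_dict(self) -> dict:
        out = {f"baseline.{age}": float(u) for age, u in self.baseline_knots.items()}
        out.update({f"screening_disutility.{m.name.lower()}": float(v)
                    for m, v in self.screening_disutility.items()})
        out.update({
            "diagnostic_disutility": float(self.diagnostic_disutility),
            "surveillance_disutility": float(self.surveillance_disutility),
            "complication_disutility": float(self.complication_disutility),
        })
        for i, s in enumerate(("I", "II", "III", "IV")):
            out[f"cancer_care_decrement.{s}"] = float(self.cancer_care_decrement[i])
        return out

    @classmethod
    def from_flat_dict(cls, d) -> "UtilitySchedule":
        stages = ("I", "II", "III", "IV")
        knots = {int(k.split(".")[1]): float(v) for k, v in d.items()
                 if k.startswith("baseline.")}
        return cls(
            baseline_knots=knots,
            screening_disutility={m: float(d[f"screening_disutility.{m.name.lower()}"])
                                  for m in Modality},
            diagnostic_disutility=float(d["diagnostic_disutility"]),
            surveillance_disutility=float(d["surveillance_disutility"]),
            complication_disutility=float(d["complication_disutility"]),
            cancer_care_decrement=np.array(
                [float(d[f"cancer_care_decrement.{s}"]) for s in stages]),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "UtilitySchedule":
        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))

    def zeroed(self) -> "UtilitySchedule":
        """Copy with every decrement zero and baseline utility 1 (QALYs
        then equal discounted life years)."""
        return UtilitySchedule(
            baseline_knots={0: 1.0},
            screening_disutility={m: 0.0 for m in Modality},
            diagnostic_disutility=0.0, surveillance_disutility=0.0,
            complication_disutility=0.0, cancer_care_decrement=np.zeros(4),
        )


@dataclass
class StrategyOutcome:
    """Per-1000 discounted outcomes of one strategy for one cohort."""

    strategy: str
    group: str
    n: int
    cost: float                     # USD per 1000 persons
    qaly: float                     # discounted QALYs per 1000
    qalyg: Optional[float]          # QALYs gained vs no screening, per 1000
    life_years: float               # discounted life years per 1000
    crc_cases: float                # per 1000
    screening_tests: float
    noncolonoscopy_tests: float
    screening_colonoscopies: float
    all_colonoscopies: float
    uptake_by_75: float             # fraction of cohort ever initiated

    def as_row(self) -> dict:
        return {
            "strategy": self.strategy, "group": self.group, "n": self.n,
            "crc_cases_per_1000": self.crc_cases,
            "screening_tests_per_1000": self.screening_tests,
            "noncolonoscopy_tests_per_1000": self.noncolonoscopy_tests,
            "screening_colonoscopies_per_1000": self.screening_colonoscopies,
            "all_colonoscopies_per_1000": self.all_colonoscopies,
            "uptake_by_75_pct": 100.0 * self.uptake_by_75,
            "qalyg_per_1000": self.qalyg if self.qalyg is not None else 0.0,
            "cost_per_1000_million_usd": self.cost / 1e6,
        }


def accumulate_outcomes(
    ledger: EventLedger,
    costs: CostSchedule,
    utilities: UtilitySchedule,
    spec: DiscountSpec,
    baseline: Optional[StrategyOutcome] = None,
) -> StrategyOutcome:
    """Convert an event ledger into a per-1000 discounted StrategyOutcome.

    `baseline` is the seed-matched no-screening outcome of the identical
    cohort; when given, QALYG is the paired difference in QALYs.
    """
    if baseline is not None and baseline.n != ledger.n:
        raise ValueError(
            f"QALYG pairing requires identical cohort sizes (got {ledger.n} vs {baseline.n})"
        )
    frame = ledger.frame
    ref = ledger.start_age
    scale = 1000.0 / ledger.n
    v = 1.0 / (1.0 + spec.rate)

    # --- event-level costs and disutilities ---
    total_cost = 0.0
    total_disutility = 0.0
    if len(frame):
        years = frame["age"].to_numpy(dtype=float) - ref
        disc = spec.factor(years)
        ev = frame["event"].to_numpy()
        detail = frame["detail"].to_numpy()
        cost_per_event = np.zeros(len(frame))
        dis_per_event = np.zeros(len(frame))
        is_screen = ev == EventType.SCREEN.value
        for m in Modality:
            sel = is_screen & (detail == int(m))
            cost_per_event[sel] = costs.screening[m]
            dis_per_event[sel] = utilities.screening_disutility[m]
        sel = ev == EventType.DIAGNOSTIC_COLONOSCOPY.value
        cost_per_event[sel] = costs.diagnostic_colonoscopy
        dis_per_event[sel] = utilities.diagnostic_disutility
        sel = ev == EventType.SURVEILLANCE_COLONOSCOPY.value
        cost_per_event[sel] = costs.surveillance_colonoscopy
        dis_per_event[sel] = utilities.surveillance_disutility
        sel = ev == EventType.COMPLICATION.value
        cost_per_event[sel] = costs.complication
        dis_per_event[sel] = utilities.complication_disutility
        total_cost += float((cost_per_event * disc).sum())
        total_disutility += float((dis_per_event * disc).sum())

    # --- per-person life years, baseline QALYs, cancer care ---
    persons = ledger.person_table()
    death_age = persons["death_age"].to_numpy()
    end_age = np.where(np.isnan(death_age), ledger.max_age - 1, death_age).astype(int)
    # discounted baseline utility accrues for each year alive, ref..end_age
    ages = np.arange(ref, ledger.max_age)
    disc_by_age = spec.factor(ages - ref)
    cum_ly = np.concatenate([[0.0], np.cumsum(disc_by_age)])
    cum_qaly = np.concatenate([[0.0], np.cumsum(utilities.baseline(ages) * disc_by_age)])
    k_end = end_age - ref + 1
    life_years = float(cum_ly[k_end].sum())
    qaly = float(cum_qaly[k_end].sum())

    dx = persons["dx_stage"].to_numpy() > 0
    if dx.any():
        stage_ix = persons["dx_stage"].to_numpy()[dx] - 1
        dx_age = persons["dx_age"].to_numpy()[dx].astype(int)
        p_end = end_age[dx]
        dx_disc = spec.factor(dx_age - ref)
        total_cost += float((costs.cancer_initial[stage_ix] * dx_disc).sum())
        # continuing-care years dx_age+1 .. end (discount geometric series)
        n_cont = np.maximum(p_end - dx_age, 0)
        if spec.rate > 0:
            series = dx_disc * v * (1.0 - v**n_cont) / (1.0 - v)
        else:
            series = n_cont.astype(float)
        total_cost += float((costs.cancer_continuing[stage_ix] * series).sum())
        # terminal phase replaces continuing care in a CRC death year
        crc_death = persons["death_cause"].to_numpy()[dx] == EventType.DEATH_CRC.value
        if crc_death.any():
            t_disc = spec.factor(p_end[crc_death] - ref)
            extra = costs.cancer_terminal - costs.cancer_continuing[stage_ix[crc_death]]
            total_cost += float((extra * t_disc).sum())
        # per-year cancer-care disutility from diagnosis year through end
        n_care = p_end - dx_age + 1
        if spec.rate > 0:
            care_series = dx_disc * (1.0 - v**n_care) / (1.0 - v)
        else:
            care_series = n_care.astype(float)
        total_disutility += float(
            (utilities.cancer_care_decrement[stage_ix] * care_series).sum()
        )

    qaly -= total_disutility

    counts = frame["event"].value_counts() if len(frame) else {}
    n_screen = int(counts.get(EventType.SCREEN.value, 0))
    screen_events = ledger.events(EventType.SCREEN)
    n_screen_colo = int((screen_events["detail"] == int(Modality.COLONOSCOPY)).sum()) if n_screen else 0
    n_diag = int(counts.get(EventType.DIAGNOSTIC_COLONOSCOPY.value, 0))
    n_surv = int(counts.get(EventType.SURVEILLANCE_COLONOSCOPY.value, 0))
    initiated = ledger.events(EventType.INITIATED)["person_id"].nunique()

    qaly_scaled = qaly * scale
    return StrategyOutcome(
        strategy=ledger.strategy, group=ledger.group, n=ledger.n,
        cost=total_cost * scale,
        qaly=qaly_scaled,
        qalyg=None if baseline is None else qaly_scaled - baseline.qaly,
        life_years=life_years * scale,
        crc_cases=int(dx.sum()) * scale,
        screening_tests=n_screen * scale,
        noncolonoscopy_tests=(n_screen - n_screen_colo) * scale,
        screening_colonoscopies=n_screen_colo * scale,
        all_colonoscopies=(n_screen_colo + n_diag + n_surv) * scale,
        uptake_by_75=initiated / ledger.n,
    )
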