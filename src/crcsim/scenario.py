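"""Wiring layer: one demographic group's full model configuration, the
strategy runner, and the calibration summary statistics.

A :class:`Scenario` bundles the natural-history parameters, behavioral
inputs, cost/utility schedules and discounting for one race-gender
group.  Strategies replay the same initialized cohort under common
random numbers, and QALYG/cost outcomes are paired against the
seed-matched no-screening run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import (
    CostSchedule,
    DiscountSpec,
    StrategyOutcome,
    UtilitySchedule,
    accumulate_outcomes,
)
from .natural_history import (
    Cohort,
    EventLedger,
    EventType,
    ScreeningPolicy,
    initialize_cohort,
    simulate_lifetime,
)
from .params import DiseaseParams
from .screening import (
    AdherenceProfile,
    Modality,
    StrategyRule,
    derive_strategy_profile,
)
from .states import Group
from .tables import (
    REPEAT_OR_CTC_BLACK,
    RR_INITIAL,
    TEST_PERFORMANCE,
    status_quo_profile,
)

STRATEGY_ORDER = ("no_screening", "status_quo", "ctc_only",
                  "colonoscopy_only", "fit_only", "mtsdna_only")

INCIDENCE_BANDS = ((45, 54), (55, 64), (65, 74), (75, 84))
PREVALENCE_AGES = (50, 60, 70)
STAGE_LABELS = ("I", "II", "III", "IV")


@dataclass
class Scenario:
    """Full model configuration for one demographic group."""

    group: Group
    disease: DiseaseParams
    profile: AdherenceProfile
    performance: Dict[Modality, "object"] = field(
        default_factory=lambda: copy.deepcopy(TEST_PERFORMANCE))
    costs: CostSchedule = field(default_factory=CostSchedule)
    utilities: UtilitySchedule = field(default_factory=UtilitySchedule)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    multipliers: Dict[str, float] = field(default_factory=lambda: dict(RR_INITIAL))
    repeat_or_ctc_black: float = REPEAT_OR_CTC_BLACK
    complication_rate: float = 0.002
    origin_split_colonoscopy: float = 0.85
    start_age: int = 40
    seeding_age: int = 20
    max_age: int = 100

    @classmethod
    def default(cls, group: Group, disease: DiseaseParams) -> "Scenario":
        return cls(group=group, disease=disease, profile=status_quo_profile(group))

    def copy(self) -> "Scenario":
        return copy.deepcopy(self)

    # -- strategy plumbing -----------------------------------------------------

    def rule_for(self, strategy: str) -> StrategyRule:
        m = self.multipliers
        rules = {
            "no_screening": StrategyRule("no_screening", None, screens=False),
            "status_quo": StrategyRule("status_quo", None, switching_allowed=True),
            "ctc_only": StrategyRule("ctc_only", Modality.CTC,
                                     m["ctc_vs_colonoscopy"], m["ctc_vs_fit"],
                                     "colonoscopy", self.repeat_or_ctc_black),
            "colonoscopy_only": StrategyRule("colonoscopy_only", Modality.COLONOSCOPY,
                                             1.0, m["colonoscopy_vs_fit"], "colonoscopy"),
            "fit_only": StrategyRule("fit_only", Modality.FIT,
                                     m["fit_vs_colonoscopy"], 1.0, "fit"),
            "mtsdna_only": StrategyRule("mtsdna_only", Modality.MTSDNA,
                                        m["fit_vs_colonoscopy"], 1.0, "fit"),
        }
        try:
            return rules[strategy]
        except KeyError:
            raise ValueError(f"unknown strategy {strategy!r}") from None

    def policy_for(self, strategy: str) -> ScreeningPolicy:
        rule = self.rule_for(strategy)
        profile = None if not rule.screens else derive_strategy_profile(self.profile, rule, self.group)
        return ScreeningPolicy(rule, profile, dict(self.performance), self.complication_rate)

    # -- simulation ------------------------------------------------------------

    def make_cohort(self, n: int, seed: int) -> Cohort:
        return initialize_cohort(
            n, self.group, self.start_age, self.disease, seed,
            seeding_age=self.seeding_age,
            origin_split_colonoscopy=self.origin_split_colonoscopy,
        )

    def run(self, strategy: str, n: int, seed: int,
            cohort: Optional[Cohort] = None, probe_ages: Sequence[int] = ()) -> EventLedger:
        if cohort is None:
            cohort = self.make_cohort(n, seed)
        return simulate_lifetime(cohort, self.disease, self.policy_for(strategy),
                                 self.max_age, probe_ages=probe_ages)

    def outcomes(self, strategies: Sequence[str], n: int, seed: int) -> List[StrategyOutcome]:
        """Run strategies on one shared cohort; QALYG paired vs no screening."""
        cohort = self.make_cohort(n, seed)
        base_ledger = self.run("no_screening", n, seed, cohort=cohort)
        baseline = accumulate_outcomes(base_ledger, self.costs, self.utilities, self.discount)
        baseline.qalyg = 0.0
        results = []
        for strat in strategies:
            if strat == "no_screening":
                results.append(baseline)
                continue
            ledger = self.run(strat, n, seed, cohort=cohort)
            results.append(accumulate_outcomes(ledger, self.costs, self.utilities,
                                               self.discount, baseline=baseline))
        return results

    def outcomes_frame(self, strategies: Sequence[str], n: int, seed: int) -> pd.DataFrame:
        rows = [o.as_row() for o in self.outcomes(strategies, n, seed)]
        df = pd.DataFrame(rows)
        df["cost"] = df["cost_per_1000_million_usd"] * 1e6
        df["qalyg"] = df["qalyg_per_1000"]
        return df

    # -- parameter addressing for sensitivity analyses -------------------------

    def with_param(self, path: str, value: float) -> "Scenario":
        """Return a copy with one addressable parameter replaced.

        Paths: performance.<modality>.<field>, multipliers.<pair>,
        followup.<modality>, surveillance.<low_risk|high_risk>,
        repeat_or_ctc_black, complication_rate, costs.screening.<modality>,
        costs.<field>, discount.rate.
        """
        return self.with_params({path: value})

    def with_params(self, updates: Mapping[str, float]) -> "Scenario":
        """Copy once, then apply many addressable-parameter updates."""
        out = self.copy()
        for path, value in updates.items():
            out._set_param(path, value)
        return out

    def _set_param(self, path: str, value: float) -> None:
        out = self
        parts = path.split(".")
        head = parts[0]
        if head == "performance":
            mod = Modality[parts[1].upper()]
            perf = out.performance[mod]
            if not hasattr(perf, parts[2]):
                raise KeyError(path)
            setattr(perf, parts[2], value)
        elif head == "multipliers":
            if parts[1] not in out.multipliers:
                raise KeyError(path)
            out.multipliers[parts[1]] = value
        elif head == "followup":
            out.profile.followup[Modality[parts[1].upper()]] = value
        elif head == "surveillance":
            low, high = out.profile.surveillance
            if parts[1] == "low_risk":
                out.profile.surveillance = (value, high)
            elif parts[1] == "high_risk":
                out.profile.surveillance = (low, value)
            else:
                raise KeyError(path)
        elif head == "repeat_or_ctc_black":
            out.repeat_or_ctc_black = value
        elif head == "complication_rate":
            out.complication_rate = value
        elif head == "costs":
            if parts[1] == "screening":
                out.costs.screening[Modality[parts[2].upper()]] = value
            elif parts[1] in ("cancer_initial", "cancer_continuing"):
                getattr(out.costs, parts[1])[STAGE_LABELS.index(parts[2])] = value
            elif hasattr(out.costs, parts[1]):
                setattr(out.costs, parts[1], value)
            else:
                raise KeyError(path)
        elif head == "discount":
            out.discount = DiscountSpec(rate=value, reference_age=out.discount.reference_age)
        else:
            raise KeyError(path)


# -- calibration summaries -----------------------------------------------------


def apply_calibration_params(base: DiseaseParams, params: Mapping[str, float]) -> DiseaseParams:
    """Overlay the free calibrated parameters on a base parameter set.

    Free parameters: ``onset_scale`` and ``detection_scale`` multiply the
    age-banded onset and per-stage clinical-detection schedules; the three
    growth/malignancy rates are set directly.
    """
    return base.with_updates(
        adenoma_onset=np.clip(base.adenoma_onset * params.get("onset_scale", 1.0), 0, 1),
        growth_dim_to_small=params.get("growth_dim_to_small", base.growth_dim_to_small),
        growth_small_to_large=params.get("growth_small_to_large", base.growth_small_to_large),
        large_to_preclinical=params.get("large_to_preclinical", base.large_to_preclinical),
        clinical_detection=np.clip(base.clinical_detection * params.get("detection_scale", 1.0), 0, 1),
    )


def summarize_for_targets(
    scenario: Scenario, n: int = 20_000, seed: int = 0
) -> Dict[str, float]:
    """Every target-named statistic from one status-quo simulation of the
    scenario's parameters (plus a screening-off replay for the
    non-screening-era stage distribution).

    Families: age-banded clinical CRC incidence per 100,000 person-years,
    stage distribution at diagnosis in the screening and non-screening
    eras, cross-sectional adenoma prevalence, polypectomy size mix, and
    screening-utilization proportions at 65.
    """
    cohort = scenario.make_cohort(n, seed)
    led_sq = simulate_lifetime(cohort, scenario.disease, scenario.policy_for("status_quo"),
                               scenario.max_age, probe_ages=PREVALENCE_AGES)
    led_ns = simulate_lifetime(cohort, scenario.disease, scenario.policy_for("no_screening"),
                               scenario.max_age)
    out: Dict[str, float] = {}

    persons = led_sq.person_table()
    death_age = persons["death_age"].to_numpy()
    end_age = np.where(np.isnan(death_age), scenario.max_age - 1, death_age)
    dx = led_sq.events(EventType.CRC_DIAGNOSIS).sort_values("age").drop_duplicates("person_id")
    dx_age = dx["age"].to_numpy()
    for lo, hi in INCIDENCE_BANDS:
        py = float(np.clip(np.minimum(end_age, hi) - lo + 1, 0, None).sum())
        cases = int(((dx_age >= lo) & (dx_age <= hi)).sum())
        out[f"incidence_{lo}_{hi}"] = 1e5 * cases / py if py > 0 else 0.0

    for label, ledger in (("screenera", led_sq), ("noscreen", led_ns)):
        d = ledger.events(EventType.CRC_DIAGNOSIS)
        total = max(len(d), 1)
        shares = d["detail"].value_counts()
        for k, s in enumerate(STAGE_LABELS, start=1):
            out[f"stage_{label}_{s}"] = float(shares.get(k, 0)) / total

    for age in PREVALENCE_AGES:
        probe = led_sq.probes[age]
        alive_n = max(probe["alive"], 1)
        out[f"adenoma_prev_{age}"] = probe["adenoma"] / alive_n
        out[f"adenoma_small_prev_{age}"] = probe["adenoma_small"] / alive_n
        out[f"adenoma_large_prev_{age}"] = probe["adenoma_large"] / alive_n

    polyps = led_sq.events(EventType.POLYPECTOMY)["detail"]
    n_polyp = max(len(polyps), 1)
    out["polyp_share_small"] = float((polyps == 2).sum()) / n_polyp
    out["polyp_share_large"] = float((polyps == 3).sum()) / n_polyp

    # screening utilization at 65 among those alive at 65
    alive65 = np.isnan(death_age) | (death_age >= 65)
    n65 = max(int(alive65.sum()), 1)
    frame = led_sq.frame
    pre65 = frame[frame["age"] < 65]
    screens = pre65[pre65["event"] == EventType.SCREEN.value]
    colo_events = set(screens.loc[screens["detail"] == int(Modality.COLONOSCOPY), "person_id"])
    colo_events |= set(pre65.loc[pre65["event"].isin(
        [EventType.DIAGNOSTIC_COLONOSCOPY.value, EventType.SURVEILLANCE_COLONOSCOPY.value]
    ), "person_id"])
    stool_people = set(screens.loc[screens["detail"].isin(
        [int(Modality.FIT), int(Modality.MTSDNA)]), "person_id"])
    alive_ids = set(np.flatnonzero(alive65))
    out["ever_colonoscopy_65"] = len(colo_events & alive_ids) / n65
    out["ever_stool_65"] = len(stool_people & alive_ids) / n65
    out["ever_both_65"] = len(colo_events & stool_people & alive_ids) / n65
    recent = set(frame.loc[(frame["event"] == EventType.SCREEN.value)
                           & (frame["age"] >= 62) & (frame["age"] < 65), "person_id"])
    out["recent_screen_65"] = len(recent & alive_ids) / n65
    return out


def calibration_summary_fn(scenario: Scenario, n: int = 20_000, seed: int = 0):
    """Candidate-parameter objective hook: overlays the free parameters on
    the scenario's base disease params and summarizes (common random
    numbers: same seed for every candidate)."""

    def summarize(params: Mapping[str, float]) -> Dict[str, float]:
        sc = scenario.copy()
        sc.disease = apply_calibration_params(scenario.disease, params)
        return summarize_for_targets(sc, n=n, seed=seed)

    return summarize
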