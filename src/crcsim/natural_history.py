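"""Annual-cycle microsimulation of CRC natural history and screening.

One simulated person occupies exactly one health state per yearly cycle
and makes at most one forward transition along the adenoma–carcinoma
chain per cycle.  The engine is vectorized over a cohort: every person's
fields live in parallel numpy arrays, and each stochastic decision draws
a counter-based uniform addressed by (seed, person, age, channel), so
results are bit-identical under any person ordering and strategies
compared under one seed share common random numbers.

Within-cycle event order (fixed for determinism):

1. screening / surveillance decision and testing,
2. treatment effects of polypectomy or diagnosis,
3. disease progression (one step; preclinical detection competes with
   stage progression, detection evaluated first),
4. mortality (CRC excess death for clinical stages within the survival
   horizon, then other-cause death for every living state).

Cohort initialization simulates from a lesion-free state at a seeding
age (default 20) forward to the start age with screening disabled and
mortality suspended, so everyone is alive at the start age; the rare
person who would reach clinical cancer during burn-in is reset to the
lesion-free state (the cohort represents average-risk adults with no
CRC history).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import Channel, uniform
from .params import DiseaseParams, onset_band_index
from .screening import (
    SCREENING_START_AGE,
    SCREENING_STOP_AGE,
    AdherenceProfile,
    Modality,
    StrategyRule,
    TestPerformance,
    initial_age_band,
)
from .states import AdenomaTier, Group, HealthState, Person

_NEVER = np.int16(30000)
_MOD_INTERVALS = np.array([10, 5, 1, 3], dtype=np.int16)  # by Modality code


class EventType(str, enum.Enum):
    INITIATED = "initiated"
    SCREEN = "screen"
    DIAGNOSTIC_COLONOSCOPY = "diagnostic_colonoscopy"
    SURVEILLANCE_COLONOSCOPY = "surveillance_colonoscopy"
    POLYPECTOMY = "polypectomy"
    CRC_DIAGNOSIS = "crc_diagnosis"
    COMPLICATION = "complication"
    DEATH_CRC = "death_crc"
    DEATH_OTHER = "death_other"
    ALIVE_AT_END = "alive_at_end"


@dataclass
class ScreeningPolicy:
    """Bundle of the behavioral inputs the engine needs for one strategy."""

    rule: StrategyRule
    profile: Optional[AdherenceProfile]
    performance: Dict[Modality, TestPerformance] = field(default_factory=dict)
    complication_rate: float = 0.002  # per colonoscopy, any type

    def __post_init__(self) -> None:
        self._thresholds: Dict[int, np.ndarray] = {}
        for mod, perf in self.performance.items():
            # positive-test probability by pre-clinical health-state code
            t = np.zeros(8)
            t[HealthState.NO_LESION] = 1.0 - perf.specificity
            t[HealthState.ADENOMA_DIMINUTIVE] = perf.sens_diminutive
            t[HealthState.ADENOMA_SMALL] = perf.sens_small
            t[HealthState.ADENOMA_LARGE] = perf.sens_large
            t[4:8] = perf.sens_crc
            self._thresholds[int(mod)] = t

    def positive_threshold(self, modality_codes: np.ndarray, states: np.ndarray) -> np.ndarray:
        out = np.empty(len(states))
        for mod, t in self._thresholds.items():
            sel = modality_codes == mod
            if sel.any():
                out[sel] = t[states[sel]]
        return out

    def colonoscopy_sensitivity(self, states: np.ndarray) -> np.ndarray:
        t = self._thresholds[int(Modality.COLONOSCOPY)]
        return t[states]


NO_SCREENING = ScreeningPolicy(StrategyRule("no_screening", None, screens=False), None)


class _Recorder:
    __slots__ = ("pids", "ages", "codes", "details")

    def __init__(self) -> None:
        self.pids, self.ages, self.codes, self.details = [], [], [], []

    def add(self, pids: np.ndarray, age: int, event: EventType, detail=None) -> None:
        if len(pids) == 0:
            return
        self.pids.append(np.asarray(pids, dtype=np.int64))
        self.ages.append(np.full(len(pids), age, dtype=np.int16))
        self.codes.append(np.full(len(pids), event.value, dtype=object))
        if detail is None:
            self.details.append(np.full(len(pids), -1, dtype=np.int16))
        else:
            self.details.append(np.broadcast_to(np.asarray(detail, dtype=np.int16), (len(pids),)).copy())

    def to_frame(self) -> pd.DataFrame:
        if not self.pids:
            return pd.DataFrame(
                {"person_id": pd.Series(dtype=np.int64), "age": pd.Series(dtype=np.int16),
                 "event": pd.Series(dtype=object), "detail": pd.Series(dtype=np.int16)}
            )
        return pd.DataFrame(
            {"person_id": np.concatenate(self.pids), "age": np.concatenate(self.ages),
             "event": np.concatenate(self.codes), "detail": np.concatenate(self.details)}
        )


@dataclass
class EventLedger:
    """Per-person timed event log of one cohort simulation."""

    frame: pd.DataFrame
    n: int
    start_age: int
    max_age: int
    group: str = ""
    strategy: str = ""
    probes: Dict[int, Dict[str, int]] = field(default_factory=dict)

    def events(self, *types: EventType) -> pd.DataFrame:
        labels = [t.value for t in types]
        return self.frame[self.frame["event"].isin(labels)]

    def count(self, *types: EventType) -> int:
        return int(len(self.events(*types)))

    def conservation_ok(self) -> bool:
        """Every person ends dead or alive at max_age, exactly once."""
        terminal = self.events(EventType.DEATH_CRC, EventType.DEATH_OTHER, EventType.ALIVE_AT_END)
        return len(terminal) == self.n and terminal["person_id"].nunique() == self.n

    def person_table(self) -> pd.DataFrame:
        """One row per person: death age/cause, first CRC diagnosis, life years.

        A person alive at the start of a cycle accrues that full year, so
        life years run from start_age through the death-cycle age inclusive
        (survivors accrue max_age - start_age years).
        """
        out = pd.DataFrame(index=pd.RangeIndex(self.n, name="person_id"))
        out["death_age"] = np.nan
        out["death_cause"] = ""
        for ev in (EventType.DEATH_CRC, EventType.DEATH_OTHER):
            d = self.events(ev)
            out.loc[d["person_id"].to_numpy(), "death_age"] = d["age"].to_numpy(dtype=float)
            out.loc[d["person_id"].to_numpy(), "death_cause"] = ev.value
        dx = self.events(EventType.CRC_DIAGNOSIS).sort_values("age").drop_duplicates("person_id")
        out["dx_age"] = np.nan
        out["dx_stage"] = 0
        out.loc[dx["person_id"].to_numpy(), "dx_age"] = dx["age"].to_numpy(dtype=float)
        out.loc[dx["person_id"].to_numpy(), "dx_stage"] = dx["detail"].to_numpy()
        ly = np.where(np.isnan(out["death_age"]), self.max_age - self.start_age,
                      out["death_age"] - self.start_age + 1)
        out["life_years"] = ly
        return out

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, n: int, start_age: int, max_age: int, **meta) -> "EventLedger":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame, n=n, start_age=start_age, max_age=max_age, **meta)


@dataclass
class Cohort:
    """Vectorized cohort: one entry per person in each parallel array."""

    group: Group
    age: int
    seed: int
    pid: np.ndarray
    state: np.ndarray
    tier: np.ndarray
    years_since_dx: np.ndarray
    origin: np.ndarray          # 0 = colonoscopy-origin, 1 = FIT-origin
    current_modality: np.ndarray
    initiated: np.ndarray
    next_due: np.ndarray
    surveillance_due: np.ndarray

    def __len__(self) -> int:
        return len(self.pid)

    @property
    def alive(self) -> np.ndarray:
        return self.state < HealthState.DEAD_CRC

    def copy(self) -> "Cohort":
        return Cohort(
            self.group, self.age, self.seed,
            *(a.copy() for a in (self.pid, self.state, self.tier, self.years_since_dx,
                                 self.origin, self.current_modality, self.initiated,
                                 self.next_due, self.surveillance_due)),
        )

    def permuted(self, perm: np.ndarray) -> "Cohort":
        """Reorder persons; draws are keyed by person id, so simulated
        summary statistics are invariant to this."""
        out = self.copy()
        for name in ("pid", "state", "tier", "years_since_dx", "origin",
                     "current_modality", "initiated", "next_due", "surveillance_due"):
            setattr(out, name, getattr(self, name)[perm])
        return out

    def persons(self) -> list:
        return [
            Person(int(self.pid[i]), self.age, HealthState(int(self.state[i])),
                   AdenomaTier(int(self.tier[i])),
                   None if self.years_since_dx[i] < 0 else int(self.years_since_dx[i]))
            for i in range(len(self))
        ]


def initialize_cohort(
    n: int,
    group: Group,
    start_age: int = 40,
    params: Optional[DiseaseParams] = None,
    seed: int = 0,
    *,
    seeding_age: int = 20,
    origin_split_colonoscopy: float = 0.85,
) -> Cohort:
    """Create a cohort aged `start_age` whose disease states reflect steady
    accumulation from a lesion-free state at `seeding_age`, with screening
    disabled and survival to `start_age` conditioned on."""
    if n <= 0:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if not isinstance(group, Group):
        group = Group.parse(str(group))
    if params is None:
        raise ValueError("params is required")
    pid = np.arange(n, dtype=np.uint64)
    origin = (uniform(seed, pid, 0, Channel.ORIGIN) >= origin_split_colonoscopy).astype(np.int8)
    current = np.where(origin == 1, np.int8(Modality.FIT), np.int8(Modality.COLONOSCOPY))
    coh = Cohort(
        group=group, age=seeding_age, seed=seed, pid=pid,
        state=np.zeros(n, dtype=np.int8),
        tier=np.zeros(n, dtype=np.int8),
        years_since_dx=np.full(n, -1, dtype=np.int16),
        origin=origin, current_modality=current.astype(np.int8),
        initiated=np.zeros(n, dtype=bool),
        next_due=np.full(n, _NEVER, dtype=np.int16),
        surveillance_due=np.full(n, _NEVER, dtype=np.int16),
    )
    rec = _Recorder()
    while coh.age < start_age:
        _advance_cycle(coh, params, NO_SCREENING, rec, burn_in=True)
    return coh


def step_year(person: Person, params: DiseaseParams, rng) -> Person:
    """Advance one person one annual cycle of progression and mortality.

    Scalar counterpart of the cohort kernel (no screening): at most one
    forward transition along the chain, clinical detection before stage
    progression, CRC excess death before other-cause death.
    """
    if not person.alive:
        raise ValueError("step_year requires a living person; filter the dead upstream")
    s = person.state
    if s is HealthState.NO_LESION:
        if rng.random() < params.adenoma_onset[int(onset_band_index(person.age))]:
            person.state = HealthState.ADENOMA_DIMINUTIVE
    elif s is HealthState.ADENOMA_DIMINUTIVE:
        if rng.random() < params.growth_dim_to_small:
            person.state = HealthState.ADENOMA_SMALL
    elif s is HealthState.ADENOMA_SMALL:
        if rng.random() < params.growth_small_to_large:
            person.state = HealthState.ADENOMA_LARGE
    elif s is HealthState.ADENOMA_LARGE:
        if rng.random() < params.large_to_preclinical:
            person.state = HealthState.PRECLINICAL_CRC_I
    elif s.is_preclinical:
        k = s.stage - 1
        if rng.random() < params.clinical_detection[k]:
            person.state = HealthState(int(s) + 4)
            person.years_since_diagnosis = 0
        elif k < 3 and rng.random() < params.stage_progression[k]:
            person.state = HealthState(int(s) + 1)
    elif s.is_clinical:
        person.years_since_diagnosis = (person.years_since_diagnosis or 0) + 1
    if person.state.is_clinical and (person.years_since_diagnosis or 0) < params.survival_horizon:
        if rng.random() < params.crc_mortality[person.state.stage - 1]:
            person.state = HealthState.DEAD_CRC
    if person.alive and rng.random() < params.other_cause_mortality[person.age]:
        person.state = HealthState.DEAD_OTHER
    person.age += 1
    return person


def simulate_lifetime(
    cohort: Cohort,
    params: DiseaseParams,
    policy: ScreeningPolicy = NO_SCREENING,
    max_age: int = 100,
    probe_ages: Sequence[int] = (),
) -> EventLedger:
    """Run a cohort from its current age to max_age under one policy.

    The input cohort is not mutated, so the same initialized cohort can be
    replayed under every strategy with common random numbers.  `probe_ages`
    snapshots cross-sectional state counts (alive, any adenoma, preclinical
    cancer) at the start of those cycles, e.g. for prevalence targets.
    """
    if max_age < cohort.age:
        raise ValueError(f"max_age {max_age} below cohort age {cohort.age}")
    coh = cohort.copy()
    start_age = coh.age
    rec = _Recorder()
    probes: Dict[int, Dict[str, int]] = {}
    probe_set = set(int(a) for a in probe_ages)
    while coh.age < max_age:
        if coh.age in probe_set:
            alive = coh.alive
            st = coh.state
            probes[coh.age] = {
                "alive": int(alive.sum()),
                "adenoma": int((alive & (st >= HealthState.ADENOMA_DIMINUTIVE)
                                & (st <= HealthState.ADENOMA_LARGE)).sum()),
                "adenoma_diminutive": int((alive & (st == HealthState.ADENOMA_DIMINUTIVE)).sum()),
                "adenoma_small": int((alive & (st == HealthState.ADENOMA_SMALL)).sum()),
                "adenoma_large": int((alive & (st == HealthState.ADENOMA_LARGE)).sum()),
                "preclinical": int((alive & (st >= HealthState.PRECLINICAL_CRC_I)
                                    & (st <= HealthState.PRECLINICAL_CRC_IV)).sum()),
            }
        _advance_cycle(coh, params, policy, rec, burn_in=False)
    rec.add(coh.pid[coh.alive], max_age, EventType.ALIVE_AT_END)
    return EventLedger(
        frame=rec.to_frame(), n=len(coh), start_age=start_age, max_age=max_age,
        group=coh.group.label, strategy=policy.rule.name, probes=probes,
    )


def _advance_cycle(coh: Cohort, params: DiseaseParams, policy: ScreeningPolicy,
                   rec: _Recorder, burn_in: bool) -> None:
    age = coh.age
    seed = coh.seed
    pid = coh.pid
    state = coh.state
    alive = state < HealthState.DEAD_CRC
    was_clinical = (state >= HealthState.CLINICAL_CRC_I) & alive

    screening_on = (
        not burn_in
        and policy.rule.screens
        and policy.profile is not None
        and SCREENING_START_AGE <= age <= SCREENING_STOP_AGE
    )
    if screening_on:
        _screening_block(coh, policy, rec)
        state = coh.state  # may have been rewritten by resolution
        alive = state < HealthState.DEAD_CRC

    # --- disease progression: at most one forward step ---
    up = uniform(seed, pid, age, Channel.PROGRESS)
    ud = uniform(seed, pid, age, Channel.CLINICAL_DETECT)
    nxt = state.copy()
    onset_p = params.adenoma_onset[int(onset_band_index(age))]
    nxt[alive & (state == HealthState.NO_LESION) & (up < onset_p)] = HealthState.ADENOMA_DIMINUTIVE
    nxt[alive & (state == HealthState.ADENOMA_DIMINUTIVE) & (up < params.growth_dim_to_small)] = HealthState.ADENOMA_SMALL
    nxt[alive & (state == HealthState.ADENOMA_SMALL) & (up < params.growth_small_to_large)] = HealthState.ADENOMA_LARGE
    nxt[alive & (state == HealthState.ADENOMA_LARGE) & (up < params.large_to_preclinical)] = HealthState.PRECLINICAL_CRC_I
    for k in range(4):
        pre = HealthState.PRECLINICAL_CRC_I + k
        here = alive & (state == pre)
        detect = here & (ud < params.clinical_detection[k])
        if detect.any():
            nxt[detect] = pre + 4
            coh.years_since_dx[detect] = 0
            if not burn_in:
                rec.add(pid[detect], age, EventType.CRC_DIAGNOSIS, k + 1)
        if k < 3:
            prog = here & ~detect & (up < params.stage_progression[k])
            nxt[prog] = pre + 1
    coh.years_since_dx[was_clinical] += 1

    # --- mortality ---
    if burn_in:
        # survival to start age is conditioned on; clinical cancer during
        # burn-in is excluded from the average-risk cohort
        entered_clinical = (nxt >= HealthState.CLINICAL_CRC_I) & (nxt < HealthState.DEAD_CRC)
        nxt[entered_clinical] = HealthState.NO_LESION
        coh.years_since_dx[entered_clinical] = -1
    else:
        clin = (nxt >= HealthState.CLINICAL_CRC_I) & (nxt < HealthState.DEAD_CRC)
        excess = clin & (coh.years_since_dx < params.survival_horizon)
        if excess.any():
            ucd = uniform(seed, pid, age, Channel.CRC_DEATH)
            stage_ix = np.clip(nxt - HealthState.CLINICAL_CRC_I, 0, 3)
            dead_crc = excess & (ucd < params.crc_mortality[stage_ix])
            if dead_crc.any():
                nxt[dead_crc] = HealthState.DEAD_CRC
                rec.add(pid[dead_crc], age, EventType.DEATH_CRC)
        still = alive & (nxt < HealthState.DEAD_CRC)
        uoc = uniform(seed, pid, age, Channel.OTHER_DEATH)
        dead_oc = still & (uoc < params.other_cause_mortality[age])
        if dead_oc.any():
            nxt[dead_oc] = HealthState.DEAD_OTHER
            rec.add(pid[dead_oc], age, EventType.DEATH_OTHER)

    coh.state = nxt
    coh.age = age + 1


def _screening_block(coh: Cohort, policy: ScreeningPolicy, rec: _Recorder) -> None:
    age = coh.age
    seed = coh.seed
    pid = coh.pid
    n = len(coh)
    prof = policy.profile
    rule = policy.rule
    single_modality = rule.modality is not None

    alive = coh.state < HealthState.DEAD_CRC

    # mark the fraction already screened before 45 as initiated, with a due
    # date drawn uniformly within one modality interval
    if age == SCREENING_START_AGE:
        elig = alive & ~coh.initiated
        u = uniform(seed, pid, age, Channel.PRE45_SCREENED)
        mark = elig & (u < prof.pre45_screened[coh.origin])
        if mark.any():
            coh.initiated |= mark
            mods = _modality_codes(coh, rule, mark)
            iv = _MOD_INTERVALS[mods]
            off = np.floor(uniform(seed, pid[mark], age, Channel.PRE45_DUE) * iv).astype(np.int16)
            coh.next_due[mark] = age + off
            rec.add(pid[mark], age, EventType.INITIATED, mods)

    screenable = alive & (coh.state < HealthState.CLINICAL_CRC_I)

    # surveillance replaces routine screening for people with adenoma history
    surv_attend = np.zeros(n, dtype=bool)
    surv_due = screenable & (coh.tier > AdenomaTier.NONE) & (age >= coh.surveillance_due)
    if surv_due.any():
        u = uniform(seed, pid[surv_due], age, Channel.SURVEILLANCE)
        p = np.where(coh.tier[surv_due] == AdenomaTier.HIGH_RISK,
                     prof.surveillance[1], prof.surveillance[0])
        idx = np.flatnonzero(surv_due)
        surv_attend[idx[u < p]] = True
        # attenders and non-attenders alike become due one tier-interval later
        iv = np.where(coh.tier[surv_due] == AdenomaTier.HIGH_RISK,
                      prof.surveillance_interval[1], prof.surveillance_interval[0])
        coh.surveillance_due[surv_due] = age + iv.astype(np.int16)
        rec.add(pid[surv_attend], age, EventType.SURVEILLANCE_COLONOSCOPY)

    # routine screening (no adenoma history)
    routine = screenable & (coh.tier == AdenomaTier.NONE)
    newly = np.zeros(n, dtype=bool)
    uninit = routine & ~coh.initiated
    if uninit.any():
        band = int(initial_age_band(age))
        p = prof.initial[band, coh.origin[uninit]]
        u = uniform(seed, pid[uninit], age, Channel.INITIAL_SCREEN)
        idx = np.flatnonzero(uninit)
        newly[idx[u < p]] = True

    repeat = np.zeros(n, dtype=bool)
    due = routine & coh.initiated & (age >= coh.next_due)
    if due.any():
        if rule.switching_allowed and prof.switch > 0.0:
            usw = uniform(seed, pid[due], age, Channel.SWITCH)
            sw = np.flatnonzero(due)[usw < prof.switch]
            coh.current_modality[sw] = np.where(
                coh.current_modality[sw] == Modality.FIT, Modality.COLONOSCOPY, Modality.FIT
            ).astype(np.int8)
        if single_modality:
            col = coh.origin[due]
        else:
            col = (coh.current_modality[due] == Modality.FIT).astype(np.int8)
        p = prof.repeat[int(age >= 65), col]
        u = uniform(seed, pid[due], age, Channel.REPEAT_SCREEN)
        repeat[np.flatnonzero(due)[u < p]] = True

    screeners = newly | repeat
    diag_attend = np.zeros(n, dtype=bool)
    screen_colo = np.zeros(n, dtype=bool)
    detected = np.zeros(n, dtype=bool)
    if screeners.any():
        coh.initiated |= newly
        mods = _modality_codes(coh, rule, screeners)
        if newly.any():
            rec.add(pid[newly], age, EventType.INITIATED, _modality_codes(coh, rule, newly))
        rec.add(pid[screeners], age, EventType.SCREEN, mods)
        coh.next_due[screeners] = age + _MOD_INTERVALS[mods]

        thr = policy.positive_threshold(mods, coh.state[screeners])
        u = uniform(seed, pid[screeners], age, Channel.TEST_RESULT)
        pos = u < thr
        idx = np.flatnonzero(screeners)
        is_colo = mods == Modality.COLONOSCOPY
        screen_colo[idx[is_colo]] = True
        has_lesion = coh.state[screeners] > HealthState.NO_LESION
        # screening colonoscopy resolves in the same test draw
        detected[idx[is_colo & pos & has_lesion]] = True
        # positive non-colonoscopy tests need a diagnostic colonoscopy
        noncolo_pos = ~is_colo & pos
        if noncolo_pos.any():
            ufu = uniform(seed, pid[idx[noncolo_pos]], age, Channel.FOLLOW_UP)
            fu_p = np.empty(int(noncolo_pos.sum()))
            sub_mods = mods[noncolo_pos]
            for m, pr in prof.followup.items():
                fu_p[sub_mods == int(m)] = pr
            diag_attend[idx[noncolo_pos][ufu < fu_p]] = True
            rec.add(pid[diag_attend], age, EventType.DIAGNOSTIC_COLONOSCOPY)

    # diagnostic and surveillance colonoscopies detect with colonoscopy
    # performance; a false-positive referral finds nothing and changes no state
    second_look = diag_attend | surv_attend
    if second_look.any():
        sel = np.flatnonzero(second_look)
        lesion = coh.state[sel] > HealthState.NO_LESION
        sens = policy.colonoscopy_sensitivity(coh.state[sel])
        u2 = uniform(seed, pid[sel], age, Channel.COLONOSCOPY_RESULT)
        detected[sel[lesion & (u2 < sens)]] = True

    # resolution: polypectomy for adenomas, diagnosis for preclinical cancer
    if detected.any():
        st = coh.state
        for code, tier_floor in ((HealthState.ADENOMA_DIMINUTIVE, AdenomaTier.NONE),
                                 (HealthState.ADENOMA_SMALL, AdenomaTier.LOW_RISK),
                                 (HealthState.ADENOMA_LARGE, AdenomaTier.HIGH_RISK)):
            hit = detected & (st == code)
            if hit.any():
                rec.add(pid[hit], age, EventType.POLYPECTOMY, int(code))
                coh.tier[hit] = np.maximum(coh.tier[hit], np.int8(tier_floor))
                coh.state[hit] = HealthState.NO_LESION
                tiered = hit & (coh.tier > AdenomaTier.NONE)
                iv = np.where(coh.tier[tiered] == AdenomaTier.HIGH_RISK,
                              prof.surveillance_interval[1], prof.surveillance_interval[0])
                coh.surveillance_due[tiered] = age + iv.astype(np.int16)
        for k in range(4):
            pre = HealthState.PRECLINICAL_CRC_I + k
            hit = detected & (st == pre)
            if hit.any():
                coh.state[hit] = pre + 4
                coh.years_since_dx[hit] = 0
                rec.add(pid[hit], age, EventType.CRC_DIAGNOSIS, k + 1)

    # complications apply to every colonoscopy performed this cycle
    colos = screen_colo | diag_attend | surv_attend
    if colos.any() and policy.complication_rate > 0.0:
        uc = uniform(seed, pid[colos], age, Channel.COMPLICATION)
        comp = np.flatnonzero(colos)[uc < policy.complication_rate]
        rec.add(pid[comp], age, EventType.COMPLICATION)


def _modality_codes(coh: Cohort, rule: StrategyRule, mask: np.ndarray) -> np.ndarray:
    if rule.modality is not None:
        return np.full(int(mask.sum()), int(rule.modality), dtype=np.int8)
    return coh.current_modality[mask]
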