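"""Experiment orchestration: calibrate -> simulate strategies -> CEA ->
sensitivity analyses, with bit-stable tabular outputs.

Every stage is driven by a :class:`RunConfig`; a manifest records the
seed, a hash of the configuration, and the package version, and a rerun
under the same manifest reproduces every table bit-identically.
Per-1000 scaling is applied at reporting time only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_seed
from .calibration import calibrate, make_objective, write_targets
from .cea import build_icer_ladder, one_way_sa, run_psa, sample_distribution
from .reporting import adherence_table, write_table
from .scenario import (
    STRATEGY_ORDER,
    Scenario,
    apply_calibration_params,
    calibration_summary_fn,
)
from .states import GROUPS, Group
from .synthetic import default_search_space, make_targets, make_truth
from .tables import OWSA_RANGES, PSA_DISTRIBUTIONS

log = logging.getLogger("crcsim")

OUTCOME_SCHEMA = [
    "group", "strategy", "crc_cases_per_1000", "screening_tests_per_1000",
    "noncolonoscopy_tests_per_1000", "screening_colonoscopies_per_1000",
    "all_colonoscopies_per_1000", "uptake_by_75_pct", "qalyg_per_1000",
    "cost_per_1000_million_usd",
]
CEA_SCHEMA = ["group", "strategy", "cost", "qalyg", "status", "icer"]
CEAC_SCHEMA = ["group", "wtp", "strategy", "probability"]
TORNADO_SCHEMA = ["group", "parameter", "low", "high", "nmb_low", "nmb_high", "swing"]


@dataclass
class RunConfig:
    """Configuration of one full experiment."""

    groups: Sequence[str] = tuple(g.label for g in GROUPS)
    strategies: Sequence[str] = STRATEGY_ORDER
    cohort_n: int = 500_000
    calib_eval_n: int = 20_000
    calib_budget: int = 500
    calib_top_k: int = 100
    calib_sampler: str = "adaptive"
    target_noise: float = 0.05
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    psa_draws: int = 5_000
    psa_n: int = 20_000
    psa_wtp_grid: Sequence[float] = tuple(range(10_000, 500_001, 10_000))
    owsa_params: Sequence[str] = tuple(OWSA_RANGES)
    seed: int = 1
    output_dir: str = "results"

    def validate(self) -> None:
        counts = {"cohort_n": self.cohort_n, "calib_eval_n": self.calib_eval_n,
                  "calib_budget": self.calib_budget, "calib_top_k": self.calib_top_k,
                  "psa_draws": self.psa_draws, "psa_n": self.psa_n}
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"config field {name} must be >= 1, got {v}")
        if self.calib_budget < self.calib_top_k:
            raise ValueError("calib_budget must be >= calib_top_k")
        for g in self.groups:
            Group.parse(g)
        for s in self.strategies:
            if s not in STRATEGY_ORDER:
                raise ValueError(f"unknown strategy {s!r}")
        for p in self.owsa_params:
            if p not in OWSA_RANGES:
                raise ValueError(f"no one-way range packaged for parameter {p!r}")

    @classmethod
    def desk(cls, seed: int = 1, output_dir: str = "results") -> "RunConfig":
        """Desk-scale preset: small cohorts and budgets, same structure."""
        return cls(cohort_n=20_000, calib_eval_n=10_000, calib_budget=120,
                   calib_top_k=5, psa_draws=100, psa_n=4_000,
                   owsa_params=tuple(list(OWSA_RANGES)[:4]),
                   seed=seed, output_dir=output_dir)

    def config_hash(self) -> str:
        blob = json.dumps({k: list(v) if isinstance(v, (tuple, list)) else v
                           for k, v in asdict(self).items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def calibrate_group(config: RunConfig, group: Group) -> List[Dict[str, float]]:
    """Generate synthetic truth and targets for one group, search, and
    return the top-K parameter sets."""
    truth = make_truth(config.seed, group, target_noise=config.target_noise)
    targets = make_targets(truth, seed=config.seed)
    # candidates overlay the free parameters on the NOMINAL base (the truth
    # values are what calibration must recover, never an input to it)
    scenario = truth.calibration_scenario()
    scenario.discount.rate = config.discount_rate
    summarize = calibration_summary_fn(scenario, n=config.calib_eval_n,
                                       seed=substream_seed(config.seed, 77))
    objective = make_objective(summarize, targets)
    result = calibrate(
        default_search_space(), objective, budget=config.calib_budget,
        sampler=config.calib_sampler,
        seed=substream_seed(config.seed, 5, sum(group.label.encode())),
        top_k=config.calib_top_k,
    )
    return result.top_k(config.calib_top_k)


def simulate_group(
    config: RunConfig, group: Group, calib_sets: Sequence[Dict[str, float]],
    scenario: Optional[Scenario] = None, n: Optional[int] = None,
) -> pd.DataFrame:
    """Average Table-3-style strategy outcomes over calibrated sets,
    seed-aligned across strategies within each set."""
    if scenario is None:
        scenario = make_truth(config.seed, group, config.target_noise).scenario()
        scenario.discount.rate = config.discount_rate
    n = n or config.cohort_n
    frames = []
    for k, params in enumerate(calib_sets):
        sc = scenario.copy()
        sc.disease = apply_calibration_params(scenario.disease, params)
        df = sc.outcomes_frame(config.strategies, n, substream_seed(config.seed, 31, k))
        frames.append(df)
    stacked = pd.concat(frames)
    mean = stacked.groupby("strategy", sort=False).mean(numeric_only=True).reset_index()
    mean.insert(0, "group", group.label)
    return mean


def cea_group(outcomes: pd.DataFrame, wtp: float) -> pd.DataFrame:
    ladder = build_icer_ladder(outcomes[["strategy", "cost", "qalyg"]])
    table = ladder.table.copy()
    table.insert(0, "group", outcomes["group"].iloc[0])
    table.attrs["dominant"] = ladder.dominant
    table.attrs["cost_effective"] = ladder.cost_effective(wtp)
    return table


def owsa_group(config: RunConfig, group: Group, calib_set: Dict[str, float],
               n: Optional[int] = None) -> pd.DataFrame:
    """One-way sensitivity analysis of CTC-only vs status quo."""
    base = make_truth(config.seed, group, config.target_noise).scenario()
    base.discount.rate = config.discount_rate
    base.disease = apply_calibration_params(base.disease, calib_set)
    n = n or config.psa_n
    pair = ("status_quo", "ctc_only")

    def evaluate(param: str, value: float) -> Dict[str, tuple]:
        sc = base.with_param(param, value)
        out = sc.outcomes(pair, n, substream_seed(config.seed, 41))
        return {o.strategy: (o.qalyg, o.cost) for o in out}

    ranges = {p: OWSA_RANGES[p] for p in config.owsa_params}
    rows = one_way_sa(evaluate, ranges, config.wtp)
    return pd.DataFrame([
        {"group": group.label, "parameter": r.parameter, "low": r.low, "high": r.high,
         "nmb_low": r.nmb_low, "nmb_high": r.nmb_high, "swing": r.swing}
        for r in rows
    ])


def psa_group(config: RunConfig, group: Group, calib_sets: Sequence[Dict[str, float]],
              strategies: Sequence[str] = ("status_quo", "ctc_only")):
    """Probabilistic sensitivity analysis with per-draw parameter sampling;
    each draw runs on one calibrated set (rotating through the top K)."""
    base = make_truth(config.seed, group, config.target_noise).scenario()
    base.discount.rate = config.discount_rate

    def simulate_draw(d: int, rng: np.random.Generator) -> Dict[str, tuple]:
        sampled = {path: sample_distribution(spec, rng)
                   for path, spec in PSA_DISTRIBUTIONS.items()}
        sc = base.with_params(sampled)
        sc.disease = apply_calibration_params(sc.disease, calib_sets[d % len(calib_sets)])
        out = sc.outcomes(strategies, config.psa_n, substream_seed(config.seed, 61, d))
        return {o.strategy: (o.qalyg, o.cost) for o in out}

    return run_psa(simulate_draw, config.psa_draws, config.psa_wtp_grid,
                   seed=substream_seed(config.seed, 63))


def run_experiment(config: RunConfig, progress: bool = True) -> Dict[str, object]:
    """Full pipeline: calibrate, simulate, CEA, OWSA, PSA; write all tables
    plus a manifest into the configured output directory."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = time.time()
    results: Dict[str, object] = {}
    adherence_rows, outcome_frames, cea_frames, tornado_frames, ceac_frames = [], [], [], [], []

    for glabel in config.groups:
        group = Group.parse(glabel)
        t0 = time.time()
        truth = make_truth(config.seed, group, config.target_noise)
        targets = make_targets(truth, seed=config.seed)
        write_targets(targets, out_dir / f"targets_{glabel.replace(' ', '_')}.tsv")
        calib_sets = calibrate_group(config, group)
        log.info("calibration %s: %d sets kept (%.1fs)", glabel, len(calib_sets), time.time() - t0)

        scenario = truth.scenario()
        scenario.discount.rate = config.discount_rate
        for strat in config.strategies:
            rule = scenario.rule_for(strat)
            if rule.modality is None:
                continue
            tab = adherence_table(scenario.profile, rule, group)
            tab.insert(0, "strategy", strat)
            tab.insert(0, "group", glabel)
            adherence_rows.append(tab)

        outcomes = simulate_group(config, group, calib_sets, scenario=scenario)
        outcome_frames.append(outcomes)
        if len(config.strategies) >= 2:
            cea_frames.append(cea_group(outcomes, config.wtp))
        if {"status_quo", "ctc_only"} <= set(config.strategies):
            tornado_frames.append(owsa_group(config, group, calib_sets[0]))
            psa = psa_group(config, group, calib_sets)
            ceac = psa.ceac.copy()
            ceac.insert(0, "group", glabel)
            ceac_frames.append(ceac)
        log.info("group %s done (%.1fs)", glabel, time.time() - t0)

    if adherence_rows:
        adh = pd.concat(adherence_rows, ignore_index=True)
        write_table(adh, list(adh.columns), out_dir / "derived_adherence.tsv")
        results["adherence"] = adh
    outcomes_all = pd.concat(outcome_frames, ignore_index=True)
    write_table(outcomes_all[OUTCOME_SCHEMA], OUTCOME_SCHEMA, out_dir / "strategy_outcomes.tsv")
    results["outcomes"] = outcomes_all
    if cea_frames:
        cea_all = pd.concat(cea_frames, ignore_index=True)
        write_table(cea_all[CEA_SCHEMA], CEA_SCHEMA, out_dir / "cea_ladder.tsv")
        results["cea"] = cea_all
    if tornado_frames:
        torn = pd.concat(tornado_frames, ignore_index=True)
        write_table(torn[TORNADO_SCHEMA], TORNADO_SCHEMA, out_dir / "tornado.tsv")
        results["tornado"] = torn
    if ceac_frames:
        ceac_all = pd.concat(ceac_frames, ignore_index=True)
        write_table(ceac_all[CEAC_SCHEMA], CEAC_SCHEMA, out_dir / "ceac.tsv")
        results["ceac"] = ceac_all

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "wall_time_s": round(time.time() - stamp, 2),
        "tables": sorted(p.name for p in out_dir.glob("*.tsv")),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
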