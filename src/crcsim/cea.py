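"""Cost-effectiveness analysis: dominance, ICERs, NMB, and sensitivity
analyses.

Strategies are ranked by ascending cost; strictly dominated strategies
(fewer QALYs gained at higher cost) are removed, then extended dominance
is applied iteratively until the ICER sequence along the remaining
frontier is strictly increasing.  The cost-effective strategy at a
willingness-to-pay (WTP) threshold is the undominated strategy with the
largest ICER at or below the threshold — decision-equivalent to
maximizing net monetary benefit, NMB = WTP x QALYG - cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"
UNDOMINATED = "undominated"


@dataclass
class WTPSpec:
    threshold: float = 100_000.0
    psa_grid: np.ndarray = field(default_factory=lambda: np.arange(10_000, 500_001, 10_000))

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("WTP threshold must be positive")
        self.psa_grid = np.asarray(self.psa_grid, dtype=float)


@dataclass
class CEALadder:
    """Ascending-cost table with dominance status and chained ICERs."""

    table: pd.DataFrame           # strategy, cost, qalyg, status, icer
    dominant: Optional[str]       # strategy beating every alternative, if any

    def undominated(self) -> pd.DataFrame:
        return self.table[self.table["status"] == UNDOMINATED]

    def cost_effective(self, wtp: float) -> str:
        """Undominated strategy with the largest ICER <= wtp (the cheapest
        undominated strategy when every ICER exceeds wtp)."""
        und = self.undominated()
        best = und.iloc[0]["strategy"]
        for _, row in und.iterrows():
            if not math.isnan(row["icer"]) and row["icer"] <= wtp:
                best = row["strategy"]
        return str(best)


def build_icer_ladder(outcomes: pd.DataFrame) -> CEALadder:
    """Rank strategies, eliminate (extended-)dominated ones, chain ICERs.

    `outcomes` needs columns strategy, cost, qalyg.  Cost ties are broken
    by higher QALYG first; exact ties in both keep stable input order (the
    second of two identical rows is marked dominated).
    """
    required = {"strategy", "cost", "qalyg"}
    if not required.issubset(outcomes.columns):
        raise ValueError(f"outcomes must have columns {sorted(required)}")
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to compare")
    if outcomes["strategy"].duplicated().any():
        raise ValueError("strategy names must be unique")

    df = outcomes[["strategy", "cost", "qalyg"]].copy()
    df["_ix"] = np.arange(len(df))
    df = df.sort_values(["cost", "qalyg", "_ix"], ascending=[True, False, True],
                        kind="stable").reset_index(drop=True)
    status = np.full(len(df), UNDOMINATED, dtype=object)

    # simple dominance: an earlier row is at most as costly; if it has at
    # least as many QALYG, this row is dominated
    best_q = -np.inf
    for i in range(len(df)):
        if df.loc[i, "qalyg"] <= best_q:
            status[i] = DOMINATED
        else:
            best_q = df.loc[i, "qalyg"]

    # extended dominance: remove frontier points until ICERs increase
    changed = True
    while changed:
        changed = False
        keep = [i for i in range(len(df)) if status[i] == UNDOMINATED]
        for a, b, c in zip(keep, keep[1:], keep[2:]):
            icer_ab = _icer(df, a, b)
            icer_bc = _icer(df, b, c)
            if icer_ab >= icer_bc:
                status[b] = EXTENDED_DOMINATED
                changed = True
                break

    keep = [i for i in range(len(df)) if status[i] == UNDOMINATED]
    icers = np.full(len(df), np.nan)
    for prev, cur in zip(keep, keep[1:]):
        icers[cur] = _icer(df, prev, cur)

    df["status"] = status
    df["icer"] = icers
    df = df.drop(columns="_ix")

    dominant = None
    if len(keep) == 1:
        dominant = str(df.loc[keep[0], "strategy"])
    else:
        # a strategy with more QALYG at lower cost than every alternative
        top = df.loc[keep[-1]] if keep else None
        if top is not None:
            others = df.drop(index=keep[-1])
            if (top["cost"] <= others["cost"]).all() and (top["qalyg"] >= others["qalyg"]).all():
                dominant = str(top["strategy"])
    return CEALadder(table=df, dominant=dominant)


def _icer(df: pd.DataFrame, i: int, j: int) -> float:
    dq = df.loc[j, "qalyg"] - df.loc[i, "qalyg"]
    dc = df.loc[j, "cost"] - df.loc[i, "cost"]
    if dq <= 0:
        return math.inf
    return dc / dq


def nmb(qalyg: float, cost: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("WTP must be >= 0")
    return wtp * qalyg - cost


def sample_pert(mode: float, minimum: float, maximum: float, rng, lam: float = 4.0):
    """Draw from the PERT distribution (Beta reshaped to [min, max]).

    alpha = 1 + lam (mode-min)/(max-min), beta = 1 + lam (max-mode)/(max-min);
    the mean is (min + lam*mode + max) / (lam + 2).
    """
    if not minimum <= mode <= maximum:
        raise ValueError("PERT requires min <= mode <= max")
    if minimum == maximum:
        return minimum
    span = maximum - minimum
    alpha = 1.0 + lam * (mode - minimum) / span
    beta = 1.0 + lam * (maximum - mode) / span
    return minimum + span * rng.beta(alpha, beta)


def sample_distribution(spec, rng):
    """Draw from a ('beta', a, b) or ('pert', min, mode, max) spec."""
    kind = spec[0]
    if kind == "beta":
        return float(rng.beta(spec[1], spec[2]))
    if kind == "pert":
        return float(sample_pert(spec[2], spec[1], spec[3], rng))
    if kind == "fixed":
        return float(spec[1])
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass
class TornadoRow:
    parameter: str
    low: float
    high: float
    nmb_low: float          # incremental NMB at the low endpoint
    nmb_high: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def one_way_sa(
    evaluate: Callable[[str, float], Dict[str, float]],
    ranges: Dict[str, tuple],
    wtp: float,
    comparator: str = "status_quo",
    focal: str = "ctc_only",
    top: int = 10,
) -> List[TornadoRow]:
    """One-way sensitivity analysis on the incremental NMB of `focal`
    relative to `comparator`.

    `evaluate(param, value)` reruns both strategies seed-aligned with the
    named parameter set to `value` and returns {strategy: (qalyg, cost)}.
    Rows come back sorted by absolute swing, largest first, top `top` kept.
    """
    rows = []
    for name, (low, high) in ranges.items():
        if low > high:
            raise ValueError(f"invalid range for {name}: {low} > {high}")
        endpoints = []
        for value in (low, high):
            res = evaluate(name, value)
            inc = nmb(*res[focal], wtp) - nmb(*res[comparator], wtp)
            endpoints.append(inc)
        rows.append(TornadoRow(name, low, high, endpoints[0], endpoints[1]))
    rows.sort(key=lambda r: r.swing, reverse=True)
    return rows[:top]


@dataclass
class PSAResult:
    ceac: pd.DataFrame          # long format: wtp, strategy, probability
    frontier: pd.DataFrame      # wtp, strategy with highest mean NMB
    draws: pd.DataFrame         # draw, strategy, qalyg, cost

    def ceac_wide(self) -> pd.DataFrame:
        return self.ceac.pivot(index="wtp", columns="strategy", values="probability")


def run_psa(
    simulate_draw: Callable[[int, np.random.Generator], Dict[str, tuple]],
    n_draws: int,
    wtp_grid: Sequence[float],
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis over sampled parameter sets.

    `simulate_draw(draw_index, rng)` samples one parameter set, runs every
    strategy (averaging over calibrated parameter sets as configured), and
    returns {strategy: (qalyg, cost)}.  The CEAC gives, per WTP, the
    fraction of draws in which each strategy maximizes NMB; fractions sum
    to 1 at every WTP.  One master seed spawns per-draw substreams.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    master = np.random.SeedSequence(seed)
    records = []
    for d, child in enumerate(master.spawn(n_draws)):
        rng = np.random.default_rng(child)
        for strat, (qalyg, cost) in simulate_draw(d, rng).items():
            records.append({"draw": d, "strategy": strat, "qalyg": qalyg, "cost": cost})
    draws = pd.DataFrame(records)
    strategies = list(dict.fromkeys(draws["strategy"]))

    q = draws.pivot(index="draw", columns="strategy", values="qalyg")[strategies].to_numpy()
    c = draws.pivot(index="draw", columns="strategy", values="cost")[strategies].to_numpy()
    ceac_rows, frontier_rows = [], []
    for wtp in wtp_grid:
        benefit = wtp * q - c
        winner = benefit.argmax(axis=1)           # ties -> first strategy, stable
        share = np.bincount(winner, minlength=len(strategies)) / n_draws
        for s, p in zip(strategies, share):
            ceac_rows.append({"wtp": wtp, "strategy": s, "probability": p})
        frontier_rows.append({"wtp": wtp, "strategy": strategies[int(benefit.mean(axis=0).argmax())]})
    return PSAResult(pd.DataFrame(ceac_rows), pd.DataFrame(frontier_rows), draws)
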