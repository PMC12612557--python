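"""Printed-precision reporting of derived adherence schedules.

Published adherence tables carry probabilities as percentages with one
decimal.  To reproduce those printed cells exactly, the multiplier
arithmetic here runs in decimal on the printed inputs with round-half-up
(e.g. 7.0% x 3.45 = 24.15% prints as 24.2%); binary floats would tip
such half-way cells the wrong way.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .screening import (
    INITIAL_AGE_BANDS,
    REPEAT_AGE_BANDS,
    AdherenceProfile,
    StrategyRule,
    apply_repeat_odds_ratio,
)
from .states import Group, Race


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def derived_initial_percent(p: float, rr: float, decimals: int = 1) -> float:
    """Initial-adherence cell: probability x relative risk, in percent at
    printed precision.  Exact decimal arithmetic on the printed inputs."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    cell = min(Decimal(repr(p)) * Decimal(repr(rr)), Decimal(1)) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(cell.quantize(q, rounding=ROUND_HALF_UP))


def derived_repeat_percent(p: float, odds_ratio: float, decimals: int = 1) -> float:
    """Repeat-adherence cell: odds-ratio adjustment, in percent at printed
    precision."""
    return round_half_up(100.0 * apply_repeat_odds_ratio(p, odds_ratio), decimals)


def adherence_table(status_quo: AdherenceProfile, rule: StrategyRule, group: Group) -> pd.DataFrame:
    """Derived-adherence panel for one strategy and group, in percent at
    printed precision (initial rows by origin modality, repeat rows)."""
    rows = []
    mults = (rule.initial_multiplier_from_colonoscopy, rule.initial_multiplier_from_fit)
    for b, band in enumerate(INITIAL_AGE_BANDS):
        row = {"row": f"initial_{band}"}
        for col, origin in enumerate(("colonoscopy", "fit")):
            row[origin] = derived_initial_percent(float(status_quo.initial[b, col]), mults[col])
        rows.append(row)
    for b, band in enumerate(REPEAT_AGE_BANDS):
        row = {"row": f"repeat_{band}"}
        if rule.repeat_source == "colonoscopy":
            base = float(status_quo.repeat[b, 0])
        elif rule.repeat_source == "fit":
            base = float(status_quo.repeat[b, 1])
        else:
            base = None
        for col, origin in enumerate(("colonoscopy", "fit")):
            p = float(status_quo.repeat[b, col]) if base is None else base
            if rule.repeat_odds_ratio_black is not None and group.race is Race.BLACK:
                row[origin] = derived_repeat_percent(p, rule.repeat_odds_ratio_black)
            else:
                row[origin] = round_half_up(100.0 * p)
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(rows: Iterable[dict] | pd.DataFrame, schema: list[str], path) -> None:
    """Write a delimited-text table with a fixed column order and
    locale-independent number formatting."""
    rows = list(rows) if not isinstance(rows, pd.DataFrame) else rows
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=schema)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"rows missing schema columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise ValueError(f"rows carry non-schema columns {extra}")
    df[schema].to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
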