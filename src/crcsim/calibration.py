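"""Calibration of free natural-history parameters to weighted summary
targets by adaptive black-box search.

Candidate parameter sets are scored by a weighted mean squared error over
relative deviations (each deviation scaled by the target's observed value
when nonzero), which makes incidence-per-100k and proportion targets
commensurable.  The search uses a tree-structured-Parzen-estimator-style
adaptive sampler: after a random start-up phase the evaluated points are
split into a good and a bad fraction by score, one-dimensional Parzen
(Gaussian kernel) densities l(x) and g(x) are fitted to each, and the
next point maximizes l(x)/g(x) over a candidate batch drawn from l.  A
pure-random sampler is the always-available fallback.  Evaluations use a
fixed per-candidate simulation seed (common random numbers) so the
objective surface is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class CalibrationTarget:
    """One weighted summary statistic the model should reproduce."""

    name: str
    group: str = ""
    age_band: str = ""
    value: float = 0.0
    weight: float = 1.0
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"target {self.name}: weight must be positive")


def write_targets(targets: Sequence[CalibrationTarget], path) -> None:
    pd.DataFrame(
        [{"name": t.name, "group": t.group, "age_band": t.age_band,
          "value": t.value, "weight": t.weight, "tolerance": t.tolerance}
         for t in targets]
    ).to_csv(path, sep="\t", index=False)


def read_targets(path) -> List[CalibrationTarget]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    return [
        CalibrationTarget(str(r["name"]), str(r["group"]), str(r["age_band"]),
                          float(r["value"]), float(r["weight"]), float(r["tolerance"]))
        for _, r in df.iterrows()
    ]


def mse_score(summaries: Mapping[str, float], targets: Sequence[CalibrationTarget]) -> float:
    """Weighted mean of squared relative deviations from the targets."""
    if not targets:
        raise ValueError("no targets given")
    num = 0.0
    den = 0.0
    for t in targets:
        if t.name not in summaries:
            raise KeyError(f"no summary computed for target {t.name!r}")
        s = float(summaries[t.name])
        d = (s - t.value) / t.value if t.value != 0 else s - t.value
        num += t.weight * d * d
        den += t.weight
    return num / den


@dataclass
class SearchSpace:
    """Per-parameter bounds, each linear or log scaled."""

    bounds: Dict[str, tuple]                       # name -> (low, high)
    log_scale: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, (low, high) in self.bounds.items():
            if not (math.isfinite(low) and math.isfinite(high) and low < high):
                raise ValueError(f"{name}: bounds must be finite with low < high")
            if name in self.log_scale and low <= 0:
                raise ValueError(f"{name}: log-scaled bounds must be positive")

    @property
    def names(self) -> List[str]:
        return list(self.bounds)

    def to_unit(self, params: Mapping[str, float]) -> np.ndarray:
        out = np.empty(len(self.bounds))
        for i, (name, (lo, hi)) in enumerate(self.bounds.items()):
            v = params[name]
            if name in self.log_scale:
                out[i] = (math.log(v) - math.log(lo)) / (math.log(hi) - math.log(lo))
            else:
                out[i] = (v - lo) / (hi - lo)
        return out

    def from_unit(self, x: np.ndarray) -> Dict[str, float]:
        out = {}
        for i, (name, (lo, hi)) in enumerate(self.bounds.items()):
            u = float(np.clip(x[i], 0.0, 1.0))
            if name in self.log_scale:
                out[name] = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
            else:
                out[name] = lo + u * (hi - lo)
        return out


@dataclass
class CalibrationResult:
    """Evaluation log ranked by score (ties keep evaluation order)."""

    log: pd.DataFrame              # eval_index, <params...>, score
    space: SearchSpace

    def ranked(self) -> pd.DataFrame:
        return self.log.sort_values(["score", "eval_index"], kind="stable").reset_index(drop=True)

    def top_k(self, k: int = 100) -> List[Dict[str, float]]:
        return select_top_k(self, k)

    def best(self) -> Dict[str, float]:
        return self.top_k(1)[0]

    def write_log(self, path) -> None:
        self.log.to_csv(path, sep="\t", index=False)


def select_top_k(result: CalibrationResult, k: int = 100) -> List[Dict[str, float]]:
    """The k lowest-score parameter sets, stable tie order by eval index."""
    if k > len(result.log):
        raise ValueError(f"k={k} exceeds the {len(result.log)} evaluated sets")
    names = result.space.names
    head = result.ranked().head(k)
    return [{n: float(row[n]) for n in names} for _, row in head.iterrows()]


class _TPESampler:
    """Independent one-dimensional Parzen-estimator sampler.

    The `n_good = min(ceil(0.1 n), 25)` split and the shrinking per-dim
    bandwidths follow common TPE practice: candidates are drawn from the
    good-set density l(x) and ranked by log l(x) - log g(x)."""

    def __init__(self, ndim: int, rng: np.random.Generator,
                 n_startup: int = 25, n_candidates: int = 64):
        self.ndim = ndim
        self.rng = rng
        self.n_startup = n_startup
        self.n_candidates = n_candidates

    def ask(self, xs: List[np.ndarray], scores: List[float]) -> np.ndarray:
        if len(xs) < self.n_startup:
            return self.rng.random(self.ndim)
        order = np.argsort(scores, kind="stable")
        # exploitation slice: every fourth trial refines the incumbent best
        if len(xs) % 4 == 3:
            incumbent = xs[int(order[0])]
            return np.clip(incumbent + self.rng.normal(0.0, 0.03, self.ndim), 0.0, 1.0)
        n_good = max(3, min(int(math.ceil(0.1 * len(xs))), 25))
        pts = np.asarray(xs)
        good = pts[order[:n_good]]
        bad = pts[order[n_good:]]
        if len(bad) < 2:
            return self.rng.random(self.ndim)
        cand = np.empty((self.n_candidates, self.ndim))
        for j in range(self.ndim):
            centers = good[self.rng.integers(0, len(good), self.n_candidates), j]
            bw = self._bandwidth(good[:, j])
            cand[:, j] = np.clip(self.rng.normal(centers, bw), 0.0, 1.0)
        # an exploration slice keeps the sampler from collapsing early
        n_explore = max(1, self.n_candidates // 8)
        cand[:n_explore] = self.rng.random((n_explore, self.ndim))
        score = np.zeros(self.n_candidates)
        for j in range(self.ndim):
            score += self._log_density(cand[:, j], good[:, j])
            score -= self._log_density(cand[:, j], bad[:, j])
        return cand[int(np.argmax(score))]

    @staticmethod
    def _bandwidth(points: np.ndarray) -> float:
        spread = float(points.std())
        return max(spread * len(points) ** -0.2, 0.015)

    @classmethod
    def _log_density(cls, x: np.ndarray, points: np.ndarray) -> np.ndarray:
        bw = cls._bandwidth(points)
        z = (x[:, None] - points[None, :]) / bw
        # mixture of Gaussians plus a thin uniform floor for robustness
        dens = np.exp(-0.5 * z * z).mean(axis=1) / (bw * math.sqrt(2 * math.pi))
        return np.log(dens + 1e-12)


def calibrate(
    space: SearchSpace,
    objective: Callable[[Dict[str, float]], float],
    budget: int,
    sampler: str = "adaptive",
    seed: int = 0,
    top_k: int = 100,
    callback: Optional[Callable[[int, float], None]] = None,
) -> CalibrationResult:
    """Run `budget` objective evaluations and return the ranked log.

    `objective` maps a parameter dict to a score (lower is better); it is
    expected to be deterministic (use a fixed simulation seed inside).
    """
    if budget < top_k:
        raise ValueError(f"budget {budget} is below top_k {top_k}")
    if sampler not in ("adaptive", "random"):
        raise ValueError(f"unknown sampler {sampler!r}")
    rng = np.random.default_rng(seed)
    tpe = _TPESampler(len(space.bounds), rng) if sampler == "adaptive" else None
    xs: List[np.ndarray] = []
    scores: List[float] = []
    rows = []
    for i in range(budget):
        x = tpe.ask(xs, scores) if tpe is not None else rng.random(len(space.bounds))
        params = space.from_unit(x)
        s = float(objective(params))
        xs.append(x)
        scores.append(s)
        rows.append({"eval_index": i, **params, "score": s})
        if callback is not None:
            callback(i, s)
    return CalibrationResult(log=pd.DataFrame(rows), space=space)


def make_objective(
    summarize: Callable[[Dict[str, float]], Mapping[str, float]],
    targets: Sequence[CalibrationTarget],
) -> Callable[[Dict[str, float]], float]:
    """Compose a summary function and targets into an MSE objective."""

    def objective(params: Dict[str, float]) -> float:
        return mse_score(summarize(params), targets)

    return objective
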