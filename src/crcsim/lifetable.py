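"""Other-cause (background) mortality.

Ships an illustrative per-gender annual life table built from a Gompertz
hazard, swappable via config: no specific national table is asserted.
The closed-form survival/expectation helpers double as oracles for the
zero-disease limit of the microsimulation.
"""

from __future__ import annotations

import numpy as np

MAX_AGE = 110

# Gompertz q(x) ~ a * exp(b * x); parameters chosen once to give
# adult life expectancies in the low-80s (women) / high-70s (men).
_GOMPERTZ = {"men": (5.8e-5, 0.087), "women": (3.9e-5, 0.089)}


def make_life_table(gender: str = "men") -> np.ndarray:
    """Annual death probability q(age) for ages 0..MAX_AGE (inclusive)."""
    try:
        a, b = _GOMPERTZ[gender]
    except KeyError:
        raise ValueError(f"unknown gender {gender!r}") from None
    ages = np.arange(MAX_AGE + 1, dtype=float)
    q = np.clip(a * np.exp(b * ages), 0.0, 1.0)
    q[-1] = 1.0
    return q


def survival_curve(q: np.ndarray, start_age: int, max_age: int) -> np.ndarray:
    """P(alive at the start of cycle x) for x = start_age..max_age-1."""
    qs = q[start_age:max_age]
    surv = np.empty(max_age - start_age)
    surv[0] = 1.0
    np.cumprod(1.0 - qs[:-1], out=surv[1:])
    return surv


def expected_life_years(q: np.ndarray, start_age: int, max_age: int) -> float:
    """Discrete life expectancy between start_age and max_age.

    A person alive at the start of a cycle accrues that full year (no
    half-cycle correction), matching the simulator's accounting.
    """
    return float(survival_curve(q, start_age, max_age).sum())


def life_years_variance(q: np.ndarray, start_age: int, max_age: int) -> float:
    """Variance of per-person life years under the same accounting."""
    surv = survival_curve(q, start_age, max_age)
    qs = q[start_age:max_age]
    # LY = k+1 if death in cycle start_age+k; LY = max-start if survivor.
    horizon = max_age - start_age
    p_death = surv * qs                      # death during cycle k
    p_surv = float(surv[-1] * (1.0 - qs[-1]))
    ly = np.arange(1, horizon + 1, dtype=float)
    mean = float((p_death * ly).sum() + p_surv * horizon)
    second = float((p_death * ly**2).sum() + p_surv * horizon**2)
    return second - mean**2
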