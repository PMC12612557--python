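"""Counter-based random-number streams for the microsimulation.

Every stochastic decision in the annual-cycle engine draws one uniform
variate addressed by ``(seed, person_id, age, channel)``.  The variate is
produced by hashing that address with the splitmix64 finalizer, so

* results are independent of iteration order and of how the cohort is
  chunked or permuted (each person owns a private substream);
* two runs that share a seed use *common random numbers*: a person makes
  the same latent draws under every strategy or candidate parameter set,
  which keeps strategy comparisons and calibration objectives from being
  swamped by Monte-Carlo noise.

The cost is a few integer ops per draw, fully vectorized over numpy
uint64 arrays.
"""

from __future__ import annotations

import enum

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = float(2.0**-53)


class Channel(enum.IntEnum):
    """Fixed enumeration of per-cycle decision points (one draw each, max)."""

    OTHER_DEATH = 0
    CRC_DEATH = 1
    PROGRESS = 2
    CLINICAL_DETECT = 3
    INITIAL_SCREEN = 4
    REPEAT_SCREEN = 5
    SWITCH = 6
    TEST_RESULT = 7
    FOLLOW_UP = 8
    COLONOSCOPY_RESULT = 9
    SURVEILLANCE = 10
    COMPLICATION = 11
    PRE45_SCREENED = 12
    PRE45_DUE = 13
    ORIGIN = 14


def _splitmix64(z: np.ndarray) -> np.ndarray:
    z = (z + _GOLDEN).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= _MIX1
    z ^= z >> np.uint64(27)
    z *= _MIX2
    z ^= z >> np.uint64(31)
    return z


def uniform(seed: int, person_id, age: int, channel: int):
    """Uniform(0, 1) draw(s) addressed by (seed, person, age, channel).

    ``person_id`` may be a scalar or a uint64-convertible array; the result
    has the same shape.  Deterministic: the same address always yields the
    same variate.
    """
    mask = 0xFFFFFFFFFFFFFFFF
    base = np.uint64((int(seed) * 0x9E3779B97F4A7C15) & mask)
    age_key = np.uint64((int(age) * 0xBF58476D1CE4E5B9) & mask)
    chan_key = np.uint64((int(channel) * 0x94D049BB133111EB) & mask)
    pid = np.atleast_1d(np.asarray(person_id, dtype=np.uint64))
    z = _splitmix64(base ^ pid)
    z = _splitmix64(z ^ age_key)
    z = _splitmix64(z ^ chan_key)
    u = (z >> np.uint64(11)).astype(np.float64) * _INV53
    if np.ndim(person_id) == 0:
        return float(u[0])
    return u


def substream_seed(seed: int, *indices: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and index path."""
    mask = 0xFFFFFFFFFFFFFFFF
    z = np.array([(int(seed) * 0x9E3779B97F4A7C15) & mask], dtype=np.uint64)
    for ix in indices:
        key = np.uint64((int(ix) * 0xBF58476D1CE4E5B9) & mask)
        z = _splitmix64(z ^ key)
    return int(z[0] & np.uint64(0x7FFFFFFF))
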