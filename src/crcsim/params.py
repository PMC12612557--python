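"""Natural-history parameters and their flat keyed-text serialization.

All transition parameters are annual probabilities.  The adenoma onset
rate is age-banded (decadal bands from 20 to 80+); preclinical cancer
leaves via a per-stage annual clinical-detection probability (geometric
sojourn) competing with per-stage progression; clinical cancer carries a
stage-specific annual excess mortality for a configurable number of
years post-diagnosis, then background mortality only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .lifetable import MAX_AGE, make_life_table

ONSET_BAND_EDGES = np.array([20, 30, 40, 50, 60, 70, 80])
ONSET_BAND_LABELS = ("20_29", "30_39", "40_49", "50_59", "60_69", "70_79", "80_plus")
STAGE_LABELS = ("I", "II", "III", "IV")


def onset_band_index(age) -> np.ndarray:
    """Map age(s) to the adenoma-onset band index (clipped to [0, 6])."""
    return np.clip(np.searchsorted(ONSET_BAND_EDGES, age, side="right") - 1, 0, 6)


@dataclass
class DiseaseParams:
    """Race/gender-specific annual transition rates of the adenoma–carcinoma
    natural history plus competing background mortality."""

    adenoma_onset: np.ndarray                 # (7,) by decadal age band
    growth_dim_to_small: float
    growth_small_to_large: float
    large_to_preclinical: float
    stage_progression: np.ndarray             # (3,) preclinical I->II, II->III, III->IV
    clinical_detection: np.ndarray            # (4,) preclinical stage -> clinical
    crc_mortality: np.ndarray                 # (4,) annual excess death by clinical stage
    other_cause_mortality: np.ndarray = field(default_factory=lambda: make_life_table("men"))
    survival_horizon: int = 10                # years of excess CRC mortality post-diagnosis
    group: str = "White men"

    def __post_init__(self) -> None:
        self.adenoma_onset = np.asarray(self.adenoma_onset, dtype=float)
        self.stage_progression = np.asarray(self.stage_progression, dtype=float)
        self.clinical_detection = np.asarray(self.clinical_detection, dtype=float)
        self.crc_mortality = np.asarray(self.crc_mortality, dtype=float)
        self.other_cause_mortality = np.asarray(self.other_cause_mortality, dtype=float)
        self.validate()

    def validate(self) -> None:
        shapes = {
            "adenoma_onset": (self.adenoma_onset, 7),
            "stage_progression": (self.stage_progression, 3),
            "clinical_detection": (self.clinical_detection, 4),
            "crc_mortality": (self.crc_mortality, 4),
            "other_cause_mortality": (self.other_cause_mortality, MAX_AGE + 1),
        }
        for name, (arr, size) in shapes.items():
            if arr.shape != (size,):
                raise ValueError(f"{name} must have shape ({size},), got {arr.shape}")
        scalars = {
            "growth_dim_to_small": self.growth_dim_to_small,
            "growth_small_to_large": self.growth_small_to_large,
            "large_to_preclinical": self.large_to_preclinical,
        }
        for name, (arr, _) in shapes.items():
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name, value in scalars.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        ocm_40 = self.other_cause_mortality[40:]
        if np.any(np.diff(ocm_40) < -1e-12):
            raise ValueError("other_cause_mortality must be non-decreasing beyond age 40")

    # -- flat keyed-text config ------------------------------------------------

    def to_flat_dict(self) -> dict:
        out: dict = {"group": self.group, "survival_horizon": int(self.survival_horizon)}
        for label, v in zip(ONSET_BAND_LABELS, self.adenoma_onset):
            out[f"adenoma_onset.{label}"] = float(v)
        out["growth_dim_to_small"] = float(self.growth_dim_to_small)
        out["growth_small_to_large"] = float(self.growth_small_to_large)
        out["large_to_preclinical"] = float(self.large_to_preclinical)
        for (lo, hi), v in zip(zip(STAGE_LABELS[:-1], STAGE_LABELS[1:]), self.stage_progression):
            out[f"stage_progression.{lo}_{hi}"] = float(v)
        for label, v in zip(STAGE_LABELS, self.clinical_detection):
            out[f"clinical_detection.{label}"] = float(v)
        for label, v in zip(STAGE_LABELS, self.crc_mortality):
            out[f"crc_mortality.{label}"] = float(v)
        for age, v in enumerate(self.other_cause_mortality):
            out[f"other_cause_mortality.{age}"] = float(v)
        return out

    @classmethod
    def from_flat_dict(cls, d: Mapping) -> "DiseaseParams":
        ocm = np.array([float(d[f"other_cause_mortality.{a}"]) for a in range(MAX_AGE + 1)])
        return cls(
            adenoma_onset=np.array([float(d[f"adenoma_onset.{b}"]) for b in ONSET_BAND_LABELS]),
            growth_dim_to_small=float(d["growth_dim_to_small"]),
            growth_small_to_large=float(d["growth_small_to_large"]),
            large_to_preclinical=float(d["large_to_preclinical"]),
            stage_progression=np.array(
                [float(d[f"stage_progression.{lo}_{hi}"])
                 for lo, hi in zip(STAGE_LABELS[:-1], STAGE_LABELS[1:])]
            ),
            clinical_detection=np.array([float(d[f"clinical_detection.{s}"]) for s in STAGE_LABELS]),
            crc_mortality=np.array([float(d[f"crc_mortality.{s}"]) for s in STAGE_LABELS]),
            other_cause_mortality=ocm,
            survival_horizon=int(d.get("survival_horizon", 10)),
            group=str(d.get("group", "White men")),
        )

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_flat_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def load(cls, path) -> "DiseaseParams":
        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))

    def with_updates(self, **kwargs) -> "DiseaseParams":
        return replace(self, **kwargs)
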