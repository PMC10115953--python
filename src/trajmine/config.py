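"""Run configuration: every tunable day-window parameter of the pipeline.

Defaults are the analysis' stated parameters: 365-day washout and follow-up,
120-day episode-end gap, 30-day minimum supply, switch window and refill gap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    study_year: int = 2015
    washout_days: int = Field(365, gt=0)
    episode_gap_days: int = Field(120, gt=0)
    min_supply: int = Field(30, gt=0)
    switch_window: int = Field(30, gt=0)
    refill_gap: int = Field(30, gt=0)
    follow_up_days: int = Field(365, gt=0)
    default_days_supply: Optional[int] = Field(
        30, gt=0, description="applied when the source lacks a days_supply column"
    )
    distance_mode: Literal["sum", "composite"] = "sum"
    k_min: int = Field(2, ge=2)
    k_max: int = Field(10, ge=2)
    seed: int = 0

    @field_validator("k_max")
    @classmethod
    def _k_range(cls, v, info):
        if "k_min" in info.data and v < info.data["k_min"]:
            raise ValueError("k_max must be >= k_min")
        return v

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))

    def decision_flags(self) -> dict:
        """The documented choices made where the method description was open."""
        return {
            "class_collapse_rule": "latest-initiated active drug; ties by class priority "
            "SSRI>SNRI>TCA>NaSSA>OtherAD>AP",
            "distance_mode": self.distance_mode,
            "ward_variant": "Lance-Williams on squared dissimilarities (Ward.D2-style)",
            "switch_window_reading": "prior drug ends within +/- switch_window of new start",
        }
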