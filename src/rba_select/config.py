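"""Run configuration.

Every cut point, class-to-level map, combiner and threshold the method
leaves open is a named configuration key, so a run is fully determined by
its inputs plus one config object.  The shipped defaults are the "NovRBA
profile": the values used in the beef-vs-cricket case study, with the
gaps the published method leaves (bin edges, occurrence band maps) filled
by this package's documented choices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator


class LongListConfig(BaseModel):
    """Long-list assembly: the concentration-difference ("20%") rule."""

    concentration_diff_threshold: float = Field(default=0.20, ge=0)
    #: denominator of |a-b|/denom: mean of the two values (symmetric,
    #: scale-invariant), the larger value, or the reference food's value
    denominator: Literal["mean", "max", "reference_a"] = "mean"


class NutritionConfig(BaseModel):
    presence_low_fraction: float = Field(default=0.10, ge=0, le=1)
    processing_level_map: dict[str, int] = Field(
        default_factory=lambda: {
            "large_reduction": 1,
            "moderate_change": 2,
            "preserved_or_concentrated": 3,
        }
    )
    #: layer-1 intake-contribution tertile cuts; f <= cuts[0] -> 1,
    #: cuts[0] < f <= cuts[1] -> 2, f > cuts[1] -> 3
    intake_contribution_cuts: tuple[float, float] = (1 / 3, 2 / 3)
    composition_difference_level_map: dict[str, int] = Field(
        default_factory=lambda: {
            "small_difference": 1,
            "moderate_difference": 2,
            "large_difference": 3,
        }
    )
    bioavailability_level_map: dict[str, int] = Field(
        default_factory=lambda: {
            "significant": 1,
            "moderate": 2,
            "mild_or_none": 3,
        }
    )

    @field_validator("processing_level_map", "bioavailability_level_map",
                     "composition_difference_level_map")
    @classmethod
    def _levels_in_range(cls, v: dict[str, int]) -> dict[str, int]:
        bad = {k: lv for k, lv in v.items() if lv not in (1, 2, 3)}
        if bad:
            raise ValueError(f"levels must be in {{1,2,3}}, got {bad}")
        return v


class MicrobiologyConfig(BaseModel):
    prevalence_level_map: dict[str, int] = Field(
        default_factory=lambda: {"low": 1, "moderate": 2, "high": 3}
    )
    process_level_map: dict[str, int] = Field(
        default_factory=lambda: {
            "reduces_or_eliminates": 1,
            "neutral": 2,
            "can_introduce": 3,
        }
    )
    #: raw prevalence x process product (1,2,3,4,6,9) -> 1-3 band, so the
    #: final index keeps the printed 1-9 range
    occurrence_band_map: dict[int, int] = Field(
        default_factory=lambda: {1: 1, 2: 1, 3: 2, 4: 2, 6: 3, 9: 3}
    )
    #: DALY per 1000 cases bin edges: <edges[0] -> 1, <edges[1] -> 2, else 3
    severity_bins: tuple[float, float] = (10.0, 100.0)


class ToxicologyConfig(BaseModel):
    #: exposure share of total diet: < bins[0] -> 1, <= bins[1] -> 2, else 3
    exposure_bins: tuple[float, float] = (0.10, 0.50)
    occurrence_combiner: Literal["ceil_mean", "min", "max"] = "ceil_mean"
    #: number of true severity statements -> level
    severity_map: dict[int, int] = Field(
        default_factory=lambda: {0: 1, 1: 1, 2: 2, 3: 3, 4: 3}
    )


class SelectionConfig(BaseModel):
    """Inclusive short-list thresholds on the prioritization index."""

    thresholds: dict[str, int] = Field(
        default_factory=lambda: {
            "nutrition": 108,
            "microbiology": 2,
            "toxicology": 2,
        }
    )


class RunConfig(BaseModel):
    scenario_id: str = "scenario"
    longlist: LongListConfig = Field(default_factory=LongListConfig)
    nutrition: NutritionConfig = Field(default_factory=NutritionConfig)
    microbiology: MicrobiologyConfig = Field(default_factory=MicrobiologyConfig)
    toxicology: ToxicologyConfig = Field(default_factory=ToxicologyConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def default_config(scenario_id: str = "novrba") -> RunConfig:
    """The NovRBA default profile."""
    return RunConfig(scenario_id=scenario_id)
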