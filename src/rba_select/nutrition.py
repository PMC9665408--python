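"""Nutrition prioritization index.

Occurrence (criterion 1) has two sub-criteria: presence of the nutrient
in the raw material (fraction of analyzed samples in which it was
reported) and the effect of processing on its concentration.  Severity
(criterion 2) — public-health / nutrition considerations — has three:
policy relevance (dietary guidelines and fortification schemes),
contribution of the food to population intake of the nutrient, and
matrix-driven bioavailability reduction.  Each sub-criterion is graded
1-3 and all five levels are multiplied, so the index spans 1-243 and
severity carries 3/5 of the sub-criteria against 2/5 for occurrence —
nutrients are naturally present and obtainable from many foods, so
public-health impact is weighted above mere occurrence.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

from .config import NutritionConfig
from .core import ComponentProfile, Domain, PrioritizationIndex, SubScore

_DEFAULT = NutritionConfig()


def resolve_detection_sources(
    measurements: Mapping[str, float],
) -> float:
    """Pick one detection fraction from conflicting sources.

    National food-composition repositories are considered more robust
    than analytical results reported for a single sample, so a
    ``national_repository`` entry wins whenever present.
    """
    if not measurements:
        raise ValueError("no detection measurements supplied")
    if "national_repository" in measurements:
        return measurements["national_repository"]
    if len(measurements) == 1:
        return next(iter(measurements.values()))
    # several non-repository sources: take the most complete coverage
    return max(measurements.values())


def score_presence(
    sample_detection_fraction: float | Mapping[str, float] | None,
    qualitative_presence: Optional[str] = None,
    config: NutritionConfig = _DEFAULT,
) -> SubScore:
    """Grade how consistently the nutrient shows up in analyzed samples.

    Level 1: absent or reported in fewer than 10% of samples; level 3:
    present in all samples analyzed; level 2: anything in between.
    A mapping of source name -> fraction is resolved with
    :func:`resolve_detection_sources` first.
    """
    if isinstance(sample_detection_fraction, Mapping):
        fraction: Optional[float] = resolve_detection_sources(
            sample_detection_fraction
        )
    else:
        fraction = sample_detection_fraction
    if fraction is None:
        if qualitative_presence == "absent":
            fraction = 0.0
        elif qualitative_presence == "present_all":
            fraction = 1.0
        else:
            raise ValueError(
                "need a sample detection fraction or a qualitative presence flag"
            )
    if not 0 <= fraction <= 1:
        raise ValueError(f"detection fraction {fraction} outside [0, 1]")
    if fraction < config.presence_low_fraction:
        level, why = 1, f"absent or infrequent (<{config.presence_low_fraction:.0%} of samples)"
    elif fraction == 1.0:
        level, why = 3, "present in all samples analyzed"
    else:
        level, why = 2, "detected in >=10% but not all samples"
    return SubScore(
        name="presence",
        level=level,
        rationale=f"detection fraction {fraction:.2f}: {why}",
    )


def score_processing_effect(
    processing_effect_class: str, config: NutritionConfig = _DEFAULT
) -> SubScore:
    """Grade the impact of the manufacturing process on the nutrient level.

    Default map: large reduction/loss -> 1, moderate change -> 2,
    preserved or concentrated -> 3 (higher level = more of the nutrient
    survives into the consumed food).
    """
    try:
        level = config.processing_level_map[processing_effect_class]
    except KeyError:
        raise ValueError(
            f"unknown processing effect class {processing_effect_class!r}"
        ) from None
    return SubScore(
        name="processing_effect",
        level=level,
        rationale=f"processing: {processing_effect_class}",
    )


def score_policy_relevance(fbdg_scope: str, fortification_scope: str) -> SubScore:
    """Grade inclusion in food policy: food-based dietary guidelines and
    national fortification schemes.

    Level 1 if the nutrient features in neither policy instrument in any
    country under study, level 3 if either covers all countries, level 2
    for partial coverage.
    """
    scopes = {"none": 0, "some_countries": 1, "all_countries": 2}
    try:
        strongest = max(scopes[fbdg_scope], scopes[fortification_scope])
    except KeyError as exc:
        raise ValueError(f"unknown policy scope {exc.args[0]!r}") from None
    level = {0: 1, 1: 2, 2: 3}[strongest]
    return SubScore(
        name="policy_relevance",
        level=level,
        rationale=f"FBDG scope {fbdg_scope}, fortification scope {fortification_scope}",
    )


def score_intake_contribution(
    intake_contribution_fraction: Optional[float] = None,
    composition_difference_class: Optional[str] = None,
    config: NutritionConfig = _DEFAULT,
) -> SubScore:
    """Grade the contribution of the food to population intake of the
    nutrient.

    Layer 1 (preferred): the average contribution fraction of the food to
    the nutrient's intake, binned at the configured cuts (default
    tertiles 1/3 and 2/3).  Layer 2 (fallback when no intake survey
    covers the food): a qualitative class of the composition difference
    between the two foods.
    """
    if intake_contribution_fraction is not None:
        f = intake_contribution_fraction
        if not 0 <= f <= 1:
            raise ValueError(f"intake contribution {f} outside [0, 1]")
        lo, hi = config.intake_contribution_cuts
        level = 1 if f <= lo else (2 if f <= hi else 3)
        return SubScore(
            name="intake_contribution",
            level=level,
            rationale=f"layer 1: food contributes {f:.0%} of intake",
        )
    if composition_difference_class is not None:
        try:
            level = config.composition_difference_level_map[
                composition_difference_class
            ]
        except KeyError:
            raise ValueError(
                f"unknown composition difference class "
                f"{composition_difference_class!r}"
            ) from None
        return SubScore(
            name="intake_contribution",
            level=level,
            rationale=f"layer 2 fallback: {composition_difference_class}",
        )
    raise ValueError("need layer-1 fraction or layer-2 composition class")


def score_bioavailability(
    bioavailability_reduction: str, config: NutritionConfig = _DEFAULT
) -> SubScore:
    """Grade matrix impact on nutrient bioavailability.

    A strong matrix-driven reduction lowers the public-health weight of
    this food as a source of the nutrient: significant -> 1,
    moderate -> 2, mild or none -> 3.
    """
    try:
        level = config.bioavailability_level_map[bioavailability_reduction]
    except KeyError:
        raise ValueError(
            f"unknown bioavailability class {bioavailability_reduction!r}"
        ) from None
    return SubScore(
        name="bioavailability",
        level=level,
        rationale=f"bioavailability reduction: {bioavailability_reduction}",
    )


def nutrition_index(
    component_id: str,
    food_id: str,
    occurrence_subs: Sequence[SubScore],
    severity_subs: Sequence[SubScore],
) -> PrioritizationIndex:
    """Combine the five nutrition sub-scores into the prioritization index.

    occurrence = presence x processing (1-9); severity = policy x intake
    x bioavailability (1-27); index = occurrence x severity (1-243).
    """
    if len(occurrence_subs) != 2:
        raise ValueError("nutrition occurrence takes exactly 2 sub-scores")
    if len(severity_subs) != 3:
        raise ValueError("nutrition severity takes exactly 3 sub-scores")
    occ = math.prod(s.level for s in occurrence_subs)
    sev = math.prod(s.level for s in severity_subs)
    return PrioritizationIndex(
        component_id=component_id,
        food_id=food_id,
        domain=Domain.NUTRITION,
        occurrence_score=occ,
        severity_score=sev,
        index=occ * sev,
        sub_scores=list(occurrence_subs) + list(severity_subs),
    )


def score_nutrition_profile(
    profile: ComponentProfile, config: NutritionConfig = _DEFAULT
) -> PrioritizationIndex:
    """Score one nutrition profile end to end from its raw attributes."""
    a = profile.attributes
    presence = score_presence(
        profile.sample_detection_fraction,
        qualitative_presence=a.get("qualitative_presence"),
        config=config,
    )
    processing = score_processing_effect(a["processing_effect_class"], config)
    policy = score_policy_relevance(a["fbdg_scope"], a["fortification_scope"])
    intake = score_intake_contribution(
        a.get("intake_contribution_fraction"),
        a.get("composition_difference_class"),
        config,
    )
    bioavail = score_bioavailability(a["bioavailability_reduction"], config)
    return nutrition_index(
        profile.component_id,
        profile.food_id,
        [presence, processing],
        [policy, intake, bioavail],
    )
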