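"""Microbiological hazard prioritization index.

Occurrence (criterion 1) multiplies two 1-3 sub-scores — prevalence of
the hazard in the raw food and the effect of the manufacturing process
(can it reduce/eliminate the organism, or introduce it?) — and the raw
product (1..9) is banded back to 1-3 so that, after multiplication with
severity, the final index keeps its 1-9 range with the two criteria
contributing equally.  Severity (criterion 2) bins the mean disease
burden per 1,000 cases of illness, in disability-adjusted life years
(DALYs): <10 -> 1, 10-99 -> 2, 100-1,000 -> 3.
"""

from __future__ import annotations

import warnings

from .config import MicrobiologyConfig
from .core import ComponentProfile, Domain, PrioritizationIndex, SubScore

_DEFAULT = MicrobiologyConfig()


def micro_occurrence(
    prevalence_level: int,
    process_level: int,
    config: MicrobiologyConfig = _DEFAULT,
) -> int:
    """Combine prevalence and process-effect sub-scores into the 1-3
    occurrence criterion score.

    The raw product of the two levels lies in {1,2,3,4,6,9}; the default
    band map sends 1-2 -> 1, 3-4 -> 2, 6-9 -> 3.
    """
    for name, lv in (("prevalence", prevalence_level), ("process", process_level)):
        if lv not in (1, 2, 3):
            raise ValueError(f"{name} level {lv} not in {{1,2,3}}")
    raw = prevalence_level * process_level
    return config.occurrence_band_map[raw]


def micro_severity(
    daly_per_1000_cases: float, config: MicrobiologyConfig = _DEFAULT
) -> int:
    """Bin mean DALYs per 1,000 cases into the 1-3 severity score.

    Bin edges are closed on the left: exactly 10 falls in the 10-99 band
    (score 2) and exactly 100 in the 100-1,000 band (score 3).  Values
    above 1,000 exceed the top of the printed scale and clamp to 3 with
    a warning.
    """
    if daly_per_1000_cases < 0:
        raise ValueError("DALY per 1000 cases must be non-negative")
    lo, hi = config.severity_bins
    if daly_per_1000_cases > 1000:
        warnings.warn(
            f"DALY/1000 cases = {daly_per_1000_cases:g} exceeds the 1,000 "
            "top of the severity scale; clamping to score 3",
            stacklevel=2,
        )
        return 3
    if daly_per_1000_cases < lo:
        return 1
    if daly_per_1000_cases < hi:
        return 2
    return 3


def micro_index(
    component_id: str,
    food_id: str,
    occurrence: int,
    severity: int,
    sub_scores: list[SubScore] | None = None,
) -> PrioritizationIndex:
    """index = occurrence x severity, the two criteria weighted equally."""
    for name, v in (("occurrence", occurrence), ("severity", severity)):
        if v not in (1, 2, 3):
            raise ValueError(f"{name} criterion score {v} not in {{1,2,3}}")
    return PrioritizationIndex(
        component_id=component_id,
        food_id=food_id,
        domain=Domain.MICROBIOLOGY,
        occurrence_score=occurrence,
        severity_score=severity,
        index=occurrence * severity,
        sub_scores=sub_scores or [],
    )


def score_micro_profile(
    profile: ComponentProfile, config: MicrobiologyConfig = _DEFAULT
) -> PrioritizationIndex:
    """Score one microbiological hazard profile from its raw attributes."""
    a = profile.attributes
    prev_class = a["prevalence_class"]
    proc_class = a["process_effect_class"]
    try:
        prev_level = config.prevalence_level_map[prev_class]
    except KeyError:
        raise ValueError(f"unknown prevalence class {prev_class!r}") from None
    try:
        proc_level = config.process_level_map[proc_class]
    except KeyError:
        raise ValueError(f"unknown process effect class {proc_class!r}") from None

    daly = a["daly_per_1000_cases"]
    if a.get("daly_unit") == "per_case":
        daly = daly * 1000.0  # accept DALY/case inputs; scale is per 1,000 cases

    occurrence = micro_occurrence(prev_level, proc_level, config)
    severity = micro_severity(daly, config)
    subs = [
        SubScore(
            name="prevalence",
            level=prev_level,
            rationale=f"prevalence in raw food: {prev_class}",
        ),
        SubScore(
            name="process_effect",
            level=proc_level,
            rationale=f"manufacturing process: {proc_class}",
        ),
        SubScore(
            name="daly_burden",
            level=severity,
            rationale=f"{daly:g} DALYs per 1,000 cases",
        ),
    ]
    return micro_index(
        profile.component_id, profile.food_id, occurrence, severity, subs
    )
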