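"""Chemical hazard prioritization index.

Occurrence (criterion 1) has two sub-criteria.  Presence relative to
reference doses: 1 when the concentration sits below the analytical
limit of detection/quantitation (LOD/LOQ); otherwise 3 when total
exposure exceeds the health-based guidance value (HBGV, non-genotoxic
path) or the margin of exposure (MoE) is below 10,000 (genotoxic
carcinogens), and 2 when it does not.  Contribution to total dietary
exposure: >50% -> 3, 10-50% -> 2, <10% -> 1.  The two sub-scores are
combined to a single 1-3 criterion score (default: ceiling of the mean)
so the final index keeps the printed 1-9 range.

Severity (criterion 2) counts how many of four statements hold: high
incidence of the associated condition in the population, fatality,
lifelong disability, high disability (rounded disability weight > 0.4).
"""

from __future__ import annotations

import math

from .config import ToxicologyConfig
from .core import ComponentProfile, Domain, PrioritizationIndex, SubScore

_DEFAULT = ToxicologyConfig()

SEVERITY_STATEMENTS = (
    "sev_high_incidence",
    "sev_fatal",
    "sev_lifelong_disability",
    "sev_high_disability",
)


def tox_presence_score(
    above_lod_loq: bool,
    genotoxic_carcinogen: bool,
    exceeds_hbgv: bool | None = None,
    moe_below_10000: bool | None = None,
) -> SubScore:
    """Grade presence relative to reference doses.

    The exceedance flag consulted depends on the carcinogenicity path:
    genotoxic carcinogens use the MoE < 10,000 flag, everything else the
    HBGV-exceedance flag.  The flag for the applicable path is required
    whenever the compound is above LOD/LOQ.
    """
    if not above_lod_loq:
        return SubScore(
            name="presence_vs_reference",
            level=1,
            rationale="concentration below LOD/LOQ",
        )
    if genotoxic_carcinogen:
        if moe_below_10000 is None:
            raise ValueError(
                "genotoxic carcinogen above LOD/LOQ needs the MoE<10,000 flag"
            )
        if moe_below_10000:
            return SubScore(
                name="presence_vs_reference",
                level=3,
                rationale="above LOD/LOQ and MoE below 10,000",
            )
        return SubScore(
            name="presence_vs_reference",
            level=2,
            rationale="above LOD/LOQ, MoE above 10,000",
        )
    if exceeds_hbgv is None:
        raise ValueError(
            "non-genotoxic compound above LOD/LOQ needs the HBGV exceedance flag"
        )
    if exceeds_hbgv:
        return SubScore(
            name="presence_vs_reference",
            level=3,
            rationale="above LOD/LOQ and total exposure exceeds the HBGV",
        )
    return SubScore(
        name="presence_vs_reference",
        level=2,
        rationale="above LOD/LOQ, total exposure within the HBGV",
    )


def tox_exposure_contribution_score(
    exposure_share_of_diet: float, config: ToxicologyConfig = _DEFAULT
) -> SubScore:
    """Grade the share of total dietary exposure coming from this food.

    Bands read the printed "10-50" range as closed: exactly 10% and
    exactly 50% both score 2.
    """
    f = exposure_share_of_diet
    if not 0 <= f <= 1:
        raise ValueError(f"exposure share {f} outside [0, 1]")
    lo, hi = config.exposure_bins
    level = 1 if f < lo else (2 if f <= hi else 3)
    return SubScore(
        name="exposure_contribution",
        level=level,
        rationale=f"food supplies {f:.0%} of total dietary exposure",
    )


def tox_occurrence(
    presence_score: int,
    contribution_score: int,
    config: ToxicologyConfig = _DEFAULT,
) -> int:
    """Combine the two occurrence sub-scores into one 1-3 criterion score.

    Default combiner is the ceiling of the arithmetic mean, which keeps
    the final index within 1-9; ``min`` and ``max`` are selectable.
    """
    for name, v in (
        ("presence", presence_score),
        ("contribution", contribution_score),
    ):
        if v not in (1, 2, 3):
            raise ValueError(f"{name} sub-score {v} not in {{1,2,3}}")
    if config.occurrence_combiner == "ceil_mean":
        return math.ceil((presence_score + contribution_score) / 2)
    if config.occurrence_combiner == "min":
        return min(presence_score, contribution_score)
    if config.occurrence_combiner == "max":
        return max(presence_score, contribution_score)
    raise ValueError(f"unknown combiner {config.occurrence_combiner!r}")


def tox_severity(
    high_incidence: bool,
    fatal: bool,
    lifelong_disability: bool,
    high_disability: bool,
    config: ToxicologyConfig = _DEFAULT,
) -> int:
    """Count true severity statements and map the count to a 1-3 score
    (default: 0-1 true -> 1, 2 -> 2, 3-4 -> 3)."""
    k = sum(
        bool(s)
        for s in (high_incidence, fatal, lifelong_disability, high_disability)
    )
    return config.severity_map[k]


def tox_index(
    component_id: str,
    food_id: str,
    occurrence: int,
    severity: int,
    sub_scores: list[SubScore] | None = None,
) -> PrioritizationIndex:
    """index = occurrence x severity, the two criteria contributing equally."""
    for name, v in (("occurrence", occurrence), ("severity", severity)):
        if v not in (1, 2, 3):
            raise ValueError(f"{name} criterion score {v} not in {{1,2,3}}")
    return PrioritizationIndex(
        component_id=component_id,
        food_id=food_id,
        domain=Domain.TOXICOLOGY,
        occurrence_score=occurrence,
        severity_score=severity,
        index=occurrence * severity,
        sub_scores=sub_scores or [],
    )


def score_tox_profile(
    profile: ComponentProfile, config: ToxicologyConfig = _DEFAULT
) -> PrioritizationIndex:
    """Score one chemical hazard profile from its raw attributes."""
    a = profile.attributes
    presence = tox_presence_score(
        a["above_lod_loq"],
        a["genotoxic_carcinogen"],
        exceeds_hbgv=a.get("exceeds_hbgv"),
        moe_below_10000=a.get("moe_below_10000"),
    )
    contribution = tox_exposure_contribution_score(
        a["exposure_share_of_diet"], config
    )
    occurrence = tox_occurrence(presence.level, contribution.level, config)
    statements = [bool(a[k]) for k in SEVERITY_STATEMENTS]
    severity = tox_severity(*statements, config=config)
    subs = [
        presence,
        contribution,
        SubScore(
            name="outcome_severity",
            level=severity,
            rationale=f"{sum(statements)}/4 severity statements hold",
        ),
    ]
    return tox_index(
        profile.component_id, profile.food_id, occurrence, severity, subs
    )
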