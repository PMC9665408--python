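"""Long-list assembly and the evidence gate.

The long list pairs the two foods' profiles per component.  Nutrition
applies two inclusion rules specific to a substitution scenario: a
nutrient quantified in only one food is always kept (the substitution
changes its intake by definition), while a nutrient present in both is
kept only when the concentration difference exceeds a threshold
(default 20%: 10% allowed for analytical error plus a minimum meaningful
10% difference between foods).  Microbiological and toxicological
hazards are all kept — any contamination found in either food matters.

The evidence gate then removes components whose link to a health outcome
is not backed by convincing evidence.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .config import LongListConfig
from .core import (
    ComponentProfile,
    Decision,
    Domain,
    EvidenceLevel,
    LedgerEntry,
    SelectionLedger,
    Stage,
)


class UndefinedDifferenceError(ValueError):
    """Both concentrations are zero: the relative difference is undefined."""


class DuplicateProfileError(ValueError):
    """The same (component, food) appears twice in one input table."""


class LongListMember(BaseModel):
    component_id: str
    domain: Domain
    profile_a: Optional[ComponentProfile] = None
    profile_b: Optional[ComponentProfile] = None

    def profiles(self) -> list[ComponentProfile]:
        return [p for p in (self.profile_a, self.profile_b) if p is not None]


class LongList(BaseModel):
    scenario_id: str = "scenario"
    members: list[LongListMember] = Field(default_factory=list)

    def by_domain(self, domain: Domain) -> list[LongListMember]:
        return [m for m in self.members if m.domain is domain]

    def component_ids(self) -> set[str]:
        return {m.component_id for m in self.members}


def relative_difference(
    conc_a: float, conc_b: float, denominator: str = "mean"
) -> float:
    """Relative concentration difference |a - b| / denom.

    With the default ``mean`` denominator the measure is symmetric in the
    two foods and scale-invariant, and ranges over [0, 2] (2 when one
    concentration is zero).  ``max`` and ``reference_a`` are alternative
    denominators for assessors who privilege one food.
    """
    if conc_a < 0 or conc_b < 0:
        raise ValueError("concentrations must be non-negative")
    if conc_a == 0 and conc_b == 0:
        raise UndefinedDifferenceError(
            "relative difference undefined when both concentrations are zero"
        )
    diff = abs(conc_a - conc_b)
    if denominator == "mean":
        denom = (conc_a + conc_b) / 2
    elif denominator == "max":
        denom = max(conc_a, conc_b)
    elif denominator == "reference_a":
        if conc_a == 0:
            raise UndefinedDifferenceError("reference concentration is zero")
        denom = conc_a
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return diff / denom


def _index_unique(
    profiles: Sequence[ComponentProfile], label: str
) -> dict[tuple[str, Domain], ComponentProfile]:
    # keyed by (component, domain): the same substance may appear both as
    # a nutrient and as a contaminant (e.g. aluminum, chromium)
    out: dict[tuple[str, Domain], ComponentProfile] = {}
    for p in profiles:
        key = (p.component_id, p.domain)
        if key in out:
            raise DuplicateProfileError(
                f"duplicate row for component {p.component_id!r} "
                f"({p.domain.value}) in {label}"
            )
        out[key] = p
    return out


def build_long_list(
    profiles_a: Sequence[ComponentProfile],
    profiles_b: Sequence[ComponentProfile],
    config: LongListConfig | None = None,
    scenario_id: str = "scenario",
    ledger: SelectionLedger | None = None,
) -> tuple[LongList, SelectionLedger]:
    """Assemble the long list from the two foods' profile tables.

    Every candidate component receives exactly one long-list ledger entry;
    nutrition exclusions carry the computed concentration difference.
    """
    config = config or LongListConfig()
    ledger = ledger if ledger is not None else SelectionLedger()
    by_a = _index_unique(profiles_a, "food A profiles")
    by_b = _index_unique(profiles_b, "food B profiles")

    long_list = LongList(scenario_id=scenario_id)
    for cid, domain in sorted(set(by_a) | set(by_b), key=lambda k: (k[1].value, k[0])):
        pa, pb = by_a.get((cid, domain)), by_b.get((cid, domain))

        include = True
        reason = ""
        if domain is not Domain.NUTRITION:
            reason = "hazard found in at least one food"
        elif pa is None or pb is None:
            reason = "nutrient quantified in one food only (substitution)"
        elif pa.concentration is None or pb.concentration is None:
            # numeric rule needs two numbers; qualitative presence keeps it
            reason = "nutrient present in both foods, concentration not paired"
        else:
            if pa.unit != pb.unit:
                raise ValueError(
                    f"unit mismatch for {cid!r}: {pa.unit!r} vs {pb.unit!r}"
                )
            rd = relative_difference(
                pa.concentration, pb.concentration, config.denominator
            )
            if rd > config.concentration_diff_threshold:
                reason = (
                    f"concentration difference {rd:.1%} > "
                    f"{config.concentration_diff_threshold:.0%}"
                )
            else:
                include = False
                reason = (
                    f"concentration difference {rd:.1%} <= "
                    f"{config.concentration_diff_threshold:.0%}"
                )

        decision = Decision.INCLUDED if include else Decision.EXCLUDED
        for p in (pa, pb):
            if p is not None:
                ledger.record(cid, p.food_id, Stage.LONGLIST, decision, reason)
        if include:
            long_list.members.append(
                LongListMember(
                    component_id=cid, domain=domain, profile_a=pa, profile_b=pb
                )
            )
    return long_list, ledger


def evidence_gate(
    long_list: LongList, ledger: SelectionLedger | None = None
) -> tuple[LongList, SelectionLedger]:
    """Drop components whose evidence of a health-outcome link is not
    convincing ("limited" or "contradictory" evidence excludes).

    Evidence is annotated per profile; the component passes only if every
    food's annotation is convincing.
    """
    ledger = ledger if ledger is not None else SelectionLedger()
    gated = LongList(scenario_id=long_list.scenario_id)
    for member in long_list.members:
        profiles = member.profiles()
        if not profiles:
            raise ValueError(f"long-list member {member.component_id!r} empty")
        weak = [
            p for p in profiles if p.evidence_level is not EvidenceLevel.CONVINCING
        ]
        include = not weak
        for p in profiles:
            if include:
                ledger.record(
                    member.component_id,
                    p.food_id,
                    Stage.EVIDENCE_GATE,
                    Decision.INCLUDED,
                    "evidence level convincing",
                )
            else:
                levels = ", ".join(sorted({w.evidence_level.value for w in weak}))
                ledger.record(
                    member.component_id,
                    p.food_id,
                    Stage.EVIDENCE_GATE,
                    Decision.EXCLUDED,
                    f"evidence level: {levels}",
                )
        if include:
            gated.members.append(member)
    return gated, ledger
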