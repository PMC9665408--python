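"""Short-list and final-list selection.

Scored components are ranked per food and domain, cut at an inclusive
index threshold (defaults: 108 in nutrition, 2 for microbiological and
chemical hazards — the same hazard limit for both foods, giving each
field equal importance), expanded by the nutrient symmetry rule (a
nutrient short-listed for only one food of a substitution pair is
assessed for both), and finally gated on the data-availability
checklist that decides whether the quantitative health-impact model can
actually include the component.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, Field

from .config import SelectionConfig
from .core import (
    ChecklistStatus,
    Decision,
    Domain,
    PrioritizationIndex,
    SelectionLedger,
    Stage,
)

_DEFAULT = SelectionConfig()


class ShortListEntry(BaseModel):
    index: PrioritizationIndex
    rank: int


class FinalCandidate(BaseModel):
    """A component x food forwarded to the checklist gate.

    ``symmetry_added`` marks nutrients added for the food in which they
    were *not* short-listed, to assess the intake change on both sides of
    the substitution.
    """

    component_id: str
    food_id: str
    domain: Domain
    symmetry_added: bool = False


class FinalListEntry(BaseModel):
    component_id: str
    food_id: str
    domain: Domain
    symmetry_added: bool = False


def rank_components(
    indices: Sequence[PrioritizationIndex],
) -> list[PrioritizationIndex]:
    """Order components of one domain by descending prioritization index.

    Ties break deterministically: higher severity criterion first, then
    component id lexicographically.
    """
    domains = {ix.domain for ix in indices}
    if len(domains) > 1:
        raise ValueError(f"mixed domains in ranking input: {domains}")
    return sorted(
        indices,
        key=lambda ix: (-ix.index, -ix.severity_score, ix.component_id),
    )


def apply_shortlist_threshold(
    ranked: Sequence[PrioritizationIndex],
    domain: Domain,
    config: SelectionConfig = _DEFAULT,
    ledger: SelectionLedger | None = None,
) -> tuple[list[ShortListEntry], SelectionLedger]:
    """Cut the ranked list at the domain's inclusive threshold
    (index >= threshold keeps the component)."""
    ledger = ledger if ledger is not None else SelectionLedger()
    threshold = config.thresholds[domain.value]
    if threshold < 1:
        raise ValueError("thresholds must be positive integers")
    kept: list[ShortListEntry] = []
    for rank, ix in enumerate(ranked, start=1):
        if ix.domain is not domain:
            raise ValueError(
                f"index for {ix.component_id!r} is {ix.domain.value}, "
                f"expected {domain.value}"
            )
        if ix.index >= threshold:
            kept.append(ShortListEntry(index=ix, rank=rank))
            ledger.record(
                ix.component_id,
                ix.food_id,
                Stage.SHORTLIST,
                Decision.INCLUDED,
                f"index {ix.index} >= threshold {threshold}",
            )
        else:
            ledger.record(
                ix.component_id,
                ix.food_id,
                Stage.SHORTLIST,
                Decision.EXCLUDED,
                f"index {ix.index} < threshold {threshold}",
            )
    return kept, ledger


def apply_nutrient_symmetry(
    shortlist_a: Sequence[ShortListEntry],
    shortlist_b: Sequence[ShortListEntry],
    food_a: str,
    food_b: str,
) -> list[FinalCandidate]:
    """Expand the nutrition short lists so every short-listed nutrient is
    a final-list candidate for *both* foods of the substitution.

    Hazards never go through this: a hazard is a contamination of one
    specific food, so each food is considered independently there.
    """
    for entry in list(shortlist_a) + list(shortlist_b):
        if entry.index.domain is not Domain.NUTRITION:
            raise ValueError(
                "nutrient symmetry applies to the nutrition domain only"
            )
    in_a = {e.index.component_id for e in shortlist_a}
    in_b = {e.index.component_id for e in shortlist_b}
    candidates: list[FinalCandidate] = []
    for cid in sorted(in_a | in_b):
        candidates.append(
            FinalCandidate(
                component_id=cid,
                food_id=food_a,
                domain=Domain.NUTRITION,
                symmetry_added=cid not in in_a,
            )
        )
        candidates.append(
            FinalCandidate(
                component_id=cid,
                food_id=food_b,
                domain=Domain.NUTRITION,
                symmetry_added=cid not in in_b,
            )
        )
    return candidates


def hazard_candidates(
    shortlist: Sequence[ShortListEntry],
) -> list[FinalCandidate]:
    """Forward hazard short-list entries unchanged to the checklist gate."""
    return [
        FinalCandidate(
            component_id=e.index.component_id,
            food_id=e.index.food_id,
            domain=e.index.domain,
        )
        for e in shortlist
    ]


def _missing_items(status: ChecklistStatus, domain: Domain) -> list[str]:
    missing = []
    if not status.has_dose_response:
        missing.append("dose-response data")
    if not status.has_incidence:
        missing.append("health-outcome incidence data")
    if domain is Domain.MICROBIOLOGY and not status.has_source_attribution:
        missing.append("source attribution data")
    if not status.has_intake_data:
        missing.append("food intake data")
    if not status.has_composition_or_contamination:
        missing.append("composition/contamination data")
    if not status.has_daly_per_case:
        missing.append("DALY per case")
    return missing


def apply_checklist_gate(
    candidates: Iterable[FinalCandidate],
    checklist: Mapping[tuple[str, str], ChecklistStatus],
    ledger: SelectionLedger | None = None,
) -> tuple[list[FinalListEntry], SelectionLedger]:
    """Keep candidates for which every applicable data item is available.

    A candidate missing any item is excluded with the missing items named
    in the ledger: such components remain a source of uncertainty in the
    assessment and a priority for future data collection, so the record
    must say exactly what was lacking.
    """
    ledger = ledger if ledger is not None else SelectionLedger()
    final: list[FinalListEntry] = []
    for cand in candidates:
        key = (cand.component_id, cand.food_id)
        if key not in checklist:
            raise KeyError(f"no checklist status for component x food {key}")
        status = checklist[key]
        if (
            cand.domain is Domain.MICROBIOLOGY
            and status.has_source_attribution is None
        ):
            raise ValueError(
                f"microbiology candidate {key} needs an explicit "
                "source-attribution flag"
            )
        missing = _missing_items(status, cand.domain)
        if missing:
            ledger.record(
                cand.component_id,
                cand.food_id,
                Stage.FINALLIST,
                Decision.EXCLUDED,
                "missing: " + "; ".join(missing),
            )
        else:
            final.append(
                FinalListEntry(
                    component_id=cand.component_id,
                    food_id=cand.food_id,
                    domain=cand.domain,
                    symmetry_added=cand.symmetry_added,
                )
            )
            ledger.record(
                cand.component_id,
                cand.food_id,
                Stage.FINALLIST,
                Decision.INCLUDED,
                "all required data available",
            )
    return final, ledger
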