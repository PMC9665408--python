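"""Input/output and pipeline orchestration.

Profiles and checklists travel as comma-separated UTF-8 tables with a
header row, one row per component x food; everything the engine emits
(ledger, indices, full run report) serializes to structured JSON that
round-trips losslessly.  ``run_pipeline`` wires the stages together:
long list -> evidence gate -> scoring -> short list -> nutrient
symmetry -> checklist gate.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .config import RunConfig
from .core import (
    ChecklistStatus,
    ComponentProfile,
    Domain,
    OutcomeLink,
    PrioritizationIndex,
    SelectionLedger,
    validate_profile,
)
from .longlist import LongList, build_long_list, evidence_gate
from .microbiology import score_micro_profile
from .nutrition import score_nutrition_profile
from .selection import (
    FinalListEntry,
    ShortListEntry,
    apply_checklist_gate,
    apply_nutrient_symmetry,
    apply_shortlist_threshold,
    hazard_candidates,
    rank_components,
)
from .toxicology import score_tox_profile

logger = logging.getLogger("rba_select")

#: columns every profile table shares; anything else becomes an attribute
COMMON_COLUMNS = (
    "component_id",
    "food_id",
    "domain",
    "concentration",
    "unit",
    "prevalence_fraction",
    "sample_detection_fraction",
    "processing_effect",
    "evidence_level",
)

_CHECKLIST_FLAGS = (
    "has_dose_response",
    "has_incidence",
    "has_source_attribution",
    "has_intake_data",
    "has_composition_or_contamination",
    "has_daly_per_case",
)


class RowError(BaseModel):
    row: int  # 1-based data row number (header excluded)
    message: str


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _coerce_cell(value: Any) -> Any:
    """CSV cells carry booleans, numbers or class names; empty means absent."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return None
        if s.lower() in ("true", "false"):
            return s.lower() == "true"
        try:
            f = float(s)
        except ValueError:
            return s
        return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return value
    return value


def load_profiles(path: str | Path) -> tuple[list[ComponentProfile], list[RowError]]:
    """Read a profile table; malformed rows are collected, not raised.

    Returns the well-formed profiles plus a row-numbered error report
    (unknown domain tags, duplicate component x food keys, invalid
    field values).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("component_id", "food_id", "domain") if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path} lacks required columns {missing}")
    profiles: list[ComponentProfile] = []
    errors: list[RowError] = []
    seen: set[tuple[str, str, Domain]] = set()
    attr_cols = [c for c in df.columns if c not in COMMON_COLUMNS]
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        common = {k: _coerce_cell(row.get(k)) for k in COMMON_COLUMNS}
        attrs = {
            c: v for c in attr_cols if (v := _coerce_cell(row.get(c))) is not None
        }
        try:
            profile = ComponentProfile(
                component_id=str(common["component_id"]),
                food_id=str(common["food_id"]),
                domain=common["domain"],
                concentration=common["concentration"],
                unit=common["unit"],
                prevalence_fraction=common["prevalence_fraction"],
                sample_detection_fraction=common["sample_detection_fraction"],
                processing_effect=common["processing_effect"],
                evidence_level=common["evidence_level"] or "convincing",
                attributes=attrs,
            )
        except Exception as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        dup_key = (profile.component_id, profile.food_id, profile.domain)
        if dup_key in seen:
            errors.append(
                RowError(row=i, message=f"duplicate component x food key {profile.key}")
            )
            continue
        seen.add(dup_key)
        profiles.append(profile)
    return profiles, errors


def write_profiles(profiles: Sequence[ComponentProfile], path: str | Path) -> None:
    rows = []
    attr_cols: list[str] = []
    for p in profiles:
        row = {k: getattr(p, k, None) for k in COMMON_COLUMNS}
        row["domain"] = p.domain.value
        row["evidence_level"] = p.evidence_level.value
        row["processing_effect"] = (
            p.processing_effect.value if p.processing_effect else None
        )
        for k, v in p.attributes.items():
            if k not in attr_cols:
                attr_cols.append(k)
            row[k] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COMMON_COLUMNS) + attr_cols)
    df.to_csv(path, index=False)


def load_checklist(
    path: str | Path,
) -> dict[tuple[str, str], ChecklistStatus]:
    """Read the data-availability checklist (one row per component x food)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[tuple[str, str], ChecklistStatus] = {}
    for row in df.to_dict(orient="records"):
        kwargs: dict[str, Any] = {
            "component_id": row["component_id"],
            "food_id": row["food_id"],
        }
        for flag in _CHECKLIST_FLAGS:
            kwargs[flag] = _coerce_cell(row.get(flag))
        status = ChecklistStatus(**kwargs)
        out[status.key] = status
    return out


def load_outcome_links(path: str | Path) -> list[OutcomeLink]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        OutcomeLink(
            component_id=row["component_id"],
            outcome_name=row["outcome_name"],
            direction=row["direction"],
        )
        for row in df.to_dict(orient="records")
    ]


# --- report -------------------------------------------------------------


class ShortListSection(BaseModel):
    domain: Domain
    food_id: str
    entries: list[ShortListEntry] = Field(default_factory=list)


class RunReport(BaseModel):
    """Everything one pipeline run produced, in one serializable object."""

    scenario_id: str
    food_a: str
    food_b: str
    config: RunConfig
    long_list: LongList
    evidence_gated: LongList
    indices: list[PrioritizationIndex] = Field(default_factory=list)
    shortlists: list[ShortListSection] = Field(default_factory=list)
    final_list: list[FinalListEntry] = Field(default_factory=list)
    ledger: SelectionLedger = Field(default_factory=SelectionLedger)
    outcome_tree: dict[str, Any] = Field(default_factory=dict)

    def shortlist_ids(self, domain: Domain, food_id: str) -> list[str]:
        for sec in self.shortlists:
            if sec.domain is domain and sec.food_id == food_id:
                return [e.index.component_id for e in sec.entries]
        return []

    def final_ids(self, domain: Domain, food_id: str) -> list[str]:
        return sorted(
            e.component_id
            for e in self.final_list
            if e.domain is domain and e.food_id == food_id
        )

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.model_validate_json(text)


def emit_outcome_tree(
    final_list: Sequence[FinalListEntry],
    outcome_links: Sequence[OutcomeLink],
) -> dict[str, Any]:
    """Group component -> health-outcome edges for the final list.

    Each edge keeps its direction (adverse links render red, beneficial
    green, in graphical form); final-list components with no mapped
    outcome are listed separately, and links pointing at components not
    in the final list only warn.
    """
    final_ids = {e.component_id for e in final_list}
    components: dict[str, list[dict[str, str]]] = {
        cid: [] for cid in sorted(final_ids)
    }
    for link in outcome_links:
        if link.component_id not in final_ids:
            warnings.warn(
                f"outcome link for {link.component_id!r} ignores a component "
                "not on the final list",
                stacklevel=2,
            )
            continue
        components[link.component_id].append(
            {"outcome": link.outcome_name, "direction": link.direction.value}
        )
    no_outcome = sorted(cid for cid, edges in components.items() if not edges)
    return {
        "components": {cid: edges for cid, edges in components.items() if edges},
        "no_outcome_mapped": no_outcome,
    }


# --- pipeline -----------------------------------------------------------


def _score_profile(profile: ComponentProfile, config: RunConfig) -> PrioritizationIndex:
    if profile.domain is Domain.NUTRITION:
        return score_nutrition_profile(profile, config.nutrition)
    if profile.domain is Domain.MICROBIOLOGY:
        return score_micro_profile(profile, config.microbiology)
    return score_tox_profile(profile, config.toxicology)


def _infer_food_ids(
    profiles_a: Sequence[ComponentProfile],
    profiles_b: Sequence[ComponentProfile],
) -> tuple[str, str]:
    fa = {p.food_id for p in profiles_a}
    fb = {p.food_id for p in profiles_b}
    if len(fa) > 1 or len(fb) > 1:
        raise ValueError(f"each profile table must describe one food: {fa}, {fb}")
    return (fa.pop() if fa else "food_a"), (fb.pop() if fb else "food_b")


def run_pipeline(
    config: RunConfig,
    profiles_a: Sequence[ComponentProfile],
    profiles_b: Sequence[ComponentProfile],
    checklist: Mapping[tuple[str, str], ChecklistStatus],
    outcome_links: Optional[Sequence[OutcomeLink]] = None,
) -> RunReport:
    """Run the full three-tier selection, deterministically.

    Stage order: long list -> evidence gate -> scoring -> ranking and
    short-list threshold (per domain and food) -> nutrient symmetry ->
    checklist gate -> outcome tree.  The config snapshot is embedded in
    the report so a run is reproducible from the report alone.
    """
    food_a, food_b = _infer_food_ids(profiles_a, profiles_b)
    ledger = SelectionLedger()

    try:
        for p in list(profiles_a) + list(profiles_b):
            findings = validate_profile(p)
            if findings:
                raise ValueError(
                    f"profile {p.key} invalid: " + "; ".join(findings)
                )
    except ValueError as exc:
        raise PipelineError("validate", exc) from exc

    try:
        long_list, _ = build_long_list(
            profiles_a,
            profiles_b,
            config.longlist,
            scenario_id=config.scenario_id,
            ledger=ledger,
        )
    except Exception as exc:
        raise PipelineError("longlist", exc) from exc
    logger.info(
        "long list: %d candidates in, %d members kept",
        len({p.component_id for p in list(profiles_a) + list(profiles_b)}),
        len(long_list.members),
    )

    try:
        gated, _ = evidence_gate(long_list, ledger=ledger)
    except Exception as exc:
        raise PipelineError("evidence_gate", exc) from exc
    logger.info("evidence gate: %d members kept", len(gated.members))

    try:
        indices = [
            _score_profile(p, config)
            for member in gated.members
            for p in member.profiles()
        ]
    except Exception as exc:
        raise PipelineError("scoring", exc) from exc

    shortlists: list[ShortListSection] = []
    short_by_key: dict[tuple[str, str], list[ShortListEntry]] = {}
    try:
        for domain in Domain:
            for food in (food_a, food_b):
                pool = [
                    ix for ix in indices if ix.domain is domain and ix.food_id == food
                ]
                ranked = rank_components(pool)
                kept, _ = apply_shortlist_threshold(
                    ranked, domain, config.selection, ledger=ledger
                )
                shortlists.append(
                    ShortListSection(domain=domain, food_id=food, entries=kept)
                )
                short_by_key[(domain.value, food)] = kept
                logger.info(
                    "shortlist %s/%s: %d of %d", domain.value, food, len(kept), len(pool)
                )
    except Exception as exc:
        raise PipelineError("shortlist", exc) from exc

    try:
        candidates = apply_nutrient_symmetry(
            short_by_key[(Domain.NUTRITION.value, food_a)],
            short_by_key[(Domain.NUTRITION.value, food_b)],
            food_a,
            food_b,
        )
        for domain in (Domain.MICROBIOLOGY, Domain.TOXICOLOGY):
            for food in (food_a, food_b):
                candidates.extend(hazard_candidates(short_by_key[(domain.value, food)]))
        final, _ = apply_checklist_gate(candidates, checklist, ledger=ledger)
    except Exception as exc:
        raise PipelineError("finallist", exc) from exc
    logger.info("final list: %d of %d candidates", len(final), len(candidates))

    tree = emit_outcome_tree(final, outcome_links or [])

    return RunReport(
        scenario_id=config.scenario_id,
        food_a=food_a,
        food_b=food_b,
        config=config,
        long_list=long_list,
        evidence_gated=gated,
        indices=indices,
        shortlists=shortlists,
        final_list=final,
        ledger=ledger,
        outcome_tree=tree,
    )


def render_report_text(report: RunReport) -> str:
    """Human-readable summary: tier sizes, short lists, final list, tree."""
    lines: list[str] = []
    lines.append(f"Scenario: {report.scenario_id}")
    lines.append(f"Foods: {report.food_a} vs {report.food_b}")
    lines.append("")
    lines.append(
        f"Long list: {len(report.long_list.members)} components "
        f"({len(report.evidence_gated.members)} after evidence gate)"
    )
    for sec in report.shortlists:
        if not sec.entries:
            continue
        lines.append("")
        lines.append(f"Short list — {sec.domain.value} / {sec.food_id}:")
        for e in sec.entries:
            ix = e.index
            lines.append(
                f"  {e.rank:>3}. {ix.component_id:<40} index {ix.index:>3} "
                f"(occurrence {ix.occurrence_score} x severity {ix.severity_score})"
            )
    lines.append("")
    lines.append(f"Final list ({len(report.final_list)} component x food entries):")
    for e in sorted(report.final_list, key=lambda e: (e.domain.value, e.component_id, e.food_id)):
        tag = "  [added by symmetry]" if e.symmetry_added else ""
        lines.append(f"  {e.domain.value:<13} {e.component_id:<40} {e.food_id}{tag}")
    tree = report.outcome_tree
    if tree:
        lines.append("")
        lines.append("Outcome tree:")
        for cid, edges in tree.get("components", {}).items():
            for edge in edges:
                mark = "+" if edge["direction"] == "beneficial" else "-"
                lines.append(f"  {cid} --({mark}{edge['direction']})--> {edge['outcome']}")
        for cid in tree.get("no_outcome_mapped", []):
            lines.append(f"  {cid} --> (no outcome mapped)")
    return "\n".join(lines) + "\n"
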