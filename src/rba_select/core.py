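"""Shared domain types for the tiered component-selection pipeline.

A risk-benefit assessment (RBA) of a food substitution starts from the
compositional profiles of the two foods and narrows the candidate
components (nutrients, microbiological hazards, chemical hazards) through
three tiers: a *long list* of everything found, a *short list* of
components whose occurrence x severity prioritization index clears a
threshold, and a *final list* of components for which the data needed by
the quantitative health-impact model are actually available.

This module holds the data types every stage shares and the per-domain
profile validation; it performs no scoring.
"""

from __future__ import annotations

import enum
import json
from typing import Any, Iterable, Iterator, Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class Domain(str, enum.Enum):
    """The three assessment areas handled by the framework."""

    NUTRITION = "nutrition"
    MICROBIOLOGY = "microbiology"
    TOXICOLOGY = "toxicology"


HAZARD_DOMAINS = (Domain.MICROBIOLOGY, Domain.TOXICOLOGY)


class EvidenceLevel(str, enum.Enum):
    """Weight of evidence linking a component to a health outcome.

    Only components with *convincing* evidence pass the evidence gate;
    *limited* and *contradictory* evidence are grounds for exclusion.
    """

    CONVINCING = "convincing"
    LIMITED = "limited"
    CONTRADICTORY = "contradictory"


class ProcessingEffect(str, enum.Enum):
    """Qualitative effect of food processing on a component's level."""

    INTRODUCES_OR_INCREASES = "introduces_or_increases"
    NEUTRAL = "neutral"
    REDUCES = "reduces"
    ELIMINATES = "eliminates"


class Stage(str, enum.Enum):
    """Pipeline stages at which an include/exclude decision is taken."""

    LONGLIST = "longlist"
    EVIDENCE_GATE = "evidence_gate"
    SHORTLIST = "shortlist"
    FINALLIST = "finallist"


class Decision(str, enum.Enum):
    INCLUDED = "included"
    EXCLUDED = "excluded"


class OutcomeDirection(str, enum.Enum):
    BENEFICIAL = "beneficial"
    ADVERSE = "adverse"


class ComponentProfile(BaseModel):
    """One candidate component of one food, with the raw attributes the
    domain scorers consume.

    Common fields cover what every domain needs (identity, concentration,
    evidence level); everything domain-specific (policy flags,
    bioavailability class, DALY per case, guidance-value exceedance flags,
    exposure share, severity statements) lives in the open ``attributes``
    map and is validated per domain by :func:`validate_profile`.
    """

    component_id: str
    food_id: str
    domain: Domain
    concentration: Optional[float] = Field(default=None, ge=0)
    unit: Optional[str] = None
    prevalence_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    sample_detection_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    processing_effect: Optional[ProcessingEffect] = None
    evidence_level: EvidenceLevel = EvidenceLevel.CONVINCING
    attributes: dict[str, Any] = Field(default_factory=dict)

    model_config = {"frozen": False}

    @property
    def key(self) -> tuple[str, str]:
        return (self.component_id, self.food_id)


class SubScore(BaseModel):
    """A graded sub-criterion level (1-3) with a human-readable rationale."""

    name: str
    level: int = Field(ge=1, le=3)
    rationale: str = ""


class PrioritizationIndex(BaseModel):
    """Occurrence x severity prioritization index of one component in one food.

    The index is the product of the two criterion scores, each itself a
    product of graded 1-3 sub-criterion levels.  Nutrition uses five
    sub-criteria (2 occurrence, 3 severity), so its index spans 1-243;
    the hazard domains use one 1-3 score per criterion, spanning 1-9.
    """

    component_id: str
    food_id: str
    domain: Domain
    occurrence_score: int = Field(ge=1)
    severity_score: int = Field(ge=1)
    index: int = Field(ge=1)
    sub_scores: list[SubScore] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_product(self) -> "PrioritizationIndex":
        if self.index != self.occurrence_score * self.severity_score:
            raise ValueError(
                f"index {self.index} != occurrence {self.occurrence_score} "
                f"x severity {self.severity_score}"
            )
        hi = 243 if self.domain is Domain.NUTRITION else 9
        if not 1 <= self.index <= hi:
            raise ValueError(
                f"{self.domain.value} index {self.index} outside [1, {hi}]"
            )
        return self

    @property
    def key(self) -> tuple[str, str]:
        return (self.component_id, self.food_id)


class LedgerEntry(BaseModel):
    component_id: str
    food_id: str
    stage: Stage
    decision: Decision
    reason: str


class SelectionLedger(BaseModel):
    """Append-only audit trail of every inclusion/exclusion decision.

    Transparency is the point of the framework: a component dropped at any
    tier must be reported alongside the assessment results, so every stage
    records exactly one entry per component x food it evaluated.
    """

    entries: list[LedgerEntry] = Field(default_factory=list)

    def record(
        self,
        component_id: str,
        food_id: str,
        stage: Stage,
        decision: Decision,
        reason: str,
    ) -> None:
        self.entries.append(
            LedgerEntry(
                component_id=component_id,
                food_id=food_id,
                stage=stage,
                decision=decision,
                reason=reason,
            )
        )

    def at_stage(self, stage: Stage) -> list[LedgerEntry]:
        return [e for e in self.entries if e.stage is stage]

    def decisions(
        self, stage: Stage, decision: Decision
    ) -> set[tuple[str, str]]:
        return {
            (e.component_id, e.food_id)
            for e in self.entries
            if e.stage is stage and e.decision is decision
        }

    def extend(self, other: Iterable[LedgerEntry]) -> None:
        self.entries.extend(other)

    def __iter__(self) -> Iterator[LedgerEntry]:  # type: ignore[override]
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_ndjson(self) -> str:
        return "\n".join(json.dumps(e.model_dump(mode="json")) for e in self.entries)

    @classmethod
    def from_ndjson(cls, text: str) -> "SelectionLedger":
        entries = [
            LedgerEntry.model_validate(json.loads(line))
            for line in text.splitlines()
            if line.strip()
        ]
        return cls(entries=entries)


class ChecklistStatus(BaseModel):
    """Data-availability flags required for a component to enter the final
    list (dose-response, incidence, intake, composition/contamination and
    DALY-per-case data; source attribution applies to microbiology only).

    All flags are explicit: the final-list gate refuses to guess.
    """

    component_id: str
    food_id: str
    has_dose_response: bool
    has_incidence: bool
    has_source_attribution: Optional[bool] = None
    has_intake_data: bool
    has_composition_or_contamination: bool
    has_daly_per_case: bool

    @property
    def key(self) -> tuple[str, str]:
        return (self.component_id, self.food_id)


class OutcomeLink(BaseModel):
    """Edge from a component to one of its health outcomes.

    The same nutrient can carry both beneficial and adverse links
    (e.g. depending on intake level), so a component may have many edges.
    """

    component_id: str
    outcome_name: str
    direction: OutcomeDirection


# --- profile validation -------------------------------------------------

_NUTRITION_SCOPES = {"none", "some_countries", "all_countries"}
_BIOAVAIL_CLASSES = {"significant", "moderate", "mild_or_none"}
_NUTRITION_PROC = {"large_reduction", "moderate_change", "preserved_or_concentrated"}
_MICRO_PREVALENCE = {"low", "moderate", "high"}
_MICRO_PROCESS = {"reduces_or_eliminates", "neutral", "can_introduce"}
_TOX_SEVERITY_KEYS = (
    "sev_high_incidence",
    "sev_fatal",
    "sev_lifelong_disability",
    "sev_high_disability",
)


def _finding(findings: list[str], msg: str) -> None:
    findings.append(msg)


def _check_enum(findings: list[str], attrs: dict, key: str, allowed: set[str]) -> None:
    if key not in attrs:
        _finding(findings, f"missing attribute '{key}'")
    elif attrs[key] not in allowed:
        _finding(findings, f"attribute '{key}' has invalid value {attrs[key]!r}")


def _check_bool(findings: list[str], attrs: dict, key: str) -> None:
    if key not in attrs:
        _finding(findings, f"missing attribute '{key}'")
    elif not isinstance(attrs[key], bool):
        _finding(findings, f"attribute '{key}' must be boolean")


def validate_profile(profile: ComponentProfile) -> list[str]:
    """Check that a profile carries everything its domain's scorer needs.

    Returns a list of findings (empty iff the profile is scoreable);
    findings are data, not exceptions, so a whole table can be validated
    and reported in one pass.
    """
    findings: list[str] = []
    attrs = profile.attributes

    if profile.prevalence_fraction is not None and not (
        0 <= profile.prevalence_fraction <= 1
    ):  # pragma: no cover - pydantic blocks construction; guard for dict tampering
        _finding(findings, "prevalence_fraction outside [0, 1]")

    if profile.domain is Domain.NUTRITION:
        if (
            profile.sample_detection_fraction is None
            and "qualitative_presence" not in attrs
        ):
            _finding(
                findings,
                "missing sample_detection_fraction (or 'qualitative_presence' flag)",
            )
        _check_enum(findings, attrs, "processing_effect_class", _NUTRITION_PROC)
        _check_enum(findings, attrs, "fbdg_scope", _NUTRITION_SCOPES)
        _check_enum(findings, attrs, "fortification_scope", _NUTRITION_SCOPES)
        if (
            attrs.get("intake_contribution_fraction") is None
            and attrs.get("composition_difference_class") is None
        ):
            _finding(
                findings,
                "missing intake information: need 'intake_contribution_fraction' "
                "(layer 1) or 'composition_difference_class' (layer 2)",
            )
        _check_enum(findings, attrs, "bioavailability_reduction", _BIOAVAIL_CLASSES)

    elif profile.domain is Domain.MICROBIOLOGY:
        _check_enum(findings, attrs, "prevalence_class", _MICRO_PREVALENCE)
        _check_enum(findings, attrs, "process_effect_class", _MICRO_PROCESS)
        daly = attrs.get("daly_per_1000_cases")
        if daly is None:
            _finding(findings, "missing attribute 'daly_per_1000_cases'")
        elif not isinstance(daly, (int, float)) or daly < 0:
            _finding(findings, "attribute 'daly_per_1000_cases' must be >= 0")

    elif profile.domain is Domain.TOXICOLOGY:
        _check_bool(findings, attrs, "above_lod_loq")
        _check_bool(findings, attrs, "genotoxic_carcinogen")
        if attrs.get("above_lod_loq") is True:
            # the exceedance flag consulted depends on the carcinogenicity path
            if attrs.get("genotoxic_carcinogen") is True:
                _check_bool(findings, attrs, "moe_below_10000")
            elif attrs.get("genotoxic_carcinogen") is False:
                _check_bool(findings, attrs, "exceeds_hbgv")
        share = attrs.get("exposure_share_of_diet")
        if share is None:
            _finding(findings, "missing attribute 'exposure_share_of_diet'")
        elif not isinstance(share, (int, float)) or not 0 <= share <= 1:
            _finding(findings, "attribute 'exposure_share_of_diet' outside [0, 1]")
        for key in _TOX_SEVERITY_KEYS:
            _check_bool(findings, attrs, key)

    return findings
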