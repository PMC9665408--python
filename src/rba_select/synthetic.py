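"""Seeded synthetic component profiles with an independent ground truth.

The generator draws sub-criterion levels from configurable probability
vectors, then *inverts* each scorer's semantics to produce raw attribute
values that encode exactly those levels (e.g. a presence level of 1
becomes a detection fraction of 0.05).  Alongside the profiles it emits
the ground-truth prioritization indices and stage decisions computed by
a straight-line oracle that shares no code with the engine: every rule
is restated here as literal arithmetic against the default
configuration.  Engine-vs-oracle equivalence on these profiles is the
package's strongest correctness check.

The default sizes mirror the beef-vs-cricket case study scale
(about 40 nutrients and a dozen hazards per food).
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .core import ChecklistStatus, ComponentProfile, Domain

_LEVELS = (1, 2, 3)


class SyntheticSpec(BaseModel):
    """Distributional knobs of the generator; the seed fixes everything."""

    seed: int = 0
    n_nutrition: int = Field(default=40, ge=0)
    n_microbiology: int = Field(default=12, ge=0)
    n_toxicology: int = Field(default=10, ge=0)

    # per-sub-criterion P(level 1), P(level 2), P(level 3)
    nutrition_presence_probs: tuple[float, float, float] = (0.2, 0.3, 0.5)
    nutrition_processing_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    nutrition_policy_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    nutrition_intake_probs: tuple[float, float, float] = (0.35, 0.4, 0.25)
    nutrition_bioavailability_probs: tuple[float, float, float] = (0.2, 0.3, 0.5)
    micro_prevalence_probs: tuple[float, float, float] = (0.4, 0.35, 0.25)
    micro_process_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    micro_severity_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    tox_presence_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    tox_contribution_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    tox_severity_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)

    #: fraction of components with limited/contradictory evidence
    fraction_weak_evidence: float = Field(default=0.15, ge=0, le=1)
    #: nutrition: probability a nutrient is quantified in one food only
    fraction_single_food: float = Field(default=0.25, ge=0, le=1)
    #: nutrition pairs: probability the concentration difference stays
    #: inside the 20% rule (component dropped from the long list)
    fraction_small_difference: float = Field(default=0.3, ge=0, le=1)
    #: probability a hazard occurs in only one of the two foods
    fraction_hazard_single_food: float = Field(default=0.4, ge=0, le=1)
    #: per checklist item, probability the data are missing
    fraction_missing_checklist: float = Field(default=0.15, ge=0, le=1)
    #: nutrition intake information: probability only layer 2 is available
    fraction_layer2_intake: float = Field(default=0.2, ge=0, le=1)

    @field_validator(
        "nutrition_presence_probs",
        "nutrition_processing_probs",
        "nutrition_policy_probs",
        "nutrition_intake_probs",
        "nutrition_bioavailability_probs",
        "micro_prevalence_probs",
        "micro_process_probs",
        "micro_severity_probs",
        "tox_presence_probs",
        "tox_contribution_probs",
        "tox_severity_probs",
    )
    @classmethod
    def _probs_sum_to_one(cls, v: tuple[float, float, float]):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"level probabilities must be >=0 and sum to 1, got {v}")
        return v


class ComponentTruth(BaseModel):
    """Oracle-computed expectations for one component x food."""

    component_id: str
    food_id: str
    domain: Domain
    longlist_included: bool
    evidence_included: Optional[bool] = None
    occurrence_score: Optional[int] = None
    severity_score: Optional[int] = None
    index: Optional[int] = None
    shortlisted: Optional[bool] = None
    final_included: Optional[bool] = None
    symmetry_added: bool = False


class GroundTruth(BaseModel):
    records: list[ComponentTruth] = Field(default_factory=list)

    def by_key(self) -> dict[tuple[str, str], ComponentTruth]:
        return {(r.component_id, r.food_id): r for r in self.records}


# --- level -> attribute encodings (inverse of the scorers) --------------

_PRESENCE_FRACTION = {1: 0.05, 2: 0.5, 3: 1.0}
_PROCESSING_CLASS = {1: "large_reduction", 2: "moderate_change", 3: "preserved_or_concentrated"}
_POLICY_SCOPES = {1: ("none", "none"), 2: ("some_countries", "none"), 3: ("all_countries", "some_countries")}
_INTAKE_FRACTION = {1: 0.10, 2: 0.50, 3: 0.90}
_COMPOSITION_CLASS = {1: "small_difference", 2: "moderate_difference", 3: "large_difference"}
_BIOAVAIL_CLASS = {1: "significant", 2: "moderate", 3: "mild_or_none"}
_PREVALENCE_CLASS = {1: "low", 2: "moderate", 3: "high"}
_MICRO_PROCESS_CLASS = {1: "reduces_or_eliminates", 2: "neutral", 3: "can_introduce"}


def _draw_level(rng: np.random.Generator, probs: Sequence[float]) -> int:
    return int(rng.choice(_LEVELS, p=np.asarray(probs, dtype=float)))


# --- the independent oracle (literal default-config rules) --------------


def oracle_micro_occurrence(prevalence_level: int, process_level: int) -> int:
    raw = prevalence_level * process_level
    if raw <= 2:
        return 1
    if raw <= 4:
        return 2
    return 3


def oracle_micro_severity(daly_per_1000: float) -> int:
    if daly_per_1000 < 10:
        return 1
    if daly_per_1000 < 100:
        return 2
    return 3


def oracle_tox_occurrence(presence: int, contribution: int) -> int:
    return -((presence + contribution) // -2)  # ceil((p + c) / 2)


def oracle_tox_severity(n_true: int) -> int:
    if n_true <= 1:
        return 1
    if n_true == 2:
        return 2
    return 3


def oracle_nutrition_index(levels: Sequence[int]) -> tuple[int, int, int]:
    """(occurrence, severity, index) from the five drawn levels
    (presence, processing | policy, intake, bioavailability)."""
    occ = levels[0] * levels[1]
    sev = levels[2] * levels[3] * levels[4]
    return occ, sev, occ * sev


def oracle_relative_difference(a: float, b: float) -> float:
    return abs(a - b) / ((a + b) / 2.0)


def oracle_checklist_pass(status: ChecklistStatus, domain: Domain) -> bool:
    ok = (
        status.has_dose_response
        and status.has_incidence
        and status.has_intake_data
        and status.has_composition_or_contamination
        and status.has_daly_per_case
    )
    if domain is Domain.MICROBIOLOGY:
        ok = ok and bool(status.has_source_attribution)
    return ok


_DEFAULT_THRESHOLDS = {
    Domain.NUTRITION: 108,
    Domain.MICROBIOLOGY: 2,
    Domain.TOXICOLOGY: 2,
}


def shortlist_inclusion_probability(
    spec: SyntheticSpec, domain: Domain
) -> float:
    """Closed-form P(index >= default threshold) implied by the spec's
    level distributions, by enumeration of all level combinations."""
    threshold = _DEFAULT_THRESHOLDS[domain]
    if domain is Domain.NUTRITION:
        vectors = [
            spec.nutrition_presence_probs,
            spec.nutrition_processing_probs,
            spec.nutrition_policy_probs,
            spec.nutrition_intake_probs,
            spec.nutrition_bioavailability_probs,
        ]
        total = 0.0
        for combo in itertools.product(_LEVELS, repeat=5):
            if math.prod(combo) >= threshold:
                total += math.prod(v[l - 1] for v, l in zip(vectors, combo))
        return total
    if domain is Domain.MICROBIOLOGY:
        total = 0.0
        for pv, pr, sv in itertools.product(_LEVELS, repeat=3):
            occ = oracle_micro_occurrence(pv, pr)
            if occ * sv >= threshold:
                total += (
                    spec.micro_prevalence_probs[pv - 1]
                    * spec.micro_process_probs[pr - 1]
                    * spec.micro_severity_probs[sv - 1]
                )
        return total
    total = 0.0
    for p, c, s in itertools.product(_LEVELS, repeat=3):
        occ = oracle_tox_occurrence(p, c)
        if occ * s >= threshold:
            total += (
                spec.tox_presence_probs[p - 1]
                * spec.tox_contribution_probs[c - 1]
                * spec.tox_severity_probs[s - 1]
            )
    return total


# --- generation ---------------------------------------------------------


def _draw_checklist(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    component_id: str,
    food_id: str,
    domain: Domain,
) -> ChecklistStatus:
    p = spec.fraction_missing_checklist
    flag = lambda: bool(rng.random() >= p)  # noqa: E731
    return ChecklistStatus(
        component_id=component_id,
        food_id=food_id,
        has_dose_response=flag(),
        has_incidence=flag(),
        has_source_attribution=flag() if domain is Domain.MICROBIOLOGY else None,
        has_intake_data=flag(),
        has_composition_or_contamination=flag(),
        has_daly_per_case=flag(),
    )


def _nutrition_attributes(
    rng: np.random.Generator, spec: SyntheticSpec, levels: Sequence[int]
) -> tuple[Optional[float], dict]:
    presence, processing, policy, intake, bioavail = levels
    fbdg, fort = _POLICY_SCOPES[policy]
    attrs: dict = {
        "processing_effect_class": _PROCESSING_CLASS[processing],
        "fbdg_scope": fbdg,
        "fortification_scope": fort,
        "bioavailability_reduction": _BIOAVAIL_CLASS[bioavail],
    }
    if rng.random() < spec.fraction_layer2_intake:
        attrs["composition_difference_class"] = _COMPOSITION_CLASS[intake]
    else:
        attrs["intake_contribution_fraction"] = _INTAKE_FRACTION[intake]
    return _PRESENCE_FRACTION[presence], attrs


def generate_profiles(
    spec: SyntheticSpec,
) -> tuple[
    list[ComponentProfile],
    list[ComponentProfile],
    dict[tuple[str, str], ChecklistStatus],
    GroundTruth,
]:
    """Generate a two-food scenario plus its oracle ground truth.

    Returns (profiles of food A, profiles of food B, checklist, truth).
    Ground truth covers every component x food: long-list decision,
    evidence-gate decision, index, short-list decision under the default
    thresholds, and final-list decision after nutrient symmetry and the
    checklist gate.
    """
    rng = np.random.default_rng(spec.seed)
    profiles_a: list[ComponentProfile] = []
    profiles_b: list[ComponentProfile] = []
    checklist: dict[tuple[str, str], ChecklistStatus] = {}
    truth = GroundTruth()
    foods = ("food_a", "food_b")

    # --- nutrition -----------------------------------------------------
    nut_short: dict[str, set[str]] = {f: set() for f in foods}
    nut_rows: list[dict] = []
    for i in range(spec.n_nutrition):
        cid = f"nutrient_{i:03d}"
        weak = rng.random() < spec.fraction_weak_evidence
        evidence = (
            str(rng.choice(["limited", "contradictory"])) if weak else "convincing"
        )
        single = rng.random() < spec.fraction_single_food
        base = float(rng.uniform(1.0, 100.0))
        if single:
            present = [str(rng.choice(foods))]
            concs = {present[0]: base}
            ll_included, ll_diff = True, None
        else:
            present = list(foods)
            if rng.random() < spec.fraction_small_difference:
                ratio = float(rng.uniform(1.0, 1.2))
            else:
                ratio = float(rng.uniform(1.3, 3.0))
            concs = {"food_a": base, "food_b": base * ratio}
            ll_diff = oracle_relative_difference(concs["food_a"], concs["food_b"])
            ll_included = ll_diff > 0.2

        per_food_levels: dict[str, list[int]] = {}
        for food in present:
            levels = [
                _draw_level(rng, spec.nutrition_presence_probs),
                _draw_level(rng, spec.nutrition_processing_probs),
                _draw_level(rng, spec.nutrition_policy_probs),
                _draw_level(rng, spec.nutrition_intake_probs),
                _draw_level(rng, spec.nutrition_bioavailability_probs),
            ]
            per_food_levels[food] = levels
            fraction, attrs = _nutrition_attributes(rng, spec, levels)
            profile = ComponentProfile(
                component_id=cid,
                food_id=food,
                domain=Domain.NUTRITION,
                concentration=concs[food],
                unit="mg/100g",
                sample_detection_fraction=fraction,
                evidence_level=evidence,
                attributes=attrs,
            )
            (profiles_a if food == "food_a" else profiles_b).append(profile)
        # checklist rows for both foods: symmetry may add the other food
        for food in foods:
            checklist[(cid, food)] = _draw_checklist(
                rng, spec, cid, food, Domain.NUTRITION
            )
        nut_rows.append(
            {
                "cid": cid,
                "present": present,
                "levels": per_food_levels,
                "evidence_ok": not weak,
                "ll_included": ll_included,
            }
        )
        if ll_included and not weak:
            for food in present:
                occ, sev, index = oracle_nutrition_index(per_food_levels[food])
                if index >= 108:
                    nut_short[food].add(cid)

    # second pass: final decisions need both foods' short lists (symmetry)
    symmetry_union = nut_short["food_a"] | nut_short["food_b"]
    for row in nut_rows:
        cid = row["cid"]
        for food in foods:
            scored = row["ll_included"] and row["evidence_ok"] and food in row["present"]
            occ = sev = index = None
            shortlisted = None
            if scored:
                occ, sev, index = oracle_nutrition_index(row["levels"][food])
                shortlisted = index >= 108
            in_union = cid in symmetry_union
            final = None
            symmetry_added = False
            if in_union:
                symmetry_added = cid not in nut_short[food]
                final = oracle_checklist_pass(checklist[(cid, food)], Domain.NUTRITION)
            if food in row["present"] or in_union:
                truth.records.append(
                    ComponentTruth(
                        component_id=cid,
                        food_id=food,
                        domain=Domain.NUTRITION,
                        longlist_included=row["ll_included"],
                        evidence_included=row["evidence_ok"] if row["ll_included"] else None,
                        occurrence_score=occ,
                        severity_score=sev,
                        index=index,
                        shortlisted=shortlisted,
                        final_included=final,
                        symmetry_added=symmetry_added,
                    )
                )

    # --- hazards -------------------------------------------------------
    def gen_hazards(domain: Domain, n: int, prefix: str) -> None:
        for i in range(n):
            cid = f"{prefix}_{i:03d}"
            weak = rng.random() < spec.fraction_weak_evidence
            evidence = (
                str(rng.choice(["limited", "contradictory"])) if weak else "convincing"
            )
            if rng.random() < spec.fraction_hazard_single_food:
                present = [str(rng.choice(foods))]
            else:
                present = list(foods)
            for food in present:
                if domain is Domain.MICROBIOLOGY:
                    pv = _draw_level(rng, spec.micro_prevalence_probs)
                    pr = _draw_level(rng, spec.micro_process_probs)
                    sv = _draw_level(rng, spec.micro_severity_probs)
                    daly_bounds = {1: (0.0, 10.0), 2: (10.0, 100.0), 3: (100.0, 1000.0)}
                    daly = float(rng.uniform(*daly_bounds[sv]))
                    attrs = {
                        "prevalence_class": _PREVALENCE_CLASS[pv],
                        "process_effect_class": _MICRO_PROCESS_CLASS[pr],
                        "daly_per_1000_cases": daly,
                    }
                    occ = oracle_micro_occurrence(pv, pr)
                    sev = oracle_micro_severity(daly)
                else:
                    p = _draw_level(rng, spec.tox_presence_probs)
                    c = _draw_level(rng, spec.tox_contribution_probs)
                    s = _draw_level(rng, spec.tox_severity_probs)
                    genotoxic = bool(rng.random() < 0.3)
                    attrs = {
                        "above_lod_loq": p > 1,
                        "genotoxic_carcinogen": genotoxic,
                        "exposure_share_of_diet": {
                            1: float(rng.uniform(0.0, 0.0999)),
                            2: float(rng.uniform(0.1, 0.5)),
                            3: float(rng.uniform(0.5001, 1.0)),
                        }[c],
                    }
                    if p > 1:
                        if genotoxic:
                            attrs["moe_below_10000"] = p == 3
                        else:
                            attrs["exceeds_hbgv"] = p == 3
                    n_true = {1: int(rng.integers(0, 2)), 2: 2, 3: int(rng.integers(3, 5))}[s]
                    which = rng.permutation(4)[:n_true]
                    for j, key in enumerate(
                        (
                            "sev_high_incidence",
                            "sev_fatal",
                            "sev_lifelong_disability",
                            "sev_high_disability",
                        )
                    ):
                        attrs[key] = bool(j in which)
                    occ = oracle_tox_occurrence(p, c)
                    sev = oracle_tox_severity(n_true)

                profile = ComponentProfile(
                    component_id=cid,
                    food_id=food,
                    domain=domain,
                    prevalence_fraction=None,
                    evidence_level=evidence,
                    attributes=attrs,
                )
                (profiles_a if food == "food_a" else profiles_b).append(profile)
                status = _draw_checklist(rng, spec, cid, food, domain)
                checklist[(cid, food)] = status

                index = occ * sev
                shortlisted = index >= _DEFAULT_THRESHOLDS[domain]
                final = (
                    oracle_checklist_pass(status, domain)
                    if (not weak and shortlisted)
                    else None
                )
                truth.records.append(
                    ComponentTruth(
                        component_id=cid,
                        food_id=food,
                        domain=domain,
                        longlist_included=True,
                        evidence_included=not weak,
                        occurrence_score=occ if not weak else None,
                        severity_score=sev if not weak else None,
                        index=index if not weak else None,
                        shortlisted=shortlisted if not weak else None,
                        final_included=final,
                    )
                )

    gen_hazards(Domain.MICROBIOLOGY, spec.n_microbiology, "microbe")
    gen_hazards(Domain.TOXICOLOGY, spec.n_toxicology, "chemical")

    return profiles_a, profiles_b, checklist, truth
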