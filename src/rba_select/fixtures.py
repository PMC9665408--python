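"""Packaged NovRBA case-study fixture (minced beef vs cricket powder).

The fixture ships the case study's component universe with attribute
values synthesized to be consistent with the published short- and
final-list membership under the default configuration, plus that
expected membership and the metadata documenting every place where the
published tables and narrative disagree.  See
``data/novrba/metadata.yaml`` for the full provenance notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

from .config import RunConfig, default_config
from .core import ChecklistStatus, ComponentProfile, OutcomeLink
from .io import load_checklist, load_outcome_links, load_profiles

_DATA = resources.files("rba_select") / "data" / "novrba"


@dataclass
class NovRBAFixture:
    """The case-study inputs plus expected tier membership."""

    food_a: str
    food_b: str
    profiles_a: list[ComponentProfile]
    profiles_b: list[ComponentProfile]
    checklist: dict[tuple[str, str], ChecklistStatus]
    outcome_links: list[OutcomeLink]
    #: domain -> food -> sorted component ids
    expected_shortlist: dict[str, dict[str, list[str]]]
    expected_final: dict[str, dict[str, list[str]]]
    metadata: dict[str, Any] = field(default_factory=dict)

    def config(self) -> RunConfig:
        return default_config(scenario_id=self.metadata.get("scenario_id", "novrba"))


def load_novrba_fixture() -> NovRBAFixture:
    """Load the packaged beef-vs-cricket fixture."""
    with resources.as_file(_DATA / "metadata.yaml") as p:
        metadata = yaml.safe_load(p.read_text(encoding="utf-8"))
    with resources.as_file(_DATA / "profiles_beef.csv") as p:
        profiles_a, errs_a = load_profiles(p)
    with resources.as_file(_DATA / "profiles_cricket.csv") as p:
        profiles_b, errs_b = load_profiles(p)
    if errs_a or errs_b:  # the packaged tables must be clean
        raise RuntimeError(f"fixture tables malformed: {errs_a + errs_b}")
    with resources.as_file(_DATA / "checklist.csv") as p:
        checklist = load_checklist(p)
    with resources.as_file(_DATA / "outcome_links.csv") as p:
        links = load_outcome_links(p)
    return NovRBAFixture(
        food_a=metadata["foods"]["food_a"],
        food_b=metadata["foods"]["food_b"],
        profiles_a=profiles_a,
        profiles_b=profiles_b,
        checklist=checklist,
        outcome_links=links,
        expected_shortlist={
            d: {f: sorted(ids) for f, ids in foods.items()}
            for d, foods in metadata["expected_shortlist"].items()
        },
        expected_final={
            d: {f: sorted(ids) for f, ids in foods.items()}
            for d, foods in metadata["expected_final"].items()
        },
        metadata=metadata,
    )
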