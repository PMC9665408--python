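"""Ranking, short-list thresholds, nutrient symmetry, checklist gate."""

import pytest

from rba_select.config import SelectionConfig
from rba_select.core import (
    ChecklistStatus,
    Decision,
    Domain,
    PrioritizationIndex,
    Stage,
)
from rba_select.selection import (
    FinalCandidate,
    ShortListEntry,
    apply_checklist_gate,
    apply_nutrient_symmetry,
    apply_shortlist_threshold,
    rank_components,
)


def ix(cid, index, occ=None, domain=Domain.MICROBIOLOGY, food="beef"):
    if occ is None:
        occ = 1
    assert index % occ == 0
    return PrioritizationIndex(
        component_id=cid,
        food_id=food,
        domain=domain,
        occurrence_score=occ,
        severity_score=index // occ,
        index=index,
    )


def status(cid, food="beef", micro=False, **overrides):
    base = dict(
        component_id=cid,
        food_id=food,
        has_dose_response=True,
        has_incidence=True,
        has_source_attribution=True if micro else None,
        has_intake_data=True,
        has_composition_or_contamination=True,
        has_daly_per_case=True,
    )
    base.update(overrides)
    return ChecklistStatus(**base)


class TestRanking:
    def test_ties_break_by_id_after_severity(self):
        ranked = rank_components([ix("B", 3), ix("A", 9), ix("C", 9)])
        assert [r.component_id for r in ranked] == ["A", "C", "B"]

    def test_severity_breaks_ties_before_id(self):
        # same index 9, different occurrence x severity split
        a = ix("Z", 9, occ=3)  # severity 3
        b = ix("A", 9, occ=9, domain=Domain.NUTRITION)  # wrong domain guard below
        with pytest.raises(ValueError, match="mixed"):
            rank_components([a, b])
        c = PrioritizationIndex(
            component_id="A",
            food_id="beef",
            domain=Domain.MICROBIOLOGY,
            occurrence_score=9,
            severity_score=1,
            index=9,
        )
        assert [r.component_id for r in rank_components([c, a])] == ["Z", "A"]

    def test_identity_cases(self):
        assert rank_components([]) == []
        single = [ix("A", 4)]
        assert rank_components(single) == single


class TestShortlistThreshold:
    def test_inclusive_at_printed_thresholds(self):
        nut = [
            ix("hi", 108, occ=4, domain=Domain.NUTRITION),
            ix("lo", 107, occ=107, domain=Domain.NUTRITION),
        ]
        # 107 occ x 1 sev is a degenerate construction: 107 is prime and
        # unattainable as a product of levels, used purely as a below-108 probe
        kept, ledger = apply_shortlist_threshold(
            rank_components(nut), Domain.NUTRITION
        )
        assert [e.index.component_id for e in kept] == ["hi"]
        assert ledger.decisions(Stage.SHORTLIST, Decision.EXCLUDED) == {("lo", "beef")}

    def test_hazard_threshold_two_inclusive(self):
        kept, _ = apply_shortlist_threshold(
            rank_components([ix("A", 2), ix("B", 1)]), Domain.MICROBIOLOGY
        )
        assert [e.index.component_id for e in kept] == ["A"]

    def test_raising_an_index_never_removes_it(self):
        cfg = SelectionConfig()
        base = [ix("A", 3), ix("B", 2), ix("C", 1)]
        kept_before, _ = apply_shortlist_threshold(base, Domain.MICROBIOLOGY, cfg)
        bumped = [ix("A", 9), ix("B", 2), ix("C", 1)]
        kept_after, _ = apply_shortlist_threshold(bumped, Domain.MICROBIOLOGY, cfg)
        ids = lambda ks: {e.index.component_id for e in ks}  # noqa: E731
        assert ids(kept_before) <= ids(kept_after)


class TestNutrientSymmetry:
    def entry(self, cid, food):
        return ShortListEntry(index=ix(cid, 108, occ=4, domain=Domain.NUTRITION, food=food), rank=1)

    def test_single_food_nutrient_added_for_other_food(self):
        cands = apply_nutrient_symmetry(
            [self.entry("Vitamin B12", "beef")], [], "beef", "cricket"
        )
        by_food = {(c.component_id, c.food_id): c for c in cands}
        assert set(by_food) == {("Vitamin B12", "beef"), ("Vitamin B12", "cricket")}
        assert not by_food[("Vitamin B12", "beef")].symmetry_added
        assert by_food[("Vitamin B12", "cricket")].symmetry_added

    def test_nutrient_in_both_lists_unchanged(self):
        cands = apply_nutrient_symmetry(
            [self.entry("Iron", "beef")], [self.entry("Iron", "cricket")], "beef", "cricket"
        )
        assert all(not c.symmetry_added for c in cands)
        assert len(cands) == 2

    def test_empty_lists_give_no_candidates(self):
        assert apply_nutrient_symmetry([], [], "beef", "cricket") == []

    def test_hazard_domain_rejected(self):
        hazard_entry = ShortListEntry(index=ix("Salmonella spp.", 4), rank=1)
        with pytest.raises(ValueError, match="nutrition"):
            apply_nutrient_symmetry([hazard_entry], [], "beef", "cricket")


class TestChecklistGate:
    def cand(self, cid, domain=Domain.NUTRITION, food="beef"):
        return FinalCandidate(component_id=cid, food_id=food, domain=domain)

    def test_all_flags_true_included(self):
        final, ledger = apply_checklist_gate(
            [self.cand("Iron")], {("Iron", "beef"): status("Iron")}
        )
        assert [e.component_id for e in final] == ["Iron"]
        assert ledger.at_stage(Stage.FINALLIST)[0].decision is Decision.INCLUDED

    def test_missing_dose_response_named_in_reason(self):
        final, ledger = apply_checklist_gate(
            [self.cand("Copper")],
            {("Copper", "beef"): status("Copper", has_dose_response=False)},
        )
        assert final == []
        assert "dose-response" in ledger.at_stage(Stage.FINALLIST)[0].reason

    def test_source_attribution_required_only_for_microbiology(self):
        micro = self.cand("Listeria monocytogenes", Domain.MICROBIOLOGY)
        chem = self.cand("PAH", Domain.TOXICOLOGY)
        table = {
            ("Listeria monocytogenes", "beef"): status(
                "Listeria monocytogenes", micro=True, has_source_attribution=False
            ),
            ("PAH", "beef"): status("PAH", has_source_attribution=False),
        }
        final, ledger = apply_checklist_gate([micro, chem], table)
        assert [e.component_id for e in final] == ["PAH"]
        assert "source attribution" in ledger.at_stage(Stage.FINALLIST)[0].reason

    def test_micro_candidate_needs_explicit_source_flag(self):
        micro = self.cand("Salmonella spp.", Domain.MICROBIOLOGY)
        with pytest.raises(ValueError, match="source-attribution"):
            apply_checklist_gate(
                [micro], {("Salmonella spp.", "beef"): status("Salmonella spp.")}
            )

    def test_missing_status_is_an_error(self):
        with pytest.raises(KeyError):
            apply_checklist_gate([self.cand("Iron")], {})
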