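"""Long-list assembly: the 20% concentration rule and the evidence gate."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rba_select.config import LongListConfig
from rba_select.core import ComponentProfile, Decision, SelectionLedger, Stage
from rba_select.longlist import (
    DuplicateProfileError,
    UndefinedDifferenceError,
    build_long_list,
    evidence_gate,
    relative_difference,
)


def nutrient(cid, food, conc, unit="mg/100g", evidence="convincing"):
    return ComponentProfile(
        component_id=cid,
        food_id=food,
        domain="nutrition",
        concentration=conc,
        unit=unit,
        evidence_level=evidence,
    )


def hazard(cid, food, domain="microbiology", evidence="convincing"):
    return ComponentProfile(
        component_id=cid, food_id=food, domain=domain, evidence_level=evidence
    )


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(100, 100, 0.0), (100, 150, 0.4), (0, 50, 2.0), (50, 0, 2.0)],
    )
    def test_mean_denominator(self, a, b, expected):
        assert relative_difference(a, b) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedDifferenceError):
            relative_difference(0.0, 0.0)

    def test_alternative_denominators(self):
        assert relative_difference(100, 150, "max") == pytest.approx(1 / 3)
        assert relative_difference(100, 150, "reference_a") == pytest.approx(0.5)

    @given(
        a=st.floats(min_value=0.0, max_value=1e6),
        b=st.floats(min_value=1e-6, max_value=1e6),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_scale_invariance(self, a, b, c):
        rd = relative_difference(a, b)
        assert rd == pytest.approx(relative_difference(b, a))
        assert relative_difference(a * c, b * c) == pytest.approx(rd, rel=1e-9)
        assert 0.0 <= rd <= 2.0


class TestBuildLongList:
    def test_single_food_nutrient_included(self):
        ll, ledger = build_long_list([nutrient("Lysine", "beef", 10.0)], [])
        assert ll.component_ids() == {"Lysine"}
        entry = ledger.at_stage(Stage.LONGLIST)[0]
        assert entry.decision is Decision.INCLUDED
        assert "one food only" in entry.reason

    def test_small_difference_excluded_with_computed_diff(self):
        # |100-115| / 107.5 = 13.95% <= 20%
        ll, ledger = build_long_list(
            [nutrient("Calcium", "beef", 100.0)], [nutrient("Calcium", "cricket", 115.0)]
        )
        assert ll.members == []
        reasons = {e.reason for e in ledger.at_stage(Stage.LONGLIST)}
        assert reasons == {"concentration difference 14.0% <= 20%"}

    def test_large_difference_included(self):
        ll, _ = build_long_list(
            [nutrient("Iron", "beef", 100.0)], [nutrient("Iron", "cricket", 150.0)]
        )
        assert ll.component_ids() == {"Iron"}

    def test_threshold_is_strict(self):
        # exactly 20% difference does not clear a "higher than 20%" rule
        ll, _ = build_long_list(
            [nutrient("Zinc", "beef", 90.0)], [nutrient("Zinc", "cricket", 110.0)]
        )
        assert ll.members == []

    def test_all_hazards_included_even_single_food(self):
        ll, _ = build_long_list(
            [hazard("Salmonella spp.", "beef")],
            [hazard("PAH", "cricket", domain="toxicology")],
        )
        assert ll.component_ids() == {"Salmonella spp.", "PAH"}

    def test_duplicate_rows_rejected(self):
        with pytest.raises(DuplicateProfileError):
            build_long_list(
                [nutrient("Iron", "beef", 1.0), nutrient("Iron", "beef", 2.0)], []
            )

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            build_long_list(
                [nutrient("Iron", "beef", 100.0, unit="mg/100g")],
                [nutrient("Iron", "cricket", 150.0, unit="ug/100g")],
            )

    def test_ledger_covers_every_candidate(self):
        pa = [nutrient("A", "beef", 1.0), nutrient("B", "beef", 100.0)]
        pb = [nutrient("B", "cricket", 101.0), hazard("C", "cricket")]
        ll, ledger = build_long_list(pa, pb)
        logged = {(e.component_id, e.food_id) for e in ledger.at_stage(Stage.LONGLIST)}
        assert logged == {("A", "beef"), ("B", "beef"), ("B", "cricket"), ("C", "cricket")}
        # output members + logged exclusions partition the candidates
        excluded = ledger.decisions(Stage.LONGLIST, Decision.EXCLUDED)
        assert ll.component_ids() == {"A", "C"}
        assert {c for c, _ in excluded} == {"B"}

    def test_same_name_nutrient_and_contaminant_kept_apart(self):
        pa = [nutrient("Aluminum", "beef", 5.0), hazard("Aluminum", "beef", "toxicology")]
        ll, _ = build_long_list(pa, [])
        assert len(ll.members) == 2


class TestEvidenceGate:
    @pytest.mark.parametrize(
        "evidence,kept", [("convincing", True), ("limited", False), ("contradictory", False)]
    )
    def test_only_convincing_evidence_passes(self, evidence, kept):
        ll, _ = build_long_list([hazard("X", "beef", evidence=evidence)], [])
        gated, ledger = evidence_gate(ll)
        assert (len(gated.members) == 1) is kept
        entry = ledger.at_stage(Stage.EVIDENCE_GATE)[0]
        assert (entry.decision is Decision.INCLUDED) is kept
        if not kept:
            assert "evidence level" in entry.reason

    def test_output_subset_and_ledger_closure(self):
        pa = [
            nutrient("A", "beef", 10.0),
            hazard("B", "beef", evidence="limited"),
            hazard("C", "beef"),
        ]
        ll, _ = build_long_list(pa, [])
        gated, ledger = evidence_gate(ll)
        kept = gated.component_ids()
        assert kept <= ll.component_ids()
        excluded = {c for c, _ in ledger.decisions(Stage.EVIDENCE_GATE, Decision.EXCLUDED)}
        assert kept | excluded == ll.component_ids()
        assert kept & excluded == set()
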