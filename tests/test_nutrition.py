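"""Nutrition scoring: five 1-3 sub-criteria multiplied into a 1-243 index."""

import itertools
import math

import pytest

from rba_select.core import Domain, SubScore
from rba_select.nutrition import (
    nutrition_index,
    resolve_detection_sources,
    score_bioavailability,
    score_intake_contribution,
    score_policy_relevance,
    score_presence,
    score_processing_effect,
)


def sub(level, name="s"):
    return SubScore(name=name, level=level)


class TestPresence:
    @pytest.mark.parametrize(
        "fraction,level", [(0.0, 1), (0.05, 1), (0.0999, 1), (0.10, 2), (0.5, 2), (0.999, 2), (1.0, 3)]
    )
    def test_bands(self, fraction, level):
        assert score_presence(fraction).level == level

    def test_national_repository_overrides_single_sample(self):
        # a single analytical sample says always-present, the national
        # repository says rare: the repository wins
        fraction = resolve_detection_sources(
            {"single_sample": 1.0, "national_repository": 0.05}
        )
        assert score_presence(fraction).level == 1
        assert score_presence({"single_sample": 1.0, "national_repository": 0.05}).level == 1

    def test_qualitative_flags(self):
        assert score_presence(None, qualitative_presence="absent").level == 1
        assert score_presence(None, qualitative_presence="present_all").level == 3
        with pytest.raises(ValueError):
            score_presence(None)


class TestSeveritySubScores:
    @pytest.mark.parametrize(
        "cls,level",
        [("large_reduction", 1), ("moderate_change", 2), ("preserved_or_concentrated", 3)],
    )
    def test_processing(self, cls, level):
        assert score_processing_effect(cls).level == level

    def test_unknown_processing_class(self):
        with pytest.raises(ValueError, match="unknown"):
            score_processing_effect("vaporized")

    @pytest.mark.parametrize(
        "fbdg,fort,level",
        [
            ("none", "none", 1),
            ("some_countries", "none", 2),
            ("none", "some_countries", 2),
            ("all_countries", "none", 3),
            ("all_countries", "some_countries", 3),
            ("some_countries", "all_countries", 3),
        ],
    )
    def test_policy_relevance(self, fbdg, fort, level):
        assert score_policy_relevance(fbdg, fort).level == level

    @pytest.mark.parametrize(
        "fraction,level", [(0.0, 1), (0.2, 1), (1 / 3, 1), (0.5, 2), (2 / 3, 2), (0.7, 3), (1.0, 3)]
    )
    def test_intake_layer1_tertiles(self, fraction, level):
        assert score_intake_contribution(fraction).level == level

    def test_intake_layer2_fallback(self):
        assert (
            score_intake_contribution(None, "large_difference").level == 3
        )
        assert score_intake_contribution(None, "small_difference").level == 1
        with pytest.raises(ValueError, match="layer"):
            score_intake_contribution(None, None)

    def test_layer1_preferred_over_layer2(self):
        assert score_intake_contribution(0.1, "large_difference").level == 1

    @pytest.mark.parametrize(
        "cls,level", [("significant", 1), ("moderate", 2), ("mild_or_none", 3)]
    )
    def test_bioavailability(self, cls, level):
        assert score_bioavailability(cls).level == level


class TestNutritionIndex:
    @pytest.mark.parametrize(
        "occ,sev,expected",
        [((3, 3), (3, 3, 3), 243), ((1, 1), (1, 1, 1), 1), ((2, 2), (3, 3, 3), 108)],
    )
    def test_products(self, occ, sev, expected):
        ix = nutrition_index("X", "beef", [sub(l) for l in occ], [sub(l) for l in sev])
        assert ix.index == expected
        assert ix.domain is Domain.NUTRITION

    def test_sub_score_counts_enforced(self):
        # the 2-occurrence / 3-severity split carries the deliberate
        # 2/5 vs 3/5 weighting of occurrence against public-health impact
        with pytest.raises(ValueError):
            nutrition_index("X", "b", [sub(1)], [sub(1), sub(1), sub(1)])
        with pytest.raises(ValueError):
            nutrition_index("X", "b", [sub(1), sub(1)], [sub(1), sub(1)])
        ix = nutrition_index("X", "b", [sub(2), sub(3)], [sub(1), sub(2), sub(3)])
        assert len(ix.sub_scores) == 5

    def test_exhaustive_enumeration_matches_closed_form(self):
        # all 3^5 = 243 level combinations: index equals the product and
        # spans exactly the 3-smooth attainable values with extremes 1, 243
        seen = set()
        for combo in itertools.product((1, 2, 3), repeat=5):
            ix = nutrition_index(
                "X", "b", [sub(l) for l in combo[:2]], [sub(l) for l in combo[2:]]
            )
            assert ix.index == math.prod(combo)
            assert ix.index == ix.occurrence_score * ix.severity_score
            seen.add(ix.index)
        assert min(seen) == 1 and max(seen) == 243
        assert 108 in seen  # the short-list threshold is attainable
        assert 107 not in seen  # primes above 3 are not products of {1,2,3}

    def test_monotone_in_every_sub_score(self):
        for combo in itertools.product((1, 2, 3), repeat=5):
            base = math.prod(combo)
            for pos in range(5):
                if combo[pos] < 3:
                    bumped = list(combo)
                    bumped[pos] += 1
                    assert math.prod(bumped) > base
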