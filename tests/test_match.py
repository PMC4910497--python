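"""Edit distance and checklist cross-mapping."""

import random
from functools import lru_cache

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gnkit.canonical import canonicalize_string
from gnkit.match import (
    CATEGORY_CANONICAL_EXACT,
    CATEGORY_CANONICAL_FUZZY,
    CATEGORY_EXACT,
    CATEGORY_GENUS_PART,
    CATEGORY_NONE,
    CATEGORY_PARTIAL_CANONICAL,
    EditDistanceParams,
    TargetIndex,
    cross_map,
    dl_distance,
    fuzzy_candidates,
    match_profile,
)


def osa_oracle(a: str, b: str) -> int:
    """Independent recursive definition of the restricted
    Damerau-Levenshtein (optimal string alignment) distance."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


class TestDistance:
    def test_six_difference_reference_pair(self):
        src = canonicalize_string("Lasidioplodia pseudobromae").match_key
        tgt = canonicalize_string(
            "Lasiodiplodia pseudotheobromae A.J.L. Phillips, A. Alves & Crous 2008"
        ).match_key
        assert dl_distance(src, tgt) == 6

    def test_adjacent_transposition_costs_one(self):
        assert dl_distance("dorsophila melanogaster", "drosophila melanogaster") == 1

    @pytest.mark.parametrize(
        "neighbour", ["cumia", "mimia", "mucia", "mukia", "numia", "rumia"]
    )
    def test_one_edit_genus_neighbours(self, neighbour):
        assert dl_distance("mumia", neighbour) == 1

    def test_identity(self):
        for x in ["", "a", "bison bison"]:
            assert dl_distance(x, x) == 0

    def test_agrees_with_recursive_oracle_on_random_pairs(self):
        rng = random.Random(20150515)
        alphabet = "abc"
        for _ in range(600):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 7)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 7)))
            assert dl_distance(a, b) == osa_oracle(a, b), (a, b)

    @given(st.text(alphabet="abcd", max_size=7), st.text(alphabet="abcd", max_size=7))
    def test_symmetric_and_zero_iff_equal(self, a, b):
        assert dl_distance(a, b) == dl_distance(b, a)
        assert (dl_distance(a, b) == 0) == (a == b)

    def test_per_token_mode_sums_component_distances(self):
        params = EditDistanceParams(per_token=True)
        assert dl_distance("lasidioplodia pseudobromae",
                           "lasiodiplodia pseudotheobromae", params) == 6

    def test_without_transpositions_swap_costs_two(self):
        params = EditDistanceParams(allow_transposition=False)
        assert dl_distance("ab", "ba", params) == 2

    def test_tolerance_ceiling_is_enforced(self):
        with pytest.raises(ValueError):
            EditDistanceParams(max_tolerance=7)


class TestFuzzyCandidates:
    def test_all_ties_returned(self, target_checklist):
        index = TargetIndex(target_checklist)
        hits = fuzzy_candidates(
            canonicalize_string("Mumia"), index, EditDistanceParams(max_tolerance=1)
        )
        assert [k for k, _ in hits] == ["cumia", "mimia", "mucia", "mukia", "numia", "rumia"]
        assert all(d == 1 for _, d in hits)

    def test_tolerance_zero_returns_only_exact_keys(self, target_checklist):
        index = TargetIndex(target_checklist)
        assert fuzzy_candidates(
            canonicalize_string("Mumia"), index, EditDistanceParams(max_tolerance=0)
        ) == []

    def test_dropped_leading_character_is_recovered(self, target_checklist):
        index = TargetIndex(target_checklist)
        hits = fuzzy_candidates(
            canonicalize_string("chneumon dorsalis"),
            index,
            EditDistanceParams(max_tolerance=1),
        )
        assert hits == [("ichneumon dorsalis", 1)]


class TestCrossMap:
    @pytest.fixture()
    def results(self, source_checklist, target_checklist):
        return {
            r.source_id: r
            for r in cross_map(source_checklist, target_checklist,
                               EditDistanceParams(max_tolerance=1))
        }

    def test_exact_tier(self, results):
        assert results["s1"].category == CATEGORY_EXACT
        assert results["s1"].edit_distance == 0

    def test_canonical_exact_over_rank_marker_variation(self, results):
        assert results["s2"].category == CATEGORY_CANONICAL_EXACT

    def test_partial_canonical_for_infraspecific_source(self, results):
        r = results["s3"]
        assert r.category == CATEGORY_PARTIAL_CANONICAL
        assert r.targets[0][1] == "Cnemidophorus tigris Baird & Girard, 1852"

    def test_genus_part_is_last_resort(self, results):
        r = results["s4"]
        assert r.category == CATEGORY_GENUS_PART
        assert r.targets == [("t4", "Lysandra")]

    def test_multi_target_fuzzy_ties(self, results):
        r = results["s5"]
        assert r.category == CATEGORY_CANONICAL_FUZZY
        assert len(r.targets) == 6
        assert r.needs_human_check

    def test_no_match(self, results):
        assert results["s10"].category == CATEGORY_NONE

    def test_hyphen_variant_matches_canonically(self, results):
        assert results["s7"].category == CATEGORY_CANONICAL_EXACT

    def test_authorship_conflict_halves_confidence(self, results):
        assert round(results["s9"].confidence, 2) == 0.75

    def test_six_edit_match_found_at_full_tolerance(
        self, source_checklist, target_checklist
    ):
        results = {
            r.source_id: r
            for r in cross_map(source_checklist, target_checklist,
                               EditDistanceParams(max_tolerance=6))
        }
        r = results["s8"]
        assert r.category == CATEGORY_CANONICAL_FUZZY
        assert r.edit_distance == 6
        assert r.needs_human_check

    def test_tier_exclusivity(self, source_checklist, target_checklist):
        """A record with an exact hit is never reported under another
        category, and every record yields exactly one result."""
        results = cross_map(source_checklist, target_checklist)
        assert len(results) == len(source_checklist)
        raw_targets = {name for _, name in target_checklist}
        for r in results:
            if r.source_name in raw_targets:
                assert r.category == CATEGORY_EXACT

    def test_tolerance_monotonicity(self, source_checklist, target_checklist):
        """Raising the tolerance never loses a match and never changes a
        result found at a tolerance-independent tier."""
        stable = {CATEGORY_EXACT, CATEGORY_CANONICAL_EXACT}
        by_tol = {
            tol: {r.source_id: r for r in cross_map(
                source_checklist, target_checklist,
                EditDistanceParams(max_tolerance=tol))}
            for tol in (0, 1, 3, 6)
        }
        tols = sorted(by_tol)
        for lo, hi in zip(tols, tols[1:]):
            for sid, r_lo in by_tol[lo].items():
                r_hi = by_tol[hi][sid]
                if r_lo.category in stable:
                    assert r_hi.category == r_lo.category
                    assert r_hi.targets == r_lo.targets
                if r_lo.category != CATEGORY_NONE:
                    assert r_hi.category != CATEGORY_NONE
                if r_lo.category == CATEGORY_CANONICAL_FUZZY:
                    assert r_hi.category == CATEGORY_CANONICAL_FUZZY
                    assert r_hi.edit_distance <= r_lo.edit_distance

    def test_duplicate_source_ids_are_an_error(self, target_checklist):
        with pytest.raises(ValueError):
            cross_map([("a", "Bison bison"), ("a", "Bison")], target_checklist)

    def test_empty_target_yields_all_none(self, source_checklist):
        results = cross_map(source_checklist, [])
        assert all(r.category == CATEGORY_NONE for r in results)

    def test_homonym_alert(self, target_checklist):
        results = cross_map(
            [("s", "Bison bison")], target_checklist, homonyms=["Bison bison"]
        )
        assert results[0].homonym_alert

    def test_needs_human_check_iff_low_confidence_or_deep_fuzz(self, results):
        for r in results.values():
            if r.category == CATEGORY_NONE:
                continue
            expected = r.confidence <= 0.5 or (r.edit_distance or 0) >= 2
            assert r.needs_human_check == expected


def test_inflation_statistic(source_checklist, target_checklist):
    results = cross_map(source_checklist, target_checklist)
    profile = match_profile(results)
    matched = [r for r in results if r.category != CATEGORY_NONE]
    total_targets = sum(len(r.targets) for r in matched)
    assert total_targets >= len(matched)
    assert profile["inflation"] == pytest.approx(total_targets / len(matched) - 1)
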