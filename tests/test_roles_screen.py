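"""Role filtering, earliest-year dedup, profiles, and exclusion screening."""

import numpy as np
import pytest

from chembib.corpus import CitationRecord, Corpus, filter_by_roles
from chembib.corpus import ChemicalList
from chembib.screen import (
    ExclusionRuleSet,
    apply_exclusions,
    build_profiles,
    dedup_earliest,
    food_constituent_screen,
)
from conftest import random_corpus


# ---------------------------------------------------------------- roles

def test_filter_all_requires_every_role(toy_corpus):
    kept = filter_by_roles(toy_corpus, {"ANST", "POL"}, "all")
    assert [r.record_id for r in kept] == ["r1", "r2", "r5"]


def test_filter_any_requires_one_role(toy_corpus):
    kept = filter_by_roles(toy_corpus, {"POL", "BIOL"}, "any")
    assert [r.record_id for r in kept] == ["r1", "r2", "r4", "r5"]


def test_empty_required_is_identity(toy_corpus):
    kept = filter_by_roles(toy_corpus, set(), "all")
    assert len(kept) == len(toy_corpus)


def test_roles_matched_case_insensitively(toy_corpus):
    kept = filter_by_roles(toy_corpus, {" anst ", "pol"}, "all")
    assert [r.record_id for r in kept] == ["r1", "r2", "r5"]


def test_unknown_role_warns_not_errors(toy_corpus):
    warnings: list[str] = []
    kept = filter_by_roles(toy_corpus, {"XYZZY"}, "all", warnings=warnings)
    assert len(kept) == 0
    assert any("XYZZY" in w for w in warnings)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_all_mode_subset_of_any_mode(seed):
    rng = np.random.default_rng(seed)
    corpus = random_corpus(rng)
    required = set(rng.choice(["ANST", "POL", "BIOL"], size=2, replace=False))
    ids_all = {r.record_id for r in filter_by_roles(corpus, required, "all")}
    ids_any = {r.record_id for r in filter_by_roles(corpus, required, "any")}
    assert ids_all <= ids_any


# ---------------------------------------------------------------- dedup

def test_dedup_earliest_years(toy_corpus):
    first_years, ordered = dedup_earliest(toy_corpus)
    assert first_years == {"50-00-0": 1999, "71-43-2": 1999, "7439-92-1": 2005}
    assert ordered == ["50-00-0", "71-43-2", "7439-92-1"]


def test_dedup_same_year_tie_listed_once_sorted():
    corpus = Corpus(
        [
            CitationRecord("a", 2000, {"ANST"}, {"71-43-2"}),
            CitationRecord("b", 2000, {"ANST"}, {"71-43-2", "50-00-0"}),
        ]
    )
    first_years, ordered = dedup_earliest(corpus)
    assert ordered == ["50-00-0", "71-43-2"]
    assert first_years["71-43-2"] == 2000


def test_dedup_idempotent_on_own_output(toy_corpus):
    first_years, ordered = dedup_earliest(toy_corpus)
    # re-express the output as a one-record-per-substance corpus
    single = Corpus(
        [
            CitationRecord(f"s{i}", first_years[c], {"ANST"}, {c})
            for i, c in enumerate(ordered)
        ]
    )
    again_years, again_ordered = dedup_earliest(single)
    assert again_years == first_years
    assert again_ordered == ordered


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dedup_invariant_to_record_order(seed):
    rng = np.random.default_rng(seed)
    corpus = random_corpus(rng)
    shuffled = list(corpus.records)
    rng.shuffle(shuffled)
    assert dedup_earliest(Corpus(shuffled)) == dedup_earliest(corpus)


def test_dedup_empty_corpus_errors():
    with pytest.raises(ValueError):
        dedup_earliest(Corpus([]))


# -------------------------------------------------------------- profiles

def test_profile_totals_match_hand_count(toy_corpus):
    profiles = build_profiles(toy_corpus)
    assert profiles["50-00-0"].total_count == 3
    assert profiles["71-43-2"].total_count == 3
    assert profiles["7439-92-1"].total_count == 2
    assert profiles["50-00-0"].first_year == 1999
    # counts_by_year zero-filled over the full window
    assert set(profiles["50-00-0"].counts_by_year) == set(range(1999, 2006))
    assert profiles["50-00-0"].counts_by_year[2003] == 0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_profile_conservation_vs_brute_force_tally(seed):
    """Sum of profile totals equals a brute-force row-by-row tally."""
    corpus = random_corpus(np.random.default_rng(seed))
    brute = 0
    for rec in corpus.records:
        for _ in rec.casrns:
            brute += 1
    profiles = build_profiles(corpus)
    assert sum(p.total_count for p in profiles.values()) == brute == corpus.total_counts
    for p in profiles.values():
        assert p.total_count == sum(p.counts_by_year.values())
        assert p.first_year == min(y for y, n in p.counts_by_year.items() if n)


# ------------------------------------------------------------- screening

def _profiles_of(casrns):
    corpus = Corpus([CitationRecord(f"r{i}", 2000, {"ANST"}, {c}) for i, c in enumerate(casrns)])
    return build_profiles(corpus)


def test_first_matching_category_attribution():
    profiles = _profiles_of(["50-00-0", "71-43-2"])
    ruleset = ExclusionRuleSet(
        categories=[
            ("minerals", frozenset({"50-00-0"})),
            ("polymers", frozenset({"50-00-0", "71-43-2"})),
        ]
    )
    kept, report = apply_exclusions(profiles, ruleset)
    assert kept == {}
    assert report.removed_by_category == {"minerals": 1, "polymers": 1}
    assert profiles["50-00-0"].excluded_by == "minerals"


def test_whitelist_supremacy_example():
    profiles = _profiles_of(["14797-55-8", "50-00-0"])  # nitrate + formaldehyde
    ruleset = ExclusionRuleSet(
        categories=[("inorganic salts", frozenset({"14797-55-8", "50-00-0"}))],
        whitelist=frozenset({"14797-55-8"}),
    )
    kept, report = apply_exclusions(profiles, ruleset)
    assert "14797-55-8" in kept
    assert report.removed_total == 1


def test_empty_ruleset_is_identity():
    profiles = _profiles_of(["50-00-0"])
    kept, report = apply_exclusions(profiles, ExclusionRuleSet())
    assert kept == profiles
    assert report.removed_total == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_screening_conservation_and_whitelist_supremacy(seed):
    rng = np.random.default_rng(seed)
    corpus = random_corpus(rng, n_substances=30)
    profiles = build_profiles(corpus)
    casrns = sorted(profiles)
    cats = []
    for name in ("c1", "c2", "c3"):
        members = frozenset(rng.choice(casrns, size=rng.integers(1, 15), replace=False))
        cats.append((name, members))
    whitelist = frozenset(rng.choice(casrns, size=5, replace=False))
    kept, report = apply_exclusions(profiles, ExclusionRuleSet(cats, whitelist))
    assert report.input_count == report.kept_count + report.removed_total
    assert whitelist & set(profiles) <= set(kept)


def test_food_constituent_screen_composes():
    profiles = _profiles_of(["50-00-0", "71-43-2", "7439-92-1"])
    food = ChemicalList("foodb-like", frozenset({"71-43-2", "1746-01-6"}), "food")
    kept, report = food_constituent_screen(profiles, food)
    assert set(kept) == {"50-00-0", "7439-92-1"}
    assert report.removed_total == 1


def test_food_casrn_on_whitelist_kept():
    profiles = _profiles_of(["71-43-2"])
    food = ChemicalList("foodb-like", frozenset({"71-43-2"}), "food")
    kept, _ = food_constituent_screen(profiles, food, whitelist={"71-43-2"})
    assert "71-43-2" in kept


def test_disjoint_food_list_is_identity():
    profiles = _profiles_of(["50-00-0"])
    food = ChemicalList("foodb-like", frozenset({"1746-01-6"}), "food")
    kept, _ = food_constituent_screen(profiles, food)
    assert kept == profiles
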