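"""Trend tables, percent shares, top-N concentration, new-substance series."""

import math

import numpy as np
import pandas as pd
import pytest

from chembib.corpus import CitationRecord, Corpus
from chembib.screen import build_profiles, dedup_earliest
from chembib.trends import (
    ConcentrationCurve,
    annual_class_counts,
    format_percent,
    newly_reported_series,
    share_series,
    substance_share,
    top_n_share,
)
from conftest import random_corpus


@pytest.fixture
def two_class_corpus():
    # 2 years x 2 classes, hand-computable
    return Corpus(
        [
            CitationRecord("r1", 2000, {"ANST"}, {"50-00-0", "71-43-2"}),
            CitationRecord("r2", 2000, {"ANST"}, {"50-00-0"}),
            CitationRecord("r3", 2001, {"ANST"}, {"71-43-2"}),
        ]
    )


def classified(corpus, mapping):
    profiles = build_profiles(corpus)
    for c, label in mapping.items():
        profiles[c].class_label = label
    return profiles


def test_annual_class_counts_hand_matrix(two_class_corpus):
    profiles = classified(two_class_corpus, {"50-00-0": "A", "71-43-2": "B"})
    trend = annual_class_counts(two_class_corpus, profiles)
    assert trend.table.at[2000, "A"] == 2
    assert trend.table.at[2000, "B"] == 1
    assert trend.table.at[2001, "A"] == 0
    assert trend.table.at[2001, "B"] == 1
    assert trend.grand_total == two_class_corpus.total_counts


def test_class_with_no_members_gives_zero_column(two_class_corpus):
    profiles = classified(two_class_corpus, {"50-00-0": "A", "71-43-2": "A"})
    profiles["50-00-0"].class_label = "A"
    trend = annual_class_counts(two_class_corpus, profiles)
    assert set(trend.labels) == {"A"}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matrix_total_matches_brute_force_row_tally(seed):
    corpus = random_corpus(np.random.default_rng(seed))
    profiles = build_profiles(corpus)
    trend = annual_class_counts(corpus, profiles)
    brute = sum(len(r.casrns) for r in corpus.records)
    assert trend.grand_total == brute


def test_share_series_single_class_is_100(two_class_corpus):
    profiles = classified(two_class_corpus, {"50-00-0": "A", "71-43-2": "A"})
    trend = annual_class_counts(two_class_corpus, profiles)
    assert (share_series(trend, "A").dropna() == 100.0).all()


def test_share_series_absent_year_is_zero_and_gap_year_is_nan():
    corpus = Corpus(
        [
            CitationRecord("r1", 2000, {"ANST"}, {"50-00-0"}),
            CitationRecord("r2", 2002, {"ANST"}, {"71-43-2"}),
        ]
    )
    profiles = classified(corpus, {"50-00-0": "A", "71-43-2": "B"})
    trend = annual_class_counts(corpus, profiles)
    s = share_series(trend, "A")
    assert s[2000] == 100.0
    assert s[2002] == 0.0  # class absent that year, total nonzero
    assert math.isnan(s[2001])  # no reports at all: undefined, not 0


def test_share_series_partition_sums_to_100(two_class_corpus):
    profiles = classified(two_class_corpus, {"50-00-0": "A", "71-43-2": "B"})
    trend = annual_class_counts(two_class_corpus, profiles)
    total = sum(share_series(trend, label).fillna(0) for label in trend.labels)
    assert np.allclose(total, 100.0)


def test_share_series_unknown_label_errors(two_class_corpus):
    profiles = classified(two_class_corpus, {"50-00-0": "A", "71-43-2": "B"})
    trend = annual_class_counts(two_class_corpus, profiles)
    with pytest.raises(KeyError):
        share_series(trend, "nope")


# ------------------------------------------------------------ concentration

def test_top_n_share_small_example():
    curve = ConcentrationCurve.from_totals({"a-00-0": 5, "b-00-0": 3, "c-00-0": 2})
    assert top_n_share(curve, 2) == pytest.approx(0.8)
    assert top_n_share(curve, 3) == pytest.approx(1.0)


def test_top_n_share_out_of_range():
    curve = ConcentrationCurve.from_totals({"a-00-0": 5})
    with pytest.raises(ValueError):
        top_n_share(curve, 0)
    with pytest.raises(ValueError):
        top_n_share(curve, 2)


def test_ties_broken_by_casrn_ascending():
    curve = ConcentrationCurve.from_totals({"71-43-2": 3, "50-00-0": 3, "100-42-5": 1})
    assert curve.casrns == ["50-00-0", "71-43-2", "100-42-5"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_top_n_share_monotone_and_order_invariant(seed):
    rng = np.random.default_rng(seed)
    corpus = random_corpus(rng)
    profiles = build_profiles(corpus)
    curve = ConcentrationCurve.from_profiles(profiles)
    shares = [top_n_share(curve, n) for n in range(1, len(curve) + 1)]
    assert all(b >= a for a, b in zip(shares, shares[1:]))
    assert shares[-1] == pytest.approx(1.0)
    # permutation invariance of records
    shuffled = list(corpus.records)
    rng.shuffle(shuffled)
    curve2 = ConcentrationCurve.from_profiles(build_profiles(Corpus(shuffled)))
    assert curve2.casrns == curve.casrns
    assert (curve2.sorted_totals == curve.sorted_totals).all()


# ------------------------------------------------------------- formatting

@pytest.mark.parametrize(
    "x, expected",
    [
        (0.3402, "34%"),
        (0.0078948, "0.79%"),
        (0.0, "0%"),
        (0.64, "64%"),
        (0.5394, "54%"),
        (0.015069, "1.5%"),
        (0.01136, "1.1%"),
        (0.0017994, "0.18%"),
        (0.105, "11%"),  # round-half-up at the integer rule
        (0.0995, "10%"),  # two-sig-fig rounding crossing the 10% boundary
    ],
)
def test_format_percent_table_rule(x, expected):
    assert format_percent(x) == expected


def test_format_percent_other_rules():
    assert format_percent(0.34567, "int") == "35%"
    assert format_percent(0.34567, "1dp") == "34.6%"
    with pytest.raises(ValueError):
        format_percent(0.5, "bogus")
    with pytest.raises(ValueError):
        format_percent(-0.1)


def test_substance_share_formats():
    assert substance_share(73_043, 9_251_975) == "0.79%"
    assert substance_share(743, 413_007) == "0.18%"
    assert substance_share(0, 413_007) == "0%"
    with pytest.raises(ValueError):
        substance_share(1, 0)


# --------------------------------------------------------- newly reported

def test_all_substances_first_year_then_zeros():
    corpus = Corpus(
        [
            CitationRecord("r1", 2000, {"ANST"}, {"50-00-0", "71-43-2"}),
            CitationRecord("r2", 2001, {"ANST"}, {"50-00-0"}),
            CitationRecord("r3", 2002, {"ANST"}, {"71-43-2"}),
        ]
    )
    profiles = build_profiles(corpus)
    first_years, _ = dedup_earliest(corpus)
    trend = annual_class_counts(corpus, profiles)
    series = newly_reported_series(first_years, trend)
    assert series["new_substances"].tolist() == [2, 0, 0]
    assert series["pct_of_total_reports"][2000] == 100.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_newly_reported_conservation(seed):
    """New-substance counts sum to the number of unique substances,
    checked against a brute-force first-occurrence scan."""
    corpus = random_corpus(np.random.default_rng(seed))
    profiles = build_profiles(corpus)
    first_years, _ = dedup_earliest(corpus)
    # brute-force oracle: scan records sorted by year, note first sightings
    seen: set[str] = set()
    brute: dict[int, int] = {}
    for rec in sorted(corpus.records, key=lambda r: r.year):
        for c in rec.casrns:
            if c not in seen:
                seen.add(c)
                brute[rec.year] = brute.get(rec.year, 0) + 1
    trend = annual_class_counts(corpus, profiles)
    series = newly_reported_series(first_years, trend)
    assert int(series["new_substances"].sum()) == len(corpus.unique_casrns)
    for year, n in brute.items():
        assert series["new_substances"][year] == n
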