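"""Reconstruction of the published worked examples from printed counts.

The real citation corpus is proprietary, so the published exhibits
cannot be recomputed from raw data. What CAN be recomputed exactly is
their arithmetic: the printed count columns (top-N cumulative counts,
grand totals, per-substance counts, screening tallies, inventory
overlaps and declared sizes) are inputs, and this module rebuilds
minimal synthetic objects that are exactly consistent with them, so the
pipeline's statistics can be run forward and compared with the printed
percentages.

All per-substance detail here is synthetic: only the block sums, list
sizes, per-set overlaps, and union count are taken from the published
numbers. Quantities the publication does not print (e.g. the individual
Venn region counts) are chosen once, arbitrarily but consistently.
"""

from __future__ import annotations

import numpy as np

from .corpus import Inventory, SubstanceProfile
from .data import fig5_counts, screening_counts, table1_counts
from .screen import ExclusionRuleSet
from .synthetic import synthetic_casrns
from .trends import ConcentrationCurve

__all__ = [
    "printed_concentration_curve",
    "printed_substance_counts",
    "screening_fixture",
    "classified_fixture",
    "overlap_fixture",
    "WATER_POLLUTANT_WHITELIST",
]

#: Well-known water-pollutant ions exempt from the inorganic-salt
#: exclusion: perchlorate, nitrate, phosphate, sulfate, cyanide.
WATER_POLLUTANT_WHITELIST = (
    "14797-73-0",  # perchlorate
    "14797-55-8",  # nitrate
    "14265-44-2",  # phosphate
    "14808-79-8",  # sulfate
    "57-12-5",  # cyanide ion
)

_TOP_ROWS = ("top_10", "top_100", "top_200", "top_300", "top_500")
_TOP_NS = (10, 100, 200, 300, 500)


def _spread(total: int, k: int) -> list[int]:
    """Split ``total`` into k non-increasing integers summing exactly."""
    base, rem = divmod(total, k)
    return [base + 1] * rem + [base] * (k - rem)


def printed_concentration_curve(column: str = "anst_pol_counts") -> ConcentrationCurve:
    """A concentration curve over the published number of substances
    whose cumulative counts at every printed top-N cut equal the printed
    cumulative counts, and whose grand total equals the printed grand
    total.

    Within each rank block the counts are spread as evenly as integers
    allow; the blockwise averages decrease, so the sequence is globally
    non-increasing, as a sorted curve requires.
    """
    df = table1_counts().set_index("row")
    grand = int(df.at["grand_total", column])
    n_substances = int(screening_counts()["final_casrns"])
    cuts = [0] + [int(df.at[r, column]) for r in _TOP_ROWS] + [grand]
    sizes = [b - a for a, b in zip((0,) + _TOP_NS, _TOP_NS + (n_substances,))]
    totals: list[int] = []
    for (lo, hi), k in zip(zip(cuts, cuts[1:]), sizes):
        totals.extend(_spread(hi - lo, k))
    arr = np.array(totals, dtype=np.int64)
    if not (np.diff(arr) <= 0).all():
        raise AssertionError("printed block sums do not yield a sorted curve")
    casrns = synthetic_casrns(n_substances)
    return ConcentrationCurve(casrns=casrns, sorted_totals=arr, grand_total=grand)


def printed_substance_counts(column: str = "anst_pol_counts") -> dict[str, tuple[int, int]]:
    """Per-substance printed counts: substance row -> (count, grand
    total) for the named-substance rows (lead, cadmium, DDT, TCDD)."""
    df = table1_counts()
    grand = int(df.set_index("row").at["grand_total", column])
    out = {}
    for _, row in df.iterrows():
        if isinstance(row["casrn"], str) and row["casrn"]:
            out[row["row"]] = (int(row[column]), grand)
    return out


def _trivial_profiles(casrns: list[str], year: int = 2000) -> dict[str, SubstanceProfile]:
    return {
        c: SubstanceProfile(casrn=c, first_year=year, counts_by_year={year: 1}, total_count=1)
        for c in casrns
    }


def screening_fixture(
    n_categories: int = 8,
) -> tuple[dict[str, SubstanceProfile], ExclusionRuleSet]:
    """The published screening problem at full printed size.

    The universe holds the printed initial count of substances
    (including the five whitelisted water-pollutant ions); the exclusion
    categories flag the printed number of exclusions plus the
    whitelisted ions, so that applying the screen removes exactly the
    printed number and keeps the printed final count.
    """
    counts = screening_counts()
    n_total = counts["initial_casrns"]
    n_excluded = counts["excluded_casrns"]
    whitelist = list(WATER_POLLUTANT_WHITELIST)
    universe = synthetic_casrns(n_total - len(whitelist)) + whitelist
    profiles = _trivial_profiles(universe)

    category_names = [
        "acids",
        "alloys and complex structures",
        "mass-labeled compounds",
        "minerals",
        "simple inorganic salts",
        "essential elements",
        "polymers",
        "natural products and mixtures",
    ][:n_categories]
    flagged = universe[:n_excluded]
    chunks = np.array_split(np.array(flagged, dtype=object), len(category_names))
    categories = [
        (name, frozenset(chunk.tolist())) for name, chunk in zip(category_names, chunks)
    ]
    # The whitelisted ions sit in the salts category but must survive.
    salts_i = category_names.index("simple inorganic salts")
    categories[salts_i] = (
        "simple inorganic salts",
        categories[salts_i][1] | frozenset(whitelist),
    )
    return profiles, ExclusionRuleSet(categories=categories, whitelist=frozenset(whitelist))


def classified_fixture() -> dict[str, SubstanceProfile]:
    """A classified analysis list at the printed final size, with the
    pharmaceutical and current-use pesticide classes together holding
    exactly the number of substances the overlap pre-filter removes."""
    counts = screening_counts()
    n_final = counts["final_casrns"]
    n_removed = counts["overlap_prefilter_removed"]
    n_pharma = 1809  # published pharmaceutical class size
    n_pest = n_removed - n_pharma
    profiles = _trivial_profiles(synthetic_casrns(n_final))
    for i, profile in enumerate(profiles.values()):
        if i < n_pharma:
            profile.class_label = "pharmaceutical"
        elif i < n_pharma + n_pest:
            profile.class_label = "current-use pesticide"
    return profiles


# Venn region counts (A-only, B-only, C-only, AB, AC, BC, ABC) chosen to
# be consistent with the printed per-inventory overlaps (3499, 2974,
# 1576) and the printed union (4253); the publication does not print the
# individual regions, so this split is a synthetic stand-in.
_REGIONS = {"100": 599, "010": 78, "001": 280, "110": 2000, "101": 400, "011": 396, "111": 500}


def overlap_fixture() -> tuple[set[str], list[Inventory]]:
    """Reference CASRN set at the printed reduced-list size, plus three
    fixture inventories whose overlaps with it equal the printed
    per-inventory overlap counts and whose declared sizes are the
    printed real inventory sizes."""
    counts = screening_counts()
    reference = set(synthetic_casrns(counts["overlap_reference_casrns"]))
    ordered = sorted(reference)
    members: dict[str, set[str]] = {"A": set(), "B": set(), "C": set()}
    pos = 0
    for bits, n in _REGIONS.items():
        chunk = ordered[pos : pos + n]
        pos += n
        for flag, key in zip(bits, "ABC"):
            if flag == "1":
                members[key].update(chunk)
    inv_df = fig5_counts().set_index("inventory")
    inventories = []
    for key, name in zip("ABC", ("TSCA", "IECSC", "REACH")):
        inventories.append(
            Inventory(name, frozenset(members[key]), int(inv_df.at[name, "declared_size"]))
        )
    return reference, inventories
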