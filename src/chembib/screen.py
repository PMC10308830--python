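"""Earliest-year deduplication, substance profiles, and exclusion screening.

Deduplication follows the sequential-earliest-year rule: when a substance
appears in many records, the occurrence that defines its first-report
year is its earliest-year occurrence, with ties within a year broken by
canonical CASRN sort. The exclusion screen removes substances unlikely to
be labeled contaminants (essential elements, minerals, simple inorganic
salts, natural products, polymers, mass-labeled compounds, ...) as
declarative category files, with a whitelist of well-known water
pollutants (perchlorate, nitrate, phosphate, sulfate, cyanide ion) that
is always kept regardless of category membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .corpus import ChemicalList, Corpus, SubstanceProfile

__all__ = [
    "ExclusionRuleSet",
    "ScreeningReport",
    "dedup_earliest",
    "build_profiles",
    "apply_exclusions",
    "food_constituent_screen",
]


@dataclass
class ExclusionRuleSet:
    """Ordered exclusion categories plus a whitelist.

    Each category is ``(name, member CASRN set)``. Order is precedence: a
    substance matching several categories is removed once, attributed to
    the first match. Whitelist members are exempt from every category.
    """

    categories: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.categories]
        if len(names) != len(set(names)):
            raise ValueError("exclusion category names must be unique")


@dataclass
class ScreeningReport:
    input_count: int
    removed_by_category: dict[str, int]
    kept_count: int

    @property
    def removed_total(self) -> int:
        return sum(self.removed_by_category.values())

    def check(self) -> None:
        if self.input_count != self.kept_count + self.removed_total:
            raise AssertionError("screening conservation violated")


def dedup_earliest(corpus: Corpus) -> tuple[dict[str, int], list[str]]:
    """First-report year per CASRN, plus the unique CASRN list ordered by
    (first_year ascending, canonical CASRN ascending).

    The output is a deterministic function of corpus content, independent
    of record order.
    """
    if not corpus.records:
        raise ValueError("corpus is empty")
    first_year: dict[str, int] = {}
    for rec in corpus.records:
        for c in rec.casrns:
            y = first_year.get(c)
            if y is None or rec.year < y:
                first_year[c] = rec.year
    ordered = sorted(first_year, key=lambda c: (first_year[c], c))
    return first_year, ordered


def build_profiles(corpus: Corpus) -> dict[str, SubstanceProfile]:
    """Aggregate the corpus into per-substance profiles.

    Conservation: the profile totals sum to the corpus total CASRN count.
    ``counts_by_year`` is zero-filled over the full corpus window.
    """
    years = corpus.years
    counts: dict[str, dict[int, int]] = {}
    for rec in corpus.records:
        for c in rec.casrns:
            by_year = counts.setdefault(c, {})
            by_year[rec.year] = by_year.get(rec.year, 0) + 1
    profiles: dict[str, SubstanceProfile] = {}
    for c in sorted(counts):
        by_year = counts[c]
        full = {y: by_year.get(y, 0) for y in years}
        profiles[c] = SubstanceProfile(
            casrn=c,
            first_year=min(y for y, n in by_year.items() if n > 0),
            counts_by_year=full,
            total_count=sum(by_year.values()),
        )
    return profiles


def apply_exclusions(
    profiles: dict[str, SubstanceProfile],
    ruleset: ExclusionRuleSet,
) -> tuple[dict[str, SubstanceProfile], ScreeningReport]:
    """Remove profiles matching exclusion categories.

    Whitelisted substances are always kept. A substance matching several
    categories is counted once, under the first category in ruleset
    order; removed profiles get ``excluded_by`` set. An empty ruleset is
    the identity.
    """
    kept: dict[str, SubstanceProfile] = {}
    removed_by_category = {name: 0 for name, _ in ruleset.categories}
    for casrn, profile in profiles.items():
        hit = None
        if casrn not in ruleset.whitelist:
            for name, members in ruleset.categories:
                if casrn in members:
                    hit = name
                    break
        if hit is None:
            kept[casrn] = profile
        else:
            profile.excluded_by = hit
            removed_by_category[hit] += 1
    report = ScreeningReport(
        input_count=len(profiles),
        removed_by_category=removed_by_category,
        kept_count=len(kept),
    )
    report.check()
    return kept, report


def food_constituent_screen(
    profiles: dict[str, SubstanceProfile],
    food_list: ChemicalList,
    whitelist: Iterable[str] = (),
) -> tuple[dict[str, SubstanceProfile], ScreeningReport]:
    """Screen out natural food constituents (a FooDB-style list), acting
    as one more exclusion category; composes with ``apply_exclusions``."""
    ruleset = ExclusionRuleSet(
        categories=[(f"food constituent ({food_list.name})", food_list.members)],
        whitelist=frozenset(whitelist),
    )
    return apply_exclusions(profiles, ruleset)
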