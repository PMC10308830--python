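"""Seeded generator of synthetic literature corpora.

The real corpus behind this kind of bibliometric analysis (a curated
citation database with per-substance indexing roles) is proprietary, so
this module generates corpora with the statistical structure the
analysis assumes:

* exponential growth in annual publication volume,
* heavy-tailed per-substance citation counts (Zipf-like popularity,
  optionally mixed with citation-proportional preferential attachment,
  which produces the rich-get-richer concentration of measurements),
* staggered substance emergence years (a substance cannot be cited
  before it emerges),
* multiple CASRNs per record (truncated geometric),
* a class mixture assigning each substance to one named class, to the
  CEC-only pool, or to "not characterized".

Every draw is derived from a single root seed, with per-year substreams
so extending the year window never perturbs earlier years. The generator
exports ground truth (true first-report years, classes, popularity
weights, realized totals) for exact recovery tests of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .casrn import make_casrn
from .classify import CEC_ONLY, NOT_CHARACTERIZED, ClassTaxonomy, assign_classes
from .corpus import ChemicalList, CitationRecord, Corpus
from .screen import build_profiles, dedup_earliest
from .trends import ConcentrationCurve, top_n_share

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "RecoveryReport",
    "generate",
    "recover",
    "synthetic_casrns",
    "DEFAULT_CLASS_MIXTURE",
]

# Structural stand-in for the class composition of an environmental
# analysis list: ~56% on named class lists, ~15% only on a broad CEC
# screening list, ~29% on no list at all.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "pharmaceutical": 0.09,
    "current-use pesticide": 0.09,
    "legacy OC pesticide": 0.03,
    "PCBs": 0.02,
    "PCDD/Fs": 0.01,
    "PBDEs": 0.01,
    "other flame retardants": 0.02,
    "PFAS": 0.03,
    "CFC-HFC": 0.01,
    "PAH/PAC": 0.04,
    "alkane/ene": 0.02,
    "VOC/gas": 0.03,
    "inorganic ions": 0.02,
    "inorganic acids/salts": 0.01,
    "disinfection byproducts": 0.01,
    "metals/isotopes": 0.03,
    "fragrances": 0.01,
    "plastics additives": 0.03,
    "food additives": 0.02,
    "bisphenols/siloxanes": 0.02,
    "BZT/BT/AA": 0.01,
    CEC_ONLY: 0.15,
    NOT_CHARACTERIZED: 0.29,
}


def synthetic_casrns(n: int, start: int = 0) -> list[str]:
    """n distinct valid synthetic CASRNs (bodies counted up from
    ``start``; the check digit is computed, so every one validates)."""
    return [make_casrn(str(10000 + start + i)) for i in range(n)]


@dataclass
class SyntheticConfig:
    """Generator parameters.

    n_substances: size of the substance universe.
    years: inclusive (start, end) calendar window.
    base_records_per_year: records in the first year; year y gets
        round(base * growth^(y-start)).
    annual_growth_rate: multiplicative yearly growth (>= 1).
    popularity_exponent: Zipf exponent s > 0; substance of popularity
        rank r has fixed weight proportional to r^-s.
    preferential_attachment_weight: w in [0, 1]; sampling probability is
        (1-w) * zipf_weight + w * (citations so far + 1), each normalized
        over the substances that have emerged.
    emergence_schedule: "uniform" (emergence years uniform over the
        window) or "all_at_start" (everything available from year one).
    casrns_per_record_mean: mean of the truncated geometric number of
        CASRNs per record.
    max_casrns_per_record: geometric truncation cap.
    class_mixture: label -> fraction, summing to 1.
    seed: root seed; identical config + seed gives a byte-identical
        corpus.
    """

    n_substances: int = 5000
    years: tuple[int, int] = (1989, 2018)
    base_records_per_year: int = 100
    annual_growth_rate: float = 1.08
    popularity_exponent: float = 1.0
    preferential_attachment_weight: float = 0.3
    emergence_schedule: str = "uniform"
    casrns_per_record_mean: float = 4.0
    max_casrns_per_record: int = 20
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    seed: int = 0

    def validate(self) -> None:
        start, end = self.years
        if end < start:
            raise ValueError("years end must be >= start")
        if self.n_substances <= 0 or self.base_records_per_year <= 0:
            raise ValueError("counts must be positive")
        if self.annual_growth_rate < 1:
            raise ValueError("annual_growth_rate must be >= 1")
        if self.popularity_exponent <= 0:
            raise ValueError("popularity_exponent must be > 0")
        if not 0 <= self.preferential_attachment_weight <= 1:
            raise ValueError("preferential_attachment_weight must be in [0, 1]")
        if self.emergence_schedule not in ("uniform", "all_at_start"):
            raise ValueError(f"unknown emergence_schedule {self.emergence_schedule!r}")
        if self.casrns_per_record_mean < 1:
            raise ValueError("casrns_per_record_mean must be >= 1")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture must sum to 1, sums to {total}")


@dataclass
class GroundTruth:
    """What the generator knows to be true about its corpus."""

    casrns: list[str]
    first_year: dict[str, int]  # first year actually cited (emitted substances)
    class_label: dict[str, str]
    zipf_weight: dict[str, float]
    emergence_year: dict[str, int]
    realized_totals: dict[str, int]  # zero for never-cited substances


@dataclass
class RecoveryReport:
    n_substances_cited: int
    first_year_match_rate: float
    class_count_max_deviation: int
    totals_match: bool
    top_n: int
    top_n_share_pipeline: float
    top_n_share_truth: float


def _taxonomy_from_truth(truth: GroundTruth) -> ClassTaxonomy:
    by_label: dict[str, set[str]] = {}
    for casrn, label in truth.class_label.items():
        by_label.setdefault(label, set()).add(casrn)
    lists = [
        ChemicalList(label, frozenset(by_label.get(label, set())), label, rank)
        for rank, label in enumerate(
            l for l in sorted(by_label) if l not in (CEC_ONLY, NOT_CHARACTERIZED)
        )
    ]
    cec = ChemicalList(
        "CEC screening list", frozenset(by_label.get(CEC_ONLY, set())), CEC_ONLY, 10_000
    )
    return ClassTaxonomy(lists, cec_list=cec)


def generate(config: SyntheticConfig) -> tuple[Corpus, list[ChemicalList], GroundTruth]:
    """Generate (corpus, class lists, ground truth).

    Class lists include one list per named class plus the CEC screening
    list (category "CEC-only", lowest precedence).
    """
    config.validate()
    start, end = config.years
    n = config.n_substances
    rng_setup = np.random.default_rng([config.seed, 0])

    casrns = synthetic_casrns(n)
    labels = list(config.class_mixture)
    fractions = np.array([config.class_mixture[l] for l in labels])
    class_idx = rng_setup.choice(len(labels), size=n, p=fractions / fractions.sum())

    # Popularity rank is a random permutation so popularity is independent
    # of class and emergence; zipf weight of rank r is (r+1)^-s.
    rank = rng_setup.permutation(n)
    zipf = (rank + 1.0) ** (-config.popularity_exponent)
    zipf /= zipf.sum()

    if config.emergence_schedule == "all_at_start":
        emergence = np.full(n, start, dtype=np.int64)
    else:
        emergence = rng_setup.integers(start, end + 1, size=n)

    citations = np.zeros(n, dtype=np.float64)
    totals = np.zeros(n, dtype=np.int64)
    first_cited: dict[str, int] = {}
    records: list[CitationRecord] = []
    w = config.preferential_attachment_weight
    geom_p = 1.0 / config.casrns_per_record_mean

    for year in range(start, end + 1):
        rng_y = np.random.default_rng([config.seed, 1, year])
        n_rec = int(round(config.base_records_per_year * config.annual_growth_rate ** (year - start)))
        eligible = np.flatnonzero(emergence <= year)
        if eligible.size == 0:
            raise ValueError(f"no substance has emerged by year {year}")
        zw = zipf[eligible]
        zw = zw / zw.sum()
        for j in range(n_rec):
            k = int(rng_y.geometric(geom_p))
            k = min(k, config.max_casrns_per_record, eligible.size)
            if w > 0:
                pa = citations[eligible] + 1.0
                p = (1.0 - w) * zw + w * (pa / pa.sum())
                p = p / p.sum()
            else:
                p = zw
            drawn = rng_y.choice(eligible.size, size=k, replace=False, p=p)
            idx = eligible[drawn]
            citations[idx] += 1.0
            totals[idx] += 1
            rec_casrns = []
            for i in idx:
                c = casrns[i]
                rec_casrns.append(c)
                if c not in first_cited:
                    first_cited[c] = year
            roles = {"ANST", "POL"}
            if rng_y.random() < 0.5:
                roles.add("BIOL")
            records.append(
                CitationRecord(f"R{year}-{j:05d}", year, frozenset(roles), frozenset(rec_casrns))
            )

    truth = GroundTruth(
        casrns=casrns,
        first_year=dict(first_cited),
        class_label={casrns[i]: labels[class_idx[i]] for i in range(n)},
        zipf_weight={casrns[i]: float(zipf[i]) for i in range(n)},
        emergence_year={casrns[i]: int(emergence[i]) for i in range(n)},
        realized_totals={casrns[i]: int(totals[i]) for i in range(n)},
    )
    taxonomy = _taxonomy_from_truth(truth)
    class_lists = list(taxonomy.lists)
    if taxonomy.cec_list is not None:
        class_lists.append(taxonomy.cec_list)
    return Corpus(records, year_range=(start, end)), class_lists, truth


def recover(corpus: Corpus, truth: GroundTruth, top_n: int = 100) -> RecoveryReport:
    """Run the analysis pipeline on a generated corpus and compare with
    ground truth.

    First-report years are determined by the corpus, so recovery must be
    exact; class counts and per-substance totals likewise. Raises
    ``ValueError`` if the ground truth does not describe this corpus.
    """
    profiles = build_profiles(corpus)
    unknown = set(profiles) - set(truth.casrns)
    if unknown:
        raise ValueError(f"corpus contains CASRNs absent from ground truth: {sorted(unknown)[:3]}")

    first_years, _ = dedup_earliest(corpus)
    matches = sum(1 for c, y in first_years.items() if truth.first_year.get(c) == y)
    match_rate = matches / len(first_years)

    taxonomy = _taxonomy_from_truth(truth)
    summary = assign_classes(profiles, taxonomy)
    true_counts: dict[str, int] = {}
    for c in profiles:
        true_counts[truth.class_label[c]] = true_counts.get(truth.class_label[c], 0) + 1
    all_labels = set(summary.counts) | set(true_counts)
    max_dev = max(
        abs(summary.counts.get(l, 0) - true_counts.get(l, 0)) for l in all_labels
    )

    totals_match = all(
        p.total_count == truth.realized_totals[c] for c, p in profiles.items()
    ) and sum(truth.realized_totals.values()) == corpus.total_counts

    pipeline_curve = ConcentrationCurve.from_profiles(profiles)
    truth_curve = ConcentrationCurve.from_totals(
        {c: t for c, t in truth.realized_totals.items() if t > 0}
    )
    n_eff = min(top_n, len(pipeline_curve), len(truth_curve))
    return RecoveryReport(
        n_substances_cited=len(profiles),
        first_year_match_rate=match_rate,
        class_count_max_deviation=max_dev,
        totals_match=totals_match,
        top_n=n_eff,
        top_n_share_pipeline=top_n_share(pipeline_curve, n_eff),
        top_n_share_truth=top_n_share(truth_curve, n_eff),
    )
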