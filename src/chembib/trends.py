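"""Temporal trend series and top-N concentration statistics.

The concentration of measurements on already-measured substances (the
Matthew effect) is quantified as the share of the grand-total citation
counts carried by the N most-reported substances. Percentages follow a
mixed display rule common in summary tables: round-half-up, integers for
shares at or above 10%, two significant figures below 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import Corpus, SubstanceProfile

__all__ = [
    "TrendTable",
    "ConcentrationCurve",
    "annual_class_counts",
    "share_series",
    "top_n_share",
    "substance_share",
    "newly_reported_series",
    "format_percent",
]


@dataclass
class TrendTable:
    """Year x class matrix of citation counts.

    ``table`` is indexed by consecutive calendar years with one column
    per class label; when the taxonomy partitions all substances the row
    sums equal the corpus per-year totals.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        years = self.table.index.to_numpy()
        if len(years) and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError("trend table years must be consecutive with no gaps")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.table.index]

    @property
    def labels(self) -> list[str]:
        return list(self.table.columns)

    @property
    def totals_by_year(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format (year, class, count, share_pct) for TSV export."""
        totals = self.totals_by_year
        rows = []
        for label in self.labels:
            for year in self.years:
                n = int(self.table.at[year, label])
                tot = int(totals[year])
                rows.append(
                    {
                        "year": year,
                        "class": label,
                        "count": n,
                        "share_pct": (100.0 * n / tot) if tot else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ConcentrationCurve:
    """Per-substance totals sorted descending, with cumulative shares.

    Ties are broken by canonical CASRN ascending so top-N cuts are
    deterministic.
    """

    casrns: list[str]
    sorted_totals: np.ndarray
    grand_total: int
    cum_share: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sorted_totals = np.asarray(self.sorted_totals, dtype=np.int64)
        if self.grand_total <= 0:
            raise ValueError("grand_total must be positive")
        self.cum_share = np.cumsum(self.sorted_totals) / float(self.grand_total)

    @classmethod
    def from_totals(cls, totals: Mapping[str, int]) -> "ConcentrationCurve":
        order = sorted(totals, key=lambda c: (-totals[c], c))
        arr = np.array([totals[c] for c in order], dtype=np.int64)
        return cls(casrns=order, sorted_totals=arr, grand_total=int(arr.sum()))

    @classmethod
    def from_profiles(cls, profiles: Mapping[str, SubstanceProfile]) -> "ConcentrationCurve":
        return cls.from_totals({c: p.total_count for c, p in profiles.items()})

    def __len__(self) -> int:
        return len(self.sorted_totals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "casrn": self.casrns,
                "total": self.sorted_totals,
                "cum_share": self.cum_share,
            }
        )


def annual_class_counts(
    corpus: Corpus, profiles: Mapping[str, SubstanceProfile]
) -> TrendTable:
    """Cell (year, class) = number of (record, CASRN) pairs in that year
    whose CASRN carries that class label. Conserves the corpus total."""
    labels = sorted({p.class_label for p in profiles.values()})
    label_of = {c: p.class_label for c, p in profiles.items()}
    years = corpus.years
    table = pd.DataFrame(0, index=pd.Index(years, name="year"), columns=labels, dtype=np.int64)
    for rec in corpus.records:
        for casrn in rec.casrns:
            label = label_of.get(casrn)
            if label is not None:
                table.at[rec.year, label] += 1
    return TrendTable(table)


def share_series(trend: TrendTable, label: str) -> pd.Series:
    """Per-year percent of total annual reports carried by one class.

    Years with a zero total are NaN (undefined), not 0.
    """
    if label not in trend.table.columns:
        raise KeyError(f"unknown class label {label!r}")
    totals = trend.totals_by_year.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = 100.0 * trend.table[label].astype(float) / totals.replace(0, np.nan)
    return shares


def top_n_share(curve: ConcentrationCurve, n: int) -> float:
    """Fraction of the grand total carried by the n most-reported
    substances. Non-decreasing in n; equals 1 at n = len(curve)."""
    if not 1 <= n <= len(curve):
        raise ValueError(f"n must be in [1, {len(curve)}], got {n}")
    return float(curve.cum_share[n - 1])


def format_percent(x: float, rule: str = "table1") -> str:
    """Render a fraction as percent text.

    Rule "table1" (default): round-half-up; integer display at >= 10%,
    two significant figures below 10%; exact zero prints "0%".
    Rule "int": round-half-up integer. Rule "1dp": one decimal place.
    """
    if x < 0 or not math.isfinite(x):
        raise ValueError(f"fraction must be finite and non-negative, got {x}")
    pct = Decimal(repr(x)) * 100
    if rule == "int":
        return f"{pct.quantize(Decimal('1'), rounding=ROUND_HALF_UP)}%"
    if rule == "1dp":
        return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"
    if rule != "table1":
        raise ValueError(f"unknown percent format rule {rule!r}")
    if pct == 0:
        return "0%"
    if pct >= 10:
        return f"{pct.quantize(Decimal('1'), rounding=ROUND_HALF_UP)}%"
    # two significant figures: quantize at 10^(floor(log10)-1)
    exponent = int(math.floor(math.log10(float(pct))))
    quantum = Decimal(1).scaleb(exponent - 1)
    out = pct.quantize(quantum, rounding=ROUND_HALF_UP)
    if out >= 10:  # rounding crossed the 10% boundary, e.g. 9.96
        return f"{out.quantize(Decimal('1'))}%"
    return f"{out}%"


def substance_share(total_count: int, grand_total: int, rule: str = "table1") -> str:
    """Formatted share of the grand total for one substance row."""
    if grand_total <= 0:
        raise ValueError("grand_total must be positive")
    return format_percent(total_count / grand_total, rule)


def newly_reported_series(
    first_years: Mapping[str, int], trend: TrendTable
) -> pd.DataFrame:
    """Per-year count of substances reported for the first time, and that
    count as a percent of the year's total reports.

    Conservation: the new-substance counts sum to the number of unique
    substances in ``first_years``. Years with zero total reports get NaN
    percent.
    """
    years = trend.years
    new_counts = pd.Series(0, index=pd.Index(years, name="year"), dtype=np.int64)
    for casrn, year in first_years.items():
        if year in new_counts.index:
            new_counts[year] += 1
    totals = trend.totals_by_year.astype(float).replace(0, np.nan)
    return pd.DataFrame(
        {
            "new_substances": new_counts,
            "pct_of_total_reports": 100.0 * new_counts / totals,
        }
    )
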