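"""Domain types for literature corpora of chemical citations.

The central object is a :class:`Corpus`: a sequence of citation records,
each carrying a publication year, a set of indexing roles (for example
ANST = analytical study, POL = pollutant, BIOL = biological study), and
the set of registry numbers (CASRNs) the record reports. The corpus
"total counts" denominator used throughout the trend and concentration
statistics is the sum over records of the number of CASRNs each reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "CitationRecord",
    "Corpus",
    "SubstanceProfile",
    "ChemicalList",
    "Inventory",
    "filter_by_roles",
]


def _norm_role(role: str) -> str:
    return role.strip().upper()


@dataclass(frozen=True)
class CitationRecord:
    """One literature record: an opaque id, a calendar year, its indexing
    roles, and the CASRNs it reports."""

    record_id: str
    year: int
    roles: frozenset[str]
    casrns: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", frozenset(_norm_role(r) for r in self.roles))
        object.__setattr__(self, "casrns", frozenset(self.casrns))


@dataclass
class Corpus:
    """An ordered collection of citation records with a year range.

    ``year_range`` defaults to the observed (min, max) record years.
    ``total_counts`` is the paper-style denominator: one count per
    (record, CASRN) pair.
    """

    records: list[CitationRecord]
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate record_id in corpus: {dup!r}")
        if self.year_range is None and self.records:
            years = [r.year for r in self.records]
            self.year_range = (min(years), max(years))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CitationRecord]:
        return iter(self.records)

    @property
    def total_counts(self) -> int:
        """Total CASRN citation counts: sum over records of |casrns|."""
        return sum(len(r.casrns) for r in self.records)

    @property
    def unique_casrns(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.casrns
        return out

    @property
    def years(self) -> list[int]:
        """Every calendar year in the corpus window, gap-free."""
        if self.year_range is None:
            return []
        lo, hi = self.year_range
        return list(range(lo, hi + 1))


@dataclass
class SubstanceProfile:
    """Per-CASRN aggregate over a corpus.

    ``first_year`` is the earliest year with a non-zero count;
    ``counts_by_year`` is complete (zero-filled) over the corpus window;
    ``total_count`` equals the sum of the yearly counts.
    """

    casrn: str
    first_year: int
    counts_by_year: dict[int, int]
    total_count: int
    names: list[str] = field(default_factory=list)
    identifiers: str | None = None  # SMILES/InChI pass-through, unvalidated
    class_label: str = "not characterized"
    tp_flag: bool = False
    excluded_by: str | None = None


@dataclass
class ChemicalList:
    """A named set of CASRNs with a class category tag and a precedence
    rank (lower rank = higher precedence when lists compete)."""

    name: str
    members: frozenset[str]
    category: str = ""
    precedence: int = 0

    def __contains__(self, casrn: str) -> bool:
        return casrn in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Inventory:
    """A jurisdictional chemical inventory.

    ``declared_size`` is the real-world inventory size; ``members`` may be
    a subset stand-in. Coverage percentages always use ``declared_size``.
    """

    name: str
    members: frozenset[str]
    declared_size: int

    def __post_init__(self) -> None:
        if len(self.members) > self.declared_size:
            raise ValueError(
                f"inventory {self.name!r}: |members|={len(self.members)} exceeds "
                f"declared_size={self.declared_size}"
            )


def filter_by_roles(
    corpus: Corpus,
    required: Iterable[str],
    mode: str = "all",
    *,
    warnings: list[str] | None = None,
) -> Corpus:
    """Retain records whose roles satisfy ``mode`` ("all" or "any") over
    ``required``. Matching is case-insensitive after trimming; an empty
    ``required`` set is the identity. Role codes absent from the corpus
    vocabulary produce a warning entry, never an error.
    """
    req = {_norm_role(r) for r in required}
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    if warnings is not None and req:
        vocab: set[str] = set()
        for r in corpus.records:
            vocab |= r.roles
        for code in sorted(req - vocab):
            warnings.append(f"role code {code!r} not present in corpus vocabulary")
    if not req:
        return Corpus(list(corpus.records), corpus.year_range)
    if mode == "all":
        kept = [r for r in corpus.records if req <= r.roles]
    else:
        kept = [r for r in corpus.records if req & r.roles]
    return Corpus(kept, corpus.year_range)
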