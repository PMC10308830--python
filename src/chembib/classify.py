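"""Single-label classification of substances by precedence-ordered lists.

Each substance is matched against an ordered collection of class lists
(pharmaceuticals, current-use pesticides, PCBs, PBDEs, PFAS, ...); the
highest-precedence list containing it supplies its label. A substance on
no named list but on the broad suspect-screening list of chemicals of
emerging concern (a SUSDAT-like list) is labeled "CEC-only"; everything
else falls through to "not characterized". Transformation products (TPs)
— degradation products of a parent chemical — are generally absent from
the public lists and are mapped to their parent's class through an
explicit parent→TP table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .corpus import ChemicalList, SubstanceProfile

__all__ = [
    "CEC_ONLY",
    "NOT_CHARACTERIZED",
    "ClassTaxonomy",
    "ClassificationSummary",
    "assign_classes",
    "annotate_transformation_products",
    "dedupe_lists",
]

CEC_ONLY = "CEC-only"
NOT_CHARACTERIZED = "not characterized"


@dataclass
class ClassTaxonomy:
    """Precedence-ordered named class lists plus an optional CEC list
    ranked below all of them."""

    lists: list[ChemicalList]
    cec_list: ChemicalList | None = None
    fallback_label: str = NOT_CHARACTERIZED

    def __post_init__(self) -> None:
        ranks = [cl.precedence for cl in self.lists]
        if len(ranks) != len(set(ranks)):
            raise ValueError("precedence ranks must be strictly ordered (unique)")
        self.lists = sorted(self.lists, key=lambda cl: cl.precedence)

    @property
    def labels(self) -> list[str]:
        return [cl.category or cl.name for cl in self.lists]

    def label_of(self, casrn: str) -> str:
        for cl in self.lists:
            if casrn in cl.members:
                return cl.category or cl.name
        if self.cec_list is not None and casrn in self.cec_list.members:
            return CEC_ONLY
        return self.fallback_label


@dataclass
class ClassificationSummary:
    """Counts per class label; the labels partition the classified set."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def known_count(self) -> int:
        """Substances on any named class list (incl. TP annotations)."""
        return sum(
            n for label, n in self.counts.items() if label not in (CEC_ONLY, NOT_CHARACTERIZED)
        )

    @property
    def cec_only_count(self) -> int:
        return self.counts.get(CEC_ONLY, 0)

    @property
    def uncharacterized_count(self) -> int:
        return self.counts.get(NOT_CHARACTERIZED, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def assign_classes(
    profiles: dict[str, SubstanceProfile],
    taxonomy: ClassTaxonomy,
) -> ClassificationSummary:
    """Label every profile in place and return the summary.

    Every substance gets exactly one label (partition property); the
    summary counts sum to the number of profiles. Invariant to the input
    ordering of profiles.
    """
    if not taxonomy.lists and taxonomy.cec_list is None:
        raise ValueError("taxonomy is empty")
    tally: Counter[str] = Counter()
    for casrn, profile in profiles.items():
        label = taxonomy.label_of(casrn)
        profile.class_label = label
        tally[label] += 1
    return ClassificationSummary(counts=dict(tally))


def annotate_transformation_products(
    profiles: dict[str, SubstanceProfile],
    tp_map: Iterable[tuple[str, str, str]],
    taxonomy: ClassTaxonomy,
    *,
    warnings: list[str] | None = None,
) -> int:
    """Apply a (parent CASRN, TP CASRN, class) table.

    A TP inherits the mapped class unless a named list of higher
    precedence already classified it; annotated profiles get their TP
    flag set. Rows naming a class absent from the taxonomy are skipped
    with a warning. Returns the number of profiles annotated.
    """
    known_labels = set(taxonomy.labels)
    named_rank = {
        cl.category or cl.name: cl.precedence for cl in taxonomy.lists
    }
    annotated = 0
    for parent, tp, cls in tp_map:
        if cls not in known_labels:
            if warnings is not None:
                warnings.append(
                    f"tp_map: class {cls!r} (parent {parent}) not in taxonomy; row skipped"
                )
            continue
        profile = profiles.get(tp)
        if profile is None:
            continue
        current = profile.class_label
        if current in named_rank and named_rank[current] <= named_rank[cls]:
            continue  # an equal- or higher-precedence list already claimed it
        profile.class_label = cls
        profile.tp_flag = True
        annotated += 1
    return annotated


def dedupe_lists(taxonomy: ClassTaxonomy) -> tuple[ClassTaxonomy, list[tuple[str, str, str]]]:
    """Resolve cross-list duplicates to the highest-precedence list.

    Returns a taxonomy in which every CASRN appears in at most one named
    list, plus a collision report of (casrn, removed_from, kept_in).
    """
    claimed: dict[str, str] = {}
    collisions: list[tuple[str, str, str]] = []
    new_lists: list[ChemicalList] = []
    for cl in sorted(taxonomy.lists, key=lambda c: c.precedence):
        label = cl.category or cl.name
        keep: set[str] = set()
        for casrn in sorted(cl.members):
            owner = claimed.get(casrn)
            if owner is None:
                claimed[casrn] = label
                keep.add(casrn)
            else:
                collisions.append((casrn, label, owner))
        new_lists.append(
            ChemicalList(cl.name, frozenset(keep), cl.category, cl.precedence)
        )
    return (
        ClassTaxonomy(new_lists, taxonomy.cec_list, taxonomy.fallback_label),
        collisions,
    )
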