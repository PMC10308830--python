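"""Overlap of the analysis list with industrial chemical inventories.

Compares the screened substance list against jurisdictional inventories
(TSCA-like, REACH-like, IECSC-like) as a three-set membership analysis
restricted to the reference universe, mirroring the upper row of a Venn
diagram. Coverage percentages use each inventory's declared real size,
so fixture inventories can be small subsets.

Because inventories generally omit pesticides and pharmaceuticals (those
classes sit under separate regulatory legislation), the reference list is
first reduced by dropping those classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .corpus import Inventory, SubstanceProfile
from .trends import format_percent

__all__ = [
    "VennResult",
    "reduce_for_overlap",
    "venn3",
    "inventory_coverage",
]

#: matplotlib-venn style region order for (A, B, C): bits are membership
#: flags in the order A, B, C.
REGION_ORDER = ("100", "010", "110", "001", "101", "011", "111")


@dataclass
class VennResult:
    """Region counts over the 7 non-empty membership patterns of three
    sets, computed within a reference universe."""

    set_names: tuple[str, str, str]
    region_counts: dict[str, int]  # keyed by bit pattern, e.g. "101"
    union_count: int

    def __post_init__(self) -> None:
        if sum(self.region_counts.values()) != self.union_count:
            raise AssertionError("venn region counts do not sum to the union")

    def per_set_overlap(self, name: str) -> int:
        """Total overlap of one set with the reference: the sum of all
        regions containing that set."""
        i = self.set_names.index(name)
        return sum(n for bits, n in self.region_counts.items() if bits[i] == "1")

    def pattern_labels(self) -> dict[str, str]:
        """Human-readable region labels like "A&!B&C"."""
        a, b, c = self.set_names
        out = {}
        for bits in REGION_ORDER:
            parts = [
                (name if flag == "1" else f"!{name}")
                for name, flag in zip((a, b, c), bits)
            ]
            out[bits] = "&".join(parts)
        return out

    def as_counts_tuple(self) -> tuple[int, ...]:
        """The 7 counts in matplotlib-venn subset order."""
        return tuple(self.region_counts[b] for b in REGION_ORDER)


def reduce_for_overlap(
    profiles: Mapping[str, SubstanceProfile],
    excluded_classes: Iterable[str],
    *,
    warnings: list[str] | None = None,
) -> set[str]:
    """Drop substances whose class label is in ``excluded_classes`` and
    return the remaining CASRN set. Never grows the input; idempotent.
    Unknown labels warn rather than fail."""
    excluded = set(excluded_classes)
    present = {p.class_label for p in profiles.values()}
    if warnings is not None:
        for label in sorted(excluded - present):
            warnings.append(f"excluded class {label!r} matches no substance")
    return {c for c, p in profiles.items() if p.class_label not in excluded}


def venn3(
    reference: set[str],
    inv_a: Inventory,
    inv_b: Inventory,
    inv_c: Inventory,
) -> VennResult:
    """Three-set region counts of the inventories restricted to the
    reference list: each element of reference ∩ (A∪B∪C) is assigned to
    exactly one of the 7 membership patterns."""
    counts = {bits: 0 for bits in REGION_ORDER}
    sets = (inv_a.members, inv_b.members, inv_c.members)
    union = 0
    for casrn in reference:
        bits = "".join("1" if casrn in s else "0" for s in sets)
        if bits != "000":
            counts[bits] += 1
            union += 1
    return VennResult(
        set_names=(inv_a.name, inv_b.name, inv_c.name),
        region_counts=counts,
        union_count=union,
    )


def inventory_coverage(
    overlap_count: int, inventory: Inventory, rule: str = "table1"
) -> str:
    """Overlap as a formatted percentage of the inventory's declared
    size (the real inventory size, not the fixture member count)."""
    if inventory.declared_size <= 0:
        raise ValueError(f"inventory {inventory.name!r} has zero declared size")
    return format_percent(overlap_count / inventory.declared_size, rule)
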