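"""Readers and writers for corpora, class lists, and inventories.

File contracts
--------------
Corpus: delimited text (TSV by default) with a header naming the columns
``record_id``, ``year``, ``roles``, ``casrns``; the ``roles`` and
``casrns`` cells are themselves delimited lists (``;`` by default). Class
lists and inventories: TSV with columns ``casrn`` and optional ``name`` /
``category``, or a flat newline-delimited CASRN file; an inventory's real
size may be declared in a ``#declared_size=N`` header comment. All output
is UTF-8 with LF line endings.

Invalid CASRN tokens are never fatal: they are dropped and tallied in the
ingest report, split by failure reason (malformed pattern vs checksum
mismatch). A duplicated record id is a hard error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

from .casrn import validate_casrn
from .corpus import ChemicalList, CitationRecord, Corpus, Inventory

__all__ = [
    "Dialect",
    "IngestReport",
    "read_corpus",
    "write_corpus",
    "read_chemical_list",
    "read_inventory",
    "write_chemical_list",
]

REQUIRED_COLUMNS = ("record_id", "year", "roles", "casrns")


@dataclass(frozen=True)
class Dialect:
    """Corpus file dialect: the column delimiter, the within-cell
    delimiter for role/CASRN lists, and the admissible year window."""

    delimiter: str = "\t"
    cell_delimiter: str = ";"
    year_window: tuple[int, int] = (1900, 2100)


@dataclass
class IngestReport:
    """Exact tally of what a reader kept and dropped."""

    rows_read: int = 0
    records_kept: int = 0
    rows_rejected_year: int = 0
    rows_rejected_empty: int = 0
    invalid_casrns: Counter = field(default_factory=Counter)
    duplicates_collapsed: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def invalid_casrn_total(self) -> int:
        return sum(self.invalid_casrns.values())


def _open(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_corpus(
    source: str | Path | IO[str], dialect: Dialect = Dialect()
) -> tuple[Corpus, IngestReport]:
    """Parse a delimited corpus file into a :class:`Corpus`.

    Every retained CASRN is canonical; record order is preserved. Rows
    with an unparseable or out-of-window year, or with no valid CASRN
    left after validation, are rejected and tallied. A missing required
    column or a duplicated ``record_id`` raises ``ValueError``.
    """
    fh, should_close = _open(source)
    report = IngestReport()
    records: list[CitationRecord] = []
    seen_ids: set[str] = set()
    try:
        header_line = fh.readline()
        if not header_line:
            raise ValueError("empty corpus file: no header")
        header = [h.strip() for h in header_line.rstrip("\r\n").split(dialect.delimiter)]
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in REQUIRED_COLUMNS if c not in col]
        if missing:
            raise ValueError(f"corpus file missing required column(s): {', '.join(missing)}")
        lo, hi = dialect.year_window
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            report.rows_read += 1
            cells = line.split(dialect.delimiter)
            record_id = cells[col["record_id"]].strip()
            if record_id in seen_ids:
                raise ValueError(f"duplicate record_id: {record_id!r}")
            try:
                year = int(cells[col["year"]].strip())
            except ValueError:
                report.rows_rejected_year += 1
                continue
            if not lo <= year <= hi:
                report.rows_rejected_year += 1
                continue
            roles = frozenset(
                t.strip() for t in cells[col["roles"]].split(dialect.cell_delimiter) if t.strip()
            )
            casrns: set[str] = set()
            for token in cells[col["casrns"]].split(dialect.cell_delimiter):
                token = token.strip()
                if not token:
                    continue
                v = validate_casrn(token)
                if v.ok:
                    casrns.add(v.casrn)  # type: ignore[arg-type]
                else:
                    report.invalid_casrns[v.reason] += 1
            if not casrns:
                report.rows_rejected_empty += 1
                continue
            seen_ids.add(record_id)
            records.append(CitationRecord(record_id, year, roles, frozenset(casrns)))
            report.records_kept += 1
    finally:
        if should_close:
            fh.close()
    return Corpus(records), report


def write_corpus(
    corpus: Corpus, target: str | Path | IO[str], dialect: Dialect = Dialect()
) -> None:
    """Serialize a corpus; ``read_corpus(write_corpus(c)) == c`` for
    canonical corpora. Role and CASRN cells are sorted for determinism."""
    fh: IO[str]
    if isinstance(target, (str, Path)):
        fh = open(target, "w", encoding="utf-8", newline="\n")
        should_close = True
    else:
        fh, should_close = target, False
    d, cd = dialect.delimiter, dialect.cell_delimiter
    try:
        fh.write(d.join(REQUIRED_COLUMNS) + "\n")
        for r in corpus.records:
            fh.write(
                d.join(
                    (
                        r.record_id,
                        str(r.year),
                        cd.join(sorted(r.roles)),
                        cd.join(sorted(r.casrns)),
                    )
                )
                + "\n"
            )
    finally:
        if should_close:
            fh.close()


def _read_member_table(
    source: str | Path | IO[str],
) -> tuple[list[tuple[str, str, str]], dict[str, str], IngestReport]:
    """Shared parser for list/inventory files.

    Returns (rows of (casrn, name, category), header comments, report).
    Header comments are ``#key=value`` lines before the data.
    """
    fh, should_close = _open(source)
    report = IngestReport()
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    try:
        header_cols: dict[str, int] | None = None
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = [c.strip() for c in line.split("\t")]
            if header_cols is None and cells[0].lower() == "casrn":
                header_cols = {name.lower(): i for i, name in enumerate(cells)}
                continue
            report.rows_read += 1
            idx = header_cols or {"casrn": 0, "name": 1, "category": 2}
            token = cells[idx["casrn"]] if idx["casrn"] < len(cells) else ""
            v = validate_casrn(token)
            if not v.ok:
                report.invalid_casrns[v.reason] += 1
                continue
            assert v.casrn is not None
            if v.casrn in seen:
                report.duplicates_collapsed += 1
                continue
            seen.add(v.casrn)

            def cell(name: str) -> str:
                i = idx.get(name)
                return cells[i] if i is not None and i < len(cells) else ""

            rows.append((v.casrn, cell("name"), cell("category")))
            report.records_kept += 1
    finally:
        if should_close:
            fh.close()
    if report.rows_read == 0:
        raise ValueError("empty list file: no data rows")
    return rows, meta, report


def read_chemical_list(
    source: str | Path | IO[str],
    name: str | None = None,
    category: str = "",
    precedence: int = 0,
) -> tuple[ChemicalList, IngestReport]:
    """Read a class list. Invalid CASRNs are tallied and dropped;
    duplicate members collapse. An empty file is an error."""
    rows, meta, report = _read_member_table(source)
    list_name = name or meta.get("name") or (
        Path(source).stem if isinstance(source, (str, Path)) else "list"
    )
    cat = category or meta.get("category", "") or next(
        (c for _, _, c in rows if c), ""
    )
    members = frozenset(c for c, _, _ in rows)
    return ChemicalList(list_name, members, cat, precedence), report


def read_inventory(
    source: str | Path | IO[str],
    name: str | None = None,
    declared_size: int | None = None,
) -> tuple[Inventory, IngestReport]:
    """Read an inventory. ``declared_size`` comes from the argument or a
    ``#declared_size=N`` header; it defaults to the member count. A
    declared size below the member count violates the inventory invariant
    and raises ``ValueError``."""
    rows, meta, report = _read_member_table(source)
    inv_name = name or meta.get("name") or (
        Path(source).stem if isinstance(source, (str, Path)) else "inventory"
    )
    members = frozenset(c for c, _, _ in rows)
    if declared_size is None:
        declared_size = int(meta["declared_size"]) if "declared_size" in meta else len(members)
    return Inventory(inv_name, members, declared_size), report


def write_chemical_list(clist: ChemicalList, target: str | Path) -> None:
    with open(target, "w", encoding="utf-8", newline="\n") as fh:
        if clist.category:
            fh.write(f"#category={clist.category}\n")
        fh.write("casrn\n")
        for c in sorted(clist.members):
            fh.write(c + "\n")
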