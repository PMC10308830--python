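"""End-to-end orchestration: corpus → screen → classify → trends → overlap.

`run_pipeline` wires the stages together from a declarative
:class:`RunConfig` and writes one TSV per exhibit (screening report,
classification summary, trend table, concentration table, venn table)
plus a run log. Outputs are deterministic given identical inputs; every
table carries a content digest of the inputs in a header comment so a
reader can tell which inputs produced it.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .classify import ClassTaxonomy, assign_classes, annotate_transformation_products
from .corpus import ChemicalList, Corpus, Inventory, SubstanceProfile, filter_by_roles
from .io import Dialect, read_chemical_list, read_corpus, read_inventory
from .overlap import VennResult, inventory_coverage, reduce_for_overlap, venn3
from .screen import ExclusionRuleSet, apply_exclusions, build_profiles, dedup_earliest
from .trends import (
    ConcentrationCurve,
    annual_class_counts,
    format_percent,
    newly_reported_series,
    substance_share,
    top_n_share,
)

logger = logging.getLogger("chembib")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_table1", "load_taxonomy", "load_exclusions"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    corpus: Path
    taxonomy: Path | None = None
    exclusions: Path | None = None  # combined TSV: casrn <tab> category
    whitelist: Path | None = None
    inventories: list[Path] = field(default_factory=list)
    tp_map: Path | None = None
    roles: list[str] = field(default_factory=list)
    role_mode: str = "all"
    year_window: tuple[int, int] = (1900, 2100)
    percent_rule: str = "table1"
    top_n: list[int] = field(default_factory=lambda: [10, 100, 200, 300, 500])
    exclude_classes: list[str] = field(
        default_factory=lambda: ["pharmaceutical", "current-use pesticide"]
    )
    out_dir: Path = Path("chembib_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        for key in (
            "corpus", "taxonomy", "exclusions", "whitelist", "tp_map", "out_dir",
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        for key in ("roles", "top_n", "exclude_classes"):
            if key in raw:
                kwargs[key] = list(raw[key])
        if "inventories" in raw:
            kwargs["inventories"] = [Path(p) for p in raw["inventories"]]
        for key in ("role_mode", "percent_rule"):
            if key in raw:
                kwargs[key] = raw[key]
        if "year_window" in raw:
            kwargs["year_window"] = tuple(raw["year_window"])
        return cls(**kwargs)


def _digest(paths: Sequence[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(set(map(Path, paths))):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, digest: str, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# input_digest={digest}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def load_taxonomy(path: str | Path) -> ClassTaxonomy:
    """Taxonomy config: YAML with ``classes`` (ordered label/path/
    precedence entries) and an optional ``cec`` entry."""
    base = Path(path).parent
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    lists = []
    for i, entry in enumerate(raw.get("classes", [])):
        clist, _ = read_chemical_list(
            base / entry["path"],
            name=entry.get("label"),
            category=entry.get("label", ""),
            precedence=int(entry.get("precedence", i)),
        )
        lists.append(clist)
    cec = None
    if raw.get("cec"):
        cec, _ = read_chemical_list(
            base / raw["cec"]["path"], name=raw["cec"].get("label", "CEC screening list")
        )
    return ClassTaxonomy(lists, cec_list=cec)


def load_exclusions(
    path: str | Path, whitelist_path: str | Path | None = None
) -> ExclusionRuleSet:
    """Combined exclusion TSV (columns ``casrn``, ``category``; category
    precedence = first-appearance order) plus an optional flat whitelist."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"casrn", "category"} <= set(df.columns):
        raise ValueError("exclusions file needs 'casrn' and 'category' columns")
    ordered: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        ordered.setdefault(row["category"], set()).add(row["casrn"])
    whitelist: frozenset[str] = frozenset()
    if whitelist_path is not None:
        wl, _ = read_chemical_list(whitelist_path, name="whitelist")
        whitelist = wl.members
    return ExclusionRuleSet(
        categories=[(k, frozenset(v)) for k, v in ordered.items()], whitelist=whitelist
    )


def _load_tp_map(path: Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"parent_casrn", "tp_casrn", "class"}
    if not need <= set(df.columns):
        raise ValueError("tp_map needs columns parent_casrn, tp_casrn, class")
    return [tuple(r) for r in df[["parent_casrn", "tp_casrn", "class"]].itertuples(index=False)]


@dataclass
class ReportBundle:
    corpus: Corpus
    profiles: dict[str, SubstanceProfile]
    screening: pd.DataFrame | None
    summary: pd.DataFrame | None
    trend: pd.DataFrame
    concentration: pd.DataFrame
    venn: pd.DataFrame | None
    out_dir: Path


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage the config enables; any stage error aborts with
    the stage name and cause."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = [config.corpus] + [p for p in (
        config.taxonomy, config.exclusions, config.whitelist, config.tp_map
    ) if p] + list(config.inventories)
    digest = _digest([p for p in inputs if Path(p).exists()])
    log_lines: list[str] = []

    def stage(name: str):
        t0 = time.perf_counter()
        logger.info("stage %s", name)

        def done():
            log_lines.append(f"{name}\t{time.perf_counter() - t0:.3f}s")

        return done

    try:
        name = "ingest"
        done = stage(name)
        corpus, report = read_corpus(config.corpus, Dialect(year_window=config.year_window))
        if config.roles:
            corpus = filter_by_roles(corpus, config.roles, config.role_mode)
        log_lines.append(
            f"ingest\trows={report.rows_read} kept={report.records_kept} "
            f"invalid_casrns={report.invalid_casrn_total}"
        )
        done()

        name = "dedup"
        done = stage(name)
        first_years, _ = dedup_earliest(corpus)
        profiles = build_profiles(corpus)
        done()

        screening_df = None
        name = "screen"
        if config.exclusions is not None:
            done = stage(name)
            ruleset = load_exclusions(config.exclusions, config.whitelist)
            profiles, screport = apply_exclusions(profiles, ruleset)
            screening_df = pd.DataFrame(
                [("input", screport.input_count)]
                + sorted(screport.removed_by_category.items())
                + [("removed_total", screport.removed_total), ("kept", screport.kept_count)],
                columns=["category", "count"],
            )
            _write_table(screening_df, out / "screening_report.tsv", digest)
            done()

        summary_df = None
        taxonomy = None
        name = "classification"
        if config.taxonomy is not None:
            done = stage(name)
            if not Path(config.taxonomy).exists():
                raise FileNotFoundError(f"taxonomy path not found: {config.taxonomy}")
            taxonomy = load_taxonomy(config.taxonomy)
            summary = assign_classes(profiles, taxonomy)
            if config.tp_map is not None:
                annotate_transformation_products(profiles, _load_tp_map(config.tp_map), taxonomy)
                summary = assign_classes(profiles, taxonomy)  # recount after TP moves
            summary_df = pd.DataFrame(
                sorted(summary.counts.items()), columns=["class", "count"]
            )
            _write_table(summary_df, out / "classification_summary.tsv", digest)
            done()

        name = "trends"
        done = stage(name)
        trend = annual_class_counts(corpus, profiles)
        trend_long = trend.to_long()
        _write_table(trend_long, out / "trend_table.tsv", digest)
        newly = newly_reported_series(
            {c: y for c, y in first_years.items() if c in profiles}, trend
        )
        _write_table(newly, out / "newly_reported.tsv", digest, index=True)
        done()

        name = "concentration"
        done = stage(name)
        curve = ConcentrationCurve.from_profiles(profiles)
        conc = curve.to_frame()
        _write_table(conc, out / "concentration.tsv", digest)
        done()

        venn_df = None
        name = "overlap"
        if len(config.inventories) == 3:
            done = stage(name)
            invs = [read_inventory(p)[0] for p in config.inventories]
            reference = reduce_for_overlap(profiles, config.exclude_classes)
            result = venn3(reference, *invs)
            labels = result.pattern_labels()
            rows = [(labels[b], b, n) for b, n in result.region_counts.items()]
            rows.append(("union", "any", result.union_count))
            for inv in invs:
                rows.append(
                    (
                        f"coverage:{inv.name}",
                        inventory_coverage(result.per_set_overlap(inv.name), inv, config.percent_rule),
                        result.per_set_overlap(inv.name),
                    )
                )
            venn_df = pd.DataFrame(rows, columns=["pattern", "bits_or_pct", "count"])
            _write_table(venn_df, out / "venn.tsv", digest)
            done()

        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        return ReportBundle(corpus, profiles, screening_df, summary_df, trend_long, conc, venn_df, out)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise PipelineError(name, exc) from exc


def make_table1(
    profiles: Mapping[str, SubstanceProfile],
    n_values: Sequence[int],
    substances_of_interest: Sequence[str] = (),
    rule: str = "table1",
    *,
    warnings: list[str] | None = None,
) -> pd.DataFrame:
    """Summary table: a row per top-N cut and per named substance, with
    total counts and formatted shares of the grand total. An unknown
    substance of interest gets a zero-count row and a warning."""
    curve = ConcentrationCurve.from_profiles(profiles)
    grand = curve.grand_total
    rows: list[tuple[str, int, str]] = []
    rows.append(("all substances", grand, ""))
    for n in n_values:
        n_eff = min(n, len(curve))
        csum = int(curve.sorted_totals[:n_eff].sum())
        rows.append((f"top {n}", csum, format_percent(top_n_share(curve, n_eff), rule)))
    for casrn in substances_of_interest:
        p = profiles.get(casrn)
        if p is None:
            if warnings is not None:
                warnings.append(f"substance of interest {casrn!r} not in profiles")
            rows.append((casrn, 0, format_percent(0.0, rule)))
        else:
            rows.append((casrn, p.total_count, substance_share(p.total_count, grand, rule)))
    return pd.DataFrame(rows, columns=["row", "total_count", "pct_of_total"])
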