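"""End-to-end pipeline orchestration and summary tables.

``run_pipeline`` sequences the stages — CNV filtering, family exclusion,
event detection with QC, the count and burden tests, the deleteriousness
filters and the sensitivity re-analyses — and writes the report bundle:
events, carrier summary, annotation and per-gene filter tables, a
statistics table, and a run log.  All outputs are TSV with header rows and
are byte-deterministic for a fixed input set.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .burden_stats import (
    aggregate_cadd,
    bonferroni_threshold,
    is_significant,
    logistic_burden_test,
    pooled_count_test,
)
from .compound_het import (
    DEFAULT_FUZZY_BORDER,
    QcThresholds,
    call_quality_filter,
    carrier_summary,
    detect_events_cohort,
    transmitting_parent_id,
)
from .deleterious_filters import (
    DEFAULT_CADD_THRESHOLD,
    sensitivity_reanalysis,
    union_filter,
)
from .family_prioritization import exclude_families, filter_cnv_calls
from .io_formats import (
    read_cadd_table,
    read_cnv_table,
    read_gene_table,
    read_pedigree,
    read_vcf,
)
from .models import CONSEQUENCE_CATEGORIES, OTHER_CATEGORY, CompoundHetEvent

logger = logging.getLogger(__name__)


def annotation_summary(events: Sequence[CompoundHetEvent]) -> pd.DataFrame:
    """Tally countable events by consequence category and carrier group.

    Returns the nine-category table (plus an ``other`` row when present)
    with a ``total`` row equal to the column sums.
    """
    counts: Dict[str, Dict[str, int]] = {
        cat: {"proband": 0, "parent": 0} for cat in CONSEQUENCE_CATEGORIES
    }
    other = {"proband": 0, "parent": 0}
    for ev in events:
        if not ev.countable:
            continue
        target = counts.get(ev.variant.category, other)
        target[ev.carrier] += 1
    rows = {cat: counts[cat] for cat in CONSEQUENCE_CATEGORIES}
    if any(other.values()):
        rows[OTHER_CATEGORY] = other
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("category")
    df.loc["total"] = df.sum()
    return df


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``total`` row (column sums) to a category x group table."""
    out = table.copy()
    out.loc["total"] = out.sum()
    return out


@dataclass
class RunConfig:
    """Source of truth for one pipeline run (loadable from YAML)."""

    ped_path: str
    cnv_path: str
    vcf_path: str
    genes_path: str
    cadd_path: str
    out_dir: str
    qc: QcThresholds = field(default_factory=QcThresholds)
    fuzzy_border: int = DEFAULT_FUZZY_BORDER
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD
    min_algorithms: int = 2
    max_freq: float = 0.10
    min_length: int = 5000
    alpha: float = 0.05
    n_tests: int = 3
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("ped_path", "cnv_path", "vcf_path", "genes_path", "cadd_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such file: {path}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc = QcThresholds(**raw.pop("qc", {}))
    return RunConfig(qc=qc, **raw)


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


@dataclass
class ReportBundle:
    events: List[CompoundHetEvent]
    carrier: object
    annotation: pd.DataFrame
    per_gene_filters: pd.DataFrame
    statistics: pd.DataFrame
    output_paths: Dict[str, Path]


_EVENT_COLUMNS = (
    "family_id",
    "carrier",
    "sample_id",
    "gene_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "scenario",
    "countable",
    "category",
    "scaled_cadd",
    "in_segdup",
)


def events_to_frame(events: Sequence[CompoundHetEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        v = ev.variant
        rows.append(
            {
                "family_id": ev.family_id,
                "carrier": ev.carrier,
                "sample_id": v.sample_id,
                "gene_id": ev.gene.gene_id,
                "gene": ev.gene.name,
                "chrom": v.chrom,
                "pos": v.pos + 1,  # external 1-based
                "ref": v.ref,
                "alt": v.alt,
                "scenario": ev.scenario,
                "countable": int(ev.countable),
                "category": v.category,
                "scaled_cadd": v.scaled_cadd if v.scaled_cadd is not None else "",
                "in_segdup": int(v.in_segdup),
            }
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Stage order: read inputs -> CNV filter -> family exclusion -> event
    detection (with call QC) -> count test -> CADD burden tests ->
    deleteriousness filters -> sensitivity re-analyses -> report tables.
    Any stage failure aborts with a stage-named diagnostic and removes the
    partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out_dir / "events.tsv",
        "carrier_summary": out_dir / "carrier_summary.tsv",
        "annotation_table": out_dir / "annotation_table.tsv",
        "filter_table": out_dir / "filter_table.tsv",
        "statistics": out_dir / "statistics.tsv",
        "run_log": out_dir / "run.log",
        "resolved_config": out_dir / "resolved_config.yaml",
    }
    log_lines: List[str] = [f"comphet {__version__}"]
    stage = "setup"
    try:
        stage = "read_inputs"
        config.validate_paths()
        pedigrees = read_pedigree(config.ped_path)
        cnv_calls = read_cnv_table(config.cnv_path)
        genes = read_gene_table(config.genes_path)
        variants = read_vcf(config.vcf_path)
        cadd = read_cadd_table(config.cadd_path)
        log_lines.append(
            f"read_inputs: {len(pedigrees)} families, {len(cnv_calls)} CNV calls, "
            f"{len(genes)} genes, {len(variants)} variant calls, "
            f"{len(cadd)} CADD scores"
        )

        stage = "attach_cadd"
        variants = [
            dataclasses.replace(v, scaled_cadd=cadd.get(v.site_key))
            if v.scaled_cadd is None
            else v
            for v in variants
        ]

        stage = "filter_cnv_calls"
        filtered = filter_cnv_calls(
            cnv_calls, config.min_algorithms, config.max_freq, config.min_length
        )
        log_lines.append(f"filter_cnv_calls: {len(cnv_calls)} in, {len(filtered)} out")

        stage = "exclude_families"
        retained, exclusions = exclude_families(pedigrees, filtered)
        log_lines.append(
            f"exclude_families: {len(pedigrees)} in, {len(retained)} retained, "
            f"{len(exclusions)} excluded"
        )

        stage = "call_quality_filter"
        qc_pass = [v for v in variants if call_quality_filter(v, config.qc)[0]]
        log_lines.append(f"call_quality_filter: {len(variants)} in, {len(qc_pass)} out")

        stage = "detect_events"
        events = detect_events_cohort(
            retained, filtered, genes, qc_pass, config.qc, config.fuzzy_border
        )
        n_countable = sum(1 for ev in events if ev.countable)
        log_lines.append(
            f"detect_events: {len(events)} events, {n_countable} countable (scenario 1)"
        )

        stage = "carrier_summary"
        n_parents = sum(len(p.parent_ids) for p in retained)
        summary = carrier_summary(
            events,
            proband_denominator=len(retained),
            parent_denominator=n_parents,
        )

        stage = "statistics"
        stats_rows = []
        threshold = bonferroni_threshold(config.alpha, config.n_tests)

        def add_pooled(name: str, res) -> None:
            stats_rows.append(
                {
                    "analysis": name,
                    "statistic": "chi_square",
                    "value": round(res.chi_square, 6),
                    "df": res.df,
                    "n_proband": res.n_proband,
                    "n_parent": res.n_parent,
                    "p_value": f"{res.p_value:.6g}",
                    "significant": int(is_significant(res.p_value, config.alpha, config.n_tests)),
                }
            )

        if summary.n_proband_variants + summary.n_parent_variants > 0:
            add_pooled(
                "pooled_count",
                pooled_count_test(summary.n_proband_variants, summary.n_parent_variants),
            )

        transmitting: List[Tuple[str, str]] = []
        for ped in retained:
            transmitting.append((ped.proband_id, "proband"))
            for deletion in (
                c
                for c in filtered
                if c.sample_id == ped.proband_id
                and c.cnv_type == "del"
                and c.inheritance in ("maternal", "paternal")
            ):
                pid = transmitting_parent_id(ped, deletion)
                if pid is not None and (pid, "parent") not in transmitting:
                    transmitting.append((pid, "parent"))

        for mode, individuals in (
            ("carriers", None),
            ("full", transmitting),
        ):
            sums = aggregate_cadd(
                events, cadd, all_individuals=individuals, missing_score_policy="skip"
            )
            labels = [group for (_, group) in sums]
            if len(set(labels)) == 2:
                burden = logistic_burden_test(list(sums.values()), labels)
                stats_rows.append(
                    {
                        "analysis": f"cadd_burden_{mode}",
                        "statistic": "beta",
                        "value": round(burden.beta, 6) if burden.converged else "",
                        "df": "",
                        "n_proband": sum(1 for l in labels if l == "proband"),
                        "n_parent": sum(1 for l in labels if l == "parent"),
                        "p_value": f"{burden.p_value:.6g}" if burden.converged else "",
                        "significant": (
                            int(is_significant(burden.p_value, config.alpha, config.n_tests))
                            if burden.converged
                            else ""
                        ),
                    }
                )

        stage = "deleterious_filters"
        outcome = union_filter(events, config.cadd_threshold)
        union_p = outcome.group_tallies["proband"]["union"]
        union_t = outcome.group_tallies["parent"]["union"]
        if union_p + union_t > 0:
            add_pooled("union_filtered", pooled_count_test(union_p, union_t))

        stage = "sensitivity"
        for mode in ("exclude_synonymous", "exclude_segdup"):
            try:
                add_pooled(f"sensitivity_{mode}", sensitivity_reanalysis(events, mode))
            except ValueError:
                log_lines.append(f"sensitivity_{mode}: no events left; skipped")

        log_lines.append(f"bonferroni_threshold: {threshold:.6g}")

        stage = "write_outputs"
        events_to_frame(events).to_csv(paths["events"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "group": "proband",
                    "n_carriers": summary.n_proband_carriers,
                    "n_variants": summary.n_proband_variants,
                    "denominator": summary.proband_denominator,
                    "carrier_pct": (
                        f"{summary.proband_carrier_pct:.1f}"
                        if summary.proband_carrier_pct is not None
                        else ""
                    ),
                },
                {
                    "group": "parent",
                    "n_carriers": summary.n_parent_carriers,
                    "n_variants": summary.n_parent_variants,
                    "denominator": summary.parent_denominator,
                    "carrier_pct": (
                        f"{summary.parent_carrier_pct:.1f}"
                        if summary.parent_carrier_pct is not None
                        else ""
                    ),
                },
            ]
        ).to_csv(paths["carrier_summary"], sep="\t", index=False)
        annotation = annotation_summary(events)
        annotation.to_csv(paths["annotation_table"], sep="\t")
        outcome.per_gene.to_csv(paths["filter_table"], sep="\t", index=False)
        statistics = pd.DataFrame(
            stats_rows,
            columns=[
                "analysis",
                "statistic",
                "value",
                "df",
                "n_proband",
                "n_parent",
                "p_value",
                "significant",
            ],
        )
        statistics.to_csv(paths["statistics"], sep="\t", index=False)
        with open(paths["resolved_config"], "w") as fh:
            resolved = dataclasses.asdict(config)
            yaml.safe_dump(resolved, fh, sort_keys=True)
        with open(paths["run_log"], "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        for path in paths.values():
            if path.exists():
                path.unlink()
        raise PipelineError(f"stage {stage}: {exc}") from exc

    return ReportBundle(
        events=events,
        carrier=summary,
        annotation=annotation,
        per_gene_filters=outcome.per_gene,
        statistics=statistics,
        output_paths=paths,
    )
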