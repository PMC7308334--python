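"""Deleteriousness filters and sensitivity re-analyses.

Two per-variant filters select the putatively most deleterious variants:

* CADD-10: scaled CADD score >= 10, i.e. the top 10% of all possible
  genome variants under the scaled score's rank construction (inclusive at
  10; threshold configurable).
* Protein-altering: consequence predicts a change to the encoded protein —
  missense and splice-site-altering categories.

Variants passing either (or both) filters form the union set; a variant
passing both is counted once.  Sensitivity re-analyses remove a defined
subset (synonymous variants, or variants in segmental duplications) from
both carrier groups and re-run the pooled count test.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .burden_stats import pooled_count_test
from .models import (
    OTHER_CATEGORY,
    PROTEIN_ALTERING_CATEGORIES,
    CompoundHetEvent,
    FilterResult,
    PooledBurdenResult,
    VariantCall,
)

DEFAULT_CADD_THRESHOLD = 10.0


def cadd10_filter(
    variants: Sequence[VariantCall],
    threshold: float = DEFAULT_CADD_THRESHOLD,
    strict_missing: bool = False,
) -> List[bool]:
    """Flag variants whose scaled CADD score is >= threshold.

    A variant without a score fails the filter with a warning, or raises
    when ``strict_missing`` is set.
    """
    flags: List[bool] = []
    for v in variants:
        if v.scaled_cadd is None:
            msg = f"variant {v.chrom}:{v.pos + 1} {v.ref}>{v.alt} has no CADD score"
            if strict_missing:
                raise ValueError(msg)
            warnings.warn(msg + "; fails CADD-10 filter")
            flags.append(False)
        else:
            flags.append(v.scaled_cadd >= threshold)
    return flags


def protein_altering_filter(variants: Sequence[VariantCall]) -> List[bool]:
    """Flag variants whose consequence predicts a protein change.

    Passing categories are missense, missense-with-splice-region, and
    splice-region-in-intron; everything else (including ``other``, with a
    warning) fails.
    """
    flags: List[bool] = []
    for v in variants:
        if v.category == OTHER_CATEGORY:
            warnings.warn(
                f"variant {v.chrom}:{v.pos + 1} has category 'other'; "
                "fails protein-altering filter"
            )
            flags.append(False)
        else:
            flags.append(v.category in PROTEIN_ALTERING_CATEGORIES)
    return flags


@dataclass
class UnionFilterOutcome:
    """Per-variant filter results plus carrier-group and per-gene tallies."""

    results: List[FilterResult]
    #: group -> counts for keys "cadd10", "protein_altering", "union"
    group_tallies: Dict[str, Dict[str, int]] = field(default_factory=dict)
    #: per-gene table in the Table-2 layout (rows: gene; columns:
    #: filter x group counts)
    per_gene: Optional[pd.DataFrame] = None


_TALLY_KEYS = ("cadd10", "protein_altering", "union")


def union_filter(
    events: Sequence[CompoundHetEvent],
    cadd_threshold: float = DEFAULT_CADD_THRESHOLD,
) -> UnionFilterOutcome:
    """Apply both deleteriousness filters to countable events.

    Produces one :class:`FilterResult` per countable event, tallies by
    carrier group, and a per-gene count matrix (CADD-10, protein-altering,
    and union counts split by parents/probands).  A variant passing both
    filters is counted once in the union.  Tallies are order-invariant.
    """
    countable = [ev for ev in events if ev.countable]
    variants = [ev.variant for ev in countable]
    cadd_flags = cadd10_filter(variants)
    prot_flags = protein_altering_filter(variants)
    results = [
        FilterResult(variant=v, passes_cadd10=c, passes_protein_altering=p)
        for v, c, p in zip(variants, cadd_flags, prot_flags)
    ]

    group_tallies: Dict[str, Dict[str, int]] = {
        "proband": dict.fromkeys(_TALLY_KEYS, 0),
        "parent": dict.fromkeys(_TALLY_KEYS, 0),
    }
    gene_counter: Counter = Counter()
    gene_names: Dict[str, str] = {}
    for ev, res in zip(countable, results):
        gene_names[ev.gene.gene_id] = ev.gene.name
        for key, flag in (
            ("cadd10", res.passes_cadd10),
            ("protein_altering", res.passes_protein_altering),
            ("union", res.passes_union),
        ):
            if flag:
                group_tallies[ev.carrier][key] += 1
                gene_counter[(ev.gene.gene_id, key, ev.carrier)] += 1

    rows = []
    for gene_id in sorted(gene_names):
        row = {"gene_id": gene_id, "gene": gene_names[gene_id]}
        for key in _TALLY_KEYS:
            for group in ("parent", "proband"):
                row[f"{key}_{group}s"] = gene_counter.get((gene_id, key, group), 0)
        rows.append(row)
    per_gene = pd.DataFrame(
        rows,
        columns=["gene_id", "gene"]
        + [f"{k}_{g}s" for k in _TALLY_KEYS for g in ("parent", "proband")],
    )
    return UnionFilterOutcome(results=results, group_tallies=group_tallies, per_gene=per_gene)


SENSITIVITY_MODES = ("exclude_synonymous", "exclude_segdup")


def sensitivity_reanalysis(
    events: Sequence[CompoundHetEvent],
    mode: str,
) -> PooledBurdenResult:
    """Re-run the pooled count test after excluding a variant subset.

    ``exclude_synonymous`` removes synonymous variants from both groups;
    ``exclude_segdup`` removes variants flagged as lying in a segmental
    duplication.  Only countable (scenario-1) events enter the counts.
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    if mode == "exclude_synonymous":
        keep = lambda ev: ev.variant.category != "synonymous"  # noqa: E731
    else:
        keep = lambda ev: not ev.variant.in_segdup  # noqa: E731
    counts = Counter(
        ev.carrier for ev in events if ev.countable and keep(ev)
    )
    return pooled_count_test(counts.get("proband", 0), counts.get("parent", 0))


def sensitivity_from_counts(
    n_proband: int,
    n_parent: int,
    remove_proband: int = 0,
    remove_parent: int = 0,
) -> PooledBurdenResult:
    """Counts-level form of the sensitivity re-analysis.

    Subtracts the excluded tallies from each group's pooled count and
    re-runs the test; used when working from published count tables rather
    than event-level data.
    """
    return pooled_count_test(n_proband - remove_proband, n_parent - remove_parent)
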