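"""Compound-heterozygosity event detection.

Determines the gene content of inherited deletions (with a fuzzy border),
applies per-call quality criteria and the identical-call genotype exclusion
rule, and emits per-family events for the proband and the
deletion-transmitting parent.  A variant in a covered gene is a scenario-1
event when it lies inside the deletion boundaries (the countable kind) and
a scenario-2 event when it lies in the gene but outside the deletion.

The fuzzy border applies only when deciding which genes a deletion covers;
scenario membership uses the reported deletion boundaries themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .models import (
    CnvCall,
    CompoundHetEvent,
    GeneModel,
    Genotype,
    Pedigree,
    VariantCall,
)

logger = logging.getLogger(__name__)

DEFAULT_FUZZY_BORDER = 500_000


def gene_content(
    deletion: CnvCall,
    genes: Sequence[GeneModel],
    fuzzy_border: int = DEFAULT_FUZZY_BORDER,
) -> List[GeneModel]:
    """Genes covered by a deletion, allowing a fuzzy border at both ends.

    A gene counts as covered when its interval overlaps the deletion padded
    by ``fuzzy_border`` bases on each side (clipped at zero).  Returned in
    deterministic order by start coordinate.
    """
    padded = deletion.interval.padded(fuzzy_border)
    hits = [g for g in genes if g.interval.overlaps(padded)]
    return sorted(hits, key=lambda g: (g.interval.start, g.gene_id))


@dataclass(frozen=True)
class QcThresholds:
    """Call-quality criteria; comparisons follow the stated wording:
    coverage is inclusive (at least), the rest strict."""

    min_depth: int = 10            # depth >= min_depth
    min_quality: float = 20.0      # site quality > min_quality
    min_allele_balance: float = 0.15  # non-reference fraction > threshold
    min_strand_reads: int = 3      # supporting reads > threshold on BOTH strands
    max_identical_reads: int = 5   # identical supporting reads <= threshold


QC_CRITERIA = ("coverage", "quality", "allele_balance", "strand_support", "identical_reads")


def call_quality_filter(
    variant: VariantCall,
    thresholds: Optional[QcThresholds] = None,
) -> Tuple[bool, List[str]]:
    """Evaluate the five call-quality criteria for one variant call.

    Returns (passed, failed-criteria).  An absent QC field fails its
    criterion: lack of evidence is not evidence of quality.
    """
    t = thresholds or QcThresholds()
    failed: List[str] = []
    if variant.depth is None or variant.depth < t.min_depth:
        failed.append("coverage")
    if variant.site_quality is None or not variant.site_quality > t.min_quality:
        failed.append("quality")
    if variant.allele_balance is None or not variant.allele_balance > t.min_allele_balance:
        failed.append("allele_balance")
    if variant.strand_support is None or not (
        variant.strand_support[0] > t.min_strand_reads
        and variant.strand_support[1] > t.min_strand_reads
    ):
        failed.append("strand_support")
    if (
        variant.identical_read_count is None
        or variant.identical_read_count > t.max_identical_reads
    ):
        failed.append("identical_reads")
    return (not failed, failed)


@dataclass
class GenotypeDecision:
    retain_proband: bool
    retain_parent: bool
    reason: Optional[str] = None  # "identical_homozygous" when both excluded


def _effective_genotype(call: Optional[VariantCall]) -> Genotype:
    """Homozygous-reference and uncalled genotypes are both coded missing."""
    if call is None:
        return Genotype.MISSING
    if call.genotype in (Genotype.HOM_REF, Genotype.MISSING):
        return Genotype.MISSING
    return call.genotype


def genotype_exclusion_filter(
    proband_call: Optional[VariantCall],
    parent_call: Optional[VariantCall],
) -> GenotypeDecision:
    """Apply the identical-call exclusion at one site.

    When proband and transmitting parent both show the same
    hemizygous/homozygous-alt allele, the variant cannot distinguish them
    (the parent is unaffected despite the identical compound genotype) and
    both are excluded.  A carrier whose genotype is hom-ref or uncalled is
    treated as missing and contributes no event; the other carrier's call is
    retained.
    """
    if (
        proband_call is not None
        and parent_call is not None
        and proband_call.site_key[:3] != parent_call.site_key[:3]
    ):
        # same (chrom, pos, ref) required; differing alts are compared as
        # distinct alleles of a decomposed multi-allelic site
        raise ValueError(
            f"site mismatch: {proband_call.site_key} vs {parent_call.site_key}"
        )
    gt_p = _effective_genotype(proband_call)
    gt_t = _effective_genotype(parent_call)
    if (
        gt_p is Genotype.HOM_ALT_OR_HEMI
        and gt_t is Genotype.HOM_ALT_OR_HEMI
        and proband_call.alt == parent_call.alt
    ):
        return GenotypeDecision(False, False, "identical_homozygous")
    return GenotypeDecision(
        retain_proband=gt_p is not Genotype.MISSING,
        retain_parent=gt_t is not Genotype.MISSING,
    )


def transmitting_parent_id(family: Pedigree, deletion: CnvCall) -> Optional[str]:
    """Resolve which genotyped parent transmitted a deletion.

    Uses the CNV table's inheritance field; returns ``None`` (caller skips
    with a warning) when inheritance is de novo/unknown or the implicated
    parent has no genotype data.
    """
    if deletion.inheritance == "paternal":
        return family.father_id
    if deletion.inheritance == "maternal":
        return family.mother_id
    return None


def detect_events(
    family: Pedigree,
    cnv_calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    variants: Sequence[VariantCall],
    fuzzy_border: int = DEFAULT_FUZZY_BORDER,
) -> List[CompoundHetEvent]:
    """Detect compound-heterozygosity events for one family.

    For each inherited deletion of the family's proband and each gene that
    deletion covers, variants carried by the proband or the transmitting
    parent inside the gene body become events; the identical-call exclusion
    is applied site-wise between the two carriers.  The non-transmitting
    parent of a trio is never a carrier source.  Variants are expected to be
    QC-filtered already (see :func:`call_quality_filter`).

    A variant site yields at most one event per carrier per deletion; when
    covered genes overlap it is attributed to the first covering gene by
    start coordinate.  Events of both scenarios are returned; only
    scenario-1 events are countable.
    """
    proband_dels = [
        c
        for c in cnv_calls
        if c.sample_id == family.proband_id
        and c.cnv_type == "del"
        and c.inheritance in ("maternal", "paternal")
    ]
    by_sample: Dict[str, Dict[Tuple[str, int, str, str], VariantCall]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, {})[v.site_key] = v

    events: List[CompoundHetEvent] = []
    for deletion in proband_dels:
        parent_id = transmitting_parent_id(family, deletion)
        if parent_id is None:
            logger.warning(
                "family %s: deletion %s:%d-%d has no identifiable transmitting "
                "parent (inheritance=%s); skipped",
                family.family_id,
                deletion.interval.chrom,
                deletion.interval.start,
                deletion.interval.end,
                deletion.inheritance,
            )
            continue
        covered = gene_content(deletion, genes, fuzzy_border)
        proband_vars = by_sample.get(family.proband_id, {})
        parent_vars = by_sample.get(parent_id, {})

        seen: Set[Tuple[str, Tuple[str, int, str, str]]] = set()
        for gene in covered:
            gi = gene.interval
            sites = {
                k
                for k, v in list(proband_vars.items()) + list(parent_vars.items())
                if gi.contains_pos(v.chrom, v.pos)
            }
            for site in sorted(sites):
                decision = genotype_exclusion_filter(
                    proband_vars.get(site), parent_vars.get(site)
                )
                for carrier, call, keep in (
                    ("proband", proband_vars.get(site), decision.retain_proband),
                    ("parent", parent_vars.get(site), decision.retain_parent),
                ):
                    if not keep or call is None:
                        continue
                    if (carrier, site) in seen:
                        continue  # overlapping covered genes: first gene wins
                    seen.add((carrier, site))
                    scenario = (
                        1
                        if deletion.interval.contains_pos(call.chrom, call.pos)
                        else 2
                    )
                    events.append(
                        CompoundHetEvent(
                            family_id=family.family_id,
                            gene=gene,
                            deletion=deletion,
                            variant=call,
                            carrier=carrier,
                            scenario=scenario,
                        )
                    )
    return events


def detect_events_cohort(
    pedigrees: Sequence[Pedigree],
    cnv_calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    variants: Sequence[VariantCall],
    thresholds: Optional[QcThresholds] = None,
    fuzzy_border: int = DEFAULT_FUZZY_BORDER,
) -> List[CompoundHetEvent]:
    """QC-filter variants, then run per-family detection over the cohort.

    Per-family detection is pure: one family's events never depend on
    another family's data.
    """
    passing = [v for v in variants if call_quality_filter(v, thresholds)[0]]
    events: List[CompoundHetEvent] = []
    for ped in pedigrees:
        events.extend(detect_events(ped, cnv_calls, genes, passing, fuzzy_border))
    return events


@dataclass
class CarrierSummary:
    """Counts of carriers (>=1 countable event) and pooled variant counts."""

    n_proband_carriers: int
    n_parent_carriers: int
    n_proband_variants: int
    n_parent_variants: int
    proband_denominator: Optional[int] = None
    parent_denominator: Optional[int] = None

    @property
    def proband_carrier_pct(self) -> Optional[float]:
        if not self.proband_denominator:
            return None
        return 100.0 * self.n_proband_carriers / self.proband_denominator

    @property
    def parent_carrier_pct(self) -> Optional[float]:
        if not self.parent_denominator:
            return None
        return 100.0 * self.n_parent_carriers / self.parent_denominator


def carrier_summary(
    events: Iterable[CompoundHetEvent],
    proband_denominator: Optional[int] = None,
    parent_denominator: Optional[int] = None,
) -> CarrierSummary:
    """Tally countable (scenario-1) events per carrier group.

    Carrier percentages use the supplied denominators (typically the number
    of analyzed families per group); the parent denominator is configurable
    because the appropriate base — transmitting parents or all genotyped
    parents — depends on the question asked.
    """
    carriers: Dict[str, Set[Tuple[str, str]]] = {"proband": set(), "parent": set()}
    counts = {"proband": 0, "parent": 0}
    for ev in events:
        if not ev.countable:
            continue
        carriers[ev.carrier].add((ev.family_id, ev.variant.sample_id))
        counts[ev.carrier] += 1
    return CarrierSummary(
        n_proband_carriers=len(carriers["proband"]),
        n_parent_carriers=len(carriers["parent"]),
        n_proband_variants=counts["proband"],
        n_parent_variants=counts["parent"],
        proband_denominator=proband_denominator,
        parent_denominator=parent_denominator,
    )
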