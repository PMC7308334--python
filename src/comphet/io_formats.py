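"""Readers and writers for the file formats the pipeline touches.

PED (6-column), a BED-like TSV for CNV calls, a BED-like TSV for genes,
VCF 4.x (via cyvcf2), and a 5-column CADD score table.  All coordinates are
converted to the internal 0-based half-open convention on ingestion and back
to the external convention on writing, so write-then-read is the identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from cyvcf2 import VCF

from .models import (
    CONSEQUENCE_CATEGORIES,
    OTHER_CATEGORY,
    CnvCall,
    GeneModel,
    GenomicInterval,
    Genotype,
    Pedigree,
    VariantCall,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


# ---------------------------------------------------------------------------
# Consequence dialect
# ---------------------------------------------------------------------------

#: Default mapping from SnpEff-style consequence tokens to the internal
#: nine-category vocabulary.  The VCF producer's exact tokens vary between
#: annotation pipelines, so the table is a parameter of :func:`read_vcf`.
SNPEFF_DIALECT: Dict[str, str] = {
    "3_prime_UTR_variant": "utr3",
    "downstream_gene_variant": "downstream_gene",
    "intron_variant": "intron",
    "missense_variant": "missense",
    "missense_variant&splice_region_variant": "missense_splice_region",
    "non_coding_exon_variant": "noncoding_exon",
    "non_coding_transcript_exon_variant": "noncoding_exon",
    "splice_region_variant&intron_variant": "splice_region_intron",
    "synonymous_variant": "synonymous",
    "upstream_gene_variant": "upstream_gene",
}

#: Internal category -> canonical external token (used when writing VCF).
CATEGORY_TO_TOKEN: Dict[str, str] = {
    "utr3": "3_prime_UTR_variant",
    "downstream_gene": "downstream_gene_variant",
    "intron": "intron_variant",
    "missense": "missense_variant",
    "missense_splice_region": "missense_variant&splice_region_variant",
    "noncoding_exon": "non_coding_exon_variant",
    "splice_region_intron": "splice_region_variant&intron_variant",
    "synonymous": "synonymous_variant",
    "upstream_gene": "upstream_gene_variant",
    OTHER_CATEGORY: "other",
}


def normalize_consequence(token: str, dialect: Optional[Dict[str, str]] = None) -> str:
    """Map an annotation token to the internal vocabulary.

    Tokens already in the internal vocabulary pass through; anything
    unrecognised becomes ``other`` with a warning.
    """
    dialect = SNPEFF_DIALECT if dialect is None else dialect
    if token in CONSEQUENCE_CATEGORIES or token == OTHER_CATEGORY:
        return token
    if token in dialect:
        return dialect[token]
    warnings.warn(f"consequence token {token!r} not in vocabulary; recorded as 'other'")
    return OTHER_CATEGORY


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

MISSING_PED_ID = "0"


def read_pedigree(path: PathLike) -> List[Pedigree]:
    """Read a 6-column PED file into one :class:`Pedigree` per family.

    Families are classified as pair or trio by the number of parents that
    appear as genotyped individuals (their own rows) in the file.  A family
    with more than one affected child is flagged multiplex; the first
    affected child listed is taken as the proband.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(parts)}"
                )
            fam, iid, father, mother, sex, affected = parts
            if iid in (father, mother):
                raise ParseError(
                    f"{path}: line {lineno}: individual {iid} listed as own parent"
                )
            rows.append((fam, iid, father, mother, sex, affected))

    by_family: Dict[str, list] = {}
    for row in rows:
        by_family.setdefault(row[0], []).append(row)

    genotyped = {row[1] for row in rows}
    pedigrees: List[Pedigree] = []
    for fam, fam_rows in by_family.items():
        children = [r for r in fam_rows if r[2] != MISSING_PED_ID or r[3] != MISSING_PED_ID]
        affected_children = [r for r in children if r[5] == "2"]
        if not affected_children:
            raise ParseError(f"{path}: family {fam} has no affected child")
        proband = affected_children[0]
        father, mother = proband[2], proband[3]
        parent_ids = tuple(
            p for p in (father, mother) if p != MISSING_PED_ID and p in genotyped
        )
        pedigrees.append(
            Pedigree(
                family_id=fam,
                proband_id=proband[1],
                parent_ids=parent_ids,
                father_id=father if father != MISSING_PED_ID and father in genotyped else None,
                mother_id=mother if mother != MISSING_PED_ID and mother in genotyped else None,
                multiplex=len(affected_children) > 1,
            )
        )
    return pedigrees


def write_pedigree(pedigrees: Sequence[Pedigree], path: PathLike) -> None:
    """Write families back to 6-column PED (parents first, then proband)."""
    with open(path, "w") as fh:
        for ped in pedigrees:
            for pid in ped.parent_ids:
                sex = "1" if pid == ped.father_id else "2"
                fh.write(f"{ped.family_id}\t{pid}\t0\t0\t{sex}\t1\n")
            father = ped.father_id or MISSING_PED_ID
            mother = ped.mother_id or MISSING_PED_ID
            fh.write(f"{ped.family_id}\t{ped.proband_id}\t{father}\t{mother}\t1\t2\n")


# ---------------------------------------------------------------------------
# CNV table
# ---------------------------------------------------------------------------

CNV_COLUMNS = (
    "sample",
    "chrom",
    "start",
    "end",
    "type",
    "inheritance",
    "n_algorithms",
    "cohort_freq",
    "zygosity",
)


def read_cnv_table(path: PathLike) -> List[CnvCall]:
    """Read a BED-like CNV TSV; start/end are 1-based inclusive on disk."""
    calls: List[CnvCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CNV_COLUMNS:
            raise ParseError(f"{path}: unexpected CNV header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(CNV_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(CNV_COLUMNS)} columns"
                )
            sample, chrom, start, end, cnv_type, inh, n_alg, freq, zyg = parts
            if cnv_type not in ("del", "dup"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown CNV type {cnv_type!r}"
                )
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ParseError(
                    f"{path}: line {lineno}: end {end_i} must exceed start {start_i}"
                )
            try:
                interval = GenomicInterval.from_1based_inclusive(chrom, start_i, end_i)
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        interval=interval,
                        cnv_type=cnv_type,
                        inheritance=inh,
                        n_algorithms=int(n_alg),
                        cohort_freq=float(freq),
                        zygosity=zyg,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return calls


def write_cnv_table(calls: Sequence[CnvCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CNV_COLUMNS) + "\n")
        for c in calls:
            start1, end1 = c.interval.to_1based_inclusive()
            fh.write(
                f"{c.sample_id}\t{c.interval.chrom}\t{start1}\t{end1}\t"
                f"{c.cnv_type}\t{c.inheritance}\t{c.n_algorithms}\t"
                f"{c.cohort_freq:g}\t{c.zygosity}\n"
            )


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

GENE_COLUMNS = ("chrom", "start", "end", "gene_id", "name", "brain_relevant", "in_segdup")


def read_gene_table(path: PathLike) -> List[GeneModel]:
    """Read a BED-like gene TSV (0-based half-open, like BED)."""
    genes: List[GeneModel] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_COLUMNS:
            raise ParseError(f"{path}: unexpected gene header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            chrom, start, end, gene_id, name, brain, segdup = line.split("\t")
            if gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    name=name,
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    brain_relevant=brain == "1",
                    in_segdup=segdup == "1",
                )
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.gene_id}\t{g.name}\t{int(g.brain_relevant)}\t{int(g.in_segdup)}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfDialect:
    """Which VCF tags carry each QC metric and annotation.

    The upstream variant caller's FORMAT tags are not standardised, so the
    mapping is configurable; defaults match the files this package writes.
    """

    depth: str = "DP"
    allele_balance: str = "AB"
    strand_forward: str = "SF"
    strand_reverse: str = "SR"
    identical_reads: str = "IR"
    consequence_info: str = "ANN"
    segdup_info: str = "SEGDUP"
    cadd_info: str = "CADD"
    consequence_dialect: Dict[str, str] = field(
        default_factory=lambda: dict(SNPEFF_DIALECT)
    )


def _genotype_from_alleles(alleles: Sequence[int]) -> Genotype:
    """Normalise cyvcf2 allele indices (haploid or diploid) to a state.

    Hemizygous "1" and homozygous "1/1" both normalise to
    ``HOM_ALT_OR_HEMI``: calls inside a deletion are haploid and present as
    homozygous.
    """
    if len(alleles) == 0 or all(a < 0 for a in alleles):
        return Genotype.MISSING
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    if all(a == 0 for a in alleles):
        return Genotype.HOM_REF
    if all(a > 0 for a in alleles):
        return Genotype.HOM_ALT_OR_HEMI
    return Genotype.HET


def _fmt_scalar(record, tag: str, i: int):
    try:
        arr = record.format(tag)
    except KeyError:  # tag not declared in this file's header
        return None
    if arr is None:
        return None
    val = arr[i][0] if arr.ndim == 2 else arr[i]
    try:
        f = float(val)
    except (TypeError, ValueError):
        return None
    if f != f or f <= -2147483648:  # NaN or htslib int missing sentinel
        return None
    # htslib stores floats single-precision; report 6 significant digits
    return float(f"{f:.6g}")


def read_vcf(
    path: PathLike,
    dialect: Optional[VcfDialect] = None,
    include_missing: bool = False,
) -> List[VariantCall]:
    """Read a VCF into per-sample :class:`VariantCall` records.

    One record is produced per sample x site with a called genotype; pass
    ``include_missing=True`` to also emit records for samples whose genotype
    at a site is missing (``./.``).  Absent QC fields stay ``None``.  A
    consequence token outside the vocabulary is recorded as ``other`` with a
    warning.  Multi-allelic sites must be decomposed upstream (one ALT per
    record); this reader raises on multiple ALTs.
    """
    dialect = dialect or VcfDialect()
    vcf = VCF(str(path))
    samples = vcf.samples
    calls: List[VariantCall] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ParseError(
                f"{path}: site {record.CHROM}:{record.POS} is multi-allelic; "
                "decompose to one ALT per record first"
            )
        category = normalize_consequence(
            str(record.INFO.get(dialect.consequence_info, OTHER_CATEGORY)),
            dialect.consequence_dialect,
        )
        in_segdup = bool(record.INFO.get(dialect.segdup_info, False))
        cadd_raw = record.INFO.get(dialect.cadd_info)
        scaled_cadd = float(cadd_raw) if cadd_raw is not None else None
        for i, sample in enumerate(samples):
            gt = _genotype_from_alleles(record.genotypes[i][:-1])
            if gt is Genotype.MISSING and not include_missing:
                continue
            depth = _fmt_scalar(record, dialect.depth, i)
            ab = _fmt_scalar(record, dialect.allele_balance, i)
            fwd = _fmt_scalar(record, dialect.strand_forward, i)
            rev = _fmt_scalar(record, dialect.strand_reverse, i)
            ident = _fmt_scalar(record, dialect.identical_reads, i)
            calls.append(
                VariantCall(
                    sample_id=sample,
                    chrom=record.CHROM,
                    pos=record.POS - 1,
                    ref=record.REF,
                    alt=record.ALT[0],
                    genotype=gt,
                    depth=int(depth) if depth is not None else None,
                    site_quality=(
                        float(f"{record.QUAL:.6g}") if record.QUAL is not None else None
                    ),
                    allele_balance=ab,
                    strand_support=(
                        (int(fwd), int(rev)) if fwd is not None and rev is not None else None
                    ),
                    identical_read_count=int(ident) if ident is not None else None,
                    category=category,
                    scaled_cadd=scaled_cadd,
                    in_segdup=in_segdup,
                )
            )
    return calls


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=ANN,Number=1,Type=String,Description="Consequence category token">',
    '##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="Variant in segmental duplication">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AB,Number=1,Type=Float,Description="Non-reference allele fraction">',
    '##FORMAT=<ID=SF,Number=1,Type=Integer,Description="Forward-strand supporting reads">',
    '##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Reverse-strand supporting reads">',
    '##FORMAT=<ID=IR,Number=1,Type=Integer,Description="Maximum identical supporting reads">',
]

_GT_STRING = {
    Genotype.HOM_ALT_OR_HEMI: "1/1",
    Genotype.HET: "0/1",
    Genotype.HOM_REF: "0/0",
    Genotype.MISSING: "./.",
}


def write_vcf(calls: Sequence[VariantCall], samples: Sequence[str], path: PathLike) -> None:
    """Write per-sample calls as a merged multi-sample VCF 4.2 text file.

    Sites are grouped on (chrom, pos, ref, alt); samples without a call at a
    site get ``./.``.  CADD scores are not written here (they live in the
    side table); the consequence category and segdup flag go to INFO.
    """
    by_site: Dict[Tuple[str, int, str, str], Dict[str, VariantCall]] = {}
    for call in calls:
        site = by_site.setdefault(call.site_key, {})
        if call.sample_id in site:
            raise ValueError(f"duplicate call for sample {call.sample_id} at {call.site_key}")
        site[call.sample_id] = call

    def chrom_key(chrom: str):
        body = chrom[3:] if chrom.startswith("chr") else chrom
        return (0, int(body)) if body.isdigit() else (1, body)

    contigs = sorted({k[0] for k in by_site}, key=chrom_key)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header_cols.extend(samples)
        fh.write("\t".join(header_cols) + "\n")
        for key in sorted(by_site, key=lambda k: (chrom_key(k[0]), k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            site = by_site[key]
            any_call = next(iter(site.values()))
            qual = f"{any_call.site_quality:g}" if any_call.site_quality is not None else "."
            info = f"ANN={CATEGORY_TO_TOKEN[any_call.category]}"
            if any_call.in_segdup:
                info += ";SEGDUP"
            cols = [chrom, str(pos + 1), ".", ref, alt, qual, ".", info, "GT:DP:AB:SF:SR:IR"]
            for sample in samples:
                call = site.get(sample)
                if call is None:
                    cols.append("./.:.:.:.:.:.")
                    continue
                dp = str(call.depth) if call.depth is not None else "."
                ab = f"{call.allele_balance:g}" if call.allele_balance is not None else "."
                if call.strand_support is not None:
                    sf, sr = (str(v) for v in call.strand_support)
                else:
                    sf = sr = "."
                ir = str(call.identical_read_count) if call.identical_read_count is not None else "."
                cols.append(f"{_GT_STRING[call.genotype]}:{dp}:{ab}:{sf}:{sr}:{ir}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# CADD table
# ---------------------------------------------------------------------------


class CaddTable:
    """Lookup of scaled CADD scores keyed on (chrom, pos, ref, alt).

    ``pos`` is internal 0-based.  A missing variant signals absence
    (``get`` returns ``None``; ``[]`` raises ``KeyError``) rather than
    reporting zero.
    """

    def __init__(self, scores: Optional[Dict[Tuple[str, int, str, str], float]] = None):
        self._scores: Dict[Tuple[str, int, str, str], float] = dict(scores or {})

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, key) -> bool:
        return key in self._scores

    def __getitem__(self, key) -> float:
        return self._scores[key]

    def get(self, key, default=None):
        return self._scores.get(key, default)

    def items(self):
        return self._scores.items()


def read_cadd_table(path: PathLike) -> CaddTable:
    """Read a 5-column CADD TSV (chrom, 1-based pos, ref, alt, scaled score).

    Duplicate keys keep the last score with a warning; a non-numeric score is
    a parse error.
    """
    scores: Dict[Tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ("chrom", "pos", "ref", "alt", "scaled_cadd"):
            raise ParseError(f"{path}: unexpected CADD header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            chrom, pos, ref, alt, score = line.split("\t")
            try:
                score_f = float(score)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric score {score!r}"
                ) from exc
            key = (chrom, int(pos) - 1, ref, alt)
            if key in scores:
                warnings.warn(
                    f"{path}: line {lineno}: duplicate CADD key {key}; keeping last"
                )
            scores[key] = score_f
    return CaddTable(scores)


def write_cadd_table(table: CaddTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tscaled_cadd\n")
        for (chrom, pos, ref, alt), score in sorted(table.items()):
            fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{score:.4f}\n")
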