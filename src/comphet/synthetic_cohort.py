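"""Synthetic family cohorts with plantable compound-heterozygosity events.

Emulates the study design the pipeline targets: ~149 families (a mix of
proband-parent pairs and complete trios), each proband carrying an inherited
heterozygous deletion that covers a handful of brain-relevant genes, with
sequence variants planted on the remaining allele in both the proband and
the deletion-transmitting parent.  Variants inside the deletion are emitted
in the hemizygous/homozygous-alt encoding genotype callers produce for
haploid regions.  A truth record accompanies every cohort so detection can
be scored exactly.

The proband enrichment effect is a single multiplier
(``proband_rate_ratio``) on the per-gene variant rate, so the expected
pooled proband:parent count ratio is known analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .io_formats import (
    write_cadd_table,
    write_cnv_table,
    write_gene_table,
    write_pedigree,
    write_vcf,
    CaddTable,
)
from .models import (
    CONSEQUENCE_CATEGORIES,
    CnvCall,
    GeneModel,
    GenomicInterval,
    Genotype,
    Pedigree,
    VariantCall,
)

#: Consequence-category distribution of the 109 observed variants
#: (proband + parent columns of the annotation table combined).
DEFAULT_CATEGORY_WEIGHTS: Tuple[float, ...] = (
    4 / 109,   # utr3
    7 / 109,   # downstream_gene
    55 / 109,  # intron
    15 / 109,  # missense
    1 / 109,   # missense_splice_region
    4 / 109,   # noncoding_exon
    2 / 109,   # splice_region_intron
    14 / 109,  # synonymous
    7 / 109,   # upstream_gene
)

#: Exponential rate for scaled CADD scores: P(score >= 10) = 0.10 exactly,
#: matching the scaled score's definition as a genome-wide top-percentage
#: rank, so the CADD-10 filter's selectivity is analytically known.
DEFAULT_CADD_RATE: float = math.log(10) / 10


@dataclass
class CohortSimParams:
    """Parameters of the cohort generator.

    Defaults reproduce the study conditions: 149 families of which 47 are
    complete trios, 3.08 brain-relevant genes per deletion on average, and a
    parent per-gene variant rate calibrated so the expected pooled counts at
    the default rate ratio 68/41 are ~68 proband and ~41 parent variants.
    """

    n_families: int = 149
    trio_fraction: float = 47 / 149
    mean_genes_per_deletion: float = 3.08
    per_gene_variant_rate_parent: float = 41 / (149 * 3.08)
    proband_rate_ratio: float = 68 / 41
    category_weights: Tuple[float, ...] = DEFAULT_CATEGORY_WEIGHTS
    cadd_rate: float = DEFAULT_CADD_RATE
    scenario2_fraction: float = 0.2
    segdup_gene_fraction: float = 0.02
    deletions_per_family: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.trio_fraction <= 1.0:
            raise ValueError("trio_fraction must be in [0, 1]")
        if len(self.category_weights) != len(CONSEQUENCE_CATEGORIES):
            raise ValueError(
                f"category_weights must have {len(CONSEQUENCE_CATEGORIES)} entries"
            )
        if abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        for name in (
            "mean_genes_per_deletion",
            "per_gene_variant_rate_parent",
            "proband_rate_ratio",
            "cadd_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.scenario2_fraction <= 1.0:
            raise ValueError("scenario2_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthEvent:
    """One planted variant, sufficient to score detection exactly."""

    family_id: str
    carrier: str  # "proband" | "parent"
    sample_id: str
    gene_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    scenario: int
    category: str
    scaled_cadd: float


@dataclass
class SyntheticCohort:
    pedigrees: List[Pedigree] = field(default_factory=list)
    genes: List[GeneModel] = field(default_factory=list)
    cnv_calls: List[CnvCall] = field(default_factory=list)
    variant_calls: List[VariantCall] = field(default_factory=list)
    cadd_table: CaddTable = field(default_factory=CaddTable)
    truth: List[TruthEvent] = field(default_factory=list)

    @property
    def sample_ids(self) -> List[str]:
        ids: List[str] = []
        for ped in self.pedigrees:
            ids.extend(ped.parent_ids)
            ids.append(ped.proband_id)
        return ids


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson whose mean equals ``mean``.

    Every deletion in the cohort covers at least one gene, so gene counts
    are drawn zero-truncated; the underlying rate is solved so the truncated
    mean matches the requested average genes per deletion.
    """
    if mean <= 1.0:
        raise ValueError("mean genes per deletion must exceed 1 for truncation")
    return brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 10 * mean)


def _draw_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    while True:
        k = rng.poisson(lam)
        if k > 0:
            return int(k)


_BASES = ("A", "C", "G", "T")


def _draw_alleles(rng: np.random.Generator) -> Tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def generate_cohort(params: Optional[CohortSimParams] = None) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under ``params``.

    For each family one inherited heterozygous deletion (by default) is
    planted in the proband and its transmitting parent; genes overlap the
    deletion, some extending beyond its breakpoints so that scenario-2
    variants (in the gene, outside the deletion) are possible.  All QC
    metrics are drawn strictly above the pipeline's call-quality thresholds,
    so every planted variant survives QC.
    """
    params = params or CohortSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    lam = _truncated_poisson_lambda(params.mean_genes_per_deletion)
    n_trios = int(round(params.trio_fraction * params.n_families))

    cohort = SyntheticCohort()
    used_positions: set = set()
    cadd_scores: Dict[Tuple[str, int, str, str], float] = {}
    gene_serial = 0

    for i in range(params.n_families):
        fam = f"F{i + 1:04d}"
        proband = f"{fam}-P"
        father, mother = f"{fam}-F", f"{fam}-M"
        is_trio = i < n_trios
        transmitting = "paternal" if rng.random() < 0.5 else "maternal"
        transmitting_parent = father if transmitting == "paternal" else mother
        if is_trio:
            parent_ids: Tuple[str, ...] = (father, mother)
        else:
            parent_ids = (transmitting_parent,)
        cohort.pedigrees.append(
            Pedigree(
                family_id=fam,
                proband_id=proband,
                parent_ids=parent_ids,
                father_id=father if father in parent_ids else None,
                mother_id=mother if mother in parent_ids else None,
            )
        )

        chrom = f"chr{(i % 22) + 1}"
        base = 2_000_000 + (i // 22) * 20_000_000

        for d in range(params.deletions_per_family):
            del_len = int(10_000 * (500_000 / 10_000) ** rng.random())  # log-uniform 10kb-500kb
            del_start = base + d * 3_000_000 + int(rng.integers(0, 100_000))
            deletion = GenomicInterval(chrom, del_start, del_start + del_len)
            cohort.cnv_calls.append(
                CnvCall(
                    sample_id=proband,
                    interval=deletion,
                    cnv_type="del",
                    inheritance=transmitting,
                    n_algorithms=int(rng.integers(2, 4)),
                    cohort_freq=round(float(rng.uniform(0.0, 0.09)), 4),
                    zygosity="het",
                )
            )
            cohort.cnv_calls.append(
                CnvCall(
                    sample_id=transmitting_parent,
                    interval=deletion,
                    cnv_type="del",
                    inheritance="unknown",
                    n_algorithms=int(rng.integers(2, 4)),
                    cohort_freq=round(float(rng.uniform(0.0, 0.09)), 4),
                    zygosity="het",
                )
            )

            n_genes = _draw_truncated_poisson(rng, lam)
            genes: List[GeneModel] = []
            for _ in range(n_genes):
                gene_serial += 1
                anchor = int(rng.integers(deletion.start, deletion.end))
                glen = int(5_000 * (50_000 / 5_000) ** rng.random())
                gene = GeneModel(
                    gene_id=f"G{gene_serial:05d}",
                    name=f"GENE{gene_serial}",
                    interval=GenomicInterval(chrom, anchor, anchor + glen),
                    brain_relevant=True,
                    in_segdup=bool(rng.random() < params.segdup_gene_fraction),
                )
                genes.append(gene)
                cohort.genes.append(gene)

            for gene in genes:
                inside = (
                    max(gene.interval.start, deletion.start),
                    min(gene.interval.end, deletion.end),
                )
                outside = (deletion.end, gene.interval.end)  # gene tail past the deletion
                for carrier, sample_id, rate in (
                    ("proband", proband,
                     params.per_gene_variant_rate_parent * params.proband_rate_ratio),
                    ("parent", transmitting_parent,
                     params.per_gene_variant_rate_parent),
                ):
                    for _ in range(rng.poisson(rate)):
                        want_s2 = (
                            rng.random() < params.scenario2_fraction
                            and outside[1] > outside[0]
                        )
                        lo, hi = outside if want_s2 else inside
                        pos = int(rng.integers(lo, hi))
                        while (chrom, pos) in used_positions:
                            pos = int(rng.integers(lo, hi))
                        used_positions.add((chrom, pos))
                        scenario = 2 if want_s2 else 1
                        ref, alt = _draw_alleles(rng)
                        category = CONSEQUENCE_CATEGORIES[
                            rng.choice(len(CONSEQUENCE_CATEGORIES), p=params.category_weights)
                        ]
                        cadd = round(float(rng.exponential(1.0 / params.cadd_rate)), 4)
                        cadd_scores[(chrom, pos, ref, alt)] = cadd
                        cohort.variant_calls.append(
                            VariantCall(
                                sample_id=sample_id,
                                chrom=chrom,
                                pos=pos,
                                ref=ref,
                                alt=alt,
                                genotype=(
                                    Genotype.HOM_ALT_OR_HEMI if scenario == 1 else Genotype.HET
                                ),
                                depth=int(rng.integers(10, 61)),
                                site_quality=round(float(rng.uniform(21.0, 60.0)), 1),
                                allele_balance=round(float(rng.uniform(0.2, 1.0)), 3),
                                strand_support=(
                                    int(rng.integers(4, 31)),
                                    int(rng.integers(4, 31)),
                                ),
                                identical_read_count=int(rng.integers(1, 6)),
                                category=category,
                                scaled_cadd=cadd,
                                in_segdup=gene.in_segdup,
                            )
                        )
                        cohort.truth.append(
                            TruthEvent(
                                family_id=fam,
                                carrier=carrier,
                                sample_id=sample_id,
                                gene_id=gene.gene_id,
                                chrom=chrom,
                                pos=pos,
                                ref=ref,
                                alt=alt,
                                scenario=scenario,
                                category=category,
                                scaled_cadd=cadd,
                            )
                        )

    cohort.cadd_table = CaddTable(cadd_scores)
    return cohort


TRUTH_COLUMNS = (
    "family_id",
    "carrier",
    "sample_id",
    "gene_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "scenario",
    "category",
    "scaled_cadd",
)


def write_cohort(cohort: SyntheticCohort, directory) -> Dict[str, Path]:
    """Write the cohort as the six pipeline input/verification files.

    Emits PED, CNV TSV, gene TSV, VCF, CADD TSV — all readable by
    :mod:`comphet.io_formats` — plus the truth record TSV, which the
    pipeline itself never consumes.  Fixed seed implies byte-identical
    output.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": directory / "cohort.ped",
        "cnv": directory / "cnv_calls.tsv",
        "genes": directory / "genes.tsv",
        "vcf": directory / "variants.vcf",
        "cadd": directory / "cadd.tsv",
        "truth": directory / "truth.tsv",
    }
    write_pedigree(cohort.pedigrees, paths["ped"])
    write_cnv_table(cohort.cnv_calls, paths["cnv"])
    write_gene_table(cohort.genes, paths["genes"])
    write_vcf(cohort.variant_calls, cohort.sample_ids, paths["vcf"])
    write_cadd_table(cohort.cadd_table, paths["cadd"])
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in cohort.truth:
            fh.write(
                f"{t.family_id}\t{t.carrier}\t{t.sample_id}\t{t.gene_id}\t"
                f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.scenario}\t"
                f"{t.category}\t{t.scaled_cadd:.4f}\n"
            )
    return paths
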