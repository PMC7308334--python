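"""Core domain types shared across the pipeline.

All genomic coordinates are stored 0-based, half-open ([start, end)).
External formats that use 1-based inclusive coordinates (VCF positions,
"start-end" CNV tables) are converted at the I/O boundary; see
:func:`GenomicInterval.from_1based_inclusive`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple


class Genotype(enum.Enum):
    """Normalised genotype state.

    Inside a deletion the single remaining allele is reported by callers as a
    homozygous (or haploid) call, so hemizygous-alt and homozygous-alt are
    collapsed into one state.
    """

    HOM_ALT_OR_HEMI = "hom_alt_or_hemi"
    HET = "het"
    HOM_REF = "hom_ref"
    MISSING = "missing"


#: The closed consequence vocabulary used for reporting, plus "other".
CONSEQUENCE_CATEGORIES: Tuple[str, ...] = (
    "utr3",
    "downstream_gene",
    "intron",
    "missense",
    "missense_splice_region",
    "noncoding_exon",
    "splice_region_intron",
    "synonymous",
    "upstream_gene",
)

OTHER_CATEGORY = "other"

#: Categories that predict a change to the encoded protein: missense and
#: splice-site-altering variants.
PROTEIN_ALTERING_CATEGORIES: frozenset = frozenset(
    {"missense", "missense_splice_region", "splice_region_intron"}
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored coordinate range, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @classmethod
    def from_1based_inclusive(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (VCF / table dialect)."""
        return cls(chrom, start - 1, end)

    def to_1based_inclusive(self) -> Tuple[int, int]:
        """Inverse of :meth:`from_1based_inclusive`."""
        return self.start + 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Whether a 0-based position lies inside the interval."""
        return chrom == self.chrom and self.start <= pos < self.end

    def padded(self, pad: int) -> "GenomicInterval":
        """Extend both ends by ``pad`` bases, clipped at zero."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its locus and the two annotation flags the analysis uses."""

    gene_id: str
    name: str
    interval: GenomicInterval
    brain_relevant: bool = False
    in_segdup: bool = False


@dataclass(frozen=True)
class Pedigree:
    """One family: the affected child (proband) and 1-2 genotyped parents."""

    family_id: str
    proband_id: str
    parent_ids: Tuple[str, ...]
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    multiplex: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.parent_ids) <= 2:
            raise ValueError(
                f"family {self.family_id}: need 1 or 2 parents, "
                f"got {len(self.parent_ids)}"
            )
        if self.proband_id in self.parent_ids:
            raise ValueError(
                f"family {self.family_id}: proband {self.proband_id} "
                "listed as own parent"
            )

    @property
    def is_trio(self) -> bool:
        return len(self.parent_ids) == 2


@dataclass(frozen=True)
class CnvCall:
    """A copy-number call with the metadata the filters and pairing need."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str  # "del" | "dup"
    inheritance: str  # "denovo" | "maternal" | "paternal" | "unknown"
    n_algorithms: int
    cohort_freq: float
    zygosity: str = "het"  # "het" | "hom"

    def __post_init__(self) -> None:
        if self.cnv_type not in ("del", "dup"):
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.inheritance not in ("denovo", "maternal", "paternal", "unknown"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.n_algorithms < 1:
            raise ValueError("n_algorithms must be >= 1")
        if not 0.0 <= self.cohort_freq <= 1.0:
            raise ValueError("cohort_freq must be in [0, 1]")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class VariantCall:
    """A per-sample sequence variant with QC metrics and annotation.

    ``pos`` is 0-based internal; QC fields that were absent in the source are
    ``None`` (absent, not zero). ``scaled_cadd`` is the scaled (PHRED-like)
    CADD score or ``None`` when no score is known.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    depth: Optional[int] = None
    site_quality: Optional[float] = None
    allele_balance: Optional[float] = None
    strand_support: Optional[Tuple[int, int]] = None
    identical_read_count: Optional[int] = None
    category: str = OTHER_CATEGORY
    scaled_cadd: Optional[float] = None
    in_segdup: bool = False

    def __post_init__(self) -> None:
        if self.allele_balance is not None and not 0.0 <= self.allele_balance <= 1.0:
            raise ValueError("allele_balance must be in [0, 1]")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.category != OTHER_CATEGORY and self.category not in CONSEQUENCE_CATEGORIES:
            raise ValueError(f"category {self.category!r} not in vocabulary")

    @property
    def site_key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CompoundHetEvent:
    """A (family, gene, deletion, variant) co-occurrence.

    ``scenario`` is 1 when the variant lies inside the deletion boundaries
    (the countable event), 2 when it lies in the gene but outside the
    deletion.  ``carrier`` says whose allele carries the variant.
    """

    family_id: str
    gene: GeneModel
    deletion: CnvCall
    variant: VariantCall
    carrier: str  # "proband" | "parent"
    scenario: int  # 1 | 2

    def __post_init__(self) -> None:
        if self.carrier not in ("proband", "parent"):
            raise ValueError(f"unknown carrier {self.carrier!r}")
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        inside = self.deletion.interval.contains_pos(self.variant.chrom, self.variant.pos)
        if (self.scenario == 1) != inside:
            raise ValueError(
                "scenario label inconsistent with variant position vs deletion"
            )
        if self.variant.genotype in (Genotype.MISSING, Genotype.HOM_REF):
            raise ValueError("event carrier genotype must be non-missing, non-hom-ref")

    @property
    def countable(self) -> bool:
        return self.scenario == 1


@dataclass
class PooledBurdenResult:
    """Result of the pooled equal-sequence count comparison."""

    n_proband: int
    n_parent: int
    chi_square: float
    p_value: float
    df: int = 1


@dataclass
class BurdenTestResult:
    """Result of the logistic regression on per-individual summed CADD."""

    beta: Optional[float]
    standard_error: Optional[float]
    p_value: Optional[float]
    n_individuals: int
    converged: bool
    message: str = ""


@dataclass
class FilterResult:
    """Per-variant outcome of the two deleteriousness filters and their union."""

    variant: VariantCall
    passes_cadd10: bool
    passes_protein_altering: bool
    passes_union: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passes_union = self.passes_cadd10 or self.passes_protein_altering
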