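"""Shared builders for event-level test objects."""

from comphet.models import (
    CnvCall,
    CompoundHetEvent,
    GeneModel,
    GenomicInterval,
    Genotype,
    VariantCall,
)

_DELETION = CnvCall(
    sample_id="P1",
    interval=GenomicInterval("chr1", 1_000_000, 1_100_000),
    cnv_type="del",
    inheritance="paternal",
    n_algorithms=3,
    cohort_freq=0.01,
)

_GENE = GeneModel("G1", "G1", GenomicInterval("chr1", 1_040_000, 1_120_000), True)


def make_event(
    cadd=10.0,
    pos=1_050_000,
    carrier="proband",
    sample="P1",
    category="missense",
    in_segdup=False,
    family_id="F1",
):
    scenario = 1 if _DELETION.interval.contains_pos("chr1", pos) else 2
    variant = VariantCall(
        sample_id=sample,
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="T",
        genotype=Genotype.HOM_ALT_OR_HEMI if scenario == 1 else Genotype.HET,
        depth=30,
        site_quality=50.0,
        allele_balance=0.9,
        strand_support=(10, 10),
        identical_read_count=2,
        category=category,
        scaled_cadd=cadd,
        in_segdup=in_segdup,
    )
    return CompoundHetEvent(
        family_id=family_id,
        gene=_GENE,
        deletion=_DELETION,
        variant=variant,
        carrier=carrier,
        scenario=scenario,
    )
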