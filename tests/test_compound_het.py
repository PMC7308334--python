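"""Gene content, call QC, genotype exclusion, and event detection."""

import numpy as np
import pytest

from comphet.compound_het import (
    QcThresholds,
    call_quality_filter,
    carrier_summary,
    detect_events,
    detect_events_cohort,
    gene_content,
    genotype_exclusion_filter,
)
from comphet.models import (
    CnvCall,
    GeneModel,
    GenomicInterval,
    Genotype,
    Pedigree,
    VariantCall,
)


def deletion(chrom="chr1", start=1_000_000, end=1_100_000, sample="P1", inheritance="paternal"):
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        cnv_type="del",
        inheritance=inheritance,
        n_algorithms=3,
        cohort_freq=0.01,
    )


def gene(gene_id, start, end, chrom="chr1", **kwargs):
    return GeneModel(gene_id, gene_id, GenomicInterval(chrom, start, end), True, **kwargs)


def variant(sample="P1", pos=1_050_000, genotype=Genotype.HOM_ALT_OR_HEMI, alt="T", **kwargs):
    defaults = dict(
        ref="A",
        depth=30,
        site_quality=50.0,
        allele_balance=0.9,
        strand_support=(10, 10),
        identical_read_count=2,
        category="missense",
    )
    defaults.update(kwargs)
    return VariantCall(
        sample_id=sample, chrom="chr1", pos=pos, alt=alt,
        genotype=genotype, **defaults,
    )


class TestGeneContent:
    def test_gene_within_fuzzy_border_included(self):
        g = gene("G1", 1_550_000, 1_560_000)  # 450 kb downstream of the deletion
        assert gene_content(deletion(), [g]) == [g]

    def test_gene_at_exactly_border_edge_excluded(self):
        g = gene("G1", 1_600_000, 1_610_000)  # starts at del.end + 500 kb
        assert gene_content(deletion(), [g]) == []

    def test_border_clipped_at_chromosome_start(self):
        d = deletion(start=100_000, end=200_000)
        g = gene("G1", 0, 1_000)
        assert gene_content(d, [g]) == [g]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(5)
        genes = [
            gene(f"G{i}", int(s), int(s) + int(rng.integers(1_000, 80_000)))
            for i, s in enumerate(rng.integers(0, 5_000_000, size=60))
        ]
        for _ in range(20):
            start = int(rng.integers(0, 4_000_000))
            d = deletion(start=start, end=start + int(rng.integers(10_000, 400_000)))
            padded = d.interval.padded(500_000)
            oracle = sorted(
                (g for g in genes if g.interval.overlaps(padded)),
                key=lambda g: (g.interval.start, g.gene_id),
            )
            assert gene_content(d, genes) == oracle


class TestCallQualityFilter:
    def test_boundary_passing_call(self):
        v = variant(
            depth=10, site_quality=21.0, allele_balance=0.16,
            strand_support=(4, 4), identical_read_count=5,
        )
        passed, failed = call_quality_filter(v)
        assert passed and failed == []

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            ({"depth": 9}, "coverage"),
            ({"site_quality": 20.0}, "quality"),
            ({"allele_balance": 0.15}, "allele_balance"),
            ({"strand_support": (3, 10)}, "strand_support"),
            ({"strand_support": (10, 3)}, "strand_support"),
            ({"identical_read_count": 6}, "identical_reads"),
            ({"depth": None}, "coverage"),  # absent field fails its criterion
        ],
    )
    def test_single_criterion_failures(self, kwargs, reason):
        passed, failed = call_quality_filter(variant(**kwargs))
        assert not passed and failed == [reason]

    def test_matches_brute_force_conjunction(self):
        rng = np.random.default_rng(9)
        t = QcThresholds()
        for _ in range(1000):
            v = variant(
                depth=int(rng.integers(0, 20)),
                site_quality=float(rng.uniform(10, 30)),
                allele_balance=float(rng.uniform(0, 0.4)),
                strand_support=(int(rng.integers(0, 8)), int(rng.integers(0, 8))),
                identical_read_count=int(rng.integers(0, 10)),
            )
            expected = (
                v.depth >= t.min_depth
                and v.site_quality > t.min_quality
                and v.allele_balance > t.min_allele_balance
                and v.strand_support[0] > t.min_strand_reads
                and v.strand_support[1] > t.min_strand_reads
                and v.identical_read_count <= t.max_identical_reads
            )
            assert call_quality_filter(v, t)[0] == expected


class TestGenotypeExclusion:
    def test_identical_hemizygous_calls_excluded(self):
        d = genotype_exclusion_filter(
            variant(sample="P1", alt="T"), variant(sample="D1", alt="T")
        )
        assert (d.retain_proband, d.retain_parent) == (False, False)
        assert d.reason == "identical_homozygous"

    def test_different_alt_alleles_both_retained(self):
        d = genotype_exclusion_filter(
            variant(sample="P1", alt="T"),
            variant(sample="D1", alt="G", ref="A"),
        )
        # different alternate alleles are different variants, never "identical"
        assert d.retain_proband and d.retain_parent

    def test_parent_missing_retains_proband_only(self):
        d = genotype_exclusion_filter(variant(sample="P1"), None)
        assert d.retain_proband and not d.retain_parent and d.reason is None

    def test_hom_ref_coded_missing(self):
        d = genotype_exclusion_filter(
            variant(sample="P1", genotype=Genotype.HOM_REF),
            variant(sample="D1"),
        )
        assert not d.retain_proband and d.retain_parent

    def test_het_vs_hom_retained(self):
        d = genotype_exclusion_filter(
            variant(sample="P1", genotype=Genotype.HET),
            variant(sample="D1"),
        )
        assert d.retain_proband and d.retain_parent

    def test_site_mismatch_rejected(self):
        with pytest.raises(ValueError, match="site mismatch"):
            genotype_exclusion_filter(variant(pos=100), variant(pos=200))


class TestDetectEvents:
    FAMILY = Pedigree("F1", "P1", ("D1",), father_id="D1")
    GENES = [gene("G1", 1_040_000, 1_120_000)]  # spans the deletion 3' breakpoint

    def test_variant_inside_deletion_is_countable_scenario1(self):
        events = detect_events(self.FAMILY, [deletion()], self.GENES, [variant()])
        (ev,) = events
        assert ev.scenario == 1 and ev.countable and ev.carrier == "proband"

    def test_variant_in_gene_outside_deletion_is_scenario2(self):
        v = variant(pos=1_110_000, genotype=Genotype.HET)
        (ev,) = detect_events(self.FAMILY, [deletion()], self.GENES, [v])
        assert ev.scenario == 2 and not ev.countable

    def test_identical_calls_excluded_pairwise(self):
        vs = [variant(sample="P1"), variant(sample="D1")]
        assert detect_events(self.FAMILY, [deletion()], self.GENES, vs) == []

    def test_unknown_inheritance_skipped_with_warning(self, caplog):
        d = deletion(inheritance="unknown")
        # inherited filter drops unknown before pairing, so no events
        assert detect_events(self.FAMILY, [d], self.GENES, [variant()]) == []

    def test_maternal_deletion_without_genotyped_mother_warns(self, caplog):
        d = deletion(inheritance="maternal")
        with caplog.at_level("WARNING"):
            events = detect_events(self.FAMILY, [d], self.GENES, [variant()])
        assert events == []
        assert "no identifiable transmitting parent" in caplog.text

    def test_non_transmitting_parent_never_a_carrier(self):
        trio = Pedigree("F1", "P1", ("D1", "M1"), father_id="D1", mother_id="M1")
        vs = [variant(sample="M1")]  # mother carries a variant, father transmitted
        assert detect_events(trio, [deletion()], self.GENES, vs) == []

    def test_queried_gene_sets_equal_for_proband_and_parent(self, default_cohort):
        """The pooled proband and parent sequences are identical in gene
        identity by construction: events are emitted against the same
        per-family covered gene set for both carriers."""
        events = detect_events_cohort(
            default_cohort.pedigrees,
            default_cohort.cnv_calls,
            default_cohort.genes,
            default_cohort.variant_calls,
        )
        for ev in events:
            assert ev.deletion.sample_id == f"{ev.family_id}-P"
            if ev.countable:
                assert ev.deletion.interval.contains_pos(ev.variant.chrom, ev.variant.pos)


class TestTruthRecovery:
    def test_pipeline_recovers_exactly_the_planted_scenario1_events(self, default_cohort):
        events = detect_events_cohort(
            default_cohort.pedigrees,
            default_cohort.cnv_calls,
            default_cohort.genes,
            default_cohort.variant_calls,
        )
        detected = {
            (ev.family_id, ev.carrier, ev.variant.chrom, ev.variant.pos)
            for ev in events
            if ev.countable
        }
        planted = {
            (t.family_id, t.carrier, t.chrom, t.pos)
            for t in default_cohort.truth
            if t.scenario == 1
        }
        assert detected == planted  # sensitivity 1, zero false positives

    def test_carrier_summary_matches_truth_tallies(self, default_cohort):
        events = detect_events_cohort(
            default_cohort.pedigrees,
            default_cohort.cnv_calls,
            default_cohort.genes,
            default_cohort.variant_calls,
        )
        summary = carrier_summary(events, proband_denominator=149)
        s1 = [t for t in default_cohort.truth if t.scenario == 1]
        assert summary.n_proband_variants == sum(t.carrier == "proband" for t in s1)
        assert summary.n_parent_variants == sum(t.carrier == "parent" for t in s1)
        assert summary.n_proband_carriers == len(
            {t.sample_id for t in s1 if t.carrier == "proband"}
        )
        assert summary.n_parent_carriers == len(
            {t.sample_id for t in s1 if t.carrier == "parent"}
        )


class TestCarrierSummary:
    def test_percentage_uses_supplied_denominator(self):
        events = []
        fam = Pedigree("F1", "P1", ("D1",), father_id="D1")
        for i in range(20):
            d = deletion(sample=f"P{i}")
            g = gene(f"G{i}", 1_040_000, 1_090_000)
            from comphet.models import CompoundHetEvent

            events.append(
                CompoundHetEvent(
                    family_id=f"F{i}",
                    gene=g,
                    deletion=d,
                    variant=variant(sample=f"P{i}"),
                    carrier="proband",
                    scenario=1,
                )
            )
        summary = carrier_summary(events, proband_denominator=149)
        assert summary.n_proband_carriers == 20
        assert summary.proband_carrier_pct == pytest.approx(13.4, abs=0.05)

    def test_no_events_gives_zero_carriers(self):
        s = carrier_summary([], proband_denominator=10)
        assert s.n_proband_carriers == 0 and s.proband_carrier_pct == 0.0
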