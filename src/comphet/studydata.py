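"""Published count tables of the ASD compound-heterozygosity study.

These are the study's printed summary tables, shipped as data so the
headline statistics can be recomputed without access to the restricted
individual-level data (dbGaP accession phs000267.v5.p2).  The pipeline
itself never reads them; they feed the reporting layer and the
reproduction script.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

#: Cohort composition: 47 complete trios and 102 proband-parent pairs.
N_FAMILIES = 149
N_TRIOS = 47
N_PAIRS = 102

#: Carriers of at least one SNV-deletion event.
N_PROBAND_CARRIERS = 20
N_PARENT_CARRIERS = 16

#: Consequence annotation of the 109 variants found on the remaining
#: alleles of inherited deletions: category -> (probands, parents).
TABLE1_COUNTS: Dict[str, Tuple[int, int]] = {
    "utr3": (3, 1),
    "downstream_gene": (4, 3),
    "intron": (36, 19),
    "missense": (8, 7),
    "missense_splice_region": (1, 0),
    "noncoding_exon": (2, 2),
    "splice_region_intron": (2, 0),
    "synonymous": (7, 7),
    "upstream_gene": (5, 2),
}

#: Per-gene counts after the two deleteriousness filters:
#: (gene, cadd10_parents, cadd10_probands, protein_parents,
#:  protein_probands, union_parents, union_probands).
#: Counts are as printed; for two genes with overlapping loci (OR2L2 and
#: PITRM1-AS1) the source table attributes shared variants differently
#: between the per-filter and union columns, so per-row union consistency
#: holds only in aggregate.
TABLE2_ROWS = [
    ("ABCC6", 1, 0, 2, 0, 2, 0),
    ("AF001548.6", 1, 0, 0, 0, 1, 0),
    ("AKAP9", 0, 0, 0, 1, 0, 1),
    ("CAMK2B", 0, 1, 0, 0, 0, 1),
    ("CDK11A", 0, 1, 0, 1, 0, 1),
    ("CTD-2245F17.6", 0, 2, 0, 0, 0, 2),
    ("FANCA", 0, 1, 0, 1, 0, 2),
    ("FKBP15", 1, 0, 1, 0, 1, 0),
    ("MYH11", 1, 0, 1, 0, 1, 0),
    ("NDE1", 0, 2, 0, 0, 0, 2),
    ("OR2L1P", 0, 1, 0, 0, 0, 1),
    ("OR2L2", 0, 1, 2, 0, 2, 0),
    ("PITRM1-AS1", 0, 0, 0, 0, 0, 1),
    ("PPL", 1, 0, 1, 0, 1, 0),
    ("PRAMEF4", 0, 0, 0, 1, 0, 1),
    ("RP11-15A1.2", 0, 2, 0, 0, 0, 2),
    ("ZNF257", 0, 1, 0, 1, 0, 1),
    ("ZNF45", 0, 0, 0, 2, 0, 2),
    ("ZNF92", 0, 0, 0, 4, 0, 4),
]

TABLE2_COLUMNS = [
    "gene",
    "cadd10_parents",
    "cadd10_probands",
    "protein_altering_parents",
    "protein_altering_probands",
    "union_parents",
    "union_probands",
]

#: Union-filtered variants in segmental duplications (rs75355616,
#: overlapping PRAMEF4; carried by a proband) removed in the post-hoc
#: re-analysis: (probands, parents).
SEGDUP_UNION_EXCLUSIONS = (1, 0)


def table1() -> pd.DataFrame:
    """The annotation table as a category x group DataFrame."""
    return pd.DataFrame.from_dict(
        TABLE1_COUNTS, orient="index", columns=["proband", "parent"]
    ).rename_axis("category")


def table2() -> pd.DataFrame:
    """The per-gene deleteriousness-filter table."""
    return pd.DataFrame(TABLE2_ROWS, columns=TABLE2_COLUMNS).set_index("gene")
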