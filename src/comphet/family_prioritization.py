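"""CNV call filtering, family exclusion rules, and the family priority score.

Families are ranked for sequencing by a weighted rank sum over six
per-family CNV features, with deletion features weighted twice as heavily
as duplication features:

    R_i = 2 * (rank(n_del) + rank(n_brain_del) + rank(inherit_ratio_del))
        + 1 * (rank(n_dup) + rank(n_brain_dup) + rank(inherit_ratio_dup))

where a larger feature value receives a larger rank and ties take the
average (mid) rank.  A preference for fewer de novo CNVs is applied as a
separate ascending sort key ahead of R_i rather than inside the formula.
The feature set is configurable so alternative readings of the score can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import math

from scipy.stats import rankdata

from .models import CnvCall, GeneModel, Pedigree


def filter_cnv_calls(
    calls: Sequence[CnvCall],
    min_algorithms: int = 2,
    max_freq: float = 0.10,
    min_length: int = 5000,
) -> List[CnvCall]:
    """Retain reliable, rare CNV calls.

    A call passes when it was made by at least ``min_algorithms`` concordant
    callers, its cohort frequency is strictly below ``max_freq``, and its
    length strictly exceeds ``min_length`` bases.  Order is preserved; the
    filter is idempotent.
    """
    return [
        c
        for c in calls
        if c.n_algorithms >= min_algorithms
        and c.cohort_freq < max_freq
        and c.length > min_length
    ]


@dataclass
class ExclusionRecord:
    family_id: str
    reason: str  # "multiplex" | "homozygous_deletion"


def exclude_families(
    pedigrees: Sequence[Pedigree],
    cnv_calls: Sequence[CnvCall],
) -> Tuple[List[Pedigree], List[ExclusionRecord]]:
    """Drop multiplex families and probands carrying homozygous deletions.

    Multiplex families (more than one affected child) are excluded because
    the same compound-heterozygous event recurring in several children is
    unlikely; homozygous deletions are excluded as likely pathogenic on
    their own.  Returns retained families plus a per-exclusion log.
    """
    known_samples = set()
    for ped in pedigrees:
        known_samples.add(ped.proband_id)
        known_samples.update(ped.parent_ids)
    for call in cnv_calls:
        if call.sample_id not in known_samples:
            raise ValueError(
                f"CNV call sample {call.sample_id!r} not in any pedigree"
            )

    hom_del_probands = {
        c.sample_id
        for c in cnv_calls
        if c.cnv_type == "del" and c.zygosity == "hom"
    }
    retained: List[Pedigree] = []
    log: List[ExclusionRecord] = []
    for ped in pedigrees:
        if ped.multiplex:
            log.append(ExclusionRecord(ped.family_id, "multiplex"))
        elif ped.proband_id in hom_del_probands:
            log.append(ExclusionRecord(ped.family_id, "homozygous_deletion"))
        else:
            retained.append(ped)
    return retained, log


@dataclass
class PriorityFeatures:
    """Per-family CNV features, their cohort ranks, and the weighted sum."""

    family_id: str
    n_del: int = 0
    n_dup: int = 0
    n_brain_del: int = 0
    n_brain_dup: int = 0
    inherit_ratio_del: float = 0.0
    inherit_ratio_dup: float = 0.0
    n_denovo: int = 0
    ranks: Dict[str, float] = field(default_factory=dict)
    r_i: float = float("nan")


FEATURE_NAMES = (
    "n_del",
    "n_brain_del",
    "inherit_ratio_del",
    "n_dup",
    "n_brain_dup",
    "inherit_ratio_dup",
)

#: Weight per feature in the rank sum; deletion terms count double.
DEFAULT_WEIGHTS: Dict[str, float] = {
    "n_del": 2.0,
    "n_brain_del": 2.0,
    "inherit_ratio_del": 2.0,
    "n_dup": 1.0,
    "n_brain_dup": 1.0,
    "inherit_ratio_dup": 1.0,
}

_INHERITED = ("maternal", "paternal")


def compute_features(
    pedigrees: Sequence[Pedigree],
    cnv_calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
) -> List[PriorityFeatures]:
    """Count per-family CNV features from the proband's filtered calls."""
    brain_genes = [g for g in genes if g.brain_relevant]
    by_sample: Dict[str, List[CnvCall]] = {}
    for call in cnv_calls:
        by_sample.setdefault(call.sample_id, []).append(call)

    out: List[PriorityFeatures] = []
    for ped in pedigrees:
        feats = PriorityFeatures(family_id=ped.family_id)
        calls = by_sample.get(ped.proband_id, [])
        inherited = [c for c in calls if c.inheritance in _INHERITED]
        feats.n_denovo = sum(1 for c in calls if c.inheritance == "denovo")
        for cnv_type, n_attr, brain_attr, ratio_attr in (
            ("del", "n_del", "n_brain_del", "inherit_ratio_del"),
            ("dup", "n_dup", "n_brain_dup", "inherit_ratio_dup"),
        ):
            of_type = [c for c in calls if c.cnv_type == cnv_type]
            inh_of_type = [c for c in inherited if c.cnv_type == cnv_type]
            setattr(feats, n_attr, len(inh_of_type))
            setattr(
                feats,
                brain_attr,
                sum(
                    1
                    for c in inh_of_type
                    if any(c.interval.overlaps(g.interval) for g in brain_genes)
                ),
            )
            setattr(
                feats,
                ratio_attr,
                len(inh_of_type) / len(of_type) if of_type else 0.0,
            )
        out.append(feats)
    return out


def priority_score(
    features: Sequence[PriorityFeatures],
    weights: Optional[Dict[str, float]] = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> List[PriorityFeatures]:
    """Rank each feature across families and combine into R_i.

    Larger feature values get larger ranks (mid-rank for ties); R_i is the
    weighted sum of the six ranks.  Returns the features sorted by
    (ascending de novo CNV count, descending R_i), i.e. the sequencing
    priority order.  A single family gets all ranks 1 and R_i = 9 under the
    default weights.
    """
    if not features:
        raise ValueError("need at least one family")
    weights = DEFAULT_WEIGHTS if weights is None else weights
    for name in feature_names:
        values = [getattr(f, name) for f in features]
        if any(isinstance(v, float) and math.isnan(v) for v in values):
            raise ValueError(f"feature {name} contains NaN")
        ranks = rankdata(values, method="average")
        for f, r in zip(features, ranks):
            f.ranks[name] = float(r)
    for f in features:
        f.r_i = sum(weights[name] * f.ranks[name] for name in feature_names)
    return sorted(features, key=lambda f: (f.n_denovo, -f.r_i))
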