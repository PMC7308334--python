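"""The study's three statistical procedures.

1. Pooled count test: the combined proband gene sequence is, by design,
   identical in gene identity and length to the combined transmitting-parent
   sequence, so under the null the pooled variant counts split 50:50.  The
   test is a one-degree-of-freedom chi-square goodness-of-fit against the
   equal split, without continuity correction.
2. CADD burden test: per-individual summed scaled CADD scores, compared
   between probands and parents by logistic regression (proband coded 1).
3. Bonferroni correction at alpha / m over the m primary analyses.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .io_formats import CaddTable
from .models import BurdenTestResult, CompoundHetEvent, PooledBurdenResult


def pooled_count_test(n_proband: int, n_parent: int) -> PooledBurdenResult:
    """Chi-square goodness-of-fit of two pooled counts against a 50:50 split.

    With counts a, b and E = (a + b) / 2, X^2 = (a-E)^2/E + (b-E)^2/E on one
    degree of freedom.  No continuity correction is applied.  Symmetric in
    its arguments and strictly increasing in |a - b| at fixed a + b.
    """
    if n_proband < 0 or n_parent < 0:
        raise ValueError("counts must be non-negative")
    if n_proband + n_parent == 0:
        raise ValueError("pooled count test undefined for two zero counts")
    chi2, p = sps.chisquare([n_proband, n_parent])
    return PooledBurdenResult(
        n_proband=n_proband,
        n_parent=n_parent,
        chi_square=float(chi2),
        p_value=float(p),
    )


def aggregate_cadd(
    events: Iterable[CompoundHetEvent],
    cadd: Optional[CaddTable] = None,
    all_individuals: Optional[Sequence[Tuple[str, str]]] = None,
    missing_score_policy: str = "error",
) -> Dict[Tuple[str, str], float]:
    """Sum scaled CADD scores of countable events per individual.

    Keys are (sample_id, group) with group "proband" or "parent".  Scores
    come from the variant record itself or, failing that, the ``cadd``
    lookup table.  A countable variant without a score is an error under the
    default strict policy; ``missing_score_policy="skip"`` drops it with a
    warning instead.

    When ``all_individuals`` is given (full-sample mode), every listed
    (sample_id, group) appears in the result, with 0.0 for individuals
    without events.
    """
    if missing_score_policy not in ("error", "skip"):
        raise ValueError(f"unknown missing_score_policy {missing_score_policy!r}")
    sums: Dict[Tuple[str, str], float] = {}
    if all_individuals is not None:
        for key in all_individuals:
            sums[key] = 0.0
    for ev in events:
        if not ev.countable:
            continue
        score = ev.variant.scaled_cadd
        if score is None and cadd is not None:
            score = cadd.get(ev.variant.site_key)
        if score is None:
            msg = (
                f"no scaled CADD score for variant "
                f"{ev.variant.chrom}:{ev.variant.pos + 1} "
                f"{ev.variant.ref}>{ev.variant.alt}"
            )
            if missing_score_policy == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; skipped")
            continue
        key = (ev.variant.sample_id, ev.carrier)
        sums[key] = sums.get(key, 0.0) + float(score)
    return sums


def logistic_burden_test(
    scores: Sequence[float],
    labels: Sequence[str],
) -> BurdenTestResult:
    """Logistic regression of group membership on the aggregated CADD score.

    Fits log-odds(proband) = intercept + beta * score by maximum likelihood
    and reports the Wald statistics for beta.  Under complete separation the
    MLE does not exist; the result is flagged ``converged=False`` with no
    estimates rather than returning an unstable fit.
    """
    scores_arr = np.asarray(scores, dtype=float)
    if scores_arr.ndim != 1 or len(scores_arr) != len(labels):
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if not np.all(np.isfinite(scores_arr)):
        raise ValueError("scores must be finite")
    unknown = set(labels) - {"proband", "parent"}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    y = np.asarray([1 if lab == "proband" else 0 for lab in labels], dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if y.min() == y.max():
        raise ValueError("both labels must be present")

    X = sm.add_constant(scores_arr)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        return BurdenTestResult(
            beta=None,
            standard_error=None,
            p_value=None,
            n_individuals=n,
            converged=False,
            message=f"maximum likelihood did not converge: {exc}",
        )
    if not fit.mle_retvals.get("converged", False):
        return BurdenTestResult(
            beta=None,
            standard_error=None,
            p_value=None,
            n_individuals=n,
            converged=False,
            message="maximum likelihood did not converge",
        )
    return BurdenTestResult(
        beta=float(fit.params[1]),
        standard_error=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n_individuals=n,
        converged=True,
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 3) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def is_significant(p_value: float, alpha: float = 0.05, m: int = 3) -> bool:
    """Whether p falls below the Bonferroni-corrected threshold (strict <)."""
    return p_value < bonferroni_threshold(alpha, m)
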