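"""Cohort-level signature balancing.

The rank-mean classifier implicitly assumes that, absent grade-related
signal, the two directional probe sets sit at comparable average expression.
On real platforms that assumption can fail: if the up-in-G1 probes are
systematically more expressed than the up-in-G3 probes, their ranks are
inflated in every sample and calls are biased toward low genomic grade.

This module diagnoses that imbalance on a calibration cohort (grand mean
rank of each set = mean over samples of the set's per-sample mean rank) and
rebalances the signature by removing lowly expressed probes from the larger
set.  "Lowly expressed" is operationalised as lowest *cohort mean rank*
(mean over samples of a probe's within-sample rank) — a scale-free criterion
consistent with the method's rank logic.

Calibration is a training-time activity: rebalance once on a reference
cohort, freeze the signature, and classify new samples with it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grading import ExpressionMatrix, classify_matrix
from .signature import GradeSignature

__all__ = [
    "BiasReport",
    "CalibrationResult",
    "cohort_mean_ranks",
    "bias_diagnostic",
    "balance_by_count",
    "balance_to_parity",
]


@dataclass(frozen=True)
class BiasReport:
    """Rank imbalance between the two signature sets over a cohort.

    ``delta = grand_mean_rank_g3set − grand_mean_rank_g1set``; a negative
    delta means the up-in-G1 probes sit higher in the profiles, which biases
    calls toward G1.
    """

    grand_mean_rank_g3set: float
    grand_mean_rank_g1set: float
    delta: float
    call_fraction_g3: float


@dataclass(frozen=True)
class CalibrationResult:
    """A rebalanced signature plus before/after diagnostics."""

    signature: GradeSignature
    removed: tuple[str, ...]  # in removal order
    bias_before: BiasReport
    bias_after: BiasReport
    floor_reached: bool = False


def cohort_mean_ranks(matrix: ExpressionMatrix) -> pd.Series:
    """Per-probe mean (over samples) of the within-sample rank.

    Values lie in [1, n]; a probe that is the highest expressed in every
    sample has cohort mean rank n.
    """
    ranks = rankdata(matrix.frame.to_numpy(dtype=float), method="average", axis=0)
    return pd.Series(ranks.mean(axis=1), index=matrix.frame.index, name="cohort_mean_rank")


def _bias_from_cmr(
    cmr: pd.Series, matrix: ExpressionMatrix, sig: GradeSignature, min_coverage: float
) -> BiasReport:
    present = set(map(str, cmr.index))
    g3 = sorted(sig.g3_up & present)
    g1 = sorted(sig.g1_up & present)
    # grand mean rank of a set == mean of its probes' cohort mean ranks
    # (both are unweighted double averages over the same grid)
    gm3 = float(cmr.loc[g3].mean())
    gm1 = float(cmr.loc[g1].mean())
    calls = classify_matrix(matrix, sig, min_coverage=min_coverage)
    frac_g3 = sum(c.genomic_grade == "G3" for c in calls) / len(calls)
    return BiasReport(
        grand_mean_rank_g3set=gm3,
        grand_mean_rank_g1set=gm1,
        delta=gm3 - gm1,
        call_fraction_g3=frac_g3,
    )


def bias_diagnostic(
    matrix: ExpressionMatrix, sig: GradeSignature, min_coverage: float = 0.5
) -> BiasReport:
    """Measure the signature's rank imbalance on a cohort."""
    cmr = cohort_mean_ranks(matrix)
    return _bias_from_cmr(cmr, matrix, sig, min_coverage)


def _larger_set(sig: GradeSignature) -> str:
    if len(sig.g3_up) > len(sig.g1_up):
        return "g3_up"
    if len(sig.g1_up) > len(sig.g3_up):
        return "g1_up"
    raise ValueError(
        "the two signature sets are equal-sized; choose which set to prune explicitly"
    )


def _removal_order(cmr: pd.Series, probes: frozenset[str]) -> list[str]:
    # lowest cohort mean rank first; ties broken lexicographically by probe id
    present = [p for p in map(str, cmr.index) if p in probes]
    return sorted(present, key=lambda p: (float(cmr.loc[p]), p))


def balance_by_count(
    matrix: ExpressionMatrix,
    sig: GradeSignature,
    k: int,
    min_coverage: float = 0.5,
) -> CalibrationResult:
    """Remove the ``k`` most lowly expressed probes from the larger set.

    Removal order is ascending cohort mean rank with lexicographic
    tie-breaking, so the result is reproducible.  ``k`` must be smaller than
    the larger set's size.
    """
    larger = _larger_set(sig)
    larger_probes: frozenset[str] = getattr(sig, larger)
    if not 0 <= k < len(larger_probes):
        raise ValueError(
            f"k must satisfy 0 <= k < |{larger}| = {len(larger_probes)}, got {k}"
        )
    cmr = cohort_mean_ranks(matrix)
    before = _bias_from_cmr(cmr, matrix, sig, min_coverage)
    removed = _removal_order(cmr, larger_probes)[:k]
    kept = larger_probes - set(removed)
    new_sig = GradeSignature(
        name=f"{sig.name}_balanced",
        g3_up=kept if larger == "g3_up" else sig.g3_up,
        g1_up=kept if larger == "g1_up" else sig.g1_up,
    )
    after = _bias_from_cmr(cmr, matrix, new_sig, min_coverage) if k else before
    return CalibrationResult(
        signature=new_sig, removed=tuple(removed), bias_before=before, bias_after=after
    )


def balance_to_parity(
    matrix: ExpressionMatrix,
    sig: GradeSignature,
    tol: float | None = None,
    min_coverage: float = 0.5,
) -> CalibrationResult:
    """Prune the larger set greedily until the grand mean ranks agree.

    One probe (lowest cohort mean rank) is removed at a time and the grand
    mean ranks recomputed, until ``|delta| <= tol`` or half the larger set's
    original size has been removed (the floor).  ``tol`` defaults to 1% of
    the number of probes on the platform.  Hitting the floor before parity
    returns the result with ``floor_reached=True`` rather than failing.
    """
    n = matrix.n_probes
    if tol is None:
        tol = 0.01 * n
    if tol <= 0:
        raise ValueError("tol must be positive")
    larger = _larger_set(sig)
    larger_probes: frozenset[str] = getattr(sig, larger)
    floor = len(larger_probes) - len(larger_probes) // 2  # keep at least half
    cmr = cohort_mean_ranks(matrix)
    before = _bias_from_cmr(cmr, matrix, sig, min_coverage)
    order = _removal_order(cmr, larger_probes)
    removed: list[str] = []
    current = sig
    report = before
    floor_reached = False
    while abs(report.delta) > tol:
        if len(getattr(current, larger)) <= floor:
            floor_reached = True
            break
        probe = order[len(removed)]
        removed.append(probe)
        kept = larger_probes - set(removed)
        candidate = GradeSignature(
            name=f"{sig.name}_balanced",
            g3_up=kept if larger == "g3_up" else sig.g3_up,
            g1_up=kept if larger == "g1_up" else sig.g1_up,
        )
        new_report = _bias_from_cmr(cmr, matrix, candidate, min_coverage)
        if abs(new_report.delta) > abs(report.delta):
            # pruning the larger set can only raise its grand mean rank; if
            # that moves the sets further apart, stop instead of looping to
            # the floor
            removed.pop()
            break
        current, report = candidate, new_report
    if not removed:
        current = sig
    return CalibrationResult(
        signature=current,
        removed=tuple(removed),
        bias_before=before,
        bias_after=report,
        floor_reached=floor_reached,
    )
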