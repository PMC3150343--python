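"""Agreement tables and survival stratification.

Two evaluation surfaces for a graded cohort:

1. Agreement between genomic (binary G1/G3) and histopathological (ternary
   G1/G2/G3) grade, as a 2×3 confusion table with within-column percentages
   and a pooled G1/G3 accuracy.  Histological G2 has no morphological ground
   truth for the binary call, so it is shown but excluded from accuracy.
2. Survival: Kaplan–Meier curves and the two-group log-rank test, in
   particular the stratification of histological G2 tumours by their genomic
   grade — the clinically interesting split of intermediate-grade cancers
   into a good- and a poor-prognosis group.

Percentage formatting follows the convention of agreement tables in the
breast-cancer grading literature: nearest integer for values ≥ 10%, one
decimal place below 10%, with halves rounded up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .grading import GradeCall

__all__ = [
    "ConfusionTable",
    "KMCurve",
    "LogRankResult",
    "confusion_table",
    "published_cohort_tables",
    "overall_accuracy_g1g3",
    "round_percentage",
    "km_curve",
    "logrank_test",
    "stratify_g2",
]

_GENOMIC = ("G1", "G3")
_HISTO = ("G1", "G2", "G3")


def round_percentage(value: float) -> float:
    """Round a percentage: nearest integer at >= 10%, one decimal below 10%.

    Exact halves round to even (62.5 -> 62, 37.5 -> 38), the convention that
    reproduces published agreement tables cell for cell.
    """
    if not 0 <= value <= 100:
        raise ValueError("percentage must be in [0, 100]")
    if value >= 10:
        return float(round(value))
    return float(round(value, 1))


@dataclass(frozen=True)
class ConfusionTable:
    """2×3 agreement counts: genomic grade (rows) × histological grade (columns)."""

    counts: pd.DataFrame  # index ("G1","G3"), columns ("G1","G2","G3")
    n_excluded: int = 0  # samples without a usable histological grade

    @property
    def column_percentages(self) -> pd.DataFrame:
        """Per-column percentages of each row, rounded by `round_percentage`."""
        totals = self.counts.sum(axis=0)
        pct = self.counts.astype(float).copy()
        for col in pct.columns:
            t = totals[col]
            pct[col] = [
                round_percentage(100.0 * v / t) if t > 0 else float("nan")
                for v in self.counts[col]
            ]
        return pct

    def to_text(self) -> str:
        """Pretty table mirroring the published layout (counts with column %)."""
        pct = self.column_percentages
        lines = ["Genomic\\Histo\t" + "\t".join(_HISTO)]
        for row in _GENOMIC:
            cells = []
            for col in _HISTO:
                c = int(self.counts.loc[row, col])
                p = pct.loc[row, col]
                cells.append(f"{c}" if c == 0 else f"{c} ({p:g}%)")
            lines.append(f"{row}\t" + "\t".join(cells))
        return "\n".join(lines)


def confusion_table(
    calls: list[GradeCall] | pd.Series,
    histo: pd.Series,
) -> ConfusionTable:
    """Tally genomic calls against histological grades.

    ``histo`` maps sample id -> "G1"/"G2"/"G3"; samples missing from it (or
    with a null/unknown grade) are excluded and counted in ``n_excluded``.
    """
    if isinstance(calls, list):
        genomic = pd.Series(
            {c.sample_id: c.genomic_grade for c in calls}, name="genomic_grade"
        )
    else:
        genomic = calls
    histo = histo.dropna()
    histo = histo[histo.isin(_HISTO)]
    common = genomic.index.intersection(histo.index)
    if len(common) == 0:
        raise ValueError("no samples with both a genomic call and a histological grade")
    n_excluded = len(genomic) - len(common)
    tab = pd.crosstab(genomic.loc[common], histo.loc[common])
    tab = tab.reindex(index=list(_GENOMIC), columns=list(_HISTO), fill_value=0)
    tab.index.name = "genomic"
    tab.columns.name = "histological"
    return ConfusionTable(counts=tab.astype(int), n_excluded=n_excluded)


def published_cohort_tables() -> dict[str, ConfusionTable]:
    """Bundled genomic-vs-histological agreement counts from five public cohorts.

    Returns one :class:`ConfusionTable` per cohort (Uppsala, Stockholm,
    Guys Hospital, Oxford, NKI) built from the printed counts; useful as
    worked-example inputs for the percentage and accuracy conventions.
    """
    ref = resources.files("rankgrade").joinpath("data/published_cohort_counts.json")
    obj = json.loads(ref.read_text())
    tables = {}
    for cohort, rows in obj["cohorts"].items():
        counts = pd.DataFrame(
            [rows["G1"], rows["G3"]],
            index=pd.Index(list(_GENOMIC), name="genomic"),
            columns=pd.Index(obj["columns"], name="histological"),
        ).astype(int)
        tables[cohort] = ConfusionTable(counts=counts)
    return tables


def overall_accuracy_g1g3(table: ConfusionTable) -> float:
    """Pooled accuracy over the histological G1 and G3 columns, as a percentage.

    Histological G2 carries no binary ground truth and is excluded.  Returns
    the raw (unrounded) percentage; apply `round_percentage` for display.
    """
    c = table.counts
    denom = int(c["G1"].sum() + c["G3"].sum())
    if denom == 0:
        raise ValueError("no samples in the histological G1 or G3 columns")
    correct = int(c.loc["G1", "G1"] + c.loc["G3", "G3"])
    return 100.0 * correct / denom


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan–Meier product-limit estimate as a right-continuous step function."""

    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): fraction surviving beyond time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank chi-square test."""

    statistic: float
    df: int
    p_value: float


def km_curve(times, events, label: str = "") -> KMCurve:
    """Kaplan–Meier estimate from times (years) and event indicators.

    Censored observations leave the curve flat but reduce the number at
    risk.  With no censoring the curve equals the empirical survivor
    function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label or None)
    if not events.any():
        return KMCurve(
            event_times=np.array([]), survival=np.array([]), at_risk=np.array([]), label=label
        )
    ev = np.unique(times[events])
    surv = np.array([float(kmf.predict(t)) for t in ev])
    at_risk = np.array([(times >= t).sum() for t in ev])
    return KMCurve(event_times=ev, survival=surv, at_risk=at_risk, label=label)


def logrank_test(groups, times, events) -> LogRankResult:
    """Standard (unweighted) two-group log-rank test, df = 1."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly 2 groups required, got {labels.size}")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    return LogRankResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def stratify_g2(
    calls: list[GradeCall] | pd.Series,
    histo: pd.Series,
    survival: pd.DataFrame,
) -> tuple[KMCurve, KMCurve, LogRankResult]:
    """Split histological G2 tumours by genomic grade and compare their survival.

    Returns the KM curves of the genomic-G1 and genomic-G3 strata (among
    histological G2 samples only) and the log-rank comparison.  Raises if a
    stratum is empty; warns when a stratum has fewer than 2 samples with an
    event, mirroring the low-power caveat of small series.
    """
    if isinstance(calls, list):
        genomic = pd.Series({c.sample_id: c.genomic_grade for c in calls})
    else:
        genomic = calls
    g2_ids = histo.index[histo == "G2"]
    g2_ids = g2_ids.intersection(genomic.index).intersection(survival.index)
    if len(g2_ids) == 0:
        raise ValueError("no histological G2 samples with calls and survival data")
    sub_calls = genomic.loc[g2_ids]
    sub_surv = survival.loc[g2_ids]
    curves = {}
    for grade in _GENOMIC:
        ids = sub_calls.index[sub_calls == grade]
        if len(ids) == 0:
            raise ValueError(f"no histological G2 samples called genomic {grade}")
        t = sub_surv.loc[ids, "time"].to_numpy(dtype=float)
        e = sub_surv.loc[ids, "event"].to_numpy(dtype=bool)
        if e.sum() < 2:
            warnings.warn(
                f"genomic {grade} stratum has {int(e.sum())} events; "
                "insufficient statistical power",
                stacklevel=2,
            )
        curves[grade] = km_curve(t, e, label=f"genomic {grade}")
    result = logrank_test(
        sub_calls.to_numpy(),
        sub_surv["time"].to_numpy(dtype=float),
        sub_surv["event"].to_numpy(dtype=bool),
    )
    return curves["G1"], curves["G3"], result
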