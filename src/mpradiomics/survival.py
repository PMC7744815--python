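"""Longitudinal feature-change tests and median-split conversion analysis.

Two-time-point comparisons use the paired two-sample t-test on
baseline-to-follow-up differences.  For conversion-time analysis, subjects
are split at the median baseline level of a feature into high/low groups
(values equal to the median go to the low group, which reproduces a
ceil/floor split of odd cohorts, e.g. 18 high / 19 low at n = 37);
Kaplan-Meier curves with Greenwood-based 95% bands and the two-group
log-rank test compare the conversion experience of the two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedSeries:
    subject_id: str
    baseline_value: float
    followup_value: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_value) and np.isfinite(self.followup_value)):
            raise ValueError("paired values must be finite")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float    # months to conversion or censoring
    event: int     # 1 = converted
    group: str     # "high" | "low"

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("time must be > 0")
        if self.group not in ("high", "low"):
            raise ValueError(f"group must be 'high'/'low', got {self.group!r}")


def paired_change_test(series: list[PairedSeries]) -> dict:
    """Paired t-test on follow-up minus baseline differences.

    Zero-variance differences yield an exact-equality report (no t).
    """
    if len({s.subject_id for s in series}) != len(series):
        raise ValueError("duplicate subject ids in paired series")
    diffs = np.array([s.followup_value - s.baseline_value for s in series])
    n = len(diffs)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    mean_change = float(diffs.mean())
    if diffs.std(ddof=1) == 0:
        log.info("paired_change_test: zero-variance differences (all equal to %g)", mean_change)
        return {"t": None, "df": None, "p": None, "mean_change": mean_change,
                "identical": mean_change == 0.0}
    t, p = stats.ttest_rel(
        [s.followup_value for s in series], [s.baseline_value for s in series]
    )
    return {"t": float(t), "df": n - 1, "p": float(p), "mean_change": mean_change,
            "identical": False}


def median_split(values) -> np.ndarray:
    """Assign 'high' to values strictly above the median, 'low' otherwise.

    The median itself (and any duplicates of it) goes to the low group, so
    an odd cohort splits ceil(n/2) low / floor(n/2) high when values are
    distinct (18 high / 19 low at n = 37).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 values to split")
    if values.std() == 0:
        raise ValueError("all values equal; median split undefined")
    med = float(np.median(values))
    groups = np.where(values > med, "high", "low")
    n_high = int((groups == "high").sum())
    log.info("median_split: median=%g -> %d high / %d low", med, n_high, len(values) - n_high)
    return groups


def km_logrank(records: list[SurvivalRecord], ci_alpha: float = 0.05) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Confidence bands are lifelines' exponential-Greenwood (log-log scale)
    intervals.  Returns per-group survival tables plus the log-rank
    chi-square (1 df) and p-value.
    """
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if df["event"].sum() == 0:
        raise ValueError("no events; survival comparison undefined")
    for g in groups:
        if df.loc[df.group == g, "event"].sum() == 0:
            log.warning("group %r has zero events", g)
    curves = {}
    for g in groups:
        sub = df[df.group == g]
        kmf = KaplanMeierFitter(alpha=ci_alpha)
        kmf.fit(sub["time"], sub["event"], label=g)
        tab = kmf.survival_function_.join(kmf.confidence_interval_)
        tab.columns = ["survival", "ci_lower", "ci_upper"]
        curves[g] = tab
    a, b = groups
    res = logrank_test(
        df.loc[df.group == a, "time"], df.loc[df.group == b, "time"],
        event_observed_A=df.loc[df.group == a, "event"],
        event_observed_B=df.loc[df.group == b, "event"],
    )
    return {
        "curves": curves,
        "chi_square": float(res.test_statistic),
        "p": float(res.p_value),
    }


def survival_records_from_split(
    ids, times, events, baseline_values
) -> list[SurvivalRecord]:
    """Convenience: median-split a feature and build survival records."""
    groups = median_split(baseline_values)
    return [
        SurvivalRecord(subject_id=str(i), time=float(t), event=int(e), group=str(g))
        for i, t, e, g in zip(ids, times, events, groups)
    ]
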