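"""Group comparisons and summary conventions for the study design.

Each animal contributes one tissue sample and each sample several image
volumes, so volume-level metrics are compared between age groups with a
one-way ANOVA in which sample is a nested random factor: the group effect is
tested against between-sample variability, never against the (pseudo-
replicated) between-volume variability.  Sample-level metrics use two-sided
unpaired Student (equal-variance) t-tests, and the non-affinity delta-DV is
tested against zero with a one-sample t-test.  Significance is p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "nested_anova",
    "two_group_tests",
    "one_sample_test",
    "box_summary",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSample:
    """One volume-level observation: which group and sample it came from."""

    group: str
    sample_id: str
    volume_id: str
    value: float


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data[["group", "sample_id", "value"]].copy()
    else:
        df = pd.DataFrame(
            [(d.group, d.sample_id, d.value) for d in data],
            columns=["group", "sample_id", "value"],
        )
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("values must be finite")
    return df


def nested_anova(data) -> dict:
    """One-way ANOVA with sample nested in group as the error stratum.

    Accepts a DataFrame with columns ``group, sample_id, value`` (one row
    per volume) or an iterable of :class:`GroupSample`.  The F statistic is
    MS(group) / MS(sample within group) with degrees of freedom
    ``(g - 1, sum_g (s_g - 1))`` — the expected-mean-squares test, exact for
    balanced designs and the standard approximation otherwise.  For a
    balanced design it coincides with a one-way ANOVA on the per-sample
    means.

    Returns ``{"F_statistic", "p_value", "df", "significant"}``.
    """
    df = _as_frame(data)
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples_per_group = df.groupby("group")["sample_id"].nunique()
    if (samples_per_group < 2).any():
        raise ValueError("each group needs >= 2 samples to identify the nesting")

    grand = df["value"].mean()
    g_stats = df.groupby("group")["value"].agg(["mean", "count"])
    ss_group = float((g_stats["count"] * (g_stats["mean"] - grand) ** 2).sum())

    s_stats = df.groupby(["group", "sample_id"])["value"].agg(["mean", "count"]).reset_index()
    s_stats = s_stats.merge(
        g_stats["mean"].rename("group_mean"), left_on="group", right_index=True
    )
    ss_sample = float((s_stats["count"] * (s_stats["mean"] - s_stats["group_mean"]) ** 2).sum())

    df_group = len(groups) - 1
    df_sample = int((samples_per_group - 1).sum())
    ms_group = ss_group / df_group
    ms_sample = ss_sample / df_sample
    if ms_sample == 0:
        raise ValueError("zero between-sample variability; F undefined")
    F = ms_group / ms_sample
    p = float(sps.f.sf(F, df_group, df_sample))
    return {
        "F_statistic": float(F),
        "p_value": p,
        "df": (df_group, df_sample),
        "significant": p < ALPHA,
    }


def _flag_degenerate(t: float, p: float) -> dict:
    flagged = not np.isfinite(t)
    if flagged:
        # zero within-group variance with unequal means: report the limit
        p = 0.0
    return {"t": float(t), "p": float(p), "significant": p < ALPHA, "flagged": flagged}


def two_group_tests(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided unpaired Student t-test (equal variances pooled)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return {"test": "unpaired Student t", "df": a.size + b.size - 2,
                "t": 0.0, "p": 1.0, "significant": False, "flagged": False}
    t, p = sps.ttest_ind(a, b, equal_var=True)
    out = {"test": "unpaired Student t", "df": a.size + b.size - 2}
    out.update(_flag_degenerate(float(t), float(p)))
    return out


def one_sample_test(values: Sequence[float], popmean: float = 0.0) -> dict:
    """Two-sided one-sample t-test against ``popmean`` (default: the affine
    null delta-DV = 0)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if np.ptp(v) == 0:
        # constant sample: no evidence against the null when equal to it
        if v[0] == popmean:
            return {"test": "one-sample t", "df": v.size - 1, "t": 0.0, "p": 1.0,
                    "significant": False, "flagged": False}
        out = {"test": "one-sample t", "df": v.size - 1}
        out.update(_flag_degenerate(np.sign(v[0] - popmean) * np.inf, 0.0))
        return out
    t, p = sps.ttest_1samp(v, popmean)
    out = {"test": "one-sample t", "df": v.size - 1}
    out.update(_flag_degenerate(float(t), float(p)))
    return out


def box_summary(values: Sequence[float]) -> dict:
    """Box-and-whisker summary: quartiles by linear interpolation, whiskers
    at the min/max of non-outliers, outliers beyond 1.5 IQR from the box."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": np.sort(outliers).tolist(),
    }
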