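"""Scalar statistics supporting the morphometric analyses.

Covers the non-shape inference used across a developmental imaging study:
Mann-Whitney comparisons of volumes and indices per timepoint,
Benjamini-Hochberg discovery screening of the resulting p-value family, a
robust FDR-based outlier screen, Mantel-Haenszel logrank tests on the day a
developmental milestone first appears, and cumulative-incidence step curves.

Milestone records are rows of a tidy table with columns ``specimen_id,
group, milestone, event_day, observed_through``: ``event_day`` is the first
postnatal day the trait was observed, or missing if it never appeared by the
last test day, in which case the animal is censored at ``observed_through``
(testing runs daily from PD1 to PD15 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MilestoneRecord",
    "ScalarTestResult",
    "MILESTONES",
    "mann_whitney",
    "bh_discoveries",
    "rout_outliers",
    "logrank_test",
    "cumulative_incidence",
    "milestone_frame",
]

MILESTONES = (
    "incisor_eruption",
    "eye_opening",
    "tactile_orientation",
    "vibrissae_placing",
    "blast_response",
    "pinna_detachment",
)

EXACT_MW_LIMIT = 12  # combined n at or below which the exact null is enumerated


@dataclass
class MilestoneRecord:
    specimen_id: str
    group: str
    milestone: str
    event_day: int | None  # first day observed; None = never by observed_through
    observed_through: int = 15

    def __post_init__(self) -> None:
        if self.event_day is not None and not 1 <= self.event_day <= self.observed_through:
            raise ValueError(
                f"{self.specimen_id}: event_day {self.event_day} outside "
                f"[1, {self.observed_through}]"
            )


def milestone_frame(records: list[MilestoneRecord]) -> pd.DataFrame:
    """Tidy DataFrame from a list of milestone records."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "group": [r.group for r in records],
            "milestone": [r.milestone for r in records],
            "event_day": pd.array(
                [r.event_day for r in records], dtype="Int64"
            ),
            "observed_through": [r.observed_through for r in records],
        }
    )


@dataclass
class ScalarTestResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    adjusted: bool = False


def mann_whitney(x, y) -> ScalarTestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact null enumeration when the combined sample size is at most 12
    and there are no ties (small experimental groups, where exactness
    matters), otherwise the normal approximation with tie and continuity
    corrections.  The reported statistic is U for the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ScalarTestResult(
        method=f"mann_whitney_{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group={"x": x.size, "y": y.size},
    )


def bh_discoveries(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at FDR rate ``q``.

    Finds the largest rank i with p_(i) <= i * q / m and flags all
    hypotheses with p-value at or below that threshold.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("Q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= thresholds)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        cutoff = sorted_p[passing[-1]]
        flags = p <= cutoff
    return flags


def rout_outliers(values, q: float = 0.01) -> np.ndarray:
    """Simplified univariate (constant-model) ROUT outlier screen.

    Robust center = median; robust spread = MAD scaled to the normal
    (1.4826 x MAD).  Absolute standardized residuals are converted to
    two-sided t-tail p-values (n - 1 df) and tested outside-in with a
    Benjamini-Hochberg threshold at the maximum desired FDR ``q``.  Flags
    are invariant to affine rescaling of the input.  This is the univariate
    reduction of the regression-based ROUT procedure, applied here because
    the screened quantities are single measurement groups.
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 4:
        raise ValueError("ROUT screen requires n >= 4")
    if not 0 < q <= 0.3:
        raise ValueError("Q must lie in (0, 0.3]")
    center = np.median(v)
    mad = np.median(np.abs(v - center))
    if mad > 0.0:
        scale = 1.4826 * mad
    else:
        # degenerate MAD (over half the values at the median): fall back to
        # the mean absolute deviation, likewise scaled to the normal
        scale = 1.2533 * float(np.mean(np.abs(v - center)))
        if scale == 0.0:
            return np.zeros(n, dtype=bool)
    scores = np.abs(v - center) / scale
    p = 2.0 * stats.t.sf(scores, df=n - 1)
    return bh_discoveries(p, q)


def logrank_test(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    milestone: str | None = None,
) -> ScalarTestResult:
    """Mantel-Haenszel logrank test on day of milestone appearance.

    The first day a trait appears is the event; animals with no event by
    their last test day are censored there.  Observed-minus-expected events
    are summed over distinct event days with hypergeometric variance terms;
    the statistic (O-E)^2 / V is chi-squared with 1 df.  Symmetric in the
    two group labels.
    """
    df = records
    if milestone is not None:
        df = df[df["milestone"] == milestone]
    df = df[df["group"].isin([group_a, group_b])]
    if df.empty:
        raise ValueError("no records for the requested groups")
    n_a = int((df["group"] == group_a).sum())
    n_b = int((df["group"] == group_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("a group has zero at-risk animals")

    event_day = df["event_day"].to_numpy(dtype=float)  # NaN when censored
    observed_flag = ~np.isnan(event_day)
    time = np.where(observed_flag, event_day, df["observed_through"].to_numpy(dtype=float))
    in_a = (df["group"] == group_a).to_numpy()
    if not observed_flag.any():
        raise ValueError("no events in the pooled sample")

    o_minus_e = 0.0
    variance = 0.0
    for t in np.unique(time[observed_flag]):
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n_at = int((at_risk & in_a).sum())
        d_t = int((observed_flag & (time == t)).sum())
        d_at = int((observed_flag & (time == t) & in_a).sum())
        if n_t == 0:
            continue
        expected = d_t * n_at / n_t
        o_minus_e += d_at - expected
        if n_t > 1:
            variance += (
                d_t * (n_at / n_t) * (1 - n_at / n_t) * (n_t - d_t) / (n_t - 1)
            )
    if variance == 0.0:
        statistic = 0.0
        p_value = 1.0
    else:
        statistic = o_minus_e**2 / variance
        p_value = float(stats.chi2.sf(statistic, df=1))
    return ScalarTestResult(
        method="logrank_mantel_haenszel",
        statistic=float(statistic),
        p_value=p_value,
        n_per_group={group_a: n_a, group_b: n_b},
    )


def cumulative_incidence(
    records: pd.DataFrame,
    group: str,
    milestone: str | None = None,
) -> pd.DataFrame:
    """Per-day cumulative percentage of a group that achieved a milestone.

    Returns a step table with columns ``day, percent, sem``; the SEM is the
    binomial standard error sqrt(p(1-p)/n) x 100.  The percentage is
    monotone non-decreasing in day.
    """
    df = records
    if milestone is not None:
        df = df[df["milestone"] == milestone]
    df = df[df["group"] == group]
    if df.empty:
        raise ValueError(f"group {group!r} has no records")
    n = len(df)
    last_day = int(df["observed_through"].max())
    event_day = df["event_day"].to_numpy(dtype=float)
    days = np.arange(1, last_day + 1)
    achieved = np.array([np.sum(event_day <= day) for day in days], dtype=float)
    p_hat = achieved / n
    sem = np.sqrt(p_hat * (1 - p_hat) / n) * 100.0
    return pd.DataFrame({"day": days, "percent": p_hat * 100.0, "sem": sem})
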