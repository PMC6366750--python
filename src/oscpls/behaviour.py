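"""Behavioural summaries, group statistics and trial-selection rules.

Covers the per-subject summaries (recognition accuracy, mean correct RT),
the pooled-variance two-sample t test computed from printed group summaries
(means, SDs, ns), the first-half/last-half RT split used as a fatigue
check, the RT > 1 s correct-trial filter feeding the response-locked
analysis, and the 2.5 SD outlier rule.

Conventions: accuracy counts non-responses as incorrect (forced-choice
design; every one of the 204 trials is a response opportunity), and mean RT
is taken over correct trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_subject",
    "summarize_trials",
    "pooled_t",
    "welch_t",
    "split_half_rt",
    "select_response_locked",
    "outlier_flag",
    "group_summary",
]

TRIAL_COLUMNS = ["subject", "group", "trial_index", "condition", "response", "rt_ms"]


def summarize_subject(trials: pd.DataFrame) -> tuple[float, float]:
    """(accuracy %, mean correct RT ms) for one subject's trials.

    Accuracy is 100 * #correct / #trials (all trials are response
    opportunities; non-responses count as incorrect). RT averages correct
    trials only; with zero correct trials the RT is NaN and a warning is
    issued.
    """
    if len(trials) == 0:
        raise ValueError("summarize_subject needs at least one trial")
    correct = trials["response"] == "correct"
    accuracy = 100.0 * correct.sum() / len(trials)
    if correct.any():
        mean_rt = float(trials.loc[correct, "rt_ms"].mean())
    else:
        warnings.warn("subject has zero correct trials; RT undefined", stacklevel=2)
        mean_rt = float("nan")
    return float(accuracy), mean_rt


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject behaviour table: subject, group, accuracy_pct, mean_rt_ms."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns and c != "condition"]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    rows = []
    for (subject, group), sub in trials.groupby(["subject", "group"], sort=False):
        acc, rt = summarize_subject(sub)
        rows.append({"subject": subject, "group": group, "accuracy_pct": acc, "mean_rt_ms": rt})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    infinite: bool = False

    @property
    def t_squared(self) -> float:
        return self.t**2


def pooled_t(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sample t from summary statistics, df = n1+n2-2.

    Degenerate inputs: equal means with both SDs zero give t = 0; unequal
    means with both SDs zero give a signed infinite t, flagged.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if m1 == m2:
            return TTestResult(0.0, df, 1.0)
        t = float(np.inf) if m1 > m2 else float(-np.inf)
        return TTestResult(t, df, 0.0, infinite=True)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def welch_t(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Welch's unequal-variance t from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return pooled_t(m1, sd1, n1, m2, sd2, n2)
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def split_half_rt(trials: pd.DataFrame, n_expected: int = 204) -> tuple[float, float]:
    """Mean correct RT on the first versus the last half of trials.

    The split is strictly by trial index (<= half vs > half). With the full
    204 trials that is the first/last 102; with missing trials the split is
    proportional and a warning is issued.
    """
    n = int(trials["trial_index"].max())
    if len(trials) != n_expected:
        warnings.warn(
            f"expected {n_expected} trials, got {len(trials)}; splitting proportionally",
            stacklevel=2,
        )
    half = n / 2.0
    correct = trials[trials["response"] == "correct"]
    first = correct.loc[correct["trial_index"] <= half, "rt_ms"].mean()
    last = correct.loc[correct["trial_index"] > half, "rt_ms"].mean()
    return float(first), float(last)


def select_response_locked(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Trials entering the response-locked analysis: correct AND rt > 1000 ms
    (strict), so activity during the delay period is never captured.

    Returns the selected subset and the per-subject retained count.
    """
    keep = (trials["response"] == "correct") & (trials["rt_ms"] > 1000.0)
    subset = trials.loc[keep]
    counts = (
        subset.groupby("subject").size().reindex(trials["subject"].unique(), fill_value=0)
    )
    counts.name = "n_response_locked"
    return subset, counts


def outlier_flag(values: np.ndarray | pd.Series, k: float = 2.5) -> np.ndarray:
    """Flag values farther than k sample-SDs from the mean (strict |.| > k*SD).

    Mean and SD (ddof=1) include the candidate value itself, matching the
    screening rule applied within an age group. Zero SD flags nothing. Note
    the rule is insensitive at tiny n: a single extreme value inflates the
    SD enough to shelter itself.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier rule needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


def group_summary(behaviour: pd.DataFrame, groups: list[str] | None = None) -> pd.DataFrame:
    """Mean (SD) of each behavioural measure per group, plus pooled t tests.

    Mirrors the layout of a volumes-and-behaviour summary table: one row per
    group and a trailing block of between-group statistics (t, df, p, t^2)
    per measure.
    """
    measures = [c for c in ("hipp_volume_mm3", "accuracy_pct", "mean_rt_ms") if c in behaviour]
    if groups is None:
        groups = list(pd.unique(behaviour["group"]))
    rows = []
    for g in groups:
        sub = behaviour[behaviour["group"] == g]
        row: dict[str, object] = {"group": g, "n": len(sub)}
        for m in measures:
            row[f"{m}_mean"] = sub[m].mean()
            row[f"{m}_sd"] = sub[m].std(ddof=1)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(groups) == 2:
        g1 = behaviour[behaviour["group"] == groups[0]]
        g2 = behaviour[behaviour["group"] == groups[1]]
        stat_row: dict[str, object] = {"group": f"{groups[0]} vs {groups[1]}", "n": len(g1) + len(g2)}
        for m in measures:
            res = pooled_t(
                g1[m].mean(), g1[m].std(ddof=1), len(g1),
                g2[m].mean(), g2[m].std(ddof=1), len(g2),
            )
            stat_row[f"{m}_mean"] = res.t
            stat_row[f"{m}_sd"] = res.p
        out = pd.concat([out, pd.DataFrame([stat_row])], ignore_index=True)
    return out
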