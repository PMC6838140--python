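"""Behavioral summaries and two-sample group contrasts from summary statistics.

Error rates are per-condition fractions of trials where the recorded action
differs from the condition's correct action. Group contrasts of summary
statistics (n, mean, SD per group) use Student's pooled-variance t by
default and Welch's unequal-variance t on request; both delegate to
``scipy.stats.ttest_ind_from_stats``. SDs are sample SDs (n-1 denominator).

Repeated-measures ANOVA and regression on fitted parameters are outside
this package; tidy per-subject exports are provided for external tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .task import Condition, DataError, TrialRecord

__all__ = ["ConditionSummary", "GroupSummary", "error_rates", "pooled_t", "welch_t",
           "error_rates_frame", "tidy_long"]


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition error rates of one session."""

    rates: dict[Condition, float]
    n_trials: dict[Condition, int]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: size, mean, sample SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def error_rates(trials) -> ConditionSummary:
    """Fraction of trials per condition whose action is not the correct one."""
    counts = {c: 0 for c in Condition}
    errors = {c: 0 for c in Condition}
    for tr in trials:
        c = Condition(tr.condition)
        counts[c] += 1
        if tr.action != c.correct_action:
            errors[c] += 1
    empty = [c.label for c in Condition if counts[c] == 0]
    if empty:
        raise DataError(f"no trials for condition(s): {', '.join(empty)}")
    rates = {c: errors[c] / counts[c] for c in Condition}
    return ConditionSummary(rates=rates, n_trials=counts)


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Student's two-sample t (pooled variance) from summary statistics.

    Returns (t, df) with df = n_a + n_b - 2 and sign mean(a) - mean(b).
    """
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True)
    return float(res.statistic), a.n + b.n - 2


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Welch's unequal-variance t with Welch-Satterthwaite df."""
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df)


# --------------------------------------------------------------------------
# tidy exports
# --------------------------------------------------------------------------

def error_rates_frame(sessions: dict[str, list[TrialRecord]],
                      groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-subject, per-condition error-rate table (long format)."""
    rows = []
    for sid, trials in sessions.items():
        summary = error_rates(trials)
        for cond, rate in summary.rates.items():
            rows.append({
                "subject": sid,
                "group": (groups or {}).get(sid, ""),
                "condition": cond.label,
                "error_rate": rate,
                "n_trials": summary.n_trials[cond],
            })
    return pd.DataFrame(rows)


def tidy_long(frame: pd.DataFrame, id_cols=("subject", "group")) -> pd.DataFrame:
    """Melt a wide per-subject table into (subject, group, measure, value)."""
    value_cols = [c for c in frame.columns if c not in id_cols]
    return frame.melt(id_vars=list(id_cols), value_vars=value_cols,
                      var_name="measure", value_name="value")
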