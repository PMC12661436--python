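"""Operant behavior: reinforcement schedules, cumulative records, press-rate
and discrimination statistics, learning-stage splits, and the two-way
repeated-measures ANOVA with residual-normality reporting.

Schedules
---------
CRF rewards every press; FR(k) rewards every k-th press; VI(mean, jitter)
arms after a Uniform(mean-jitter, mean+jitter) interval and rewards the first
subsequent press, drawing the next interval at the moment of reward (the
first interval is drawn at t=0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_util import normality_gated_paired_test, lilliefors_pvalue

log = logging.getLogger("optoentrain")


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass
class CRF:
    """Continuous reinforcement: every press rewarded."""


@dataclass
class FR:
    """Fixed ratio: every k-th press rewarded."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"FR ratio must be >= 1, got {self.k}")


@dataclass
class VI:
    """Variable interval: first press after a randomized interval rewarded."""

    mean: float  # s
    jitter: float = 0.0  # s; interval ~ Uniform(mean-jitter, mean+jitter)

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.jitter < 0 or self.jitter > self.mean:
            raise ValueError(f"invalid VI parameters mean={self.mean} jitter={self.jitter}")


Schedule = CRF | FR | VI


def run_schedule(schedule: Schedule, press_times: Sequence[float],
                 seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Assign reward times to sorted *press_times* under *schedule*.

    Only VI consumes randomness (*seed*): each reward draws the next arming
    interval Uniform(mean-jitter, mean+jitter) from the reward time; the first
    interval is drawn at t=0.
    """
    presses = np.asarray(press_times, dtype=float)
    if np.any(np.diff(presses) < 0):
        raise ValueError("press_times must be sorted")
    if isinstance(schedule, CRF):
        return presses.copy()
    if isinstance(schedule, FR):
        return presses[schedule.k - 1::schedule.k].copy()
    if isinstance(schedule, VI):
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        lo, hi = schedule.mean - schedule.jitter, schedule.mean + schedule.jitter
        rewards = []
        arm_time = rng.uniform(lo, hi)
        i = 0
        while i < presses.size:
            if presses[i] >= arm_time:
                rewards.append(presses[i])
                arm_time = presses[i] + rng.uniform(lo, hi)
            i += 1
        return np.asarray(rewards)
    raise ValueError(f"unknown schedule {schedule!r}")


def cumulative_record(presses: Sequence[float], rewards: Sequence[float] = (),
                      reset: int = 50) -> pd.DataFrame:
    """Cumulative press count that resets to zero after every *reset* presses.

    Returns a frame with press times, the displayed count (1..reset cycling),
    the number of resets accrued so far, and a reward flag per press.
    """
    presses = np.asarray(presses, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    idx = np.arange(1, presses.size + 1)
    count = (idx - 1) % reset + 1
    resets = idx // reset
    rewarded = np.isin(presses, rewards)
    return pd.DataFrame({"time_s": presses, "count": count,
                         "resets": resets, "rewarded": rewarded})


# ---------------------------------------------------------------------------
# per-trial press rates and discrimination performance
# ---------------------------------------------------------------------------

def press_rate_by_condition(blocks, presses: Sequence[float],
                            alpha: float = 0.05) -> dict:
    """Per-trial press rates (Hz) on opto vs control trials + gated paired test.

    Trials are paired in temporal order within condition; if counts are
    unbalanced the comparison falls back to an unpaired rank-sum with a warning.
    """
    presses = np.asarray(presses, dtype=float)
    rates: dict[bool, list[float]] = {True: [], False: []}
    for b in blocks:
        if b.duration <= 0:
            raise ValueError("zero-duration trial block")
        n = int(np.sum((presses >= b.start) & (presses < b.end)))
        rates[bool(b.opto)].append(n / b.duration)
    opto = np.asarray(rates[True])
    ctrl = np.asarray(rates[False])
    if opto.size != ctrl.size:
        warnings.warn("unbalanced opto/control trial counts; using unpaired rank-sum")
        stat, p = stats.ranksums(opto, ctrl)
        test = "rank_sum"
    else:
        if opto.size < 5:
            raise ValueError("need >= 5 trials per condition")
        test, stat, p = normality_gated_paired_test(opto, ctrl, alpha)
    return {"opto_rates": opto, "control_rates": ctrl, "test_used": test,
            "statistic": stat, "p": p, "significant": p < alpha}


def percent_correct(blocks, presses: Sequence[float],
                    condition_set: Literal["A", "B"]) -> float:
    """Percent correct = 100 * S+ presses / (S+ presses + S- presses).

    Computed within one condition set only (A or B); returns NaN (flagged via
    log) if the set's blocks contain no presses.
    """
    presses = np.asarray(presses, dtype=float)
    splus = sminus = 0
    for b in blocks:
        if not b.type.endswith(condition_set):
            continue
        n = int(np.sum((presses >= b.start) & (presses < b.end)))
        if b.type.startswith("S+"):
            splus += n
        elif b.type.startswith("S-"):
            sminus += n
    total = splus + sminus
    if total == 0:
        log.warning("percent_correct undefined: no presses in condition set %s", condition_set)
        return float("nan")
    return 100.0 * splus / total


def stage_split(days: Sequence) -> dict[str, list]:
    """Split training days into first / middle / last seven-day stages.

    First and last stages are the first and last 7 days; the middle stage is
    the 7 days centered on the median training day. Requires >= 21 days so the
    stages cannot overlap.
    """
    days = sorted(days)
    n = len(days)
    if n < 21:
        raise ValueError(f"need >= 21 training days for non-overlapping stages, got {n}")
    mid = (n - 1) // 2
    return {"first": days[:7], "middle": days[mid - 3: mid + 4], "last": days[-7:]}


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """F/df/p per effect of a two-way within-design ANOVA."""

    effects: dict = field(default_factory=dict)  # name -> dict(F, df1, df2, p)
    residual_normality_p: float = float("nan")

    def f(self, name: str) -> float:
        return self.effects[name]["F"]

    def p(self, name: str) -> float:
        return self.effects[name]["p"]


def _f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> dict:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else float("inf")
    p = float(stats.f.sf(F, df_eff, df_err))
    return {"F": float(F), "df1": df_eff, "df2": df_err, "p": p}


def rm_anova_2way(table: pd.DataFrame, dv: str = "percent_correct",
                  condition: str = "condition", day: str = "day",
                  subject: str = "subject",
                  unit: Literal["day", "subject"] = "day") -> AnovaResult:
    """Repeated-measures ANOVA for condition x day performance tables.

    ``unit="day"`` (default) averages over subjects and treats days as the
    paired replication unit, giving the condition effect F(1, n_days-1); the
    day and interaction effects are not estimable in this design and are
    returned as NaN. ``unit="subject"`` runs the full two-way within-subject
    ANOVA (both factors within), testing each effect against its
    effect-by-subject interaction. A Lilliefors test on the conditional
    residuals is reported alongside.
    """
    cols = [subject, day, condition]
    counts = table.groupby(cols, observed=True)[dv].count()
    n_cells = int(np.prod([table[c].nunique() for c in cols]))
    if counts.empty or (counts != 1).any() or len(counts) != n_cells:
        raise ValueError("design must be complete and balanced with one value per cell")

    if unit == "day":
        cell = table.groupby([day, condition], observed=True)[dv].mean().unstack(condition)
        if cell.isna().any().any() or cell.shape[1] != 2:
            raise ValueError("need exactly 2 conditions with every day present")
        y = cell.to_numpy()  # days x 2
        D = y.shape[0]
        gm = y.mean()
        cond_means = y.mean(axis=0)
        day_means = y.mean(axis=1)
        ss_cond = D * float(np.sum((cond_means - gm) ** 2))
        resid = y - day_means[:, None] - cond_means[None, :] + gm
        ss_err = float(np.sum(resid ** 2))
        eff = {"condition": _f_test(ss_cond, 1, ss_err, D - 1),
               "day": {"F": float("nan"), "df1": None, "df2": None, "p": float("nan")},
               "interaction": {"F": float("nan"), "df1": None, "df2": None, "p": float("nan")}}
        norm_p = lilliefors_pvalue(resid.ravel())
        return AnovaResult(eff, norm_p)

    # full two-way within-subject design
    pivot = table.pivot_table(index=subject, columns=[condition, day], values=dv)
    subjects = pivot.index
    conds = pivot.columns.get_level_values(0).unique()
    days_lv = pivot.columns.get_level_values(1).unique()
    S, C, D = len(subjects), len(conds), len(days_lv)
    y = pivot.to_numpy().reshape(S, C, D)
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_c = y.mean(axis=(0, 2))
    m_d = y.mean(axis=(0, 1))
    m_sc = y.mean(axis=2)
    m_sd = y.mean(axis=1)
    m_cd = y.mean(axis=0)

    ss_c = S * D * float(np.sum((m_c - gm) ** 2))
    ss_d = S * C * float(np.sum((m_d - gm) ** 2))
    ss_cd = S * float(np.sum((m_cd - m_c[:, None] - m_d[None, :] + gm) ** 2))
    ss_sc = D * float(np.sum((m_sc - m_s[:, None] - m_c[None, :] + gm) ** 2))
    ss_sd = C * float(np.sum((m_sd - m_s[:, None] - m_d[None, :] + gm) ** 2))
    resid = (y - m_sc[:, :, None] - m_sd[:, None, :] - m_cd[None, :, :]
             + m_s[:, None, None] + m_c[None, :, None] + m_d[None, None, :] - gm)
    ss_scd = float(np.sum(resid ** 2))

    eff = {
        "condition": _f_test(ss_c, C - 1, ss_sc, (C - 1) * (S - 1)),
        "day": _f_test(ss_d, D - 1, ss_sd, (D - 1) * (S - 1)),
        "interaction": _f_test(ss_cd, (C - 1) * (D - 1), ss_scd, (C - 1) * (D - 1) * (S - 1)),
    }
    norm_p = lilliefors_pvalue(resid.ravel())
    return AnovaResult(eff, norm_p)
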