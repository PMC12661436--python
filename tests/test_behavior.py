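"""Schedule engine, cumulative records, behavior statistics, rm-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import optoentrain as oe


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def test_crf_rewards_equal_presses():
    presses = np.array([1.0, 2.5, 7.0])
    assert np.array_equal(oe.run_schedule(oe.CRF(), presses), presses)


def test_fr_floor_semantics():
    assert oe.run_schedule(oe.FR(10), np.arange(1.0, 36.0)).size == 3
    assert np.array_equal(oe.run_schedule(oe.FR(10), np.arange(1.0, 36.0)),
                          [10.0, 20.0, 30.0])


def test_vi_deterministic_trace_jitter_zero():
    rewards = oe.run_schedule(oe.VI(30.0, 0.0), np.arange(1.0, 301.0), seed=0)
    assert rewards.size == 10
    assert np.all(np.diff(rewards) == 30.0)


def test_unknown_schedule_rejected():
    with pytest.raises(ValueError):
        oe.run_schedule("VI30", np.array([1.0]))
    with pytest.raises(ValueError):
        oe.VI(30.0, 40.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), mean=st.floats(5.0, 60.0), jitter=st.floats(0.0, 5.0))
def test_schedule_conservation_property(seed, mean, jitter):
    rng = np.random.default_rng(seed)
    presses = np.sort(rng.uniform(0, 600, rng.poisson(120)))
    rewards = oe.run_schedule(oe.VI(mean, min(jitter, mean)), presses, seed=seed)
    assert rewards.size <= presses.size
    assert set(rewards).issubset(set(presses))
    assert rewards.size <= 600 / max(mean - jitter, 1e-9) + 1


# ---------------------------------------------------------------------------
# cumulative record
# ---------------------------------------------------------------------------

def test_cumulative_record_resets():
    rec = oe.cumulative_record(np.arange(120.0), reset=50)
    assert rec["resets"].iloc[-1] == 2
    assert rec["count"].max() == 50
    assert list(rec["count"][48:52]) == [49, 50, 1, 2]


def test_cumulative_record_empty():
    rec = oe.cumulative_record(np.array([]))
    assert len(rec) == 0


def test_cumulative_record_slope_is_press_rate():
    presses = np.arange(0, 100, 2.0)  # steady 0.5 Hz
    rec = oe.cumulative_record(presses, reset=1000)
    window = rec[(rec.time_s >= 20) & (rec.time_s < 60)]
    slope = (window["count"].iloc[-1] - window["count"].iloc[0]) / (
        window.time_s.iloc[-1] - window.time_s.iloc[0])
    assert slope == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# press rate by condition
# ---------------------------------------------------------------------------

def _trial_session(rate_opto, rate_ctrl, n_trials=30, seed=0):
    rng = np.random.default_rng(seed)
    blocks, presses = [], []
    t = 0.0
    for i in range(n_trials):
        opto = i % 2 == 0
        r = rate_opto if opto else rate_ctrl
        blocks.append(oe.TrialBlock("plain", t, t + 60.0, opto))
        presses.append(np.sort(rng.uniform(t, t + 60.0, rng.poisson(60.0 * r))))
        t += 62.0
    return blocks, np.concatenate(presses)


def test_press_rate_null_no_effect():
    hits = 0
    for seed in range(60):
        blocks, presses = _trial_session(0.3, 0.3, seed=seed)
        res = oe.press_rate_by_condition(blocks, presses)
        hits += res["significant"]
    assert hits <= 9  # ~alpha of 60


def test_press_rate_halved_detected():
    blocks, presses = _trial_session(0.15, 0.3, seed=1)
    res = oe.press_rate_by_condition(blocks, presses)
    assert res["significant"]
    assert res["opto_rates"].mean() < res["control_rates"].mean()


def test_zero_duration_trial_rejected():
    with pytest.raises(ValueError):
        oe.press_rate_by_condition([oe.TrialBlock("plain", 1.0, 1.0, False)],
                                   np.array([]))


# ---------------------------------------------------------------------------
# percent correct
# ---------------------------------------------------------------------------

def test_percent_correct_arithmetic():
    blocks = [oe.TrialBlock("S+B", 0, 100), oe.TrialBlock("S-B", 100, 200)]
    presses = np.concatenate([np.linspace(1, 99, 120), np.linspace(101, 199, 40)])
    assert oe.percent_correct(blocks, np.sort(presses), "B") == pytest.approx(75.0)


def test_percent_correct_all_splus():
    blocks = [oe.TrialBlock("S+A", 0, 100), oe.TrialBlock("S-A", 100, 200)]
    assert oe.percent_correct(blocks, np.linspace(1, 99, 10), "A") == 100.0


def test_percent_correct_scaling_invariance():
    blocks = [oe.TrialBlock("S+B", 0, 100), oe.TrialBlock("S-B", 100, 200)]
    p1 = np.concatenate([np.linspace(1, 99, 30), np.linspace(101, 199, 10)])
    p3 = np.concatenate([np.linspace(1, 99, 90), np.linspace(101, 199, 30)])
    assert oe.percent_correct(blocks, np.sort(p1), "B") == pytest.approx(
        oe.percent_correct(blocks, np.sort(p3), "B"))


def test_percent_correct_no_presses_nan():
    blocks = [oe.TrialBlock("S+A", 0, 10), oe.TrialBlock("S-A", 10, 20)]
    assert np.isnan(oe.percent_correct(blocks, np.array([]), "A"))


# ---------------------------------------------------------------------------
# stage split
# ---------------------------------------------------------------------------

def test_stage_split_exact_partition():
    s = oe.stage_split(range(1, 22))
    assert s["first"] == list(range(1, 8))
    assert s["middle"] == list(range(8, 15))
    assert s["last"] == list(range(15, 22))


def test_stage_split_centering_25_days():
    s = oe.stage_split(range(1, 26))
    assert s["middle"] == list(range(10, 17))


def test_stage_split_too_few_days():
    with pytest.raises(ValueError):
        oe.stage_split(range(1, 21))


# ---------------------------------------------------------------------------
# rm-ANOVA
# ---------------------------------------------------------------------------

def _fixture_table(seed=0, effect=5.0, n_subj=4, n_days=3):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        subj_off = rng.normal(0, 2)
        for d in range(n_days):
            for c, add in (("control", 0.0), ("opto", effect)):
                rows.append((f"s{s}", d, c, 55 + 2 * d + subj_off + add + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["subject", "day", "condition", "percent_correct"])


def test_rm_anova_matches_brute_force_sums_of_squares():
    """F values equal the definitional SS decomposition computed from scratch."""
    df = _fixture_table()
    res = oe.rm_anova_2way(df, unit="subject")

    y = df.pivot_table(index="subject", columns=["condition", "day"],
                       values="percent_correct").to_numpy().reshape(4, 2, 3)
    gm = y.mean()
    # brute force: explicit loops over the definitional sums of squares
    ss_c = sum((y[:, c, :].mean() - gm) ** 2 for c in range(2)) * 4 * 3
    ss_sc = sum((y[s, c, :].mean() - y[s].mean() - y[:, c, :].mean() + gm) ** 2
                for s in range(4) for c in range(2)) * 3
    F_cond = (ss_c / 1) / (ss_sc / 3)
    assert res.f("condition") == pytest.approx(F_cond, rel=1e-10)

    ss_d = sum((y[:, :, d].mean() - gm) ** 2 for d in range(3)) * 4 * 2
    ss_sd = sum((y[s, :, d].mean() - y[s].mean() - y[:, :, d].mean() + gm) ** 2
                for s in range(4) for d in range(3)) * 2
    F_day = (ss_d / 2) / (ss_sd / 6)
    assert res.f("day") == pytest.approx(F_day, rel=1e-10)


def test_rm_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    df = _fixture_table(seed=3)
    res = oe.rm_anova_2way(df, unit="subject")
    ref = pg.rm_anova(df, dv="percent_correct", within=["condition", "day"],
                      subject="subject", detailed=True)
    for name, src in (("condition", "condition"), ("day", "day"),
                      ("interaction", "condition * day")):
        assert res.f(name) == pytest.approx(
            float(ref.loc[ref.Source == src, "F"].iloc[0]), rel=1e-9)


def test_rm_anova_day_unit_equals_paired_t_squared():
    from scipy import stats
    df = _fixture_table(seed=4, n_subj=5, n_days=7)
    res = oe.rm_anova_2way(df, unit="day")
    cell = df.groupby(["day", "condition"])["percent_correct"].mean().unstack()
    t, p = stats.ttest_rel(cell["opto"], cell["control"])
    assert res.f("condition") == pytest.approx(t**2, rel=1e-9)
    assert res.p("condition") == pytest.approx(p, rel=1e-9)
    assert res.effects["condition"]["df1"] == 1
    assert res.effects["condition"]["df2"] == 6  # the printed F(1,6) design
    assert np.isnan(res.f("day"))


def test_rm_anova_rejects_incomplete_design():
    df = _fixture_table().iloc[:-1]
    with pytest.raises(ValueError):
        oe.rm_anova_2way(df, unit="subject")


def test_rm_anova_condition_f_increases_with_effect():
    med = []
    for eff in (0.0, 5.0, 10.0, 15.0):
        fs = []
        for seed in range(25):
            recipe = oe.LearningRecipe(opto_effect={"first": eff, "middle": 0, "last": 0},
                                       session_noise_sd=3.0)
            df = oe.simulate_discrimination_course(recipe, seed=seed)
            sub = df[df.day <= 7]
            fs.append(oe.rm_anova_2way(sub, unit="day").f("condition"))
        med.append(np.median(fs))
    assert med[0] < med[1] < med[2] < med[3]


def test_end_to_end_stage_specific_recovery():
    """First-stage-only opto effect: significant early, ns late (most seeds)."""
    ok = 0
    n = 40
    for seed in range(n):
        df = oe.simulate_discrimination_course(oe.LearningRecipe(), seed=seed)
        stages = oe.stage_split(sorted(df.day.unique()))
        first = oe.rm_anova_2way(df[df.day.isin(stages["first"])], unit="day")
        last = oe.rm_anova_2way(df[df.day.isin(stages["last"])], unit="day")
        ok += (first.p("condition") < 0.05) and (last.p("condition") >= 0.05)
    assert ok >= 0.8 * n
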