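"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

import optoentrain as oe


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f, n_expected, width", [(40.0, 40, 0.0125), (5.0, 5, 0.1)])
def test_pulse_train_arithmetic(f, n_expected, width):
    pt = oe.make_pulse_train(f, 0.5, 1.0, 0.0)
    assert pt.n_pulses == n_expected
    assert np.allclose(pt.offsets - pt.onsets, width)
    assert pt.onsets[0] == 0.0
    pt.validate()


def test_pulse_train_too_short_rejected():
    with pytest.raises(ValueError):
        oe.make_pulse_train(40.0, 0.5, 0.01)
    with pytest.raises(ValueError):
        oe.make_pulse_train(-5.0, 0.5, 1.0)
    with pytest.raises(ValueError):
        oe.make_pulse_train(40.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

def _onoff_rates(spikes, stim):
    on = off = 0
    t = spikes.times
    for a, b in zip(stim.onsets, stim.offsets):
        on += np.sum((t >= a) & (t < b))
        off += np.sum((t >= b) & (t < a + stim.period))
    dur_on = np.sum(stim.offsets - stim.onsets)
    dur_off = stim.n_pulses * stim.period - dur_on
    return on / dur_on, off / dur_off


def test_excited_on_rates_recovered(stim40):
    st = oe.simulate_unit(oe.UnitArchetype("excited_on", 5.0, 20.0), stim40, 100.0, seed=1)
    r_on, r_off = _onoff_rates(st, stim40)
    # Poisson SE on 50 s of data at 25 / 5 Hz
    assert abs(r_on - 25.0) < 3 * np.sqrt(25.0 / 50.0)
    assert abs(r_off - 5.0) < 3 * np.sqrt(5.0 / 50.0)


def test_full_suppression_silences_light_on(stim40):
    st = oe.simulate_unit(oe.UnitArchetype("inhibited", 20.0, suppression=1.0),
                          stim40, 100.0, seed=2)
    t = st.times
    for a, b in zip(stim40.onsets, stim40.offsets):
        assert not np.any((t >= a) & (t < b))


def test_onset_weighted_excitation_preserves_mean_rate(stim40):
    st = oe.simulate_unit(oe.UnitArchetype("excited_on", 5.0, 20.0, onset_tau=0.003),
                          stim40, 100.0, seed=3)
    r_on, _ = _onoff_rates(st, stim40)
    assert abs(r_on - 25.0) < 3 * np.sqrt(25.0 / 50.0)


def test_rebound_unit_fires_after_offsets(stim40):
    arch = oe.UnitArchetype("rebound", 2.0, suppression=1.0,
                            rebound_rate=40.0, rebound_window=0.00625)
    st = oe.simulate_unit(arch, stim40, 100.0, seed=4)
    phases = oe.phases_during_stim(st, stim40)
    # light-off half-cycle is [pi, 2pi); nearly all spikes should be there
    assert np.mean(phases >= np.pi) > 0.9


def test_md_biphasic_transient_vs_sustained(train_stim40):
    arch = oe.UnitArchetype("md_biphasic", 10.0, gain=15.0, suppression=1.0,
                            transient_inhib_window=0.1)
    st = oe.simulate_unit(arch, train_stim40, 85.0, seed=5)
    spans = oe.group_pulse_trains(train_stim40)
    t = st.times
    trans = sum(np.sum((t >= a) & (t < a + 0.1)) for a, _ in spans)
    rest = sum(np.sum((t >= a + 0.1) & (t < b)) for a, b in spans)
    assert trans == 0  # fully suppressed in the first 100 ms
    assert rest / (0.9 * len(spans)) > 15.0  # elevated for the remainder


def test_unmodulated_rayleigh_p_uniform(stim40):
    """Null phases from an unmodulated Poisson unit give Uniform(0,1) Rayleigh p."""
    pvals = []
    for seed in range(200):
        st = oe.simulate_unit(oe.UnitArchetype("unmodulated", 10.0), stim40, 100.0, seed=seed)
        phases = oe.phases_during_stim(st, stim40)
        pvals.append(oe.rayleigh_test(phases)[2])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_unit_generator_deterministic(stim40):
    a = oe.simulate_unit(oe.UnitArchetype("excited_on", 5, 20), stim40, 100.0, seed=42)
    b = oe.simulate_unit(oe.UnitArchetype("excited_on", 5, 20), stim40, 100.0, seed=42)
    assert np.array_equal(a.times, b.times)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def test_entrained_lfp_psd_peak_at_stim_freq():
    stim = oe.make_pulse_train(40.0, 0.5, 30.0)
    recipe = oe.LfpRecipe(pink_noise_sd=0.5, entrain_amp=1.0)
    sig, comps = oe.simulate_lfp(recipe, stim, None, 1000.0, 30.0, seed=0)
    epochs, kept, _ = oe.epoch_and_reject(sig)
    freqs, spec = oe.psd(epochs[kept], sig.rate)
    inband = (freqs >= 5) & (freqs <= 100)
    assert freqs[inband][np.argmax(spec[inband])] == 40.0
    assert set(comps) == {"pink", "entrain", "gamma", "artifacts"}


def test_gamma_gate_amplitude_ratio_squares_in_power():
    states = [("high", 0.0, 150.0), ("low", 150.0, 300.0)]
    recipe = oe.LfpRecipe(pink_noise_sd=0.0, gamma_burst_amp=1.0, gamma_freq=50.0,
                          behavior_gate={"high": 2.0, "low": 1.0})
    sig, comps = oe.simulate_lfp(recipe, None, states, 200.0, 300.0, seed=1)
    epochs, kept, centers = oe.epoch_and_reject(sig)
    powers = oe.epoch_band_powers(epochs, sig.rate)
    hi = powers[centers < 150].mean()
    lo = powers[centers >= 150].mean()
    assert 3.0 < hi / lo < 5.0  # 2:1 amplitude -> 4:1 power


def test_zero_amplitude_recipe_gives_zero_signal():
    recipe = oe.LfpRecipe(pink_noise_sd=0.0)
    sig, comps = oe.simulate_lfp(recipe, None, None, 200.0, 5.0, seed=0)
    assert np.all(sig.samples == 0.0)


def test_lfp_nyquist_guard():
    stim = oe.make_pulse_train(40.0, 0.5, 2.0)
    with pytest.raises(ValueError):
        oe.simulate_lfp(oe.LfpRecipe(entrain_amp=1.0), stim, None, 100.0, 2.0, seed=0)


def test_lfp_deterministic():
    recipe = oe.LfpRecipe(pink_noise_sd=1.0, gamma_burst_amp=0.5)
    a, _ = oe.simulate_lfp(recipe, None, None, 200.0, 10.0, seed=9)
    b, _ = oe.simulate_lfp(recipe, None, None, 200.0, 10.0, seed=9)
    assert np.array_equal(a.samples, b.samples)


def test_artifacts_present_when_requested():
    recipe = oe.LfpRecipe(pink_noise_sd=0.0, artifact_rate=0.5, artifact_amp=10.0)
    sig, comps = oe.simulate_lfp(recipe, None, None, 200.0, 60.0, seed=2)
    assert np.abs(comps["artifacts"]).max() > 5.0


# ---------------------------------------------------------------------------
# operant sessions and trial sequences
# ---------------------------------------------------------------------------

def test_crf_rewards_every_press():
    ev = oe.simulate_operant_session(oe.CRF(), 0.2, 300.0, seed=0)
    assert np.array_equal(ev.presses, ev.rewards)


def test_fr10_reward_count():
    presses = np.linspace(1, 35, 35)
    assert oe.run_schedule(oe.FR(10), presses).size == 3


def test_vi30_deterministic_trace():
    presses = np.arange(1.0, 301.0)
    rewards = oe.run_schedule(oe.VI(30.0, 0.0), presses, seed=0)
    assert rewards.size == 10
    assert np.all(np.abs(np.diff(rewards) - 30.0) <= 1.0)


def test_trial_sequence_counts_runs_and_determinism():
    types = ("S+A", "S-A", "S+B", "S-B")
    blocks = oe.make_trial_sequence(60, types, max_run=3, seed=11)
    kinds = [b.type for b in blocks]
    for tp in types:
        assert kinds.count(tp) == 15
    # exact equalization of total time per type
    tot = {tp: sum(b.duration for b in blocks if b.type == tp) for tp in types}
    assert max(tot.values()) - min(tot.values()) < 1e-9
    again = oe.make_trial_sequence(60, types, max_run=3, seed=11)
    assert [b.type for b in again] == kinds
    assert all(b.opto == (b.type.endswith("A")) for b in blocks)


def test_trial_sequence_run_length_property():
    types = ("S+A", "S-A", "S+B", "S-B")
    for seed in range(2000):
        kinds = [b.type for b in oe.make_trial_sequence(16, types, max_run=3, seed=seed)]
        run = 1
        for a, b in zip(kinds, kinds[1:]):
            run = run + 1 if a == b else 1
            assert run <= 3


def test_trial_sequence_infeasible_rejected():
    with pytest.raises(ValueError):
        oe.make_trial_sequence(60, ("S+A", "S-A"), max_run=0, seed=0)
    with pytest.raises(ValueError):
        oe.make_trial_sequence(61, ("S+A", "S-A"), max_run=3, seed=0)


# ---------------------------------------------------------------------------
# discrimination course
# ---------------------------------------------------------------------------

def test_null_learning_course_has_no_condition_effect():
    recipe = oe.LearningRecipe(n_subjects=20, opto_effect={"first": 0, "middle": 0, "last": 0})
    df = oe.simulate_discrimination_course(recipe, seed=3)
    piv = df.pivot_table(index="subject", columns="condition", values="percent_correct")
    t, p = stats.ttest_rel(piv["opto"], piv["control"])
    assert p > 0.05


def test_flat_chance_course_sits_at_fifty():
    recipe = oe.LearningRecipe(asymptote=50.0, slope=0.0, session_noise_sd=0.0,
                               opto_effect={"first": 0, "middle": 0, "last": 0})
    df = oe.simulate_discrimination_course(recipe, seed=0)
    assert np.allclose(df["percent_correct"], 50.0)


def test_course_respects_bounds_and_balance():
    df = oe.simulate_discrimination_course(oe.LearningRecipe(), seed=5)
    assert df["percent_correct"].between(0, 100).all()
    counts = df.groupby(["subject", "day"])["condition"].count()
    assert (counts == 2).all()
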