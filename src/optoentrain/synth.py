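"""Synthetic session generator with known ground truth.

Emulates the statistical structure the analysis stages assume: units excited,
inhibited or rebound-activated by 5-40 Hz, 50%-duty pulse trains
(inhomogeneous-Poisson spiking via exact thinning); LFPs built from 1/f
background plus a stimulation-locked oscillation (with a decaying harmonic
series so the 2f spike-field harmonic is reproducible) and behavior-gated
gamma bursts; VI/FR operant sessions; and multi-day discrimination-learning
courses with a stage-specific optogenetic effect. Every generator is a pure
function of (parameters, seed), and composite signals are returned together
with their ground-truth components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import behavior
from .session import (ContinuousSignal, EventSeries, PulseTrain, Session,
                      SpikeTrain, TrialBlock)
from .stim_response import group_pulse_trains

STIM_FREQS = (5.0, 10.0, 20.0, 30.0, 40.0)  # Hz, protocol frequencies
DUTY = 0.5


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------

def make_pulse_train(f: float, duty: float, duration: float, t0: float = 0.0) -> PulseTrain:
    """Periodic pulse train: onsets every 1/f from *t0*, on-width duty/f."""
    if f <= 0 or duty <= 0 or duty > 1:
        raise ValueError(f"invalid pulse parameters f={f}, duty={duty}")
    n = int(np.floor(f * duration + 1e-9))
    if n < 1:
        raise ValueError(f"duration {duration}s holds no complete pulse at {f} Hz")
    onsets = t0 + np.arange(n) / f
    return PulseTrain(onsets, onsets + duty / f, f, duty)


def make_train_sequence(f: float, duty: float = DUTY, train_dur: float = 1.0,
                        n_trains: int = 10, gap: float = 3.0,
                        t0: float = 0.0) -> PulseTrain:
    """*n_trains* pulse trains of *train_dur* s separated by *gap* s pauses."""
    ons, offs = [], []
    t = t0
    for _ in range(n_trains):
        pt = make_pulse_train(f, duty, train_dur, t)
        ons.append(pt.onsets)
        offs.append(pt.offsets)
        t += train_dur + gap
    return PulseTrain(np.concatenate(ons), np.concatenate(offs), f, duty)


# ---------------------------------------------------------------------------
# spiking units
# ---------------------------------------------------------------------------

@dataclass
class UnitArchetype:
    """Ground-truth firing model of one simulated unit.

    kinds: excited_on (baseline + gain while the light is on), inhibited
    (baseline * (1 - suppression) while on), rebound (inhibited while on plus
    rebound_rate for rebound_window after each offset), md_biphasic
    (suppressed for the first transient_inhib_window of each stimulation
    train, then baseline + gain for the rest of the train), unmodulated.

    onset_tau (s, excited_on only): when set, the light-on rate increment is
    exponentially onset-weighted, gain * c * exp(-(t-onset)/tau) with c chosen
    so the mean on-rate stays baseline + gain — short-latency ChR2-driven
    onset firing rather than a flat boxcar.
    """

    kind: str = "unmodulated"
    baseline_rate: float = 5.0  # Hz
    gain: float = 20.0  # Hz added during light-on
    suppression: float = 1.0  # fraction of baseline removed during light-on
    rebound_rate: float = 40.0  # Hz added during the rebound window
    rebound_window: float = 0.00625  # s after each light offset
    transient_inhib_window: float = 0.1  # s (md_biphasic)
    onset_tau: float | None = None  # s (excited_on)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.gain < 0 or self.rebound_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.suppression <= 1:
            raise ValueError(f"suppression must be in [0,1], got {self.suppression}")
        if self.rebound_window < 0 or self.transient_inhib_window < 0:
            raise ValueError("windows must be >= 0")
        known = {"excited_on", "inhibited", "rebound", "md_biphasic", "unmodulated"}
        if self.kind not in known:
            raise ValueError(f"unknown archetype kind {self.kind!r}")


def _rate_function(arch: UnitArchetype, stim: PulseTrain | None):
    """Return (rate_fn(times)->Hz, rate_max) for thinning."""
    base = arch.baseline_rate
    if arch.kind == "unmodulated" or stim is None or stim.n_pulses == 0:
        return (lambda t: np.full(np.asarray(t).size, base)), max(base, 1e-12)

    onsets, offsets = stim.onsets, stim.offsets
    if arch.kind == "md_biphasic":
        trains = np.asarray(group_pulse_trains(stim))

    def fn(t):
        t = np.asarray(t, dtype=float)
        r = np.full(t.size, base)
        i = np.searchsorted(onsets, t, side="right") - 1
        has = i >= 0
        ii = np.clip(i, 0, None)
        in_on = has & (t < offsets[ii])
        if arch.kind == "excited_on":
            if arch.onset_tau:
                w = float(np.mean(offsets - onsets))
                tau = arch.onset_tau
                c = w / (tau * (1.0 - np.exp(-w / tau)))
                dt = t - onsets[ii]
                r = np.where(in_on, base + arch.gain * c * np.exp(-dt / tau), r)
            else:
                r = np.where(in_on, base + arch.gain, r)
        elif arch.kind == "inhibited":
            r = np.where(in_on, base * (1 - arch.suppression), r)
        elif arch.kind == "rebound":
            r = np.where(in_on, base * (1 - arch.suppression), r)
            in_reb = has & ~in_on & (t >= offsets[ii]) & (t < offsets[ii] + arch.rebound_window)
            r = np.where(in_reb, base + arch.rebound_rate, r)
        elif arch.kind == "md_biphasic":
            j = np.searchsorted(trains[:, 0], t, side="right") - 1
            jj = np.clip(j, 0, None)
            in_train = (j >= 0) & (t < trains[jj, 1])
            in_trans = in_train & (t < trains[jj, 0] + arch.transient_inhib_window)
            r = np.where(in_train, base + arch.gain, r)
            r = np.where(in_trans, base * (1 - arch.suppression), r)
        return r

    peak = base + arch.gain
    if arch.kind == "excited_on" and arch.onset_tau:
        w = float(np.mean(stim.offsets - stim.onsets))
        tau = arch.onset_tau
        peak = base + arch.gain * w / (tau * (1.0 - np.exp(-w / tau)))
    rmax = max(base, peak if arch.kind in ("excited_on", "md_biphasic") else base,
               base + arch.rebound_rate if arch.kind == "rebound" else 0.0)
    return fn, max(rmax, 1e-12)


def simulate_unit(arch: UnitArchetype, stim: PulseTrain | None, duration: float,
                  seed, unit_id: str = "sim", region: str = "other") -> SpikeTrain:
    """Inhomogeneous-Poisson spike train via exact thinning of the rate model."""
    if stim is not None and stim.n_pulses and stim.offsets[-1] > duration + 1e-9:
        raise ValueError("duration does not cover the stimulation train")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fn, rmax = _rate_function(arch, stim)
    n = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    rates = fn(cand)
    if np.any(rates < 0):
        raise ValueError("negative instantaneous rate")
    keep = rng.uniform(0.0, rmax, n) < rates
    times = cand[keep]
    # guard against exact duplicates from float collisions (vanishing probability)
    times = np.unique(times)
    return SpikeTrain(times, unit_id, region)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

@dataclass
class LfpRecipe:
    """Ground-truth composition of a simulated LFP channel (arbitrary units)."""

    pink_noise_sd: float = 1.0
    entrain_amp: float = 0.0
    entrain_phase_lag: float = 0.0  # rad at the fundamental
    harmonics: bool = True
    harmonic_amps: tuple = (1.0, 0.5, 0.25)  # relative amps at k*f, k = 1..K
    gamma_burst_amp: float = 0.0
    gamma_freq: float = 50.0  # Hz, center of the 40-60 Hz band
    gamma_bandwidth: float = 10.0  # Hz, full width of the narrowband noise
    behavior_gate: dict = field(default_factory=dict)  # state label -> amp multiplier
    artifact_rate: float = 0.0  # events/s
    artifact_amp: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pink_noise_sd, self.entrain_amp, self.gamma_burst_amp,
               self.artifact_rate, self.artifact_amp) < 0:
            raise ValueError("amplitudes and rates must be >= 0")


def _pink_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])  # power ~ 1/f, no DC
    x = np.fft.irfft(X * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_lfp(recipe: LfpRecipe, stim: PulseTrain | None, states,
                 rate: float, duration: float, seed,
                 region: str = "other", name: str = "lfp"
                 ) -> tuple[ContinuousSignal, dict[str, np.ndarray]]:
    """Simulate one LFP channel; returns (signal, ground-truth components).

    Components (same length as the signal): ``pink`` 1/f background,
    ``entrain`` the stimulation-locked oscillation (fundamental plus a
    decaying harmonic series when ``harmonics`` is on, phase 0 at each train
    onset, masked to stimulation trains), ``gamma`` narrowband 40-60 Hz noise
    whose amplitude is multiplied per behavioral state (*states* is an
    iterable of (label, start_s, end_s)), and ``artifacts`` sparse
    high-amplitude transients.
    """
    if stim is not None and rate < 4.0 * stim.freq:
        raise ValueError(f"sampling rate {rate} too low for stimulation at {stim.freq} Hz")
    if recipe.gamma_burst_amp > 0 and rate < 4.0 * recipe.gamma_freq:
        raise ValueError(f"sampling rate {rate} too low for gamma at {recipe.gamma_freq} Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(rate * duration))
    t = np.arange(n) / rate

    pink = _pink_noise(rng, n, rate, recipe.pink_noise_sd)

    entrain = np.zeros(n)
    if recipe.entrain_amp > 0 and stim is not None and stim.n_pulses:
        amps = recipe.harmonic_amps if recipe.harmonics else (recipe.harmonic_amps[0],)
        lag_t = recipe.entrain_phase_lag / (2.0 * np.pi * stim.freq)
        for a, b in group_pulse_trains(stim):
            sel = (t >= a) & (t < b)
            tp = t[sel] - a - lag_t
            w = np.zeros(tp.size)
            for k, h in enumerate(amps, start=1):
                if k * stim.freq < rate / 2.0:
                    w += h * np.sin(2.0 * np.pi * k * stim.freq * tp)
            entrain[sel] = recipe.entrain_amp * w

    gamma = np.zeros(n)
    if recipe.gamma_burst_amp > 0:
        half_bw = recipe.gamma_bandwidth / 2.0
        lo = max(recipe.gamma_freq - half_bw, 0.5) / (rate / 2.0)
        hi = min(recipe.gamma_freq + half_bw, rate / 2.0 - 0.5) / (rate / 2.0)
        sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
        nb = sps.sosfiltfilt(sos, rng.standard_normal(n))
        s = nb.std()
        if s > 0:
            nb /= s
        mult = np.ones(n)
        for label, a, b in states or ():
            m = recipe.behavior_gate.get(label)
            if m is not None:
                mult[(t >= a) & (t < b)] = m
        gamma = recipe.gamma_burst_amp * mult * nb

    artifacts = np.zeros(n)
    if recipe.artifact_rate > 0 and recipe.artifact_amp > 0:
        n_art = rng.poisson(recipe.artifact_rate * duration)
        kernel_n = max(int(0.03 * rate), 1)
        kernel = np.exp(-np.arange(kernel_n) / (0.01 * rate))
        for _ in range(n_art):
            i0 = rng.integers(0, n)
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            j = min(kernel_n, n - i0)
            artifacts[i0:i0 + j] += sign * recipe.artifact_amp * kernel[:j]

    total = pink + entrain + gamma + artifacts
    sig = ContinuousSignal(total, rate, 0.0, region, name)
    return sig, {"pink": pink, "entrain": entrain, "gamma": gamma, "artifacts": artifacts}


# ---------------------------------------------------------------------------
# operant behavior
# ---------------------------------------------------------------------------

def simulate_operant_session(schedule: behavior.Schedule, press_rate,
                             duration: float, seed,
                             max_rate: float | None = None) -> EventSeries:
    """Poisson lever pressing under a reinforcement schedule.

    *press_rate* is a constant rate in Hz or a callable t -> rate (thinned
    against *max_rate*). Rewards come from the schedule engine.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if callable(press_rate):
        if not max_rate or max_rate <= 0:
            raise ValueError("callable press_rate requires max_rate > 0")
        n = rng.poisson(max_rate * duration)
        cand = np.sort(rng.uniform(0.0, duration, n))
        keep = rng.uniform(0.0, max_rate, n) < np.asarray(press_rate(cand), dtype=float)
        presses = cand[keep]
    else:
        if press_rate <= 0:
            raise ValueError(f"press rate must be > 0, got {press_rate}")
        n = rng.poisson(press_rate * duration)
        presses = np.sort(rng.uniform(0.0, duration, n))
    rewards = behavior.run_schedule(schedule, presses, rng)
    return EventSeries(presses, rewards)


def make_trial_sequence(n_trials: int = 60, types=("S+A", "S-A", "S+B", "S-B"),
                        max_run: int = 3, seed=0, dur_range=(57.0, 63.0),
                        iti_range=(1.0, 4.0), opto_types=("S+A", "S-A"),
                        t_start: float = 0.0) -> list[TrialBlock]:
    """Randomized trial-block sequence with equal counts per type.

    No type repeats more than *max_run* times in a row; trial durations are
    Uniform(dur_range) with the same duration multiset used for every type
    (total time per type exactly equalized); inter-trial gaps are
    Uniform(iti_range). Types in *opto_types* carry the opto flag.
    """
    types = list(types)
    if n_trials % len(types):
        raise ValueError("n_trials must be divisible by the number of types")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    per = n_trials // len(types)
    if len(types) == 1 and per > max_run:
        raise ValueError("infeasible run-length constraint")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    seq = None
    for _ in range(1000):  # constructive sampling with restart on dead ends
        remaining = {tp: per for tp in types}
        out: list[str] = []
        run_tp, run_len = None, 0
        ok = True
        for _ in range(n_trials):
            allowed = [tp for tp in types if remaining[tp] > 0
                       and not (tp == run_tp and run_len >= max_run)]
            if not allowed:
                ok = False
                break
            wts = np.array([remaining[tp] for tp in allowed], dtype=float)
            tp = allowed[rng.choice(len(allowed), p=wts / wts.sum())]
            out.append(tp)
            remaining[tp] -= 1
            run_len = run_len + 1 if tp == run_tp else 1
            run_tp = tp
        if ok:
            seq = out
            break
    if seq is None:
        raise ValueError("could not satisfy run-length constraint")

    base_durs = rng.uniform(dur_range[0], dur_range[1], per)
    durs: dict[str, list[float]] = {tp: list(rng.permutation(base_durs)) for tp in types}
    blocks = []
    t = t_start
    for tp in seq:
        d = durs[tp].pop()
        blocks.append(TrialBlock(tp, t, t + d, opto=tp in opto_types))
        t += d + rng.uniform(iti_range[0], iti_range[1])
    return blocks


# ---------------------------------------------------------------------------
# discrimination learning
# ---------------------------------------------------------------------------

@dataclass
class LearningRecipe:
    """Multi-day discrimination-learning course with a stage-specific effect."""

    n_subjects: int = 7
    n_days: int = 21
    asymptote: float = 85.0  # % correct
    slope: float = 0.3  # logistic growth per day
    chance: float = 50.0  # % correct
    opto_effect: dict = field(default_factory=lambda: {"first": 15.0, "middle": 0.0, "last": 0.0})
    session_noise_sd: float = 3.0  # %

    def __post_init__(self) -> None:
        if not 0 <= self.chance <= self.asymptote <= 100:
            raise ValueError("need 0 <= chance <= asymptote <= 100")
        if self.n_subjects < 1 or self.n_days < 21:
            raise ValueError("need >= 1 subject and >= 21 days (three 7-day stages)")


def simulate_discrimination_course(recipe: LearningRecipe, seed) -> pd.DataFrame:
    """Performance table (subject x day x condition -> percent correct).

    Control curve: chance + (asymptote - chance) * logistic(slope*(day - mid))
    plus N(0, noise_sd); the opto condition adds the stage's opto_effect.
    Values are clipped to [0, 100].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = list(range(1, recipe.n_days + 1))
    stages = behavior.stage_split(days)
    stage_of = {d: s for s, ds in stages.items() for d in ds}
    mid = (recipe.n_days + 1) / 2.0
    rows = []
    for subj in range(1, recipe.n_subjects + 1):
        for day in days:
            curve = recipe.chance + (recipe.asymptote - recipe.chance) / (
                1.0 + np.exp(-recipe.slope * (day - mid)))
            eff = recipe.opto_effect.get(stage_of.get(day, ""), 0.0)
            for cond, add in (("control", 0.0), ("opto", eff)):
                pc = curve + add + rng.normal(0.0, recipe.session_noise_sd)
                rows.append((f"s{subj:02d}", day, cond, float(np.clip(pc, 0.0, 100.0))))
    return pd.DataFrame(rows, columns=["subject", "day", "condition", "percent_correct"])


# ---------------------------------------------------------------------------
# presets (whole sessions)
# ---------------------------------------------------------------------------

def preset_entrain40(seed=0, duration: float = 120.0, rate: float = 1000.0,
                     continuous: bool = True) -> tuple[Session, dict]:
    """40 Hz-entrained anesthetized-style session: entrained LFP + unit zoo.

    With ``continuous`` the stimulation runs the whole session (the spike-field
    fixture); otherwise it is delivered as 1 s trains with 3 s pauses (the
    modulation-classification fixture).
    """
    rng = np.random.default_rng(seed)
    if continuous:
        stim = make_pulse_train(40.0, DUTY, duration)
    else:
        n_trains = int(duration // 4.0)
        stim = make_train_sequence(40.0, DUTY, 1.0, n_trains, 3.0, t0=2.0)
    recipe = LfpRecipe(pink_noise_sd=1.0, entrain_amp=1.0, harmonics=True)
    lfp, comps = simulate_lfp(recipe, stim, None, rate, duration, rng,
                              region="LHb", name="lhb_lfp")
    units = [
        simulate_unit(UnitArchetype("excited_on", 5.0, 20.0, onset_tau=0.003),
                      stim, duration, rng, "u_excited", "VP"),
        simulate_unit(UnitArchetype("inhibited", 10.0, suppression=0.9),
                      stim, duration, rng, "u_inhibited", "LHb"),
        simulate_unit(UnitArchetype("rebound", 2.0, suppression=1.0,
                                    rebound_rate=40.0, rebound_window=0.00625),
                      stim, duration, rng, "u_rebound", "LHb"),
        simulate_unit(UnitArchetype("unmodulated", 10.0),
                      stim, duration, rng, "u_flat", "LHb"),
    ]
    sess = Session([lfp], units, [stim], [], EventSeries(),
                   {"preset": "entrain40", "seed": int(seed) if np.isscalar(seed) else None})
    return sess.validate(), comps


def preset_vi30(seed=0, duration: float = 600.0, rate: float = 200.0,
                press_window: float = 10.0) -> tuple[Session, dict]:
    """Operant VI30 session with behavior-gated gamma in VP but not AC.

    Lever pressing alternates between engaged (high-rate) and paused states;
    the VP channel's gamma amplitude follows the behavioral state at 2:1
    (engaged:paused) while the AC channel is ungated.
    """
    rng = np.random.default_rng(seed)
    # alternating engaged/paused periods, 60 s / 30 s on average
    states = []
    t = 0.0
    while t < duration:
        eng = float(min(rng.uniform(40.0, 80.0), duration - t))
        states.append(("engaged", t, t + eng))
        t += eng
        if t >= duration:
            break
        pause = float(min(rng.uniform(20.0, 40.0), duration - t))
        states.append(("paused", t, t + pause))
        t += pause

    def press_rate(tt):
        tt = np.asarray(tt, dtype=float)
        r = np.zeros(tt.size)
        for label, a, b in states:
            r[(tt >= a) & (tt < b)] = 0.4 if label == "engaged" else 0.0
        return r

    events = simulate_operant_session(behavior.VI(30.0, 5.0), press_rate,
                                      duration, rng, max_rate=0.4)
    gate_vp = {"engaged": 1.0, "paused": 0.5}
    vp, comps_vp = simulate_lfp(
        LfpRecipe(pink_noise_sd=1.0, gamma_burst_amp=0.5, gamma_freq=50.0,
                  behavior_gate=gate_vp),
        None, states, rate, duration, rng, region="VP", name="vp_lfp")
    ac, comps_ac = simulate_lfp(
        LfpRecipe(pink_noise_sd=1.0, gamma_burst_amp=0.5, gamma_freq=50.0,
                  behavior_gate={}),
        None, states, rate, duration, rng, region="AC", name="ac_lfp")
    sess = Session([vp, ac], [], [], [], events,
                   {"preset": "vi30", "schedule": "VI30+/-5", "states": states})
    return sess.validate(), {"VP": comps_vp, "AC": comps_ac, "states": states}
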