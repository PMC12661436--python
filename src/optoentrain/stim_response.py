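"""Event-locked firing-rate analysis: PSTH, modulation classification with a
normality-gated paired test, transient-window (first 100 ms) classification,
chi-square count tests, and the depth-binned activation profile.

The pairing unit for the stimulation-vs-baseline tests is the stimulation
*train* (a contiguous run of pulses, nominally 1 s); the baseline is the
equal-duration window immediately preceding each train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import PulseTrain, SpikeTrain
from .stats_util import normality_gated_paired_test

log = logging.getLogger("optoentrain")


def psth(spikes: SpikeTrain | np.ndarray, onsets, window: tuple[float, float] = (-0.5, 1.5),
         binwidth: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Peri-stimulus time histogram: trial-averaged firing rate in Hz.

    Returns (bin_edges, rates). Bins are half-open [left, right): a spike on a
    shared edge counts in the right-hand bin, and a spike at the final edge is
    outside the window.
    """
    t = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("psth needs at least one event onset")
    pre, post = window
    if binwidth <= 0 or post - pre < binwidth:
        raise ValueError("window must span at least one positive-width bin")
    n_bins = int(np.floor((post - pre) / binwidth + 1e-9))
    edges = pre + binwidth * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for on in onsets:
        rel = t - on
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]  # strict right edge
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rates = counts / (onsets.size * binwidth)
    return edges, rates


def group_pulse_trains(stim: PulseTrain, max_gap: float | None = None) -> list[tuple[float, float]]:
    """Group pulses into stimulation trains separated by pauses.

    Consecutive onsets more than *max_gap* apart (default 1.5 periods) start a
    new train. Each train spans [first onset, first onset + n_pulses/f), i.e.
    whole stimulation cycles including the light-off half-cycles.
    """
    if stim.n_pulses == 0:
        return []
    if max_gap is None:
        max_gap = 1.5 * stim.period
    breaks = np.nonzero(np.diff(stim.onsets) > max_gap)[0] + 1
    spans = []
    for chunk in np.split(stim.onsets, breaks):
        spans.append((float(chunk[0]), float(chunk[0] + chunk.size * stim.period)))
    return spans


def _rates_in_windows(times: np.ndarray, windows) -> np.ndarray:
    out = np.empty(len(windows))
    for i, (a, b) in enumerate(windows):
        out[i] = np.sum((times >= a) & (times < b)) / (b - a)
    return out


@dataclass
class ModulationResult:
    unit_id: str
    baseline_rate: float  # Hz, mean across trains
    stim_rate: float      # Hz
    test_used: str
    statistic: float
    p: float
    klass: str  # excited | inhibited | ns


def _classify(unit_id: str, base: np.ndarray, stim_r: np.ndarray,
              alpha: float) -> ModulationResult:
    test, stat, p = normality_gated_paired_test(stim_r, base, alpha)
    b, s = float(base.mean()), float(stim_r.mean())
    if p >= alpha:
        klass = "ns"
    else:
        klass = "excited" if s > b else "inhibited"
    return ModulationResult(unit_id, b, s, test, stat, p, klass)


def classify_modulation(spikes: SpikeTrain, stim: PulseTrain, alpha: float = 0.05,
                        max_gap: float | None = None) -> ModulationResult:
    """Classify a unit as excited / inhibited / ns during stimulation trains.

    Per-train firing rates during each train are paired with rates in the
    equal-duration immediately-preceding baseline window; the paired test is
    normality-gated (paired t if the rate differences pass both Lilliefors and
    Anderson-Darling at 5%, Wilcoxon signed-rank otherwise).
    """
    trains = group_pulse_trains(stim, max_gap)
    if len(trains) < 5:
        raise ValueError(f"need >= 5 stimulation trains, got {len(trains)}")
    if spikes.n_spikes == 0:
        log.warning("unit %s: empty spike train, classified ns", spikes.unit_id)
        return ModulationResult(spikes.unit_id, 0.0, 0.0, "degenerate", 0.0, 1.0, "ns")
    stim_windows = trains
    base_windows = [(a - (b - a), a) for a, b in trains]
    stim_r = _rates_in_windows(spikes.times, stim_windows)
    base_r = _rates_in_windows(spikes.times, base_windows)
    return _classify(spikes.unit_id, base_r, stim_r, alpha)


def transient_window_classify(spikes: SpikeTrain, stim: PulseTrain,
                              transient: float = 0.1, alpha: float = 0.05,
                              max_gap: float | None = None) -> ModulationResult:
    """Classify the response in the first *transient* seconds of each train.

    Rates on [train_onset, train_onset + transient) are compared against
    equal-duration pre-train baselines with the gated paired test; used to
    detect the transient inhibition preceding net excitation.
    """
    trains = group_pulse_trains(stim, max_gap)
    if len(trains) < 5:
        raise ValueError(f"need >= 5 stimulation trains, got {len(trains)}")
    if spikes.n_spikes == 0:
        log.warning("unit %s: empty spike train, classified ns", spikes.unit_id)
        return ModulationResult(spikes.unit_id, 0.0, 0.0, "degenerate", 0.0, 1.0, "ns")
    stim_windows = [(a, a + transient) for a, _ in trains]
    base_windows = [(a - transient, a) for a, _ in trains]
    stim_r = _rates_in_windows(spikes.times, stim_windows)
    base_r = _rates_in_windows(spikes.times, base_windows)
    return _classify(spikes.unit_id, base_r, stim_r, alpha)


def chi_square_counts(observed, expected_proportions=None) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square on category counts.

    Default expected proportions are equal. No continuity correction.
    Returns (chi2, df, p).
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if expected_proportions is None:
        props = np.full(obs.size, 1.0 / obs.size)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        props = props / props.sum()
    if np.any((props == 0) & (obs > 0)):
        raise ValueError("expected proportion 0 with nonzero observed count")
    exp = props * obs.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class DepthProfile:
    bin_centers: np.ndarray  # mm
    mean_response: np.ndarray  # Hz increase over baseline per bin
    n_per_bin: np.ndarray
    anova_F: float
    anova_p: float


def depth_profile(stim_sites, bin_width: float = 0.5) -> DepthProfile:
    """Bin stimulation depths and test the response-by-depth effect.

    *stim_sites* is a sequence of (depth_mm, response_hz). Bins are half-open
    [lo, lo+bin_width) anchored at the shallowest depth rounded down to a
    multiple of bin_width; a one-way ANOVA across non-empty bins gives F and p
    (NaN when fewer than two non-empty bins).
    """
    sites = np.asarray(stim_sites, dtype=float)
    if sites.ndim != 2 or sites.shape[1] != 2 or sites.shape[0] == 0:
        raise ValueError("stim_sites must be a non-empty (n, 2) array of (depth, response)")
    depths, resp = sites[:, 0], sites[:, 1]
    lo = np.floor(depths.min() / bin_width) * bin_width
    idx = np.floor((depths - lo) / bin_width).astype(int)
    n_bins = idx.max() + 1
    centers = lo + bin_width * (np.arange(n_bins) + 0.5)
    groups = [resp[idx == k] for k in range(n_bins)]
    means = np.array([g.mean() if g.size else np.nan for g in groups])
    counts = np.array([g.size for g in groups])
    nonempty = [g for g in groups if g.size]
    if len(nonempty) < 2:
        log.warning("depth_profile: single non-empty bin, ANOVA not applicable")
        F = p = float("nan")
    elif np.ptp(resp) == 0:
        F, p = 0.0, 1.0  # no variance anywhere: zero between-group effect
    elif max(g.size for g in nonempty) < 2:
        log.warning("depth_profile: every bin has a single site, ANOVA not applicable")
        F = p = float("nan")
    else:
        F, p = stats.f_oneway(*nonempty)
    return DepthProfile(centers, means, counts, float(F), float(p))
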