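"""Spike-phase locking to pulsatile stimulation.

Spike phases relative to the stimulus are computed on the stimulus clock as
``2*pi*f*(spt - t0) mod 2*pi`` with phase 0 at pulse onset, so with a 50%
duty cycle the light-on half-period maps to [0, pi). Non-uniformity of the
phase distribution is assessed with the Rayleigh test (Zar small-sample
approximation, as in the MATLAB circular-statistics ``circ_rtest``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .session import PulseTrain, SpikeTrain

log = logging.getLogger("optoentrain")

TWO_PI = 2.0 * np.pi


def spike_phases(spike_times, f: float, t0: float = 0.0) -> np.ndarray:
    """Phases (rad, in [0, 2pi)) of spike times relative to an f Hz stimulus.

    phase = 2*pi*f*(spt - t0) mod 2*pi, with t0 the first pulse onset. The
    caller is responsible for restricting spikes to stimulation-on epochs
    (see :func:`phases_during_stim`).
    """
    if f <= 0:
        raise ValueError(f"stimulation frequency must be > 0, got {f}")
    spt = np.asarray(spike_times, dtype=float)
    return np.mod(TWO_PI * f * (spt - t0), TWO_PI)


def phases_during_stim(spikes: SpikeTrain, stim: PulseTrain) -> np.ndarray:
    """Phases of the spikes that fall inside full stimulation cycles.

    A stimulation cycle is [onset, onset + 1/f) for each pulse; spikes outside
    every cycle are excluded (count logged). Phase origin is each spike's own
    cycle onset, equivalent to 2*pi*f*(spt - first_onset) mod 2*pi when pulses
    are exactly periodic.
    """
    t = spikes.times
    spans = stim.cycle_spans()
    idx = np.searchsorted(spans[:, 0], t, side="right") - 1
    inside = (idx >= 0) & (t < spans[np.clip(idx, 0, None), 1])
    n_excluded = int((~inside).sum())
    if n_excluded:
        log.info("unit %s: excluded %d spike(s) outside stimulation epochs",
                 spikes.unit_id, n_excluded)
    kept = t[inside]
    onsets = spans[idx[inside], 0]
    return np.mod(TWO_PI * stim.freq * (kept - onsets), TWO_PI)


def rayleigh_test(phases) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns (R, Z, p): resultant length R = |sum exp(i phi)| / n, Z = n R^2,
    and the small-sample-corrected p-value
    p = exp( sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n) ).
    """
    phi = np.asarray(phases, dtype=float)
    n = phi.size
    if n < 2:
        raise ValueError("Rayleigh test needs >= 2 phases")
    C = np.cos(phi).sum()
    S = np.sin(phi).sum()
    Rn = np.hypot(C, S)
    R = Rn / n
    Z = n * R * R
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n)))
    return float(R), float(Z), min(p, 1.0)


def preferred_phase(phases, n_bins: int = 18) -> tuple[float, float, np.ndarray]:
    """Circular mean, histogram-mode phase, and the histogram itself.

    The mode is the center of the maximal-count bin of an n_bins histogram
    over [0, 2pi) (half-open bins; ties resolved to the lowest bin). The mean
    is NaN when the resultant length is zero (antipodal/symmetric input).
    """
    phi = np.asarray(phases, dtype=float)
    if phi.size < 1:
        raise ValueError("need >= 1 phase")
    if n_bins < 4:
        raise ValueError("need >= 4 histogram bins")
    C = np.cos(phi).mean()
    S = np.sin(phi).mean()
    R = np.hypot(C, S)
    if R < 1e-12:
        mean = float("nan")
    else:
        mean = float(np.mod(np.arctan2(S, C), TWO_PI))
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(np.mod(phi, TWO_PI), bins=edges)
    k = int(np.argmax(counts))
    mode = float((edges[k] + edges[k + 1]) / 2.0)
    return mean, mode, counts


def classify_side(mean_phase: float, duty: float = 0.5) -> str:
    """Classify a preferred phase as light_on or light_off.

    With phase 0 at pulse onset the light-on interval maps to [0, 2*pi*duty);
    the boundary belongs to light_off. NaN means are unclassified.
    """
    if not 0 < duty <= 1:
        raise ValueError(f"duty must be in (0,1], got {duty}")
    if np.isnan(mean_phase):
        return "unclassified"
    return "light_on" if np.mod(mean_phase, TWO_PI) < TWO_PI * duty else "light_off"


@dataclass
class PhaseLockingResult:
    unit_id: str
    f: float
    phases: np.ndarray
    R: float
    rayleigh_Z: float
    rayleigh_p: float
    mean_phase: float
    mode_phase: float
    n_spikes: int
    locked: bool
    side: str


def phase_locking_analysis(spikes: SpikeTrain, stim: PulseTrain,
                           alpha: float = 0.05, n_bins: int = 18) -> PhaseLockingResult:
    """Full per-unit phase-locking analysis for one frequency condition."""
    phases = phases_during_stim(spikes, stim)
    if phases.size < 2:
        raise ValueError(f"unit {spikes.unit_id}: too few spikes in stimulation epochs")
    R, Z, p = rayleigh_test(phases)
    mean, mode, _ = preferred_phase(phases, n_bins)
    return PhaseLockingResult(
        unit_id=spikes.unit_id, f=stim.freq, phases=phases, R=R,
        rayleigh_Z=Z, rayleigh_p=p, mean_phase=mean, mode_phase=mode,
        n_spikes=int(phases.size), locked=bool(p < alpha),
        side=classify_side(mean, stim.duty),
    )
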