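"""Spike-triggered average (STA) and spike-field coherence (SFC).

The STA is the mean of 200 ms LFP epochs centered on spike times. The SFC is
the power spectrum of the STA divided by the mean power spectrum of the
contributing epochs, SFC(f) = P_STA(f) / Pbar(f): a dimensionless quantity in
[0, 1] (Cauchy-Schwarz: |mean FFT|^2 <= mean |FFT|^2), equal to 1 at a
frequency where every epoch has identical phase, and with expectation ~1/n
for spikes independent of the field. Spectra are computed on an exactly
200 ms window (rectangular, no taper), so the frequency grid has 5 Hz
resolution and the 35 Hz control frequency falls on a grid point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import ContinuousSignal, SpikeTrain
from .stats_util import normality_gated_paired_test

log = logging.getLogger("optoentrain")


def spike_centered_epochs(lfp: ContinuousSignal, spikes: SpikeTrain | np.ndarray,
                          half_window: float = 0.1) -> tuple[np.ndarray, int]:
    """Extract LFP epochs of +/- *half_window* s centered on each spike.

    Returns (epochs, n_dropped): one row per retained spike, length
    2*round(half_window*rate)+1 samples; spikes without full coverage inside
    the signal are dropped and counted.
    """
    t = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, dtype=float)
    half = int(round(half_window * lfp.rate))
    centers = np.round((t - lfp.t0) * lfp.rate).astype(int)
    ok = (centers - half >= 0) & (centers + half < lfp.samples.size)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("spike_centered_epochs: dropped %d spike(s) near signal edges", n_dropped)
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no spikes with full epoch coverage inside the signal")
    offsets = np.arange(-half, half + 1)
    epochs = lfp.samples[centers[:, None] + offsets[None, :]]
    return epochs, n_dropped


def spike_triggered_average(epochs: np.ndarray) -> np.ndarray:
    """Pointwise mean across spike-centered epochs."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need >= 1 epoch")
    return epochs.mean(axis=0)


@dataclass
class SpikeFieldResult:
    site_id: str
    sta: np.ndarray          # 2*half+1 samples centered on the spike
    freqs: np.ndarray        # Hz, 5 Hz resolution for 200 ms epochs
    sfc: np.ndarray          # in [0,1]; NaN where Pbar == 0
    n_epochs: int
    p_bar: np.ndarray        # mean epoch power spectrum


def spike_field_coherence(epochs: np.ndarray, rate: float,
                          site_id: str = "site") -> SpikeFieldResult:
    """SFC(f) = P_STA(f) / Pbar(f) on the epoch-length frequency grid.

    Spectra are taken over the first 2*half samples (exactly the epoch window,
    e.g. 0.2 s -> 5 Hz grid); the center-symmetric extra sample is kept in the
    STA for display only. Grid points where Pbar vanishes are NaN-flagged.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_ep, n_samp = epochs.shape
    if n_ep < 2:
        raise ValueError("spike-field coherence needs >= 2 epochs")
    nfft = n_samp - 1 if n_samp % 2 == 1 else n_samp  # exact window length
    sta = epochs.mean(axis=0)
    ffts = np.fft.rfft(epochs[:, :nfft], axis=1)
    p_bar = np.mean(np.abs(ffts) ** 2, axis=0)
    p_sta = np.abs(ffts.mean(axis=0)) ** 2  # == |rfft(sta[:nfft])|^2 by linearity
    with np.errstate(invalid="ignore", divide="ignore"):
        sfc = np.where(p_bar > 0, p_sta / np.maximum(p_bar, 1e-300), np.nan)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    return SpikeFieldResult(site_id, sta, freqs, sfc, n_ep, p_bar)


def sfc_peaks(result: SpikeFieldResult, fmin: float = 5.0, fmax: float = 100.0,
              guard_bins: int = 1) -> tuple[float, float]:
    """Global SFC maximum and the next local maximum in [fmin, fmax].

    Returns (f_peak, f_harmonic): the frequency of the global maximum, and the
    frequency of the largest remaining local maximum after excluding the
    global peak bin and *guard_bins* neighbors on each side.
    """
    sel = (result.freqs >= fmin) & (result.freqs <= fmax)
    f = result.freqs[sel]
    s = np.where(np.isnan(result.sfc[sel]), -np.inf, result.sfc[sel])
    k0 = int(np.argmax(s))
    masked = s.copy()
    masked[max(0, k0 - guard_bins): k0 + guard_bins + 1] = -np.inf
    # local maxima of the masked curve
    cand = [k for k in range(len(f))
            if np.isfinite(masked[k])
            and (k == 0 or masked[k] >= masked[k - 1])
            and (k == len(f) - 1 or masked[k] >= masked[k + 1])]
    if not cand:
        return float(f[k0]), float("nan")
    k1 = max(cand, key=lambda k: masked[k])
    return float(f[k0]), float(f[k1])


@dataclass
class SfcContrast:
    site_id: str
    sfc_target: np.ndarray   # per-segment SFC at the target frequency
    sfc_control: np.ndarray  # per-segment SFC at the control frequency
    delta: float             # mean(target - control)
    test_used: str
    statistic: float
    p: float


def compare_sfc(lfp: ContinuousSignal, spikes: SpikeTrain,
                f_target: float = 40.0, f_control: float = 35.0,
                n_segments: int = 10, half_window: float = 0.1,
                alpha: float = 0.05, site_id: str = "site") -> SfcContrast:
    """Within-site contrast of SFC at the stimulation vs a control frequency.

    Spikes are split into *n_segments* contiguous equal-spike-count segments;
    the SFC is computed per segment and its value at the target and control
    frequencies compared with the normality-gated paired test.
    """
    if n_segments < 5:
        raise ValueError("need >= 5 segments for the within-site test")
    epochs, _ = spike_centered_epochs(lfp, spikes, half_window)
    n = epochs.shape[0]
    if n < 2 * n_segments:
        raise ValueError("too few epochs for the requested number of segments")
    bounds = np.linspace(0, n, n_segments + 1).astype(int)
    t_vals, c_vals = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        res = spike_field_coherence(epochs[a:b], lfp.rate, site_id)
        it = int(np.argmin(np.abs(res.freqs - f_target)))
        ic = int(np.argmin(np.abs(res.freqs - f_control)))
        if abs(res.freqs[it] - f_target) > 1e-6 or abs(res.freqs[ic] - f_control) > 1e-6:
            raise ValueError("target/control frequency off the epoch frequency grid")
        t_vals.append(res.sfc[it])
        c_vals.append(res.sfc[ic])
    t_vals = np.asarray(t_vals)
    c_vals = np.asarray(c_vals)
    test, stat, p = normality_gated_paired_test(t_vals, c_vals, alpha)
    return SfcContrast(site_id, t_vals, c_vals, float(np.mean(t_vals - c_vals)),
                       test, stat, p)


def population_sfc_test(contrasts) -> tuple[float, float]:
    """Signed-rank test of per-site mean SFC differences against zero."""
    deltas = np.asarray([c.delta for c in contrasts], dtype=float)
    if deltas.size < 5:
        raise ValueError("need >= 5 sites for the population test")
    stat, p = stats.wilcoxon(deltas, alternative="two-sided")
    return float(stat), float(p)
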