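"""LFP band-power pipeline: down-sample, 1 s epoching with robust artifact
rejection, per-epoch FFT power spectra (Parseval-normalized), gamma-band
(40-60 Hz) power, behavioral labeling of epochs, and the rank-based group
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats

from .session import ContinuousSignal, TrialBlock

log = logging.getLogger("optoentrain")

GAMMA_BAND = (40.0, 60.0)  # Hz


def downsample(sig: ContinuousSignal, target_rate: float = 200.0) -> ContinuousSignal:
    """Anti-alias low-pass and decimate to *target_rate* (rational factors OK)."""
    if target_rate >= sig.rate:
        raise ValueError(f"target rate {target_rate} must be below signal rate {sig.rate}")
    frac = Fraction(target_rate / sig.rate).limit_denominator(10_000)
    out = sps.resample_poly(sig.samples, frac.numerator, frac.denominator)
    return ContinuousSignal(out, target_rate, sig.t0, sig.region, sig.name)


def epoch_and_reject(sig: ContinuousSignal, epoch_len: float = 1.0,
                     k_sd: float = 6.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut non-overlapping epochs and flag artifact epochs.

    Returns (epochs, kept_mask, epoch_centers_s). An epoch is rejected if any
    sample deviates from the signal median by more than k_sd robust standard
    deviations (1.4826*MAD), or if it contains >= 3 consecutive identical
    extreme values (saturation). The trailing remainder shorter than one epoch
    is dropped.
    """
    n_per = int(round(epoch_len * sig.rate))
    n_ep = sig.samples.size // n_per
    if n_ep == 0:
        raise ValueError("signal shorter than one epoch")
    x = sig.samples[: n_ep * n_per].reshape(n_ep, n_per)
    med = np.median(sig.samples)
    rsd = 1.4826 * np.median(np.abs(sig.samples - med))
    if rsd == 0:
        amp_bad = np.zeros(n_ep, dtype=bool)
    else:
        amp_bad = np.any(np.abs(x - med) > k_sd * rsd, axis=1)
    lo, hi = sig.samples.min(), sig.samples.max()
    extreme = (x == lo) | (x == hi)
    runs = extreme[:, :-2] & extreme[:, 1:-1] & extreme[:, 2:]
    same = (x[:, :-2] == x[:, 1:-1]) & (x[:, 1:-1] == x[:, 2:])
    sat_bad = np.any(runs & same, axis=1) if lo != hi else np.zeros(n_ep, dtype=bool)
    kept = ~(amp_bad | sat_bad)
    centers = sig.t0 + (np.arange(n_ep) + 0.5) * epoch_len
    return x, kept, centers


def psd(epochs: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean periodogram over epochs, Parseval-normalized.

    Each epoch is demeaned; the one-sided spectrum is scaled so that its sum
    over the frequency grid equals the epoch variance (for a 1 s epoch at
    200 Hz the grid is 0..100 Hz at 1 Hz resolution).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need >= 1 epoch")
    n = epochs.shape[1]
    x = epochs - epochs.mean(axis=1, keepdims=True)
    X = np.fft.rfft(x, axis=1)
    p = np.abs(X) ** 2 / n**2
    p[:, 1:] *= 2.0
    if n % 2 == 0:
        p[:, -1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, p.mean(axis=0)


def epoch_band_powers(epochs: np.ndarray, rate: float,
                      band: tuple[float, float] = GAMMA_BAND) -> np.ndarray:
    """Per-epoch band power: mean Parseval-normalized spectral value in *band*."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n = epochs.shape[1]
    x = epochs - epochs.mean(axis=1, keepdims=True)
    X = np.fft.rfft(x, axis=1)
    p = np.abs(X) ** 2 / n**2
    p[:, 1:] *= 2.0
    if n % 2 == 0:
        p[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or band[0] < 0 or band[1] > freqs[-1]:
        raise ValueError(f"band {band} outside frequency grid 0..{freqs[-1]} Hz")
    return p[:, sel].mean(axis=1)


def band_power(freqs: np.ndarray, spectrum: np.ndarray,
               band: tuple[float, float] = GAMMA_BAND) -> float:
    """Mean spectral value over grid points within *band* (edges inclusive)."""
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or band[0] < 0 or band[1] > freqs[-1]:
        raise ValueError(f"band {band} outside frequency grid 0..{freqs[-1]} Hz")
    return float(np.asarray(spectrum, dtype=float)[sel].mean())


def label_press_epochs(press_times, epoch_centers, window: float = 10.0,
                       high_min: int = 2, low_max: int = 0) -> np.ndarray:
    """Label epochs by lever-press density in a centered window.

    high if >= high_min presses fall in [center - window/2, center + window/2),
    low if <= low_max presses, otherwise excluded.
    """
    presses = np.asarray(press_times, dtype=float)
    centers = np.asarray(epoch_centers, dtype=float)
    counts = (np.searchsorted(presses, centers + window / 2, side="left")
              - np.searchsorted(presses, centers - window / 2, side="left"))
    labels = np.where(counts >= high_min, "high",
                      np.where(counts <= low_max, "low", "excluded"))
    return labels


@dataclass
class BandPowerComparison:
    test: str
    statistic: float
    p: float
    adjusted_alpha: float
    n: tuple


def compare_band_power(a, b, design: str = "unpaired", n_comparisons: int = 1,
                       alpha: float = 0.05) -> BandPowerComparison:
    """Compare two band-power samples with the design-appropriate rank test.

    unpaired (epoch-level, e.g. high vs low pressing): Wilcoxon rank-sum;
    paired_sessions (per-session pairs): Wilcoxon signed-rank;
    sign (region-by-schedule family member): sign test. *n_comparisons* sets
    the Bonferroni-adjusted alpha reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need >= 5 observations per group")
    adj = alpha / n_comparisons
    if design == "unpaired":
        stat, p = stats.ranksums(a, b)
        name = "wilcoxon_rank_sum"
    elif design == "paired_sessions":
        d = a - b
        if np.all(d == 0):
            return BandPowerComparison("wilcoxon_signed_rank", 0.0, 1.0, adj, (a.size, b.size))
        stat, p = stats.wilcoxon(a, b, zero_method="wilcox")
        name = "wilcoxon_signed_rank"
    elif design == "sign":
        d = a - b
        n_pos = int(np.sum(d > 0))
        n_nonzero = int(np.sum(d != 0))
        if n_nonzero == 0:
            return BandPowerComparison("sign_test", 0.0, 1.0, adj, (a.size, b.size))
        res = stats.binomtest(n_pos, n_nonzero, 0.5, alternative="two-sided")
        stat, p = float(n_pos), res.pvalue
        name = "sign_test"
    else:
        raise ValueError(f"unknown design {design!r}")
    return BandPowerComparison(name, float(stat), float(p), adj, (a.size, b.size))


def block_band_power(sig: ContinuousSignal, blocks: list[TrialBlock],
                     epoch_len: float = 1.0, k_sd: float = 6.0,
                     band: tuple[float, float] = GAMMA_BAND) -> dict[str, np.ndarray]:
    """Per-condition (S+ vs S-) epoch band powers for one signal.

    Artifact-free epochs are assigned to the block containing their center;
    epochs straddling a block edge follow their center (logged). Raises if any
    block contains no epoch.
    """
    epochs, kept, centers = epoch_and_reject(sig, epoch_len, k_sd)
    powers = epoch_band_powers(epochs[kept], sig.rate, band)
    centers = centers[kept]
    out: dict[str, list[float]] = {"S+": [], "S-": []}
    per_block = {id(b): 0 for b in blocks}
    for c, pw in zip(centers, powers):
        for b in blocks:
            if b.start <= c < b.end:
                if b.start > c - epoch_len / 2 or b.end < c + epoch_len / 2:
                    log.info("epoch at %.1fs straddles a block edge; assigned by center", c)
                per_block[id(b)] += 1
                if b.type.startswith("S+"):
                    out["S+"].append(pw)
                elif b.type.startswith("S-"):
                    out["S-"].append(pw)
                break
    if any(v == 0 for v in per_block.values()):
        raise ValueError("a trial block contains no artifact-free epoch")
    return {k: np.asarray(v) for k, v in out.items()}
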