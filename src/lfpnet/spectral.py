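"""Welch power spectral density, relative power, and band summaries.

Spectral power is estimated from the accepted 2-s analysis windows: one
Hann-tapered periodogram per window (the sliding-window overlap is handled
at the epoch level), averaged across windows.  A 2-s window at 512 Hz gives
a 0.5 Hz frequency resolution.  Power is then expressed as *relative* power
over the 1-256 Hz analysis grid — each bin divided by the total power on the
grid — so per-animal spectra are comparable regardless of electrode gain.

Band edges are half-open ``[lo, hi)`` so the delta/theta and theta/gamma
partitions never double-count a bin.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .preprocess import EpochSet, Recording

__all__ = [
    "BANDS",
    "FMIN",
    "FMAX",
    "welch_psd",
    "relative_power",
    "band_power",
]

FMIN, FMAX = 1.0, 256.0

#: Canonical oscillation bands (Hz), half-open intervals.
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "gamma": (30.0, 80.0)}


def _hann_periodogram_scale(win: np.ndarray, rate: float) -> float:
    return 1.0 / (rate * np.sum(win**2))


def welch_psd(rec: Recording, eps: EpochSet, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a channel over the accepted epochs.

    Returns ``(freqs, psd)`` where ``psd`` is the mean of per-window
    Hann-tapered periodograms, in uV^2/Hz, on the full 0..Nyquist grid.
    """
    wins = eps.accepted_windows
    if len(wins) == 0:
        raise ValueError("no accepted epochs: nothing to average")
    x = rec.channel(channel)
    n = int(wins[0, 1] - wins[0, 0])
    win = signal.get_window("hann", n)
    scale = _hann_periodogram_scale(win, rec.rate)
    freqs = np.fft.rfftfreq(n, 1.0 / rec.rate)
    acc = np.zeros(freqs.size)
    for s, e in wins:
        spec = np.fft.rfft(x[s:e] * win)
        p = (spec.real**2 + spec.imag**2) * scale
        if n % 2 == 0:
            p[1:-1] *= 2.0
        else:
            p[1:] *= 2.0
        acc += p
    return freqs, acc / len(wins)


def relative_power(
    freqs: np.ndarray, psd: np.ndarray, fmin: float = FMIN, fmax: float = FMAX
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a PSD to relative power over the ``[fmin, fmax)`` grid.

    Returns the restricted frequency grid and a vector summing to 1.
    """
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("PSD must be non-negative")
    mask = (freqs >= fmin) & (freqs < fmax)
    total = psd[mask].sum()
    if total <= 0:
        raise ValueError("total power over the analysis grid is zero")
    return freqs[mask], psd[mask] / total


def band_power(freqs: np.ndarray, rel: np.ndarray, band: tuple[float, float]) -> float:
    """Sum of relative power over a half-open band ``[lo, hi)``."""
    lo, hi = band
    if not (FMIN <= lo < hi <= FMAX):
        raise ValueError(f"band ({lo}, {hi}) outside the {FMIN}-{FMAX} Hz grid")
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.asarray(rel)[mask].sum())
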