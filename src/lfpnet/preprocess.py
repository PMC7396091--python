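"""Preprocessing of continuous multichannel LFP recordings.

Covers the steps between raw acquisition and spectral analysis: powerline
notch filtering, band-limiting, segmentation into 2-s analysis windows gated
by the motion (PIR) envelope, and rejection of artifact windows.  The
resulting :class:`EpochSet` is the common input of the spectral,
connectivity and phase-amplitude-coupling stages.

All filters are applied forward-backward (zero phase) so that between-channel
phase estimates downstream are not biased by filter group delay.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "remove_line_noise",
    "bandpass",
    "segment_epochs",
    "reject_artifacts",
    "accepted_segments",
    "ACCEPTED",
    "REJECTED_ARTIFACT",
    "REJECTED_INACTIVE",
]

ACCEPTED = "accepted"
REJECTED_ARTIFACT = "rejected_artifact"
REJECTED_INACTIVE = "rejected_inactive"

#: Electrode labels used throughout the package (left/right olfactory bulb,
#: frontal cortex, left entorhinal cortex, left/dorsal hippocampal CA1,
#: basolateral amygdala).  The motion envelope travels alongside as its own
#: trace, not as an LFP channel.
LFP_CHANNELS = ("OBL", "OBR", "FC", "ECL", "CA1L", "CA1D", "BLA")


@dataclass
class Recording:
    """Continuous multichannel LFP plus a motion envelope.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``, microvolts.
    rate:
        Sampling rate in Hz.  Analyses assume 512 Hz (1-256 Hz band).
    channel_map:
        Mapping from channel label to row index of ``data``.
    motion:
        Motion envelope (passive-infrared activity), arbitrary units,
        one value per sample.
    """

    data: np.ndarray
    rate: float
    channel_map: Mapping[str, int]
    motion: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 1 or self.motion.size != self.data.shape[1]:
            raise ValueError("motion envelope must match channel length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_map[label]]
        except KeyError:
            found = ", ".join(sorted(self.channel_map))
            raise KeyError(
                f"channel {label!r} not present; found channels: {found}"
            ) from None


@dataclass
class EpochSet:
    """Fixed-length analysis windows with accept/reject labels.

    ``windows`` holds ``(start, end)`` sample indices of equal-length
    windows on a fixed stride; ``labels`` holds one of :data:`ACCEPTED`,
    :data:`REJECTED_ARTIFACT`, :data:`REJECTED_INACTIVE` per window.
    """

    windows: np.ndarray
    labels: np.ndarray
    win_s: float
    stride_s: float
    motion_threshold_abs: float
    mean_motion: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def accepted_mask(self) -> np.ndarray:
        return self.labels == ACCEPTED

    @property
    def accepted_windows(self) -> np.ndarray:
        return self.windows[self.accepted_mask]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted_mask.sum())


def remove_line_noise(
    rec: Recording, line_freq: float = 50.0, bandwidth_hz: float = 1.0
) -> Recording:
    """Notch out powerline contamination with a zero-phase IIR notch.

    The notch is narrow (default -3 dB bandwidth 1 Hz) so that power more
    than 2 Hz away from ``line_freq`` is left essentially untouched
    (< 1 dB), while the line bin itself is attenuated far beyond 30 dB.
    """
    if not 0 < line_freq < rec.nyquist:
        raise ValueError(
            f"line frequency {line_freq} Hz must lie in (0, {rec.nyquist}) Hz"
        )
    b, a = signal.iirnotch(line_freq, line_freq / bandwidth_hz, fs=rec.rate)
    data = signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=data)


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 256.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band limiting (acquisition band 1-256 Hz).

    When ``hi`` reaches the Nyquist frequency only the high-pass half is
    applied.  The forward-backward 4th-order design gives ~48 dB/octave of
    effective roll-off, comfortably above the 20 dB-per-octave contract.
    """
    if not 0 < lo < hi or hi > rec.nyquist + 1e-9:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz for Nyquist {rec.nyquist} Hz")
    if hi >= rec.nyquist * (1 - 1e-9):
        sos = signal.butter(order, lo, btype="highpass", fs=rec.rate, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def segment_epochs(
    rec: Recording,
    win_s: float = 2.0,
    stride_s: float = 1.0,
    motion_threshold: float = 0.2,
) -> EpochSet:
    """Cut the recording into sliding windows gated by the motion envelope.

    A window is motion-positive iff its mean motion envelope is at least
    ``motion_threshold`` times the recording's maximum envelope (per-animal
    normalisation: PIR units are arbitrary).  ``motion_threshold = 0``
    accepts every window.  Windows failing the gate are labelled
    ``rejected_inactive``.
    """
    win = int(round(win_s * rec.rate))
    stride = int(round(stride_s * rec.rate))
    if win <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    if rec.n_samples < win:
        raise ValueError("recording shorter than one analysis window")
    starts = np.arange(0, rec.n_samples - win + 1, stride, dtype=int)
    windows = np.stack([starts, starts + win], axis=1)
    mean_motion = np.array([rec.motion[s:e].mean() for s, e in windows])
    thr_abs = motion_threshold * (rec.motion.max() if rec.motion.size else 0.0)
    if motion_threshold == 0:
        positive = np.ones(len(windows), dtype=bool)
    else:
        positive = (mean_motion >= thr_abs) & (mean_motion > 0)
    labels = np.where(positive, ACCEPTED, REJECTED_INACTIVE).astype(object)
    eps = EpochSet(windows, labels, win_s, stride_s, float(thr_abs), mean_motion)
    if eps.n_accepted == 0:
        warnings.warn(
            "no motion-positive windows accepted; downstream stages will refuse",
            stacklevel=2,
        )
    return eps


def _window_delta_fraction(seg: np.ndarray, rate: float, delta=(1.0, 4.0)) -> float:
    """Max-over-channels delta-band fraction of 1-256 Hz power in a window."""
    n = seg.shape[1]
    win = signal.get_window("hann", n)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = np.abs(np.fft.rfft(seg * win, axis=1)) ** 2
    total_mask = (freqs >= 1.0) & (freqs < 256.0)
    delta_mask = (freqs >= delta[0]) & (freqs < delta[1])
    tot = spec[:, total_mask].sum(axis=1)
    dl = spec[:, delta_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, dl / tot, 0.0)
    return float(frac.max())


def reject_artifacts(
    rec: Recording,
    eps: EpochSet,
    amp_limit: float = 1000.0,
    slow_power_limit: float = 0.6,
    motion_threshold: float | None = None,
) -> EpochSet:
    """Reject accepted windows that contain artifacts.

    A window is rejected when any channel exceeds ``amp_limit`` microvolts in
    absolute value, or when its delta-band (1-4 Hz) relative power exceeds
    ``slow_power_limit`` while the window's motion is below threshold
    (high-voltage slow waves without locomotion).  Labels are only ever
    tightened, never un-rejected.

    ``motion_threshold`` (fraction of the recording's maximum envelope)
    overrides the threshold the epoch set was built with; this matters when
    segmentation ran unattended (threshold 0).
    """
    if motion_threshold is None:
        thr_abs = eps.motion_threshold_abs
    else:
        thr_abs = motion_threshold * (rec.motion.max() if rec.motion.size else 0.0)
    labels = eps.labels.copy()
    for i in np.flatnonzero(eps.accepted_mask):
        s, e = eps.windows[i]
        seg = rec.data[:, s:e]
        if np.abs(seg).max() > amp_limit:
            labels[i] = REJECTED_ARTIFACT
            continue
        quiescent = eps.mean_motion[i] < thr_abs
        if quiescent and _window_delta_fraction(seg, rec.rate) > slow_power_limit:
            labels[i] = REJECTED_ARTIFACT
    return replace(eps, labels=labels)


def accepted_segments(rec: Recording, eps: EpochSet, channel: str) -> list[np.ndarray]:
    """Merge accepted windows into maximal contiguous sample runs.

    Overlapping or abutting accepted windows (sliding stride) are unioned so
    each returned segment is a contiguous stretch of the original signal;
    used by the wavelet stage, which must not convolve across gaps.
    """
    wins = eps.accepted_windows
    if len(wins) == 0:
        return []
    x = rec.channel(channel)
    order = np.argsort(wins[:, 0])
    merged: list[list[int]] = []
    for s, e in wins[order]:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return [x[s:e] for s, e in merged]
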