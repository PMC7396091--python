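"""Cross-spectral coherency, magnitude-squared coherence, imaginary coherency.

Coherency is the cross-spectrum normalised by the square root of the product
of the autospectra, ``C(f) = S_AB(f) / sqrt(S_AA(f) S_BB(f))``.  Its squared
magnitude (msc, in [0, 1]) measures similarity up to a constant phase shift;
its imaginary part (imcoh) is insensitive to instantaneous (zero-lag) volume
conduction and is therefore the connectivity summary of choice here, averaged
over the 25-35 Hz interval for the inter-bulb pair.

Spectra use the same accepted 2-s Hann-tapered epochs as the power stage.
The cross-spectrum convention is ``S_AB = <X_A conj(X_B)>``, which makes
``imcoh(A, B) = sin(omega * tau)`` when B is A delayed by ``tau`` — and makes
imcoh antisymmetric under channel swap.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .preprocess import EpochSet, Recording

__all__ = [
    "DEFAULT_PAIRS",
    "IMCOH_SUMMARY_BAND",
    "cross_spectra",
    "coherency",
    "msc",
    "imcoh",
    "band_imcoh",
]

#: Electrode pairs analysed by default (inter-bulb plus bulb/hippocampal,
#: hippocampal/amygdalar and entorhinal pairs).
DEFAULT_PAIRS = (
    ("OBL", "OBR"),
    ("OBL", "CA1L"),
    ("CA1L", "BLA"),
    ("ECL", "CA1L"),
    ("ECL", "BLA"),
)

IMCOH_SUMMARY_BAND = (25.0, 35.0)


def cross_spectra(
    rec: Recording, eps: EpochSet, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Epoch-averaged cross- and auto-spectra ``(freqs, S_AB, S_AA, S_BB)``.

    Requires at least two accepted epochs: coherence estimated from a single
    segment is identically 1 and carries no information.
    """
    wins = eps.accepted_windows
    if len(wins) < 2:
        raise ValueError("need at least two accepted epochs for cross-spectra")
    a = rec.channel(pair[0])
    b = rec.channel(pair[1])
    n = int(wins[0, 1] - wins[0, 0])
    win = signal.get_window("hann", n)
    scale = 1.0 / (rec.rate * np.sum(win**2))
    freqs = np.fft.rfftfreq(n, 1.0 / rec.rate)
    sab = np.zeros(freqs.size, dtype=complex)
    saa = np.zeros(freqs.size)
    sbb = np.zeros(freqs.size)
    for s, e in wins:
        xa = np.fft.rfft(a[s:e] * win)
        xb = np.fft.rfft(b[s:e] * win)
        sab += xa * np.conj(xb) * scale
        saa += (xa * np.conj(xa)).real * scale
        sbb += (xb * np.conj(xb)).real * scale
    m = len(wins)
    if pair[0] == pair[1]:
        # self-pair: the cross-spectrum IS the autospectrum, bit for bit
        return freqs, (saa / m).astype(complex), saa / m, saa / m
    return freqs, sab / m, saa / m, sbb / m


def coherency(sab: np.ndarray, saa: np.ndarray, sbb: np.ndarray) -> np.ndarray:
    """Normalised cross-spectrum; bins with a zero autospectrum become NaN."""
    denom = np.sqrt(saa * sbb)
    out = np.full(sab.shape, np.nan + 0j, dtype=complex)
    ok = denom > 0
    out[ok] = sab[ok] / denom[ok]
    return out


def msc(coh: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence, in [0, 1] where defined."""
    return np.abs(coh) ** 2


def imcoh(coh: np.ndarray) -> np.ndarray:
    """Imaginary part of coherency, in [-1, 1] where defined."""
    return np.imag(coh)


def band_imcoh(
    freqs: np.ndarray,
    imcoh_vec: np.ndarray,
    band: tuple[float, float] = IMCOH_SUMMARY_BAND,
    absolute: bool = False,
) -> float:
    """Mean imaginary coherency over a half-open band ``[lo, hi)``.

    The signed mean is the default (it preserves the antisymmetry of imcoh
    under channel swap); set ``absolute=True`` to average ``|imcoh|``.
    """
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi) & np.isfinite(imcoh_vec)
    if not mask.any():
        raise ValueError(f"no valid bins in band ({lo}, {hi}) Hz")
    vals = np.abs(imcoh_vec[mask]) if absolute else imcoh_vec[mask]
    return float(vals.mean())
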