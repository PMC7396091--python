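"""Between-group inference on frequency-resolved and scalar summaries.

Scalars (band powers, PAC summaries, band imcoh) are compared with a Welch
two-sample t-test and a 95% CI of the mean difference.  Frequency-resolved
vectors (relative power, imcoh) go through threshold-free cluster enhancement
(TFCE, H = 2, E = 0.5) of the per-bin t-statistic, with family-wise
calibration against the permutation distribution of the maximum |TFCE|
statistic under group-label exchange.

TFCE integrates, over supra-threshold heights h (step dh), the quantity
``extent(h, x)^E * h^H * dh`` where extent is the length in bins of the
contiguous supra-threshold run containing bin x.  Positive and negative parts
of the statistic are enhanced separately (aging effects go both directions:
delta up, gamma down) and recombined with their signs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "TFCEResult",
    "two_sample_test",
    "tfce_enhance",
    "tfce_permutation",
]

TFCE_H = 2.0
TFCE_E = 0.5
TFCE_ALPHA = 0.05
#: number of integration steps when dh is derived from the data (dh = max|t|/100)
TFCE_N_STEPS = 100
#: full label enumeration is used when C(n, n_a) does not exceed this
#: (12870 = C(16, 8), the study's design size)
ENUMERATION_LIMIT = 12870


@dataclass
class TTestResult:
    t: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    df: float


def two_sample_test(a, b, alpha: float = 0.05) -> TTestResult:
    """Welch (unequal-variance) two-sample t-test with a CI on the difference.

    Degenerate input with zero variance in both groups and equal means is
    reported as t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, 0.0, 0.0, 0.0, float(a.size + b.size - 2))
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(t, 0.0, diff, diff, diff, float(a.size + b.size - 2))
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(1 - alpha)
    return TTestResult(
        float(res.statistic), float(res.pvalue), diff,
        float(ci.low), float(ci.high), float(res.df),
    )


# ---------------------------------------------------------------------------
# TFCE enhancement
# ---------------------------------------------------------------------------

def _enhance_positive_numpy(s: np.ndarray, dh: float, H: float, E: float) -> np.ndarray:
    out = np.zeros_like(s)
    smax = s.max()
    k = 1
    while True:
        h = k * dh
        if h > smax + 1e-9 * dh:
            break
        mask = s >= h - 1e-9 * dh
        if not mask.any():
            break
        edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
        for st, en in zip(edges[0::2], edges[1::2]):
            out[st:en] += (en - st) ** E * h**H * dh
        k += 1
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _enhance_positive_numba(s, dh, H, E):  # pragma: no cover
        n = s.size
        out = np.zeros(n)
        smax = 0.0
        for i in range(n):
            if s[i] > smax:
                smax = s[i]
        k = 1
        while True:
            h = k * dh
            if h > smax + 1e-9 * dh:
                break
            thr = h - 1e-9 * dh
            i = 0
            while i < n:
                if s[i] >= thr:
                    j = i
                    while j < n and s[j] >= thr:
                        j += 1
                    val = (j - i) ** E * h**H * dh
                    for b in range(i, j):
                        out[b] += val
                    i = j
                else:
                    i += 1
            k += 1
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _enhance_positive(s: np.ndarray, dh: float, H: float, E: float) -> np.ndarray:
    if _HAVE_NUMBA:
        return _enhance_positive_numba(np.ascontiguousarray(s), dh, H, E)
    return _enhance_positive_numpy(s, dh, H, E)


def tfce_enhance(
    stat,
    H: float = TFCE_H,
    E: float = TFCE_E,
    dh: float | None = None,
    n_steps: int = TFCE_N_STEPS,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D statistic vector.

    Positive and negative parts are enhanced separately and the output keeps
    the input's sign.  When ``dh`` is not given it is ``max|stat| / n_steps``;
    with a fixed ``dh`` the transform is monotone — raising any ``|stat|``
    never lowers any ``|tfce|``.
    """
    s = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("statistic vector must be finite")
    out = np.zeros_like(s)
    m = float(np.abs(s).max()) if s.size else 0.0
    if m == 0:
        return out
    if dh is None:
        dh = m / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    out += _enhance_positive(np.clip(s, 0, None), dh, H, E)
    out -= _enhance_positive(np.clip(-s, 0, None), dh, H, E)
    return out


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


@dataclass
class TFCEResult:
    """TFCE group inference over a frequency grid."""

    freqs: np.ndarray
    t_stat: np.ndarray
    tfce_stat: np.ndarray
    perm_null: np.ndarray
    p_values: np.ndarray
    sig_mask: np.ndarray
    clusters: list[tuple[float, float]]
    alpha: float
    n_perm: int
    exhaustive: bool


def _welch_t_vector(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-bin Welch t between two (n_subjects, n_bins) matrices."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def tfce_permutation(
    group_a,
    group_b,
    freqs=None,
    H: float = TFCE_H,
    E: float = TFCE_E,
    alpha: float = TFCE_ALPHA,
    n_perm: int = 1000,
    seed: int = 0,
    n_steps: int = TFCE_N_STEPS,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> TFCEResult:
    """Frequency-resolved TFCE with max-statistic permutation calibration.

    ``group_a`` / ``group_b`` are per-animal vectors over the same frequency
    grid, shape ``(n_animals, n_bins)``.  Group labels are exchanged under
    the null; all label assignments are enumerated when their count is at
    most C(16, 8) = 12870, otherwise a seeded random subset of ``n_perm``
    assignments (always including the observed one) is used.  Per-bin
    family-wise p-values come from the null distribution of the maximum
    |TFCE| over bins.
    """
    xa = np.atleast_2d(np.asarray(group_a, dtype=float))
    xb = np.atleast_2d(np.asarray(group_b, dtype=float))
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups must share the frequency grid")
    na, nb = xa.shape[0], xb.shape[0]
    n = na + nb
    if n < 6:
        raise ValueError("need at least six animals in total")
    data = np.vstack([xa, xb])
    if freqs is None:
        freqs = np.arange(data.shape[1], dtype=float)
    freqs = np.asarray(freqs, dtype=float)

    t_obs = _welch_t_vector(xa, xb)
    tfce_obs = tfce_enhance(t_obs, H=H, E=E, n_steps=n_steps)

    n_assign = math.comb(n, na)
    exhaustive = n_assign <= enumeration_limit
    if exhaustive:
        assignments = combinations(range(n), na)
        total = n_assign
    else:
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations without full enumeration")
        rng = np.random.default_rng(seed)
        idx_obs = tuple(range(na))
        assignments = [idx_obs] + [
            tuple(rng.permutation(n)[:na]) for _ in range(n_perm - 1)
        ]
        total = n_perm

    null_max = np.empty(total)
    all_idx = np.arange(n)
    for pi, sel in enumerate(assignments):
        sel = np.asarray(sel)
        rest = np.setdiff1d(all_idx, sel, assume_unique=True)
        t = _welch_t_vector(data[sel], data[rest])
        tf = tfce_enhance(t, H=H, E=E, n_steps=n_steps)
        null_max[pi] = np.abs(tf).max() if tf.size else 0.0

    abs_obs = np.abs(tfce_obs)
    p_values = np.array([np.mean(null_max >= v) for v in abs_obs])
    sig = (p_values <= alpha) & (abs_obs > 0)

    clusters: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.r_[0, sig.astype(np.int8), 0]))
    for st, en in zip(edges[0::2], edges[1::2]):
        clusters.append((float(freqs[st]), float(freqs[en - 1])))

    return TFCEResult(
        freqs, t_obs, tfce_obs, null_max, p_values, sig, clusters,
        alpha, total, exhaustive,
    )
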