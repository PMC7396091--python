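"""The LTP arm: evoked-sweep feature extraction and potentiation statistics.

A :class:`Sweep` is a single stimulation-evoked waveform recorded at the
CA1 stratum pyramidale in response to Schaffer-collateral stimulation.  The
module extracts its standard features (fEPSP latency/amplitude/slope and the
population spike amplitude), applies the study's inclusion windows, builds
sigmoidal input/output curves with 50%-of-maximum test-stimulus selection,
normalises HFS time courses to the pre-tetanus baseline, and compares early
(0-30 min) and late (60-90 min) post-HFS phases between groups.

Feature definitions
-------------------
* negative peak: minimum voltage inside the search window;
* latency: time of that minimum, in ms after the stimulus;
* slope: least-squares line over the central 80% of the interval between the
  artifact (blanking) end and the negative peak, trimming 10% at each end;
* amplitude: baseline-to-peak deflection;
* PSA: tangent method — vertical distance from the line joining the two
  positive inflection peaks flanking the population spike to the spike
  trough.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "Sweep",
    "SweepFeatures",
    "IOCurve",
    "LTPTimecourse",
    "PhaseStats",
    "INCLUSION_WINDOWS",
    "STANDARD_INTENSITIES_MV",
    "extract_features",
    "check_inclusion",
    "build_io_curve",
    "timecourse_from_sweeps",
    "normalize_timecourse",
    "ltp_phase_stats",
    "mixed_anova",
]

#: Inclusion windows for a usable fEPSP at 200 us stimulus duration:
#: latency to peak negative deflection in ms, maximum amplitude in uV,
#: and maximum slope magnitude in uV/ms.
INCLUSION_WINDOWS = {
    "latency": (6.0, 10.0),
    "amplitude": (1500.0, 2500.0),
    "slope": (400.0, 900.0),
}

#: Standard stimulation ladder for input/output curves (mV).
STANDARD_INTENSITIES_MV = tuple(float(v) for v in range(1000, 10001, 1000))

#: High-frequency stimulation protocol attached to time courses as metadata.
HFS_PROTOCOL = {
    "n_trains": 2,
    "pulses_per_train": 50,
    "train_freq_hz": 100.0,
    "pulse_width_us": 200.0,
    "intertrain_interval_s": 30.0,
}


@dataclass
class SweepFeatures:
    latency_ms: float
    amplitude_uv: float
    slope_uv_per_ms: float
    psa_uv: float
    qc_pass: bool
    qc_reason: str = ""


@dataclass
class Sweep:
    """One evoked waveform on a time grid relative to the stimulus (ms)."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    stim_intensity_mv: float = float("nan")
    timepoint_min: float | None = None
    features: SweepFeatures | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.shape != self.voltage_uv.shape:
            raise ValueError("time and voltage must have equal length")


@dataclass
class IOCurve:
    """Input/output curve: per-intensity mean responses and a 4PL fit."""

    intensities_mv: np.ndarray
    mean_slope: np.ndarray
    mean_psa: np.ndarray
    floor: float = float("nan")
    ceiling: float = float("nan")
    half_max_mv: float = float("nan")
    steepness_mv: float = float("nan")
    test_stimulus_mv: float | None = None
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class LTPTimecourse:
    """Baseline-normalised potentiation time course (percent of baseline)."""

    timepoints_min: np.ndarray
    fepsp_pct: np.ndarray
    psa_pct: np.ndarray
    hfs_time_min: float = 0.0
    baseline_mask: np.ndarray | None = None
    hfs_protocol: Mapping[str, float] = field(default_factory=lambda: dict(HFS_PROTOCOL))


@dataclass
class PhaseStats:
    """Group comparison of early/late post-HFS phases."""

    table: pd.DataFrame
    anova: pd.DataFrame
    dunnett: pd.DataFrame


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    sweep: Sweep,
    blanking_ms: float = 1.5,
    search_window_ms: tuple[float, float] = (4.0, 15.0),
    min_response_uv: float = 50.0,
    noise_mult: float = 5.0,
) -> Sweep:
    """Extract fEPSP and population-spike features from one sweep.

    The negative peak is searched after the stimulus-artifact blanking
    period.  A sweep with no deflection below the noise floor (``noise_mult``
    times the pre-stimulus SD, at least ``min_response_uv``) fails QC with
    reason ``"no response"`` and carries NaN features.
    """
    if search_window_ms[0] < blanking_ms:
        raise ValueError("search window must start after the blanking period")
    t, v = sweep.time_ms, sweep.voltage_uv
    pre = v[t < 0]
    base = float(pre.mean()) if pre.size else 0.0
    noise_sd = float(pre.std()) if pre.size else 0.0

    mask = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    if not mask.any():
        raise ValueError("search window contains no samples")
    idx = np.flatnonzero(mask)
    trough_idx = idx[np.argmin(v[idx])]
    t_peak = float(t[trough_idx])
    depth = base - float(v[trough_idx])

    if depth < max(min_response_uv, noise_mult * noise_sd):
        feats = SweepFeatures(np.nan, np.nan, np.nan, np.nan, False, "no response")
        return replace(sweep, features=feats)

    # central 80% of [blanking end, negative peak]
    span = t_peak - blanking_ms
    fit_lo, fit_hi = blanking_ms + 0.1 * span, t_peak - 0.1 * span
    fmask = (t >= fit_lo) & (t <= fit_hi)
    if fmask.sum() < 2:
        feats = SweepFeatures(t_peak, depth, np.nan, np.nan, False, "slope interval too short")
        return replace(sweep, features=feats)
    slope = float(np.polyfit(t[fmask], v[fmask], 1)[0])

    psa = _population_spike_amplitude(t, v, trough_idx, blanking_ms)
    feats = SweepFeatures(t_peak, depth, slope, psa, True, "")
    return replace(sweep, features=feats)


def _population_spike_amplitude(
    t: np.ndarray,
    v: np.ndarray,
    trough_idx: int,
    blanking_ms: float,
    max_flank_ms: float = 1.0,
) -> float:
    """Tangent method: chord across the two positivities flanking the spike.

    The spike trough is the sweep's negative peak; the flanking positivities
    are the highest points within ``max_flank_ms`` on each side of the trough
    (the spike is a fast deflection, so its inflection peaks sit within a
    millisecond of the trough).  The chord joining them is evaluated at the
    trough time.  NaN when a flank window is empty.  Only meaningful when a
    population spike is actually present.
    """
    t_tr = t[trough_idx]
    left = np.flatnonzero(
        (t >= max(blanking_ms, t_tr - max_flank_ms)) & (t < t_tr)
    )
    right = np.flatnonzero((t > t_tr) & (t <= t_tr + max_flank_ms))
    if left.size == 0 or right.size == 0:
        return float("nan")
    i0 = left[np.argmax(v[left])]
    i1 = right[np.argmax(v[right])]
    frac = (t_tr - t[i0]) / (t[i1] - t[i0])
    chord = v[i0] + frac * (v[i1] - v[i0])
    return float(chord - v[trough_idx])


def check_inclusion(sweep: Sweep) -> tuple[bool, str]:
    """Apply the study's inclusion windows; report the first violation.

    Pass iff latency is within 6-10 ms, amplitude within 1500-2500 uV and
    slope magnitude within 400-900 uV/ms.  Boundaries are inclusive.
    """
    f = sweep.features
    if f is None:
        raise ValueError("extract features before checking inclusion")
    if not f.qc_pass or not np.isfinite(f.latency_ms):
        return False, "no response"
    checks = [
        ("latency", f.latency_ms),
        ("amplitude", f.amplitude_uv),
        ("slope", abs(f.slope_uv_per_ms)),
    ]
    for name, value in checks:
        lo, hi = INCLUSION_WINDOWS[name]
        if not (lo <= value <= hi):
            return False, name
    return True, ""


# ---------------------------------------------------------------------------
# input/output curves
# ---------------------------------------------------------------------------

def _logistic4(x, floor, ceiling, x0, k):
    return floor + (ceiling - floor) / (1.0 + np.exp(-(x - x0) / k))


def build_io_curve(
    sweeps_by_intensity: Mapping[float, Sequence[Sweep]],
    n_per_intensity: int = 3,
    residual_limit: float = 0.2,
) -> IOCurve:
    """Build an I/O curve from 3 sweeps per intensity and fit a sigmoid.

    The per-intensity response is the mean slope magnitude (and mean PSA) of
    exactly ``n_per_intensity`` sweeps; sweeps that failed QC with "no
    response" contribute zero (sub-threshold stimulation).  A four-parameter
    logistic is fitted to slope vs. intensity by least squares and the test
    stimulus is the intensity whose fitted response equals 50% of the fitted
    maximum.  Curves without dynamic range or with poor fits are flagged and
    carry no test stimulus.
    """
    intensities = np.array(sorted(sweeps_by_intensity), dtype=float)
    mean_slope = np.empty_like(intensities)
    mean_psa = np.empty_like(intensities)
    for i, inten in enumerate(intensities):
        sweeps = list(sweeps_by_intensity[inten])
        if len(sweeps) != n_per_intensity:
            raise ValueError(
                f"expected {n_per_intensity} sweeps at {inten} mV, got {len(sweeps)}"
            )
        slopes, psas = [], []
        for sw in sweeps:
            if sw.features is None:
                sw = extract_features(sw)
            f = sw.features
            slopes.append(abs(f.slope_uv_per_ms) if f.qc_pass else 0.0)
            psas.append(f.psa_uv if f.qc_pass and np.isfinite(f.psa_uv) else 0.0)
        mean_slope[i] = np.mean(slopes)
        mean_psa[i] = np.mean(psas)

    curve = IOCurve(intensities, mean_slope, mean_psa)
    ymax = mean_slope.max()
    if ymax <= 0 or (ymax - mean_slope.min()) < 0.05 * ymax:
        curve.flagged = True
        curve.flag_reason = "no dynamic range"
        return curve

    span = intensities.max() - intensities.min()
    p0 = (mean_slope.min(), ymax, float(np.median(intensities)), span / 8)
    bounds = (
        [0.0, ymax, intensities.min(), 1e-3 * span],
        [ymax, 10.0 * ymax, intensities.max(), span],
    )
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, intensities, mean_slope, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        curve.flagged = True
        curve.flag_reason = "fit failed"
        return curve
    floor, ceiling, x0, k = (float(p) for p in popt)
    resid = mean_slope - _logistic4(intensities, *popt)
    if np.sqrt(np.mean(resid**2)) > residual_limit * (ceiling - floor):
        curve.flagged = True
        curve.flag_reason = "poor fit"
        return curve

    curve.floor, curve.ceiling, curve.half_max_mv, curve.steepness_mv = floor, ceiling, x0, k
    target = 0.5 * ceiling
    if floor < target < ceiling:
        curve.test_stimulus_mv = float(x0 - k * np.log((ceiling - target) / (target - floor)))
    else:
        curve.flagged = True
        curve.flag_reason = "50% of maximum outside fitted range"
    return curve


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def timecourse_from_sweeps(
    sweeps: Sequence[Sweep], n_per_timepoint: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate sweeps into per-timepoint means of slope magnitude and PSA.

    Each timepoint must contribute exactly ``n_per_timepoint`` sweeps (the
    recording protocol averages 5 responses per 2.5-min timepoint).
    """
    by_tp: dict[float, list[Sweep]] = {}
    for sw in sweeps:
        if sw.timepoint_min is None:
            raise ValueError("sweep without a timepoint")
        by_tp.setdefault(float(sw.timepoint_min), []).append(sw)
    tps = np.array(sorted(by_tp), dtype=float)
    fepsp = np.empty_like(tps)
    psa = np.empty_like(tps)
    for i, tp in enumerate(tps):
        group = by_tp[tp]
        if len(group) != n_per_timepoint:
            raise ValueError(
                f"timepoint {tp} min has {len(group)} sweeps, expected {n_per_timepoint}"
            )
        feats = [
            (sw.features if sw.features is not None else extract_features(sw).features)
            for sw in group
        ]
        fepsp[i] = np.mean([abs(f.slope_uv_per_ms) for f in feats])
        psa[i] = np.mean([f.psa_uv for f in feats])
    return tps, fepsp, psa


def normalize_timecourse(
    timepoints_min: np.ndarray,
    fepsp: np.ndarray,
    psa: np.ndarray,
    hfs_time_min: float = 0.0,
    baseline_span_min: float = 30.0,
    baseline_mode: str = "window",
    baseline_n_points: int = 12,
) -> LTPTimecourse:
    """Express fEPSP slope and PSA as percent of the pre-HFS baseline.

    ``baseline_mode="window"`` (default) averages the last
    ``baseline_span_min`` minutes before HFS; ``"n_points"`` averages the
    last ``baseline_n_points`` pre-HFS timepoints instead.  The baseline mean
    of the normalised series is 100 exactly by construction.
    """
    t = np.asarray(timepoints_min, dtype=float)
    fepsp = np.asarray(fepsp, dtype=float)
    psa = np.asarray(psa, dtype=float)
    pre = t < hfs_time_min
    if not pre.any() or (hfs_time_min - t.min()) < baseline_span_min - 1e-9:
        raise ValueError("need at least the baseline span of pre-HFS timepoints")
    if baseline_mode == "window":
        bmask = pre & (t >= hfs_time_min - baseline_span_min)
    elif baseline_mode == "n_points":
        pre_idx = np.flatnonzero(pre)
        bmask = np.zeros_like(pre)
        bmask[pre_idx[-baseline_n_points:]] = True
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    out = []
    for series in (fepsp, psa):
        bmean = series[bmask].mean()
        if bmean <= 0:
            raise ValueError("baseline mean must be positive")
        out.append(100.0 * series / bmean)
    return LTPTimecourse(t, out[0], out[1], hfs_time_min, bmask)


# ---------------------------------------------------------------------------
# phase statistics
# ---------------------------------------------------------------------------

PHASES = {"early": (0.0, 30.0), "late": (60.0, 90.0)}


def _phase_mask(tc: LTPTimecourse, lo: float, hi: float) -> np.ndarray:
    rel = tc.timepoints_min - tc.hfs_time_min
    return (rel > lo) & (rel <= hi)


def mixed_anova(values: np.ndarray, groups: Sequence[str]) -> pd.DataFrame:
    """Mixed-design ANOVA: one between factor (group), one within factor.

    ``values`` has shape ``(n_subjects, n_levels)``; ``groups`` assigns each
    subject to a group.  Returns the classical SS decomposition with F and p
    for the group, within-factor and interaction effects.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n, L = y.shape
    glabels = np.unique(groups)
    G = len(glabels)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    level_mean = y.mean(axis=0)
    g_mean = np.array([y[groups == g].mean() for g in glabels])
    n_g = np.array([(groups == g).sum() for g in glabels])
    gl_mean = np.array([y[groups == g].mean(axis=0) for g in glabels])

    ss_group = float((n_g * L * (g_mean - grand) ** 2).sum())
    ss_subj = float(
        L * sum(((subj_mean[groups == g] - g_mean[i]) ** 2).sum() for i, g in enumerate(glabels))
    )
    ss_level = float(n * ((level_mean - grand) ** 2).sum())
    ss_inter = float(
        sum(
            n_g[i] * ((gl_mean[i] - g_mean[i] - level_mean + grand) ** 2).sum()
            for i in range(G)
        )
    )
    resid = y.copy()
    for i, g in enumerate(glabels):
        sel = groups == g
        resid[sel] -= (
            subj_mean[sel][:, None] + gl_mean[i][None, :] - g_mean[i]
        )
    ss_err = float((resid**2).sum())

    df_group, df_subj = G - 1, n - G
    df_level, df_err = L - 1, (n - G) * (L - 1)
    rows = []
    for name, ss, df, ms_err, df_err_ in (
        ("group", ss_group, df_group, ss_subj / df_subj, df_subj),
        ("phase", ss_level, df_level, ss_err / df_err, df_err),
        ("group_x_phase", ss_inter, df_group * df_level, ss_err / df_err, df_err),
    ):
        ms = ss / df if df else np.nan
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, df, df_err_)) if np.isfinite(F) else 0.0
        rows.append({"effect": name, "ss": ss, "df": df, "F": F, "p": p})
    return pd.DataFrame(rows)


def ltp_phase_stats(
    tc_young: Sequence[LTPTimecourse],
    tc_aged: Sequence[LTPTimecourse],
    phases: Mapping[str, tuple[float, float]] | None = None,
) -> PhaseStats:
    """Compare early/late post-HFS phases between young and aged groups.

    Per animal, each phase is summarised by the mean of the normalised values
    over its window; the group difference is reported in percent of the young
    mean, with a Welch two-sample test.  A mixed ANOVA (group x phase, with
    the baseline window as an additional within level) and Dunnett contrasts
    of each phase against baseline within each group complete the picture.
    """
    from .groupstats import two_sample_test  # local import avoids a cycle

    if len(tc_young) < 2 or len(tc_aged) < 2:
        raise ValueError("need at least two animals per group")
    phases = dict(phases or PHASES)

    def phase_means(tcs, metric):
        out = {}
        for name, (lo, hi) in phases.items():
            vals = []
            for tc in tcs:
                m = _phase_mask(tc, lo, hi)
                if not m.any():
                    raise ValueError(f"time course lacks coverage of phase {name!r}")
                vals.append(getattr(tc, metric)[m].mean())
            out[name] = np.array(vals)
        # baseline level for the ANOVA
        vals = []
        for tc in tcs:
            bm = tc.baseline_mask
            if bm is None:
                bm = tc.timepoints_min < tc.hfs_time_min
            vals.append(getattr(tc, metric)[bm].mean())
        out["baseline"] = np.array(vals)
        return out

    rows, anova_rows, dunnett_rows = [], [], []
    for metric, attr in (("fepsp", "fepsp_pct"), ("psa", "psa_pct")):
        ym = phase_means(tc_young, attr)
        am = phase_means(tc_aged, attr)
        for name in phases:
            res = two_sample_test(am[name], ym[name])
            young_mean = float(ym[name].mean())
            aged_mean = float(am[name].mean())
            rows.append(
                {
                    "metric": metric,
                    "phase": name,
                    "young_mean_pct": young_mean,
                    "aged_mean_pct": aged_mean,
                    "pct_difference": 100.0 * (aged_mean - young_mean) / young_mean,
                    "t": res.t,
                    "p": res.p,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
        levels = ["baseline"] + list(phases)
        values = np.vstack(
            [
                np.column_stack([ym[lv] for lv in levels]),
                np.column_stack([am[lv] for lv in levels]),
            ]
        )
        glab = ["young"] * len(tc_young) + ["aged"] * len(tc_aged)
        an = mixed_anova(values, glab)
        an.insert(0, "metric", metric)
        anova_rows.append(an)

        # Dunnett: each phase vs. baseline within group, on per-animal
        # per-timepoint observations
        for gname, tcs in (("young", tc_young), ("aged", tc_aged)):
            samples = []
            for name, (lo, hi) in phases.items():
                samples.append(
                    np.concatenate([getattr(tc, attr)[_phase_mask(tc, lo, hi)] for tc in tcs])
                )
            control = np.concatenate(
                [
                    getattr(tc, attr)[
                        tc.baseline_mask
                        if tc.baseline_mask is not None
                        else tc.timepoints_min < tc.hfs_time_min
                    ]
                    for tc in tcs
                ]
            )
            dres = stats.dunnett(*samples, control=control)
            for name, p in zip(phases, np.atleast_1d(dres.pvalue)):
                dunnett_rows.append(
                    {"metric": metric, "group": gname, "phase": name, "p_vs_baseline": float(p)}
                )

    return PhaseStats(
        table=pd.DataFrame(rows),
        anova=pd.concat(anova_rows, ignore_index=True),
        dunnett=pd.DataFrame(dunnett_rows),
    )
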