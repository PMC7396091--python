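"""Sweep feature extraction, inclusion gating, I/O curves and LTP statistics."""
import numpy as np
import pytest
from scipy.signal import find_peaks

from lfpnet.evoked import (
    INCLUSION_WINDOWS,
    Sweep,
    SweepFeatures,
    build_io_curve,
    check_inclusion,
    extract_features,
    ltp_phase_stats,
    mixed_anova,
    normalize_timecourse,
    timecourse_from_sweeps,
)
from lfpnet.synthgen import (
    EvokedGroundTruth,
    SigmoidIO,
    generate_sweep,
)

DT = 1 / 3.0


def make_sweep(v, t=None):
    if t is None:
        t = np.arange(-5.0, -5.0 + len(v) * DT - 1e-9, DT)[: len(v)]
    return Sweep(np.asarray(t, float), np.asarray(v, float))


class TestFeatureExtraction:
    def test_linear_ramp_slope_recovered_within_one_percent(self):
        t = np.arange(-5.0, 45.0, DT)
        v = np.zeros_like(t)
        ramp = (t >= 1.5) & (t <= 8.0)
        v[ramp] = -60.0 * (t[ramp] - 1.5)
        v[t > 8.0] = -60.0 * 6.5
        sw = extract_features(make_sweep(v, t), search_window_ms=(4.0, 9.0))
        assert sw.features.slope_uv_per_ms == pytest.approx(-60.0, abs=0.6)

    def test_generator_sweep_slope_recovered_within_one_percent(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0, spike_amplitude_uv=0.0)
        sw = extract_features(generate_sweep(truth, 4000.0))
        # at the half-max test stimulus the ramp slope is half the ceiling slope
        expected = -0.5 * truth.epsp_slope_uv_per_ms
        assert sw.features.slope_uv_per_ms == pytest.approx(expected, rel=0.01)

    def test_flat_trace_fails_qc(self):
        sw = extract_features(make_sweep(np.zeros(150)))
        assert not sw.features.qc_pass
        assert sw.features.qc_reason == "no response"

    def test_psa_matches_dense_closed_form_tangent_oracle(self):
        truth = EvokedGroundTruth(
            noise_sd_uv=0.0,
            spike_amplitude_uv=800.0,
            sigmoid_io=SigmoidIO(half_max_mv=100.0, steepness_mv=10.0),
        )
        sw = extract_features(generate_sweep(truth, 10000.0))

        # oracle: evaluate the closed-form waveform on a dense grid and apply
        # the tangent (chord across flanking positivities) rule by hand
        td = np.arange(2.0, 20.0, 1e-3)
        amp, S = truth.epsp_amplitude_uv, truth.spike_amplitude_uv
        on, pk = truth.epsp_onset_ms, truth.epsp_peak_ms
        fe = pk + truth.epsp_flat_width_ms
        vd = np.where(
            td < pk,
            -amp * (td - on) / (pk - on),
            np.where(td <= fe, -amp, -amp * np.exp(-(td - fe) / truth.recovery_tau_ms)),
        )
        d = td - truth.spike_center_ms
        vd = (
            vd
            + truth.spike_positivity_ratio
            * S
            * np.exp(-(d**2) / (2 * truth.spike_positivity_width_ms**2))
            - S * np.exp(-(d**2) / (2 * truth.spike_width_ms**2))
        )
        trough = np.argmin(vd)
        maxima, _ = find_peaks(vd)
        i0 = maxima[maxima < trough][-1]
        i1 = maxima[maxima > trough][0]
        frac = (td[trough] - td[i0]) / (td[i1] - td[i0])
        expected = vd[i0] + frac * (vd[i1] - vd[i0]) - vd[trough]

        assert sw.features.psa_uv == pytest.approx(expected, rel=0.05)

    def test_translation_equivariance(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0)
        sw = generate_sweep(truth, 4000.0)
        f0 = extract_features(sw).features
        shift = 2.0
        shifted = Sweep(sw.time_ms + shift, sw.voltage_uv)
        f1 = extract_features(
            shifted, blanking_ms=1.5 + shift, search_window_ms=(4.0 + shift, 15.0 + shift)
        ).features
        assert f1.latency_ms == pytest.approx(f0.latency_ms + shift, abs=1e-9)
        assert f1.slope_uv_per_ms == pytest.approx(f0.slope_uv_per_ms, rel=1e-9)
        assert f1.amplitude_uv == pytest.approx(f0.amplitude_uv, rel=1e-9)
        assert f1.psa_uv == pytest.approx(f0.psa_uv, rel=1e-9)

    def test_slope_error_grows_with_noise(self):
        truth0 = EvokedGroundTruth(noise_sd_uv=0.0, spike_amplitude_uv=0.0)
        ref = extract_features(generate_sweep(truth0, 4000.0)).features.slope_uv_per_ms

        def mean_err(sd):
            errs = []
            for seed in range(20):
                truth = EvokedGroundTruth(noise_sd_uv=sd, spike_amplitude_uv=0.0)
                f = extract_features(generate_sweep(truth, 4000.0, seed=seed)).features
                errs.append(abs(f.slope_uv_per_ms - ref))
            return np.mean(errs)

        assert mean_err(10.0) < mean_err(80.0)


class TestInclusion:
    @pytest.mark.parametrize(
        "latency,amplitude,slope,expected",
        [
            (7.0, 2000.0, 600.0, (True, "")),
            (6.0, 1500.0, 400.0, (True, "")),  # boundaries inclusive
            (10.0, 2500.0, 900.0, (True, "")),
            (5.0, 2000.0, 600.0, (False, "latency")),
            (7.0, 3000.0, 600.0, (False, "amplitude")),
            (7.0, 2000.0, 300.0, (False, "slope")),
            (5.0, 3000.0, 300.0, (False, "latency")),  # first violation reported
        ],
    )
    def test_inclusion_windows(self, latency, amplitude, slope, expected):
        sw = make_sweep(np.zeros(10))
        sw.features = SweepFeatures(latency, amplitude, -slope, 500.0, True)
        assert check_inclusion(sw) == expected

    def test_inclusion_requires_features(self):
        with pytest.raises(ValueError):
            check_inclusion(make_sweep(np.zeros(10)))

    def test_no_response_fails_inclusion(self):
        sw = extract_features(make_sweep(np.zeros(150)))
        assert check_inclusion(sw) == (False, "no response")


class TestIOCurve:
    def io_sweeps(self, truth):
        return {
            float(i): [extract_features(generate_sweep(truth, i, seed=s)) for s in range(3)]
            for i in range(1000, 10001, 1000)
        }

    def test_half_max_recovered_on_noiseless_sigmoid(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0, sigmoid_io=SigmoidIO(half_max_mv=4000.0))
        curve = build_io_curve(self.io_sweeps(truth))
        assert not curve.flagged
        assert curve.test_stimulus_mv == pytest.approx(4000.0, abs=100.0)
        assert curve.ceiling >= curve.mean_slope.max()

    def test_default_parameters_put_test_stimulus_in_study_range(self):
        curve = build_io_curve(self.io_sweeps(EvokedGroundTruth()))
        assert not curve.flagged
        assert 3300.0 <= curve.test_stimulus_mv <= 4700.0

    def test_constant_responses_flagged_without_test_stimulus(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0)
        sw = extract_features(generate_sweep(truth, 8000.0))
        curve = build_io_curve({float(i): [sw] * 3 for i in range(1000, 10001, 1000)})
        assert curve.flagged
        assert curve.flag_reason == "no dynamic range"
        assert curve.test_stimulus_mv is None

    def test_wrong_sweep_count_refused(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0)
        sw = extract_features(generate_sweep(truth, 5000.0))
        with pytest.raises(ValueError, match="expected 3"):
            build_io_curve({5000.0: [sw, sw]})


class TestTimecourse:
    tps = np.concatenate([np.arange(-30.0, 0.0, 2.5), np.arange(2.5, 92.5, 2.5)])

    def test_constant_series_normalises_to_100(self):
        vals = np.full(self.tps.size, 7.7)
        tc = normalize_timecourse(self.tps, vals, vals)
        np.testing.assert_allclose(tc.fepsp_pct, 100.0)
        np.testing.assert_allclose(tc.psa_pct, 100.0)

    def test_post_hfs_scaling_reflected_in_percent(self):
        vals = np.where(self.tps < 0, 4.0, 6.0)
        tc = normalize_timecourse(self.tps, vals, vals)
        assert tc.fepsp_pct[self.tps >= 0] == pytest.approx(150.0)

    def test_baseline_mean_exactly_100_and_idempotent(self):
        rng = np.random.default_rng(0)
        vals = 5.0 + 0.3 * rng.standard_normal(self.tps.size)
        tc = normalize_timecourse(self.tps, vals, vals)
        assert tc.fepsp_pct[tc.baseline_mask].mean() == pytest.approx(100.0, abs=1e-12)
        tc2 = normalize_timecourse(self.tps, tc.fepsp_pct, tc.psa_pct)
        np.testing.assert_allclose(tc2.fepsp_pct, tc.fepsp_pct, atol=1e-12)

    def test_six_point_baseline_config(self):
        vals = np.ones(self.tps.size)
        tc = normalize_timecourse(
            self.tps, vals, vals, baseline_mode="n_points", baseline_n_points=6
        )
        assert tc.baseline_mask.sum() == 6

    def test_nonpositive_baseline_refused(self):
        vals = np.zeros(self.tps.size)
        with pytest.raises(ValueError, match="baseline mean"):
            normalize_timecourse(self.tps, vals, vals)

    def test_insufficient_baseline_refused(self):
        tps = np.arange(-10.0, 90.0, 2.5)
        vals = np.ones(tps.size)
        with pytest.raises(ValueError, match="baseline"):
            normalize_timecourse(tps, vals, vals)

    def test_aggregation_requires_five_sweeps_per_timepoint(self):
        truth = EvokedGroundTruth(noise_sd_uv=0.0)
        sweeps = [
            generate_sweep(truth, 4000.0, timepoint_min=0.0) for _ in range(4)
        ]
        with pytest.raises(ValueError, match="expected 5"):
            timecourse_from_sweeps(sweeps)


def synthetic_timecourse(pot_early, scale=1.0, seed=0):
    tps = np.concatenate([np.arange(-30.0, 0.0, 2.5), np.arange(2.5, 92.5, 2.5)])
    rng = np.random.default_rng(seed)
    factor = np.where(tps < 0, 1.0, pot_early)
    vals = scale * factor * (1.0 + 0.01 * rng.standard_normal(tps.size))
    return normalize_timecourse(tps, vals, vals)


class TestPhaseStats:
    def test_identical_groups_give_zero_difference(self):
        tcs = [synthetic_timecourse(2.0, seed=s) for s in range(3)]
        stats = ltp_phase_stats(tcs, tcs)
        assert np.allclose(stats.table["pct_difference"], 0.0, atol=1e-9)
        assert np.all(stats.table["p"] > 0.99)

    def test_aged_multiplier_recovered_as_percent_difference(self):
        young = [synthetic_timecourse(2.0, seed=s) for s in range(6)]
        aged = [synthetic_timecourse(2.0 * 0.62, seed=100 + s) for s in range(6)]
        stats = ltp_phase_stats(young, aged)
        early = stats.table[
            (stats.table["metric"] == "fepsp") & (stats.table["phase"] == "early")
        ].iloc[0]
        assert early["pct_difference"] == pytest.approx(-38.0, abs=2.0)
        assert early["p"] < 0.01
        dn = stats.dunnett
        assert (dn[dn["group"] == "young"]["p_vs_baseline"] < 0.01).all()

    def test_single_animal_group_refused(self):
        tc = synthetic_timecourse(2.0)
        with pytest.raises(ValueError):
            ltp_phase_stats([tc], [tc, tc])


def test_mixed_anova_matches_reference_implementation():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(5)
    n, levels = 6, 3
    groups = ["young"] * 3 + ["aged"] * 3
    values = rng.standard_normal((n, levels)) + np.array([0.0, 1.0, 0.5])
    values[3:] += 0.8
    ours = mixed_anova(values, groups)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), levels),
            "group": np.repeat(groups, levels),
            "phase": np.tile([f"p{j}" for j in range(levels)], n),
            "y": values.ravel(),
        }
    )
    ref = pg.mixed_anova(
        data=df, dv="y", within="phase", between="group", subject="subject"
    )
    assert ours[ours["effect"] == "group"]["F"].iloc[0] == pytest.approx(
        ref[ref["Source"] == "group"]["F"].iloc[0], rel=1e-6
    )
    assert ours[ours["effect"] == "phase"]["F"].iloc[0] == pytest.approx(
        ref[ref["Source"] == "phase"]["F"].iloc[0], rel=1e-6
    )
    assert ours[ours["effect"] == "group_x_phase"]["F"].iloc[0] == pytest.approx(
        ref[ref["Source"] == "Interaction"]["F"].iloc[0], rel=1e-6
    )
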