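"""Morlet phase/amplitude extraction and modulation-index estimation."""
import numpy as np
import pytest

from lfpnet.pac import (
    F_HIGH_GRID,
    F_LOW_GRID,
    FULL_WINDOW,
    THETA_GAMMA_WINDOW,
    Comodulogram,
    comodulogram,
    mean_abs_z,
    modulation_index,
    morlet_phase_amp,
    pac_summary,
    surrogate_threshold,
)
from lfpnet.synthgen import generate_pac_signal

FS = 512.0


class TestMorlet:
    def test_tone_amplitude_constant_and_phase_advances_linearly(self):
        f = 20.0
        t = np.arange(int(10 * FS)) / FS
        x = 2.5 * np.cos(2 * np.pi * f * t)
        phase, amp, edge = morlet_phase_amp(x, FS, f)
        core = slice(edge, -edge)
        a = amp[core]
        assert a.std() / a.mean() < 0.01
        assert a.mean() == pytest.approx(2.5, rel=0.02)
        dphi = np.diff(np.unwrap(phase[core]))
        assert dphi.mean() == pytest.approx(2 * np.pi * f / FS, rel=1e-3)

    def test_quadrature_inputs_differ_by_half_pi(self):
        f = 12.0
        t = np.arange(int(8 * FS)) / FS
        pc, _, edge = morlet_phase_amp(np.cos(2 * np.pi * f * t), FS, f)
        ps, _, _ = morlet_phase_amp(np.sin(2 * np.pi * f * t), FS, f)
        core = slice(edge, -edge)
        diff = np.angle(np.exp(1j * (pc[core] - ps[core])))
        np.testing.assert_allclose(diff, np.pi / 2, atol=1e-4)

    def test_amplitude_modulated_carrier_envelope_recovered(self):
        t = np.arange(int(20 * FS)) / FS
        env = 1.0 + 0.5 * np.cos(2 * np.pi * 4.0 * t)
        x = env * np.cos(2 * np.pi * 60.0 * t)
        _, amp, edge = morlet_phase_amp(x, FS, 60.0)
        core = slice(edge, -edge)
        r = np.corrcoef(amp[core], env[core])[0, 1]
        assert r > 0.99

    def test_signal_shorter_than_wavelet_refused(self):
        with pytest.raises(ValueError, match="shorter than wavelet"):
            morlet_phase_amp(np.zeros(100), FS, 2.0)


class TestModulationIndex:
    def test_analytic_mean_vector_length_is_half(self):
        # A = 1 + cos(phi) over uniform full cycles: |<A e^{i phi}>| = 1/2
        phase = 2 * np.pi * np.arange(50000) * 97 / 50000
        amp = 1.0 + np.cos(phase)
        assert modulation_index(phase, amp) == pytest.approx(0.5, rel=1e-6)

    def test_constant_amplitude_uniform_phase_gives_zero(self):
        phase = 2 * np.pi * np.arange(10000) * 13 / 10000
        amp = np.ones_like(phase)
        assert modulation_index(phase, amp) < 1e-10

    def test_raw_index_linear_in_scale_normalised_invariant(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1.0 + 0.4 * np.cos(phase) + 0.05 * rng.standard_normal(5000)
        mi = modulation_index(phase, amp)
        assert modulation_index(phase, 2.0 * amp) == pytest.approx(2.0 * mi, rel=1e-12)
        assert modulation_index(phase, 2.0 * amp, normalized=True) == pytest.approx(
            modulation_index(phase, amp, normalized=True), rel=1e-12
        )

    def test_monotone_in_modulation_depth(self):
        mis = []
        for depth in (0.0, 0.3, 0.6, 0.9):
            x = generate_pac_signal(7.0, 57.5, depth, 30.0, noise_sd=0.5, seed=21)
            phase, _, e1 = morlet_phase_amp(x, FS, 7.0)
            _, amp, e2 = morlet_phase_amp(x, FS, 57.5)
            e = max(e1, e2)
            mis.append(modulation_index(phase[e:-e], amp[e:-e]))
        assert mis == sorted(mis)

    def test_mean_abs_z_is_coupling_blind(self):
        phase = 2 * np.pi * np.arange(10000) * 7 / 10000
        coupled = 1.0 + np.cos(phase)
        scrambled = np.roll(coupled, 1234)
        assert mean_abs_z(phase, coupled) == pytest.approx(
            mean_abs_z(phase, scrambled), rel=1e-12
        )

    def test_empty_series_refused(self):
        with pytest.raises(ValueError):
            modulation_index(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def coupled():
    x = generate_pac_signal(6.0, 60.0, 0.8, 60.0, noise_sd=0.3, seed=5)
    return comodulogram(x, FS)


class TestComodulogram:
    def test_grid_shape_is_6_by_39(self, coupled):
        assert coupled.mi.shape == (6, 39)
        assert F_LOW_GRID.size == 6 and F_HIGH_GRID.size == 39

    def test_argmax_at_construction_frequencies(self, coupled):
        assert coupled.argmax() == (6.0, 60.0)

    def test_uncoupled_signal_stays_below_surrogate_threshold(self):
        x = generate_pac_signal(6.0, 60.0, 0.0, 60.0, noise_sd=0.3, seed=6)
        phase, _, e1 = morlet_phase_amp(x, FS, 6.0)
        _, amp, e2 = morlet_phase_amp(x, FS, 60.0)
        e = max(e1, e2)
        phase, amp = phase[e:-e], amp[e:-e]
        thr = surrogate_threshold(phase, amp, FS, quantile=0.99, seed=1)
        assert modulation_index(phase, amp) < thr

    def test_coupled_signal_collapses_under_circular_shift_surrogates(self):
        # a frequency-drifting slow rhythm: circular shifts decorrelate
        # amplitude from phase (a strictly periodic fixture would not)
        rng = np.random.default_rng(7)
        n = int(60 * FS)
        inst_freq = 6.0 + 20.0 * np.convolve(
            rng.standard_normal(n), np.ones(512) / 512, mode="same"
        )
        phase = 2 * np.pi * np.cumsum(inst_freq) / FS
        phase = np.angle(np.exp(1j * phase))
        amp = 1.0 + 0.6 * np.cos(phase) + 0.05 * rng.standard_normal(n)
        thr = surrogate_threshold(phase, amp, FS, seed=2)
        mi = modulation_index(phase, amp)
        assert mi > thr  # empirical p < 0.05 against the shift null
        assert mi > 5 * thr  # and the null mass sits far below the coupled MI

    def test_segment_pooling_matches_single_segment_weighting(self):
        # two copies of the same segment pool to the same MI as one copy
        x = generate_pac_signal(6.0, 60.0, 0.5, 30.0, noise_sd=0.2, seed=8)
        single = comodulogram(x, FS, f_low=np.array([6.0]), f_high=np.array([60.0]))
        double = comodulogram([x, x], FS, f_low=np.array([6.0]), f_high=np.array([60.0]))
        assert double.mi[0, 0] == pytest.approx(single.mi[0, 0], rel=1e-12)


class TestPacSummary:
    def test_constant_matrix_returns_constant(self):
        c = Comodulogram(F_LOW_GRID, F_HIGH_GRID, np.full((6, 39), 0.7))
        assert pac_summary(c, THETA_GAMMA_WINDOW) == pytest.approx(0.7)

    def test_full_window_is_global_mean(self):
        rng = np.random.default_rng(1)
        mi = rng.uniform(size=(6, 39))
        c = Comodulogram(F_LOW_GRID, F_HIGH_GRID, mi)
        assert pac_summary(c, FULL_WINDOW) == pytest.approx(mi.mean())

    def test_coupled_window_exceeds_full_window_on_coupled_fixture(self):
        x = generate_pac_signal(6.0, 60.0, 0.8, 60.0, noise_sd=0.3, seed=9)
        c = comodulogram(x, FS)
        assert pac_summary(c, THETA_GAMMA_WINDOW) > pac_summary(c, FULL_WINDOW)

    def test_window_outside_grid_refused(self):
        c = Comodulogram(F_LOW_GRID, F_HIGH_GRID, np.zeros((6, 39)))
        with pytest.raises(ValueError):
            pac_summary(c, ((0.1, 0.5), (300.0, 400.0)))
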