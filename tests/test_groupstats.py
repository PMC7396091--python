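"""Welch t-tests, TFCE enhancement and permutation calibration."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lfpnet.groupstats import (
    _enhance_positive_numpy,
    tfce_enhance,
    tfce_permutation,
    two_sample_test,
)


def brute_force_tfce_positive(s, dh, H, E):
    """Independent height-discretised double loop over bins and heights."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    k = 1
    while k * dh <= s.max() + 1e-9 * dh:
        h = k * dh
        above = s >= h - 1e-9 * dh
        for i in range(s.size):
            if not above[i]:
                continue
            lo = i
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = i
            while hi < s.size - 1 and above[hi + 1]:
                hi += 1
            out[i] += (hi - lo + 1) ** E * h**H * dh
        k += 1
    return out


class TestTwoSampleTest:
    def test_identical_groups_give_t_zero_p_one(self):
        res = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_welch_on_three_vs_three(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        # hand computation: means 2 and 5, both variances 1
        se = np.sqrt(1 / 3 + 1 / 3)
        t_exp = (2 - 5) / se
        df_exp = (1 / 3 + 1 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        p_exp = 2 * sps.t.sf(abs(t_exp), df_exp)
        res = two_sample_test(a, b)
        assert res.t == pytest.approx(t_exp, rel=1e-12)
        assert res.df == pytest.approx(df_exp, rel=1e-12)
        assert res.p == pytest.approx(p_exp, rel=1e-12)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(0)
        reps, alpha = 2000, 0.05
        hits = sum(
            two_sample_test(rng.standard_normal(7), rng.standard_normal(8)).p < alpha
            for _ in range(reps)
        )
        rate = hits / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se

    def test_small_groups_refused(self):
        with pytest.raises(ValueError):
            two_sample_test([1.0], [2.0, 3.0])


class TestTfceEnhance:
    def test_zeros_map_to_zeros(self):
        np.testing.assert_array_equal(tfce_enhance(np.zeros(10)), np.zeros(10))

    def test_single_bin_matches_discrete_integral(self):
        h = 3.0
        stat = np.zeros(9)
        stat[4] = h
        dh = h / 100
        expected = sum((k * dh) ** 2 * dh for k in range(1, 101))
        out = tfce_enhance(stat)
        assert out[4] == pytest.approx(expected, abs=1e-12)
        assert np.all(out[np.arange(9) != 4] == 0)

    def test_wider_plateau_enhanced_by_sqrt_extent_ratio(self):
        stat = np.zeros(30)
        stat[2:5] = 1.0  # width 3
        stat[10:16] = 1.0  # width 6
        out = tfce_enhance(stat)
        assert out[12] / out[3] == pytest.approx(np.sqrt(2.0), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        stat = rng.standard_normal(50) * 3
        dh = np.abs(stat).max() / 100
        expected = brute_force_tfce_positive(
            np.clip(stat, 0, None), dh, 2.0, 0.5
        ) - brute_force_tfce_positive(np.clip(-stat, 0, None), dh, 2.0, 0.5)
        out = tfce_enhance(stat)
        np.testing.assert_allclose(out, expected, atol=1e-10)
        # the pure-numpy path agrees with the compiled path
        np.testing.assert_allclose(
            _enhance_positive_numpy(np.clip(stat, 0, None), dh, 2.0, 0.5),
            brute_force_tfce_positive(np.clip(stat, 0, None), dh, 2.0, 0.5),
            atol=1e-10,
        )

    def test_sign_preserved(self):
        stat = np.array([0.0, -2.0, 0.0, 3.0])
        out = tfce_enhance(stat)
        assert out[1] < 0 < out[3]
        assert out[0] == out[2] == 0.0

    def test_non_finite_input_refused(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.array([1.0, np.nan]))

    @given(
        st.lists(st.floats(-5, 5), min_size=5, max_size=40),
        st.data(),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_under_pointwise_magnitude_increase(self, vals, data):
        stat = np.array(vals)
        i = data.draw(st.integers(0, stat.size - 1))
        bump = data.draw(st.floats(0.1, 3.0))
        raised = stat.copy()
        raised[i] += bump if raised[i] >= 0 else -bump
        dh = 0.05  # fixed integration step: monotonicity holds exactly
        base = np.abs(tfce_enhance(stat, dh=dh))
        more = np.abs(tfce_enhance(raised, dh=dh))
        assert np.all(more >= base - 1e-12)


class TestTfcePermutation:
    def test_identical_group_vectors_find_nothing(self):
        v = np.tile(np.sin(np.linspace(0, 3, 40)), (4, 1))
        res = tfce_permutation(v, v.copy(), n_perm=200, seed=0)
        assert not res.sig_mask.any()
        assert res.clusters == []

    def test_p_values_symmetric_under_group_relabelling(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 30))
        b = rng.standard_normal((4, 30))
        r1 = tfce_permutation(a, b, seed=3)
        r2 = tfce_permutation(b, a, seed=3)
        assert r1.exhaustive and r2.exhaustive  # C(8,4)=70 assignments
        np.testing.assert_allclose(r1.p_values, r2.p_values, atol=1e-12)
        np.testing.assert_allclose(r1.tfce_stat, -r2.tfce_stat, atol=1e-12)

    def test_seeded_subsampling_is_deterministic(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((8, 50))
        b = rng.standard_normal((8, 50))
        r1 = tfce_permutation(a, b, n_perm=300, seed=7, enumeration_limit=0)
        r2 = tfce_permutation(a, b, n_perm=300, seed=7, enumeration_limit=0)
        np.testing.assert_array_equal(r1.sig_mask, r2.sig_mask)
        np.testing.assert_array_equal(r1.perm_null, r2.perm_null)

    def test_strong_cluster_detected_with_correct_extent(self):
        rng = np.random.default_rng(4)
        freqs = np.arange(100, dtype=float)
        a = rng.standard_normal((8, 100))
        b = rng.standard_normal((8, 100))
        b[:, 40:50] += 4.0  # strong contiguous effect
        res = tfce_permutation(a, b, freqs=freqs, n_perm=500, seed=5,
                               enumeration_limit=0)
        assert res.sig_mask[40:50].all()
        assert any(lo <= 40 and hi >= 49 for lo, hi in res.clusters)

    def test_too_few_animals_refused(self):
        with pytest.raises(ValueError):
            tfce_permutation(np.zeros((2, 10)), np.zeros((3, 10)))
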