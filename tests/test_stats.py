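"""Circular statistics, JTK-style rhythmicity test, Grubbs outliers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special
from scipy import stats as sps

from chronobug.stats import (
    grubbs_test,
    harding_null_sf,
    hours_to_radians,
    jtk_cycle,
    kendall_s,
    rayleigh_test,
    watson_u2,
)


class TestHoursToRadians:
    @pytest.mark.parametrize(
        "hours, expected",
        [(6.0, math.pi / 2), (24.0, 0.0), (20.0, 5 * math.pi / 3), (0.0, 0.0)],
    )
    def test_known_angles(self, hours, expected):
        assert hours_to_radians(hours) == pytest.approx(expected)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            hours_to_radians(3.0, period_h=0.0)


class TestRayleigh:
    def test_point_mass_maximally_concentrated(self):
        r = rayleigh_test(np.full(20, 1.3))
        assert r.rho == pytest.approx(1.0)
        assert r.p_value < 1e-6

    def test_perfect_symmetry_uniform(self):
        r = rayleigh_test(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert r.rho == pytest.approx(0.0, abs=1e-12)
        assert r.p_value > 0.9

    def test_von_mises_rho_matches_bessel_ratio(self):
        rng = np.random.default_rng(7)
        r = rayleigh_test(rng.vonmises(1.0, 2.0, 1000))
        assert abs(r.rho - special.i1(2.0) / special.i0(2.0)) < 0.03

    def test_rotation_invariance_of_p(self, rng):
        a = rng.vonmises(0.5, 1.5, 40)
        p0 = rayleigh_test(a).p_value
        for rot in (0.7, 2.9, 5.1):
            assert rayleigh_test(np.mod(a + rot, 2 * np.pi)).p_value == pytest.approx(p0)

    def test_single_angle_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([1.0])


class TestWatsonU2:
    def test_identical_samples_null(self):
        a = np.linspace(0.1, 6.0, 12)
        u2, p = watson_u2(a, a, n_permutations=99, seed=0)
        assert u2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_antipodal_clusters_detected(self, rng):
        a = np.mod(rng.normal(0.0, 0.1, 20), 2 * np.pi)
        b = np.mod(rng.normal(np.pi, 0.1, 20), 2 * np.pi)
        _, p = watson_u2(a, b, n_permutations=999, seed=1)
        assert p < 0.01

    def test_rotation_and_swap_invariance(self, rng):
        a = rng.vonmises(1.0, 2.0, 15)
        b = rng.vonmises(2.0, 1.0, 18)
        u2, _ = watson_u2(a, b, n_permutations=9, seed=0)
        u2_sw, _ = watson_u2(b, a, n_permutations=9, seed=0)
        assert u2_sw == pytest.approx(u2, abs=1e-12)
        for rot in (0.31, 4.0):
            u2_rot, _ = watson_u2(
                np.mod(a + rot, 2 * np.pi), np.mod(b + rot, 2 * np.pi),
                n_permutations=9, seed=0,
            )
            assert u2_rot == pytest.approx(u2, abs=1e-10)

    def test_null_p_uniform_under_exchangeability(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pooled = rng.vonmises(0.0, 1.0, 32)
            _, p = watson_u2(pooled[:16], pooled[16:], n_permutations=199, seed=seed)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestKendallAndHarding:
    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(-50, 50), min_size=2, max_size=12),
        st.integers(0, 10_000),
    )
    def test_kendall_s_matches_pair_enumeration(self, xs, ref_seed):
        x = np.array(xs, dtype=float)
        ref = np.random.default_rng(ref_seed).integers(-3, 4, len(x)).astype(float)
        brute = 0
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                brute += int(np.sign(x[j] - x[i]) * np.sign(ref[j] - ref[i]))
        assert kendall_s(x, ref) == brute

    def test_harding_matches_mann_whitney(self):
        # two groups: JT reduces to Mann-Whitney U; compare with enumeration
        pmf = harding_null_sf([3, 4])
        from itertools import combinations

        counts = np.zeros(13)
        labels = [0] * 3 + [1] * 4
        ranks = range(7)
        for pos in combinations(ranks, 3):
            u = sum(1 for i in pos for j in ranks if j not in pos and j > i)
            counts[u] += 1
        np.testing.assert_allclose(pmf, counts / counts.sum(), atol=1e-12)

    def test_harding_mean_matches_theory(self):
        sizes = [3, 6, 6, 3]
        pmf = harding_null_sf(sizes)
        jt_mean = float(np.arange(len(pmf)) @ pmf)
        expect = sum(
            sizes[i] * sizes[j]
            for i in range(len(sizes))
            for j in range(i + 1, len(sizes))
        ) / 2.0
        assert jt_mean == pytest.approx(expect)


class TestJTK:
    def _design(self):
        return np.tile(np.arange(0.0, 24.0, 4.0), 3)

    def test_noiseless_cosine_peak_recovered(self):
        t = self._design()
        x = np.cos(2 * np.pi * (t - 8.0) / 24.0)
        x += np.random.default_rng(0).normal(0, 1e-9, len(x))  # break exact ties
        r = jtk_cycle(t, x)
        assert r.best_lag_h == 8.0
        assert r.p_value < 0.01
        assert r.tau_statistic > 0.8

    def test_constant_data_p_one(self):
        t = self._design()
        r = jtk_cycle(t, np.ones_like(t))
        assert r.p_value == 1.0 and r.tau_statistic == 0.0

    def test_sign_flip_shifts_lag_half_period(self):
        t = self._design()
        rng = np.random.default_rng(1)
        x = np.cos(2 * np.pi * (t - 8.0) / 24.0) + rng.normal(0, 1e-9, len(t))
        r_pos = jtk_cycle(t, x)
        r_neg = jtk_cycle(t, -x)
        assert (r_neg.best_lag_h - r_pos.best_lag_h) % 24.0 == 12.0

    def test_type_i_error_controlled(self):
        t = self._design()
        hits = 0
        n_sim = 500
        for seed in range(n_sim):
            x = np.random.default_rng(seed).normal(size=len(t))
            hits += jtk_cycle(t, x).p_value < 0.05
        assert hits / n_sim <= 0.07

    def test_power_at_double_noise_amplitude(self):
        t = self._design()
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            x = 2.0 * np.cos(2 * np.pi * (t - 8.0) / 24.0) + rng.normal(size=len(t))
            hits += jtk_cycle(t, x).p_value < 0.05
        assert hits / n_sim >= 0.9

    def test_exact_and_permutation_agree(self):
        t = self._design()
        rng = np.random.default_rng(5)
        x = 1.0 * np.cos(2 * np.pi * (t - 4.0) / 24.0) + rng.normal(size=len(t))
        p_exact = jtk_cycle(t, x, method="exact").p_value
        p_perm = jtk_cycle(t, x, method="permutation", n_permutations=4000, seed=0).p_value
        assert p_perm == pytest.approx(p_exact, rel=0.3, abs=0.02)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            jtk_cycle([0.0, 8.0, 16.0], [1.0, 2.0, 3.0])


class TestGrubbs:
    def test_gross_outlier_flagged(self):
        x = np.r_[np.arange(1.0, 10.0), 100.0]
        assert grubbs_test(x, alpha=0.05) == 9

    def test_equal_values_none(self):
        assert grubbs_test(np.full(10, 2.0)) is None

    def test_false_positive_rate_near_alpha(self):
        hits = 0
        n_sim = 2000
        for seed in range(n_sim):
            x = np.random.default_rng(seed).normal(size=20)
            hits += grubbs_test(x, alpha=0.05) is not None
        assert abs(hits / n_sim - 0.05) < 0.02
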