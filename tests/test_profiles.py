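"""Profile analytics: smoothing, extrema, metaplots, tests, controls."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from polconvoy.observe import Profile
from polconvoy.profiles import (
    autocorrelation,
    bartlett_band,
    call_extrema,
    metaplot,
    normalize_to_fraction,
    rank_tests,
    shuffle_control,
    smooth_blackman,
    spearman,
)


def brute_force_extrema(values, order, sign):
    """O(n*order) double-loop oracle with clipped-index comparisons.

    Strict inequality against every neighbour within +/-order; indices are
    clipped to the array, so a boundary position compares with itself and
    can never qualify.  (No plateau handling: intended for tie-free input.)
    """
    v = sign * np.asarray(values, float)
    n = len(v)
    out = []
    for i in range(n):
        ok = True
        for d in range(1, order + 1):
            for j in (min(max(i - d, 0), n - 1), min(max(i + d, 0), n - 1)):
                if j == i or not v[i] > v[j]:
                    ok = False
        if ok:
            out.append(i)
    return np.array(out, dtype=int)


class TestNormalizeToFraction:
    def test_hand_arithmetic(self):
        prof = normalize_to_fraction(np.array([1, 1, 2]))
        np.testing.assert_allclose(
            prof.values, [0.25 + 1e-7, 0.25 + 1e-7, 0.5 + 1e-7]
        )

    def test_pseudocount_floor_and_total(self):
        prof = normalize_to_fraction(np.array([0, 5, 0, 5]))
        assert prof.values.min() >= 1e-7
        assert prof.values.sum() == pytest.approx(1 + 4e-7)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_fraction(np.zeros(5))


class TestSmoothBlackman:
    def test_constant_profile_unchanged(self):
        out = smooth_blackman(Profile(np.full(50, 0.3)), 10)
        np.testing.assert_allclose(out.values, 0.3)

    def test_delta_reproduces_normalized_kernel(self):
        v = np.zeros(101)
        v[50] = 1.0
        out = smooth_blackman(Profile(v), 11)
        kernel = np.blackman(11) / np.blackman(11).sum()
        np.testing.assert_allclose(out.values[45:56], kernel, atol=1e-12)

    def test_mass_preserved_on_interior_signal(self):
        rng = np.random.default_rng(0)
        v = np.zeros(200)
        v[50:150] = rng.random(100)
        out = smooth_blackman(Profile(v), 10)
        assert out.values.sum() == pytest.approx(v.sum(), abs=1e-9)

    def test_window_longer_than_profile_rejected(self):
        with pytest.raises(ValueError):
            smooth_blackman(Profile(np.ones(5)), 10)


class TestCallExtrema:
    def test_worked_example(self):
        peaks, troughs = call_extrema(np.array([0, 1, 3, 2, 5, 1, 0]), order=1)
        np.testing.assert_array_equal(peaks.positions, [2, 4])
        np.testing.assert_array_equal(troughs.positions, [3])

    def test_monotone_profile_has_no_internal_extrema(self):
        peaks, troughs = call_extrema(np.arange(50, dtype=float), order=3)
        assert len(peaks) == 0 and len(troughs) == 0

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 120))
            order = int(rng.integers(1, 12))
            v = rng.random(n)
            peaks, troughs = call_extrema(v, order)
            np.testing.assert_array_equal(
                peaks.positions, brute_force_extrema(v, order, +1)
            )
            np.testing.assert_array_equal(
                troughs.positions, brute_force_extrema(v, order, -1)
            )

    def test_plateau_reported_at_leftmost_point(self):
        v = np.array([0.0, 1, 2, 2, 2, 1, 0])
        peaks, _ = call_extrema(v, order=2)
        np.testing.assert_array_equal(peaks.positions, [2])

    def test_shift_equivariance(self, rng):
        v = rng.random(80)
        shifted = np.concatenate([np.full(7, -1.0), v])
        p1, _ = call_extrema(v, order=4)
        p2, _ = call_extrema(shifted, order=4)
        inner1 = p1.positions[(p1.positions >= 4) & (p1.positions < 76)]
        inner2 = p2.positions[(p2.positions >= 11) & (p2.positions < 83)]
        np.testing.assert_array_equal(inner2, inner1 + 7)


class TestMetaplot:
    def test_constant_signal_gives_flat_metaplot(self):
        mp = metaplot(np.full(100, 2.5), [30, 50, 70], half_window=10)
        np.testing.assert_allclose(mp.mean_signal, 2.5)
        assert mp.n_features == 3

    def test_single_feature_returns_raw_window(self):
        rng = np.random.default_rng(1)
        v = rng.random(100)
        mp = metaplot(v, [50], half_window=8)
        np.testing.assert_allclose(mp.mean_signal, v[42:59])

    def test_periodic_signal_maxima_at_period_offsets(self):
        x = np.arange(800)
        v = np.cos(2 * np.pi * x / 80)
        features = np.arange(160, 640, 80)  # maxima of the signal
        mp = metaplot(v, features, half_window=100)
        top = mp.offsets[np.argsort(mp.mean_signal)[-3:]]
        assert set(top) == {-80, 0, 80}

    def test_boundary_windows_truncated(self):
        v = np.arange(20, dtype=float)
        mp = metaplot(v, [1], half_window=5)
        assert np.isnan(mp.mean_signal[0])  # offset -5 undefined
        assert mp.mean_signal[5] == 1.0

    def test_per_window_normalization(self):
        v = np.zeros(60)
        v[10] = 2.0
        v[40] = 8.0  # same shape, different scale
        mp = metaplot(v, [10, 40], half_window=3, per_window_normalize=True)
        assert mp.mean_signal[3] == pytest.approx(1.0)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            metaplot(np.ones(10), [], half_window=2)


class TestAutocorrelation:
    def test_cosine_dominant_spacing(self):
        x = np.arange(2000)
        v = 1.0 + 0.3 * np.cos(2 * np.pi * x / 80)
        acf, spacing = autocorrelation(v, max_lag=200)
        assert acf[0] == pytest.approx(1.0)
        assert spacing == 80

    def test_white_noise_within_bartlett_band(self, rng):
        v = rng.random(4000)
        acf, _ = autocorrelation(v, max_lag=100)
        assert np.all(np.abs(acf[1:]) < bartlett_band(4000))

    def test_constant_profile_undefined(self):
        with pytest.raises(ValueError):
            autocorrelation(np.full(100, 1.0), max_lag=10)


class TestShuffleAndSpearman:
    def test_profile_vs_itself(self):
        rng = np.random.default_rng(2)
        v = rng.random(100)
        assert spearman(v, v) == pytest.approx(1.0)

    def test_shuffle_preserves_count_multiset(self):
        counts = np.arange(100)
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(counts)
        assert shuffled.sum() == counts.sum()
        # the processed control stays a unit-scale profile (smoothing loses
        # only edge mass) and is seed-sensitive
        out = shuffle_control(counts, seed=1)
        assert out.values.sum() == pytest.approx(1.0, rel=0.02)
        other = shuffle_control(counts, seed=2)
        assert not np.allclose(out.values, other.values)

    def test_shuffle_destroys_structured_correlation(self):
        x = np.arange(2000)
        counts = (1000 * (1.5 + np.cos(2 * np.pi * x / 80))).astype(int)
        prof = smooth_blackman(normalize_to_fraction(counts), 10)
        replicate = smooth_blackman(
            normalize_to_fraction(counts + 5), 10
        )  # structured replicate
        shuffled = shuffle_control(counts, seed=3)
        assert spearman(prof, replicate) > 0.95
        assert abs(spearman(prof, shuffled)) < spearman(prof, replicate)


class TestRankTests:
    def test_identical_samples_give_high_p(self):
        x = np.arange(10.0)
        stat, p = rank_tests(x, x, "rank_sum")
        assert p > 0.9
        stat, p = rank_tests(x, x, "signed_rank")
        assert stat == 0.0 and p == 1.0

    def test_small_n_matches_exact_enumeration(self):
        x = np.array([1.0, 3.0, 5.0])
        y = np.array([2.0, 4.0, 6.0])
        _, p = rank_tests(x, y, "rank_sum")
        # enumerate all 20 assignments of ranks to group x
        ranks = np.arange(1, 7)
        u_obs = ss.rankdata(np.concatenate([x, y]))[:3].sum() - 6
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            u = ranks[list(combo)].sum() - 6
            total += 1
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        assert p == pytest.approx(count / total)

    def test_power_on_shifted_gaussians(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        for kind in ("rank_sum", "t_two_sided"):
            _, p = rank_tests(x, y, kind)
            assert p < 0.01
        _, p = rank_tests(x, y, "signed_rank")
        assert p < 0.01

    def test_unpaired_signed_rank_rejected(self):
        with pytest.raises(ValueError):
            rank_tests(np.ones(3), np.ones(4), "signed_rank")
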