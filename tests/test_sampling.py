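"""Distributional and conditional correctness of the pair samplers."""

import numpy as np
import pytest
from scipy import stats

from neuroclr.data import make_session
from neuroclr.sampling import (ConfigError, SamplingConfig, SamplingError,
                               empirical_differences, sample_batch,
                               sample_multisession_batch, sample_negative,
                               sample_positive_continuous,
                               sample_positive_discrete,
                               sample_positive_mixed, sample_positive_time,
                               sample_reference, merge_batches)
from neuroclr.data import MultiSessionDataset

ALPHA = 0.01
N_DRAWS = 10_000


class TestReferenceAndNegative:
    def test_empirical_frequencies_uniform(self, rng):
        s = make_session(rng.standard_normal((50, 2)))
        cfg = SamplingConfig(mode="time", time_offsets=(1,))
        idx = sample_reference(s, N_DRAWS, cfg, rng)
        counts = np.bincount(idx, minlength=50)
        p = stats.chisquare(counts).pvalue
        assert p > ALPHA

    def test_uniform_over_category_rebalances(self, rng):
        """A 9:1 imbalanced category is equalized to ~50/50."""
        disc = np.array([0] * 900 + [1] * 100)
        s = make_session(rng.standard_normal((1000, 2)),
                         discrete_context=disc)
        cfg = SamplingConfig(mode="discrete",
                             negative_mode="uniform_over_category")
        idx = sample_negative(s, N_DRAWS, cfg, rng)
        k_counts = np.bincount(disc[idx], minlength=2)
        p = stats.chisquare(k_counts).pvalue
        assert p > ALPHA

    def test_single_valid_window_is_forced(self, rng):
        s = make_session(rng.standard_normal((10, 2)))
        cfg = SamplingConfig(mode="time", time_offsets=(1,),
                             receptive_field=10)
        # only centre index 5 is valid for RF 10 on T=10
        assert set(sample_reference(s, 50, cfg, rng)) == {5}

    def test_nonpositive_n_raises(self, small_session, rng):
        cfg = SamplingConfig(mode="time", time_offsets=(1,))
        with pytest.raises(ValueError):
            sample_reference(small_session, 0, cfg, rng)


class TestDiscretePositive:
    def test_positives_always_share_category(self, rng):
        disc = rng.integers(0, 3, 500)
        s = make_session(rng.standard_normal((500, 2)),
                         discrete_context=disc)
        cfg = SamplingConfig(mode="discrete")
        refs = sample_reference(s, N_DRAWS, cfg, rng)
        pos = sample_positive_discrete(s, refs, cfg, rng)
        assert np.array_equal(disc[refs], disc[pos])

    def test_within_category_uniform(self, rng):
        disc = np.array([0] * 30 + [1] * 70)
        s = make_session(rng.standard_normal((100, 2)),
                         discrete_context=disc)
        cfg = SamplingConfig(mode="discrete")
        refs = np.zeros(N_DRAWS, dtype=np.int64)  # category 0 reference
        pos = sample_positive_discrete(s, refs, cfg, rng)
        counts = np.bincount(pos, minlength=30)[:30]
        assert stats.chisquare(counts).pvalue > ALPHA

    def test_single_member_category_returns_reference(self, rng):
        disc = np.array([0] * 99 + [1])
        s = make_session(rng.standard_normal((100, 2)),
                         discrete_context=disc)
        cfg = SamplingConfig(mode="discrete")
        pos = sample_positive_discrete(s, np.array([99]), cfg, rng)
        assert pos[0] == 99


class TestContinuousPositive:
    def test_linear_context_offset_one(self, linear_context_session, rng):
        """c_t = t and Δ={1}: D={1}, so the positive is exactly ref+1."""
        cfg = SamplingConfig(mode="continuous", time_offsets=(1,))
        refs = rng.integers(0, 150, size=200)
        pos = sample_positive_continuous(linear_context_session, refs, cfg,
                                         rng)
        np.testing.assert_array_equal(pos, refs + 1)

    def test_constant_context_tie_breaks_to_smallest(self, rng):
        s = make_session(rng.standard_normal((50, 2)),
                         continuous_context=np.zeros(50))
        cfg = SamplingConfig(mode="continuous", time_offsets=(1,))
        pos = sample_positive_continuous(s, np.array([30, 7]), cfg, rng)
        assert list(pos) == [0, 0]

    def test_realized_offsets_match_difference_multiset(self, rng):
        """KS test of realized c_pos - c_ref against the multiset D."""
        T = 1000
        c = np.cumsum(rng.standard_normal(T))  # a random walk context
        s = make_session(rng.standard_normal((T, 2)), continuous_context=c)
        cfg = SamplingConfig(mode="continuous", time_offsets=(1, 2, 5))
        D = empirical_differences(s, cfg.time_offsets).ravel()
        refs = sample_reference(s, N_DRAWS, cfg, rng)
        pos = sample_positive_continuous(s, refs, cfg, rng)
        realized = c[pos] - c[refs]
        assert stats.ks_2samp(realized, D).pvalue > ALPHA

    def test_empty_difference_multiset_raises(self, rng):
        s = make_session(rng.standard_normal((5, 2)),
                         continuous_context=np.arange(5.0))
        with pytest.raises(SamplingError):
            empirical_differences(s, (10,))


class TestDeltaPositive:
    def test_zero_delta_returns_reference(self, linear_context_session, rng):
        cfg = SamplingConfig(mode="delta", delta=1e-12)
        refs = rng.integers(0, 200, size=100)
        pos = sample_positive_continuous(linear_context_session, refs, cfg,
                                         rng)
        np.testing.assert_array_equal(pos, refs)

    def test_realized_distance_is_folded_normal(self, rng):
        """On a dense 1-D context, |c_pos - c_ref| ~ |N(0, δ²)|."""
        T = 20_000
        c = np.sort(rng.uniform(0, 100, T))
        s = make_session(rng.standard_normal((T, 1)), continuous_context=c)
        delta = 0.5
        cfg = SamplingConfig(mode="delta", delta=delta)
        refs = sample_reference(s, 4000, cfg, rng)
        pos = sample_positive_continuous(s, refs, cfg, rng)
        realized = np.abs(c[pos] - c[refs])
        expected = np.abs(delta * rng.standard_normal(20_000))
        assert stats.ks_2samp(realized, expected).pvalue > ALPHA


class TestTimePositive:
    def test_singleton_offset(self, small_session, rng):
        cfg = SamplingConfig(mode="time", time_offsets=(10,))
        pos = sample_positive_time(small_session, np.arange(50), cfg, rng)
        np.testing.assert_array_equal(pos, np.arange(50) + 10)

    def test_offsets_uniform(self, rng):
        s = make_session(rng.standard_normal((500, 2)))
        cfg = SamplingConfig(mode="time", time_offsets=tuple(range(1, 11)))
        refs = np.full(N_DRAWS, 100)
        pos = sample_positive_time(s, refs, cfg, rng)
        counts = np.bincount(pos - 100, minlength=11)[1:]
        assert stats.chisquare(counts).pvalue > ALPHA

    def test_boundary_reference_raises(self, small_session, rng):
        cfg = SamplingConfig(mode="time", time_offsets=(10,))
        with pytest.raises(SamplingError):
            sample_positive_time(small_session, np.array([99]), cfg, rng)


class TestMixedPositive:
    def test_positives_never_cross_direction(self, rng):
        """Direction-conditioned positives keep the direction label."""
        T = 1000
        direction = (np.arange(T) // 100) % 2
        c = np.cumsum(rng.standard_normal(T))
        s = make_session(rng.standard_normal((T, 2)), continuous_context=c,
                         discrete_context=direction)
        cfg = SamplingConfig(mode="mixed", time_offsets=(1, 2))
        refs = sample_reference(s, N_DRAWS, cfg, rng)
        pos = sample_positive_mixed(s, refs, cfg, rng)
        assert np.array_equal(direction[refs], direction[pos])

    def test_single_category_reduces_to_continuous(self, rng):
        T = 300
        c = np.cumsum(rng.standard_normal(T))
        s1 = make_session(rng.standard_normal((T, 2)), continuous_context=c,
                          discrete_context=np.zeros(T, dtype=int))
        s2 = make_session(s1.signal, continuous_context=c)
        refs = np.arange(100)
        cfg_m = SamplingConfig(mode="mixed", time_offsets=(1,))
        cfg_c = SamplingConfig(mode="continuous", time_offsets=(1,))
        pos_m = sample_positive_mixed(s1, refs, cfg_m,
                                      np.random.default_rng(3))
        pos_c = sample_positive_continuous(s2, refs, cfg_c,
                                           np.random.default_rng(3))
        np.testing.assert_array_equal(pos_m, pos_c)


class TestBatch:
    def test_batch_shapes(self, small_session, rng):
        cfg = SamplingConfig(mode="discrete")
        batch = sample_batch(small_session, 32, cfg, rng)
        assert batch.n == 32
        assert len(batch.positive) == len(batch.negative) == 32

    def test_full_batch_uses_every_window(self, rng):
        s = make_session(rng.standard_normal((1000, 3)),
                         continuous_context=np.arange(1000.0))
        cfg = SamplingConfig(mode="delta", delta=0.5, receptive_field=10)
        batch = sample_batch(s, "full", cfg, rng)
        assert batch.n == 991
        assert set(batch.reference) == set(range(5, 996))

    def test_reproducible_given_seed(self, small_session):
        cfg = SamplingConfig(mode="mixed", time_offsets=(1, 3))
        b1 = sample_batch(small_session, 64, cfg, np.random.default_rng(9))
        b2 = sample_batch(small_session, 64, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(b1.reference, b2.reference)
        np.testing.assert_array_equal(b1.positive, b2.positive)
        np.testing.assert_array_equal(b1.negative, b2.negative)

    def test_mode_requires_matching_context(self, rng):
        s = make_session(rng.standard_normal((50, 2)))
        with pytest.raises(ConfigError):
            sample_batch(s, 8, SamplingConfig(mode="discrete"), rng)

    def test_uniform_over_category_membership_balance(self, rng):
        """With uniform positives+negatives, batch membership carries ~no
        information about the imbalanced category."""
        disc = np.array([0] * 900 + [1] * 100)
        s = make_session(rng.standard_normal((1000, 2)),
                         discrete_context=disc)
        cfg = SamplingConfig(mode="discrete",
                             reference_mode="uniform_over_category",
                             negative_mode="uniform_over_category")
        batch = sample_batch(s, N_DRAWS, cfg, rng)
        for members in (batch.reference, batch.positive, batch.negative):
            counts = np.bincount(disc[members], minlength=2)
            assert stats.chisquare(counts).pvalue > ALPHA


class TestMultiSession:
    def _dataset(self, rng, lengths=(1000, 100)):
        sessions = []
        for i, T in enumerate(lengths):
            c = np.cumsum(rng.standard_normal(T))
            sessions.append(make_session(rng.standard_normal((T, 3 + i)),
                                         continuous_context=c,
                                         session_id=f"s{i}"))
        return MultiSessionDataset(sessions)

    def test_equal_reference_quota_despite_lengths(self, rng):
        ds = self._dataset(rng)
        cfg = SamplingConfig(mode="delta", delta=0.5)
        batches = sample_multisession_batch(ds, 100, cfg, rng)
        assert [b.n for b in batches] == [50, 50]
        assert set(batches[0].reference_session) == {0}
        assert set(batches[1].reference_session) == {1}

    def test_positive_session_uniform(self, rng):
        ds = self._dataset(rng, lengths=(800, 200))
        cfg = SamplingConfig(mode="delta", delta=0.5)
        sess_draws = []
        for _ in range(100):
            merged = merge_batches(sample_multisession_batch(ds, 100, cfg,
                                                             rng))
            sess_draws.append(merged.positive_session)
        counts = np.bincount(np.concatenate(sess_draws), minlength=2)
        assert stats.chisquare(counts).pvalue > ALPHA

    def test_single_session_reduces_to_sample_batch(self, rng):
        c = np.cumsum(rng.standard_normal(300))
        s = make_session(rng.standard_normal((300, 4)),
                         continuous_context=c)
        ds = MultiSessionDataset([s])
        cfg = SamplingConfig(mode="delta", delta=0.5)
        b1 = sample_multisession_batch(ds, 64, cfg,
                                       np.random.default_rng(5))[0]
        b2 = sample_batch(s, 64, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(b1.reference, b2.reference)
        np.testing.assert_array_equal(b1.positive, b2.positive)
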