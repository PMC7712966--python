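import math

import numpy as np
import pytest

from contactstates import SamplerConfig, run_chain, run_ensemble
from contactstates.model import (ModelParams, log_joint, log_prior,
                                 log_uniqueness, _sample_theta)
from contactstates.sampler import (ChainState, _log_partition_prob,
                                   _splittable, _stats_from_z, init_state,
                                   propose_join, propose_split, read_posterior,
                                   recategorize, reclassify, split_join_step,
                                   write_posterior)


def _state(x, z, K, alpha=None, pi=None, mu=None):
    x = np.asarray(x, dtype=np.uint8)
    xf = x.astype(float)
    z = np.asarray(z, dtype=np.int64)
    Nk, Nkj = _stats_from_z(xf, z, K)
    if alpha is None:
        alpha = float(x.shape[1] + 1)
    st = ChainState(z=z, pi=np.ones(K) / K if pi is None else np.asarray(pi),
                    mu=np.full((K, x.shape[1]), 0.5) if mu is None else np.asarray(mu),
                    alpha=alpha, Nk=Nk, Nkj=Nkj)
    return st, x, xf


class TestRecategorize:
    def test_single_category_never_changes(self, two_block_fm, rng):
        st, x, xf = _state(two_block_fm.x, np.zeros(20), 1)
        recategorize(st, xf, rng)
        assert st.z.tolist() == [0] * 20

    def test_degenerate_prototypes_classify_deterministically(self, rng):
        x = np.vstack([np.ones((3, 3)), np.zeros((3, 3))]).astype(np.uint8)
        st, x, xf = _state(x, [0, 0, 1, 1, 0, 1], 2,
                           pi=[0.5, 0.5],
                           mu=[[0.999] * 3, [0.001] * 3])
        assert recategorize(st, xf, rng) is True
        assert st.z.tolist() == [0, 0, 0, 1, 1, 1]

    def test_empirical_matches_responsibilities(self, rng):
        """Per-frame label frequencies track P(z_i=k | x_i, theta)."""
        from contactstates import responsibilities
        x = np.vstack([np.tile([1, 0], (6, 1)), np.tile([0, 1], (6, 1))]).astype(np.uint8)
        theta = ModelParams(pi=[0.6, 0.4], mu=[[0.9, 0.2], [0.1, 0.8]], alpha=3.0)
        st, x, xf = _state(x, [0] * 6 + [1] * 6, 2, pi=theta.pi, mu=theta.mu)
        counts = np.zeros((12, 2))
        reps = 4000
        for _ in range(reps):
            recategorize(st, xf, rng)
            counts[np.arange(12), st.z] += 1
        for i in range(12):
            want = responsibilities(x[i], theta)
            assert counts[i, 0] / reps == pytest.approx(want[0], abs=0.03)

    def test_rejects_draws_that_empty_a_category(self, rng):
        """With a prototype no frame supports, z must stay surjective."""
        x = np.ones((5, 2), dtype=np.uint8)
        st, x, xf = _state(x, [0, 0, 0, 0, 1], 2,
                           pi=[0.999, 0.001], mu=[[0.99, 0.99], [0.01, 0.01]])
        for _ in range(50):
            recategorize(st, xf, rng)
            assert np.unique(st.z).size == 2


class TestReclassify:
    def test_single_category_always_accepted(self, tiny_fm, rng):
        st, x, xf = _state(tiny_fm.x, [0, 0, 0], 1)
        assert reclassify(st, rng) is True

    def test_acceptance_rate_matches_uniqueness_expectation(self, rng):
        """Long-run acceptance equals E[prod(1-B)] under P(theta|z,x,U)."""
        x = np.vstack([np.tile([1, 0], (5, 1)), np.tile([0, 1], (5, 1))]).astype(np.uint8)
        st, x, xf = _state(x, [0] * 5 + [1] * 5, 2)
        reps = 3000
        acc = sum(reclassify(st, rng) for _ in range(reps)) / reps
        probe = np.random.default_rng(77)
        est = np.mean([math.exp(log_uniqueness(
            _sample_theta(st.Nk, st.Nkj, probe, st.alpha).mu))
            for _ in range(3000)])
        assert acc == pytest.approx(est, abs=0.04)

    def test_uniqueness_off_always_accepts(self, tiny_fm, rng):
        st, x, xf = _state(tiny_fm.x, [0, 1, 1], 2)
        assert all(reclassify(st, rng, uniqueness=False) for _ in range(20))


class TestProposeSplit:
    def test_two_member_partition_probability(self, rng):
        """x = (1), (0) on the chosen feature, eta=0.9: the non-degenerate
        partition L={0}, R={1} has probability 0.81/0.82."""
        x = np.array([[1], [0]], dtype=np.uint8)
        st, x, xf = _state(x, [0, 0], 1)
        hits = 0
        reps = 3000
        for _ in range(reps):
            z_new, *_rest, log_gen = propose_split(st, x, 0.9, rng)
            if z_new.tolist() == [0, 1]:
                hits += 1
                assert math.exp(log_gen) == pytest.approx(0.81 / 0.82)
        assert hits / reps == pytest.approx(0.81 / 0.82, abs=0.03)

    def test_gen_prob_sums_over_generating_features(self):
        """Identical columns are interchangeable generators of the same
        partition; the generation probability must sum them."""
        x = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        st, x, xf = _state(x, [0, 0], 1)
        rng = np.random.default_rng(0)
        z_new, *_rest, log_gen = propose_split(st, x, 0.9, rng)
        # either feature generates either partition identically
        assert math.exp(log_gen) == pytest.approx(0.81 / 0.82)

    def test_constant_category_not_splittable(self):
        x = np.array([[1, 0]] * 4, dtype=np.uint8)
        st, x, xf = _state(x, [0] * 4, 1)
        assert _splittable(st.Nk, st.Nkj).size == 0
        assert propose_split(st, x, 0.9, np.random.default_rng(0)) is None

    def test_near_deterministic_at_extreme_eta(self, rng):
        """eta close to 1: members partition by their feature value."""
        x = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        st, x, xf = _state(x, [0] * 4, 1)
        for _ in range(20):
            z_new, *_ = propose_split(st, x, 0.999, rng)
            assert z_new.tolist() == [0, 0, 1, 1]


class TestProposeJoin:
    def test_unavailable_at_k1(self, tiny_fm):
        st, x, xf = _state(tiny_fm.x, [0, 0, 0], 1)
        assert propose_join(st, np.random.default_rng(0)) is None

    def test_k2_single_choice(self, tiny_fm):
        st, x, xf = _state(tiny_fm.x, [0, 1, 1], 2)
        z_new, Nk_new, _, (keep, remove), log_gen = propose_join(st, np.random.default_rng(0))
        assert (keep, remove) == (0, 1)
        assert z_new.tolist() == [0, 0, 0]
        assert log_gen == pytest.approx(0.0)  # log 1/(K-1) with K=2

    def test_labels_stay_contiguous(self, rng):
        x = (rng.random((8, 3)) < 0.5).astype(np.uint8)
        st, x, xf = _state(x, [0, 0, 1, 1, 2, 2, 3, 3], 4)
        z_new, Nk_new, *_ = propose_join(st, rng)
        assert sorted(np.unique(z_new)) == [0, 1, 2]
        assert Nk_new.sum() == 8


class TestSplitJoinStep:
    def test_separated_blocks_split_is_accepted(self, two_block_fm):
        """Two well-separated blocks at K=1: the marginal-likelihood ratio
        for the clean split is astronomically favorable."""
        st, x, xf = _state(two_block_fm.x, np.zeros(20), 1)
        cfg = SamplerConfig(n_steps=2, burn_in=0, thin=1, split_join_prob=1.0)
        accepted = split_join_step(st, x, xf, cfg, np.random.default_rng(0))
        assert accepted and st.K == 2
        assert np.unique(st.z).size == 2

    def test_identical_rows_have_no_split(self):
        x = np.array([[1, 0]] * 5, dtype=np.uint8)
        st, x, xf = _state(x, [0] * 5, 1)
        cfg = SamplerConfig(n_steps=2, burn_in=0, thin=1, split_join_prob=1.0)
        diag = {}
        accepted = split_join_step(st, x, xf, cfg, np.random.default_rng(0), diag)
        assert not accepted and st.K == 1
        assert diag["split_attempts"] == 1

    def test_k_changes_by_one_at_most(self, two_block_fm, rng):
        st, x, xf = _state(two_block_fm.x, np.zeros(20), 1)
        cfg = SamplerConfig(n_steps=2, burn_in=0, thin=1)
        for _ in range(100):
            k0 = st.K
            split_join_step(st, x, xf, cfg, rng)
            assert abs(st.K - k0) <= 1
            assert 1 <= st.K <= 20


class TestLogPostCache:
    def test_cache_matches_recomputation_after_each_move(self, two_block_fm, rng):
        fm = two_block_fm
        cfg = SamplerConfig(n_steps=2, burn_in=0, thin=1, seed=5)
        st = init_state(fm, cfg, rng)
        xf = fm.x.astype(float)
        for move in range(40):
            recategorize(st, xf, rng)
            reclassify(st, rng)
            split_join_step(st, fm.x, xf, cfg, rng)
            th = st.theta()
            expect = log_joint(fm, st.z, th) + log_prior(th)
            if np.isfinite(expect):
                assert st.log_post == pytest.approx(expect, abs=1e-8)


class TestRunChain:
    def test_determinism_per_seed_and_chain(self, two_block_fm):
        cfg = SamplerConfig(n_steps=60, burn_in=20, thin=5, seed=42)
        a, _ = run_chain(two_block_fm, cfg, chain_id=3)
        b, _ = run_chain(two_block_fm, cfg, chain_id=3)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.z, sb.z)
            assert np.array_equal(sa.theta.mu, sb.theta.mu)
            assert sa.log_post == sb.log_post

    def test_chains_differ(self, two_block_fm):
        cfg = SamplerConfig(n_steps=60, burn_in=20, thin=5, seed=42)
        a, _ = run_chain(two_block_fm, cfg, chain_id=0)
        b, _ = run_chain(two_block_fm, cfg, chain_id=1)
        assert any(not np.array_equal(sa.z, sb.z) for sa, sb in zip(a, b))

    def test_retention_rule(self, two_block_fm):
        cfg = SamplerConfig(n_steps=100, burn_in=50, thin=10, seed=1)
        samples, _ = run_chain(two_block_fm, cfg, 0)
        assert [s.step for s in samples] == [50, 60, 70, 80, 90]

    def test_k_trace_bounded(self, two_block_fm):
        cfg = SamplerConfig(n_steps=80, burn_in=40, thin=10, seed=2)
        _, diag = run_chain(two_block_fm, cfg, 0)
        assert diag["k_trace"].min() >= 1
        assert diag["k_trace"].max() <= two_block_fm.n_frames

    def test_no_duplicate_prototypes_retained(self, two_block_fm):
        from contactstates.model import bhattacharyya_matrix
        cfg = SamplerConfig(n_steps=100, burn_in=20, thin=5, seed=3)
        samples, _ = run_chain(two_block_fm, cfg, 0)
        for s in samples:
            K = s.theta.n_categories
            if K >= 2:
                B = bhattacharyya_matrix(s.theta.mu)
                assert B[np.triu_indices(K, k=1)].max() < 1.0


class TestRunEnsemble:
    def test_reduces_to_run_chain(self, two_block_fm):
        cfg = SamplerConfig(n_steps=60, burn_in=20, thin=10, seed=9, n_chains=1)
        pooled, _ = run_ensemble(two_block_fm, cfg)
        single, _ = run_chain(two_block_fm, cfg, chain_id=0)
        assert len(pooled) == len(single)
        for a, b in zip(pooled, single):
            assert np.array_equal(a.z, b.z)

    def test_samples_tagged_by_chain(self, two_block_fm):
        cfg = SamplerConfig(n_steps=60, burn_in=20, thin=10, seed=9, n_chains=3)
        pooled, diags = run_ensemble(two_block_fm, cfg)
        assert sorted({s.chain_id for s in pooled}) == [0, 1, 2]
        assert len(diags) == 3

    def test_posterior_round_trip(self, two_block_fm, tmp_path):
        cfg = SamplerConfig(n_steps=60, burn_in=20, thin=10, seed=9, n_chains=2)
        pooled, _ = run_ensemble(two_block_fm, cfg)
        path = tmp_path / "post.npz"
        write_posterior(path, pooled)
        back = read_posterior(path)
        assert len(back) == len(pooled)
        for a, b in zip(pooled, back):
            assert np.array_equal(a.z, b.z)
            assert np.allclose(a.theta.mu, b.theta.mu)
            assert a.chain_id == b.chain_id and a.step == b.step


def test_log_partition_prob_renormalizes_degenerate_outcomes():
    """Two members, one feature, eta=0.9: enumeration of the 4 outcomes
    with the 2 degenerate ones removed leaves 0.81/0.82 and 0.01/0.82."""
    a1, a0 = np.array([1]), np.array([0])   # L member has the feature
    b1, b0 = np.array([0]), np.array([1])
    lp = _log_partition_prob(a1, a0, b1, b0, np.array([1]), 2, 0.9)
    assert math.exp(lp) == pytest.approx(0.81 / 0.82)
    lp_swap = _log_partition_prob(b1, b0, a1, a0, np.array([1]), 2, 0.9)
    assert math.exp(lp_swap) == pytest.approx(0.01 / 0.82)
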