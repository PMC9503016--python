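"""CRF potentials, brute-force Gibbs oracle, and mean-field inference."""

from itertools import product

import numpy as np
import pytest

from histoseg import ncrf
from histoseg.nn.autograd import Tensor


def random_obs(rng, g=2, d=4, scale=1.0):
    n = g * g
    return ncrf.PatchGridObservation(
        grid_shape=(g, g),
        embeddings=rng.normal(size=(n, d)),
        unary_scores=scale * rng.normal(size=(n, 3)))


def second_enumeration(obs, weights, indicator_mode="same"):
    """Independent (slow, scalar) enumeration of the Gibbs marginals."""
    n = obs.n
    probs = {}
    z = 0.0
    for x in product(range(3), repeat=n):
        e = sum(ncrf.unary_potential(obs, i, x[i]) for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                e += ncrf.pairwise_potential(
                    obs.embeddings[i], obs.embeddings[j], x[i], x[j],
                    weights[i, j], indicator_mode)
        p = np.exp(-e)
        probs[x] = p
        z += p
    q = np.zeros((n, 3))
    for x, p in probs.items():
        for i in range(n):
            q[i, x[i]] += p / z
    return q


class TestPotentials:
    def test_uniform_logits_give_log3(self):
        obs = ncrf.PatchGridObservation((1, 1), np.ones((1, 2)),
                                        np.zeros((1, 3)))
        for c in range(3):
            assert ncrf.unary_potential(obs, 0, c) == pytest.approx(np.log(3))

    def test_saturated_logits(self):
        scores = np.array([[30.0, -30.0, -30.0]])
        obs = ncrf.PatchGridObservation((1, 1), np.ones((1, 2)), scores)
        assert ncrf.unary_potential(obs, 0, 0) == pytest.approx(0.0, abs=1e-9)

    def test_unary_matches_logsumexp_oracle(self, rng):
        obs = random_obs(rng)
        for i in range(obs.n):
            s = obs.unary_scores[i]
            z = np.log(np.exp(s - s.max()).sum()) + s.max()
            for c in range(3):
                assert ncrf.unary_potential(obs, i, c) == pytest.approx(
                    z - s[c], abs=1e-9)

    def test_pairwise_zero_when_labels_differ(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert ncrf.pairwise_potential(a, b, 0, 1, 5.0) == 0.0

    def test_pairwise_zero_for_parallel_embeddings(self):
        a = np.array([1.0, 2.0])
        assert ncrf.pairwise_potential(a, 3 * a, 1, 1, 5.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_pairwise_orthogonal_hand_value(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert ncrf.pairwise_potential(a, b, 2, 2, 2.0) == pytest.approx(2.0)

    def test_zero_norm_embedding_rejected(self):
        with pytest.raises(ValueError):
            ncrf.pairwise_potential(np.zeros(3), np.ones(3), 0, 0, 1.0)


class TestEnergy:
    def test_zero_weights_energy_is_unary_sum(self, rng):
        obs = random_obs(rng)
        w = np.zeros((4, 4))
        x = [0, 1, 2, 1]
        expected = sum(ncrf.unary_potential(obs, i, x[i]) for i in range(4))
        assert ncrf.energy(x, obs, w) == pytest.approx(expected)

    def test_single_patch_energy(self, rng):
        obs = random_obs(rng, g=1)
        assert ncrf.energy([2], obs, np.zeros((1, 1))) == pytest.approx(
            ncrf.unary_potential(obs, 0, 2))

    def test_energy_matches_term_by_term_sum(self, rng):
        obs = random_obs(rng)
        w = ncrf.grid_pairwise_weights((2, 2), 1.5)
        x = [1, 1, 0, 2]
        expected = sum(ncrf.unary_potential(obs, i, x[i]) for i in range(4))
        for i in range(4):
            for j in range(i + 1, 4):
                expected += ncrf.pairwise_potential(
                    obs.embeddings[i], obs.embeddings[j], x[i], x[j],
                    w[i, j])
        assert ncrf.energy(x, obs, w) == pytest.approx(expected)


class TestBruteForce:
    def test_zero_weights_factorize(self, rng):
        obs = random_obs(rng)
        mf = ncrf.exact_marginals_bruteforce(obs, np.zeros((4, 4)))
        soft = np.exp(obs.unary_scores
                      - obs.unary_scores.max(axis=1, keepdims=True))
        soft /= soft.sum(axis=1, keepdims=True)
        assert np.allclose(mf.q, soft, atol=1e-12)

    def test_uniform_potentials_uniform_marginals(self):
        obs = ncrf.PatchGridObservation((2, 2), np.ones((4, 3)),
                                        np.zeros((4, 3)))
        mf = ncrf.exact_marginals_bruteforce(
            obs, ncrf.grid_pairwise_weights((2, 2), 0.7))
        assert np.allclose(mf.q, 1 / 3, atol=1e-12)

    def test_matches_independent_enumeration(self, rng):
        obs = random_obs(rng)
        w = ncrf.grid_pairwise_weights((2, 2), 0.8)
        mf = ncrf.exact_marginals_bruteforce(obs, w)
        assert np.allclose(mf.q.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(mf.q, second_enumeration(obs, w), atol=1e-9)

    def test_refuses_large_grids(self, rng):
        obs = random_obs(rng, g=4)
        with pytest.raises(ValueError):
            ncrf.exact_marginals_bruteforce(obs, np.zeros((16, 16)))


class TestMeanFieldUpdate:
    def test_zero_weights_update_is_decoupled_softmax(self, rng):
        obs = random_obs(rng)
        q0 = ncrf.MarginalField(q=np.full((4, 3), 1 / 3))
        out = ncrf.meanfield_update(q0, obs, np.zeros((4, 4)), 2)
        soft = np.exp(obs.unary_scores[2] - obs.unary_scores[2].max())
        soft /= soft.sum()
        assert np.allclose(out.q[2], soft, atol=1e-12)
        assert np.array_equal(out.q[[0, 1, 3]], q0.q[[0, 1, 3]])

    def test_certain_neighbors_shift_mass_by_indicator_mode(self, rng):
        """GM-certain neighbors raise GM mass under the smoothing
        (complementary) indicator and lower it under the printed one."""
        g = 2
        base = rng.normal(size=3)
        emb = base + 0.4 * rng.normal(size=(4, 3))   # similar, cos < 1
        scores = np.zeros((4, 3))
        obs = ncrf.PatchGridObservation((g, g), emb, scores)
        w = ncrf.grid_pairwise_weights((g, g), 4.0)
        q = np.zeros((4, 3))
        q[:, 1] = 1.0                                # neighbors certain: GM
        field = ncrf.MarginalField(q=q)
        decoupled = 1 / 3
        pulled = ncrf.meanfield_update(field, obs, w, 0,
                                       indicator_mode="different")
        assert pulled.q[0, 1] > decoupled
        printed = ncrf.meanfield_update(field, obs, w, 0,
                                        indicator_mode="same")
        assert printed.q[0, 1] < decoupled

    def test_update_idempotent_given_fixed_neighbors(self, rng):
        obs = random_obs(rng)
        w = ncrf.grid_pairwise_weights((2, 2), 1.3)
        q0 = ncrf.MarginalField(q=np.full((4, 3), 1 / 3))
        once = ncrf.meanfield_update(q0, obs, w, 1)
        twice = ncrf.meanfield_update(once, obs, w, 1)
        assert np.allclose(once.q, twice.q, atol=1e-14)


class TestMeanFieldInfer:
    def test_zero_weights_converges_first_sweep(self, rng):
        obs = random_obs(rng, g=3)
        field = ncrf.meanfield_infer(obs, np.zeros((9, 9)))
        soft = np.exp(obs.unary_scores
                      - obs.unary_scores.max(axis=1, keepdims=True))
        soft /= soft.sum(axis=1, keepdims=True)
        assert np.allclose(field.q, soft, atol=1e-12)
        assert len(field.iteration_trace) <= 2

    @pytest.mark.parametrize("g", [2, 3])
    def test_kl_nonincreasing_across_sweeps(self, g, rng):
        for _ in range(5):
            obs = random_obs(rng, g=g, scale=1.5)
            w = ncrf.grid_pairwise_weights((g, g),
                                           float(rng.uniform(0.2, 2.0)))
            _, assignments, p = ncrf.exact_marginals_bruteforce(
                obs, w, return_joint=True)
            kls = []
            for sweeps in range(1, 5):
                field = ncrf.meanfield_infer(obs, w, max_sweeps=sweeps,
                                             tol=0.0)
                q_joint = np.prod(
                    field.q[np.arange(obs.n), assignments], axis=1)
                kl = float(np.sum(q_joint * (np.log(q_joint + 1e-300)
                                             - np.log(p + 1e-300))))
                kls.append(kl)
            assert all(b <= a + 1e-9 for a, b in zip(kls, kls[1:]))

    def test_strong_attraction_flips_minority(self):
        # smoothing needs the complementary indicator: disagreement on
        # similar patches is what costs; 3 of 4 unaries favor GM, strong
        # coupling must pull the fourth along (checked against brute force)
        emb_mixed = np.array([[1.0, 0.0], [0.9, 0.1], [1.0, 0.05],
                              [0.8, 0.2]])
        scores = np.array([[0.0, 2.0, 0.0]] * 3 + [[0.0, 0.0, 1.0]])
        obs = ncrf.PatchGridObservation((2, 2), emb_mixed, scores)
        w = ncrf.grid_pairwise_weights((2, 2), 80.0)
        field = ncrf.meanfield_infer(obs, w, indicator_mode="different",
                                     max_sweeps=20)
        exact = ncrf.exact_marginals_bruteforce(obs, w,
                                                indicator_mode="different")
        assert list(field.labels) == list(exact.labels)
        assert list(field.labels) == [1, 1, 1, 1]

    def test_row_stochastic_after_every_sweep(self, rng):
        obs = random_obs(rng, g=3)
        w = ncrf.grid_pairwise_weights((3, 3), 1.0)
        field = ncrf.meanfield_infer(obs, w, max_sweeps=7, tol=0.0)
        assert np.allclose(field.q.sum(axis=1), 1.0, atol=1e-12)
        assert field.q.min() >= 0.0

    def test_permutation_equivariance(self, rng):
        obs = random_obs(rng, g=2)
        w = ncrf.grid_pairwise_weights((2, 2), 0.9)
        perm = np.array([2, 0, 3, 1])
        obs_p = ncrf.PatchGridObservation(
            (2, 2), obs.embeddings[perm], obs.unary_scores[perm])
        w_p = w[np.ix_(perm, perm)]
        # parallel schedule is order-free, hence exactly equivariant
        a = ncrf.meanfield_infer(obs, w, schedule="parallel", max_sweeps=6,
                                 tol=0.0)
        b = ncrf.meanfield_infer(obs_p, w_p, schedule="parallel",
                                 max_sweeps=6, tol=0.0)
        assert np.allclose(a.q[perm], b.q, atol=1e-12)


class TestLossAndGradient:
    def test_one_hot_truth_zero_loss(self):
        q = np.eye(3)
        field = ncrf.MarginalField(q=q)
        assert ncrf.ncrf_loss(field, [0, 1, 2]) == pytest.approx(0.0)

    def test_uniform_loss_is_log3(self):
        field = ncrf.MarginalField(q=np.full((5, 3), 1 / 3))
        assert ncrf.ncrf_loss(field, [0] * 5) == pytest.approx(np.log(3))

    def test_loss_matches_hand_cross_entropy(self, rng):
        q = rng.dirichlet(np.ones(3), size=6)
        labels = rng.integers(0, 3, size=6)
        field = ncrf.MarginalField(q=q)
        hand = -np.mean([np.log(q[i, labels[i]]) for i in range(6)])
        assert ncrf.ncrf_loss(field, labels) == pytest.approx(hand, abs=1e-9)

    def test_backprop_matches_finite_differences_3x3(self, rng):
        g = 3
        n = g * g
        emb = rng.normal(size=(n, 5))
        scores = rng.normal(size=(n, 3))
        w = ncrf.grid_pairwise_weights((g, g), 0.8)
        coupling = w * ncrf.cosine_distance_matrix(emb)
        labels = rng.integers(0, 3, size=n)

        def loss_value(s):
            t = Tensor(s, requires_grad=True)
            m = ncrf.meanfield_marginals_autograd(t, coupling, n_sweeps=3)
            return ncrf.ncrf_loss_autograd(m, labels), t

        out, leaf = loss_value(scores)
        out.backward()
        eps = 1e-5
        num = np.zeros_like(scores)
        for i in range(n):
            for c in range(3):
                up = scores.copy(); up[i, c] += eps
                dn = scores.copy(); dn[i, c] -= eps
                num[i, c] = (float(loss_value(up)[0].data)
                             - float(loss_value(dn)[0].data)) / (2 * eps)
        assert np.allclose(leaf.grad, num, atol=1e-4)

    def test_autograd_marginals_agree_with_numpy_path(self, rng):
        g = 2
        obs = random_obs(rng, g=g)
        w = ncrf.grid_pairwise_weights((g, g), 1.1)
        coupling = w * ncrf.cosine_distance_matrix(obs.embeddings)
        t = Tensor(obs.unary_scores, requires_grad=True)
        auto = ncrf.meanfield_marginals_autograd(t, coupling, n_sweeps=4)
        ref = ncrf.meanfield_infer(obs, w, max_sweeps=4, tol=0.0)
        assert np.allclose(auto.data, ref.q, atol=1e-12)
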