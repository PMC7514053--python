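import numpy as np
import pytest
import scipy.sparse as sp

from hovgae.graph import Graph, normalize_adjacency
from hovgae.model import (
    EncoderParams,
    HOVGAEModel,
    TrainConfig,
    balanced_reconstruction_loss,
    decode,
    encode,
    identity_features,
    init_params,
    kl_loss,
    l2_reg,
    load_checkpoint,
    loss_and_grads,
    predict_scores,
    reparameterize,
    save_checkpoint,
    total_loss,
    train,
)
from hovgae.propagation import PropagationConfig, exact_ppr_matrix, propagate
from hovgae.synthetic import SbmSpec, sbm_graph


def _softplus(x):
    return np.logaddexp(0.0, x)


class TestIdentityFeatures:
    def test_is_identity(self):
        X = identity_features(3)
        assert sp.issparse(X)
        assert np.array_equal(X.toarray(), np.eye(3))

    def test_propagate_identity_gives_score_matrix(self, er_graph):
        g = er_graph(12, 0.3, seed=0)
        An = normalize_adjacency(g)
        cfg = PropagationConfig(alpha=0.2, mode="exact")
        P = propagate(identity_features(g.n).toarray(), An, cfg)
        assert np.allclose(P, exact_ppr_matrix(An, 0.2), atol=1e-12)


class TestEncode:
    def _setup(self, er_graph, widths=(8, 4)):
        g = er_graph(10, 0.3, seed=1)
        cfg = TrainConfig(layer_widths=widths, dropout=0.0)
        params = init_params(g.n, cfg, np.random.default_rng(0))
        return g, params, cfg

    def test_zero_weights_zero_outputs(self, er_graph):
        g, params, cfg = self._setup(er_graph)
        for W in params.weights:
            W[...] = 0.0
        mu, ls = encode(identity_features(g.n), normalize_adjacency(g), params, cfg.propagation)
        assert np.array_equal(mu, np.zeros((g.n, 4)))
        assert np.array_equal(ls, np.zeros((g.n, 4)))

    def test_output_shapes(self, er_graph):
        g, params, cfg = self._setup(er_graph, widths=(16, 8, 5))
        mu, ls = encode(identity_features(g.n), normalize_adjacency(g), params, cfg.propagation)
        assert mu.shape == ls.shape == (g.n, 5)

    def test_deterministic_given_weights(self, er_graph):
        g, params, cfg = self._setup(er_graph)
        args = (identity_features(g.n), normalize_adjacency(g), params, cfg.propagation)
        mu1, ls1 = encode(*args)
        mu2, ls2 = encode(*args)
        assert np.array_equal(mu1, mu2) and np.array_equal(ls1, ls2)


class TestReparameterize:
    def test_sigma_zero_limit_returns_mu(self):
        mu = np.ones((3, 2))
        z = reparameterize(mu, np.full((3, 2), -745.0), np.random.default_rng(0))
        assert np.allclose(z, mu)

    def test_seeded_reproducible(self):
        mu, ls = np.zeros((4, 3)), np.zeros((4, 3))
        z1 = reparameterize(mu, ls, np.random.default_rng(7))
        z2 = reparameterize(mu, ls, np.random.default_rng(7))
        assert np.array_equal(z1, z2)

    def test_monte_carlo_mean_near_mu(self):
        # 10^4 unit-sigma draws: sample mean within 4 standard errors of mu
        rng = np.random.default_rng(3)
        mu = np.array([[1.5, -2.0]])
        draws = np.stack([reparameterize(mu, np.zeros_like(mu), rng) for _ in range(10_000)])
        se = 1.0 / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)


class TestDecode:
    def test_zero_embedding_gives_half(self):
        assert np.allclose(decode(np.zeros((4, 3))), 0.5)

    def test_symmetric(self):
        Z = np.random.default_rng(0).standard_normal((6, 3))
        A_hat = decode(Z)
        assert np.array_equal(A_hat, A_hat.T)

    def test_orthogonal_unit_rows(self):
        Z = np.eye(2)
        A_hat = decode(Z)
        assert A_hat[0, 1] == pytest.approx(0.5)
        assert A_hat[0, 0] == pytest.approx(1 / (1 + np.exp(-1)))


class TestLosses:
    def test_balanced_equals_twice_unweighted_at_half_density(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((5, 5))
        target = (rng.random((5, 5)) < 0.5).astype(float)
        bal = balanced_reconstruction_loss(logits, target, d=0.5)
        unw = np.sum(target * _softplus(-logits) + (1 - target) * _softplus(logits))
        assert bal == pytest.approx(2 * unw, abs=1e-10)

    def test_perfect_logits_saturate_to_zero(self):
        target = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits = np.where(target == 1, 500.0, -500.0)
        assert balanced_reconstruction_loss(logits, target, d=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_node_hand_computed(self):
        # 2 nodes, 1 edge, diagonal targets 1; fixed 2x2 embedding
        Z = np.array([[1.0, 0.5], [-0.5, 2.0]])
        logits = Z @ Z.T
        target = np.ones((2, 2))  # adjacency 1 + self-loops
        d = 1.0 - 0.25  # pretend density to keep both classes weighted
        hand = 0.0
        for i in range(2):
            for j in range(2):
                p = 1 / (1 + np.exp(-logits[i, j]))
                hand += -(target[i, j] / d) * np.log(p)
        got = balanced_reconstruction_loss(logits, target, d)
        assert got == pytest.approx(hand, abs=1e-10)

    def test_density_bounds(self):
        with pytest.raises(ValueError):
            balanced_reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 2)), d=0.0)

    def test_kl_standard_normal_zero(self):
        assert kl_loss(np.zeros((3, 2)), np.zeros((3, 2))) == 0.0

    def test_kl_single_entry_half(self):
        assert kl_loss(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            mu = rng.standard_normal((4, 3))
            ls = rng.standard_normal((4, 3))
            assert kl_loss(mu, ls) >= -1e-12

    def test_l2_reg(self):
        p = EncoderParams(hidden=[np.array([[1.0, 1.0], [1.0, 1.0]])],
                          W_mu=np.zeros((2, 1)), W_logsigma=np.zeros((2, 1)))
        assert l2_reg(p) == 2.0
        rng = np.random.default_rng(3)
        p2 = EncoderParams(hidden=[rng.standard_normal((3, 2))],
                           W_mu=rng.standard_normal((2, 2)),
                           W_logsigma=rng.standard_normal((2, 2)))
        direct = 0.5 * sum((W**2).sum() for W in p2.weights)
        assert l2_reg(p2) == pytest.approx(direct, abs=1e-12)

    def test_total_loss_composition(self):
        assert total_loss(2.0, 3.0, 100.0, v=0.0) == 5.0
        assert total_loss(2.0, 3.0, 100.0, v=1e-2) == pytest.approx(6.0)
        assert total_loss(1.0, 1.0, 1.0, v=0.2) < total_loss(1.0, 1.0, 1.0, v=0.3)


class TestGradients:
    @pytest.mark.parametrize("mode", ["power", "standard_1hop"])
    def test_finite_difference_agreement(self, er_graph, mode):
        """Backpropagated gradients match central differences entrywise."""
        g = er_graph(10, 0.4, seed=5)
        prop = PropagationConfig(alpha=0.2, k=5, mode=mode)
        cfg = TrainConfig(layer_widths=(4, 2), dropout=0.0, v=1e-3, propagation=prop)
        rng = np.random.default_rng(0)
        params = init_params(g.n, cfg, rng)
        An = normalize_adjacency(g)
        target = g.A.toarray().astype(float)
        np.fill_diagonal(target, 1.0)
        d = target.sum() / g.n**2
        eps = rng.standard_normal((g.n, 2))
        P0 = propagate(np.eye(g.n), An, prop)
        _, grads, _ = loss_and_grads(params, An, prop, target, d, eps, P0, training=False)
        h = 1e-6
        for wi, W in enumerate(params.weights):
            for idx in np.ndindex(W.shape):
                orig = W[idx]
                W[idx] = orig + h
                lp = loss_and_grads(params, An, prop, target, d, eps, P0, training=False)[0]["total"]
                W[idx] = orig - h
                lm = loss_and_grads(params, An, prop, target, d, eps, P0, training=False)[0]["total"]
                W[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[wi][idx]
                assert abs(fd - an) / max(1e-8, abs(fd), abs(an)) < 1e-4


@pytest.fixture(scope="module")
def small_sbm():
    return sbm_graph(SbmSpec(block_sizes=(30, 30), p_in=0.25, p_out=0.03, seed=7))


class TestTrain:
    def test_loss_decreases(self, small_sbm):
        cfg = TrainConfig(seed=0, max_iters=50, layer_widths=(32, 16))
        _, _, trace = train(small_sbm, cfg)
        assert trace[-1]["total"] < trace[0]["total"]

    def test_seeded_determinism(self, small_sbm):
        cfg = TrainConfig(seed=3, max_iters=15, layer_widths=(16, 8))
        _, emb1, tr1 = train(small_sbm, cfg)
        _, emb2, tr2 = train(small_sbm, cfg)
        assert np.array_equal(emb1.mu, emb2.mu)
        assert [r["total"] for r in tr1] == [r["total"] for r in tr2]

    def test_cotrain_zero_identical_to_basic(self, small_sbm):
        base = TrainConfig(seed=1, max_iters=10, layer_widths=(16, 8), cotrain_t=0)
        _, emb1, _ = train(small_sbm, base)
        _, emb2, _ = train(small_sbm, TrainConfig(seed=1, max_iters=10, layer_widths=(16, 8)))
        assert np.array_equal(emb1.mu, emb2.mu)

    def test_cotrain_changes_target_not_propagation(self, small_sbm):
        cfg = TrainConfig(seed=1, max_iters=10, layer_widths=(16, 8), cotrain_t=20)
        _, emb, _ = train(small_sbm, cfg)
        assert np.all(np.isfinite(emb.mu))

    def test_alpha_one_propagation_is_identity(self, er_graph):
        # teleporting always: the encoder degenerates to an MLP on X
        g = er_graph(12, 0.3, seed=6)
        An = normalize_adjacency(g)
        Z = np.random.default_rng(0).standard_normal((g.n, 3))
        cfg = PropagationConfig(alpha=1.0, k=25, mode="power")
        assert np.array_equal(propagate(Z, An, cfg), Z)


class TestPredictScores:
    def test_zero_mu_gives_half(self, toys):
        from hovgae.model import LatentEmbedding

        g = toys["p3"]
        emb = LatentEmbedding(mu=np.zeros((3, 2)), log_sigma=np.zeros((3, 2)), Z=np.zeros((3, 2)))
        t = predict_scores(emb, [("a", "c")], g)
        assert t.scores()[0] == 0.5

    def test_symmetric_in_pair_order(self, er_graph):
        g = er_graph(10, 0.3, seed=8)
        cfg = TrainConfig(seed=0, max_iters=5, layer_widths=(8, 4))
        model = HOVGAEModel(cfg).fit(g)
        s1 = model.score_pairs([(0, 5)])
        s2 = model.score_pairs([(5, 0)])
        assert s1[0] == s2[0]

    def test_ranking_matches_logit_order(self, er_graph):
        g = er_graph(10, 0.3, seed=8)
        model = HOVGAEModel(TrainConfig(seed=0, max_iters=5, layer_widths=(8, 4))).fit(g)
        pairs = [(0, 1), (2, 3), (4, 5)]
        mu = model.embedding.mu
        logits = [mu[i] @ mu[j] for i, j in pairs]
        scores = model.score_pairs(pairs)
        assert list(np.argsort(logits)) == list(np.argsort(scores))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, er_graph):
        g = er_graph(12, 0.3, seed=9)
        model = HOVGAEModel(TrainConfig(seed=2, max_iters=5, layer_widths=(8, 4))).fit(g)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        loaded = load_checkpoint(path)
        assert loaded.graph.node_ids == g.node_ids
        assert loaded.graph.edge_set() == g.edge_set()
        assert np.array_equal(loaded.embedding.mu, model.embedding.mu)
        pairs = [(0, 3), (1, 7)]
        assert np.allclose(loaded.score_pairs(pairs), model.score_pairs(pairs))
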