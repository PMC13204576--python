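import numpy as np
import pytest

from strokegraph import (ChebGCN, ChebLayerParams, InputError, ModelConfig,
                         SpectralDecomposition, TrainConfig, cheb_conv_forward,
                         parameter_count, scaled_laplacian, train)
from strokegraph.graphs import RegionGraph
from conftest import random_adjacency


def small_lt(rng, n=6):
    return scaled_laplacian(random_adjacency(rng, n))


class TestChebConvForward:
    def test_zero_theta_broadcasts_bias(self, rng):
        Lt = small_lt(rng)
        params = ChebLayerParams(theta=np.zeros((3, 4, 2)),
                                 bias=np.array([1.5, -2.0]))
        out = cheb_conv_forward(Lt, rng.standard_normal((6, 4)), params)
        assert np.allclose(out, [1.5, -2.0])

    def test_order_one_identity_filter(self, rng):
        Lt = small_lt(rng)
        X = rng.standard_normal((6, 4))
        params = ChebLayerParams(theta=np.eye(4)[None], bias=np.zeros(4))
        assert np.allclose(cheb_conv_forward(Lt, X, params), X)

    def test_matches_dense_spectral_construction(self, rng):
        # independent route: build each T_k(L~) densely through the eigenbasis
        Lt = small_lt(rng)
        dec = SpectralDecomposition.from_matrix(Lt)
        X = rng.standard_normal((6, 3))
        params = ChebLayerParams(theta=rng.standard_normal((4, 3, 5)),
                                 bias=rng.standard_normal(5))
        dense = params.bias.copy().astype(float) + np.zeros((6, 5))
        for k in range(4):
            tk = np.cos(k * np.arccos(np.clip(dec.Lambda, -1, 1)))
            Tk = dec.U @ np.diag(tk) @ dec.U.T
            dense = dense + Tk @ X @ params.theta[k]
        assert np.allclose(cheb_conv_forward(Lt, X, params), dense, atol=1e-9)

    def test_linear_in_input(self, rng):
        Lt = small_lt(rng)
        params = ChebLayerParams(theta=rng.standard_normal((3, 4, 4)),
                                 bias=np.zeros(4))
        x1 = rng.standard_normal((6, 4))
        x2 = rng.standard_normal((6, 4))
        lhs = cheb_conv_forward(Lt, 2.0 * x1 - 3.0 * x2, params)
        rhs = (2.0 * cheb_conv_forward(Lt, x1, params)
               - 3.0 * cheb_conv_forward(Lt, x2, params))
        assert np.allclose(lhs, rhs)

    def test_shape_mismatch_rejected(self, rng):
        params = ChebLayerParams(theta=np.zeros((3, 4, 2)), bias=np.zeros(2))
        with pytest.raises(InputError):
            cheb_conv_forward(small_lt(rng), np.zeros((6, 5)), params)


class TestBlocksAndForward:
    def test_train_mode_batchnorm_standardizes_channels(self, rng):
        model = ChebGCN(rng=1)
        Lt = scaled_laplacian(random_adjacency(rng, 40))
        X = rng.standard_normal((40, 16))
        h, _ = model.block_forward(Lt, X, 0, train=True)
        # final BN of the block recentres each channel
        assert np.allclose(h.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(h.var(axis=0), 1.0, atol=1e-4)  # var/(var+eps) shrinkage

    def test_leaky_relu_definition(self):
        cfg = ModelConfig(leaky_relu_slope=0.1)
        x = np.array([-1.0, 2.0])
        out = np.where(x < 0, cfg.leaky_relu_slope * x, x)
        assert out.tolist() == [-0.1, 2.0]

    def test_eval_block_with_unit_stats_passes_positive_conv_output(self, rng):
        model = ChebGCN(ModelConfig(dropout_rate=0.0), rng=2)
        Lt = small_lt(rng)
        X = np.abs(rng.standard_normal((6, 16)))
        model.convs[0].theta[:] = 0.0
        model.convs[0].bias[:] = 3.0  # conv output strictly positive
        for bn in (model.bn1[0], model.bn2[0]):
            bn.running_mean[:] = 0.0
            bn.running_var[:] = 1.0 - 1e-5  # unit denominator incl. epsilon
        h, _ = model.block_forward(Lt, X, 0, train=False)
        assert np.allclose(h, 3.0)

    def test_softmax_rows_sum_to_one(self, rng):
        model = ChebGCN(rng=0)
        Lt = scaled_laplacian(random_adjacency(rng, 9))
        probs, _ = model.forward(Lt, rng.standard_normal((9, 16)))
        assert probs.shape == (9, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_forward_is_deterministic(self, rng):
        model = ChebGCN(rng=0)
        Lt = scaled_laplacian(random_adjacency(rng, 9))
        X = rng.standard_normal((9, 16))
        p1, _ = model.forward(Lt, X)
        p2, _ = model.forward(Lt, X)
        assert np.array_equal(p1, p2)

    def test_permutation_equivariance(self, rng):
        model = ChebGCN(rng=4)
        A = random_adjacency(rng, 7)
        X = rng.standard_normal((7, 16))
        perm = rng.permutation(7)
        p_orig, _ = model.forward(scaled_laplacian(A), X)
        p_perm, _ = model.forward(scaled_laplacian(A[np.ix_(perm, perm)]), X[perm])
        assert np.max(np.abs(p_perm - p_orig[perm])) < 1e-6

    def test_feature_dim_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            ChebGCN(rng=0).forward(small_lt(rng), np.zeros((6, 7)))


class TestParameterCount:
    def test_table_style_conv_counts(self):
        assert 3 * 16 * 16 + 16 == 784  # one 16->16 layer at order 3
        cfg = ModelConfig()
        conv_total = sum(o * i * o_dim + o_dim for o, i, o_dim in
                         zip(cfg.cheb_orders, cfg.dims[:-1], cfg.dims[1:]))
        assert conv_total == 4 * 784 + (3 * 16 * 2 + 2)
        assert 3 * 16 * 2 + 2 == 98  # final 16->2 layer

    @pytest.mark.parametrize("seed", range(5))
    def test_formula_matches_model_introspection(self, seed):
        rng = np.random.default_rng(seed)
        n_blocks = int(rng.integers(2, 6))
        dims = [int(rng.integers(2, 20)) for _ in range(n_blocks)] + [2]
        orders = tuple(int(rng.integers(1, 6)) for _ in range(n_blocks))
        cfg = ModelConfig(n_blocks=n_blocks, dims=tuple(dims), cheb_orders=orders,
                          double_batchnorm=bool(rng.integers(0, 2)))
        model = ChebGCN(cfg, rng=0)
        assert parameter_count(cfg) == sum(p.size for p in model.parameters())


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        A = random_adjacency(rng, 9)
        Lt = scaled_laplacian(A)
        X = rng.standard_normal((9, 16))
        y = rng.integers(0, 2, 9)
        model = ChebGCN(ModelConfig(dropout_rate=0.0), rng=3)
        _, grads = model.loss_and_grads(Lt, X, y, train=True)
        params = model.parameters()
        bns = list(model.bn1) + [b for b in model.bn2 if b is not None]
        snap = [(b.running_mean.copy(), b.running_var.copy()) for b in bns]

        def restore():
            for b, (rm, rv) in zip(bns, snap):
                b.running_mean[:] = rm
                b.running_var[:] = rv

        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                l1, _ = model.loss_and_grads(Lt, X, y, train=True)
                restore()
                flat[idx] = old - eps
                l2, _ = model.loss_and_grads(Lt, X, y, train=True)
                restore()
                flat[idx] = old
                fd = (l1 - l2) / (2 * eps)
                assert abs(fd - g.reshape(-1)[idx]) <= 1e-4 + 1e-2 * abs(fd)


def _toy_graphs(rng, n_graphs=2, n=30):
    """Separable toy: lesion nodes carry a bright histogram signature."""
    graphs = []
    for _ in range(n_graphs):
        A = random_adjacency(rng, n, p=0.7)
        A[A > 0] = rng.uniform(0.2, 1.0, size=(A > 0).sum())
        A = np.triu(A, 1)
        A = A + A.T
        y = rng.integers(0, 2, n)
        X = np.zeros((n, 16))
        X[np.arange(n), np.where(y == 1, 12, 4)] = 1.0
        X += 0.05 * rng.random((n, 16))
        X /= X.sum(axis=1, keepdims=True)
        graphs.append(RegionGraph(adjacency=A, features=X, node_labels=y,
                                  sigma=1.0))
    return graphs


class TestTraining:
    def test_converges_on_separable_toy_problem(self, rng):
        graphs = _toy_graphs(rng)
        model, history = train(graphs, tcfg=TrainConfig(epochs=150, seed=0))
        correct = total = 0
        for g in graphs:
            _, preds = model.predict_graph(g)
            correct += (preds == g.node_labels).sum()
            total += len(preds)
        assert correct / total > 0.95
        # trailing moving average of the loss decreases
        assert np.mean(history[-10:]) < np.mean(history[:10])

    def test_zero_learning_rate_freezes_parameters(self, rng):
        graphs = _toy_graphs(rng, n_graphs=1)
        tcfg = TrainConfig(epochs=3, seed=1, learning_rate=0.0)
        model, _ = train(graphs, tcfg=tcfg)
        reference = ChebGCN(ModelConfig(), rng=np.random.default_rng(1))
        for p, q in zip(model.parameters(), reference.parameters()):
            assert np.array_equal(p, q)

    def test_identical_seed_identical_final_loss(self, rng):
        graphs = _toy_graphs(rng)
        _, h1 = train(graphs, tcfg=TrainConfig(epochs=10, seed=5))
        _, h2 = train(graphs, tcfg=TrainConfig(epochs=10, seed=5))
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(InputError):
            train([])

    def test_single_class_labels_warn_but_train(self, rng):
        graphs = _toy_graphs(rng, n_graphs=1)
        graphs[0].node_labels[:] = 0
        with pytest.warns(UserWarning, match="single class"):
            train(graphs, tcfg=TrainConfig(epochs=1, seed=0))

    def test_defaults_match_tuned_values(self):
        tcfg = TrainConfig()
        assert (tcfg.optimizer, tcfg.loss) == ("adadelta", "cross_entropy")
        assert tcfg.learning_rate == 0.0001
        assert tcfg.weight_decay == 6e-4
        assert tcfg.epochs == 150
        cfg = ModelConfig()
        assert cfg.n_blocks == 5 and cfg.dims == (16, 16, 16, 16, 16, 2)
        assert cfg.dropout_rate == 0.3


def test_checkpoint_round_trip_preserves_predictions(tmp_path, rng):
    graphs = _toy_graphs(rng, n_graphs=1)
    model, _ = train(graphs, tcfg=TrainConfig(epochs=5, seed=2))
    path = str(tmp_path / "ckpt.json")
    model.save(path)
    loaded = ChebGCN.load(path)
    p1, _ = model.predict_graph(graphs[0])
    p2, _ = loaded.predict_graph(graphs[0])
    assert np.array_equal(p1, p2)
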