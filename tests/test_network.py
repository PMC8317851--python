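import math

import numpy as np
import pytest

from survgate import network as net
from survgate import normalize_expression
from survgate.simulate import SimulationConfig, simulate_cohort
from survgate.features import FeatureScore, FeatureSet


def reference_forward(params, x1, x2):
    """Straight-line re-evaluation of the gated architecture, scalar loops only."""
    def mm(W, v, b):
        return np.array([sum(W[i][j] * v[j] for j in range(len(v))) + b[i]
                         for i in range(len(b))])

    def relu(v):
        return np.array([max(x, 0.0) for x in v])

    def sig(v):
        return np.array([1.0 / (1.0 + math.exp(-x)) for x in np.atleast_1d(v)])

    g1 = relu(mm(params.w12, relu(mm(params.w11, x1, params.b11)), params.b12))
    g2 = relu(mm(params.w22, relu(mm(params.w21, x2, params.b21)), params.b22))
    G = np.concatenate([sig(g2) * g1, sig(g1) * g2])
    return sig(mm(params.w32, relu(mm(params.w31, G, params.b31)), params.b32))[0]


def small_config(**kw):
    base = dict(d1=3, d2=4, h_enc=5, d_code=3, h_dec=4, dropout_rate=0.0)
    base.update(kw)
    return net.NetworkConfig(**base)


def randomized_params(cfg, seed, bias_scale=0.3):
    """Glorot weights plus non-zero biases (keeps ReLU kinks off exact zero)."""
    params = net.glorot_init(cfg, seed)
    rng = np.random.default_rng(seed + 1000)
    for name, arr in params.items():
        if name.startswith("b"):
            arr += rng.standard_normal(arr.shape) * bias_scale
    return params


class TestGlorotInit:
    def test_bounds_per_matrix(self):
        cfg = small_config(h_enc=50, d_code=10, h_dec=20)
        p = net.glorot_init(cfg, 0)
        for wname, (fi, fo) in net._WEIGHT_FANS.items():
            bound = np.sqrt(6.0 / (getattr(cfg, fi) + getattr(cfg, fo)))
            w = getattr(p, wname)
            assert np.abs(w).max() <= bound
            assert getattr(p, "b" + wname[1:]).max() == 0.0

    def test_sample_mean_near_zero(self):
        cfg = net.NetworkConfig(d1=100, d2=3, h_enc=20, d_code=3, h_dec=3)
        w = net.glorot_init(cfg, 3).w11  # 2000 entries
        bound = np.sqrt(6.0 / 120)
        se = bound / np.sqrt(3) / np.sqrt(w.size)  # uniform sd = bound/sqrt(3)
        assert abs(w.mean()) < 3 * se

    def test_deterministic(self):
        cfg = small_config()
        a, b = net.glorot_init(cfg, 7), net.glorot_init(cfg, 7)
        for (_, x), (_, y) in zip(a.items(), b.items()):
            np.testing.assert_array_equal(x, y)


class TestForward:
    def test_zero_params_give_half(self):
        cfg = small_config()
        p = net.glorot_init(cfg, 0)
        for name, arr in p.items():
            arr[...] = 0.0
        assert net.forward(p, np.ones(3), np.ones(4)) == pytest.approx(0.5)

    def test_dead_first_branch_halves_gate(self):
        # g1'=0 -> first half of G is 0 and second half is 0.5*g2'
        cfg = small_config()
        p = randomized_params(cfg, 1)
        p.w11[...] = 0.0
        p.b11[...] = -1.0  # encoder-1 hidden all inactive -> g1' = relu(b12)
        p.b12[...] = -1.0  # g1' = 0 exactly
        x1, x2 = np.ones(3), np.ones(4)
        c = net._forward_cache(p, x1[None], x2[None])
        np.testing.assert_allclose(c["G"][0, :3], 0.0)
        np.testing.assert_allclose(c["G"][0, 3:], 0.5 * c["g2"][0])

    def test_matches_reference_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            cfg = small_config()
            p = randomized_params(cfg, trial)
            x1, x2 = rng.standard_normal(3), rng.standard_normal(4)
            assert net.forward(p, x1, x2) == pytest.approx(
                reference_forward(p, x1, x2), abs=1e-12)

    def test_batch_equals_per_row(self):
        cfg = small_config()
        p = randomized_params(cfg, 5)
        rng = np.random.default_rng(5)
        X1, X2 = rng.random((8, 3)), rng.random((8, 4))
        batch = net.forward(p, X1, X2)
        single = [net.forward(p, X1[i], X2[i]) for i in range(8)]
        np.testing.assert_allclose(batch, single, atol=1e-14)
        assert np.all((batch > 0) & (batch < 1))

    def test_shape_mismatch_errors(self):
        p = net.glorot_init(small_config(), 0)
        with pytest.raises(ValueError, match="dims"):
            net.forward(p, np.ones(5), np.ones(4))

    def test_branch_swap_symmetry(self):
        """Swapping inputs, encoder blocks and the gate halves leaves y' fixed."""
        cfg = net.NetworkConfig(d1=3, d2=3, h_enc=4, d_code=2, h_dec=3,
                                dropout_rate=0.0)
        p = randomized_params(cfg, 9)
        q = p.copy()
        q.w11, q.b11, q.w12, q.b12, q.w21, q.b21, q.w22, q.b22 = \
            p.w21, p.b21, p.w22, p.b22, p.w11, p.b11, p.w12, p.b12
        # swap the two halves of the decoder input weights consistently
        q.w31 = np.concatenate([p.w31[:, 2:], p.w31[:, :2]], axis=1)
        rng = np.random.default_rng(9)
        x1, x2 = rng.random(3), rng.random(3)
        assert net.forward(p, x1, x2) == pytest.approx(
            net.forward(q, x2, x1), abs=1e-12)


class TestFocalLoss:
    def test_closed_forms(self):
        assert net.focal_loss(1, 0.5, 0.2, 2) == pytest.approx(
            0.2 * 0.25 * math.log(2), abs=1e-9)
        assert net.focal_loss(0, 0.5, 0.2, 2) == pytest.approx(
            0.8 * 0.25 * math.log(2), abs=1e-9)

    def test_vanishes_at_confident_correct(self):
        assert net.focal_loss(1, 1 - 1e-9) < 1e-6
        assert net.focal_loss(0, 1e-9) < 1e-6

    def test_gamma0_alpha_half_is_half_crossentropy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        ce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert net.focal_loss(y, p, alpha=0.5, gamma=0.0) == pytest.approx(ce / 2)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        p = rng.uniform(0, 1, 100)
        assert net.focal_loss(y, p) >= 0.0


class TestGradient:
    def finite_diff(self, params, X1, X2, y, masks=None, h=1e-5):
        grads = {}
        for name, arr in params.items():
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = net.focal_loss(y, net._forward_cache(params, X1, X2, masks)["p"])
                arr[idx] = orig - h
                lm = net.focal_loss(y, net._forward_cache(params, X1, X2, masks)["p"])
                arr[idx] = orig
                g[idx] = (lp - lm) / (2 * h)
            grads[name] = g
        return grads

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for trial in range(5):
            cfg = small_config(d1=3, d2=3, h_enc=2, d_code=2, h_dec=2)
            p = randomized_params(cfg, trial)
            X1, X2 = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
            y = rng.integers(0, 2, 4).astype(float)
            _, g = net.loss_gradient(p, X1, X2, y)
            fd = self.finite_diff(p, X1, X2, y)
            for name, arr in g.items():
                rel = np.abs(arr - fd[name]) / np.maximum(
                    np.maximum(np.abs(arr), np.abs(fd[name])), 1e-8)
                worst = max(worst, rel.max())
        assert worst <= 1e-4

    def test_matches_finite_differences_with_dropout_masks(self):
        rng = np.random.default_rng(3)
        cfg = small_config(d1=3, d2=3, h_enc=3, d_code=2, h_dec=3, dropout_rate=0.2)
        p = randomized_params(cfg, 11)
        n = 5
        X1, X2 = rng.standard_normal((n, 3)), rng.standard_normal((n, 3))
        y = rng.integers(0, 2, n).astype(float)
        shapes = [(n, 3), (n, 2), (n, 3), (n, 2), (n, 3)]
        masks = net._dropout_masks(np.random.default_rng(4), shapes, 0.2)
        _, g = net.loss_gradient(p, X1, X2, y, masks=masks)
        fd = self.finite_diff(p, X1, X2, y, masks=masks)
        for name, arr in g.items():
            rel = np.abs(arr - fd[name]) / np.maximum(
                np.maximum(np.abs(arr), np.abs(fd[name])), 1e-8)
            assert rel.max() <= 1e-4, name

    def test_dead_branch_has_zero_first_layer_gradient(self):
        cfg = small_config()
        p = randomized_params(cfg, 2)
        rng = np.random.default_rng(2)
        X1 = np.zeros((6, 3))
        p.b11[...] = -1.0  # branch-1 hidden layer fully inactive
        X2 = rng.random((6, 4))
        y = rng.integers(0, 2, 6).astype(float)
        _, g = net.loss_gradient(p, X1, X2, y)
        np.testing.assert_allclose(g.w11, 0.0)
        np.testing.assert_allclose(g.b11, 0.0)


def _toy_featureset(expr, d1, d2):
    genes = expr.gene_ids
    scores = [FeatureScore(g, 1.0, 0.01, 0.01) for g in genes[: d1 + d2]]
    group_of = {g: (1 if i < d1 else 2) for i, g in enumerate(genes[: d1 + d2])}
    return FeatureSet(scores, group_of)


@pytest.fixture(scope="module")
def separable():
    cohort = simulate_cohort(SimulationConfig(
        n_samples=120, n_genes=40, n_informative_g1=10, n_informative_g2=15,
        effect_size=3.0, seed=7))
    expr = normalize_expression(cohort.expr)
    labels = (cohort.truth["subgroup"] == 2).astype(int)
    fs = FeatureSet(
        [FeatureScore(g, 1.0, 0.01, 0.01)
         for g in cohort.truth["module1_genes"] + cohort.truth["module2_genes"]],
        {**{g: 1 for g in cohort.truth["module1_genes"]},
         **{g: 2 for g in cohort.truth["module2_genes"]}},
    )
    return expr, fs, labels


class TestTrain:
    def test_learns_separable_labels(self, separable):
        expr, fs, labels = separable
        cfg = net.NetworkConfig(d1=1, d2=1, epochs=300, seed=0)
        params, hist = net.train(expr, fs, labels, cfg)
        preds = net.classify(net.predict_proba(params, expr, fs))
        assert (preds == labels).mean() >= 0.95

    def test_zero_learning_rate_freezes_params(self, separable):
        expr, fs, labels = separable
        cfg = net.NetworkConfig(d1=1, d2=1, epochs=5, learning_rate=0.0, seed=0,
                                patience=10, dropout_rate=0.0)
        params, hist = net.train(expr, fs, labels, cfg)
        fresh = net.glorot_init(
            net.NetworkConfig(d1=10, d2=15, seed=0),
            seed=_train_init_seed(0))
        np.testing.assert_array_equal(params.w11, fresh.w11)
        assert np.ptp(hist.train_loss) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_history(self, separable):
        expr, fs, labels = separable
        cfg = net.NetworkConfig(d1=1, d2=1, epochs=40, seed=3)
        _, h1 = net.train(expr, fs, labels, cfg)
        _, h2 = net.train(expr, fs, labels, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_single_class_rejected(self, separable):
        expr, fs, _ = separable
        cfg = net.NetworkConfig(d1=1, d2=1, epochs=5)
        with pytest.raises(ValueError, match="class"):
            net.train(expr, fs, np.ones(expr.n_samples, dtype=int), cfg)


def _train_init_seed(seed):
    ss = np.random.SeedSequence(seed)
    return int(ss.spawn(3)[0].generate_state(1)[0] % (2**31 - 1))


class TestPredictClassify:
    def test_predict_matches_forward(self, separable):
        expr, fs, labels = separable
        cfg = net.NetworkConfig(d1=1, d2=1, epochs=10, seed=0)
        params, _ = net.train(expr, fs, labels, cfg)
        probs = net.predict_proba(params, expr, fs)
        X1, X2 = net.branch_inputs(expr, fs)
        for i in (0, 5, 17):
            assert probs[i] == pytest.approx(net.forward(params, X1[i], X2[i]))
        assert np.all((probs > 0) & (probs < 1))

    def test_classify_threshold_convention(self):
        probs = np.array([0.2, 0.5, 0.9])
        np.testing.assert_array_equal(net.classify(probs), [0, 1, 1])
        np.testing.assert_array_equal(net.classify(probs, threshold=0.91), [0, 0, 0])


class TestSaveLoad:
    def test_round_trip_bit_identical(self, tmp_path, separable):
        expr, fs, labels = separable
        cfg = net.NetworkConfig(d1=10, d2=15, epochs=5, seed=0)
        params = net.glorot_init(cfg, 42)
        path = tmp_path / "model.json"
        net.save_params(path, params, cfg, feature_set=fs)
        loaded, cfg2, feats = net.load_params(path)
        for (_, a), (_, b) in zip(params.items(), loaded.items()):
            np.testing.assert_array_equal(a, b)
        assert cfg2 == cfg
        assert feats["group_of"] == fs.group_of

    def test_truncated_file_errors(self, tmp_path):
        path = tmp_path / "model.json"
        cfg = net.NetworkConfig(d1=2, d2=2)
        net.save_params(path, net.glorot_init(cfg, 0), cfg)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ValueError, match="corrupt"):
            net.load_params(path)

    def test_shape_conflict_errors(self, tmp_path):
        import json
        path = tmp_path / "model.json"
        cfg = net.NetworkConfig(d1=2, d2=2)
        net.save_params(path, net.glorot_init(cfg, 0), cfg)
        doc = json.loads(path.read_text())
        doc["config"]["d1"] = 5
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="shape"):
            net.load_params(path)

    def test_version_mismatch_errors(self, tmp_path):
        import json
        path = tmp_path / "model.json"
        cfg = net.NetworkConfig(d1=2, d2=2)
        net.save_params(path, net.glorot_init(cfg, 0), cfg)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            net.load_params(path)
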