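"""Stacked denoising autoencoder: building blocks, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonodae.errors import DivergenceError, InvalidLabelError, ShapeError
from sonodae.sdae import (
    CorruptionSpec,
    DAELayer,
    TrainConfig,
    corrupt,
    dae_gradients,
    decode,
    encode,
    finetune,
    load_model,
    pretrain_layer,
    pretrain_stack,
    reconstruction_loss,
    save_model,
    sigmoid,
    train_classifier,
    _finetune_loss_and_grads,
)


def random_layer(n_vis, n_hid, rng, with_decoder=True):
    return DAELayer(
        W=rng.normal(0, 0.5, (n_hid, n_vis)),
        b=rng.normal(0, 0.1, n_hid),
        b_prime=rng.normal(0, 0.1, n_vis) if with_decoder else None,
    )


class TestSigmoid:
    def test_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(2.0) == pytest.approx(0.8807970779778823, abs=1e-15)

    @given(st.floats(-1e3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_stability(self, t):
        assert sigmoid(t) + sigmoid(-t) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= sigmoid(t) <= 1.0


class TestCorrupt:
    def test_masking_extremes(self):
        rng = np.random.default_rng(0)
        x = np.ones(50)
        assert np.array_equal(corrupt(x, CorruptionSpec("masking", 0.0), rng), x)
        assert np.all(corrupt(x, CorruptionSpec("masking", 1.0), rng) == 0)

    def test_masking_fraction_concentrates(self):
        rng = np.random.default_rng(0)
        x = np.ones(10_000)
        frac = 1.0 - corrupt(x, CorruptionSpec("masking", 0.3), rng).mean()
        assert 0.28 <= frac <= 0.32

    def test_gaussian_moments(self):
        rng = np.random.default_rng(0)
        x = np.zeros(50_000)
        out = corrupt(x, CorruptionSpec("gaussian", 0.2), rng)
        assert abs(out.mean()) < 0.01
        assert out.std() == pytest.approx(0.2, rel=0.05)

    def test_determinism(self):
        x = np.linspace(0, 1, 64)
        a = corrupt(x, CorruptionSpec("masking", 0.5), np.random.default_rng(7))
        b = corrupt(x, CorruptionSpec("masking", 0.5), np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestEncodeDecode:
    def test_zero_weights_give_half(self):
        layer = DAELayer(W=np.zeros((3, 4)), b=np.zeros(3), b_prime=np.zeros(4))
        assert np.allclose(encode(layer, np.array([1.0, -2.0, 0.3, 9.0])), 0.5)
        assert np.allclose(decode(layer, np.array([0.1, 0.9, 0.5])), 0.5)

    def test_hand_computed(self):
        layer = DAELayer(W=np.array([[1.0, 2.0]]), b=np.array([-1.0]), b_prime=np.zeros(2))
        assert encode(layer, np.array([1.0, 1.0]))[0] == pytest.approx(0.8807970779778823)
        out = decode(layer, np.array([1.0]))
        assert out == pytest.approx([sigmoid(1.0), sigmoid(2.0)])

    def test_shape_errors(self):
        layer = DAELayer(W=np.zeros((3, 4)), b=np.zeros(3), b_prime=np.zeros(4))
        with pytest.raises(ShapeError):
            encode(layer, np.zeros(5))
        with pytest.raises(ShapeError):
            decode(layer, np.zeros(4))


def finite_difference_layer_grads(layer, x_clean, x_tilde, h=1e-5):
    """Central finite differences of the batch reconstruction loss."""
    grads = []
    for arr in (layer.W, layer.b, layer.b_prime):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp = reconstruction_loss(layer, x_clean, x_tilde)
            arr[idx] = orig - h
            lm = reconstruction_loss(layer, x_clean, x_tilde)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads.append(g)
    return grads


def max_rel_error(analytic, numeric):
    denom = np.maximum(np.abs(analytic) + np.abs(numeric), 1e-8)
    return float(np.max(np.abs(analytic - numeric) / denom))


class TestDAEGradients:
    def test_zero_at_perfect_reconstruction(self):
        # a 1x1 layer pinned so that decode(encode(x)) == x exactly
        layer = DAELayer(W=np.array([[0.0]]), b=np.array([0.0]), b_prime=np.array([0.0]))
        x = np.array([[0.5]])
        gW, gb, gbp = dae_gradients(layer, x, x)
        assert np.allclose(gW, 0) and np.allclose(gb, 0) and np.allclose(gbp, 0)

    def test_scalar_case_matches_finite_differences(self):
        layer = DAELayer(W=np.array([[0.1]]), b=np.array([0.1]), b_prime=np.array([0.1]))
        x = np.array([[0.5]])
        gW, gb, gbp = dae_gradients(layer, x, x)
        fW, fb, fbp = finite_difference_layer_grads(layer, x, x)
        assert max_rel_error(gW, fW) < 1e-5
        assert max_rel_error(gb, fb) < 1e-5
        assert max_rel_error(gbp, fbp) < 1e-5

    @pytest.mark.parametrize("seed", range(5))
    def test_random_layers_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_layer(3, 5, rng)
        x = rng.uniform(0, 1, (4, 3))
        xt = corrupt(x, CorruptionSpec("masking", 0.3), rng)
        analytic = dae_gradients(layer, x, xt)
        numeric = finite_difference_layer_grads(layer, x, xt)
        for a, n in zip(analytic, numeric):
            assert max_rel_error(a, n) < 1e-5


class TestPretrain:
    def test_zero_epochs_returns_seeded_init(self):
        data = np.random.default_rng(0).uniform(0, 1, (10, 6))
        cfg = TrainConfig(hidden_sizes=(4,), epochs_pretrain=0, seed=42)
        layer, trace = pretrain_layer(data, 4, cfg, np.random.default_rng(42))
        ref_rng = np.random.default_rng(42)
        r = np.sqrt(6.0 / (6 + 4))
        assert np.array_equal(layer.W, ref_rng.uniform(-r, r, (4, 6)))
        assert trace == []

    def test_descent_on_repeated_pattern(self):
        pattern = np.tile(np.linspace(0.1, 0.9, 8), (50, 1))
        cfg = TrainConfig(
            hidden_sizes=(4,), alpha=0.5, epochs_pretrain=200,
            corruption=CorruptionSpec("masking", 0.0), seed=0,
        )
        _, trace = pretrain_layer(pattern, 4, cfg, np.random.default_rng(0))
        assert trace[-1] < trace[0]
        # full-batch descent with zero corruption: monotone after burn-in
        tail = np.array(trace[len(trace) // 10 :])
        assert np.all(np.diff(tail) <= 1e-12)

    def test_bit_identical_reruns(self):
        data = np.random.default_rng(3).uniform(0, 1, (20, 10))
        cfg = TrainConfig(hidden_sizes=(5,), epochs_pretrain=50, seed=9)
        l1, _ = pretrain_layer(data, 5, cfg, np.random.default_rng(9))
        l2, _ = pretrain_layer(data, 5, cfg, np.random.default_rng(9))
        assert np.array_equal(l1.W, l2.W)
        assert np.array_equal(l1.b, l2.b)
        assert np.array_equal(l1.b_prime, l2.b_prime)

    def test_divergence_guard_reports_epoch(self):
        # the squared-error loss through a saturating sigmoid is bounded, so a
        # non-finite loss can only come from non-finite state; the guard must
        # catch it and name the epoch
        data = np.random.default_rng(0).uniform(0, 1, (5, 4))
        data[0, 0] = np.nan
        cfg = TrainConfig(hidden_sizes=(3,), epochs_pretrain=50, seed=0)
        with pytest.raises(DivergenceError) as exc:
            pretrain_layer(data, 3, cfg, np.random.default_rng(0))
        assert exc.value.epoch == 0


class TestPretrainStack:
    def test_structure_and_chaining(self):
        data = np.random.default_rng(0).uniform(0, 1, (12, 20))
        model, traces = pretrain_stack(data, TrainConfig(hidden_sizes=(8, 3), epochs_pretrain=5, seed=0))
        assert [l.n_hidden for l in model.layers] == [8, 3]
        assert model.layers[1].n_visible == 8
        assert model.features(data).shape == (12, 3)
        assert all(l.b_prime is None for l in model.layers)
        assert len(traces) == 2

    def test_layer2_trains_on_layer1_clean_encodings(self):
        data = np.random.default_rng(1).uniform(0, 1, (10, 12))
        cfg = TrainConfig(hidden_sizes=(6, 2), epochs_pretrain=20, seed=5)
        model, _ = pretrain_stack(data, cfg)
        # reproduce layer 2 by hand from the same seeded stream
        rng = np.random.default_rng(5)
        l1, _ = pretrain_layer(data, 6, cfg, rng)
        z1 = encode(l1, data)
        l2, _ = pretrain_layer(z1, 2, cfg, rng)
        assert np.array_equal(model.layers[1].W, l2.W)

    def test_no_corruption_single_layer_is_plain_autoencoder(self):
        # masking level 0 makes corrupt() the identity, so the parameter
        # trajectory equals a plain autoencoder's on the same stream
        data = np.random.default_rng(2).uniform(0, 1, (8, 6))
        cfg = TrainConfig(
            hidden_sizes=(4,), epochs_pretrain=30,
            corruption=CorruptionSpec("masking", 0.0), seed=1,
        )
        model, _ = pretrain_stack(data, cfg)
        rng = np.random.default_rng(1)
        from sonodae.sdae import init_layer

        layer = init_layer(6, 4, rng)
        for _ in range(30):
            gW, gb, gbp = dae_gradients(layer, data, data)
            layer.W -= cfg.alpha * gW
            layer.b -= cfg.alpha * gb
            layer.b_prime -= cfg.alpha * gbp
        assert np.allclose(model.layers[0].W, layer.W)


def finite_difference_network_grads(model, data, labels, loss_kind, h=1e-5):
    def loss_of():
        return _finetune_loss_and_grads(model, data, labels, loss_kind)[0]

    out = []
    for layer in model.layers:
        for arr in (layer.W, layer.b):
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss_of()
                arr[idx] = orig - h
                lm = loss_of()
                arr[idx] = orig
                g[idx] = (lp - lm) / (2 * h)
            out.append(g)
    gV = np.zeros_like(model.V)
    for i in range(model.V.size):
        orig = model.V[i]
        model.V[i] = orig + h
        lp = loss_of()
        model.V[i] = orig - h
        lm = loss_of()
        model.V[i] = orig
        gV[i] = (lp - lm) / (2 * h)
    orig = model.c
    model.c = orig + h
    lp = loss_of()
    model.c = orig - h
    lm = loss_of()
    model.c = orig
    return out, gV, (lp - lm) / (2 * h)


class TestFinetune:
    @pytest.mark.parametrize("loss_kind", ["cross_entropy", "squared_error"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_network_gradient_matches_finite_differences(self, loss_kind, seed):
        rng = np.random.default_rng(seed)
        from sonodae.sdae import SDAEClassifier

        model = SDAEClassifier(
            layers=[random_layer(6, 4, rng, with_decoder=False), random_layer(4, 2, rng, with_decoder=False)],
            V=rng.normal(0, 0.5, 2),
            c=0.3,
        )
        data = rng.uniform(0, 1, (5, 6))
        labels = rng.integers(0, 2, 5).astype(float)
        _, layer_grads, gV, gc = _finetune_loss_and_grads(model, data, labels, loss_kind)
        fd_layers, fd_V, fd_c = finite_difference_network_grads(model, data, labels, loss_kind)
        flat_analytic = [g for pair in layer_grads for g in pair]
        for a, n in zip(flat_analytic, fd_layers):
            assert max_rel_error(a, n) < 1e-5
        assert max_rel_error(gV, fd_V) < 1e-5
        assert max_rel_error(np.array([gc]), np.array([fd_c])) < 1e-5

    def test_zero_epochs_predicts_half(self):
        data = np.random.default_rng(0).uniform(0, 1, (6, 8))
        model, _ = pretrain_stack(data, TrainConfig(hidden_sizes=(4,), epochs_pretrain=5, seed=0))
        finetune(model, data, np.zeros(6), TrainConfig(hidden_sizes=(4,), epochs_finetune=0))
        prob, pred = model.predict(data)
        assert np.all(prob == 0.5)
        assert np.all(pred == 1)  # tie goes to malignant

    def test_separable_toy_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        n = 40
        x = np.vstack([rng.normal(0.25, 0.03, (n, 2)), rng.normal(0.75, 0.03, (n, 2))])
        y = np.repeat([0, 1], n)
        cfg = TrainConfig(hidden_sizes=(4,), alpha=1.0, epochs_pretrain=100, epochs_finetune=2000, seed=0)
        model, _ = train_classifier(x, y, cfg)
        _, pred = model.predict(x)
        assert (pred == y).mean() == 1.0

    def test_invalid_labels_rejected(self):
        data = np.random.default_rng(0).uniform(0, 1, (4, 5))
        model, _ = pretrain_stack(data, TrainConfig(hidden_sizes=(3,), epochs_pretrain=0, seed=0))
        with pytest.raises(InvalidLabelError):
            finetune(model, data, np.array([0, 1, 2, 1]), TrainConfig(hidden_sizes=(3,)))


class TestRestartProtocol:
    def test_unreachable_threshold_escalates_to_no_pretraining(self):
        # impossible plateau criteria force every restart; the last
        # attempt drops pretraining entirely and is returned
        data = np.random.default_rng(0).uniform(0, 1, (12, 6))
        labels = np.random.default_rng(1).integers(0, 2, 12)
        cfg = TrainConfig(
            hidden_sizes=(4,), epochs_pretrain=20, epochs_finetune=5, seed=0,
            max_restarts=4, plateau_loss=-1.0,
        )
        _, traces = train_classifier(data, labels, cfg)
        assert traces["restarts"] == 3
        assert traces["pretrain"] == [[]]  # ep_pt=0 on the final attempt

    def test_satisfied_first_attempt_does_not_restart(self):
        rng = np.random.default_rng(0)
        n = 20
        x = np.vstack([rng.normal(0.2, 0.02, (n, 3)), rng.normal(0.8, 0.02, (n, 3))])
        y = np.repeat([0, 1], n)
        cfg = TrainConfig(
            hidden_sizes=(4,), alpha=1.0, epochs_pretrain=50, epochs_finetune=1500,
            seed=0, max_restarts=4,
        )
        _, traces = train_classifier(x, y, cfg)
        assert traces["restarts"] == 0


class TestModelArchive:
    def test_round_trip_is_lossless(self, tmp_path):
        data = np.random.default_rng(0).uniform(0, 1, (10, 12))
        cfg = TrainConfig(hidden_sizes=(6, 3), epochs_pretrain=10, epochs_finetune=10, seed=2)
        model, _ = train_classifier(data, np.random.default_rng(1).integers(0, 2, 10), cfg)
        path = tmp_path / "model.npz"
        save_model(path, model, cfg)
        loaded, meta = load_model(path)
        assert meta["hidden_sizes"] == [6, 3]
        assert meta["config"]["seed"] == 2
        for a, b in zip(model.layers, loaded.layers):
            assert np.array_equal(a.W, b.W)
            assert np.array_equal(a.b, b.b)
        assert np.array_equal(model.V, loaded.V)
        assert model.c == loaded.c
        x = np.random.default_rng(3).uniform(0, 1, 12)
        assert model.predict_proba(x) == loaded.predict_proba(x)


class TestDeterminism:
    def test_identical_config_bit_identical_models(self):
        data = np.random.default_rng(0).uniform(0, 1, (15, 10))
        labels = np.random.default_rng(1).integers(0, 2, 15)
        cfg = TrainConfig(hidden_sizes=(6, 3), epochs_pretrain=30, epochs_finetune=30, seed=11)
        m1, _ = train_classifier(data, labels, cfg)
        m2, _ = train_classifier(data, labels, cfg)
        for a, b in zip(m1.layers, m2.layers):
            assert np.array_equal(a.W, b.W) and np.array_equal(a.b, b.b)
        assert np.array_equal(m1.V, m2.V) and m1.c == m2.c

    def test_prediction_is_pure(self):
        data = np.random.default_rng(0).uniform(0, 1, (5, 8))
        model, _ = pretrain_stack(data, TrainConfig(hidden_sizes=(4,), epochs_pretrain=5, seed=0))
        p1, _ = model.predict(data)
        p2, _ = model.predict(data)
        assert np.array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))
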