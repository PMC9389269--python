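"""Temporal attention algebra, backbones, and the training loop."""

import numpy as np
import pytest

from stressfuse.errors import DegenerateDataset, InvalidConfiguration
from stressfuse.nn import (
    ArrayDataset,
    BackboneConfig,
    TAMParams,
    TemporalAttention,
    TrainConfig,
    build_image_net,
    build_video_net,
    count_parameters,
    predict_posteriors,
    softmax,
    tam_excite,
    tam_scale,
    tam_squeeze,
    train_modality,
)
from stressfuse.nn.models import parameter_shapes


def dense_tam_oracle(u, W1, W2):
    """Independent dense computation of squeeze-excite-scale."""
    T = u.shape[0]
    z = np.array([u[t].sum() / u[t].size for t in range(T)])
    h = np.maximum(W1 @ z, 0.0)
    S = 1.0 / (1.0 + np.exp(-(W2 @ h)))
    return z, S, np.stack([S[t] * u[t] for t in range(T)])


class TestTAMAlgebra:
    def test_squeeze_of_constant_frames(self):
        u = np.stack([np.full((2, 3, 3), c) for c in (1.0, -2.0, 0.5)])
        assert np.allclose(tam_squeeze(u), [1.0, -2.0, 0.5])

    def test_squeeze_scalar_frames(self):
        u = np.arange(1.0, 5.0).reshape(4, 1, 1, 1)
        assert np.allclose(tam_squeeze(u), [1, 2, 3, 4])

    def test_composition_matches_dense_oracle(self, rng):
        for _ in range(20):
            u = rng.normal(size=(8, 4, 6, 6))
            params = TAMParams.init(8, r=4, seed=int(rng.integers(1 << 30)))
            z = tam_squeeze(u)
            S = tam_excite(z, params)
            out = tam_scale(u, S)
            zb, Sb, ob = dense_tam_oracle(u, params.W1, params.W2)
            assert np.allclose(z, zb, atol=1e-12)
            assert np.allclose(S.S, Sb, atol=1e-12)
            assert np.allclose(out, ob, atol=1e-6)

    def test_zero_weights_give_half_gates(self, rng):
        u = np.arange(1.0, 5.0).reshape(4, 1, 1, 1)
        params = TAMParams(W1=np.zeros((1, 4)), W2=np.zeros((4, 1)))
        S = tam_excite(tam_squeeze(u), params)
        assert np.all(S.S == 0.5)
        out = tam_scale(u, S)
        assert np.allclose(out.ravel(), [0.5, 1.0, 1.5, 2.0])

    def test_gates_strictly_inside_unit_interval(self, rng):
        for _ in range(10):
            z = rng.normal(scale=10, size=6)
            params = TAMParams.init(6, r=2, seed=int(rng.integers(1 << 30)))
            S = tam_excite(z, params).S
            assert np.all(S > 0.0) and np.all(S < 1.0)

    def test_scale_is_contraction(self, rng):
        u = rng.normal(size=(5, 2, 4, 4))
        params = TAMParams.init(5, seed=0)
        out = tam_scale(u, tam_excite(tam_squeeze(u), params))
        assert np.all(np.abs(out) <= np.abs(u) + 1e-15)

    def test_dimension_mismatch_rejected(self):
        params = TAMParams.init(8, seed=0)
        with pytest.raises(InvalidConfiguration):
            tam_excite(np.zeros(5), params)
        with pytest.raises(InvalidConfiguration):
            tam_scale(np.zeros((4, 1, 2, 2)), np.zeros(8))

    def test_batched_layer_matches_functional_path(self, rng):
        layer = TemporalAttention(T=6, r=3, seed=2, name="tam")
        x = rng.normal(size=(3, 4, 6, 5, 5))  # (N, C, T, H, W)
        out = layer.forward(x)
        params = TAMParams(W1=layer.W1.value, W2=layer.W2.value)
        for n in range(3):
            u = x[n].transpose(1, 0, 2, 3)  # (T, C, H, W)
            expected = tam_scale(u, tam_excite(tam_squeeze(u), params))
            assert np.allclose(out[n].transpose(1, 0, 2, 3), expected, atol=1e-12)


class TestBackbones:
    def test_tiny_nets_emit_simplex_posteriors(self, rng):
        cfg = BackboneConfig(seed=0)
        video = build_video_net(cfg)
        image = build_image_net(cfg)
        clip = rng.uniform(size=(2, 3, 64, 32, 32))
        img = rng.uniform(size=(2, 3, 64, 64))
        for model, x in ((video, clip), (image, img)):
            post = softmax(model.forward(x))
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
            assert np.array_equal(model.forward(x), model.forward(x))  # deterministic

    def test_ablation_differs_only_in_tam(self):
        cfg = BackboneConfig(seed=7)
        on = build_video_net(cfg, tam=True)
        off = build_video_net(cfg, tam=False)
        T = cfg.tam_T
        hidden = max(1, round(T / cfg.reduction))
        assert count_parameters(on) - count_parameters(off) == 2 * T * hidden
        shapes_on = parameter_shapes(on)
        shapes_off = parameter_shapes(off)
        assert set(shapes_on) - set(shapes_off) == {"tam.W1", "tam.W2"}
        # shared layers are value-identical at initialization
        state_on = on.state_dict()
        state_off = off.state_dict()
        for name in shapes_off:
            assert np.array_equal(state_on[name], state_off[name])

    def test_residual_identity_when_branch_zeroed(self, rng):
        model = build_image_net(BackboneConfig(seed=1))
        block = model.layers[4]  # first residual stage
        for p in block.parameters():
            p.value[...] = 0.0
        x = np.abs(rng.normal(size=(1, 16, 16, 16)))  # nonnegative input
        assert np.allclose(block.forward(x), x)

    def test_full_image_net_matches_published_bottleneck_plan(self):
        from stressfuse.nn.models import RESNET50_STAGES, _Bottleneck

        model = build_image_net(BackboneConfig(variant="full", seed=0))
        bottlenecks = [l for l in model.layers if isinstance(l, _Bottleneck)]
        assert len(bottlenecks) == sum(blocks for _, _, blocks, _ in RESNET50_STAGES) == 16

    def test_full_video_net_has_nine_inception_modules(self):
        from stressfuse.nn.models import _Inception3d

        model = build_video_net(BackboneConfig(variant="full", seed=0))
        modules = [l for l in model.layers if isinstance(l, _Inception3d)]
        assert len(modules) == 9
        assert modules[-1].c_out == 1024

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfiguration):
            BackboneConfig(variant="huge")
        with pytest.raises(InvalidConfiguration):
            BackboneConfig(clip_len=10, t_stride=4)


def blob_dataset(n=40, n_classes=2, seed=0):
    """Linearly separable images: each class lights a distinct region."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    regions = [(slice(40, 120), slice(40, 140)), (slice(120, 200), slice(160, 280))]
    for i in range(n):
        img = rng.uniform(0, 0.2, size=(230, 307)).astype(np.float32)
        cls = i % n_classes
        img[regions[cls]] += 0.7
        X.append(np.clip(img, 0, 1))
        y.append(cls)
    return X, np.asarray(y)


def simple_transforms():
    from stressfuse.pipeline import _image_eval_transform, _image_train_transform

    return _image_train_transform, _image_eval_transform


class TestTraining:
    def test_separable_blobs_reach_high_validation_accuracy(self):
        X, y = blob_dataset()
        tr, ev = simple_transforms()
        ds = ArrayDataset(X, y, tr, ev)
        model = build_image_net(BackboneConfig(seed=0))
        model, hist = train_modality(
            model, ds, TrainConfig(lr=3e-3, batch_size=16, epochs=20, seed=0)
        )
        assert max(h["val_accuracy"] for h in hist) >= 0.95

    def test_same_seed_reproduces_loss_curve(self):
        X, y = blob_dataset(n=16)
        tr, ev = simple_transforms()
        curves = []
        for _ in range(2):
            ds = ArrayDataset(X, y, tr, ev)
            model = build_image_net(BackboneConfig(seed=3))
            _, hist = train_modality(
                model, ds, TrainConfig(lr=1e-3, batch_size=8, epochs=3, seed=3)
            )
            curves.append([h["train_loss"] for h in hist])
        assert curves[0] == curves[1]

    def test_zero_learning_rate_keeps_weights(self):
        X, y = blob_dataset(n=16)
        tr, ev = simple_transforms()
        ds = ArrayDataset(X, y, tr, ev)
        model = build_image_net(BackboneConfig(seed=2))
        before = model.state_dict()
        model, _ = train_modality(model, ds, TrainConfig(lr=0.0, batch_size=8, epochs=2, seed=0))
        after = model.state_dict()
        for name in before:
            assert np.array_equal(before[name], after[name])

    def test_single_class_dataset_rejected(self):
        X, y = blob_dataset(n=10, n_classes=1)
        ds = ArrayDataset(X, y)
        model = build_image_net(BackboneConfig(seed=0))
        with pytest.raises(DegenerateDataset):
            train_modality(model, ds, TrainConfig(epochs=1))


class TestGradients:
    """Backpropagation of every trainable layer against central differences."""

    @pytest.mark.parametrize(
        "layer_factory,x_shape",
        [
            (lambda: __import__("stressfuse.nn.core", fromlist=["Dense"]).Dense(5, 4, 0, "d"), (3, 5)),
            (lambda: __import__("stressfuse.nn.core", fromlist=["Conv2d"]).Conv2d(2, 3, 3, 0, "c"), (2, 2, 6, 6)),
            (lambda: __import__("stressfuse.nn.core", fromlist=["Conv3d"]).Conv3d(2, 3, 3, 0, "c3"), (1, 2, 4, 5, 5)),
            (lambda: TemporalAttention(4, 2, 0, "tam"), (2, 3, 4, 3, 3)),
        ],
        ids=["dense", "conv2d", "conv3d", "tam"],
    )
    def test_parameter_gradients_match_central_differences(self, layer_factory, x_shape, rng):
        layer = layer_factory()
        x = rng.normal(size=x_shape)
        dout = rng.normal(size=layer.forward(x, train=True).shape)
        for p in layer.parameters():
            p.grad[...] = 0.0
        layer.backward(dout)
        eps = 1e-6
        for p in layer.parameters():
            flat_indices = list(np.ndindex(*p.value.shape))
            for idx in flat_indices[:: max(1, len(flat_indices) // 10)]:
                orig = p.value[idx]
                p.value[idx] = orig + eps
                up = np.sum(layer.forward(x) * dout)
                p.value[idx] = orig - eps
                down = np.sum(layer.forward(x) * dout)
                p.value[idx] = orig
                assert (up - down) / (2 * eps) == pytest.approx(p.grad[idx], abs=1e-6)


class TestPosteriors:
    def test_simplex_output_and_symmetry(self, rng):
        model = build_image_net(BackboneConfig(seed=0))
        x = rng.uniform(size=(3, 64, 64))
        post = predict_posteriors(model, x)
        assert post.shape == (3,)
        assert post.sum() == pytest.approx(1.0, abs=1e-6)
        # equal logits: zero the head so every class scores the same
        head = model.layers[-1]
        head.W.value[...] = 0.0
        head.b.value[...] = 0.0
        assert np.allclose(predict_posteriors(model, x), 1 / 3)

    def test_dominant_logit_saturates(self):
        assert np.allclose(softmax(np.array([[50.0, -50.0, -50.0]]))[0, 0], 1.0)
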