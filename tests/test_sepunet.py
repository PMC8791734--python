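"""SepUNet contracts: shapes, determinism, separable parameter arithmetic,
rotation-ensemble algebra with mock predictors."""

import numpy as np
import pytest

from osteoseg.sepunet import (
    EnsembleWeights,
    SepUNetConfig,
    TrainSchedule,
    build_model,
    load_model,
    predict,
    rotation_ensemble,
    save_model,
    train_segmentation,
)


TINY = SepUNetConfig(base_channels=2)


class TestModel:
    def test_shape_contract_64(self):
        model = build_model(TINY, seed=0)
        out = predict(model, np.random.default_rng(0).integers(0, 255, (64, 64)))
        assert out.values.shape == (64, 64)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_non_multiple_of_16_padded_and_unpadded(self):
        model = build_model(TINY, seed=0)
        img = np.random.default_rng(1).integers(0, 255, (70, 50))
        out = predict(model, img)
        assert out.values.shape == (70, 50)

    def test_separable_parameter_count_arithmetic(self):
        # depthwise 3x3 on 8 channels + pointwise 8->16: 8*9 + 8*16 = 200
        # versus a plain 3x3 conv 8->16: 8*16*9 = 1152
        rng = np.random.default_rng(0)
        from osteoseg import nn

        dw = nn.DepthwiseConv2d(8, 3, rng)
        pw = nn.Conv2d(8, 16, 1, rng)
        sep_weights = dw.w.data.size + pw.w.data.size
        plain = nn.Conv2d(8, 16, 3, rng)
        assert sep_weights == 200
        assert plain.w.data.size == 1152

    def test_same_seed_identical_parameters(self):
        a = build_model(TINY, seed=9)
        b = build_model(TINY, seed=9)
        assert all(
            np.array_equal(x.data, y.data)
            for x, y in zip(a.parameters(), b.parameters())
        )
        c = build_model(TINY, seed=10)
        assert any(
            not np.array_equal(x.data, y.data)
            for x, y in zip(a.parameters(), c.parameters())
        )

    def test_inference_reproducible(self):
        model = build_model(TINY, seed=4)
        img = np.random.default_rng(2).integers(0, 255, (32, 32))
        p1 = predict(model, img).values
        p2 = predict(model, img).values
        assert np.array_equal(p1, p2)

    def test_zeroed_head_gives_half_everywhere(self):
        model = build_model(TINY, seed=0)
        model.head.w.data[...] = 0.0
        model.head.b.data[...] = 0.0
        out = predict(model, np.random.default_rng(3).integers(0, 255, (32, 32)))
        assert np.allclose(out.values, 0.5)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(TINY, seed=6)
        img = np.random.default_rng(4).integers(0, 255, (32, 32))
        before = predict(model, img).values
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        assert np.allclose(predict(clone, img).values, before)


class TestEnsemble:
    def test_weights_validation(self):
        with pytest.raises(ValueError):
            EnsembleWeights(0.5, 0.5, 0.5, 0.5).validate()
        with pytest.raises(ValueError):
            EnsembleWeights(-0.2, 0.4, 0.4, 0.4).validate()
        EnsembleWeights().validate()  # (0.4, 0.2, 0.2, 0.2)

    def test_identity_weights_equal_plain_predict(self):
        model = build_model(TINY, seed=1)
        img = np.random.default_rng(5).integers(0, 255, (32, 32))
        single = predict(model, img).values
        ens = rotation_ensemble(model, img, EnsembleWeights(1.0, 0.0, 0.0, 0.0)).values
        assert np.allclose(ens, single)

    def test_constant_mock_predictor_convexity(self):
        img = np.zeros((16, 16))
        const = lambda im: np.full(im.shape, 0.37)
        out = rotation_ensemble(None, img, predict_fn=const).values
        assert np.allclose(out, 0.37)

    def test_rotation_invariant_mock_equals_single_map(self):
        # a predictor equivariant to rotation: ensemble == its single output
        rng = np.random.default_rng(6)
        base = rng.uniform(size=(16, 16))

        def equivariant(im):
            # infer the rotation applied to the marker image and rotate base
            for k in range(4):
                if im.shape == np.rot90(MARKER, k).shape and np.array_equal(
                    im, np.rot90(MARKER, k)
                ):
                    return np.rot90(base, k)
            raise AssertionError("unexpected input")

        MARKER = rng.integers(0, 255, (16, 16))
        for w in (EnsembleWeights(), EnsembleWeights(0.25, 0.25, 0.25, 0.25)):
            out = rotation_ensemble(None, MARKER, w, predict_fn=equivariant).values
            assert np.allclose(out, base)

    def test_four_distinct_maps_hand_average(self):
        rng = np.random.default_rng(7)
        maps = [rng.uniform(size=(8, 8)) for _ in range(4)]
        img = rng.integers(0, 255, (8, 8))
        calls = []

        def fn(im):
            calls.append(im)
            return maps[len(calls) - 1]

        w = EnsembleWeights(0.4, 0.2, 0.2, 0.2)
        out = rotation_ensemble(None, img, w, predict_fn=fn).values
        want = sum(
            a * np.rot90(m, -k)
            for k, (a, m) in enumerate(zip((0.4, 0.2, 0.2, 0.2), maps))
        )
        assert np.allclose(out, want)

    def test_non_square_image_shape_preserved(self):
        model = build_model(TINY, seed=2)
        img = np.random.default_rng(8).integers(0, 255, (24, 40))
        out = rotation_ensemble(model, img).values
        assert out.shape == (24, 40)


class TestTraining:
    def test_zero_epochs_returns_model_unchanged(self, small_dataset):
        model = build_model(TINY, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        out = train_segmentation(model, small_dataset, schedule=TrainSchedule(epochs=0))
        assert out is model
        assert all(np.array_equal(a, p.data) for a, p in zip(before, model.parameters()))

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation(build_model(TINY, seed=0), [])

    def test_loss_decreases_on_learnable_phantoms(self, small_dataset):
        model = build_model(SepUNetConfig(base_channels=4), seed=1)
        sched = TrainSchedule(epochs=4, batch_size=4, drop_fraction=1.0)
        train_segmentation(model, small_dataset, schedule=sched, seed=2)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_lr_schedule_shape(self):
        s = TrainSchedule(epochs=300)
        assert s.lr_at(0) == pytest.approx(1e-3)
        assert s.lr_at(199) == pytest.approx(1e-3)
        assert s.lr_at(200) == pytest.approx(1e-4)  # drop, cosine starts at peak
        assert s.lr_at(299) == pytest.approx(0.0, abs=1e-9)
        # monotone non-increasing over the tail
        tail = [s.lr_at(e) for e in range(200, 300)]
        assert all(a >= b for a, b in zip(tail, tail[1:]))
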