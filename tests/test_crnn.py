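"""Network architecture, shapes, determinism, gradients, persistence."""

import numpy as np
import pytest

import scratchdetect.crnn as crnn_mod
from scratchdetect.crnn import (
    CRNN,
    ModelSpec,
    WeightState,
    bce_loss,
    build_model,
    load_weights,
    param_count,
    save_weights,
    shape_plan,
)

TINY = ModelSpec(
    input_px=8,
    seq_len=3,
    conv_filters=(2, 2),
    lstm_units=5,
    head_widths=(4, 1),
    dropout=0.0,
    n_dropout_layers=0,
)


class TestShapePlan:
    def test_default_cascade(self):
        plan = dict(shape_plan(ModelSpec()))
        assert plan["input"] == (21, 200, 200, 1)
        assert plan["conv1"] == (200, 200, 32)
        assert plan["pool1"] == (100, 100, 32)
        assert plan["pool2"] == (50, 50, 32)
        assert plan["pool3"] == (25, 25, 32)
        assert plan["flatten"] == (20000,)
        assert plan["lstm1"] == (21, 256)
        assert plan["lstm2"] == (256,)
        assert plan["fc1"] == (128,)
        assert plan["fc5"] == (1,)

    def test_default_param_count_matches_hand_computation(self):
        # conv: (9*1*32+32) + 2*(9*32*32+32)               =     18,816
        # lstm1: 20000*1024 + 256*1024 + 1024              = 20,743,168
        # lstm2: 256*1024 + 256*1024 + 1024                =    525,312
        # head: 256*128+128, 128*128+128, 128*32+32, 32*8+8, 8*1+1
        assert param_count(ModelSpec()) == 21_341_105

    def test_param_count_matches_allocated_arrays(self):
        model = build_model(TINY, seed=0)
        assert model.n_params() == param_count(TINY)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(head_widths=(128, 2)),
            dict(lstm_activation="gelu"),
            dict(input_px=100),  # not divisible by 8
            dict(dropout=1.5),
            dict(conv_kernel=4),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelSpec(**bad).validate()


class TestForward:
    def test_same_seed_gives_identical_weights(self):
        a = build_model(TINY, seed=11)
        b = build_model(TINY, seed=11)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_output_in_open_unit_interval(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((4, 3, 8, 8)).astype(np.float32)
        p = model.forward(x)
        assert ((p > 0) & (p < 1)).all() and p.shape == (4,)

    def test_inference_is_deterministic(self, rng):
        model = build_model(ModelSpec(input_px=8, seq_len=3, conv_filters=(2,),
                                      lstm_units=4, head_widths=(4, 1)), seed=0)
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_batch_order_preserving(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((5, 3, 8, 8)).astype(np.float32)
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(
            model.forward(x)[perm], model.forward(x[perm]), rtol=1e-5
        )

    def test_wrong_input_size_errors(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model.forward(np.zeros((1, 3, 9, 9), np.float32))

    def test_encoder_weights_shared_across_time(self, rng):
        """Per-frame encoder outputs commute with any frame permutation."""
        model = build_model(TINY, seed=0)
        frames = rng.random((6, 8, 8)).astype(np.float32)
        feats = model.encode_frames(frames).copy()
        perm = np.array([5, 2, 0, 1, 4, 3])
        feats_perm = model.encode_frames(frames[perm]).copy()
        np.testing.assert_array_equal(feats_perm, feats[perm])

    def test_features_match_full_forward(self, rng):
        """The sliding-window inference path equals the segment path."""
        model = build_model(TINY, seed=1)
        x = rng.random((3, 3, 8, 8)).astype(np.float32)
        p_full = model.forward(x)
        feats = np.stack(
            [model.encode_frames(x[i]).copy() for i in range(3)]
        )
        p_feat = model.forward_from_features(feats)
        np.testing.assert_allclose(p_full, p_feat, rtol=1e-5)


class TestGradients:
    def test_backward_matches_numerical_gradient(self, rng, monkeypatch):
        """Hand-derived backprop agrees with central differences (float64)."""
        monkeypatch.setattr(crnn_mod, "_F32", np.float64)
        for activation in ("tanh", "relu"):
            spec = ModelSpec(
                input_px=8, seq_len=3, conv_filters=(2, 2), lstm_units=5,
                head_widths=(4, 1), dropout=0.0, n_dropout_layers=0,
                lstm_activation=activation,
            )
            model = build_model(spec, seed=0)
            x = rng.random((2, 3, 8, 8))
            y = np.array([1.0, 0.0])
            model.zero_grad()
            p = model.forward(x, train=True)
            model.backward_bce(p, y)
            eps = 1e-5
            for par in model.params():
                flat = par.value.reshape(-1)
                grad = par.grad.reshape(-1)
                for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = bce_loss(model.forward(x), y)
                    flat[i] = orig - eps
                    lm = bce_loss(model.forward(x), y)
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - grad[i]) < 1e-4 * max(1.0, abs(num)), (
                        activation, par.value.shape, num, grad[i],
                    )

    def test_single_step_decreases_loss(self, rng):
        """Gradient smoke: a small step on one segment lowers its own loss."""
        model = build_model(TINY, seed=2)
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        y = np.array([1.0], np.float32)
        p0 = model.forward(x, train=True)
        l0 = bce_loss(p0, y)
        model.zero_grad()
        model.backward_bce(p0, y)
        for par in model.params():
            par.value -= 0.01 * par.grad
        assert bce_loss(model.forward(x), y) < l0


class TestWeightState:
    def test_roundtrip(self, tmp_path, rng):
        model = build_model(TINY, seed=3)
        state = WeightState.capture(model, epochs_run=7)
        save_weights(state, tmp_path / "ckpt")
        loaded = load_weights(tmp_path / "ckpt")
        assert loaded.epochs_run == 7 and loaded.seed == 3
        fresh = build_model(TINY, seed=99)
        loaded.restore(fresh)
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), fresh.forward(x))

    def test_fingerprint_mismatch_rejected(self):
        state = WeightState.capture(build_model(TINY, seed=0))
        other = build_model(ModelSpec(input_px=8, seq_len=3, conv_filters=(2, 2),
                                      lstm_units=6, head_widths=(4, 1)), seed=0)
        with pytest.raises(ValueError, match="fingerprint"):
            state.restore(other)
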