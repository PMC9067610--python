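import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from speckleplane.reconstructor import (
    ErrorCurves,
    TrainConfig,
    UNetConfig,
    build_unet,
    convergence_epoch,
    load_model,
    npcc,
    reconstruct,
    save_model,
    train,
)
from speckleplane.system import SpecklePair
from speckleplane.objects import AmplitudeObject, generate_digits


def npcc_oracle(x, y):
    """Independent extended-precision evaluation of the NPCC definition via
    compensated summation on long doubles."""
    xv = [float(v) for v in np.asarray(x).ravel()]
    yv = [float(v) for v in np.asarray(y).ravel()]
    n = len(xv)
    mx = math.fsum(xv) / n
    my = math.fsum(yv) / n
    num = math.fsum((a - mx) * (b - my) for a, b in zip(xv, yv))
    dx = math.fsum((a - mx) ** 2 for a in xv)
    dy = math.fsum((b - my) ** 2 for b in yv)
    return -num / math.sqrt(dx) / math.sqrt(dy)


class TestNpcc:
    def test_self_correlation_is_minus_one(self):
        x = np.arange(16.0).reshape(4, 4)
        assert npcc(x, x) == pytest.approx(-1.0, abs=1e-12)

    def test_anticorrelation_is_plus_one(self):
        x = np.arange(16.0).reshape(4, 4)
        assert npcc(x, 7.0 - x) == pytest.approx(1.0, abs=1e-12)

    def test_known_pair_matches_direct_formula(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert npcc(x, y) == pytest.approx(npcc_oracle(x, y), abs=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            npcc(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    def test_oracle_agreement_on_random_pairs(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            x = rng.random((12, 12)) * 255
            y = rng.random((12, 12)) * 255
            worst = max(worst, abs(npcc(x, y) - npcc_oracle(x, y)))
        assert worst < 1e-10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (5, 5), elements=st.floats(0, 255)),
        arrays(np.float64, (5, 5), elements=st.floats(0, 255)),
        st.floats(0.1, 10.0),
        st.floats(-50.0, 50.0),
    )
    def test_symmetry_and_affine_invariance(self, x, y, a, b):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert npcc(x, y) == pytest.approx(npcc(y, x), abs=1e-12)
        assert npcc(a * x + b, y) == pytest.approx(npcc(x, y), abs=1e-9)


class TestUNetShapes:
    def test_paper_preset_deepest_tensor(self):
        cfg = UNetConfig(input_side=256, levels=5, base_channels=4)
        assert cfg.deepest_side == 8
        assert cfg.channels[-1] == 64

    def test_desk_64_preset_deepest_tensor(self):
        cfg = UNetConfig(input_side=64, levels=3, base_channels=16)
        assert cfg.deepest_side == 8
        assert cfg.channels[-1] == 64

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="bottleneck"):
            UNetConfig(input_side=64, levels=3, base_channels=8)

    def test_zero_input_forward_finite(self):
        model = build_unet(UNetConfig(16, 2, 32), seed=0)
        out = model.forward(np.zeros((1, 1, 16, 16), np.float32))
        assert out.shape == (1, 1, 16, 16)
        assert np.isfinite(out).all()


def _identity_pairs(n, side=32, seed=0):
    """Pairs whose speckle equals the ground-truth rendering (identity task)."""
    objs = generate_digits(n, size=side, seed=seed)
    pairs = []
    splits = ["train"] * int(n * 0.75) + ["val"] * (n - int(n * 0.75))
    for o, sp in zip(objs, splits):
        img = np.rint(o.pixels * 255).astype(np.uint8)
        pairs.append(
            SpecklePair(speckle=img, truth=o, target=img, condition={"split": sp})
        )
    return pairs


class TestTraining:
    def test_single_epoch_curves(self):
        pairs = _identity_pairs(8, seed=3)
        model = build_unet(UNetConfig(32, 3, 16), seed=0)
        _, curves = train(model, pairs, TrainConfig(epochs=1, batch_size=4, seed=0))
        assert len(curves.train) == len(curves.val) == 1
        assert -1.0 <= curves.train[0] <= 1.0
        assert -1.0 <= curves.val[0] <= 1.0

    def test_identity_task_converges(self):
        """With speckle := ground truth the inverse map is the identity and
        the training NPCC must approach -1."""
        pairs = _identity_pairs(100, seed=4)
        model = build_unet(UNetConfig(32, 3, 16), seed=1)
        _, curves = train(
            model,
            pairs,
            TrainConfig(epochs=30, batch_size=8, seed=1, early_stop_patience=None),
        )
        assert curves.train[-1] < -0.95
        assert curves.train[-1] <= curves.train[0]
        assert all(-1.0 <= v <= 1.0 for v in curves.train + curves.val)

    def test_seed_determinism(self):
        pairs = _identity_pairs(12, seed=5)
        losses = []
        for _ in range(2):
            model = build_unet(UNetConfig(32, 3, 16), seed=2)
            _, curves = train(model, pairs, TrainConfig(epochs=2, batch_size=4, seed=2))
            losses.append((curves.train[-1], curves.val[-1]))
        assert abs(losses[0][0] - losses[1][0]) < 1e-6
        assert abs(losses[0][1] - losses[1][1]) < 1e-6

    def test_empty_split_rejected(self):
        pairs = _identity_pairs(8, seed=3)
        for p in pairs:
            p.condition["split"] = "train"
        model = build_unet(UNetConfig(32, 3, 16), seed=0)
        with pytest.raises(ValueError, match="split"):
            train(model, pairs, TrainConfig(epochs=1, seed=0))


class TestReconstruct:
    def test_shape_and_finiteness(self):
        model = build_unet(UNetConfig(16, 2, 32), seed=0)
        out = reconstruct(model, np.zeros((16, 16), np.uint8))
        assert out.shape == (16, 16)
        assert np.isfinite(out).all()
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_shape_mismatch_rejected(self):
        model = build_unet(UNetConfig(16, 2, 32), seed=0)
        with pytest.raises(ValueError, match="side"):
            reconstruct(model, np.zeros((8, 8), np.uint8))

    def test_model_round_trips_through_checkpoint(self, tmp_path):
        model = build_unet(UNetConfig(16, 2, 32), seed=4)
        x = np.random.default_rng(0).integers(0, 255, (16, 16)).astype(np.uint8)
        before = reconstruct(model, x)
        save_model(model, tmp_path / "m.npz")
        after = reconstruct(load_model(tmp_path / "m.npz"), x)
        np.testing.assert_allclose(before, after)


class TestConvergenceEpoch:
    def test_monotone_curve_tol_zero(self):
        c = ErrorCurves(train=[-0.1, -0.2, -0.3], val=[-0.1, -0.2, -0.3])
        assert convergence_epoch(c, tol=0.0) == 3

    def test_constant_curve(self):
        c = ErrorCurves(train=[-0.5] * 4, val=[-0.5] * 4)
        assert convergence_epoch(c, tol=0.0) == 1

    def test_tolerance_band(self):
        c = ErrorCurves(
            train=[0] * 5, val=[-0.2, -0.7, -0.89, -0.90, -0.90]
        )
        assert convergence_epoch(c, tol=0.02) == 3

    def test_final_gap(self):
        c = ErrorCurves(train=[-0.9], val=[-0.7])
        assert c.final_gap == pytest.approx(-0.2)
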