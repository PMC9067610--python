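import math

import numpy as np
import pytest
from scipy import ndimage

from speckleplane.metrics import (
    MetricsReport,
    SsimConstants,
    acc,
    pcc,
    ssim,
    summarize,
)
from speckleplane.reconstructor import npcc


def ssim_oracle(x, y, k=SsimConstants()):
    """Independent extended-precision evaluation of the single-window SSIM
    definition using compensated sums."""
    xv = [float(v) for v in np.asarray(x).ravel()]
    yv = [float(v) for v in np.asarray(y).ravel()]
    n = len(xv)
    mx = math.fsum(xv) / n
    my = math.fsum(yv) / n
    vx = math.fsum((a - mx) ** 2 for a in xv) / n
    vy = math.fsum((b - my) ** 2 for b in yv) / n
    cov = math.fsum((a - mx) * (b - my) for a, b in zip(xv, yv)) / n
    return ((2 * mx * my + k.c1) * (2 * cov + k.c2)) / (
        (mx * mx + my * my + k.c1) * (vx + vy + k.c2)
    )


class TestSsim:
    def test_identity_is_one(self):
        x = np.random.default_rng(0).integers(0, 256, (16, 16)).astype(float)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_black_vs_white_by_hand(self):
        # mu_x=0, mu_y=255, all variances 0:
        # SSIM = C1/(255^2+C1) * C2/C2 = 6.5025/65031.5025
        x = np.zeros((8, 8))
        y = np.full((8, 8), 255.0)
        k = SsimConstants()
        expected = k.c1 / (255.0**2 + k.c1)
        assert expected == pytest.approx(9.9996e-5, rel=1e-3)
        assert ssim(x, y) == pytest.approx(expected, abs=1e-15)

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            x = rng.integers(0, 256, (8, 8)).astype(float)
            y = rng.integers(0, 256, (8, 8)).astype(float)
            worst = max(worst, abs(ssim(x, y) - ssim_oracle(x, y)))
        assert worst < 1e-10

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 256, (8, 8)).astype(float)
        y = rng.integers(0, 256, (8, 8)).astype(float)
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-14)

    def test_bounded_and_one_only_at_equality(self):
        # |SSIM| <= 1 always; SSIM = 1 exactly when x == y; positive whenever
        # the images are non-negatively correlated.  (The global form CAN go
        # negative for anticorrelated pairs -- that is a property of the
        # formula, not a bug.)
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.integers(0, 256, (6, 6)).astype(float)
            y = rng.integers(0, 256, (6, 6)).astype(float)
            s = ssim(x, y)
            assert -1.0 <= s <= 1.0
            assert s < 1.0 - 1e-12 or np.array_equal(x, y)
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            if cov >= 0:
                assert s > 0.0
        x = rng.integers(0, 256, (6, 6)).astype(float)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_degradation_under_blur(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 256, (32, 32)).astype(float)
        values = [ssim(ndimage.gaussian_filter(x, s), x) for s in (0.5, 1.5, 3.0)]
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_windowed_variant_runs(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 256, (16, 16)).astype(float)
        y = rng.integers(0, 256, (16, 16)).astype(float)
        assert -1.0 <= ssim(x, y, windowed=True) <= 1.0


class TestPcc:
    def test_definitional_relation_to_npcc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.random((6, 6))
            y = rng.random((6, 6))
            assert abs(pcc(x, y) + npcc(x, y)) < 1e-14

    def test_perfect_and_anti(self):
        x = np.arange(9.0).reshape(3, 3)
        assert pcc(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pcc(x, 5.0 - x) == pytest.approx(-1.0, abs=1e-12)


class FixedClassifier:
    """Deterministic stub: classifies by the stored lookup, for counting."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, images):
        return np.array([self.mapping[int(img.sum()) % len(self.mapping)] for img in images])


class TestAcc:
    def test_counting(self):
        clf = FixedClassifier({0: 1, 1: 1, 2: 0, 3: 1})
        imgs = [np.full((2, 2), v, float) for v in range(4)]  # sums 0,4,8,12 -> keys 0,0,0,0
        labels = [1, 1, 1, 0]
        value = acc(clf, imgs, labels)
        assert value == pytest.approx(3 / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no reconstructions"):
            acc(FixedClassifier({0: 0}), [], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            acc(FixedClassifier({0: 0}), [np.zeros((2, 2))], [0, 1])


class TestSummarize:
    def test_mean_of_per_image_values(self):
        rng = np.random.default_rng(1)
        t1 = rng.integers(0, 256, (8, 8)).astype(float)
        t2 = rng.integers(0, 256, (8, 8)).astype(float)
        clf = FixedClassifier({k: 0 for k in range(8 * 8 * 256)})
        rep = summarize([t1, t2], [t1, t2], [0, 0], clf)
        assert rep.mean_ssim == pytest.approx(1.0, abs=1e-12)
        assert rep.mean_ssim == pytest.approx(np.mean(rep.per_image_ssim))
        assert rep.acc == 1.0

    def test_csv_round_trip_preserves_12_digits(self, tmp_path):
        import pandas as pd

        rep = MetricsReport(
            per_image_ssim=[0.123456789012345, 0.9],
            per_image_pcc=[0.5, -0.25],
            predicted_labels=[1, 2],
            true_labels=[1, 3],
            acc=0.5,
        )
        rep.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        for col, vals in (("ssim", rep.per_image_ssim), ("pcc", rep.per_image_pcc)):
            for a, b in zip(back[col], vals):
                assert a == pytest.approx(b, abs=1e-12)
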