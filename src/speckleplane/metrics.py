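"""Evaluation battery: SSIM, PCC, digit-classification accuracy (ACC).

SSIM is computed globally from whole-image statistics,

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
                 ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

with C1 = (255 * 0.01)^2 and C2 = (255 * 0.03)^2 on the 8-bit scale.  A
sliding-window variant (the common convention) is available behind
``windowed=True`` but is not the default here, because the global form is
what the evaluation protocol defines.

ACC is the fraction of reconstructions whose digit class is recognized by a
small CNN classifier trained on clean ground-truth renderings; the
classifier must reach at least 95% held-out accuracy on clean digits for
the metric to be meaningful, and training fails loudly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .nn import Adam, Conv2d, Dense, MaxPool2, ReLU
from .nn.losses import softmax_xent_and_grad
from .reconstructor import npcc
from .system import OpticalConfig, capture, field_after_d2, relay_to_camera, truth_on_camera
from .objects import to_slm_pattern

__all__ = [
    "SsimConstants",
    "MetricsReport",
    "ssim",
    "pcc",
    "pcc_sweep",
    "DigitClassifier",
    "train_digit_classifier",
    "acc",
    "summarize",
]


@dataclass(frozen=True)
class SsimConstants:
    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.dynamic_range * self.k1) ** 2

    @property
    def c2(self) -> float:
        return (self.dynamic_range * self.k2) ** 2


def ssim(x, y, k: SsimConstants = SsimConstants(), windowed: bool = False) -> float:
    """Structural similarity of two images on the 0-255 scale.

    Default is the single-window (global-statistics) form; ``windowed=True``
    computes the conventional sliding-window SSIM instead (via
    scikit-image) and is provided for comparison only.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError("images must have the same shape")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(xa, ya, data_range=k.dynamic_range))
    mx, my = xa.mean(), ya.mean()
    vx, vy = xa.var(), ya.var()
    cov = ((xa - mx) * (ya - my)).mean()
    num = (2.0 * mx * my + k.c1) * (2.0 * cov + k.c2)
    den = (mx**2 + my**2 + k.c1) * (vx + vy + k.c2)
    return float(num / den)


def pcc(x, y) -> float:
    """Pearson correlation coefficient of two images (= -NPCC)."""
    return -npcc(x, y)


def pcc_sweep(
    objects,
    cfg: OpticalConfig,
    d_values,
    d2,
    d1=None,
    seeds=(0,),
) -> pd.DataFrame:
    """Mean +/- sd PCC between ground truth and raw speckle as a function of
    the image-plane distance d.

    For each diffuser seed the screens are frozen once; for each d the same
    post-diffuser fields are relayed to the camera, so d is the only varying
    factor.  ``d_values`` are in meters; the returned table reports mm.
    Ground truth is the orientation-corrected, demagnified camera-frame
    rendering.
    """
    d_values = list(d_values)
    if not d_values:
        raise ValueError("empty d sweep")
    pats = [to_slm_pattern(o, cfg.slm_active, cfg.grid) for o in objects]
    tgts = [truth_on_camera(p, cfg) for p in pats]
    rows = []
    for seed in seeds:
        d1s = None if d1 is None else dc_replace(d1, seed=int(seed) + 101)
        d2s = dc_replace(d2, seed=int(seed))
        screens: dict = {}
        post = [field_after_d2(p, cfg, d1=d1s, d2=d2s, _screens=screens) for p in pats]
        for d in d_values:
            c = cfg.with_d(float(d))
            vals = [
                pcc(capture(relay_to_camera(u, c), c), t) for u, t in zip(post, tgts)
            ]
            rows.append(
                {
                    "d_mm": float(d) * 1e3,
                    "seed": int(seed),
                    "mean_pcc": float(np.mean(vals)),
                    "sd_pcc": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Digit classifier (ACC metric)
# ---------------------------------------------------------------------------


class DigitClassifier:
    """Two conv blocks + dense softmax head on single-channel images."""

    def __init__(self, side: int, n_classes: int = 10, seed: int = 0):
        if side % 4 != 0:
            raise ValueError("classifier input side must be divisible by 4")
        rng = np.random.default_rng(seed)
        self.side = side
        self.layers = [
            Conv2d(1, 8, 3, rng),
            ReLU(),
            MaxPool2(),
            Conv2d(8, 16, 3, rng),
            ReLU(),
            MaxPool2(),
        ]
        self.head = Dense(16 * (side // 4) ** 2, n_classes, rng)
        self.train_accuracy: float | None = None
        self.holdout_accuracy: float | None = None

    def params(self):
        ps = []
        for lay in self.layers:
            ps.extend(lay.params())
        ps.extend(self.head.params())
        return ps

    def logits(self, images: np.ndarray) -> np.ndarray:
        """images: (N, side, side) on the 0-255 scale."""
        h = (np.asarray(images, dtype=np.float32) / 255.0)[:, None]
        for lay in self.layers:
            h = lay.forward(h)
        return self.head.forward(h.reshape(h.shape[0], -1))

    def _backward(self, dlogits):
        g = self.head.backward(dlogits)
        n = dlogits.shape[0]
        g = g.reshape(n, 16, self.side // 4, self.side // 4)
        for lay in reversed(self.layers):
            g = lay.backward(g)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class per image; ties resolve to the lowest class index."""
        out = []
        for i in range(0, len(images), 64):
            out.append(self.logits(images[i : i + 64]).argmax(axis=1))
        return np.concatenate(out)


def _resize_bilinear(img: np.ndarray, side: int) -> np.ndarray:
    from scipy import ndimage

    c = np.linspace(0.0, img.shape[0] - 1.0, side)
    cy, cx = np.meshgrid(c, c, indexing="ij")
    return ndimage.map_coordinates(np.asarray(img, float), [cy, cx], order=1)


def train_digit_classifier(
    objects,
    seed: int = 0,
    side: int = 32,
    renderer=None,
    epochs: int = 25,
    batch_size: int = 16,
    lr: float = 1e-3,
    holdout_frac: float = 1 / 6,
    min_holdout_acc: float = 0.95,
) -> DigitClassifier:
    """Train the ACC classifier on clean ground-truth renderings.

    ``renderer`` maps an AmplitudeObject to a 0-255 image of shape
    (side, side); by default the object is bilinearly resized.  For
    evaluating camera-frame reconstructions pass a renderer that applies the
    same flip/demagnification as the imaging train.  Fails with
    "classifier underfit" if held-out accuracy on clean digits is below
    ``min_holdout_acc`` (the ACC metric would be meaningless).
    Deterministic given ``seed``.
    """
    labels = np.array([o.label for o in objects])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if renderer is None:
        imgs = np.stack([_resize_bilinear(o.pixels, side) * 255.0 for o in objects])
    else:
        imgs = np.stack([renderer(o) for o in objects]).astype(np.float64)
        if imgs.shape[1:] != (side, side):
            raise ValueError("renderer output does not match classifier side")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(imgs))
    n_hold = max(1, int(round(len(imgs) * holdout_frac)))
    hold, tr = order[:n_hold], order[n_hold:]
    clf = DigitClassifier(side, seed=seed)
    opt = Adam(clf.params(), lr=lr)
    for _ in range(epochs):
        perm = rng.permutation(len(tr))
        for i in range(0, len(perm), batch_size):
            idx = tr[perm[i : i + batch_size]]
            logits = clf.logits(imgs[idx])
            _, dlog = softmax_xent_and_grad(logits, labels[idx])
            opt.zero_grad()
            clf._backward(dlog)
            opt.step()
    clf.train_accuracy = float((clf.predict(imgs[tr]) == labels[tr]).mean())
    clf.holdout_accuracy = float((clf.predict(imgs[hold]) == labels[hold]).mean())
    if clf.holdout_accuracy < min_holdout_acc:
        raise RuntimeError(
            f"classifier underfit: held-out accuracy {clf.holdout_accuracy:.3f} "
            f"< {min_holdout_acc:.2f} on clean digits "
            f"(train accuracy {clf.train_accuracy:.3f}, n={len(objects)})"
        )
    return clf


def acc(classifier: DigitClassifier, reconstructions, labels) -> float:
    """Fraction of reconstructions classified as their true digit."""
    if len(reconstructions) == 0:
        raise ValueError("no reconstructions to classify")
    if len(reconstructions) != len(labels):
        raise ValueError("reconstructions and labels differ in length")
    preds = classifier.predict(np.stack([np.asarray(r) for r in reconstructions]))
    return float((preds == np.asarray(labels)).mean())


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-image and averaged evaluation of one experimental condition."""

    per_image_ssim: list[float]
    per_image_pcc: list[float]
    predicted_labels: list[int]
    true_labels: list[int]
    acc: float
    condition: dict = field(default_factory=dict)

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.per_image_ssim))

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.per_image_pcc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ssim": self.per_image_ssim,
                "pcc": self.per_image_pcc,
                "predicted": self.predicted_labels,
                "label": self.true_labels,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False, float_format="%.17g")

    def to_json_dict(self) -> dict:
        return {
            "mean_ssim": self.mean_ssim,
            "mean_pcc": self.mean_pcc,
            "acc": self.acc,
            "n_images": len(self.per_image_ssim),
            "condition": self.condition,
        }


def summarize(recons, targets, labels, classifier: DigitClassifier, condition=None) -> MetricsReport:
    """Evaluate reconstructions against their camera-frame ground truths.

    ``recons`` and ``targets`` are aligned lists of images on the 0-255
    scale; SSIM/PCC are computed per image and ACC over the whole list.
    """
    if not (len(recons) == len(targets) == len(labels)):
        raise ValueError("recons, targets and labels must be aligned")
    ssims = [ssim(r, t) for r, t in zip(recons, targets)]
    pccs = [pcc(r, t) for r, t in zip(recons, targets)]
    preds = classifier.predict(np.stack([np.asarray(r) for r in recons]))
    return MetricsReport(
        per_image_ssim=[float(s) for s in ssims],
        per_image_pcc=[float(p) for p in pccs],
        predicted_labels=[int(p) for p in preds],
        true_labels=[int(l) for l in labels],
        acc=float((preds == np.asarray(labels)).mean()),
        condition=dict(condition or {}),
    )
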