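"""U-Net speckle-to-object reconstruction trained with the NPCC loss.

The network follows the U-Net shape: an encoder of repeated
(3x3 conv, ReLU) x 2 + 2x2 max-pool stages in which the spatial side halves
and the channel depth doubles, ending at a deepest feature map whose depth
is 64; encoder and decoder are connected through a densely connected
(fully connected) bottleneck on the flattened deepest features; the decoder
mirrors the encoder with 2x2 nearest-neighbor upsampling, concatenation
skip connections, and (3x3 conv, ReLU) x 2 stages; a final linear 1x1
convolution produces the single-channel reconstruction.

The loss is the negative Pearson correlation coefficient between prediction
and ground truth, so the network is trained to reproduce structure rather
than absolute intensity scale.  Optimization uses Adam.  Training is fully
deterministic given the config seed (pure numpy; the only randomness is the
seeded weight init and batch shuffling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Concat, Conv2d, Dense, MaxPool2, ReLU, Upsample2
from .nn.losses import npcc_loss_and_grad

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "ErrorCurves",
    "UNet",
    "npcc",
    "build_unet",
    "train",
    "reconstruct",
    "convergence_epoch",
    "save_model",
    "load_model",
]


def npcc(x, y) -> float:
    """Negative Pearson correlation of two equal-shape images, in [-1, 1].

    -1 means perfect positive correlation.  Computed from the flattened
    pixel vectors: with means X_bar, Y_bar,

        NPCC = -sum((X - X_bar)(Y - Y_bar)) /
                sqrt(sum((X - X_bar)^2)) / sqrt(sum((Y - Y_bar)^2)).
    """
    xv = np.asarray(x, dtype=np.float64).ravel()
    yv = np.asarray(y, dtype=np.float64).ravel()
    if xv.shape != yv.shape:
        raise ValueError("images must have the same shape")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant image: Pearson correlation undefined")
    return float(np.clip(-(xc @ yc) / (sx * sy), -1.0, 1.0))


@dataclass(frozen=True)
class UNetConfig:
    """Shape of the reconstruction network.

    ``base_channels * 2**(levels-1)`` must equal ``bottleneck_channels``;
    the deepest feature map has side ``input_side / 2**levels``.
    """

    input_side: int
    levels: int
    base_channels: int
    bottleneck_channels: int = 64
    bottleneck_dense: bool = True
    output_kernel: int = 1

    def __post_init__(self):
        if self.input_side % (2**self.levels) != 0:
            raise ValueError("input side must be divisible by 2**levels")
        if self.base_channels * 2 ** (self.levels - 1) != self.bottleneck_channels:
            raise ValueError(
                "channel doubling must reach bottleneck_channels at the deepest level"
            )

    @property
    def deepest_side(self) -> int:
        return self.input_side // 2**self.levels

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.levels)]


def paper_unet_config() -> UNetConfig:
    """256x256 input, five pooling stages, deepest tensor 8x8x64."""
    return UNetConfig(input_side=256, levels=5, base_channels=4)


def desk_unet_config(input_side: int = 32) -> UNetConfig:
    return UNetConfig(input_side=input_side, levels=3, base_channels=16)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int | None = 10
    min_delta: float = 1e-3

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class ErrorCurves:
    """Per-epoch NPCC losses on the training and validation ('testing')
    splits, both in [-1, 1]."""

    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)

    @property
    def min_val(self) -> float:
        return min(self.val)

    @property
    def final_gap(self) -> float:
        """Final (train - val) loss difference; negative when training loss
        is lower, i.e. the generalization gap magnitude is |gap|."""
        return self.train[-1] - self.val[-1]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_npcc,val_npcc\n")
            for e, (a, b) in enumerate(zip(self.train, self.val), start=1):
                fh.write(f"{e},{a:.17g},{b:.17g}\n")


def convergence_epoch(curves: ErrorCurves, tol: float = 0.02) -> int:
    """First epoch (1-based) whose validation loss is within ``tol`` of the
    minimum validation loss."""
    if not curves.val:
        raise ValueError("empty curves")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    vmin = min(curves.val)
    for e, v in enumerate(curves.val, start=1):
        if v <= vmin + tol:
            return e
    return len(curves.val)  # pragma: no cover


class UNet:
    """Explicit-graph U-Net (see module docstring)."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.channels
        self.enc = []
        cin = 1
        for c in ch:
            self.enc.append(
                [Conv2d(cin, c, 3, rng), ReLU(), Conv2d(c, c, 3, rng), ReLU()]
            )
            cin = c
        self.pools = [MaxPool2() for _ in ch]
        s = cfg.deepest_side
        self.flat_dim = s * s * ch[-1]
        self.dense = Dense(self.flat_dim, self.flat_dim, rng) if cfg.bottleneck_dense else None
        self.dense_relu = ReLU()
        self.dec = []
        c_up = ch[-1]
        for c in reversed(ch):
            self.dec.append(
                [
                    Upsample2(),
                    Concat(),
                    Conv2d(c + c_up, c, 3, rng),
                    ReLU(),
                    Conv2d(c, c, 3, rng),
                    ReLU(),
                ]
            )
            c_up = c
        self.out_conv = Conv2d(ch[0], 1, cfg.output_kernel, rng)

    def params(self):
        ps = []
        for blk in self.enc:
            for lay in blk:
                ps.extend(lay.params())
        if self.dense is not None:
            ps.extend(self.dense.params())
        for blk in self.dec:
            for lay in blk:
                ps.extend(lay.params())
        ps.extend(self.out_conv.params())
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.cfg.input_side:
            raise ValueError(
                f"expected input (N, 1, {self.cfg.input_side}, {self.cfg.input_side})"
            )
        self._skips = []
        h = x.astype(np.float32)
        for blk, pool in zip(self.enc, self.pools):
            for lay in blk:
                h = lay.forward(h)
            self._skips.append(h)
            h = pool.forward(h)
        self._deep_shape = h.shape
        if self.dense is not None:
            h = self.dense.forward(h.reshape(h.shape[0], -1))
            h = self.dense_relu.forward(h)
            h = h.reshape(self._deep_shape)
        for blk, skip in zip(self.dec, reversed(self._skips)):
            up, cat, c1, r1, c2, r2 = blk
            h = up.forward(h)
            h = cat.forward(skip, h)
            h = r2.forward(c2.forward(r1.forward(c1.forward(h))))
        return self.out_conv.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        g = self.out_conv.backward(dy)
        dskips = [None] * len(self.dec)
        for i, blk in reversed(list(enumerate(self.dec))):
            up, cat, c1, r1, c2, r2 = blk
            g = c1.backward(r1.backward(c2.backward(r2.backward(g))))
            dskip, g = cat.backward(g)
            dskips[i] = dskip
            g = up.backward(g)
        if self.dense is not None:
            g = g.reshape(g.shape[0], -1)
            g = self.dense.backward(self.dense_relu.backward(g))
            g = g.reshape(self._deep_shape)
        for i, (blk, pool) in reversed(list(enumerate(zip(self.enc, self.pools)))):
            g = pool.backward(g)
            g = g + dskips[len(self.dec) - 1 - i]
            for lay in reversed(blk):
                g = lay.backward(g)


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet:
    """Construct the reconstruction network; raises on inconsistent config
    before any training starts."""
    return UNet(cfg, seed=seed)


def _batched_forward(model: UNet, x: np.ndarray, batch: int = 32) -> np.ndarray:
    outs = [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def _arrays_from_pairs(pairs):
    x = np.stack([p.speckle for p in pairs]).astype(np.float32) / 255.0
    y = np.stack([p.target for p in pairs]).astype(np.float32) / 255.0
    return x[:, None], y[:, None]


def train(model: UNet, pairs, tcfg: TrainConfig):
    """Train on the 'train' split, monitor NPCC on the 'val' split.

    Returns (model, ErrorCurves).  Raises on divergence (NaN loss) with the
    epoch index, and if either split is empty.
    """
    tr = [p for p in pairs if p.condition.get("split") == "train"]
    va = [p for p in pairs if p.condition.get("split") == "val"]
    if not tr or not va:
        raise ValueError("dataset must contain non-empty train and val splits")
    xtr, ytr = _arrays_from_pairs(tr)
    xva, yva = _arrays_from_pairs(va)
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params(), lr=tcfg.learning_rate)
    curves = ErrorCurves()
    best = np.inf
    best_epoch = 0
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(len(xtr))
        tot, nseen = 0.0, 0
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            pred = model.forward(xtr[idx])
            loss, grad = npcc_loss_and_grad(pred, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (NaN/inf loss) at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            tot += loss * len(idx)
            nseen += len(idx)
        train_loss = tot / nseen
        vpred = _batched_forward(model, xva)
        val_loss, _ = npcc_loss_and_grad(vpred, yva)
        curves.train.append(float(np.clip(train_loss, -1.0, 1.0)))
        curves.val.append(float(np.clip(val_loss, -1.0, 1.0)))
        if val_loss < best - tcfg.min_delta:
            best = val_loss
            best_epoch = epoch
        elif (
            tcfg.early_stop_patience is not None
            and epoch - best_epoch >= tcfg.early_stop_patience
        ):
            break
    return model, curves


def _to_8bit_scale(out: np.ndarray) -> np.ndarray:
    """Map a raw network output to the 0-255 metric scale.

    The NPCC loss is invariant to affine rescaling of the prediction, so the
    raw output carries an arbitrary per-run gain and offset; each image is
    therefore min-max rescaled to span 0-255 (the same gauge the 8-bit
    targets live in) before SSIM/ACC evaluation.  A constant output maps to
    zeros."""
    lo, hi = float(out.min()), float(out.max())
    if hi <= lo:
        return np.zeros_like(out, dtype=np.float64)
    return (out.astype(np.float64) - lo) / (hi - lo) * 255.0


def reconstruct(model: UNet, speckle: np.ndarray) -> np.ndarray:
    """Single forward pass; output rescaled to 0-255 (float) for metric
    computation (see _to_8bit_scale)."""
    img = np.asarray(speckle)
    if img.shape != (model.cfg.input_side, model.cfg.input_side):
        raise ValueError(
            f"speckle side {img.shape} does not match model input "
            f"{model.cfg.input_side}"
        )
    x = img.astype(np.float32)[None, None]
    if img.dtype == np.uint8:
        x = x / 255.0
    return _to_8bit_scale(model.forward(x)[0, 0])


def reconstruct_batch(model: UNet, speckles: np.ndarray) -> np.ndarray:
    x = speckles.astype(np.float32) / 255.0
    out = _batched_forward(model, x[:, None])[:, 0]
    return np.stack([_to_8bit_scale(o) for o in out])


def save_model(model: UNet, path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.cfg.__dict__).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> UNet:
    data = np.load(path)
    cfg = UNetConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = UNet(cfg, seed=0)
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return model
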