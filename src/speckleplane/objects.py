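"""Ground-truth amplitude objects for the simulated SLM.

The objects are handwritten-style digits rendered from stroke templates with
random affine jitter, so that a ten-class recognition task exists without any
dataset download.  An IDX (MNIST container) reader/writer is provided for
compatibility with real digit files.  Objects are amplitude transmittance maps
in [0, 1]: the SLM with crossed polarizers acts as a grayscale amplitude mask.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "AmplitudeObject",
    "SlmPattern",
    "generate_digits",
    "load_idx",
    "write_idx",
    "to_slm_pattern",
    "save_objects_png",
    "save_objects_csv",
]

IDX_IMAGES_MAGIC = 0x00000803
IDX_LABELS_MAGIC = 0x00000801


@dataclass(frozen=True)
class AmplitudeObject:
    """A square amplitude-transmittance pattern in [0, 1] with a digit label."""

    pixels: np.ndarray
    label: int
    id: str

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("object pixels must be a square 2-D array")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("amplitude values must lie in [0, 1]")
        if not (0 <= int(self.label) <= 9):
            raise ValueError("label must be in 0..9")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class SlmPattern:
    """Amplitude pattern on the full SLM grid; zero outside the active region."""

    pixels: np.ndarray
    active_extent: int

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("SLM pattern must be square")
        if self.active_extent > self.pixels.shape[0]:
            raise ValueError("active extent exceeds SLM grid")


# ---------------------------------------------------------------------------
# Stroke templates.  Unit square, x to the right, y downward. Each digit is a
# list of polylines (arrays of (x, y) vertices); arcs are sampled polylines.
# ---------------------------------------------------------------------------


def _arc(cx, cy, rx, ry, deg0, deg1, n=28):
    t = np.deg2rad(np.linspace(deg0, deg1, n))
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _line(*pts):
    return np.asarray(pts, dtype=float)


def _digit_templates() -> dict[int, list[np.ndarray]]:
    return {
        0: [_arc(0.5, 0.5, 0.26, 0.36, 0, 360)],
        1: [_line((0.36, 0.30), (0.54, 0.14), (0.54, 0.86))],
        2: [
            np.vstack(
                [
                    _arc(0.5, 0.32, 0.24, 0.18, 170, -10),
                    _line((0.74, 0.38), (0.28, 0.84)),
                ]
            ),
            _line((0.28, 0.86), (0.76, 0.86)),
        ],
        3: [
            np.vstack(
                [
                    _arc(0.47, 0.32, 0.22, 0.17, 150, -90),
                    _arc(0.47, 0.67, 0.24, 0.19, -90, 160),
                ]
            )
        ],
        4: [
            _line((0.62, 0.14), (0.26, 0.62), (0.78, 0.62)),
            _line((0.62, 0.14), (0.62, 0.88)),
        ],
        5: [
            np.vstack(
                [
                    _line((0.72, 0.16), (0.32, 0.16), (0.30, 0.48)),
                    _arc(0.48, 0.66, 0.23, 0.20, -80, 160),
                ]
            )
        ],
        6: [
            np.vstack(
                [
                    _arc(0.60, 0.30, 0.30, 0.42, 230, 180),
                    _arc(0.50, 0.66, 0.21, 0.20, 180, 520),
                ]
            )
        ],
        7: [_line((0.26, 0.16), (0.76, 0.16), (0.42, 0.88))],
        8: [
            _arc(0.5, 0.32, 0.19, 0.17, 90, 450),
            _arc(0.5, 0.68, 0.23, 0.19, -90, 270),
        ],
        9: [
            _arc(0.45, 0.34, 0.21, 0.19, 0, 360),
            _line((0.66, 0.34), (0.64, 0.88)),
        ],
    }


_TEMPLATES = _digit_templates()


def _rasterize(polylines, size, halfwidth, softness=1.0):
    """Anti-aliased stroke rendering: amplitude 1 inside the stroke core,
    linear falloff over ``softness`` pixels at the edge."""
    ys, xs = np.mgrid[0:size, 0:size]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    dmin = np.full(pts.shape[0], np.inf)
    for poly in polylines:
        for p0, p1 in zip(poly[:-1], poly[1:]):
            seg = p1 - p0
            seg2 = float(seg @ seg)
            if seg2 == 0.0:
                d = np.hypot(*(pts - p0).T)
            else:
                t = np.clip((pts - p0) @ seg / seg2, 0.0, 1.0)
                proj = p0 + t[:, None] * seg
                d = np.hypot(*(pts - proj).T)
            np.minimum(dmin, d, out=dmin)
    amp = np.clip(1.0 - (dmin - halfwidth) / softness, 0.0, 1.0)
    return amp.reshape(size, size)


def _jitter(polylines, rng, size):
    """Random affine: rotation <= 15 deg, scale 0.8-1.2, translation <= 10%."""
    ang = np.deg2rad(rng.uniform(-15.0, 15.0))
    sc = rng.uniform(0.8, 1.2)
    tx, ty = rng.uniform(-0.10, 0.10, size=2) * size
    c, s = np.cos(ang), np.sin(ang)
    rot = sc * np.array([[c, -s], [s, c]])
    ctr = np.array([size / 2.0, size / 2.0])
    out = []
    for poly in polylines:
        pts = poly * size  # unit square -> pixel coords
        out.append((pts - ctr) @ rot.T + ctr + np.array([tx, ty]))
    return out


def generate_digits(n, size=48, class_set=frozenset(range(10)), seed=0):
    """Generate ``n`` stroke-rendered digit objects, deterministic in ``seed``.

    Labels are drawn uniformly from ``class_set``; each rendering receives an
    independent affine jitter so that recognition is non-trivial.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not class_set:
        raise ValueError("no classes")
    classes = sorted(int(c) for c in class_set)
    if any(c < 0 or c > 9 for c in classes):
        raise ValueError("classes must be digits 0..9")
    if size < 16:
        raise ValueError(f"size {size} too small to render strokes (min 16)")
    rng = np.random.default_rng(seed)
    labels = rng.choice(classes, size=n)
    halfwidth = 0.050 * size
    out = []
    for i, lab in enumerate(labels):
        polys = _jitter(_TEMPLATES[int(lab)], rng, size)
        pix = _rasterize(polys, size, halfwidth)
        out.append(AmplitudeObject(pixels=pix, label=int(lab), id=f"dig{i:05d}s{seed}"))
    return out


# ---------------------------------------------------------------------------
# IDX container format (optional compatibility reader/writer)
# ---------------------------------------------------------------------------


def load_idx(images_path, labels_path):
    """Read digit objects from IDX image/label files (the MNIST container).

    Pixel bytes 0..255 are rescaled to amplitudes in [0, 1].
    """
    img_bytes = Path(images_path).read_bytes()
    lab_bytes = Path(labels_path).read_bytes()
    magic_i, n_i, rows, cols = struct.unpack(">IIII", img_bytes[:16])
    if magic_i != IDX_IMAGES_MAGIC:
        raise ValueError("not IDX: bad image magic number")
    magic_l, n_l = struct.unpack(">II", lab_bytes[:8])
    if magic_l != IDX_LABELS_MAGIC:
        raise ValueError("not IDX: bad label magic number")
    if n_i != n_l:
        raise ValueError(f"image count {n_i} != label count {n_l}")
    data = np.frombuffer(img_bytes, dtype=np.uint8, count=n_i * rows * cols, offset=16)
    if data.size != n_i * rows * cols:
        raise ValueError("truncated IDX image file")
    labels = np.frombuffer(lab_bytes, dtype=np.uint8, count=n_l, offset=8)
    imgs = data.reshape(n_i, rows, cols).astype(np.float64) / 255.0
    return [
        AmplitudeObject(pixels=imgs[k], label=int(labels[k]), id=f"idx{k:05d}")
        for k in range(n_i)
    ]


def write_idx(objects, images_path, labels_path):
    """Write objects to IDX files (amplitudes quantized to 8 bits)."""
    if not objects:
        raise ValueError("no objects to write")
    size = objects[0].size
    stack = np.stack([np.rint(o.pixels * 255.0).astype(np.uint8) for o in objects])
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_IMAGES_MAGIC, len(objects), size, size))
        fh.write(stack.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_LABELS_MAGIC, len(objects)))
        fh.write(np.array([o.label for o in objects], dtype=np.uint8).tobytes())


# ---------------------------------------------------------------------------
# SLM rendering
# ---------------------------------------------------------------------------


def to_slm_pattern(obj: AmplitudeObject, active_extent: int, grid: int = 512) -> SlmPattern:
    """Resample an object (bilinear) to the active SLM region and zero-pad.

    The object fills the central ``active_extent`` x ``active_extent`` block of
    a ``grid`` x ``grid`` SLM; everything outside is opaque (amplitude 0).
    """
    if active_extent > grid:
        raise ValueError("active extent larger than SLM grid")
    src = obj.pixels
    coords = np.linspace(0.0, src.shape[0] - 1.0, active_extent)
    cy, cx = np.meshgrid(coords, coords, indexing="ij")
    block = ndimage.map_coordinates(src, [cy, cx], order=1, mode="nearest")
    full = np.zeros((grid, grid), dtype=np.float64)
    off = (grid - active_extent) // 2
    full[off : off + active_extent, off : off + active_extent] = block
    return SlmPattern(pixels=np.clip(full, 0.0, 1.0), active_extent=active_extent)


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------


def save_objects_png(objects, outdir):
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for o in objects:
        iio.imwrite(outdir / f"{o.id}.png", np.rint(o.pixels * 255).astype(np.uint8))


def save_objects_csv(objects, path, seed=None):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "size", "seed"])
        for o in objects:
            w.writerow([o.id, o.label, o.size, "" if seed is None else seed])
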