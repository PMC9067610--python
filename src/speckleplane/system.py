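"""The 4f imaging train: illumination, diffusers, relay, camera.

Layout (distances measured along the axis):

    plane wave -> [D1] --100 mm--> SLM --80 mm--> [D2] --d--> L1
        --f1--> Fourier plane (iris) --f2--> L2 --f2--> camera

The camera sits at the back focal plane of L2, which the 4f relay conjugates
to the plane at distance f1 in front of L1.  Changing d therefore selects
which object-side plane is imaged: d = f1 images the D2 surface, while
d = f1 - (SLM->D2 distance) images the SLM (the object).  The relay inverts
the image and magnifies it by -f2/f1.

The L1 -> iris -> L2 segment is computed as two exact focal-plane Fourier
transforms, with the iris applied as a hard circular mask in physical
Fourier-plane coordinates.  Free-space segments use the band-limited angular
spectrum method.

Two presets are provided.  "paper" stores the benchtop geometry (632.8 nm,
f1 = 150 mm, f2 = 50 mm, 36 um SLM pixels, 7.5 mm iris, 3.75 um camera
pixels, 256x256 crop); its 5 and 120 degree diffusers are far beyond the
Nyquist angle of any practical grid, so screen creation refuses them with a
clear error.  "desk" is a self-consistent scaled-down bench that preserves
the regimes that drive the investigated effect: near-field object-to-D2
separation (Fresnel number ~20), an iris acceptance angle well below the
strong diffuser's scattering angle and above the weak one's, and the same
conjugate-plane relationships.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .diffusers import DiffuserSpec, make_phase_screen
from .objects import AmplitudeObject, SlmPattern, to_slm_pattern
from .optics import ComplexField, apply_iris, focal_fourier, plane_wave, propagate

__all__ = [
    "OpticalConfig",
    "SpecklePair",
    "paper_config",
    "desk_config",
    "desk_weak_diffuser",
    "desk_strong_diffuser",
    "image_through_system",
    "field_after_d2",
    "relay_to_camera",
    "capture",
    "truth_on_camera",
    "generate_dataset",
    "split_indices",
    "save_dataset",
    "load_dataset",
]

# The paper's acquisition protocol: 3000 captures split 2220/560/200.
SPLIT_WEIGHTS = {"train": 2220, "val": 560, "test": 200}


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of the simulated bench (lengths in meters)."""

    wavelength: float
    f1: float
    f2: float
    dist_d1_slm: float
    dist_slm_d2: float
    d: float  # D2-to-L1 distance, the swept variable
    iris_diameter: float | None
    slm_pitch: float
    cam_pitch: float
    grid: int
    camera_crop: int
    slm_active: int  # side of the used central SLM region, in SLM pixels
    preset: str = "desk"
    shot_noise_photons: float | None = None  # mean photons at max pixel, if set

    def __post_init__(self) -> None:
        for name in ("wavelength", "f1", "f2", "dist_d1_slm", "dist_slm_d2", "slm_pitch", "cam_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d + self.dist_slm_d2 < 0:
            raise ValueError("d + SLM->D2 distance must be nonnegative")
        if self.grid < 2 or (self.grid & (self.grid - 1)) != 0:
            raise ValueError("grid must be a power of two")

    @property
    def d_object_conjugate(self) -> float:
        """d at which the SLM (object) plane is imaged: d + SLM->D2 = f1."""
        return self.f1 - self.dist_slm_d2

    @property
    def d_diffuser_conjugate(self) -> float:
        """d at which the D2 surface is imaged: d = f1."""
        return self.f1

    @property
    def magnification(self) -> float:
        return -self.f2 / self.f1

    def with_d(self, d: float) -> "OpticalConfig":
        return replace(self, d=d)

    def digest_fields(self, ignore=("d",)) -> str:
        rec = {k: v for k, v in asdict(self).items() if k not in ignore}
        return json.dumps(rec, sort_keys=True)


def paper_config(d: float = 0.150, grid: int = 512) -> OpticalConfig:
    """The benchtop geometry as published (d defaults to the D2 conjugate)."""
    return OpticalConfig(
        wavelength=632.8e-9,
        f1=0.150,
        f2=0.050,
        dist_d1_slm=0.100,
        dist_slm_d2=0.080,
        d=d,
        iris_diameter=7.5e-3,
        slm_pitch=36e-6,
        cam_pitch=3.75e-6,
        grid=grid,
        camera_crop=256,
        slm_active=160,
        preset="paper",
    )


def desk_config(d: float | None = None, grid: int = 512) -> OpticalConfig:
    """Scaled-down bench that is resolvable on a desktop grid.

    d defaults to the D2-conjugate distance (f1 = 6 mm)."""
    cfg = OpticalConfig(
        wavelength=632.8e-9,
        f1=6.0e-3,
        f2=2.0e-3,
        dist_d1_slm=3.0e-3,
        dist_slm_d2=2.4e-3,
        d=6.0e-3 if d is None else d,
        iris_diameter=1.2e-3,
        slm_pitch=2.0e-6,
        cam_pitch=6.0e-6,
        grid=grid,
        camera_crop=32,
        slm_active=180,
        preset="desk",
    )
    return cfg


def desk_weak_diffuser(seed: int = 0) -> DiffuserSpec:
    """Desk-scale analog of the 5-degree holographic diffuser."""
    return DiffuserSpec(diffusion_angle=1.0, seed=seed, name="weak")


def desk_strong_diffuser(seed: int = 1) -> DiffuserSpec:
    """Desk-scale analog of the 120-degree white diffusing glass."""
    return DiffuserSpec(diffusion_angle=4.0, seed=seed, name="strong")


@dataclass(frozen=True)
class SpecklePair:
    """An 8-bit camera capture paired with its ground truth.

    ``target`` is the orientation-corrected (4f-flipped), demagnified,
    camera-frame rendering of the truth, the reference reconstructions are
    compared against.
    """

    speckle: np.ndarray  # uint8, camera_crop x camera_crop
    truth: AmplitudeObject
    target: np.ndarray  # uint8, camera_crop x camera_crop
    condition: dict


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _screen_for(spec: DiffuserSpec | None, cfg: OpticalConfig):
    if spec is None:
        return None
    return make_phase_screen(spec, cfg.grid, cfg.slm_pitch, cfg.wavelength)


def field_after_d2(
    pattern: SlmPattern,
    cfg: OpticalConfig,
    d1: DiffuserSpec | None = None,
    d2: DiffuserSpec | None = None,
    d_mid: DiffuserSpec | None = None,
    mid_frac: float = 0.5,
    _screens: dict | None = None,
) -> ComplexField:
    """Field just behind the D2 position (after the D2 screen, if present).

    This part of the train does not depend on d, so a d-sweep can reuse it.
    ``d_mid`` optionally inserts a second post-object diffuser part-way
    (fraction ``mid_frac``) between the SLM and the D2 position, for the
    two-diffusers-in-front-of-the-object configuration.  Frozen screens and
    the D1-scrambled illumination are cached in ``_screens`` so one diffuser
    realization serves a whole dataset.
    """
    if pattern.pixels.shape[0] != cfg.grid:
        raise ValueError("SLM pattern grid does not match the optical config")
    screens = _screens if _screens is not None else {}

    def screen(key, spec):
        if spec is None:
            return None
        if key not in screens:
            screens[key] = _screen_for(spec, cfg)
        return screens[key]

    if "illum" not in screens:
        u0 = plane_wave(cfg.grid, cfg.slm_pitch, cfg.wavelength)
        s1 = screen("d1", d1)
        if s1 is not None:
            u0 = replace(u0, values=u0.values * s1.transmission)
            u0 = propagate(u0, cfg.dist_d1_slm)
        screens["illum"] = u0
    u = replace(screens["illum"], values=screens["illum"].values * pattern.pixels)
    sm = screen("d_mid", d_mid)
    if sm is not None:
        u = propagate(u, cfg.dist_slm_d2 * mid_frac)
        u = replace(u, values=u.values * sm.transmission)
        u = propagate(u, cfg.dist_slm_d2 * (1.0 - mid_frac))
    else:
        u = propagate(u, cfg.dist_slm_d2)
    s2 = screen("d2", d2)
    if s2 is not None:
        u = replace(u, values=u.values * s2.transmission)
    return u


def relay_to_camera(u: ComplexField, cfg: OpticalConfig) -> ComplexField:
    """From just behind D2 to the camera plane: free space to the front
    focal plane of L1, then L1 -> iris -> L2 as exact focal transforms."""
    u = propagate(u, cfg.d - cfg.f1)  # negative = back-propagation
    u = focal_fourier(u, cfg.f1)
    if cfg.iris_diameter is not None:
        u = apply_iris(u, cfg.iris_diameter)
    return focal_fourier(u, cfg.f2)


def image_through_system(
    pattern: SlmPattern,
    cfg: OpticalConfig,
    d1: DiffuserSpec | None = None,
    d2: DiffuserSpec | None = None,
    d_mid: DiffuserSpec | None = None,
    mid_frac: float = 0.5,
    _screens: dict | None = None,
) -> ComplexField:
    """Propagate a plane wave through the full train to the camera plane."""
    u = field_after_d2(pattern, cfg, d1, d2, d_mid, mid_frac, _screens)
    return relay_to_camera(u, cfg)


def capture(field: ComplexField, cfg: OpticalConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """8-bit camera model: intensity, pixel-area averaging, central crop,
    per-image max normalization to 255, rounding.

    Optional Poisson shot noise (cfg.shot_noise_photons) is applied to the
    pixel-averaged intensity before normalization; it needs an ``rng``.
    """
    intensity = np.abs(field.values) ** 2
    binf = max(1, int(round(cfg.cam_pitch / field.pitch)))
    crop_px = cfg.camera_crop * binf
    n = intensity.shape[0]
    if crop_px > n:
        raise ValueError("camera crop exceeds the simulated field")
    off = (n - crop_px) // 2
    sub = intensity[off : off + crop_px, off : off + crop_px]
    binned = sub.reshape(cfg.camera_crop, binf, cfg.camera_crop, binf).mean(axis=(1, 3))
    if cfg.shot_noise_photons is not None:
        if rng is None:
            raise ValueError("shot noise requires an rng")
        peak = binned.max()
        if peak > 0:
            lam = binned / peak * cfg.shot_noise_photons
            binned = rng.poisson(lam).astype(np.float64)
    peak = binned.max()
    if peak == 0.0:
        return np.zeros((cfg.camera_crop, cfg.camera_crop), dtype=np.uint8)
    return np.rint(binned / peak * 255.0).astype(np.uint8)


def truth_on_camera(pattern: SlmPattern, cfg: OpticalConfig) -> np.ndarray:
    """Ideal geometric camera image of the pattern: inverted (4f flip),
    demagnified by f2/f1, pixel-averaged and cropped exactly like `capture`.

    The camera records intensity, so the ideal image is the squared
    amplitude of the flipped pattern.  Returned as uint8 (max-normalized),
    matching the capture convention.
    """
    ideal = ComplexField(
        values=pattern.pixels[::-1, ::-1].astype(np.complex128),
        pitch=cfg.slm_pitch * cfg.f2 / cfg.f1,
        wavelength=cfg.wavelength,
    )
    return capture(ideal, cfg)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def split_indices(n: int) -> dict[str, np.ndarray]:
    """Assign train/val/test indices in the paper's 2220:560:200 proportion,
    scaled to n (rounded; train receives the remainder)."""
    if n < 3:
        raise ValueError(f"dataset of {n} objects too small to split")
    total = sum(SPLIT_WEIGHTS.values())
    n_val = max(1, int(round(n * SPLIT_WEIGHTS["val"] / total)))
    n_test = max(1, int(round(n * SPLIT_WEIGHTS["test"] / total)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError(f"dataset of {n} objects too small to split")
    idx = np.arange(n)
    return {
        "train": idx[:n_train],
        "val": idx[n_train : n_train + n_val],
        "test": idx[n_train + n_val :],
    }


def generate_dataset(
    objects: list[AmplitudeObject],
    cfg: OpticalConfig,
    d1: DiffuserSpec | None = None,
    d2: DiffuserSpec | None = None,
    master_seed: int = 0,
    d_mid: DiffuserSpec | None = None,
) -> list[SpecklePair]:
    """Render one SpecklePair per object through frozen diffuser screens.

    The diffuser realizations depend only on the DiffuserSpec seeds (one
    physical diffuser for the whole dataset and for any paired condition
    sharing the specs); ``master_seed`` drives only the optional camera shot
    noise.  Split assignment (train/val/test) is recorded per pair.
    """
    if not objects:
        raise ValueError("object list is empty")
    screens: dict = {}
    rng = np.random.default_rng(master_seed)
    splits = split_indices(len(objects))
    split_of = {}
    for name, idx in splits.items():
        for i in idx:
            split_of[int(i)] = name
    pairs = []
    for i, obj in enumerate(objects):
        pattern = to_slm_pattern(obj, cfg.slm_active, cfg.grid)
        fld = image_through_system(pattern, cfg, d1=d1, d2=d2, d_mid=d_mid, _screens=screens)
        img = capture(fld, cfg, rng=rng)
        tgt = truth_on_camera(pattern, cfg)
        cond = {
            "d_mm": cfg.d * 1e3,
            "preset": cfg.preset,
            "d1_seed": None if d1 is None else d1.seed,
            "d2_seed": None if d2 is None else d2.seed,
            "d1_angle": None if d1 is None else d1.diffusion_angle,
            "d2_angle": None if d2 is None else d2.diffusion_angle,
            "master_seed": master_seed,
            "split": split_of[i],
            "index": i,
        }
        pairs.append(SpecklePair(speckle=img, truth=obj, target=tgt, condition=cond))
    return pairs


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def save_dataset(path, pairs: list[SpecklePair], cfg: OpticalConfig) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("speckle", data=np.stack([p.speckle for p in pairs]))
        h5.create_dataset("target", data=np.stack([p.target for p in pairs]))
        h5.create_dataset(
            "truth", data=np.stack([p.truth.pixels for p in pairs]).astype(np.float32)
        )
        h5.create_dataset("labels", data=np.array([p.truth.label for p in pairs]))
        ids = np.array([p.truth.id for p in pairs], dtype=h5py.string_dtype())
        h5.create_dataset("ids", data=ids)
        h5.attrs["config"] = json.dumps(asdict(cfg))
        h5.attrs["conditions"] = json.dumps([p.condition for p in pairs])


def load_dataset(path):
    import h5py

    with h5py.File(path, "r") as h5:
        cfg = OpticalConfig(**json.loads(h5.attrs["config"]))
        conds = json.loads(h5.attrs["conditions"])
        speckle = h5["speckle"][:]
        target = h5["target"][:]
        truth = h5["truth"][:]
        labels = h5["labels"][:]
        ids = [s.decode() if isinstance(s, bytes) else s for s in h5["ids"][:]]
    pairs = [
        SpecklePair(
            speckle=speckle[k],
            truth=AmplitudeObject(
                pixels=truth[k].astype(np.float64), label=int(labels[k]), id=ids[k]
            ),
            target=target[k],
            condition=conds[k],
        )
        for k in range(len(labels))
    ]
    return pairs, cfg
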