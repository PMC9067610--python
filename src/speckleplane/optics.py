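"""Scalar wave optics on a square sampled grid.

Free-space propagation uses the band-limited angular-spectrum method: the
field is decomposed into plane waves, each multiplied by the exact transfer
function exp(i 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2)); evanescent components
are zeroed and spatial frequencies whose transfer-function phase would alias
at the given distance are suppressed, which removes wrap-around artifacts.

Lens-to-focal-plane mappings are provided as exact scaled Fourier transforms
(`focal_fourier`), the standard route for simulating a 4f relay whose
Fourier-plane sampling differs from the object-plane grid by lambda*f/(N*p).
Thin-lens phase masks and hard circular irides are also available as direct
element operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "ComplexField",
    "plane_wave",
    "propagate",
    "apply_lens",
    "apply_iris",
    "focal_fourier",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComplexField:
    """A sampled 2-D complex optical field.

    ``pitch`` is the sample spacing in meters; coordinates are centered so
    that sample (n/2, n/2) sits on the optical axis (n even).
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("field grid must be square")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> float:
        return self.n * self.pitch

    def coords(self):
        """Centered physical coordinates (x, y) of each sample, meters."""
        n = self.n
        ax = (np.arange(n) - n // 2) * self.pitch
        return np.meshgrid(ax, ax, indexing="xy")

    def energy(self) -> float:
        """Total intensity integrated over the grid (area element included)."""
        return float(np.sum(np.abs(self.values) ** 2)) * self.pitch**2


def plane_wave(n: int, pitch: float, wavelength: float, amplitude: float = 1.0) -> ComplexField:
    return ComplexField(
        values=np.full((n, n), amplitude, dtype=np.complex128),
        pitch=pitch,
        wavelength=wavelength,
    )


def propagate(field: ComplexField, distance: float) -> ComplexField:
    """Band-limited angular-spectrum free-space propagation.

    ``distance`` may be negative (back-propagation).  Evanescent components
    are zeroed; the band limit suppresses frequencies that would wrap around
    on the periodic grid at this distance.  The clipped energy fraction is
    logged at debug level.
    """
    if distance == 0.0:
        return field
    n, p, lam = field.n, field.pitch, field.wavelength
    h = _transfer_function(n, p, lam, float(distance))
    spec = np.fft.fft2(field.values)
    e_in = float(np.sum(np.abs(spec) ** 2))
    spec = spec * h
    e_out = float(np.sum(np.abs(spec) ** 2))
    if e_in > 0 and e_out < e_in * (1.0 - 1e-12):
        log.debug(
            "propagate(z=%.3g m): clipped %.3g of spectral energy",
            distance,
            1.0 - e_out / e_in,
        )
    return replace(field, values=np.fft.ifft2(spec))


@lru_cache(maxsize=64)
def _transfer_function(n: int, pitch: float, lam: float, distance: float) -> np.ndarray:
    """Band-limited angular-spectrum transfer function (cached; treat as
    read-only).  Frequencies beyond |f| <= 1/(lam sqrt((2 df z)^2 + 1)) per
    axis are zeroed to suppress wrap-around on the periodic grid."""
    f = np.fft.fftfreq(n, d=pitch)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    kz2 = 1.0 / lam**2 - fx**2 - fy**2
    prop_mask = kz2 > 0.0
    kz = np.sqrt(np.where(prop_mask, kz2, 0.0))
    df = 1.0 / (n * pitch)
    f_lim = 1.0 / (lam * np.sqrt((2.0 * df * abs(distance)) ** 2 + 1.0))
    bmask = (np.abs(fx) <= f_lim) & (np.abs(fy) <= f_lim)
    h = np.where(prop_mask & bmask, np.exp(1j * 2.0 * np.pi * distance * kz), 0.0)
    h.setflags(write=False)
    return h


def apply_lens(field: ComplexField, focal_length: float) -> ComplexField:
    """Thin-lens quadratic phase exp(-i pi (x^2 + y^2) / (lambda f))."""
    if focal_length == 0.0:
        raise ValueError("focal length must be nonzero")
    x, y = field.coords()
    phase = -np.pi * (x**2 + y**2) / (field.wavelength * focal_length)
    return replace(field, values=field.values * np.exp(1j * phase))


def apply_iris(field: ComplexField, diameter: float) -> ComplexField:
    """Hard circular amplitude mask of the given diameter, centered on axis."""
    if diameter <= 0:
        raise ValueError("iris diameter must be positive")
    x, y = field.coords()
    mask = (x**2 + y**2) <= (diameter / 2.0) ** 2
    return replace(field, values=field.values * mask)


def focal_fourier(field: ComplexField, focal_length: float) -> ComplexField:
    """Exact front-focal-plane to back-focal-plane mapping of an ideal lens.

    U_out(u, v) = (1 / (i lambda f)) * FT[U](u / (lambda f), v / (lambda f)),
    evaluated by a centered DFT.  The output pitch becomes
    lambda * f / (n * pitch); total energy is preserved (Parseval).
    """
    if focal_length <= 0:
        raise ValueError("focal length must be positive for a focal relay")
    n, p, lam = field.n, field.pitch, field.wavelength
    ft = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field.values)))
    out = ft * (p**2 / (1j * lam * focal_length))
    new_pitch = lam * focal_length / (n * p)
    return ComplexField(values=out, pitch=new_pitch, wavelength=lam)
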