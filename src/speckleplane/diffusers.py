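"""Thin random phase-screen diffusers.

A diffuser is modelled as a multiplicative phase map: a Gaussian random field
smoothed to a correlation length l_c and scaled to a phase standard deviation
of 2*pi (fully developed scattering, no ballistic component).  The
correlation length is calibrated numerically so that the far-field intensity
of a plane wave through the screen has the requested full width at half
maximum (the diffuser's nominal "diffusion angle").

Target angles too small to realize at that phase depth on the given aperture
fall back to a weak screen (phase std scaled down linearly, correlation
length clamped to a quarter of the aperture); in the limit of vanishing angle
this degenerates to an essentially flat screen, the no-diffuser limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "DiffuserSpec",
    "PhaseScreen",
    "make_phase_screen",
    "calibrate_screen",
    "far_field_fwhm",
    "nyquist_angle_deg",
]

FULL_PHASE_STD = 2.0 * np.pi  # phase std of a fully developed screen, radians


@dataclass(frozen=True)
class DiffuserSpec:
    """Nominal diffuser: far-field full-width diffusion angle plus a seed."""

    diffusion_angle: float  # degrees, full width at half maximum
    seed: int
    name: str = "diffuser"

    def __post_init__(self) -> None:
        if not (0.0 < self.diffusion_angle < 180.0):
            raise ValueError("diffusion angle must be in (0, 180) degrees")


@dataclass(frozen=True)
class PhaseScreen:
    """A frozen realization of a diffuser on a specific grid."""

    phase: np.ndarray  # radians
    pitch: float  # meters
    realized_angle: float  # degrees, measured far-field FWHM

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(1j * self.phase)


def nyquist_angle_deg(pitch: float, wavelength: float) -> float:
    """Largest full diffusion angle representable at this sample pitch."""
    s = min(1.0, wavelength / (2.0 * pitch))
    return float(np.degrees(np.arcsin(s)))


def _smoothed_unit_field(grid: int, pitch: float, corr_length: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((grid, grid))
    sigma_px = max(corr_length / pitch, 1e-6)
    sm = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    sd = sm.std()
    if sd == 0.0:
        return np.zeros_like(sm)
    return sm / sd


def _marginal_fwhm_bins(marginal: np.ndarray) -> float:
    """FWHM of a centered 1-D profile, in bins, by interpolated half-maximum
    crossings around the (smoothed) peak."""
    m = ndimage.gaussian_filter1d(marginal.astype(np.float64), 2.0, mode="wrap")
    peak = m.max()
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    k0 = int(m.argmax())
    lo = k0
    while lo > 0 and m[lo - 1] > half:
        lo -= 1
    hi = k0
    while hi < m.size - 1 and m[hi + 1] > half:
        hi += 1
    # interpolate the crossings just outside [lo, hi]
    left = lo - (m[lo] - half) / (m[lo] - m[lo - 1]) if lo > 0 else 0.0
    right = hi + (m[hi] - half) / (m[hi] - m[hi + 1]) if hi < m.size - 1 else m.size - 1.0
    return float(right - left)


def far_field_fwhm(phase: np.ndarray, pitch: float, wavelength: float) -> float:
    """FWHM (degrees) of the far-field intensity envelope of a plane wave
    through the screen.

    The single-realization far field is fully developed speckle, so the
    envelope width is estimated from the axis marginals of the power
    spectrum of exp(i*phase) (each marginal averages a full grid column of
    speckle; for the Gaussian-like envelope these screens produce, the
    marginal FWHM equals the radial-envelope FWHM).  The two axis estimates
    are averaged.
    """
    n = phase.shape[0]
    spec = np.fft.fftshift(np.abs(np.fft.fft2(np.exp(1j * phase))) ** 2)
    fwhm_bins = 0.5 * (
        _marginal_fwhm_bins(spec.sum(axis=0)) + _marginal_fwhm_bins(spec.sum(axis=1))
    )
    half_width_sin = 0.5 * fwhm_bins / (n * pitch) * wavelength
    if half_width_sin >= 1.0:
        return 180.0
    return float(2.0 * np.degrees(np.arcsin(half_width_sin)))


@lru_cache(maxsize=256)
def _fwhm_at(corr_length, grid, pitch, wavelength, seed, phase_std):
    field = _smoothed_unit_field(grid, pitch, corr_length, seed)
    return far_field_fwhm(phase_std * field, pitch, wavelength)


@lru_cache(maxsize=128)
def calibrate_screen(
    target_angle: float,
    grid: int,
    pitch: float,
    wavelength: float,
    seed: int,
    phase_std: float = FULL_PHASE_STD,
    rel_tol: float = 0.05,
) -> float:
    """Bisection over correlation length until the simulated far-field FWHM
    matches ``target_angle`` within ``rel_tol`` relative.  Returns the
    calibrated correlation length in meters.  Monotone: smaller correlation
    length gives a larger diffusion angle.
    """
    if target_angle > nyquist_angle_deg(pitch, wavelength):
        raise ValueError(
            f"diffusion angle {target_angle:g} deg unresolvable at pitch "
            f"{pitch * 1e6:g} um (Nyquist {nyquist_angle_deg(pitch, wavelength):.2f} deg); "
            "use the desk preset's scaled angles"
        )
    lo = pitch  # small correlation -> wide angle
    hi = grid * pitch / 4.0  # large correlation -> narrow angle
    a_lo = _fwhm_at(lo, grid, pitch, wavelength, seed, phase_std)
    a_hi = _fwhm_at(hi, grid, pitch, wavelength, seed, phase_std)
    if target_angle >= a_lo:
        return lo
    if target_angle <= a_hi:
        return hi
    for _ in range(50):
        mid = np.sqrt(lo * hi)  # bisect in log space
        a_mid = _fwhm_at(mid, grid, pitch, wavelength, seed, phase_std)
        if abs(a_mid - target_angle) <= rel_tol * target_angle:
            return float(mid)
        if a_mid > target_angle:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"screen calibration did not converge in 50 iterations; "
        f"last bracket [{lo:.3e}, {hi:.3e}] m for target {target_angle:g} deg"
    )


def make_phase_screen(
    spec: DiffuserSpec, grid: int, pitch: float, wavelength: float
) -> PhaseScreen:
    """Realize a diffuser as a frozen random phase screen on the given grid.

    Deterministic given ``spec.seed``.  Raises if the requested angle exceeds
    the Nyquist angle asin(lambda / (2 * pitch)) of the grid.
    """
    if spec.diffusion_angle > nyquist_angle_deg(pitch, wavelength):
        raise ValueError(
            f"diffusion angle {spec.diffusion_angle:g} deg unresolvable at this "
            f"pitch (Nyquist {nyquist_angle_deg(pitch, wavelength):.2f} deg); "
            "use the desk preset's scaled angles"
        )
    l_max = grid * pitch / 4.0
    a_min = _fwhm_at(l_max, grid, pitch, wavelength, spec.seed, FULL_PHASE_STD)
    if spec.diffusion_angle > a_min:
        corr = calibrate_screen(spec.diffusion_angle, grid, pitch, wavelength, spec.seed)
        phase_std = FULL_PHASE_STD
    else:
        # weaker than realizable at full depth: scale the phase down linearly
        corr = l_max
        phase_std = FULL_PHASE_STD * spec.diffusion_angle / max(a_min, 1e-12)
    phase = phase_std * _smoothed_unit_field(grid, pitch, corr, spec.seed)
    realized = far_field_fwhm(phase, pitch, wavelength)
    return PhaseScreen(phase=phase, pitch=pitch, realized_angle=realized)
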