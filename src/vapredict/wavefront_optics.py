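"""Wavefront construction, pupil functions and point-spread functions.

The eye's monochromatic aberrations are described by a Zernike expansion of
the wavefront error over a circular pupil, using the OSA/ANSI single-index
convention with unit-variance normalization (ANSI Z80.28): index ``j`` maps
to radial order ``n`` and azimuthal frequency ``m`` through
``n = ceil((-3 + sqrt(9 + 8 j)) / 2)`` and ``m = 2 j - n (n + 2)``.

Coefficients are expressed in micrometres for a fixed pupil radius (default
1.5 mm, i.e. the standardized 3 mm pupil that clinical aberrometers report).
From the wavefront the module builds the complex pupil function, including a
Stiles-Crawford amplitude apodization, and computes the incoherent
point-spread function (PSF) by Fourier propagation.

It also implements the clinically motivated coefficient manipulations used
throughout the toolkit: zeroing the second-order terms to emulate best
spectacle correction, shifting the defocus term ``c_2^0`` to emulate
trial-lens defocus, and the sphero-cylinder spherical equivalent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "N_COEFFS",
    "ZernikeSet",
    "PupilGrid",
    "PupilFunction",
    "PointSpreadFunction",
    "osa_to_nm",
    "zernike_polynomial",
    "wavefront",
    "pupil_function",
    "psf_from_pupil",
    "diopter_to_z20",
    "apply_correction",
    "apply_defocus_condition",
    "spherical_equivalent",
    "vergence_correction",
    "strehl_ratio",
]

#: Number of coefficients carried per eye (OSA j = 0..35, up to 7th order).
N_COEFFS = 36

#: Default pupil radius in mm (standardized 3 mm pupil diameter).
DEFAULT_PUPIL_RADIUS_MM = 1.5

#: Default simulation wavelength in nm (photopic peak).
DEFAULT_WAVELENGTH_NM = 555.0

#: Default Stiles-Crawford apodization parameter, mm^-2.
DEFAULT_RHO_SC = 0.05

# OSA indices of the second-order terms.
J_ASTIG_OBLIQUE = 3   # Z_2^-2
J_DEFOCUS = 4         # Z_2^0
J_ASTIG_VERTICAL = 5  # Z_2^+2


@dataclass(frozen=True)
class ZernikeSet:
    """Per-eye Zernike coefficients with their optical context.

    Parameters
    ----------
    coeffs
        36 OSA-indexed coefficients (j = 0..35) in micrometres.
    pupil_radius
        Pupil radius in mm the coefficients refer to.
    wavelength
        Simulation wavelength in nm.
    """

    coeffs: np.ndarray
    pupil_radius: float = DEFAULT_PUPIL_RADIUS_MM
    wavelength: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (N_COEFFS,):
            raise ValueError(f"expected {N_COEFFS} coefficients, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("Zernike coefficients must all be finite")
        if not self.pupil_radius > 0:
            raise ValueError("pupil_radius must be positive")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        object.__setattr__(self, "coeffs", c)

    @classmethod
    def zeros(cls, pupil_radius: float = DEFAULT_PUPIL_RADIUS_MM,
              wavelength: float = DEFAULT_WAVELENGTH_NM) -> "ZernikeSet":
        return cls(np.zeros(N_COEFFS), pupil_radius, wavelength)

    def with_coeffs(self, coeffs: Sequence[float]) -> "ZernikeSet":
        return replace(self, coeffs=np.asarray(coeffs, dtype=float))


@dataclass(frozen=True)
class PupilGrid:
    """Sampling geometry for pupil-plane fields and their PSFs.

    The pupil disc is inscribed with a one-sample margin: sample ``n/2`` is
    the exact disc centre and the disc radius spans ``n/2 - 1`` samples, so
    the sampled aperture is exactly invariant under 90-degree index
    rotations about the centre sample.
    """

    n: int = 256
    pad_factor: int = 3

    def __post_init__(self) -> None:
        if self.n < 64 or self.n % 2:
            raise ValueError("n must be an even integer >= 64")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    @property
    def n_padded(self) -> int:
        return self.n * self.pad_factor

    def unit_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized pupil coordinates (x, y) with the disc edge at 1."""
        k = np.arange(self.n, dtype=float)
        ax = (k - self.n / 2) / (self.n / 2 - 1)
        return np.meshgrid(ax, ax, indexing="xy")

    def sample_spacing_mm(self, pupil_radius_mm: float) -> float:
        return pupil_radius_mm / (self.n / 2 - 1)

    def psf_pixels_per_degree(self, pupil_radius_mm: float, wavelength_nm: float) -> float:
        """Angular sampling density of the PSF plane, pixels per degree."""
        dx_mm = self.sample_spacing_mm(pupil_radius_mm)
        lam_mm = wavelength_nm * 1e-6
        pixel_rad = lam_mm / (self.n_padded * dx_mm)
        return math.pi / 180.0 / pixel_rad


@dataclass
class PupilFunction:
    """Complex pupil-plane field with its aperture mask."""

    field: np.ndarray
    mask: np.ndarray
    grid: PupilGrid
    pupil_radius: float
    wavelength: float
    rho_sc: float = DEFAULT_RHO_SC


@dataclass
class PointSpreadFunction:
    """Non-negative PSF raster with angular pixel scale."""

    data: np.ndarray
    pixels_per_degree: float
    normalized: bool = True

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("PSF values must be non-negative")


def osa_to_nm(j: int) -> tuple[int, int]:
    """Map an OSA single index to the (n, m) radial/azimuthal pair."""
    if not 0 <= j < N_COEFFS:
        raise IndexError(f"OSA index must be in [0, {N_COEFFS - 1}], got {j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho, dtype=float)
    for s in range((n - m) // 2 + 1):
        coef = ((-1) ** s * math.factorial(n - s)
                / (math.factorial(s)
                   * math.factorial((n + m) // 2 - s)
                   * math.factorial((n - m) // 2 - s)))
        out = out + coef * rho ** (n - 2 * s)
    return out


def zernike_polynomial(j: int, rho, theta):
    """Evaluate the unit-variance Zernike polynomial Z_j at (rho, theta).

    Normalization follows ANSI Z80.28: sqrt(2(n+1)) for m != 0 and
    sqrt(n+1) for m == 0, so each mode has unit variance over the disc.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    n, m = osa_to_nm(j)
    norm = math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1)
    r = _radial_poly(n, m, rho)
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(theta)
    val = norm * r * ang
    return float(val) if val.ndim == 0 else val


def wavefront(zset: ZernikeSet, grid: PupilGrid) -> np.ndarray:
    """Wavefront height map W(x, y) in micrometres over the pupil grid.

    W = sum_j c_j Z_j(rho, theta) inside the unit disc, zero outside.
    """
    x, y = grid.unit_coords()
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    inside = rho <= 1.0
    rho_in = np.where(inside, rho, 0.0)
    w = np.zeros_like(rho)
    for j, c in enumerate(zset.coeffs):
        if c != 0.0:
            w += c * zernike_polynomial(j, rho_in, theta)
    w[~inside] = 0.0
    return w


def pupil_function(zset: ZernikeSet, grid: PupilGrid | None = None,
                   rho_sc: float = DEFAULT_RHO_SC) -> PupilFunction:
    """Complex pupil function with Stiles-Crawford apodization.

    P = A(r) exp(i 2 pi W / lambda) inside the disc, zero outside, with
    A(r) = 10^(-rho_sc r_mm^2 / 2) describing the reduced luminous
    efficiency of marginal rays.
    """
    if rho_sc < 0:
        raise ValueError("rho_sc must be >= 0")
    grid = grid or PupilGrid()
    x, y = grid.unit_coords()
    rho = np.hypot(x, y)
    inside = rho <= 1.0
    w_um = wavefront(zset, grid)
    lam_um = zset.wavelength * 1e-3
    r_mm = rho * zset.pupil_radius
    amplitude = 10.0 ** (-rho_sc * r_mm ** 2 / 2.0)
    field = amplitude * np.exp(1j * 2.0 * np.pi * w_um / lam_um)
    field[~inside] = 0.0
    return PupilFunction(field=field, mask=inside, grid=grid,
                         pupil_radius=zset.pupil_radius,
                         wavelength=zset.wavelength, rho_sc=rho_sc)


def psf_from_pupil(p: PupilFunction, normalize: bool = True) -> PointSpreadFunction:
    """Incoherent PSF as the squared magnitude of the pupil's Fourier transform.

    The pupil field is zero-padded by the grid's pad factor before the FFT so
    the diffraction core is resolved; the result is centred and, by default,
    normalized to unit sum.
    """
    grid = p.grid
    if grid.pad_factor < 2:
        warnings.warn("pad_factor < 2 may undersample the diffraction core",
                      stacklevel=2)
    n_pad = grid.n_padded
    padded = np.zeros((n_pad, n_pad), dtype=complex)
    padded[:grid.n, :grid.n] = p.field
    psf = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2
    if normalize:
        psf /= psf.sum()
    ppd = grid.psf_pixels_per_degree(p.pupil_radius, p.wavelength)
    return PointSpreadFunction(data=psf, pixels_per_degree=ppd,
                               normalized=normalize)


def strehl_ratio(zset: ZernikeSet, grid: PupilGrid | None = None,
                 rho_sc: float = DEFAULT_RHO_SC) -> float:
    """Peak of the aberrated PSF over the peak of the aberration-free PSF."""
    grid = grid or PupilGrid()
    psf = psf_from_pupil(pupil_function(zset, grid, rho_sc), normalize=False)
    ref = psf_from_pupil(
        pupil_function(ZernikeSet.zeros(zset.pupil_radius, zset.wavelength),
                       grid, rho_sc),
        normalize=False)
    return float(psf.data.max() / ref.data.max())


def diopter_to_z20(d: float, pupil_radius: float = DEFAULT_PUPIL_RADIUS_MM) -> float:
    """Convert a defocus power in diopters to a c_2^0 increment in micrometres.

    c = d r^2 / (4 sqrt(3)) with r the pupil radius in mm; positive d
    (myopic wavefront defocus) gives a positive coefficient.
    """
    if not pupil_radius > 0:
        raise ValueError("pupil_radius must be positive")
    return d * pupil_radius ** 2 / (4.0 * math.sqrt(3.0))


def apply_correction(zset: ZernikeSet) -> ZernikeSet:
    """Best spectacle correction: zero the three second-order terms.

    Z_2^-2 (j=3), Z_2^0 (j=4) and Z_2^+2 (j=5) are set to zero; all other
    coefficients are untouched.
    """
    c = zset.coeffs.copy()
    c[[J_ASTIG_OBLIQUE, J_DEFOCUS, J_ASTIG_VERTICAL]] = 0.0
    return zset.with_coeffs(c)


def apply_defocus_condition(zset: ZernikeSet, delta_d: float) -> ZernikeSet:
    """Trial-lens defocus of ``delta_d`` D relative to best correction.

    Both second-order astigmatism terms are zeroed and c_2^0 is set to the
    increment corresponding to ``delta_d`` over the corrected baseline,
    matching clinical defocus curves that start from best correction.
    """
    corrected = apply_correction(zset)
    c = corrected.coeffs.copy()
    c[J_DEFOCUS] = diopter_to_z20(delta_d, zset.pupil_radius)
    return zset.with_coeffs(c)


def spherical_equivalent(sphere: float, cylinder: float) -> float:
    """Spherical equivalent SE = S + C/2 in diopters."""
    if not (np.isfinite(sphere) and np.isfinite(cylinder)):
        raise ValueError("sphere and cylinder must be finite")
    return sphere + cylinder / 2.0


def vergence_correction(distance_m: float) -> float:
    """Vergence correction -1/d (D) for a chart at finite distance d (m)."""
    if not distance_m > 0:
        raise ValueError("distance must be positive")
    return -1.0 / distance_m
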