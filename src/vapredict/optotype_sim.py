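"""Sloan optotype rendering and the end-to-end aberrated-optotype pipeline.

Letters are drawn dark-on-light on the classic Sloan 5x5 grid (stroke width
= 1/5 of letter height) as programmatic geometric glyphs, sized by the
logMAR convention: a 0.0 logMAR letter subtends 5 arcmin, and each 0.1
logMAR step scales the angle by 10^0.1. The default canvas is 224 x 224
pixels spanning 1 degree of visual field (224 pixels/degree), so the
largest protocol letter (1.0 logMAR, 50 arcmin) fits with margin.

``simulate_optotype`` chains the full simulation: render a sharp letter,
convolve with the subject's PSF, band-limit to the retinal sampling rate,
filter by the neural transfer function, and add Gaussian neural noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .neural_filter import (AgeContext, SCSFParams, add_gaussian_noise,
                            apply_ntf_filter, retinal_sampling)
from .wavefront_optics import (PupilGrid, ZernikeSet, psf_from_pupil,
                               pupil_function)

__all__ = [
    "SLOAN_LETTERS",
    "OptotypeImage",
    "OptotypeSpec",
    "SimConfig",
    "letter_height_pixels",
    "render_sloan",
    "psf_kernel_for",
    "convolve_psf",
    "simulate_optotype",
    "generate_image_set",
    "split_counts",
]

#: The ten Sloan optotype letters used on ETDRS charts.
SLOAN_LETTERS = ("C", "D", "H", "K", "N", "O", "R", "S", "V", "Z")

CANVAS_SIDE = 224
DEFAULT_PPD = 224.0

#: Protocol VA levels, 1.0 down to -0.3 logMAR in 0.1 steps.
PROTOCOL_LEVELS = tuple(round(1.0 - 0.1 * k, 2) for k in range(14))


@dataclass
class OptotypeImage:
    """Square intensity raster on [0, 1] with its angular pixel scale."""

    data: np.ndarray
    pixels_per_degree: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("optotype image must be square")
        if d.min() < -1e-9 or d.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be positive")
        self.data = d


@dataclass(frozen=True)
class OptotypeSpec:
    """A letter at a logMAR size, dark-on-light by default."""

    letter: str
    logmar: float
    polarity: str = "dark-on-light"

    def __post_init__(self) -> None:
        if self.letter not in SLOAN_LETTERS:
            raise ValueError(f"letter must be one of {SLOAN_LETTERS}, got {self.letter!r}")


def letter_height_pixels(logmar: float, ppd: float = DEFAULT_PPD,
                         canvas: int = CANVAS_SIDE) -> int:
    """Letter height in pixels for a logMAR size at a given pixel scale.

    A 0.0 logMAR letter subtends 5 arcmin; height = round(5 * 10^logmar
    / 60 * ppd).
    """
    if not ppd > 0:
        raise ValueError("ppd must be positive")
    h = int(round(5.0 * 10.0 ** logmar / 60.0 * ppd))
    if h > canvas:
        raise ValueError(f"letter height {h}px exceeds the {canvas}px canvas")
    return h


# ---------------------------------------------------------------------------
# Glyph geometry. Each glyph is a boolean ink-mask function of normalized
# letter-box coordinates u (rightward), v (downward) in [0, 1], with the
# Sloan stroke width t = 1/5. These are geometric approximations on the
# 5x5 grid, not a copy of any font file.

_T = 0.2  # stroke width in letter-box units


def _bar(u, v, u0, u1, v0, v1):
    return (u >= u0) & (u <= u1) & (v >= v0) & (v <= v1)


def _ring(u, v, cu, cv, ro, ri):
    r = np.hypot(u - cu, v - cv)
    return (r <= ro) & (r > ri)


def _seg(u, v, a, b, t=_T):
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    s = np.clip(((u - ax) * dx + (v - ay) * dy) / L2, 0.0, 1.0)
    return np.hypot(u - (ax + s * dx), v - (ay + s * dy)) <= t / 2.0


def _glyph_C(u, v):
    gap = _T / 2.0
    return _ring(u, v, 0.5, 0.5, 0.5, 0.3) & ~((u > 0.5) & (np.abs(v - 0.5) < gap))


def _glyph_O(u, v):
    return _ring(u, v, 0.5, 0.5, 0.5, 0.3)


def _glyph_D(u, v):
    outer = ((u <= 0.5) & (v >= 0) & (v <= 1)) | (np.hypot(u - 0.5, v - 0.5) <= 0.5)
    inner = ((u >= _T) & (u <= 0.5) & (v >= _T) & (v <= 1 - _T)) | \
            ((u > 0.5) & (np.hypot(u - 0.5, v - 0.5) <= 0.3))
    return outer & ~inner & (u >= 0)


def _glyph_H(u, v):
    return (_bar(u, v, 0.0, _T, 0.0, 1.0) | _bar(u, v, 1 - _T, 1.0, 0.0, 1.0)
            | _bar(u, v, _T, 1 - _T, 0.4, 0.6))


def _glyph_K(u, v):
    return (_bar(u, v, 0.0, _T, 0.0, 1.0)
            | _seg(u, v, (_T, 0.5), (1.0 - _T / 2, _T / 2))
            | _seg(u, v, (_T, 0.5), (1.0 - _T / 2, 1.0 - _T / 2)))


def _glyph_N(u, v):
    return (_bar(u, v, 0.0, _T, 0.0, 1.0) | _bar(u, v, 1 - _T, 1.0, 0.0, 1.0)
            | _seg(u, v, (_T / 2, _T / 2), (1 - _T / 2, 1 - _T / 2)))


def _glyph_R(u, v):
    bubble = (_bar(u, v, _T, 0.7, 0.0, _T) | _bar(u, v, _T, 0.7, 0.4, 0.6)
              | (_ring(u, v, 0.7, 0.3, 0.3, 0.1) & (u >= 0.7)))
    leg = _seg(u, v, (0.55, 0.6), (1.0 - _T / 2, 1.0 - _T / 2))
    return _bar(u, v, 0.0, _T, 0.0, 1.0) | bubble | leg


def _glyph_S(u, v):
    top = _ring(u, v, 0.5, 0.3, 0.3, 0.1) & ~((u > 0.5) & (v > 0.3))
    bot = _ring(u, v, 0.5, 0.7, 0.3, 0.1) & ~((u < 0.5) & (v < 0.7))
    return top | bot


def _glyph_V(u, v):
    return (_seg(u, v, (_T / 2, _T / 2), (0.5, 1.0 - _T / 2))
            | _seg(u, v, (1 - _T / 2, _T / 2), (0.5, 1.0 - _T / 2)))


def _glyph_Z(u, v):
    return (_bar(u, v, 0.0, 1.0, 0.0, _T) | _bar(u, v, 0.0, 1.0, 1 - _T, 1.0)
            | _seg(u, v, (1 - _T / 2, _T), (_T / 2, 1 - _T)))


_GLYPHS: dict[str, Callable] = {
    "C": _glyph_C, "D": _glyph_D, "H": _glyph_H, "K": _glyph_K,
    "N": _glyph_N, "O": _glyph_O, "R": _glyph_R, "S": _glyph_S,
    "V": _glyph_V, "Z": _glyph_Z,
}


def render_sloan(spec: OptotypeSpec, ppd: float = DEFAULT_PPD,
                 canvas: int = CANVAS_SIDE) -> OptotypeImage:
    """Render a centred Sloan letter; background 1.0, ink 0.0."""
    h = letter_height_pixels(spec.logmar, ppd, canvas)
    k = np.arange(h, dtype=float) + 0.5
    u, v = np.meshgrid(k / h, k / h, indexing="xy")
    mask = _GLYPHS[spec.letter](u, v)
    img = np.ones((canvas, canvas))
    r0 = (canvas - h) // 2
    box = img[r0:r0 + h, r0:r0 + h]
    box[mask] = 0.0
    return OptotypeImage(data=img, pixels_per_degree=ppd,
                         meta={"letter": spec.letter, "logmar": spec.logmar,
                               "stage": "sharp"})


# ---------------------------------------------------------------------------
# Simulation pipeline


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the optotype-simulation pipeline.

    ``ppd`` is the canvas angular sampling (pixels/degree); the PSF is
    resampled onto this scale before convolution. ``retina_spd`` is the
    retinal sampling density in samples/degree (None disables the stage);
    ``noise_variance`` is on the [0, 1] intensity scale.
    """

    canvas: int = CANVAS_SIDE
    ppd: float = DEFAULT_PPD
    grid_n: int = 256
    pad_factor: int = 3
    rho_sc: float = 0.05
    retina_spd: float | None = 120.0
    noise_variance: float = 0.01
    noise_seed: int | None = 0
    ntf_form: str = "sum"
    scsf: SCSFParams = field(default_factory=SCSFParams)


def psf_kernel_for(zset: ZernikeSet, config: SimConfig | None = None) -> np.ndarray:
    """Unit-sum PSF kernel resampled to the canvas pixel scale.

    The PSF is computed at its natural Fourier sampling and bilinearly
    resampled onto the canvas's pixels-per-degree, then cropped to the
    smallest centred window holding all but 1e-9 of its mass.
    """
    config = config or SimConfig()
    grid = PupilGrid(n=config.grid_n, pad_factor=config.pad_factor)
    psf = psf_from_pupil(pupil_function(zset, grid, config.rho_sc))
    factor = config.ppd / psf.pixels_per_degree
    data = ndimage.zoom(psf.data, factor, order=1, grid_mode=True,
                        mode="grid-constant")
    data = np.clip(data, 0.0, None)
    data /= data.sum()
    side = data.shape[0]
    c = side // 2
    # smallest centred odd window capturing >= 1 - 1e-9 of the mass
    max_half = min(c, side - 1 - c, config.canvas // 2)
    half = max_half
    for w in range(2, max_half + 1):
        m = data[c - w:c + w + 1, c - w:c + w + 1].sum()
        if m >= 1.0 - 1e-9:
            half = w
            break
    kern = data[c - half:c + half + 1, c - half:c + half + 1].copy()
    kern /= kern.sum()
    return kern


def convolve_psf(img: OptotypeImage, kernel: np.ndarray) -> OptotypeImage:
    """Linear convolution with background padding (background = 1.0).

    The image is embedded in a background-valued frame wide enough that the
    kernel never wraps, convolved, and cropped back, avoiding periodic
    ghosting at the canvas edges.
    """
    half = kernel.shape[0] // 2
    padded = np.pad(img.data, half, mode="constant", constant_values=1.0)
    out = signal.fftconvolve(padded, kernel, mode="same")
    out = out[half:half + img.data.shape[0], half:half + img.data.shape[1]]
    return OptotypeImage(data=np.clip(out, 0.0, 1.0),
                         pixels_per_degree=img.pixels_per_degree,
                         meta={**img.meta, "stage": "optical"})


def simulate_optotype(zset: ZernikeSet, ctx: AgeContext, spec: OptotypeSpec,
                      config: SimConfig | None = None,
                      keep_stages: bool = False,
                      _kernel: np.ndarray | None = None):
    """Run the full pipeline: render, blur, retinal sampling, NTF, noise.

    Returns the final "neural image"; with ``keep_stages=True`` returns
    ``(image, stages)`` where ``stages`` maps stage names to intermediates.
    A precomputed PSF kernel can be passed to amortize the optical stage
    across letters of the same eye.
    """
    config = config or SimConfig()
    stages: dict[str, OptotypeImage] = {}
    img = render_sloan(spec, config.ppd, config.canvas)
    stages["sharp"] = img
    kernel = _kernel if _kernel is not None else psf_kernel_for(zset, config)
    img = convolve_psf(img, kernel)
    stages["optical"] = img
    if config.retina_spd is not None:
        img = retinal_sampling(img, config.retina_spd)
        stages["retina"] = img
    img = apply_ntf_filter(img, ctx, config.scsf, config.ntf_form)
    stages["ntf"] = img
    if config.noise_variance > 0:
        img = add_gaussian_noise(img, config.noise_variance, config.noise_seed)
        stages["noise"] = img
    img.meta.update({"letter": spec.letter, "logmar": spec.logmar})
    if keep_stages:
        return img, stages
    return img


def split_counts(n: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """Train/val/test row counts for a dataset of n rows."""
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    return n_train, n_val, n - n_train - n_val


def generate_image_set(cohort: pd.DataFrame,
                       va_levels=PROTOCOL_LEVELS,
                       letters_per_level: int = 5,
                       seed: int = 0,
                       labeler: Callable | None = None,
                       fractions=(0.70, 0.15, 0.15)) -> pd.DataFrame:
    """Build the labelled image manifest: one row per (eye, level, letter).

    ``cohort`` must carry one row per eye with at least subject/eye ids,
    ``age`` and Zernike columns. Letters are drawn uniformly at random
    without replacement within each 5-letter line (seeded). ``labeler`` is
    called as ``labeler(row, letter, logmar, rng)`` and must return a
    recognized flag; rows are flagged with label -1 when no labeler (or
    clinical response) is available. Rows are assigned to train/val/test
    splits at the given fractions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, eye_row in cohort.iterrows():
        for level in va_levels:
            letters = list(rng.choice(SLOAN_LETTERS, size=letters_per_level,
                                      replace=False))
            for letter in letters:
                if labeler is not None:
                    label = int(labeler(eye_row, letter, level, rng))
                else:
                    label = -1
                rows.append({
                    "subject_id": eye_row.get("subject_id", ""),
                    "eye": eye_row.get("eye", ""),
                    "letter": letter,
                    "logmar": level,
                    "label": label,
                })
    manifest = pd.DataFrame(rows)
    n = len(manifest)
    n_train, n_val, n_test = split_counts(n, fractions)
    split = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng.shuffle(split)
    manifest["split"] = split
    if (manifest["label"] == -1).any() and labeler is None:
        warnings.warn("manifest rows lack recognition labels; flagged with -1",
                      stacklevel=2)
    return manifest
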