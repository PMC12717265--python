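"""Neural-stage filtering: contrast sensitivity, mean OTF and neural noise.

After optical blurring, the simulation pipeline models post-optical
processing with a radially symmetric neural transfer function (NTF), the
ratio of a standard contrast sensitivity function (SCSF) to a mean optical
transfer function (MOTF) that carries an age factor, followed by retinal
sampling and additive Gaussian neural noise.

The SCSF is a difference of two sech lobes,

    SCSF(f) = psi sech[(f / (phi f0))^p] - a sech[f / (phi f1)],

with frequency f in cycles/degree. The MOTF combines four exponential
terms, two of which are divided by ``1 + AF/7`` where ``AF = 1 +
(age/70)^4`` is an age factor; it is published as a plain four-term sum,
but the paired weights (0.426 + 0.574 and 0.123 + 0.877, each summing to
one) suggest a product of two bracketed factors, so both forms are
available ("sum" is the default for fidelity to the printed expression).
The NTF used for image filtering is normalized to unit gain at zero
frequency, so the form choice affects only the filter's shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SCSFParams",
    "AgeContext",
    "scsf",
    "age_factor",
    "motf",
    "ntf",
    "ntf_filter_grid",
    "apply_ntf_filter",
    "retinal_sampling",
    "add_gaussian_noise",
]

#: Default retinal sampling density, samples/degree (foveal cone spacing).
DEFAULT_SAMPLES_PER_DEGREE = 120.0


@dataclass(frozen=True)
class SCSFParams:
    """Standard contrast sensitivity function parameters.

    Defaults are the published fit: gain psi, high- and low-frequency scale
    frequencies f0 and f1 (cycles/degree), low-frequency lobe weight a,
    exponent p and overall frequency scale phi.
    """

    psi: float = 373.08
    f0: float = 4.1726
    f1: float = 1.3625
    a: float = 0.8493
    p: float = 0.7786
    phi: float = 1.0

    def __post_init__(self) -> None:
        if not (self.psi > 0 and self.f0 > self.f1 > 0 and self.a >= 0
                and self.p > 0 and self.phi > 0):
            raise ValueError("invalid SCSF parameters")


@dataclass(frozen=True)
class AgeContext:
    """Subject age with the normalization constant of the age factor."""

    age: float
    d_norm: float = 70.0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if not self.d_norm > 0:
            raise ValueError("d_norm must be positive")


def _sech(x):
    return 1.0 / np.cosh(x)


def scsf(f, params: SCSFParams | None = None):
    """Standard contrast sensitivity at frequency f (cycles/degree)."""
    params = params or SCSFParams()
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    val = (params.psi * _sech((f / (params.phi * params.f0)) ** params.p)
           - params.a * _sech(f / (params.phi * params.f1)))
    return float(val) if val.ndim == 0 else val


def age_factor(ctx: AgeContext) -> float:
    """AF = 1 + (age / d_norm)^4, dimensionless and >= 1."""
    return 1.0 + (ctx.age / ctx.d_norm) ** 4


def motf(f, ctx: AgeContext, form: str = "sum"):
    """Mean optical transfer function at frequency f (cycles/degree).

    ``form="sum"`` evaluates the four-term expression as printed;
    ``form="product"`` multiplies the two bracketed weight pairs.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    af = age_factor(ctx)
    den = 1.0 + af / 7.0
    t1 = 0.426 * np.exp(-0.028 * f) / den
    t2 = 0.574 * np.exp(-0.37 * f)
    t3 = 0.123 * np.exp(-37.0 * f) / den
    t4 = 0.877 * np.exp(-360.0 * f)
    if form == "sum":
        val = t1 + t2 + t3 + t4
    elif form == "product":
        val = (t1 + t2) * (t3 + t4)
    else:
        raise ValueError(f"form must be 'sum' or 'product', got {form!r}")
    return float(val) if val.ndim == 0 else val


def ntf(f, ctx: AgeContext, params: SCSFParams | None = None,
        form: str = "sum"):
    """Neural transfer function SCSF(f) / MOTF(f).

    The MOTF is clamped at 1e-12 before division; with the default forms
    this only matters at frequencies far outside the visible band.
    """
    s = np.asarray(scsf(f, params), dtype=float)
    m = np.asarray(motf(f, ctx, form), dtype=float)
    clipped = m < 1e-12
    if np.any(clipped):
        warnings.warn("MOTF clamped at 1e-12 before NTF division", stacklevel=2)
        m = np.where(clipped, 1e-12, m)
    val = s / m
    return float(val) if val.ndim == 0 else val


def ntf_filter_grid(side: int, pixels_per_degree: float,
                    ctx: AgeContext, params: SCSFParams | None = None,
                    form: str = "sum") -> np.ndarray:
    """NTF sampled on an image's 2-D frequency grid, DC-normalized to 1.

    Returned in numpy's unshifted FFT layout, ready to multiply a spectrum
    from ``np.fft.fft2``.
    """
    fx = np.fft.fftfreq(side) * pixels_per_degree  # cycles/degree
    fr = np.hypot(*np.meshgrid(fx, fx, indexing="xy"))
    vals = ntf(fr, ctx, params, form)
    dc = vals.flat[0]
    if dc <= 0:
        raise ValueError("NTF gain at DC must be positive")
    vals = np.maximum(vals / dc, 0.0)
    return vals


def apply_ntf_filter(img, ctx: AgeContext, params: SCSFParams | None = None,
                     form: str = "sum"):
    """Filter an optotype image by the NTF in the Fourier domain.

    The image's centered spectrum is multiplied by the radially symmetric
    NTF evaluated at each pixel's frequency in cycles/degree, with the
    zero-frequency gain normalized to 1 so the spatial mean is preserved
    before clipping; over/undershoot from the mid-frequency contrast boost
    is clipped back to [0, 1].
    """
    from .optotype_sim import OptotypeImage  # local import avoids a cycle

    if img.pixels_per_degree is None or not img.pixels_per_degree > 0:
        raise ValueError("image pixel scale (pixels_per_degree) is required")
    side = img.data.shape[0]
    filt = ntf_filter_grid(side, img.pixels_per_degree, ctx, params, form)
    spectrum = np.fft.fft2(img.data)
    out = np.real(np.fft.ifft2(spectrum * filt))
    out = np.clip(out, 0.0, 1.0)
    return OptotypeImage(data=out, pixels_per_degree=img.pixels_per_degree,
                         meta={**img.meta, "stage": "ntf"})


def retinal_sampling(img, samples_per_degree: float = DEFAULT_SAMPLES_PER_DEGREE):
    """Band-limit an image to the retinal sampling rate.

    Models photoreceptor sampling by removing spectral content above the
    Nyquist frequency of the retinal mosaic (``samples_per_degree / 2``
    cycles/degree) with a raised-cosine spectral edge, then returns the
    result on the original canvas. If the retinal rate is at least the
    canvas sampling rate the image is already adequately sampled and is
    returned unchanged.
    """
    from .optotype_sim import OptotypeImage

    if not samples_per_degree > 0:
        raise ValueError("samples_per_degree must be positive")
    ppd = img.pixels_per_degree
    if samples_per_degree >= ppd:
        warnings.warn("retinal sampling rate above canvas rate; no-op",
                      stacklevel=2)
        return OptotypeImage(data=img.data.copy(), pixels_per_degree=ppd,
                             meta={**img.meta, "stage": "retina"})
    side = img.data.shape[0]
    fx = np.fft.fftfreq(side) * ppd
    fr = np.hypot(*np.meshgrid(fx, fx, indexing="xy"))
    nyq = samples_per_degree / 2.0
    # raised-cosine transition over 10% of the cutoff
    width = 0.1 * nyq
    lp = np.clip((nyq - fr) / width + 0.5, 0.0, 1.0)
    lp = 0.5 - 0.5 * np.cos(np.pi * lp)
    out = np.real(np.fft.ifft2(np.fft.fft2(img.data) * lp))
    out = np.clip(out, 0.0, 1.0)
    return OptotypeImage(data=out, pixels_per_degree=ppd,
                         meta={**img.meta, "stage": "retina"})


def add_gaussian_noise(img, variance: float = 0.01,
                       seed: int | np.random.Generator | None = None):
    """Add i.i.d. zero-mean Gaussian neural noise and clip to [0, 1].

    ``variance`` is interpreted on the [0, 1] intensity scale; the draw is
    deterministic under a fixed seed.
    """
    from .optotype_sim import OptotypeImage

    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return OptotypeImage(data=img.data.copy(),
                             pixels_per_degree=img.pixels_per_degree,
                             meta={**img.meta, "stage": "noise"})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = img.data + rng.normal(0.0, np.sqrt(variance), size=img.data.shape)
    return OptotypeImage(data=np.clip(noisy, 0.0, 1.0),
                         pixels_per_degree=img.pixels_per_degree,
                         meta={**img.meta, "stage": "noise"})
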