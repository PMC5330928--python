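"""Matched filtering with Gaussian kernels (MFGK).

Growth rings and ribs are locally straight line segments, so they respond
maximally to a kernel whose cross-section is a Gaussian line profile
``-exp(-(x / a)^2 / (2 sigma^2))`` (negative: the lines are darker than
the background on CT scans) swept along the line direction.  The kernel
is rotated through a set of orientations and the response image keeps,
per pixel, the maximum over orientations together with the maximizing
angle.  Zero-mean shifting of the kernel makes flat regions respond
exactly zero, the usual matched-filter convention for vessel-like
structure enhancement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "MFGKParams",
    "ResponseImage",
    "build_kernel",
    "mfgk_response",
    "normalize_response",
    "DegenerateResponseError",
]


class DegenerateResponseError(ValueError):
    """Raised when a response image has zero variance."""


def default_theta_set() -> tuple[float, ...]:
    return tuple(float(t) for t in range(10, 180, 10))


@dataclass(frozen=True)
class MFGKParams:
    """Matched-filter bank parameters.

    ``a`` dilates the Gaussian profile (effective cross-line width is
    ``a * sigma_kernel`` pixels); ``b`` is the profile translation and is
    kept 0 because convolution already scans all translations.  The
    default 17 orientations step from 10 to 170 degrees in 10-degree
    increments.  ``polarity`` selects dark-line ("dark", the CT
    convention) or bright-line ("bright") enhancement.
    """

    a: float = 8.0
    b: float = 0.0
    sigma_kernel: float = 2.0
    theta_set: tuple[float, ...] = field(default_factory=default_theta_set)
    support: int | None = None
    along_support: int | None = None
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.sigma_kernel <= 0:
            raise ValueError("a and sigma_kernel must be positive")
        if not self.theta_set:
            raise ValueError("theta_set must be nonempty")
        if any(not 0 <= t < 180 for t in self.theta_set):
            raise ValueError("angles must lie in [0, 180)")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")

    @property
    def half_extent(self) -> int:
        needed = math.ceil(3.0 * self.a * self.sigma_kernel)
        if self.support is None:
            return needed
        if self.support < needed:
            raise ValueError(
                f"support {self.support} too small for 3*a*sigma = {needed}"
            )
        return int(self.support)

    @property
    def half_along(self) -> int:
        return self.half_extent if self.along_support is None else int(self.along_support)


@dataclass
class ResponseImage:
    """Per-pixel max response over orientations and the argmax angle."""

    values: np.ndarray
    argmax_angle: np.ndarray


def build_kernel(params: MFGKParams, theta: float) -> np.ndarray:
    """Rotated zero-mean matched kernel for one orientation.

    ``theta`` is the line direction in degrees CCW from the +col axis; at
    theta = 0 the kernel profile varies across rows and is constant along
    columns.  The Gaussian value is shifted so the kernel sums to zero
    over its support.
    """
    half = params.half_extent
    half_along = params.half_along
    size = 2 * max(half, half_along) + 1
    off = np.arange(size) - size // 2
    dr, dc = np.meshgrid(off, off, indexing="ij")
    t = math.radians(theta)
    # line direction at angle theta is (sin t, cos t) in (row, col);
    # "across" is the perpendicular profile coordinate
    across = dr * math.cos(t) - dc * math.sin(t)
    along = dr * math.sin(t) + dc * math.cos(t)
    support = (np.abs(across) <= half + 0.5) & (np.abs(along) <= half_along + 0.5)
    prof = -np.exp(-(((across - params.b) / params.a) ** 2) / (2.0 * params.sigma_kernel**2))
    if params.polarity == "bright":
        prof = -prof
    kernel = np.where(support, prof, 0.0)
    kernel[support] -= kernel[support].mean()
    return kernel


def mfgk_response(img: np.ndarray, params: MFGKParams) -> ResponseImage:
    """Max-over-orientations matched-filter response.

    Convolution uses reflected padding at the image boundary so border
    pixels see plausible context instead of zeros.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    pad = max(params.half_extent, params.half_along)
    padded = np.pad(img, pad, mode="reflect")
    best = None
    best_angle = None
    for theta in params.theta_set:
        kernel = build_kernel(params, theta)
        resp = fftconvolve(padded, kernel, mode="same")[pad:-pad, pad:-pad]
        if best is None:
            best = resp
            best_angle = np.full(img.shape, theta, dtype=float)
        else:
            better = resp > best
            best = np.where(better, resp, best)
            best_angle = np.where(better, theta, best_angle)
    return ResponseImage(values=best, argmax_angle=best_angle)


def normalize_response(resp: ResponseImage | np.ndarray) -> np.ndarray:
    """Global z-scoring of the response: f = (M - mu) / sigma.

    mu and sigma are the mean and population standard deviation of the
    whole response image, so the output has mean 0 and sd 1 regardless of
    the input's intensity scale.
    """
    values = resp.values if isinstance(resp, ResponseImage) else np.asarray(resp, dtype=float)
    mu = values.mean()
    sigma = values.std()  # population sd (divide by N)
    if sigma == 0:
        raise DegenerateResponseError("constant response image cannot be normalized")
    return (values - mu) / sigma
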