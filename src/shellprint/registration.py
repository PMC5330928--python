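"""Affine registration of matched skeletons and the overlap ratio.

Corresponding node positions of matched cyclic structures give point
pairs; a least-squares affine map (linear and quadratic variants are kept
behind the same interface) warps one skeleton into the other's frame.
The overlap ratio ra is the fraction of warped pixels that land within a
small tolerance (default 1 px, the shift actually observed between
repeated captures) of the reference skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk

__all__ = [
    "AffineTransform",
    "OverlapResult",
    "estimate_affine",
    "estimate_transform",
    "warp_skeleton",
    "overlap_ratio",
]


@dataclass
class AffineTransform:
    """p_B = linear @ p_A + translation, in (row, col) coordinates."""

    linear: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.linear)) <= 1e-8:
            raise ValueError("affine linear part is (near-)singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))


@dataclass
class OverlapResult:
    ra: float
    aligned_pixels: int
    reference_pixels: int
    shift_tolerance: float
    valid: bool = True


def _collinear(points: np.ndarray) -> bool:
    p = points - points.mean(axis=0)
    return np.linalg.matrix_rank(p, tol=1e-9) < 2


def estimate_affine(matches: list[tuple[np.ndarray, np.ndarray]] | tuple) -> AffineTransform:
    """Least-squares affine fit mapping A-points onto B-points.

    Needs at least three non-collinear correspondences; exact
    correspondences are recovered to machine precision.
    """
    src = np.asarray([m[0] for m in matches], dtype=float)
    dst = np.asarray([m[1] for m in matches], dtype=float)
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    if _collinear(src):
        raise ValueError("source points are collinear")
    X = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    pred = X @ coef
    rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    return AffineTransform(linear, translation, residual_rms=rms)


def estimate_transform(
    matches, model: str = "affine"
) -> AffineTransform | "QuadraticTransform":
    """Dispatch over transformation families; affine is the default."""
    if model in ("affine", "linear"):
        t = estimate_affine(matches)
        if model == "linear":
            # similarity restriction: orthogonal Procrustes on the fit
            src = np.asarray([m[0] for m in matches], dtype=float)
            dst = np.asarray([m[1] for m in matches], dtype=float)
            sc, dc = src.mean(0), dst.mean(0)
            s0, d0 = src - sc, dst - dc
            u, s, vt = np.linalg.svd(d0.T @ s0)
            R = u @ vt
            scale = s.sum() / np.sum(s0**2)
            return AffineTransform(scale * R, dc - scale * R @ sc)
        return t
    if model == "quadratic":
        return QuadraticTransform.fit(matches)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class QuadraticTransform:
    """Full 2-D quadratic polynomial map (6 coefficients per axis)."""

    coef: np.ndarray  # (6, 2)

    @staticmethod
    def _design(points: np.ndarray) -> np.ndarray:
        r, c = points[:, 0], points[:, 1]
        return np.stack([np.ones_like(r), r, c, r * c, r**2, c**2], axis=1)

    @classmethod
    def fit(cls, matches) -> "QuadraticTransform":
        src = np.asarray([m[0] for m in matches], dtype=float)
        dst = np.asarray([m[1] for m in matches], dtype=float)
        if len(src) < 6:
            raise ValueError("quadratic model needs >= 6 point pairs")
        X = cls._design(src)
        coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
        return cls(coef=coef)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self._design(np.asarray(points, dtype=float)) @ self.coef


def warp_skeleton(
    skel: np.ndarray,
    T: AffineTransform,
    target_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Nearest-neighbor warp of a binary skeleton into the target frame.

    ``T`` maps source coordinates to target coordinates; the warp pulls
    each target pixel back through the inverse, so the output stays a
    strict binary mask.
    """
    skel = np.asarray(skel, dtype=bool)
    shape = target_shape if target_shape is not None else skel.shape
    inv = T.inverse()
    return ndimage.affine_transform(
        skel.astype(np.uint8),
        inv.linear,
        offset=inv.translation,
        output_shape=shape,
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)


def overlap_ratio(
    skelA_warped: np.ndarray,
    skelB: np.ndarray,
    tol: float = 1.0,
    symmetric: bool = False,
) -> OverlapResult:
    """ra = fraction of A's pixels within ``tol`` of a pixel of B.

    Implemented by dilating B with a disk of radius ``tol`` before
    intersecting, so a pure 1-px shift at tol = 1 still scores 1.0.  The
    reference set is the warped A skeleton; ``symmetric`` averages both
    directions instead.
    """
    A = np.asarray(skelA_warped, dtype=bool)
    B = np.asarray(skelB, dtype=bool)
    if not A.any():
        return OverlapResult(0.0, 0, 0, tol, valid=False)
    btol = dilation(B, disk(int(round(tol)))) if tol >= 1 else B
    aligned = int(np.count_nonzero(A & btol))
    ra = aligned / int(np.count_nonzero(A))
    if symmetric:
        back = overlap_ratio(B, A, tol=tol, symmetric=False)
        ra = 0.5 * (ra + back.ra)
    return OverlapResult(
        ra=float(ra),
        aligned_pixels=aligned,
        reference_pixels=int(np.count_nonzero(A)),
        shift_tolerance=tol,
    )
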