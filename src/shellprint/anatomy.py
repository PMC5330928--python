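"""Radial ribs, growth rings, the origin growth point, and growth rates.

Ribs are straight lines converging at the umbo; they are detected with a
Hough transform run separately in angular sectors (six 30-degree sectors
by default) so each sector contributes its few strongest lines.  The
umbo is the least-squares intersection of all detected rib lines.  Rings
are concentric around the umbo: a radial occupancy profile (mask pixels
per 1-px radius bin, normalized by the in-image annulus area) is peak-
picked with neighborhood suppression so only spatially separated circles
survive.  The along-rib distance between consecutive rings is the local
growth increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage.transform import hough_line, hough_line_peaks

__all__ = [
    "RibLine",
    "RibSet",
    "Ring",
    "RingSet",
    "detect_ribs",
    "detect_rings",
    "growth_rates",
]


@dataclass
class RibLine:
    """Hough line in normal form: cos(t)*col + sin(t)*row = offset.

    ``angle`` is the line *direction* in degrees CCW from the +col axis,
    in [0, 180); ``normal_angle`` the Hough normal angle in radians.
    """

    angle: float
    normal_angle: float
    offset: float
    support: int


@dataclass
class RibSet:
    lines: list[RibLine]
    origin: np.ndarray | None      # (row, col) or None when < 2 lines


@dataclass
class Ring:
    center: np.ndarray
    radius: float
    score: float


@dataclass
class RingSet:
    rings: list[Ring]

    @property
    def radii(self) -> np.ndarray:
        return np.array([r.radius for r in self.rings])

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.radii)


def detect_ribs(
    mask: np.ndarray,
    n_sectors: int = 6,
    max_lines_per_sector: int = 4,
    threshold_frac: float = 0.5,
    angle_step: float = 1.0,
) -> RibSet:
    """Sector-restricted Hough line detection plus origin estimation.

    The 180-degree direction range is split into ``n_sectors`` equal
    sectors; in each, a straight-line Hough transform restricted to that
    sector's angles keeps up to ``max_lines_per_sector`` peaks above
    ``threshold_frac`` of the sector's maximum vote.  The origin is the
    least-squares solution of all kept line equations; it is None
    (flagged) when fewer than two lines are found.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    width = 180.0 / n_sectors
    # global vote reference: a sector without ribs must not promote its
    # own weak maxima to detections
    h_all, _, _ = hough_line(mask, theta=np.deg2rad(np.arange(-90.0, 90.0, angle_step)))
    global_max = h_all.max()
    if global_max == 0:
        return RibSet(lines=[], origin=None)
    lines: list[RibLine] = []
    for s in range(n_sectors):
        lo = s * width
        hi = (s + 1) * width
        # direction t in [lo, hi) <-> Hough normal angle t - 90 degrees
        thetas = np.deg2rad(np.arange(lo - 90.0, hi - 90.0, angle_step))
        h, angles, dists = hough_line(mask, theta=thetas)
        accum, angs, ds = hough_line_peaks(
            h,
            angles,
            dists,
            num_peaks=max_lines_per_sector,
            threshold=threshold_frac * global_max,
            min_angle=2,
            min_distance=5,
        )
        for votes, na, d in zip(accum, angs, ds):
            direction = (math.degrees(na) + 90.0) % 180.0
            lines.append(
                RibLine(
                    angle=direction,
                    normal_angle=float(na),
                    offset=float(d),
                    support=int(votes),
                )
            )
    origin = None
    if len(lines) >= 2:
        origin, lines = _converging_origin(lines)
    return RibSet(lines=lines, origin=origin)


def _converging_origin(
    lines: list[RibLine], tol: float = 4.0
) -> tuple[np.ndarray | None, list[RibLine]]:
    """Least-squares intersection, robust to non-converging lines.

    Ring arcs occasionally produce straight Hough chords that do not pass
    through the umbo; the fit therefore trims the worst-residual line
    until all residuals are below ``tol`` pixels, then keeps only the
    lines consistent with the intersection (ribs converge, chords do
    not).
    """
    active = list(lines)

    def fit(ls: list[RibLine]) -> tuple[np.ndarray, np.ndarray]:
        A = np.array([[math.sin(l.normal_angle), math.cos(l.normal_angle)] for l in ls])
        b = np.array([l.offset for l in ls])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        return sol, np.abs(A @ sol - b)

    while True:
        sol, res = fit(active)
        if len(active) <= 2 or res.max() <= tol:
            break
        active.pop(int(np.argmax(res)))
    if len(active) < 2:
        return None, lines
    kept = [
        l
        for l in lines
        if abs(
            math.sin(l.normal_angle) * sol[0]
            + math.cos(l.normal_angle) * sol[1]
            - l.offset
        )
        <= tol
    ]
    if len(kept) >= 2:
        sol, _ = fit(kept)
        return sol, kept
    return sol, active


def detect_rings(
    mask: np.ndarray,
    origin: np.ndarray,
    suppression_radius: float | None = None,
    bin_width: float = 1.0,
    smooth_bins: int = 3,
    min_score_frac: float = 0.25,
    ribs: RibSet | None = None,
    rib_clear_px: float = 2.0,
) -> RingSet:
    """Concentric-ring detection by radial profiling with peak suppression.

    The occupancy profile is smoothed over ``smooth_bins`` bins (so mild
    eccentricity still pools into one peak); candidate peaks are accepted
    greedily by score, suppressing any candidate within
    ``suppression_radius`` of an accepted one.  When the suppression
    radius is not given it defaults to half the median spacing of a first
    unsuppressed pass.  Passing the detected ``ribs`` removes pixels
    within ``rib_clear_px`` of a rib line first — ribs run across every
    radius and otherwise flood the near-origin bins.  Each accepted
    radius is refined to the occupancy-weighted centroid of its peak
    neighborhood for sub-bin accuracy.
    """
    mask = np.asarray(mask, dtype=bool)
    origin = np.asarray(origin, dtype=float)
    domain = np.ones_like(mask, dtype=bool)
    if ribs is not None and ribs.lines:
        r_all, c_all = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        for line in ribs.lines:
            dist = np.abs(
                math.sin(line.normal_angle) * r_all
                + math.cos(line.normal_angle) * c_all
                - line.offset
            )
            domain &= dist > rib_clear_px
        mask = mask & domain
    if not mask.any():
        return RingSet(rings=[])
    rows, cols = np.nonzero(mask)
    rr = np.hypot(rows - origin[0], cols - origin[1])
    # normalize by the area actually available in each annulus (inside the
    # image and outside the cleared rib strips)
    dr_all, dc_all = np.nonzero(domain)
    rad_all = np.hypot(dr_all - origin[0], dc_all - origin[1])
    n_bins = int(np.ceil(rad_all.max() / bin_width)) + 1
    occ = np.bincount((rr / bin_width).astype(int), minlength=n_bins)[:n_bins]
    area = np.bincount((rad_all / bin_width).astype(int), minlength=n_bins)[:n_bins]
    # annuli with almost no available area (e.g. where all ribs converge
    # near the origin) give meaningless occupancy ratios
    min_area = 8
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(area >= min_area, occ / np.maximum(area, 1), 0.0)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        profile = np.convolve(profile, kernel, mode="same")

    peak_idx, _ = find_peaks(profile)  # plateau-aware local maxima
    if peak_idx.size == 0:
        return RingSet(rings=[])
    scores = profile[peak_idx]
    keep = scores >= min_score_frac * scores.max()
    peak_idx, scores = peak_idx[keep], scores[keep]

    if suppression_radius is None:
        order = np.sort(peak_idx)
        med = np.median(np.diff(order)) if len(order) > 1 else 10.0
        suppression_radius = max(2.0, float(med) / 2.0) * bin_width

    half_win = max(1, smooth_bins)
    accepted: list[Ring] = []
    for i in np.argsort(-scores):
        b = int(peak_idx[i])
        lo = max(0, b - half_win)
        hi = min(len(profile), b + half_win + 1)
        w = occ[lo:hi].astype(float)
        centers = (np.arange(lo, hi) + 0.5) * bin_width
        radius = float(np.average(centers, weights=w)) if w.sum() > 0 else (b + 0.5) * bin_width
        if any(abs(radius - r.radius) < suppression_radius for r in accepted):
            continue
        accepted.append(Ring(center=origin.copy(), radius=radius, score=float(scores[i])))
    accepted.sort(key=lambda r: r.radius)
    return RingSet(rings=accepted)


def _line_circle_intersections(
    line: RibLine, center: np.ndarray, radius: float
) -> list[np.ndarray]:
    """Intersections of a Hough line with a circle, as (row, col) points."""
    na = line.normal_angle
    n = np.array([math.sin(na), math.cos(na)])   # (row, col) normal
    d = np.array([math.cos(na), -math.sin(na)])  # direction along line
    foot = n * line.offset
    rel = center - foot
    t0 = rel @ d
    closest = foot + t0 * d
    h2 = radius**2 - float(np.sum((closest - center) ** 2))
    if h2 < 0:
        return []
    h = math.sqrt(h2)
    return [closest + h * d, closest - h * d]


def growth_rates(ribs: RibSet, rings: RingSet) -> dict:
    """Along-rib distances between consecutive rings.

    For each rib line the intersections with each ring (taking, per ring,
    the intersection on the same side of the origin) give positions along
    the rib; consecutive differences are the per-interval growth
    increments in pixels.  Returns per-rib interval lists and the
    across-rib mean per interval; intervals a rib misses are skipped and
    flagged.
    """
    if len(rings.rings) < 2:
        return {"per_rib": [], "mean_intervals": np.array([]), "flags": ["need >= 2 rings"]}
    center = rings.rings[0].center
    per_rib = []
    flags: list[str] = []
    for li, line in enumerate(ribs.lines):
        dists = []
        ref_dir = None
        for ring in rings.rings:
            pts = _line_circle_intersections(line, center, ring.radius)
            if not pts:
                dists.append(np.nan)
                flags.append(f"rib {li} misses ring r={ring.radius:.1f}")
                continue
            if ref_dir is None:
                # fix the outward side using the rib's nominal direction
                ref_dir = pts[0] - center
                if np.linalg.norm(ref_dir) == 0:
                    ref_dir = pts[1] - center
            chosen = max(pts, key=lambda p: float((p - center) @ ref_dir))
            dists.append(float(np.linalg.norm(chosen - center)))
        dists = np.asarray(dists)
        intervals = np.diff(dists)
        per_rib.append(intervals)
    if per_rib:
        stacked = np.vstack([iv for iv in per_rib])
        mean_intervals = np.nanmean(stacked, axis=0)
    else:
        mean_intervals = np.array([])
    return {"per_rib": per_rib, "mean_intervals": mean_intervals, "flags": flags}
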