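"""Synthetic shell phantoms and toy planar graphs.

Real shell images show a network of bright radial ribs crossed by
concentric growth rings, both emanating from the umbo (the origin growth
point).  The phantom generator rasterizes exactly that geometry — rays and
circular arcs around a configurable origin — together with the ground
truth (ray angles, ring radii, crossing coordinates) needed to score every
downstream detection stage exactly.

Coordinate convention: positions are ``(row, col)``, 0-based, origin at
the top-left; angles are in degrees measured counter-clockwise from the
+col axis, so a direction angle ``phi`` maps to the unit vector
``(sin(phi), cos(phi))`` in (row, col) components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import line as draw_line
from skimage.draw import line_aa as draw_line_aa
from skimage.morphology import dilation, disk

from .skeletongraph import SkeletonGraph

__all__ = [
    "ShellPhantomSpec",
    "CaptureParams",
    "PhantomTruth",
    "Phantom",
    "generate_phantom",
    "generate_individual_set",
    "toy_planar_graph",
    "TOY_GRAPH_NAMES",
]


def unit_vector(angle_deg: float) -> np.ndarray:
    """(row, col) unit vector for an angle in degrees CCW from +col."""
    a = math.radians(angle_deg)
    return np.array([math.sin(a), math.cos(a)])


@dataclass(frozen=True)
class ShellPhantomSpec:
    """Geometry and noise parameters of one synthetic shell image.

    ``ring_r0`` is the radius of the innermost ring; consecutive ring
    spacings grow geometrically by ``ring_growth`` starting from
    ``ring_spacing``.  ``jitter_sigma`` perturbs rib angles (degrees) and
    ring radii (pixels) with one per-individual random draw.
    """

    image_size: tuple[int, int] = (160, 160)
    origin: tuple[float, float] = (10.0, 10.0)
    n_ribs: int = 8
    rib_angle_span: float = 80.0
    rib_angle_start: float = 6.0
    n_rings: int = 6
    ring_r0: float = 48.0
    ring_spacing: float = 18.0
    ring_growth: float = 1.0
    ring_radii: tuple[float, ...] | None = None
    rib_angles: tuple[float, ...] | None = None
    arc_margin: float = 4.0
    line_width: int = 3
    jitter_seed: int = 0
    jitter_sigma: float = 0.0
    noise_sigma: float = 0.0
    background: float = 0.1
    background_gradient: tuple[float, float] = (0.0, 0.0)
    foreground: float = 1.0
    antialias: bool = False

    def validate(self) -> None:
        if self.n_ribs < 2:
            raise ValueError("need n_ribs >= 2")
        if self.n_rings < 2:
            raise ValueError("need n_rings >= 2")
        if self.line_width < 1:
            raise ValueError("need line_width >= 1")
        if not 0 < self.rib_angle_span <= 180:
            raise ValueError("rib_angle_span must be in (0, 180]")
        r, c = self.image_size
        if r < 8 or c < 8:
            raise ValueError("image too small")
        radii = self.base_ring_radii()
        orow, ocol = self.origin
        corner_dist = max(
            math.hypot(orow - er, ocol - ec)
            for er in (0, r - 1)
            for ec in (0, c - 1)
        )
        if min(radii) > corner_dist:
            raise ValueError("all rings fall outside the image")

    def base_ring_radii(self) -> np.ndarray:
        if self.ring_radii is not None:
            radii = np.asarray(self.ring_radii, dtype=float)
            if len(radii) != self.n_rings:
                raise ValueError("ring_radii length must equal n_rings")
            return radii
        radii = [float(self.ring_r0)]
        step = float(self.ring_spacing)
        for _ in range(self.n_rings - 1):
            radii.append(radii[-1] + step)
            step *= self.ring_growth
        return np.asarray(radii)

    def base_rib_angles(self) -> np.ndarray:
        if self.rib_angles is not None:
            if len(self.rib_angles) != self.n_ribs:
                raise ValueError("rib_angles length must equal n_ribs")
            return np.asarray(self.rib_angles, dtype=float)
        return self.rib_angle_start + np.linspace(
            0.0, self.rib_angle_span, self.n_ribs
        )


@dataclass(frozen=True)
class CaptureParams:
    """Per-capture perturbation emulating repeated photography.

    Defaults bound the capture transform to what registration must absorb:
    rotation uniform in +-5 degrees, translation +-3 px, scale 1 +- 0.03,
    mild illumination change, and additive sensor noise.
    """

    rot_deg: float = 5.0
    trans_px: float = 3.0
    scale: float = 0.03
    illum: float = 0.1
    noise_sigma: float = 0.03

    @classmethod
    def none(cls) -> "CaptureParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class PhantomTruth:
    """Exact geometry behind a phantom image."""

    origin: np.ndarray
    rib_angles: np.ndarray
    ring_radii: np.ndarray
    arc_span: tuple[float, float]
    crossings: np.ndarray          # (k, 2) ray-by-arc intersection points
    ray_mask: np.ndarray
    ring_mask: np.ndarray

    @property
    def line_mask(self) -> np.ndarray:
        return self.ray_mask | self.ring_mask


@dataclass
class Phantom:
    image: np.ndarray
    truth: PhantomTruth
    spec: ShellPhantomSpec


def _jittered_geometry(spec: ShellPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual geometry perturbation.

    Rib angles get independent Gaussian jitter (degrees); ring radii get
    a cumulative (random-walk) jitter of the ring spacings (pixels), the
    natural model for growth-increment variation between individuals.
    """
    angles = spec.base_rib_angles().copy()
    radii = spec.base_ring_radii().copy()
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.jitter_seed)
        angles = angles + rng.normal(0.0, spec.jitter_sigma, size=angles.shape)
        radii = radii + np.cumsum(
            rng.normal(0.0, spec.jitter_sigma, size=radii.shape)
        )
        radii = np.sort(np.abs(radii))
    return angles, radii


def _ray_endpoint(origin: np.ndarray, angle: float, shape: tuple[int, int]) -> np.ndarray:
    """Farthest in-image point along the ray from origin at ``angle``."""
    d = unit_vector(angle)
    tmax = math.hypot(*shape) * 2.0
    for _ in range(60):  # bisect the exit distance
        t = tmax
        p = origin + t * d
        if 0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1:
            break
        tmax *= 0.5
    lo, hi = tmax, tmax * 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        p = origin + mid * d
        if 0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1:
            lo = mid
        else:
            hi = mid
    return origin + lo * d


def _draw_segments(
    mask: np.ndarray, points: np.ndarray, antialias: bool
) -> None:
    """Rasterize a polyline given by float (row, col) points into mask."""
    pts = np.rint(points).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        if antialias:
            rr, cc, _ = draw_line_aa(r0, c0, r1, c1)
        else:
            rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[ok], cc[ok]] = True


def _thicken(mask: np.ndarray, line_width: int) -> np.ndarray:
    radius = (line_width - 1) // 2
    if radius >= 1:
        return dilation(mask, disk(radius))
    return mask


def generate_phantom(spec: ShellPhantomSpec) -> Phantom:
    """Rasterize a rib/ring phantom with its exact ground truth.

    Deterministic: identical spec (including seeds) gives a bitwise
    identical image.
    """
    spec.validate()
    shape = tuple(spec.image_size)
    origin = np.asarray(spec.origin, dtype=float)
    angles, radii = _jittered_geometry(spec)

    ray_mask = np.zeros(shape, dtype=bool)
    for ang in angles:
        end = _ray_endpoint(origin, ang, shape)
        _draw_segments(ray_mask, np.array([origin, end]), spec.antialias)

    a_lo = spec.rib_angle_start - spec.arc_margin
    a_hi = spec.rib_angle_start + spec.rib_angle_span + spec.arc_margin
    ring_mask = np.zeros(shape, dtype=bool)
    for rad in radii:
        n_steps = max(16, int(math.ceil(math.radians(a_hi - a_lo) * rad * 2)))
        ts = np.linspace(a_lo, a_hi, n_steps)
        pts = origin[None, :] + rad * np.stack(
            [np.sin(np.radians(ts)), np.cos(np.radians(ts))], axis=1
        )
        _draw_segments(ring_mask, pts, spec.antialias)

    ray_mask = _thicken(ray_mask, spec.line_width)
    ring_mask = _thicken(ring_mask, spec.line_width)

    crossings = []
    for ang in angles:
        d = unit_vector(ang)
        for rad in radii:
            p = origin + rad * d
            if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]:
                crossings.append(p)
    crossings = np.asarray(crossings) if crossings else np.zeros((0, 2))

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = (
        spec.background
        + spec.background_gradient[0] * rows / max(shape[0] - 1, 1)
        + spec.background_gradient[1] * cols / max(shape[1] - 1, 1)
    ).astype(float)
    img[ray_mask | ring_mask] = spec.foreground
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(spec.jitter_seed + 1_000_003)
        img = img + noise_rng.normal(0.0, spec.noise_sigma, size=shape)

    truth = PhantomTruth(
        origin=origin,
        rib_angles=angles,
        ring_radii=radii,
        arc_span=(a_lo, a_hi),
        crossings=crossings,
        ray_mask=ray_mask,
        ring_mask=ring_mask,
    )
    return Phantom(image=img, truth=truth, spec=spec)


def generate_individual_set(
    base: ShellPhantomSpec,
    n_individuals: int,
    n_images_per_individual: int,
    capture: CaptureParams | None = None,
    master_seed: int = 0,
) -> list[tuple[int, Phantom]]:
    """Repeated captures of distinct individuals.

    Each individual carries one fixed jitter realization of the base
    geometry (its "natural marking"); images of the same individual differ
    only by a small rigid-plus-scale capture transform, illumination and
    sensor noise.  Fully reproducible under ``master_seed``.
    """
    if n_individuals < 1 or n_images_per_individual < 1:
        raise ValueError("counts must be >= 1")
    capture = capture if capture is not None else CaptureParams()
    rng = np.random.default_rng(master_seed)
    out: list[tuple[int, Phantom]] = []
    center = np.array([base.image_size[0] / 2.0, base.image_size[1] / 2.0])
    for ind in range(n_individuals):
        jitter_seed = int(rng.integers(0, 2**31 - 1))
        for _ in range(n_images_per_individual):
            rot = float(rng.uniform(-capture.rot_deg, capture.rot_deg))
            trans = rng.uniform(-capture.trans_px, capture.trans_px, size=2)
            scale = float(1.0 + rng.uniform(-capture.scale, capture.scale))
            illum = float(rng.uniform(-capture.illum, capture.illum))
            noise_seed_shift = int(rng.integers(0, 2**20))

            # the individual's own (jittered) geometry in the base frame,
            # then the capture similarity transform applied to it exactly
            angles0, radii0 = _jittered_geometry(replace(base, jitter_seed=jitter_seed))
            origin = np.asarray(base.origin, dtype=float)
            a = math.radians(rot)
            # in the (row, col)/CCW-from-+col convention this matrix maps a
            # direction at angle phi to phi + rot, matching the angle shift
            rotm = np.array(
                [[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]]
            )
            new_origin = center + scale * rotm @ (origin - center) + trans
            spec = replace(
                base,
                jitter_seed=jitter_seed,
                jitter_sigma=0.0,  # jitter already applied to the geometry
                origin=(float(new_origin[0]), float(new_origin[1])),
                rib_angles=tuple(angles0 + rot),
                ring_radii=tuple(radii0 * scale),
                background=base.background * (1.0 + illum),
            )
            ph = _generate_capture(spec, rot, scale, jitter_seed, noise_seed_shift)
            out.append((ind, ph))
    return out


def _generate_capture(
    spec: ShellPhantomSpec,
    rot: float,
    scale: float,
    jitter_seed: int,
    noise_seed_shift: int,
) -> Phantom:
    """Generate with per-individual jitter but per-capture sensor noise."""
    base_noise = spec.noise_sigma
    quiet = replace(spec, noise_sigma=0.0)
    ph = generate_phantom(quiet)
    img = ph.image
    if base_noise > 0:
        nrng = np.random.default_rng(jitter_seed + 7_777_777 + noise_seed_shift)
        img = img + nrng.normal(0.0, base_noise, size=img.shape)
    return Phantom(image=img, truth=ph.truth, spec=replace(spec, noise_sigma=base_noise))


def phantom_landmarks(ph: Phantom, n_edge_semis: int = 15) -> dict[str, np.ndarray]:
    """Digitize a phantom from its ground truth.

    Returns the five fixed landmarks (umbo, plus the first/last rib's
    intersections with the innermost and outermost ring), ``n_edge_semis``
    semilandmarks along the outermost ring (the ventral edge analog), and
    all ray-ring crossings as surface semilandmark candidates.
    """
    t = ph.truth
    a0, a1 = t.rib_angles[0], t.rib_angles[-1]
    r_in, r_out = t.ring_radii[0], t.ring_radii[-1]
    fixed = np.array(
        [
            t.origin,
            t.origin + r_in * unit_vector(a0),
            t.origin + r_out * unit_vector(a0),
            t.origin + r_in * unit_vector(a1),
            t.origin + r_out * unit_vector(a1),
        ]
    )
    # interior angles only: the arc endpoints already appear among the
    # fixed landmarks, and coincident points make the TPS system singular
    edge = np.array(
        [
            t.origin + r_out * unit_vector(a)
            for a in np.linspace(a0, a1, n_edge_semis + 2)[1:-1]
        ]
    )
    return {"fixed": fixed, "edge": edge, "surface": t.crossings.copy()}


# ---------------------------------------------------------------------------
# Toy planar graphs with known minimum cycle bases


def _graph_from(nodes: dict[int, tuple[float, float]], edges: list[tuple[int, int]]) -> SkeletonGraph:
    g = SkeletonGraph()
    for nid, pos in nodes.items():
        g.add_node(nid, pos)
    for u, v in edges:
        pu = np.asarray(nodes[u], dtype=float)
        pv = np.asarray(nodes[v], dtype=float)
        path = np.linspace(pu, pv, 8)
        g.add_edge(u, v, path=path)
    return g


def _grid_2x2() -> SkeletonGraph:
    nodes = {}
    s = 10.0
    for i in range(3):
        for j in range(3):
            nodes[3 * i + j] = (s * i, s * j)
    edges = []
    for i in range(3):
        for j in range(3):
            if j < 2:
                edges.append((3 * i + j, 3 * i + j + 1))
            if i < 2:
                edges.append((3 * i + j, 3 * (i + 1) + j))
    return _graph_from(nodes, edges)


def _theta_graph() -> SkeletonGraph:
    nodes = {0: (10.0, 0.0), 1: (10.0, 20.0), 2: (0.0, 10.0), 3: (20.0, 10.0)}
    edges = [(0, 1), (0, 2), (2, 1), (0, 3), (3, 1)]
    return _graph_from(nodes, edges)


def _two_triangles_shared_edge() -> SkeletonGraph:
    nodes = {0: (0.0, 0.0), 1: (0.0, 10.0), 2: (8.0, 5.0), 3: (-8.0, 5.0)}
    edges = [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)]
    return _graph_from(nodes, edges)


def _k4_planar_embedding() -> SkeletonGraph:
    nodes = {0: (0.0, 0.0), 1: (0.0, 20.0), 2: (17.0, 10.0), 3: (6.0, 10.0)}
    edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    return _graph_from(nodes, edges)


def _hexagon() -> SkeletonGraph:
    nodes = {
        i: (10.0 + 10.0 * math.sin(math.radians(60 * i)),
            10.0 + 10.0 * math.cos(math.radians(60 * i)))
        for i in range(6)
    }
    edges = [(i, (i + 1) % 6) for i in range(6)]
    return _graph_from(nodes, edges)


def _pentagon_with_branches() -> SkeletonGraph:
    nodes = {
        i: (20.0 + 12.0 * math.sin(math.radians(72 * i)),
            20.0 + 12.0 * math.cos(math.radians(72 * i)))
        for i in range(5)
    }
    edges = [(i, (i + 1) % 5) for i in range(5)]
    # one external branch per cycle node
    for i in range(5):
        nodes[5 + i] = (
            20.0 + 20.0 * math.sin(math.radians(72 * i)),
            20.0 + 20.0 * math.cos(math.radians(72 * i)),
        )
        edges.append((i, 5 + i))
    return _graph_from(nodes, edges)


_TOY_BUILDERS = {
    "grid_2x2": _grid_2x2,
    "theta_graph": _theta_graph,
    "two_triangles_shared_edge": _two_triangles_shared_edge,
    "K4_planar_embedding": _k4_planar_embedding,
    "hexagon": _hexagon,
    "pentagon_with_branches": _pentagon_with_branches,
}

TOY_GRAPH_NAMES = tuple(sorted(_TOY_BUILDERS))


def toy_planar_graph(name: str) -> SkeletonGraph:
    """Small planar graph fixture with exact coordinates.

    These carry known minimum cycle bases (circuit rank |E| - |V| + 1 per
    connected component) and are the oracle fixtures for cycle extraction.
    """
    try:
        builder = _TOY_BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown toy graph {name!r}; choose from {TOY_GRAPH_NAMES}"
        ) from None
    return builder()
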