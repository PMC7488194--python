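"""Obstacle-patterned circular substrates and the geometric queries axon growth needs.

A substrate is a disc (2 or 4 mm diameter by default, scalable) decorated with
micrometer-sized obstacles -- crosses, circles or upward-pointing isosceles
triangles -- that either sit in small arrays or tile the whole disc
periodically.  Axons are confined to the *allowed* region (inside the disc,
outside every obstacle) and reflect specularly off obstacle boundaries and off
the substrate rim.

Dimensions are in mm throughout.  Default obstacle dimensions:

* cross: 0.130 mm high and wide, beams 0.020 mm thick, lattice pitch 0.180 mm
  (0.050 mm gaps), kept when the cross center lies at least 0.050 mm from the
  rim;
* circle: 0.120 mm diameter on a hexagonal lattice of pitch 0.170 mm
  (0.050 mm gaps), rows straddling the horizontal axis, kept when the center
  lies inside the disc;
* triangle: 0.050 mm high, 0.020 mm base, apex up, on a rectangular grid with
  0.005 mm gaps both between side-by-side bases (column pitch 0.025 mm) and
  between an apex and the base above it (row pitch 0.055 mm), kept when the
  base midpoint lies at least 0.005 mm from the rim.

The registrations of the full-coverage lattices are fixed so that the obstacle
area fractions of the built-in patterns are reproducible constants of the
geometry (13.6% for crosses, 45.0% for circles, 36.4% for triangles on the
2 mm disc); :func:`area_fraction` counts full obstacle areas, and obstacles in
the outermost lattice ring may slightly overhang the rim.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError

__all__ = [
    "ObstacleSpec",
    "SubstratePattern",
    "RasterMask",
    "RasterSubstrate",
    "Hit",
    "PATTERN_KINDS",
    "build_pattern",
    "area_fraction",
    "first_hit",
    "rasterize",
    "save_mask",
    "load_mask",
    "pattern_to_json",
    "pattern_from_json",
]

# canonical obstacle dimensions (mm) before scaling
CROSS_SIZE = 0.130
CROSS_THICKNESS = 0.020
CROSS_GAP = 0.050
CIRCLE_DIAMETER = 0.120
CIRCLE_GAP = 0.050
TRIANGLE_HEIGHT = 0.050
TRIANGLE_BASE = 0.020
ARRAY_GAP = 0.230
EDGE_RING_CROSS = 0.050
EDGE_RING_TRIANGLE = 0.005

PATTERN_KINDS = (
    "empty",
    "crosses_1array",
    "crosses_2arrays",
    "crosses_4arrays",
    "crosses_full",
    "circles_full",
    "triangles_full",
)

ShapeName = Literal["cross", "circle", "triangle"]


@dataclass(frozen=True)
class ObstacleSpec:
    """A single obstacle: shape, anchor point and shape-specific dimensions.

    ``anchor`` is the cross center, the circle center, or the midpoint of the
    triangle base.  ``dimensions`` is ``(height, thickness)`` for crosses,
    ``(diameter,)`` for circles and ``(height, base)`` for triangles.
    ``orientation`` rotates the obstacle about its anchor (radians, CCW).
    """

    shape: ShapeName
    anchor: tuple[float, float]
    dimensions: tuple[float, ...]
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("cross", "circle", "triangle"):
            raise ConfigurationError(f"unknown obstacle shape {self.shape!r}")
        if any(d <= 0 for d in self.dimensions):
            raise ConfigurationError("obstacle dimensions must be positive")

    @property
    def area(self) -> float:
        if self.shape == "cross":
            h, t = self.dimensions
            return 2.0 * h * t - t * t
        if self.shape == "circle":
            (d,) = self.dimensions
            return math.pi * (d / 2.0) ** 2
        h, b = self.dimensions
        return 0.5 * b * h

    def polygons(self) -> list[np.ndarray]:
        """CCW vertex arrays of the convex parts (empty for circles)."""
        if self.shape == "circle":
            return []
        ax, ay = self.anchor
        if self.shape == "cross":
            h, t = self.dimensions
            parts = [
                _rect(-h / 2, -t / 2, h / 2, t / 2),
                _rect(-t / 2, -h / 2, t / 2, h / 2),
            ]
        else:
            h, b = self.dimensions
            parts = [np.array([[-b / 2, 0.0], [b / 2, 0.0], [0.0, h]])]
        out = []
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        for p in parts:
            out.append(p @ rot.T + np.array([ax, ay]))
        return out


def _rect(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


@dataclass(frozen=True)
class CompiledGeometry:
    """Flat arrays for fast point/segment queries.

    ``edges``/``edge_normals``: all convex-polygon edges with unit outward
    normals; ``edge_part``: index of the convex part owning each edge;
    ``part_slices``: (start, stop) into ``edges`` per convex part;
    ``part_obstacle``: obstacle index per convex part; ``circles``: (n, 3)
    array of cx, cy, r.
    """

    edges: np.ndarray          # (m, 4) x1 y1 x2 y2
    edge_normals: np.ndarray   # (m, 2)
    part_slices: np.ndarray    # (p, 2)
    part_obstacle: np.ndarray  # (p,)
    circles: np.ndarray        # (c, 3)
    circle_obstacle: np.ndarray  # (c,)
    radius: float              # substrate radius


@dataclass(frozen=True)
class SubstratePattern:
    """A circular substrate plus its obstacle set."""

    diameter: float
    obstacles: tuple[ObstacleSpec, ...]
    edge_ring_width: float = EDGE_RING_CROSS
    scale_factor: float = 1.0
    kind: str = "custom"

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigurationError("diameter must be positive")

    # compiled geometry is derived data; cache it on first use
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def geometry(self) -> CompiledGeometry:
        if "geom" not in self._cache:
            self._cache["geom"] = _compile(self)
        return self._cache["geom"]

    def point_in_obstacle(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which of the (n, 2) points lie inside an obstacle."""
        return _points_in_obstacle(self.geometry, np.atleast_2d(points))

    def in_allowed_region(self, points: np.ndarray) -> np.ndarray:
        """Inside the disc and outside every obstacle."""
        pts = np.atleast_2d(points)
        inside = np.hypot(pts[:, 0], pts[:, 1]) <= self.radius
        return inside & ~self.point_in_obstacle(pts)

    def area_fraction(self) -> float:
        return area_fraction(self)


def _compile(pattern: SubstratePattern) -> CompiledGeometry:
    edges, normals, slices, part_obs = [], [], [], []
    circles, circ_obs = [], []
    for oi, obs in enumerate(pattern.obstacles):
        if obs.shape == "circle":
            circles.append([obs.anchor[0], obs.anchor[1], obs.dimensions[0] / 2.0])
            circ_obs.append(oi)
            continue
        for poly in obs.polygons():
            start = len(edges)
            n = len(poly)
            for k in range(n):
                a, b = poly[k], poly[(k + 1) % n]
                d = b - a
                ln = math.hypot(*d)
                # CCW polygon: interior on the left, outward normal on the right
                normals.append([d[1] / ln, -d[0] / ln])
                edges.append([a[0], a[1], b[0], b[1]])
            slices.append([start, len(edges)])
            part_obs.append(oi)
    return CompiledGeometry(
        edges=np.asarray(edges, float).reshape(-1, 4),
        edge_normals=np.asarray(normals, float).reshape(-1, 2),
        part_slices=np.asarray(slices, int).reshape(-1, 2),
        part_obstacle=np.asarray(part_obs, int),
        circles=np.asarray(circles, float).reshape(-1, 3),
        circle_obstacle=np.asarray(circ_obs, int),
        radius=pattern.radius,
    )


def _edge_side(px, py, e, nrm) -> np.ndarray:
    """Half-open membership w.r.t. one CCW edge: strictly inside, or exactly
    on the boundary when the outward normal points toward -x (or straight
    -y).  The half-open rule makes abutting shapes partition the plane and
    removes the one-pixel-per-edge bias in rasterization."""
    s = (px - e[0]) * nrm[0] + (py - e[1]) * nrm[1]
    on = np.abs(s) <= 1e-12
    include_boundary = nrm[0] < -1e-15 or (abs(nrm[0]) <= 1e-15 and nrm[1] < 0)
    return (s < -1e-12) | (on if include_boundary else False)


def _points_in_obstacle(geom: CompiledGeometry, pts: np.ndarray) -> np.ndarray:
    out = np.zeros(len(pts), bool)
    for cx, cy, r in geom.circles:
        out |= (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= r * r
    for start, stop in geom.part_slices:
        inside = np.ones(len(pts), bool)
        for e, nrm in zip(geom.edges[start:stop], geom.edge_normals[start:stop]):
            inside &= _edge_side(pts[:, 0], pts[:, 1], e, nrm)
            if not inside.any():
                break
        out |= inside
    return out


# ---------------------------------------------------------------------------
# built-in patterns


def build_pattern(
    kind: str,
    diameter: float = 2.0,
    scale_factor: float = 1.0,
) -> SubstratePattern:
    """Build one of the built-in obstacle layouts.

    ``diameter`` is the unscaled substrate diameter in mm (2 or 4);
    ``scale_factor`` scales every dimension (substrate and obstacles alike),
    which preserves the obstacle area fraction.
    """
    if kind not in PATTERN_KINDS:
        raise ConfigurationError(f"unknown pattern kind {kind!r}; expected one of {PATTERN_KINDS}")
    if diameter not in (2.0, 2, 4.0, 4):
        raise ConfigurationError("diameter must be 2 or 4 mm before scaling")
    if scale_factor not in (1, 2, 3, 4, 6, 1.0, 2.0, 3.0, 4.0, 6.0):
        raise ConfigurationError("scale_factor must be one of 1, 2, 3, 4, 6")
    if kind == "crosses_4arrays" and diameter not in (4, 4.0):
        raise ConfigurationError("crosses_4arrays is only defined for the 4 mm substrate")

    s = float(scale_factor)
    R = float(diameter) / 2.0 * s
    ring = (EDGE_RING_TRIANGLE if kind == "triangles_full" else EDGE_RING_CROSS) * s

    if kind == "empty":
        obstacles: list[ObstacleSpec] = []
    elif kind == "crosses_full":
        obstacles = _cross_lattice(R, keep_radius=R - ring, s=s)
    elif kind in ("crosses_1array", "crosses_2arrays", "crosses_4arrays"):
        n_arrays = {"crosses_1array": 1, "crosses_2arrays": 2, "crosses_4arrays": 4}[kind]
        obstacles = _cross_arrays(n_arrays, s)
    elif kind == "circles_full":
        obstacles = _circle_lattice(R, keep_radius=R, s=s)
    else:  # triangles_full
        obstacles = _triangle_lattice(R, keep_radius=R - ring, s=s)

    return SubstratePattern(
        diameter=float(diameter) * s,
        obstacles=tuple(obstacles),
        edge_ring_width=ring,
        scale_factor=s,
        kind=kind,
    )


def _cross(anchor: tuple[float, float], s: float) -> ObstacleSpec:
    return ObstacleSpec("cross", anchor, (CROSS_SIZE * s, CROSS_THICKNESS * s))


def _cross_lattice(R: float, keep_radius: float, s: float) -> list[ObstacleSpec]:
    pitch = (CROSS_SIZE + CROSS_GAP) * s
    n = int(math.ceil(keep_radius / pitch)) + 1
    out = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            x, y = i * pitch, j * pitch
            if math.hypot(x, y) <= keep_radius + 1e-12:
                out.append(_cross((x, y), s))
    return out


def _cross_arrays(n_arrays: int, s: float) -> list[ObstacleSpec]:
    pitch = (CROSS_SIZE + CROSS_GAP) * s
    side = (4 * CROSS_SIZE + 3 * CROSS_GAP) * s  # 0.670 mm at scale 1
    if n_arrays == 1:
        centers = [(0.0, 0.0)]
    elif n_arrays == 2:
        off = (side + ARRAY_GAP * s) / 2.0
        centers = [(-off, 0.0), (off, 0.0)]
    else:
        off = (side + ARRAY_GAP * s) / 2.0
        centers = [(-off, -off), (off, -off), (-off, off), (off, off)]
    out = []
    for cx, cy in centers:
        for i in range(4):
            for j in range(4):
                out.append(_cross((cx + (i - 1.5) * pitch, cy + (j - 1.5) * pitch), s))
    return out


def _circle_lattice(R: float, keep_radius: float, s: float) -> list[ObstacleSpec]:
    pitch = (CIRCLE_DIAMETER + CIRCLE_GAP) * s
    dy = pitch * math.sqrt(3.0) / 2.0
    n = int(math.ceil(keep_radius / min(pitch, dy))) + 2
    out = []
    for k in range(-n, n + 1):
        y = (k + 0.5) * dy  # rows straddle the horizontal axis
        xoff = pitch / 2.0 if k % 2 else 0.0
        for i in range(-n, n + 1):
            x = i * pitch + xoff
            if math.hypot(x, y) <= keep_radius + 1e-12:
                out.append(ObstacleSpec("circle", (x, y), (CIRCLE_DIAMETER * s,)))
    return out


def _triangle_lattice(R: float, keep_radius: float, s: float) -> list[ObstacleSpec]:
    # rectangular grid: columns 25 um apart (5 um gaps between side-by-side
    # bases) and rows 55 um apart (5 um gap between an apex and the base
    # above), no stagger.  The resulting array is a ratchet: downward-growing
    # axons are funnelled by the flanks into the base slots while upward-
    # growing ones bounce off the flat base undersides.
    ax = (TRIANGLE_BASE + 0.005) * s
    ay = (TRIANGLE_HEIGHT + 0.005) * s
    n = int(math.ceil(keep_radius / min(ax, ay))) + 2
    out = []
    for n2 in range(-n, n + 1):
        y = n2 * ay
        if abs(y) > keep_radius + ay:
            continue
        for n1 in range(-n, n + 1):
            x = n1 * ax
            if math.hypot(x, y) <= keep_radius + 1e-12:
                out.append(
                    ObstacleSpec("triangle", (x, y), (TRIANGLE_HEIGHT * s, TRIANGLE_BASE * s))
                )
    return out


def area_fraction(pattern: SubstratePattern) -> float:
    """Obstacle area divided by disc area (full shape areas, no clipping)."""
    disc = math.pi * pattern.radius**2
    return sum(o.area for o in pattern.obstacles) / disc


# ---------------------------------------------------------------------------
# segment queries


@dataclass(frozen=True)
class Hit:
    """Earliest intersection of a directed segment with the obstacle set/rim."""

    t: float                    # parametric position along the segment, in (0, 1]
    point: tuple[float, float]
    normal: tuple[float, float]  # unit outward normal, normal . direction < 0
    boundary: str               # "obstacle" or "rim"


def first_hit(
    segment: Sequence[Sequence[float]] | np.ndarray,
    pattern: SubstratePattern,
) -> Hit | None:
    """Earliest intersection of ``segment`` (= [[x0, y0], [x1, y1]]) with any
    obstacle boundary or the substrate rim, with the unit outward normal there.

    Returns None when the whole segment stays in the allowed region.  Raises
    :class:`GeometryError` when the segment starts inside an obstacle.
    """
    seg = np.asarray(segment, float)
    p, q = seg[0], seg[1]
    if pattern.point_in_obstacle(p[None, :])[0]:
        raise GeometryError("segment start lies inside an obstacle")
    geom = pattern.geometry
    t, nx, ny, kind = _hit_candidates(
        p[0], p[1], q[0], q[1], geom.edges, geom.edge_normals, geom.circles, geom.radius
    )
    if t > 1.0:
        return None
    hx, hy = p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])
    return Hit(t=float(t), point=(hx, hy), normal=(nx, ny), boundary=kind)


def _hit_candidates(px, py, qx, qy, edges, normals, circles, R):
    """Earliest hit among polygon edges, circle boundaries and the rim.

    Returns (t, nx, ny, kind); t = inf (> 1) means no hit.  Pure-numpy
    reference implementation; the growth engine uses a numba twin of the same
    math (see growth._trace kernels) validated against this one.
    """
    dx, dy = qx - px, qy - py
    best_t, best_n, kind = np.inf, (0.0, 0.0), "obstacle"
    eps = 1e-12

    if len(edges):
        ex, ey = edges[:, 0], edges[:, 1]
        fx, fy = edges[:, 2] - ex, edges[:, 3] - ey
        denom = dx * fy - dy * fx
        approach = normals[:, 0] * dx + normals[:, 1] * dy  # must be < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((ex - px) * fy - (ey - py) * fx) / denom
            u = ((ex - px) * dy - (ey - py) * dx) / denom
        ok = (np.abs(denom) > eps) & (approach < -eps) & (t > eps) & (t <= 1.0)
        ok &= (u >= -1e-9) & (u <= 1.0 + 1e-9)
        if ok.any():
            i = np.argmin(np.where(ok, t, np.inf))
            best_t = t[i]
            best_n = (normals[i, 0], normals[i, 1])

    for cx, cy, r in circles:
        t = _ray_circle(px - cx, py - cy, dx, dy, r, outside=True)
        if eps < t <= 1.0 and t < best_t:
            hx, hy = px + t * dx - cx, py + t * dy - cy
            best_t, best_n = t, (hx / r, hy / r)

    # substrate rim: reflecting wall seen from inside
    t = _ray_circle(px, py, dx, dy, R, outside=False)
    if eps < t <= 1.0 and t < best_t:
        hx, hy = px + t * dx, py + t * dy
        best_t, best_n, kind = t, (-hx / R, -hy / R), "rim"

    return best_t, best_n[0], best_n[1], kind


def _ray_circle(rx, ry, dx, dy, r, outside: bool) -> float:
    """Smallest t > 0 with |(rx, ry) + t (dx, dy)| = r.

    ``outside`` selects the entering root (start outside the circle); otherwise
    the exiting root (start inside, used for the substrate rim).
    """
    a = dx * dx + dy * dy
    if a == 0.0:
        return np.inf
    b = rx * dx + ry * dy
    c = rx * rx + ry * ry - r * r
    disc = b * b - a * c
    if disc <= 0.0:
        return np.inf
    root = math.sqrt(disc)
    if outside:
        if c < 0.0:  # started inside an obstacle circle: treat as no hit here
            return np.inf
        t = (-b - root) / a
    else:
        t = (-b + root) / a
    return t if t > 0.0 else np.inf


# ---------------------------------------------------------------------------
# rasterization and mask I/O


@dataclass(frozen=True)
class RasterMask:
    """Pixel view of a pattern: ``allowed`` (in-disc, non-obstacle) and
    ``obstacle`` grids, with the substrate center at the grid center and +y
    upward (row 0 is the top row)."""

    allowed: np.ndarray    # bool (ny, nx)
    obstacle: np.ndarray   # bool (ny, nx)
    resolution: float      # mm per pixel
    diameter: float

    @property
    def obstacle_fraction(self) -> float:
        """White-pixel count over disc-pixel count (cross-check of
        :func:`area_fraction`; counts overhanging obstacle pixels like the
        analytic value counts full shape areas)."""
        n_disc = int(self.allowed.sum() + (self.obstacle & self._disc()).sum())
        return float(self.obstacle.sum()) / n_disc

    def _disc(self) -> np.ndarray:
        ny, nx = self.allowed.shape
        xs, ys = _pixel_centers(nx, ny, self.resolution)
        return (xs[None, :] ** 2 + ys[:, None] ** 2) <= (self.diameter / 2.0) ** 2


def _pixel_centers(nx: int, ny: int, res: float) -> tuple[np.ndarray, np.ndarray]:
    # half-pixel offset: centers avoid the lattice lines obstacle edges sit
    # on, which keeps pixel counting unbiased for thin features
    xs = (np.arange(nx) - nx / 2.0 + 0.5) * res
    ys = (ny / 2.0 - np.arange(ny) - 0.5) * res  # +y upward
    return xs, ys


def rasterize(pattern: SubstratePattern, resolution: float = 0.001) -> RasterMask:
    """Rasterize at ``resolution`` mm/pixel; pixel centers are classified with
    the same point-membership predicate used by the growth engine."""
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    R = pattern.radius
    half = R + 0.1 * R  # margin for overhanging boundary obstacles
    n = 2 * int(math.ceil(half / resolution))
    xs, ys = _pixel_centers(n, n, resolution)
    geom = pattern.geometry
    obstacle = np.zeros((n, n), bool)
    # classify per obstacle part over its bounding box only
    for start, stop in geom.part_slices:
        e = geom.edges[start:stop]
        _paint_part(obstacle, xs, ys, e, geom.edge_normals[start:stop])
    for cx, cy, r in geom.circles:
        ix = np.flatnonzero(np.abs(xs - cx) <= r)
        iy = np.flatnonzero(np.abs(ys - cy) <= r)
        if len(ix) and len(iy):
            sub = (xs[ix][None, :] - cx) ** 2 + (ys[iy][:, None] - cy) ** 2 <= r * r
            obstacle[np.ix_(iy, ix)] |= sub
    disc = (xs[None, :] ** 2 + ys[:, None] ** 2) <= R * R
    return RasterMask(
        allowed=disc & ~obstacle, obstacle=obstacle,
        resolution=resolution, diameter=pattern.diameter,
    )


def _paint_part(obstacle, xs, ys, edges, normals) -> None:
    x0 = min(edges[:, 0].min(), edges[:, 2].min())
    x1 = max(edges[:, 0].max(), edges[:, 2].max())
    y0 = min(edges[:, 1].min(), edges[:, 3].min())
    y1 = max(edges[:, 1].max(), edges[:, 3].max())
    ix = np.flatnonzero((xs >= x0 - 1e-12) & (xs <= x1 + 1e-12))
    iy = np.flatnonzero((ys >= y0 - 1e-12) & (ys <= y1 + 1e-12))
    if not (len(ix) and len(iy)):
        return
    gx = np.broadcast_to(xs[ix][None, :], (len(iy), len(ix)))
    gy = np.broadcast_to(ys[iy][:, None], (len(iy), len(ix)))
    inside = np.ones((len(iy), len(ix)), bool)
    for e, nrm in zip(edges, normals):
        inside &= _edge_side(gx, gy, e, nrm)
    obstacle[np.ix_(iy, ix)] |= inside


def save_mask(mask: RasterMask, path: str | Path) -> None:
    """Write the mask as a monochrome PNG (white = obstacle, black = substrate)
    plus a JSON sidecar with resolution and diameter."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray((mask.obstacle * 255).astype(np.uint8), mode="L")
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "resolution_mm_per_pixel": mask.resolution,
        "diameter_mm": mask.diameter,
        "convention": "white=obstacle,black=substrate,y-up",
    }))


def load_mask(path: str | Path) -> RasterMask:
    from PIL import Image

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    obstacle = np.asarray(Image.open(path).convert("L")) >= 128
    res = float(sidecar["resolution_mm_per_pixel"])
    diam = float(sidecar["diameter_mm"])
    ny, nx = obstacle.shape
    xs, ys = _pixel_centers(nx, ny, res)
    disc = (xs[None, :] ** 2 + ys[:, None] ** 2) <= (diam / 2.0) ** 2
    return RasterMask(allowed=disc & ~obstacle, obstacle=obstacle,
                      resolution=res, diameter=diam)


class RasterSubstrate:
    """Adapter that lets a raster mask (user-supplied monochrome image) stand
    in for a parametric pattern in the growth engine.

    Point membership is a pixel lookup; segment hits are located by marching at
    quarter-pixel steps and refined by bisection, and the boundary normal is
    estimated from the local obstacle-indicator gradient.  Adequate for axon
    growth whose segments (10 um) are much longer than a 1 um pixel.
    """

    def __init__(self, mask: RasterMask):
        self.mask = mask
        self.diameter = mask.diameter
        self.radius = mask.diameter / 2.0
        self.obstacles: tuple = ()
        self.kind = "raster"
        ny, nx = mask.obstacle.shape
        self._nx, self._ny = nx, ny
        self._res = mask.resolution

    def point_in_obstacle(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        col = np.round(pts[:, 0] / self._res + (self._nx - 1) / 2.0).astype(int)
        row = np.round((self._ny - 1) / 2.0 - pts[:, 1] / self._res).astype(int)
        ok = (col >= 0) & (col < self._nx) & (row >= 0) & (row < self._ny)
        out = np.zeros(len(pts), bool)
        out[ok] = self.mask.obstacle[row[ok], col[ok]]
        return out

    def in_allowed_region(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        inside = np.hypot(pts[:, 0], pts[:, 1]) <= self.radius
        return inside & ~self.point_in_obstacle(pts)

    def first_hit(self, segment) -> Hit | None:
        seg = np.asarray(segment, float)
        p, q = seg[0], seg[1]
        if self.point_in_obstacle(p[None, :])[0]:
            raise GeometryError("segment start lies inside an obstacle")
        # rim first (analytic)
        t_rim = _ray_circle(p[0], p[1], q[0] - p[0], q[1] - p[1], self.radius, outside=False)
        length = math.hypot(q[0] - p[0], q[1] - p[1])
        n_steps = max(2, int(length / (self._res / 4.0)))
        ts = np.linspace(0.0, 1.0, n_steps + 1)
        pts = p[None, :] + ts[:, None] * (q - p)[None, :]
        hit_idx = np.flatnonzero(self.point_in_obstacle(pts))
        t_obs = np.inf
        if len(hit_idx):
            lo, hi = ts[hit_idx[0] - 1], ts[hit_idx[0]]
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if self.point_in_obstacle((p + mid * (q - p))[None, :])[0]:
                    hi = mid
                else:
                    lo = mid
            t_obs = hi
        t = min(t_obs, t_rim)
        if not (0.0 < t <= 1.0):
            return None
        hx, hy = p + t * (q - p)
        if t_rim <= t_obs:
            return Hit(t=float(t), point=(hx, hy),
                       normal=(-hx / self.radius, -hy / self.radius), boundary="rim")
        nx, ny = self._gradient_normal(hx, hy)
        return Hit(t=float(t), point=(hx, hy), normal=(nx, ny), boundary="obstacle")

    def _gradient_normal(self, x: float, y: float) -> tuple[float, float]:
        # outward normal ~ -grad(obstacle indicator), smoothed over a small disc
        h = 3 * self._res
        offs = np.array([(i, j) for i in (-2, -1, 0, 1, 2) for j in (-2, -1, 0, 1, 2)], float)
        pts = np.array([x, y])[None, :] + offs * (h / 2.0)
        vals = self.point_in_obstacle(pts).astype(float)
        gx = float((offs[:, 0] * vals).sum())
        gy = float((offs[:, 1] * vals).sum())
        norm = math.hypot(gx, gy)
        if norm == 0.0:
            return (1.0, 0.0)
        return (-gx / norm, -gy / norm)


# ---------------------------------------------------------------------------
# pattern (de)serialization


def pattern_to_json(pattern: SubstratePattern) -> str:
    return json.dumps({
        "diameter": pattern.diameter,
        "edge_ring_width": pattern.edge_ring_width,
        "scale_factor": pattern.scale_factor,
        "kind": pattern.kind,
        "obstacles": [
            {"shape": o.shape, "anchor": list(o.anchor),
             "dimensions": list(o.dimensions), "orientation": o.orientation}
            for o in pattern.obstacles
        ],
    })


def pattern_from_json(text: str) -> SubstratePattern:
    d = json.loads(text)
    return SubstratePattern(
        diameter=d["diameter"],
        obstacles=tuple(
            ObstacleSpec(o["shape"], tuple(o["anchor"]), tuple(o["dimensions"]),
                         o.get("orientation", 0.0))
            for o in d["obstacles"]
        ),
        edge_ring_width=d.get("edge_ring_width", EDGE_RING_CROSS),
        scale_factor=d.get("scale_factor", 1.0),
        kind=d.get("kind", "custom"),
    )
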