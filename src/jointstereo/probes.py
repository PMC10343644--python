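"""Stereological test systems: point grids, cycloid arc systems, counting frames.

All probes live in the 2-D plane of a histological section, in micrometres.
Each supports randomized placement (uniform random offset within one period)
as required for systematic uniform random sampling, and deterministic
enumeration of its elements over a bounded extent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, SamplingInfeasibleError

__all__ = [
    "Extent",
    "PointGrid",
    "CycloidSystem",
    "CountingFrame",
    "FrameSet",
    "ProbeSet",
    "build_point_grid",
    "build_cycloid_system",
    "build_frame_set",
]


@dataclass(frozen=True)
class Extent:
    """Axis-aligned bounding rectangle [xmin, xmax] x [ymin, ymax] in µm."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise InvalidParameterError(
                f"degenerate extent: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin


# ---------------------------------------------------------------------------
# Point grid (Cavalieri / Delesse point counting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointGrid:
    """Square grid of test points; each point represents ``area_per_point`` µm²
    (the probe constant a/p), so the grid pitch is sqrt(a/p)."""

    area_per_point: float
    spacing: float
    offset: np.ndarray  # (2,) µm, within [0, spacing)^2
    extent: Extent

    def __post_init__(self) -> None:
        if self.area_per_point <= 0:
            raise InvalidParameterError("area_per_point must be > 0")
        if abs(self.spacing**2 - self.area_per_point) > 1e-9 * self.area_per_point:
            raise InvalidParameterError("spacing^2 must equal area_per_point")
        off = np.asarray(self.offset, dtype=float)
        if off.shape != (2,) or np.any(off < 0) or np.any(off >= self.spacing):
            raise InvalidParameterError("offset must lie in [0, spacing)^2")
        object.__setattr__(self, "offset", off)

    def points(self) -> np.ndarray:
        """Deterministic enumeration of grid points covering the extent,
        shape (n, 2), row-major from the lower-left corner."""
        s = self.spacing
        i0 = math.floor((self.extent.xmin - self.offset[0]) / s)
        i1 = math.ceil((self.extent.xmax - self.offset[0]) / s)
        j0 = math.floor((self.extent.ymin - self.offset[1]) / s)
        j1 = math.ceil((self.extent.ymax - self.offset[1]) / s)
        xs = self.offset[0] + s * np.arange(i0, i1 + 1)
        ys = self.offset[1] + s * np.arange(j0, j1 + 1)
        xs = xs[(xs >= self.extent.xmin) & (xs <= self.extent.xmax)]
        ys = ys[(ys >= self.extent.ymin) & (ys <= self.extent.ymax)]
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


def build_point_grid(
    area_per_point: float,
    extent: Extent,
    rng_seed: int | np.random.Generator,
) -> PointGrid:
    """Point grid with a uniform random offset within one grid cell."""
    if area_per_point <= 0:
        raise InvalidParameterError("area_per_point must be > 0")
    rng = np.random.default_rng(rng_seed)
    spacing = math.sqrt(area_per_point)
    offset = rng.uniform(0.0, spacing, size=2)
    return PointGrid(area_per_point, spacing, offset, extent)


# ---------------------------------------------------------------------------
# Cycloid test system (vertical-design surface estimation)
# ---------------------------------------------------------------------------

def _cycloid_vertex_count(r: float, tol: float) -> int:
    """Number of polyline segments per half-arc so the chord (sagitta) error
    stays below ``tol`` and the rendered length is within 0.1% of 4r."""
    n = 8
    while n < 4096:
        t = np.linspace(0.0, math.pi, n + 1)
        x = r * (t - np.sin(t))
        y = r * (1.0 - np.cos(t))
        seg = np.hypot(np.diff(x), np.diff(y))
        length = seg.sum()
        # sagitta estimated from midpoint deviation
        tm = 0.5 * (t[:-1] + t[1:])
        xm = r * (tm - np.sin(tm))
        ym = r * (1.0 - np.cos(tm))
        mx = 0.5 * (x[:-1] + x[1:])
        my = 0.5 * (y[:-1] + y[1:])
        sag = np.hypot(xm - mx, ym - my).max()
        if sag <= tol and abs(length - 4.0 * r) <= 1e-3 * 4.0 * r:
            return n
        n *= 2
    return n


@dataclass(frozen=True)
class CycloidSystem:
    """Tiling of cycloid half-arcs with one test point per arc.

    Each arc is a half cycloid (parameter t in [0, pi], length 4r where
    r = ``arc_scale``), rendered with its minor (2r) axis parallel to
    ``vertical_direction``.  The tangent direction of such an arc is
    sine-weighted with respect to the vertical axis, which is what makes
    intersection counts on vertical sections unbiased for surface area.

    ``cell_width`` x ``cell_height`` is the tile each arc (and its test
    point) occupies; the test-point density is 1/(cell area).  By default
    the tile is the arc's tight bounding box (pi*r x 2r); the simulator
    passes ``area_per_point`` so the cycloid's test points have the same
    density as the Cavalieri/Delesse point grid.
    """

    length_per_point: float
    arc_scale: float  # generating-circle radius r = (l/p)/4
    vertical_direction: np.ndarray  # (2,) unit vector
    offset: np.ndarray  # (2,) µm within one tile
    extent: Extent
    cell_width: float
    cell_height: float
    phase_mirror: bool = True
    polyline_tolerance: float = 0.25
    n_segments: int = field(default=0)

    def __post_init__(self) -> None:
        if self.length_per_point <= 0:
            raise InvalidParameterError("length_per_point must be > 0")
        v = np.asarray(self.vertical_direction, dtype=float)
        nv = np.linalg.norm(v)
        if nv == 0:
            raise InvalidParameterError("vertical_direction must be non-zero")
        object.__setattr__(self, "vertical_direction", v / nv)
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.n_segments == 0:
            object.__setattr__(
                self,
                "n_segments",
                _cycloid_vertex_count(self.arc_scale, self.polyline_tolerance),
            )

    def _base_arc(self) -> np.ndarray:
        """Half-arc polyline in tile-local coordinates, (n_segments+1, 2):
        local x horizontal (span pi*r), local y vertical (span 2r)."""
        t = np.linspace(0.0, math.pi, self.n_segments + 1)
        r = self.arc_scale
        return np.column_stack([r * (t - np.sin(t)), r * (1.0 - np.cos(t))])

    def arcs(self) -> tuple[np.ndarray, np.ndarray]:
        """Render all arcs whose tiles intersect the extent.

        Returns ``(vertices, points)`` where ``vertices`` has shape
        (n_arcs, n_segments+1, 2) in world coordinates and ``points`` is the
        (n_arcs, 2) array of associated test points (one per arc, at the
        tile's anchor corner).
        """
        v = self.vertical_direction
        h = np.array([v[1], -v[0]])  # horizontal in-plane direction
        # transform extent corners into the probe frame (h, v)
        corners = np.array(
            [
                [self.extent.xmin, self.extent.ymin],
                [self.extent.xmin, self.extent.ymax],
                [self.extent.xmax, self.extent.ymin],
                [self.extent.xmax, self.extent.ymax],
            ]
        )
        basis = np.stack([h, v], axis=1)  # world <- local
        local = corners @ basis  # project onto h, v
        lx0, ly0 = local.min(axis=0)
        lx1, ly1 = local.max(axis=0)
        cw, ch = self.cell_width, self.cell_height
        i0 = math.floor((lx0 - self.offset[0]) / cw) - 1
        i1 = math.ceil((lx1 - self.offset[0]) / cw) + 1
        j0 = math.floor((ly0 - self.offset[1]) / ch) - 1
        j1 = math.ceil((ly1 - self.offset[1]) / ch) + 1
        base = self._base_arc()
        r = self.arc_scale
        # center the arc's bounding box (pi*r x 2r) within the tile
        pad_x = 0.5 * (cw - math.pi * r)
        jj = np.arange(j0, j1 + 1)
        ii = np.arange(i0, i1 + 1)
        ax = self.offset[0] + ii * cw  # (ni,)
        ay = self.offset[1] + jj * ch  # (nj,)
        mirrored = base.copy()
        mirrored[:, 0] = math.pi * r - mirrored[:, 0]
        # (nj, m, 2): arc template per row, alternate rows mirrored
        rows = np.where(
            (self.phase_mirror & (jj % 2 == 1))[:, None, None],
            mirrored[None, :, :],
            base[None, :, :],
        )
        m = base.shape[0]
        arcs_local = np.empty((jj.size, ii.size, m, 2))
        arcs_local[..., 0] = rows[:, None, :, 0] + (ax + pad_x)[None, :, None]
        arcs_local[..., 1] = rows[:, None, :, 1] + ay[:, None, None]
        anchors_local = np.empty((jj.size, ii.size, 2))
        anchors_local[..., 0] = ax[None, :]
        anchors_local[..., 1] = ay[:, None]
        world = arcs_local.reshape(-1, m, 2) @ basis.T
        pts = anchors_local.reshape(-1, 2) @ basis.T
        return world, pts

    def rendered_length(self) -> float:
        """Polyline length of one rendered arc (µm)."""
        base = self._base_arc()
        return float(np.hypot(*np.diff(base, axis=0).T).sum())


def build_cycloid_system(
    length_per_point: float,
    vertical_direction: Sequence[float],
    extent: Extent,
    rng_seed: int | np.random.Generator,
    *,
    area_per_point: float | None = None,
    polyline_tolerance: float = 0.25,
) -> CycloidSystem:
    """Cycloid test system with uniform random offset within one tile.

    ``area_per_point`` sets the tile area (test-point density 1/area);
    when omitted the arcs tile the plane tightly (tile = pi*r x 2r).
    """
    if length_per_point <= 0:
        raise InvalidParameterError("length_per_point must be > 0")
    rng = np.random.default_rng(rng_seed)
    r = length_per_point / 4.0
    ch = 2.0 * r
    if area_per_point is None:
        cw = math.pi * r
    else:
        if area_per_point <= 0:
            raise InvalidParameterError("area_per_point must be > 0")
        cw = area_per_point / ch
        if cw < math.pi * r:
            raise InvalidParameterError(
                "area_per_point too small: the cycloid arc does not fit the tile"
            )
    offset = rng.uniform(0.0, [cw, ch])
    return CycloidSystem(
        length_per_point=length_per_point,
        arc_scale=r,
        vertical_direction=np.asarray(vertical_direction, dtype=float),
        offset=offset,
        extent=extent,
        cell_width=cw,
        cell_height=ch,
        polyline_tolerance=polyline_tolerance,
    )


# ---------------------------------------------------------------------------
# Unbiased counting frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountingFrame:
    """Rectangular unbiased counting frame.

    The forbidden (exclusion) line is the left and bottom edge with their
    corner extensions; the acceptance line is the top and right edge.  A
    point profile is counted iff origin_x < x <= origin_x + width and
    origin_y < y <= origin_y + height, so frames tiling a rectangle count
    every point exactly once.
    """

    origin: np.ndarray  # (2,) lower-left corner, µm
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("frame width and height must be > 0")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Half-open counting rule; ``points`` shape (n, 2) -> bool (n,)."""
        pts = np.atleast_2d(points)
        x0, y0 = self.origin
        return (
            (pts[:, 0] > x0)
            & (pts[:, 0] <= x0 + self.width)
            & (pts[:, 1] > y0)
            & (pts[:, 1] <= y0 + self.height)
        )


@dataclass(frozen=True)
class FrameSet:
    frames: tuple[CountingFrame, ...]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def check_disjoint(self) -> bool:
        """Interiors must not overlap; shared edges (an exact tiling) are
        allowed, with a relative tolerance absorbing floating-point jitter."""
        fs = self.frames
        for i in range(len(fs)):
            for j in range(i + 1, len(fs)):
                a, b = fs[i], fs[j]
                eps = 1e-9 * max(a.width, a.height, b.width, b.height)
                if (
                    a.origin[0] < b.origin[0] + b.width - eps
                    and b.origin[0] < a.origin[0] + a.width - eps
                    and a.origin[1] < b.origin[1] + b.height - eps
                    and b.origin[1] < a.origin[1] + a.height - eps
                ):
                    return False
        return True


def build_frame_set(
    area: float,
    n_frames: int,
    region,
    rng_seed: int | np.random.Generator,
    *,
    aspect: float = 1.0,
) -> FrameSet:
    """Place ``n_frames`` congruent disjoint frames of the given area inside
    ``region`` (a shapely geometry or an :class:`Extent`) by systematic
    uniform random positioning.

    Candidate positions form a square lattice with a random offset; the
    lattice pitch is at least one frame side (guaranteeing disjointness) and
    candidates whose frame is not fully inside the region are discarded.
    The accepted candidates are thinned systematically to ``n_frames``.
    """
    from shapely.geometry import box as shapely_box
    from shapely.prepared import prep

    if area <= 0:
        raise InvalidParameterError("frame area must be > 0")
    if n_frames < 0:
        raise InvalidParameterError("n_frames must be >= 0")
    if n_frames == 0:
        return FrameSet(frames=())
    rng = np.random.default_rng(rng_seed)
    w = math.sqrt(area * aspect)
    h = area / w
    if isinstance(region, Extent):
        region = shapely_box(region.xmin, region.ymin, region.xmax, region.ymax)
    minx, miny, maxx, maxy = region.bounds
    if maxx - minx < w or maxy - miny < h:
        limiting = "width" if maxx - minx < w else "height"
        raise SamplingInfeasibleError(
            f"region {limiting} too small for a {w:.3g} x {h:.3g} µm frame"
        )
    prepared = prep(region)
    pitch = max(w, h)
    while True:
        ox = minx + rng.uniform(0.0, pitch)
        oy = miny + rng.uniform(0.0, pitch)
        xs = np.arange(ox - pitch, maxx + pitch, pitch)
        ys = np.arange(oy - pitch, maxy + pitch, pitch)
        cand = []
        for y in ys:
            for x in xs:
                if prepared.contains(shapely_box(x, y, x + w, y + h)):
                    cand.append((x, y))
        if len(cand) >= n_frames:
            break
        # one retry with a fresh offset before declaring infeasibility
        ox2 = minx + rng.uniform(0.0, pitch)
        oy2 = miny + rng.uniform(0.0, pitch)
        cand = [
            (x, y)
            for y in (oy2 + np.arange(-1, (maxy - miny) / pitch + 1) * pitch)
            for x in (ox2 + np.arange(-1, (maxx - minx) / pitch + 1) * pitch)
            if prepared.contains(shapely_box(x, y, x + w, y + h))
        ]
        if len(cand) >= n_frames:
            break
        raise SamplingInfeasibleError(
            f"region hosts only {len(cand)} disjoint frames of "
            f"{w:.3g} x {h:.3g} µm; {n_frames} requested"
        )
    idx = np.linspace(0, len(cand) - 1, n_frames).round().astype(int)
    frames = tuple(
        CountingFrame(origin=np.array(cand[i]), width=w, height=h) for i in idx
    )
    return FrameSet(frames=frames)


@dataclass(frozen=True)
class ProbeSet:
    """The probe constants of one study: point grid a/p, cycloid l/p,
    counting-frame area Af and frames per section."""

    area_per_point: float  # a/p, µm²
    length_per_point: float  # l/p, µm
    frame_area: float  # Af, µm²
    n_frames: int
    polyline_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if min(self.area_per_point, self.length_per_point, self.frame_area) <= 0:
            raise InvalidParameterError("probe constants must be > 0")
        if self.n_frames < 0:
            raise InvalidParameterError("n_frames must be >= 0")
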