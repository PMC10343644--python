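"""Vertical uniform random (VUR) sectioning of phantoms with simulated
probe counting.

A specimen is sectioned by parallel vertical planes (each containing the
z axis direction) at one random azimuth per specimen, at constant spacing
T with a uniform random start — the sampling design under which the
Cavalieri estimator is unbiased and cycloid intersection counts are
unbiased for surface area.

Each section is counted exactly as an observer would count a micrograph:
a randomly offset point grid for the Cavalieri/Delesse point counts, a
cycloid test system for interface intersections, and unbiased counting
frames inside the cartilage profile for chondrocyte profile counts.  The
result is a :class:`~jointstereo.estimators.SpecimenCounts` whose ground
truth is known, enabling Monte-Carlo validation of every estimator.

RNG streams are split hierarchically (specimen -> section -> probe) via
``SeedSequence`` spawn keys, so enlarging one stage never perturbs the
draws of another.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError, SamplingInfeasibleError
from .estimators import COMPONENTS, SURFACES, SectionCounts, SpecimenCounts
from .phantom import (
    COMPARTMENTS,
    CellFieldParams,
    CompartmentTruth,
    JointPhantom,
    phantom_truth,
)
from .probes import (
    CountingFrame,
    CycloidSystem,
    Extent,
    FrameSet,
    PointGrid,
    ProbeSet,
    build_cycloid_system,
    build_point_grid,
)

__all__ = [
    "SectionPlane",
    "CellPattern",
    "SimulatedSpecimen",
    "vur_section_planes",
    "count_points_on_section",
    "count_intersections_on_section",
    "scatter_cell_profiles",
    "count_frames",
    "place_frames_in_cartilage",
    "simulate_specimen",
]

_CARTILAGE = COMPARTMENTS.index("cartilage")  # membership code 1


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SectionPlane:
    """One vertical section: plane through ``position``·``normal`` spanned by
    the in-plane basis (horizontal ``h_axis``, vertical ``v_axis`` = z)."""

    index: int
    rotation_angle: float  # azimuth of the plane, radians in [0, pi)
    position: float  # signed distance from origin along the normal, µm
    normal: np.ndarray  # (3,) horizontal unit vector
    h_axis: np.ndarray  # (3,) in-plane horizontal unit vector
    v_axis: np.ndarray  # (3,) vertical unit vector (0, 0, 1)

    def to_world(self, xy: np.ndarray) -> np.ndarray:
        """Map in-plane (xi, eta) coordinates, shape (..., 2), to 3-D."""
        xy = np.asarray(xy, dtype=float)
        return (
            self.position * self.normal
            + xy[..., 0, None] * self.h_axis
            + xy[..., 1, None] * self.v_axis
        )


def vur_section_planes(
    phantom: JointPhantom, t_spacing: float, rng_seed: int | np.random.Generator
) -> list[SectionPlane]:
    """Systematic vertical planes with one shared random azimuth and one
    uniform random start in [0, T), covering the phantom's horizontal extent.

    The section count is floor(extent/T) or one more depending on the start
    (the study's 10-vs-11 sections behaviour).
    """
    if t_spacing <= 0:
        raise InvalidParameterError("t_spacing must be > 0")
    rng = np.random.default_rng(rng_seed)
    phi = rng.uniform(0.0, math.pi)
    s0 = rng.uniform(0.0, t_spacing)
    r = phantom.horizontal_radius
    normal = np.array([math.cos(phi), math.sin(phi), 0.0])
    h_axis = np.array([-math.sin(phi), math.cos(phi), 0.0])
    v_axis = np.array([0.0, 0.0, 1.0])
    positions = np.arange(-r + s0, r, t_spacing)
    planes = [
        SectionPlane(
            index=i,
            rotation_angle=phi,
            position=float(d),
            normal=normal,
            h_axis=h_axis,
            v_axis=v_axis,
        )
        for i, d in enumerate(positions)
    ]
    if not planes:
        raise SamplingInfeasibleError(
            f"T = {t_spacing} µm exceeds the phantom extent {2 * r:.1f} µm: no sections"
        )
    return planes


def _profile_half_widths(plane: SectionPlane, phantom: JointPhantom) -> tuple[float, float]:
    """Half extents (xi, eta) of the joint profile on this section."""
    d = abs(plane.position)
    r5 = phantom.horizontal_radius
    if d >= r5:
        return 0.0, 0.0
    a = math.sqrt(r5**2 - d**2)
    return a, a * phantom.vertical_scale


def _section_extent(plane: SectionPlane, phantom: JointPhantom) -> Extent | None:
    a, b = _profile_half_widths(plane, phantom)
    if a <= 0:
        return None
    return Extent(-a, -b, a, b)


def count_points_on_section(
    plane: SectionPlane, phantom: JointPhantom, grid: PointGrid
) -> dict[str, int]:
    """Classify every grid point by phantom membership.

    Returns ``p_ref`` (points anywhere in the joint) and ``p_<component>``
    per compartment; the membership partition guarantees that the component
    counts sum to ``p_ref`` exactly.
    """
    pts = grid.points()
    counts = {f"p_{c}": 0 for c in COMPONENTS}
    if pts.size == 0:
        return {"p_ref": 0, **counts}
    member = phantom.membership(plane.to_world(pts))
    for code, name in enumerate(COMPARTMENTS):
        counts[f"p_{name}"] = int(np.count_nonzero(member == code))
    return {"p_ref": int(np.count_nonzero(member >= 0)), **counts}


def count_intersections_on_section(
    plane: SectionPlane, phantom: JointPhantom, cycloids: CycloidSystem
) -> dict[str, int]:
    """Count transversal crossings of the cycloid polylines with the two
    tracked interfaces (cartilage edge at r2; synovial-membrane inner
    boundary), as sign changes of the inside indicator along each polyline.
    The half-open membership rule makes exact-touch vertices deterministic.
    """
    arcs, _ = cycloids.arcs()
    if arcs.size == 0:
        return {f"i_{s}": 0 for s in SURFACES}
    world = plane.to_world(arcs)  # (n_arcs, m, 3)
    c = phantom.vertical_scale
    u = world[..., 2] / c
    s = np.sqrt(world[..., 0] ** 2 + world[..., 1] ** 2 + u**2)
    out = {}
    # cartilage edge facing the synovial space: fixed radius r2
    inside = s <= phantom.radii[1]
    out["i_cartilage"] = int(np.count_nonzero(inside[:, 1:] != inside[:, :-1]))
    # membrane inner boundary: possibly angle-dependent (villous)
    with np.errstate(invalid="ignore"):
        cos_theta = np.where(s > 0, u / np.maximum(s, 1e-300), 1.0)
    b3 = phantom.boundary_radius(2, cos_theta)
    inside = s <= b3
    out["i_synovial_membrane"] = int(np.count_nonzero(inside[:, 1:] != inside[:, :-1]))
    return out


@dataclass(frozen=True)
class CellPattern:
    """Planar chondrocyte-profile pattern on one section (plane coords, µm).

    ``group_id`` is -1 for isolated profiles and a non-negative cluster id
    for members of isogenous groups.
    """

    xy: np.ndarray  # (n, 2)
    group_id: np.ndarray  # (n,) int

    @property
    def n(self) -> int:
        return self.xy.shape[0]


def _cartilage_mask(
    plane: SectionPlane, phantom: JointPhantom, xy: np.ndarray
) -> np.ndarray:
    return phantom.membership(plane.to_world(xy)) == _CARTILAGE


def scatter_cell_profiles(
    plane: SectionPlane,
    phantom: JointPhantom,
    params: CellFieldParams,
    rng_seed: int | np.random.Generator,
) -> CellPattern:
    """Simulate chondrocyte profiles on the section's cartilage region.

    Isolated profiles: homogeneous Poisson process with intensity
    ``lambda_isolated`` on the cartilage profile.  Isogenous groups: Poisson
    parents, each with 2 + Poisson(offspring_mean - 2) member profiles
    uniform within ``cluster_radius`` of the parent; members are kept inside
    the cartilage by rejection so every group retains >= 2 members.
    """
    rng = np.random.default_rng(rng_seed)
    d = abs(plane.position)
    r2 = phantom.radii[1]
    if d >= r2:
        empty = np.empty((0, 2))
        return CellPattern(xy=empty, group_id=np.empty(0, dtype=int))
    a = math.sqrt(r2**2 - d**2)
    b = a * phantom.vertical_scale
    bbox_area = (2 * a) * (2 * b)  # µm²

    def poisson_in_cartilage(lam_per_mm2: float) -> np.ndarray:
        n = rng.poisson(lam_per_mm2 * 1e-6 * bbox_area)
        if n == 0:
            return np.empty((0, 2))
        xy = rng.uniform([-a, -b], [a, b], size=(n, 2))
        return xy[_cartilage_mask(plane, phantom, xy)]

    iso = poisson_in_cartilage(params.lambda_isolated)
    parents = poisson_in_cartilage(params.lambda_parents)
    member_xy = [iso]
    member_gid = [np.full(iso.shape[0], -1, dtype=int)]
    for gid in range(parents.shape[0]):
        n_members = 2 + rng.poisson(params.offspring_mean - 2.0)
        placed = []
        for _ in range(n_members):
            pos = None
            for _attempt in range(100):
                ang = rng.uniform(0.0, 2 * math.pi)
                rad = params.cluster_radius * math.sqrt(rng.uniform())
                cand = parents[gid] + [rad * math.cos(ang), rad * math.sin(ang)]
                if _cartilage_mask(plane, phantom, cand[None, :])[0]:
                    pos = cand
                    break
            placed.append(pos if pos is not None else parents[gid].copy())
        member_xy.append(np.asarray(placed))
        member_gid.append(np.full(n_members, gid, dtype=int))
    xy = np.concatenate(member_xy) if member_xy else np.empty((0, 2))
    gid = np.concatenate(member_gid) if member_gid else np.empty(0, dtype=int)
    return CellPattern(xy=xy, group_id=gid)


def count_frames(
    pattern: CellPattern, frames: FrameSet
) -> tuple[int, int, int, int]:
    """Apply the unbiased counting rule of each frame to the point pattern.

    Returns ``(q_isolated, q_group_cells, q_groups, frames_used)``.  A point
    is counted iff it lies in the half-open frame region (interior plus top
    and right edges; the left/bottom forbidden line and its extensions
    exclude); a group is counted in ``q_groups`` iff at least one member is
    counted, and ``q_group_cells`` counts its counted members.
    """
    if not frames.check_disjoint():
        raise InvalidParameterError("counting frames must be pairwise disjoint")
    if pattern.n == 0 or frames.n_frames == 0:
        return 0, 0, 0, frames.n_frames
    counted = np.zeros(pattern.n, dtype=bool)
    for fr in frames.frames:
        counted |= fr.contains(pattern.xy)
    isolated = pattern.group_id < 0
    q_isolated = int(np.count_nonzero(counted & isolated))
    member = counted & ~isolated
    q_group_cells = int(np.count_nonzero(member))
    q_groups = int(np.unique(pattern.group_id[member]).size)
    return q_isolated, q_group_cells, q_groups, frames.n_frames


def place_frames_in_cartilage(
    plane: SectionPlane,
    phantom: JointPhantom,
    frame_area: float,
    n_frames: int,
    rng_seed: int | np.random.Generator,
) -> FrameSet:
    """Systematic uniform random placement of square counting frames fully
    inside the section's cartilage profile (an ellipse annulus).

    Candidate positions form a lattice with pitch one frame side (frames
    therefore disjoint) and random offset; the containment tests are exact
    rectangle-vs-circle tests in the de-stretched plane.  If fewer than
    ``n_frames`` candidates fit, the fit count is returned (recorded by the
    caller in ``frames_used``).
    """
    rng = np.random.default_rng(rng_seed)
    side = math.sqrt(frame_area)
    d = abs(plane.position)
    r1, r2 = phantom.radii[0], phantom.radii[1]
    c = phantom.vertical_scale
    if n_frames == 0 or d >= r2:
        return FrameSet(frames=())
    a2 = math.sqrt(r2**2 - d**2)
    a1 = math.sqrt(r1**2 - d**2) if d < r1 else 0.0
    b2 = a2 * c
    off = rng.uniform(0.0, side, size=2)
    xs = np.arange(-a2 + off[0] - side, a2 + side, side)
    ys = np.arange(-b2 + off[1] - side, b2 + side, side)
    gx, gy = np.meshgrid(xs, ys)
    x0 = gx.ravel()
    y0 = gy.ravel()
    # de-stretched coordinates: boundaries become circles of radii a1, a2
    u0, u1 = y0 / c, (y0 + side) / c
    # farthest rectangle point from origin must be inside the outer circle
    fx = np.maximum(np.abs(x0), np.abs(x0 + side))
    fu = np.maximum(np.abs(u0), np.abs(u1))
    inside_outer = fx**2 + fu**2 <= a2**2
    # nearest rectangle point must clear the inner circle
    nx = np.where((x0 <= 0) & (x0 + side >= 0), 0.0, np.minimum(np.abs(x0), np.abs(x0 + side)))
    nu = np.where((u0 <= 0) & (u1 >= 0), 0.0, np.minimum(np.abs(u0), np.abs(u1)))
    clears_inner = nx**2 + nu**2 > a1**2
    ok = np.flatnonzero(inside_outer & clears_inner)
    if ok.size == 0:
        return FrameSet(frames=())
    take = ok[np.linspace(0, ok.size - 1, min(n_frames, ok.size)).round().astype(int)]
    take = np.unique(take)
    frames = tuple(
        CountingFrame(origin=np.array([x0[i], y0[i]]), width=side, height=side)
        for i in take
    )
    return FrameSet(frames=frames)


@dataclass(frozen=True)
class SimulatedSpecimen:
    counts: SpecimenCounts
    truth: CompartmentTruth
    cell_truth: CellFieldParams | None
    seed: int
    probes: ProbeSet


def simulate_specimen(
    phantom: JointPhantom,
    probes: ProbeSet,
    cell_params: CellFieldParams | None,
    t_spacing: float,
    rng_seed: int,
    *,
    specimen_id: str = "sim",
    group: str = "sim",
    measure: Sequence[str] = ("points", "surfaces", "cells"),
) -> SimulatedSpecimen:
    """Full virtual workflow: VUR planes -> per-section probe counting ->
    :class:`SpecimenCounts`, with ground truth and seed recorded.

    ``measure`` selects which probes are simulated ("points", "surfaces",
    "cells"); skipping a probe leaves its counts at zero, which keeps
    large Monte-Carlo studies of a single estimator economical.
    """
    seed = int(rng_seed)
    planes = vur_section_planes(phantom, t_spacing, _rng_for(seed, 0))
    do_points = "points" in measure
    do_surf = "surfaces" in measure
    do_cells = "cells" in measure and cell_params is not None
    sections = []
    for plane in planes:
        extent = _section_extent(plane, phantom)
        row: dict = {"p_ref": 0}
        row.update({f"p_{c}": 0 for c in COMPONENTS})
        row.update({f"i_{s}": 0 for s in SURFACES})
        q = (0, 0, 0, 0)
        if extent is not None:
            if do_points:
                grid = build_point_grid(
                    probes.area_per_point, extent, _rng_for(seed, 1, plane.index, 0)
                )
                row.update(count_points_on_section(plane, phantom, grid))
            if do_surf:
                cyc = build_cycloid_system(
                    probes.length_per_point,
                    (0.0, 1.0),
                    extent,
                    _rng_for(seed, 1, plane.index, 1),
                    area_per_point=probes.area_per_point,
                    polyline_tolerance=probes.polyline_tolerance,
                )
                row.update(count_intersections_on_section(plane, phantom, cyc))
            if do_cells:
                pattern = scatter_cell_profiles(
                    plane, phantom, cell_params, _rng_for(seed, 1, plane.index, 2)
                )
                frames = place_frames_in_cartilage(
                    plane,
                    phantom,
                    probes.frame_area,
                    probes.n_frames,
                    _rng_for(seed, 1, plane.index, 3),
                )
                q = count_frames(pattern, frames)
        sections.append(
            SectionCounts(
                section_index=plane.index,
                p_ref=row["p_ref"],
                p_component={c: row[f"p_{c}"] for c in COMPONENTS},
                i_component={s: row[f"i_{s}"] for s in SURFACES},
                q_isolated=q[0],
                q_group_cells=q[1],
                q_groups=q[2],
                frames_used=q[3],
            )
        )
    counts = SpecimenCounts(
        specimen_id=specimen_id,
        group=group,
        sections=tuple(sections),
        t_spacing=t_spacing,
        area_per_point=probes.area_per_point,
        length_per_point=probes.length_per_point,
        frame_area=probes.frame_area,
    )
    return SimulatedSpecimen(
        counts=counts,
        truth=phantom_truth(phantom),
        cell_truth=cell_params,
        seed=seed,
        probes=probes,
    )
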