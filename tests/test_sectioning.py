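"""Virtual vertical sectioning and simulated probe counting."""
import math

import numpy as np
import pytest

import jointstereo as js
from jointstereo.errors import InvalidParameterError, SamplingInfeasibleError
from jointstereo.probes import Extent, build_cycloid_system, build_point_grid
from jointstereo.sectioning import (
    _section_extent,
    count_frames,
    count_intersections_on_section,
    count_points_on_section,
    place_frames_in_cartilage,
    scatter_cell_profiles,
    vur_section_planes,
)


class TestSectionPlanes:
    def test_section_count_is_floor_or_one_more(self, sphere_phantom):
        # extent 1810 µm at T = 50 -> 36 or 37 planes depending on the start
        counts = {
            len(vur_section_planes(sphere_phantom, 50.0, seed)) for seed in range(200)
        }
        assert counts <= {36, 37}
        assert len(counts) == 2

    def test_consecutive_positions_differ_by_t(self, sphere_phantom):
        planes = vur_section_planes(sphere_phantom, 50.0, 3)
        pos = [p.position for p in planes]
        assert np.allclose(np.diff(pos), 50.0)

    def test_shared_rotation_per_specimen(self, sphere_phantom):
        planes = vur_section_planes(sphere_phantom, 50.0, 3)
        assert len({p.rotation_angle for p in planes}) == 1

    def test_huge_spacing_yields_at_most_one_plane(self, sphere_phantom):
        for seed in range(20):
            assert len(vur_section_planes(sphere_phantom, 2 * 905.0, seed)) <= 1

    def test_same_seed_same_planes(self, sphere_phantom):
        a = vur_section_planes(sphere_phantom, 50.0, 11)
        b = vur_section_planes(sphere_phantom, 50.0, 11)
        assert [p.position for p in a] == [p.position for p in b]
        assert a[0].rotation_angle == b[0].rotation_angle

    def test_planes_contain_vertical_axis_direction(self, sphere_phantom):
        for p in vur_section_planes(sphere_phantom, 200.0, 5):
            assert abs(np.dot(p.normal, [0, 0, 1])) < 1e-12


class TestPointCounting:
    def test_grid_outside_joint_counts_zero(self, sphere_phantom):
        plane = vur_section_planes(sphere_phantom, 50.0, 0)[0]
        grid = build_point_grid(23_470.0, Extent(5000, 5000, 8000, 8000), 1)
        counts = count_points_on_section(plane, sphere_phantom, grid)
        assert counts["p_ref"] == 0

    def test_component_counts_partition_reference(self, sphere_phantom):
        for seed in range(5):
            planes = vur_section_planes(sphere_phantom, 50.0, seed)
            plane = planes[len(planes) // 2]
            grid = build_point_grid(5000.0, _section_extent(plane, sphere_phantom), seed)
            counts = count_points_on_section(plane, sphere_phantom, grid)
            assert counts["p_ref"] == sum(counts[f"p_{c}"] for c in js.COMPARTMENTS)

    def test_expected_reference_count_matches_profile_area(self, sphere_phantom):
        """E[p_ref] over random grid offsets equals profile area / (a/p)."""
        planes = vur_section_planes(sphere_phantom, 50.0, 42)
        plane = min(planes, key=lambda p: abs(p.position))
        ap = 10_000.0
        ext = _section_extent(plane, sphere_phantom)
        n_rep = 2000
        tot = 0
        for i in range(n_rep):
            grid = build_point_grid(ap, ext, i)
            tot += count_points_on_section(plane, sphere_phantom, grid)["p_ref"]
        area = math.pi * (905.0**2 - plane.position**2)
        expected = area / ap
        se = math.sqrt(expected / n_rep)  # approximate
        assert tot / n_rep == pytest.approx(expected, abs=4 * se + 0.01 * expected)


class TestIntersectionCounting:
    def test_section_missing_cartilage_has_no_cartilage_hits(self, sphere_phantom):
        planes = vur_section_planes(sphere_phantom, 50.0, 0)
        plane = next(p for p in planes if abs(p.position) > 700.0)
        cyc = build_cycloid_system(
            100.0, (0, 1), _section_extent(plane, sphere_phantom), 0, area_per_point=23_470.0
        )
        counts = count_intersections_on_section(plane, sphere_phantom, cyc)
        assert counts["i_cartilage"] == 0

    def test_straight_probe_through_circle_crosses_twice(self, sphere_phantom):
        """A polyline running straight through the joint centre crosses each
        spherical interface exactly twice (analytic-geometry oracle)."""
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 7), key=lambda p: abs(p.position)
        )
        xi = np.linspace(-1000, 1000, 2001)
        line = np.stack([xi, np.zeros_like(xi)], axis=1)[None, :, :]
        world = plane.to_world(line)
        s = np.linalg.norm(world[0], axis=1)
        for radius in (700.0, 800.0):
            inside = s <= radius
            assert int(np.count_nonzero(inside[1:] != inside[:-1])) == 2

    def test_counts_stable_under_tolerance_refinement(self, sphere_phantom):
        """Halving the polyline tolerance almost never changes the counts."""
        changed = 0
        n = 40
        for seed in range(n):
            planes = vur_section_planes(sphere_phantom, 50.0, seed)
            plane = planes[len(planes) // 2]
            ext = _section_extent(plane, sphere_phantom)
            a = build_cycloid_system(100.0, (0, 1), ext, seed, area_per_point=23_470.0,
                                     polyline_tolerance=0.25)
            b = build_cycloid_system(100.0, (0, 1), ext, seed, area_per_point=23_470.0,
                                     polyline_tolerance=0.125)
            ca = count_intersections_on_section(plane, sphere_phantom, a)
            cb = count_intersections_on_section(plane, sphere_phantom, b)
            changed += ca != cb
        assert changed <= max(1, 0.05 * n)


class TestCellField:
    def test_zero_intensity_empty_pattern(self, sphere_phantom):
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 2), key=lambda p: abs(p.position)
        )
        pat = scatter_cell_profiles(
            plane, sphere_phantom, js.CellFieldParams(0.0, 0.0), 0
        )
        assert pat.n == 0

    def test_groups_have_at_least_two_members(self, sphere_phantom):
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 2), key=lambda p: abs(p.position)
        )
        pat = scatter_cell_profiles(
            plane, sphere_phantom, js.CellFieldParams(0.0, 100.0, offspring_mean=2.5), 3
        )
        gids, counts = np.unique(pat.group_id[pat.group_id >= 0], return_counts=True)
        assert gids.size > 0
        assert counts.min() >= 2

    def test_poisson_intensity_recovered(self, sphere_phantom):
        """Observed count / cartilage profile area matches the intensity
        within 3 standard errors across seeds."""
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 9), key=lambda p: abs(p.position)
        )
        d = abs(plane.position)
        area_mm2 = math.pi * ((700.0**2 - d**2) - (500.0**2 - d**2)) / 1e6
        lam = 800.0
        n_rep = 300
        total = sum(
            scatter_cell_profiles(
                plane, sphere_phantom, js.CellFieldParams(lam, 0.0), seed
            ).n
            for seed in range(n_rep)
        )
        expected = lam * area_mm2 * n_rep
        assert abs(total - expected) < 3 * math.sqrt(expected)

    def test_all_profiles_inside_cartilage(self, sphere_phantom):
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 4), key=lambda p: abs(p.position)
        )
        pat = scatter_cell_profiles(
            plane, sphere_phantom, js.CellFieldParams(500.0, 50.0), 8
        )
        member = sphere_phantom.membership(plane.to_world(pat.xy))
        assert np.all(member == 1)


class TestFrameCounting:
    def test_forbidden_edge_excludes(self):
        fr = js.CountingFrame(origin=np.array([0.0, 0.0]), width=10.0, height=10.0)
        fs = js.FrameSet(frames=(fr,))
        pat = js.CellPattern(
            xy=np.array([[0.0, 5.0], [10.0, 5.0]]), group_id=np.array([-1, -1])
        )
        assert count_frames(pat, fs) == (1, 0, 0, 1)

    def test_tiling_counts_whole_pattern_exactly(self, rng):
        side = 20.0
        frames = tuple(
            js.CountingFrame(origin=np.array([i * side, j * side]), width=side, height=side)
            for i in range(5)
            for j in range(5)
        )
        fs = js.FrameSet(frames=frames)
        n_iso, n_grp = 400, 60
        xy = rng.uniform(0.5, 99.5, size=(n_iso + n_grp, 2))
        gid = np.concatenate([np.full(n_iso, -1), np.repeat(np.arange(n_grp // 2), 2)])
        pat = js.CellPattern(xy=xy, group_id=gid)
        q_iso, q_grp, q_groups, used = count_frames(pat, fs)
        assert q_iso == n_iso
        assert q_grp == n_grp
        assert q_groups == n_grp // 2
        assert used == 25

    def test_empty_pattern_zero_counts(self):
        fr = js.CountingFrame(origin=np.array([0.0, 0.0]), width=10.0, height=10.0)
        pat = js.CellPattern(xy=np.empty((0, 2)), group_id=np.empty(0, dtype=int))
        assert count_frames(pat, js.FrameSet(frames=(fr,)))[:3] == (0, 0, 0)

    def test_overlapping_frames_rejected(self):
        frames = (
            js.CountingFrame(origin=np.array([0.0, 0.0]), width=10.0, height=10.0),
            js.CountingFrame(origin=np.array([5.0, 5.0]), width=10.0, height=10.0),
        )
        pat = js.CellPattern(xy=np.array([[1.0, 1.0]]), group_id=np.array([-1]))
        with pytest.raises(InvalidParameterError):
            count_frames(pat, js.FrameSet(frames=frames))

    def test_placed_frames_lie_inside_cartilage(self, sphere_phantom):
        plane = min(
            vur_section_planes(sphere_phantom, 50.0, 6), key=lambda p: abs(p.position)
        )
        fs = place_frames_in_cartilage(plane, sphere_phantom, 2700.28, 6, 1)
        assert fs.n_frames == 6
        assert fs.check_disjoint()
        for fr in fs.frames:
            corners = fr.origin + np.array(
                [[0, 0], [fr.width, 0], [0, fr.height], [fr.width, fr.height]]
            )
            member = sphere_phantom.membership(plane.to_world(corners))
            assert np.all(member == 1)


def test_volume_within_three_predicted_ce_of_truth(sphere_phantom, study_probes):
    """The predicted CE is a usable error bar: the estimate falls within
    3 predicted CEs of truth in at least 99% of seeds."""
    truth = js.phantom_truth(sphere_phantom).volumes["joint"]
    n = 300
    hits = 0
    for seed in range(n):
        sim = js.simulate_specimen(
            sphere_phantom, study_probes, None, 50.0, seed, measure=("points",)
        )
        est = js.estimate_specimen(sim.counts)
        hits += abs(est.volume - truth) <= 3.0 * est.ce * est.volume
    assert hits / n >= 0.99


class TestSimulateSpecimen:
    def test_same_seed_bitwise_identical_counts(self, sphere_phantom, study_probes):
        cells = js.CellFieldParams(800.0, 40.0)
        a = js.simulate_specimen(sphere_phantom, study_probes, cells, 50.0, 77)
        b = js.simulate_specimen(sphere_phantom, study_probes, cells, 50.0, 77)
        csv_a = js.counts_to_frame([a.counts]).to_csv(index=False)
        csv_b = js.counts_to_frame([b.counts]).to_csv(index=False)
        assert csv_a == csv_b

    def test_counts_satisfy_invariants(self, simulated_specimen):
        for sec in simulated_specimen.counts.sections:
            assert sum(sec.p_component.values()) == sec.p_ref
            assert sec.q_group_cells >= sec.q_groups

    def test_t_above_extent_raises(self, sphere_phantom, study_probes):
        # with T >> extent most starts fall beyond the phantom: zero sections
        with pytest.raises(SamplingInfeasibleError):
            for seed in range(200):
                js.simulate_specimen(
                    sphere_phantom, study_probes, None, 20_000.0, seed, measure=("points",)
                )
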