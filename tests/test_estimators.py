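"""Estimator formulas against hand-computed values and a brute-force oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jointstereo as js
from jointstereo.errors import InvalidParameterError, UndefinedEstimateError
from jointstereo.estimators import CEFormula, CEParameters


def make_specimen(p_refs, *, t=50.0, ap=23_470.0, lp=100.0, af=2700.28, **extra):
    sections = []
    for i, p in enumerate(p_refs):
        kw = {k: (v[i] if isinstance(v, (list, tuple)) else v) for k, v in extra.items()}
        pc = {c: kw.pop(f"p_{c}", 0) for c in js.COMPONENTS}
        ic = {s: kw.pop(f"i_{s}", 0) for s in js.SURFACES}
        sections.append(
            js.SectionCounts(
                section_index=i, p_ref=p, p_component=pc, i_component=ic, **kw
            )
        )
    return js.SpecimenCounts(
        specimen_id="t", group="g", sections=tuple(sections),
        t_spacing=t, area_per_point=ap, length_per_point=lp, frame_area=af,
    )


# --- independent brute-force oracle: explicit sums straight from the table ---

def oracle(sp: js.SpecimenCounts) -> dict:
    P = 0
    pc = {c: 0 for c in js.COMPONENTS}
    ic = {s: 0 for s in js.SURFACES}
    q_iso = q_grp = q_g = nf = 0
    for s in sp.sections:
        P += s.p_ref
        for c in js.COMPONENTS:
            pc[c] += s.p_component[c]
        for f in js.SURFACES:
            ic[f] += s.i_component[f]
        q_iso += s.q_isolated
        q_grp += s.q_group_cells
        q_g += s.q_groups
        nf += s.frames_used
    out = {"volume": P * sp.t_spacing * sp.area_per_point / 1e9}
    if P:
        out["vv"] = {c: pc[c] / P for c in js.COMPONENTS}
        out["sv"] = {f: 2 * ic[f] / (P * sp.length_per_point) * 1e3 for f in js.SURFACES}
    if nf:
        out["nv_iso"] = q_iso / (nf * sp.frame_area) * 1e6
        out["nv_grp"] = q_grp / (nf * sp.frame_area) * 1e6
        out["nv_groups"] = q_g / (nf * sp.frame_area) * 1e6
    return out


class TestCavalieriVolume:
    def test_study_constants_give_known_volume(self):
        # 100 points, T = 50 µm, a/p = 23,470 µm² -> 0.11735 mm³
        sp = make_specimen([40, 60])
        assert js.cavalieri_volume(sp) == pytest.approx(0.11735, rel=1e-12)

    def test_zero_counts_zero_volume(self):
        assert js.cavalieri_volume(make_specimen([0, 0, 0])) == 0.0

    def test_unit_conversion_identity(self):
        sp = make_specimen([1], t=1.0, ap=1.0)
        assert js.cavalieri_volume(sp) == pytest.approx(1e-9, rel=1e-12)


class TestPredictedCE:
    def test_hand_computed_noise_prediction(self):
        # B/√A = 2√π, n = 10, ΣP = 2500 -> sqrt(0.0724*3.5449*3.1623/125000)
        sp = make_specimen([250] * 10)
        ce = js.predicted_ce(sp, CEParameters(2 * math.sqrt(math.pi)))
        assert ce == pytest.approx(2.55e-3, rel=2e-3)

    def test_more_points_decrease_ce_both_variants(self):
        a = make_specimen([250] * 10)
        b = make_specimen([500] * 10)
        for variant in CEFormula:
            pa = js.predicted_ce(a, CEParameters(4.0, variant))
            pb = js.predicted_ce(b, CEParameters(4.0, variant))
            assert pb < pa

    def test_quadrupling_sections_and_points_halves_noise_ce(self):
        # CE ∝ n^{1/4} P^{-3/4}: (4n, 4P) -> factor 4^{1/4-3/4} = 1/2
        a = make_specimen([100] * 8)
        b = make_specimen([100] * 32)
        ra = js.predicted_ce(a)
        rb = js.predicted_ce(b)
        assert rb == pytest.approx(ra / 2, rel=1e-9)

    def test_zero_points_and_single_section_raise(self):
        with pytest.raises(UndefinedEstimateError):
            js.predicted_ce(make_specimen([0, 0]))
        with pytest.raises(UndefinedEstimateError):
            js.predicted_ce(make_specimen([50]))

    def test_shape_coefficient_below_circle_rejected(self):
        with pytest.raises(InvalidParameterError):
            CEParameters(3.0)


class TestShapeCoefficient:
    def test_circle_and_square(self):
        r = 37.0
        assert js.shape_coefficient_from_profiles(
            [2 * math.pi * r], [math.pi * r**2]
        ) == pytest.approx(2 * math.sqrt(math.pi), rel=1e-12)
        s = 12.0
        assert js.shape_coefficient_from_profiles([4 * s], [s**2]) == pytest.approx(4.0)

    def test_scale_invariance(self):
        b = [100.0, 140.0, 90.0]
        a = [600.0, 1100.0, 500.0]
        k = 3.7
        v1 = js.shape_coefficient_from_profiles(b, a)
        v2 = js.shape_coefficient_from_profiles([k * x for x in b], [k**2 * x for x in a])
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestVolumeFractionAndSurface:
    def test_delesse_examples(self):
        sp = make_specimen([50, 50], p_cartilage=[10, 15], p_bone=[40, 35])
        assert js.volume_fraction(sp, "cartilage") == pytest.approx(0.25)
        assert js.volume_fraction(sp, "bone") == pytest.approx(0.75)
        assert js.volume_fraction(sp, "capsule") == 0.0
        with pytest.raises(KeyError):
            js.volume_fraction(sp, "tendon")

    def test_absolute_volume_consistent_with_published_row(self):
        # Vv = 0.16556 of a 3.02 mm³ joint -> 0.50 mm³ cartilage
        assert js.absolute_volume(0.16556, 3.02) == pytest.approx(0.50, abs=5e-4)
        assert js.absolute_volume(0.0, 3.02) == 0.0
        assert js.absolute_volume(1.0, 3.02) == 3.02

    def test_surface_density_hand_value(self):
        # ΣI = 50, ΣP = 100, l/p = 20 µm -> 0.05 µm⁻¹ = 50 mm⁻¹
        sp = make_specimen([100], lp=20.0, i_cartilage=[50])
        assert js.surface_density(sp, "cartilage") == pytest.approx(50.0)
        spec0 = make_specimen([100], lp=20.0)
        assert js.surface_density(spec0, "cartilage") == 0.0

    def test_doubling_lp_halves_sv(self):
        a = make_specimen([100], lp=20.0, i_cartilage=[50])
        b = make_specimen([100], lp=40.0, i_cartilage=[50])
        assert js.surface_density(a, "cartilage") == pytest.approx(
            2 * js.surface_density(b, "cartilage")
        )

    def test_absolute_surface_matches_published_row(self):
        # Sv = 12.667 mm⁻¹ on a 3.02 mm³ joint -> 38.25 mm² cartilage surface
        assert js.absolute_surface(12.667, 3.02) == pytest.approx(38.25, abs=5e-3)


class TestProfileDensity:
    def test_six_profiles_in_six_study_frames(self):
        # 6 profiles over 6 frames of 2700.28 µm² -> 370.33 profiles/mm²
        sp = make_specimen([10], q_isolated=[6], frames_used=[6])
        assert js.profile_density(sp, "isolated") == pytest.approx(370.33, abs=5e-3)
        assert js.profile_density(sp, "total") == pytest.approx(370.33, abs=5e-3)

    def test_doubling_frames_halves_density(self):
        a = make_specimen([10], q_isolated=[6], frames_used=[6])
        b = make_specimen([10], q_isolated=[6], frames_used=[12])
        assert js.profile_density(a, "isolated") == pytest.approx(
            2 * js.profile_density(b, "isolated")
        )

    def test_no_frames_raises(self):
        with pytest.raises(UndefinedEstimateError):
            js.profile_density(make_specimen([10]), "isolated")


class TestEstimateSpecimen:
    def test_zero_count_specimen_all_zero_with_missing_ce(self):
        est = js.estimate_specimen(make_specimen([0, 0]))
        assert est.volume == 0.0
        assert math.isnan(est.ce)
        assert all(v == 0.0 for v in est.vv.values())
        assert est.density_total == 0.0

    def test_internal_identities_and_determinism(self, simulated_specimen):
        est1 = js.estimate_specimen(simulated_specimen.counts)
        est2 = js.estimate_specimen(simulated_specimen.counts)
        assert est1 == est2
        for c in js.COMPONENTS:
            assert est1.absolute_volume[c] == est1.vv[c] * est1.volume
        for s in js.SURFACES:
            assert est1.surface_area[s] == est1.sv[s] * est1.volume
        assert est1.density_total == est1.density_isolated + est1.density_group_cells
        assert sum(est1.vv.values()) <= 1.0 + 1e-9

    def test_additivity_over_disjoint_section_sets(self):
        a = make_specimen([10, 20, 30])
        sections_b = tuple(
            js.SectionCounts(section_index=i + 3, p_ref=p) for i, p in enumerate([5, 15])
        )
        import dataclasses

        b = dataclasses.replace(a, sections=sections_b)
        combined = dataclasses.replace(a, sections=a.sections + sections_b)
        assert js.cavalieri_volume(combined) == pytest.approx(
            js.cavalieri_volume(a) + js.cavalieri_volume(b), rel=1e-12
        )


def test_estimates_scale_correctly_with_unit_rescaling():
    """Rescaling all probe lengths by k (T by k, a/p by k², l/p by k, Af by
    k²) scales V by k³, Sv by 1/k and Nv by 1/k² — the unit-consistency of
    the whole chain."""
    k = 10.0
    base = make_specimen([30, 40], i_cartilage=[5, 7], q_isolated=[3, 2],
                         frames_used=[6, 6])
    scaled = make_specimen([30, 40], i_cartilage=[5, 7], q_isolated=[3, 2],
                           frames_used=[6, 6],
                           t=50.0 * k, ap=23_470.0 * k**2, lp=100.0 * k,
                           af=2700.28 * k**2)
    assert js.cavalieri_volume(scaled) == pytest.approx(
        k**3 * js.cavalieri_volume(base), rel=1e-12
    )
    assert js.surface_density(scaled, "cartilage") == pytest.approx(
        js.surface_density(base, "cartilage") / k, rel=1e-12
    )
    assert js.profile_density(scaled, "isolated") == pytest.approx(
        js.profile_density(base, "isolated") / k**2, rel=1e-12
    )
    assert js.volume_fraction(scaled, "cartilage") == js.volume_fraction(base, "cartilage")


class TestSubsampleSections:
    def test_step_one_is_identity(self):
        sp = make_specimen(list(range(1, 11)))
        assert js.subsample_sections(sp, 1) is sp

    def test_28_to_14_sections_doubles_t(self):
        sp = make_specimen([5] * 28)
        sub = js.subsample_sections(sp, 2, 0)
        assert sub.n_sections == 14
        assert sub.t_spacing == 100.0
        assert sub.area_per_point == sp.area_per_point

    def test_mean_over_starts_recovers_full_volume_exactly(self):
        rng = np.random.default_rng(5)
        sp = make_specimen(list(rng.integers(0, 200, size=28)))
        full = js.cavalieri_volume(sp)
        for k in (2, 3, 4, 7):
            vols = [js.cavalieri_volume(js.subsample_sections(sp, k, s)) for s in range(k)]
            assert np.mean(vols) == pytest.approx(full, rel=1e-12)

    def test_invalid_subsample_rejected(self):
        sp = make_specimen([5, 5])
        with pytest.raises(InvalidParameterError):
            js.subsample_sections(sp, 2, 2)
        with pytest.raises(InvalidParameterError):
            js.subsample_sections(sp, 0)


# --- property test: package estimators agree exactly with the oracle -------

count_tables = st.lists(
    st.tuples(
        st.integers(0, 400),  # p_ref
        st.integers(0, 100),  # cartilage points (capped by p_ref below)
        st.integers(0, 50),  # i_cartilage
        st.integers(0, 30),  # q_isolated
        st.integers(0, 6),  # frames
    ),
    min_size=1,
    max_size=30,
)


@given(rows=count_tables)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_estimators_match_brute_force_oracle(rows):
    sp = make_specimen(
        [r[0] for r in rows],
        p_cartilage=[min(r[1], r[0]) for r in rows],
        i_cartilage=[r[2] for r in rows],
        q_isolated=[r[3] for r in rows],
        frames_used=[r[4] for r in rows],
    )
    ref = oracle(sp)
    assert js.cavalieri_volume(sp) == ref["volume"]
    if sp.sum_p_ref:
        assert js.volume_fraction(sp, "cartilage") == ref["vv"]["cartilage"]
        assert js.surface_density(sp, "cartilage") == ref["sv"]["cartilage"]
    if sum(s.frames_used for s in sp.sections):
        assert js.profile_density(sp, "isolated") == ref["nv_iso"]
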