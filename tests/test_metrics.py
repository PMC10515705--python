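import math

import numpy as np
import pytest

from tipapex.cohort import CohortConfig, generate_cohort
from tipapex.geometry import MissingLandmarkError, LandmarkError, View, ViewLandmarks
from tipapex.metrics import (
    CaseRadiographs,
    OutOfHeadError,
    UndefinedRatioError,
    axis_blade_angle,
    cal_tad,
    cleveland_zone,
    compute_all_metrics,
    modified_tad,
    parker_ratio,
    tad,
)
from conftest import reflect_ap_across_neck_axis, scale_view

# G1 reference values, derived analytically from the circle geometry
G1_AB = math.sqrt(484 - 25) - 12            # 9.4243
G1_BC = math.hypot(22 - math.sqrt(484 - 25), 5)  # 5.0331
G1_AP_PART = G1_AB + G1_BC                  # 14.4574 (superior screw)
G1_LAT_TERM = 10.0


def build_case(ap_tip, ap_dir, lat_tip=(12.0, 0.0), lat_dir=(1.0, 0.0), calcar=None,
               ap_diam=12.5, lat_diam=12.5, radius=22.0):
    ap = ViewLandmarks(View.AP, (0, 0), radius, (-30, 0), (1, 0), ap_tip, ap_dir, ap_diam,
                       calcar_point=calcar)
    lat = ViewLandmarks(View.LAT, (0, 0), radius, (-30, 0), (1, 0), lat_tip, lat_dir, lat_diam)
    return CaseRadiographs("t", ap, lat)


class TestTad:
    def test_g1_two_term_sum(self, g1_case):
        assert tad(g1_case) == pytest.approx(math.sqrt(125) + 10.0, abs=1e-9)

    def test_tip_at_apex_is_zero(self):
        case = build_case(ap_tip=(22.0, 0.0), ap_dir=(1, 0), lat_tip=(22.0, 0.0))
        assert tad(case) == pytest.approx(0.0, abs=1e-12)

    def test_per_view_calibration(self, g1_case):
        # AP magnified 2x, LAT shrunk 4x: the mm result must not move
        case = CaseRadiographs(
            "mag", scale_view(g1_case.ap, 2.0), scale_view(g1_case.lat, 0.25)
        )
        assert tad(case) == pytest.approx(tad(g1_case), rel=1e-12)


class TestCalTad:
    def test_coincident_calcar_axis_equals_tad(self):
        case = build_case(ap_tip=(12.0, 5.0), ap_dir=(1, 0), calcar=(-15.0, 0.0))
        assert cal_tad(case) == pytest.approx(tad(case), abs=1e-9)

    def test_calcar_line_intersection_term(self):
        # Tip on the calcar-referenced line y = -15: AP term = sqrt(484-225) - 12
        case = build_case(ap_tip=(12.0, -15.0), ap_dir=(1, 0), calcar=(-20.0, -15.0))
        expected_ap = math.sqrt(484 - 225) - 12  # 4.0935
        assert cal_tad(case) == pytest.approx(expected_ap + G1_LAT_TERM, abs=1e-9)

    def test_calcar_line_outside_head_raises(self):
        case = build_case(ap_tip=(12.0, 5.0), ap_dir=(1, 0), calcar=(-20.0, -30.0))
        with pytest.raises(LandmarkError):
            cal_tad(case)

    def test_missing_calcar_raises(self, g1_case):
        case = build_case(ap_tip=(12.0, 5.0), ap_dir=(1, 0))
        with pytest.raises(MissingLandmarkError):
            cal_tad(case)


class TestModifiedTad:
    def test_g1_superior_decomposition(self, g1_case):
        comp = modified_tad(g1_case)
        assert comp.ab_ap_mm == pytest.approx(G1_AB, abs=1e-4)
        assert comp.bc_ap_mm == pytest.approx(G1_BC, abs=1e-4)
        assert comp.bc_sign == 1
        assert not comp.penetration
        assert comp.mtad_mm == pytest.approx(G1_AP_PART + G1_LAT_TERM, abs=1e-4)
        assert comp.mtad_mm == pytest.approx(24.4574, abs=1e-4)

    def test_g1_mirrored_inferior(self, g1_case):
        comp = modified_tad(reflect_ap_across_neck_axis(g1_case))
        assert comp.bc_sign == -1
        assert comp.mtad_mm - G1_LAT_TERM == pytest.approx(G1_AB - G1_BC, abs=1e-4)
        assert comp.mtad_mm - G1_LAT_TERM == pytest.approx(4.3912, abs=1e-4)

    def test_central_screw_reduces_to_tad(self):
        case = build_case(ap_tip=(12.0, 0.0), ap_dir=(1, 0))
        comp = modified_tad(case)
        assert comp.bc_sign == 0
        assert comp.bc_ap_mm == pytest.approx(0.0, abs=1e-9)
        assert comp.mtad_mm == pytest.approx(tad(case), abs=1e-9)

    def test_penetrating_tip_flagged_negative_ab(self):
        case = build_case(ap_tip=(25.0, 0.0), ap_dir=(1, 0))
        comp = modified_tad(case)
        assert comp.penetration
        assert comp.ab_ap_mm == pytest.approx(-3.0, abs=1e-9)

    def test_mirror_antisymmetry_over_random_geometries(self, small_cohort):
        """mTAD(superior) - mTAD(inferior mirror) = 2*BC >= 0 for every case."""
        for rec in small_cohort[:200]:
            comp = modified_tad(rec.case)
            mirr = modified_tad(reflect_ap_across_neck_axis(rec.case))
            assert mirr.ab_ap_mm == pytest.approx(comp.ab_ap_mm, abs=1e-9)
            assert mirr.bc_ap_mm == pytest.approx(comp.bc_ap_mm, abs=1e-9)
            assert mirr.bc_sign == -comp.bc_sign
            diff = comp.bc_sign * (comp.mtad_mm - mirr.mtad_mm)
            assert diff == pytest.approx(2 * comp.bc_ap_mm * abs(comp.bc_sign), abs=1e-9)

    def test_mtad_monotone_in_bc_for_fixed_ab(self):
        """Superior screws score increasingly worse, inferior increasingly
        better, as B moves away from the apex at fixed insertion depth."""
        sup, inf = [], []
        for y in (1.0, 3.0, 5.0, 7.0):
            b = np.array([math.sqrt(484 - y * y), y])
            tip = b - 8.0 * np.array([1.0, 0.0])
            sup.append(modified_tad(build_case(tuple(tip), (1, 0))).mtad_mm)
            tip_inf = np.array([b[0], -y]) - 8.0 * np.array([1.0, 0.0])
            inf.append(modified_tad(build_case(tuple(tip_inf), (1, 0))).mtad_mm)
        assert np.all(np.diff(sup) > 0)
        assert np.all(np.diff(inf) < 0)


class TestParkerRatio:
    def test_axis_through_center_is_50(self, g1_case):
        assert parker_ratio(g1_case, View.LAT) == pytest.approx(50.0, abs=1e-9)

    def test_ap_crossing_by_construction(self):
        # screw axis horizontal at y = +4.4 crosses 60% of the way up from
        # the inferior end of the 44-unit vertical diameter
        case = build_case(ap_tip=(10.0, 4.4), ap_dir=(1, 0))
        assert parker_ratio(case, View.AP) == pytest.approx(60.0, abs=1e-9)

    def test_lat_measured_from_anterior_end(self):
        # anterior (+y) screw => closer to the anterior anchor => below 50%
        case = build_case(ap_tip=(10.0, 0.0), ap_dir=(1, 0), lat_tip=(10.0, 4.4))
        assert parker_ratio(case, View.LAT) == pytest.approx(40.0, abs=1e-9)

    def test_axis_below_head_flagged_out_of_range(self):
        case = build_case(ap_tip=(10.0, -25.0), ap_dir=(1, 0), lat_tip=(12.0, 0.0))
        value = parker_ratio(case, View.AP)
        assert value < 0.0
        m = compute_all_metrics(case)
        assert "parker_ap_pct_range" in m.errors

    def test_parallel_axis_undefined(self):
        case = build_case(ap_tip=(0.0, -10.0), ap_dir=(0, 1))
        with pytest.raises(UndefinedRatioError):
            parker_ratio(case, View.AP)


class TestClevelandZone:
    @pytest.mark.parametrize(
        "ap_y, lat_y, expected",
        [
            (0.0, 0.0, 5),     # center-center
            (10.0, 10.0, 1),   # superior-anterior
            (-10.0, -10.0, 9), # inferior-posterior
            (10.0, -10.0, 3),  # superior-posterior
            (-10.0, 0.0, 8),   # inferior-central
            (0.0, -10.0, 6),   # center-posterior
        ],
    )
    def test_grid_mapping(self, ap_y, lat_y, expected):
        case = build_case(ap_tip=(5.0, ap_y), ap_dir=(1, 0), lat_tip=(5.0, lat_y))
        assert cleveland_zone(case) == expected

    def test_all_nine_zones_reachable(self):
        rng = np.random.default_rng(5)
        seen = set()
        for _ in range(400):
            r, phi = 21.9 * math.sqrt(rng.uniform()), rng.uniform(0, 2 * math.pi)
            r2, phi2 = 21.9 * math.sqrt(rng.uniform()), rng.uniform(0, 2 * math.pi)
            case = build_case(
                ap_tip=(r * math.cos(phi), r * math.sin(phi)), ap_dir=(1, 0),
                lat_tip=(r2 * math.cos(phi2), r2 * math.sin(phi2)),
            )
            seen.add(cleveland_zone(case))
        assert seen == set(range(1, 10))

    def test_out_of_head_reports_nearest_zone(self):
        case = build_case(ap_tip=(5.0, 25.0), ap_dir=(1, 0))
        with pytest.raises(OutOfHeadError) as exc:
            cleveland_zone(case)
        assert exc.value.nearest_zone == 2  # superior-central


class TestAxisBladeAngle:
    def test_parallel_axes_zero(self, g1_case):
        assert axis_blade_angle(g1_case) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("deg", [3.0, 8.0, 15.0])
    def test_superior_rotation_negative(self, deg):
        d = (math.cos(math.radians(deg)), math.sin(math.radians(deg)))
        case = build_case(ap_tip=(10.0, 2.0), ap_dir=d)
        assert axis_blade_angle(case) == pytest.approx(-deg, abs=1e-9)
        mirrored = build_case(ap_tip=(10.0, -2.0), ap_dir=(d[0], -d[1]))
        assert axis_blade_angle(mirrored) == pytest.approx(deg, abs=1e-9)


class TestComputeAllMetrics:
    def test_central_case_identities(self):
        case = build_case(ap_tip=(12.0, 0.0), ap_dir=(1, 0), calcar=(-15.0, 0.0))
        m = compute_all_metrics(case)
        assert m.errors == {}
        assert m.mtad_mm == pytest.approx(m.tad_mm, abs=1e-9)
        assert m.cleveland_zone == 5
        assert m.aba_deg == pytest.approx(0.0, abs=1e-12)
        assert m.parker_ap_pct == pytest.approx(50.0, abs=1e-9)
        assert m.parker_lat_pct == pytest.approx(50.0, abs=1e-9)

    def test_g1_composition_matches_individual_ops(self, g1_case):
        m = compute_all_metrics(g1_case)
        assert m.tad_mm == pytest.approx(tad(g1_case), abs=1e-12)
        assert m.cal_tad_mm == pytest.approx(cal_tad(g1_case), abs=1e-12)
        assert m.mtad_mm == pytest.approx(modified_tad(g1_case).mtad_mm, abs=1e-12)
        assert m.cleveland_zone == cleveland_zone(g1_case)

    def test_missing_calcar_partial_computation(self):
        case = build_case(ap_tip=(12.0, 5.0), ap_dir=(1, 0))  # no calcar
        m = compute_all_metrics(case)
        assert m.cal_tad_mm is None
        assert "cal_tad_mm" in m.errors
        assert m.tad_mm is not None and m.mtad_mm is not None


class TestMagnificationInvariance:
    def test_all_metrics_invariant_under_per_view_scaling(self, small_cohort):
        for rec in small_cohort[:50]:
            case = rec.case
            scaled = CaseRadiographs(
                case.case_id,
                scale_view(case.ap, 1.73),
                scale_view(case.lat, 0.41),
                case.true_diameter_mm,
            )
            m0 = compute_all_metrics(case)
            m1 = compute_all_metrics(scaled)
            for fieldname in ("tad_mm", "cal_tad_mm", "mtad_mm", "parker_ap_pct",
                              "parker_lat_pct", "aba_deg"):
                v0, v1 = getattr(m0, fieldname), getattr(m1, fieldname)
                assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-9), fieldname
            assert m0.cleveland_zone == m1.cleveland_zone
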