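import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tipapex.cohort import CohortConfig, generate_cohort, generate_worked_example

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def g1_case():
    """Hand-checkable reference geometry (superior screw, scale 1)."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """500-case default cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_cases=500, seed=11))


def reflect_ap_across_neck_axis(case):
    """Mirror the AP screw (tip + direction) across the neck axis.

    Works for any axis orientation: reflects the tip point and flips the
    perpendicular component of the screw direction.
    """
    from tipapex.geometry import ViewLandmarks
    from tipapex.metrics import CaseRadiographs

    ap = case.ap
    d = ap.neck_axis_dir
    p0 = ap.neck_axis_point

    def reflect_point(p):
        rel = p - p0
        along = np.dot(rel, d) * d
        return p0 + 2 * along - rel

    def reflect_vector(v):
        along = np.dot(v, d) * d
        return 2 * along - v

    mirrored_ap = ViewLandmarks(
        view_label=ap.view_label,
        head_center=ap.head_center,
        head_radius=ap.head_radius,
        neck_axis_point=p0,
        neck_axis_dir=d,
        screw_tip=reflect_point(ap.screw_tip),
        screw_axis_dir=reflect_vector(ap.screw_axis_dir),
        screw_diameter_measured=ap.screw_diameter_measured,
        calcar_point=ap.calcar_point,
    )
    return CaseRadiographs(
        case_id=case.case_id + "-mirrored",
        ap=mirrored_ap,
        lat=case.lat,
        true_diameter_mm=case.true_diameter_mm,
    )


def scale_view(lm, k):
    """Uniformly magnify one view's landmarks (coordinates about the origin)."""
    from tipapex.geometry import ViewLandmarks

    return ViewLandmarks(
        view_label=lm.view_label,
        head_center=k * lm.head_center,
        head_radius=k * lm.head_radius,
        neck_axis_point=k * lm.neck_axis_point,
        neck_axis_dir=lm.neck_axis_dir,
        screw_tip=k * lm.screw_tip,
        screw_axis_dir=lm.screw_axis_dir,
        screw_diameter_measured=k * lm.screw_diameter_measured,
        calcar_point=None if lm.calcar_point is None else k * lm.calcar_point,
    )
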