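"""Trial geometry: homing vectors, template walking, and error metrics."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import tricomplete as tc
from tricomplete.exceptions import (
    TriangleError,
    UndefinedCircularMeanError,
    UndefinedDirectionError,
)
from tricomplete.geometry import wrap_angle

V = tc.PlanarVector


def make_trial(template, xD=None, rotation=0.0):
    xA, xB, xC = tc.walk_template(template, start_heading=rotation)
    trial = tc.Trial(index=1, template=template, xA=xA, xB=xB, xC=xC)
    return trial.with_response(xD) if xD is not None else trial


# --- ideal homing vector -------------------------------------------------

@pytest.mark.parametrize(
    "xA, xB, expected",
    [
        (V(0, 0), V(0, 0), V(0, 0)),
        (V(10, 0), V(-5, 8.6603), V(-5, -8.6603)),  # equilateral, 10 m sides
        (V(7.0711, 0), V(0, 7.0711), V(-7.0711, -7.0711)),  # 45-90-45
    ],
)
def test_ideal_homing_vector_examples(xA, xB, expected):
    got = tc.ideal_homing_vector(xA, xB)
    assert got.x == pytest.approx(expected.x, abs=1e-12)
    assert got.y == pytest.approx(expected.y, abs=1e-12)


def test_ideal_homing_vector_closes_the_triangle(equilateral):
    xA, xB, xC = tc.walk_template(equilateral)
    closure = xA + xB + xC
    assert abs(closure.x) < 1e-9 and abs(closure.y) < 1e-9
    assert xC.magnitude == pytest.approx(10.0, abs=1e-9)


def test_non_finite_input_rejected():
    with pytest.raises(ValueError):
        V(float("nan"), 0.0)
    with pytest.raises(ValueError):
        V(float("inf"), 1.0)


# --- walking a template ---------------------------------------------------

def test_walk_equilateral_left(equilateral):
    xA, xB, xC = tc.walk_template(equilateral, start_heading=0.0)
    assert xA.as_tuple() == pytest.approx((10.0, 0.0), abs=1e-9)
    assert xB.as_tuple() == pytest.approx((-5.0, 8.6602540378), abs=1e-9)
    assert xC.magnitude == pytest.approx(10.0, abs=1e-9)


def test_walk_isosceles_30_120_30():
    tpl = tc.TriangleTemplate.from_angles("iso", (30, 120, 30), side_c=10)
    assert tpl.side_a == pytest.approx(10 * math.sin(math.radians(30)) / math.sin(math.radians(120)), abs=1e-12)
    xA, xB, xC = tc.walk_template(tpl)
    assert xB.as_tuple() == pytest.approx((2.8867513459, 5.0), abs=1e-9)
    assert xC.magnitude == pytest.approx(10.0, abs=1e-9)


@pytest.mark.parametrize("angles", [(60, 60, 60), (30, 120, 30), (50, 75, 55)])
def test_right_handed_walk_mirrors_left(angles):
    left = tc.TriangleTemplate.from_angles("t", angles, side_c=10, handedness="left")
    right = left.mirrored()
    xAl, xBl, xCl = tc.walk_template(left)
    xAr, xBr, xCr = tc.walk_template(right)
    assert xAr.as_tuple() == pytest.approx(xAl.as_tuple(), abs=1e-12)
    assert xBr.as_tuple() == pytest.approx(xBl.mirrored().as_tuple(), abs=1e-12)
    assert xCr.as_tuple() == pytest.approx(xCl.mirrored().as_tuple(), abs=1e-12)


@given(
    ang1=st.floats(5, 170),
    ang2=st.floats(5, 170),
    side_c=st.floats(0.5, 500),
    heading=st.floats(-180, 180),
)
def test_walk_template_law_of_sines_round_trip(ang1, ang2, side_c, heading):
    """Walked side magnitudes reproduce the template sides; path closes."""
    ang3 = 180 - ang1 - ang2
    if ang3 < 5:
        return
    tpl = tc.TriangleTemplate.from_angles("h", (ang1, ang2, ang3), side_c=side_c)
    xA, xB, xC = tc.walk_template(tpl, start_heading=heading)
    assert xA.magnitude == pytest.approx(tpl.side_a, rel=1e-9)
    assert xB.magnitude == pytest.approx(tpl.side_b, rel=1e-9)
    assert xC.magnitude == pytest.approx(side_c, rel=1e-9)
    closure = xA + xB + xC
    assert abs(closure.x) < 1e-6 and abs(closure.y) < 1e-6


def test_template_validation():
    with pytest.raises(TriangleError):
        tc.TriangleTemplate.from_angles("bad", (90, 90, 30))
    with pytest.raises(TriangleError):
        tc.TriangleTemplate("bad", (60, 60, 60), 10, 10, 25, "left")  # inequality
    with pytest.raises(TriangleError):
        tc.TriangleTemplate("bad", (60, 60, 60), 10, 10, 9, "left")  # law of sines


# --- error metrics --------------------------------------------------------

@pytest.mark.parametrize("handedness", ["left", "right"])
@pytest.mark.parametrize("offset, expected", [(0.0, 0.0), (10.0, 10.0), (-10.0, -10.0)])
def test_angle_error_sign_means_overshoot(handedness, offset, expected):
    """Rotating the response further along the required turn is positive."""
    tpl = tc.TriangleTemplate.from_angles("t", (50, 75, 55), side_c=10, handedness=handedness)
    trial = make_trial(tpl)
    sign = 1.0 if handedness == "left" else -1.0
    trial = trial.with_response(trial.xC.rotated(sign * offset))
    assert tc.angle_error(trial) == pytest.approx(expected, abs=1e-9)


def test_angle_error_requires_nonzero_response(equilateral):
    trial = make_trial(equilateral, xD=V(0, 0))
    with pytest.raises(UndefinedDirectionError):
        tc.angle_error(trial)


def test_distance_error_examples(equilateral):
    trial = make_trial(equilateral)
    assert tc.distance_error(trial.with_response(trial.xC)) == pytest.approx(1.0)
    assert tc.distance_error(trial.with_response(0.5 * trial.xC)) == pytest.approx(0.5)
    # 8.70 m walked on a 10 m return is the 0.87 undershoot ratio
    xD = V.from_polar(8.70, trial.xC.heading_deg)
    assert tc.distance_error(trial.with_response(xD)) == pytest.approx(0.87)


def test_position_error_examples(equilateral):
    trial = make_trial(equilateral)
    assert tc.position_error(trial.with_response(trial.xC)) == pytest.approx(0.0, abs=1e-12)
    assert tc.position_error(trial.with_response(V(0, 0))) == pytest.approx(trial.xC.magnitude)
    assert tc.position_error(trial.with_response(trial.xC + V(3, 4))) == pytest.approx(5.0)


@given(
    rotation=st.floats(-180, 180),
    resp_mag=st.floats(0.1, 30),
    resp_head=st.floats(-180, 180),
)
def test_metrics_rotation_equivariance(rotation, resp_mag, resp_head):
    """A common rotation of the trial frame leaves all three metrics unchanged."""
    tpl = tc.TriangleTemplate.from_angles("t", (40, 105, 35), side_c=10)
    base = make_trial(tpl, xD=V.from_polar(resp_mag, resp_head))
    rot = make_trial(tpl, rotation=rotation).with_response(base.xD.rotated(rotation))
    assert tc.angle_error(rot) == pytest.approx(tc.angle_error(base), abs=1e-9)
    assert tc.distance_error(rot) == pytest.approx(tc.distance_error(base), abs=1e-9)
    assert tc.position_error(rot) == pytest.approx(tc.position_error(base), abs=1e-9)


@given(resp_mag=st.floats(0.1, 30), resp_head=st.floats(-180, 180))
def test_mirror_symmetry_of_metrics(resp_mag, resp_head):
    """Reflecting a left-handed trial yields the right-handed twin with
    identical error metrics."""
    tpl = tc.TriangleTemplate.from_angles("t", (50, 75, 55), side_c=10, handedness="left")
    xD = V.from_polar(resp_mag, resp_head)
    left = make_trial(tpl, xD=xD)
    right = make_trial(tpl.mirrored(), xD=xD.mirrored())
    assert tc.angle_error(right) == pytest.approx(tc.angle_error(left), abs=1e-9)
    assert tc.distance_error(right) == pytest.approx(tc.distance_error(left), abs=1e-9)
    assert tc.position_error(right) == pytest.approx(tc.position_error(left), abs=1e-9)


# --- circular statistics --------------------------------------------------

@pytest.mark.parametrize(
    "angles, expected",
    [
        ([30, 30, 30], 30.0),
        ([0, 90], 45.0),
        ([170, -170], 180.0),
    ],
)
def test_circular_mean_examples(angles, expected):
    assert tc.circular_mean(angles) == pytest.approx(expected, abs=1e-9)


def test_circular_mean_undefined_for_antipodal():
    with pytest.raises(UndefinedCircularMeanError):
        tc.circular_mean([90, -90])


@given(st.floats(-1e6, 1e6))
def test_wrap_angle_range_and_equivalence(a):
    w = wrap_angle(a)
    assert -180 < w <= 180
    assert math.cos(math.radians(w)) == pytest.approx(math.cos(math.radians(a)), abs=1e-6)
    assert math.sin(math.radians(w)) == pytest.approx(math.sin(math.radians(a)), abs=1e-6)


def test_session_requires_consecutive_indices(equilateral):
    t1 = make_trial(equilateral)
    with pytest.raises(ValueError):
        tc.Session("s", "custom", (t1, t1))  # duplicate index 1
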