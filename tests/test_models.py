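"""Generative model predictions: vector addition, history, encoding error."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import tricomplete as tc
from tricomplete.exceptions import DegenerateEncodingError, ParameterError

V = tc.PlanarVector


# --- Weber noise scale ----------------------------------------------------

def test_noise_scale_examples():
    assert tc.noise_scale(0.0, V(3, 4), V(1, 2)) == 0.0
    assert tc.noise_scale(0.1, V(10, 0), V(0, 10)) == pytest.approx(1.41421356, abs=1e-6)
    with pytest.raises(ParameterError):
        tc.noise_scale(-0.1, V(1, 0), V(0, 1))


@given(c=st.floats(0.01, 100), s=st.floats(0, 2))
def test_noise_scale_homogeneous(c, s):
    xA, xB = V(3, -4), V(-1, 7)
    assert tc.noise_scale(s, c * xA, c * xB) == pytest.approx(
        c * tc.noise_scale(s, xA, xB), rel=1e-12
    )


# --- Model 1 --------------------------------------------------------------

def test_model1_optimal_weights_equal_ideal_homing():
    xA, xB = V(10, 0), V(-5, 8.6603)
    assert tc.predict_model1(xA, xB, 1, 1).as_tuple() == pytest.approx(
        tc.ideal_homing_vector(xA, xB).as_tuple(), abs=1e-12
    )
    assert tc.predict_model1(xA, xB, 0, 0).as_tuple() == (0, 0)


def test_model1_reported_weights_arithmetic():
    got = tc.predict_model1(V(10, 0), V(-5, 8.6603), 0.3, 0.813)
    assert got.as_tuple() == pytest.approx((1.065, -7.0408), abs=1e-4)


@given(rot=st.floats(-180, 180), scale=st.floats(0.1, 10))
def test_model_predictions_commute_with_rotation_and_scaling(rot, scale):
    xA, xB = V(10, 0), V(-5, 8.6603)
    state = tc.HistoryState(lamA=V(1, 2), lamB=V(-3, 0.5), lamD=V(0.2, -1))
    for predict in (
        lambda a, b, s: tc.predict_model1(a, b, 0.4, 0.9),
        lambda a, b, s: tc.predict_model2(a, b, s, 0.4, 0.9, 0.15),
    ):
        base = predict(xA, xB, state)
        rotated_state = tc.HistoryState(
            lamA=state.lamA.rotated(rot) * scale,
            lamB=state.lamB.rotated(rot) * scale,
            lamD=state.lamD.rotated(rot) * scale,
        )
        got = predict(xA.rotated(rot) * scale, xB.rotated(rot) * scale, rotated_state)
        want = base.rotated(rot) * scale
        assert got.as_tuple() == pytest.approx(want.as_tuple(), abs=1e-9)


# --- history term ---------------------------------------------------------

def test_history_zero_initialization_then_first_trial():
    state = tc.HistoryState.zero()
    xA, xB, xD = V(1, 2), V(3, 4), V(5, 6)
    for alpha in (0.0, 0.5, 1.0):
        new = tc.update_history(state, xA, xB, xD, alpha)
        assert new.lamA == xA and new.lamB == xB and new.lamD == xD


def test_history_alpha_zero_keeps_only_last_trial():
    state = tc.HistoryState.zero()
    state = tc.update_history(state, V(9, 9), V(9, 9), V(9, 9), alpha=0.0)
    state = tc.update_history(state, V(1, 0), V(0, 1), V(2, 2), alpha=0.0)
    assert state.lamA == V(1, 0) and state.lamB == V(0, 1) and state.lamD == V(2, 2)


def test_history_geometric_accumulation():
    state = tc.HistoryState.zero()
    for _ in range(2):
        state = tc.update_history(state, V(1, 0), V(0, 0), V(0, 0), alpha=0.5)
    assert state.lamA == pytest.approx(V(1.5, 0).as_tuple()) or state.lamA.as_tuple() == pytest.approx((1.5, 0))


def test_history_rejects_alpha_out_of_range():
    with pytest.raises(ParameterError):
        tc.update_history(tc.HistoryState.zero(), V(1, 0), V(0, 1), V(1, 1), alpha=1.5)


# --- Model 2 --------------------------------------------------------------

def test_model2_nests_model1():
    xA, xB = V(7.07, 0), V(0, 7.07)
    state = tc.HistoryState(lamA=V(4, 1), lamB=V(-2, 3), lamD=V(1, 1))
    for bA, bB in [(1, 1), (0.3, 0.813), (-0.5, 1.7)]:
        assert tc.predict_model2(xA, xB, state, bA, bB, 0.0).as_tuple() == pytest.approx(
            tc.predict_model1(xA, xB, bA, bB).as_tuple(), abs=1e-12
        )
    # zero history: model 2 equals model 1 for any history weight
    zero = tc.HistoryState.zero()
    assert tc.predict_model2(xA, xB, zero, 0.3, 0.8, 0.7).as_tuple() == pytest.approx(
        tc.predict_model1(xA, xB, 0.3, 0.8).as_tuple(), abs=1e-12
    )


def test_model2_reported_history_weight_arithmetic():
    state = tc.HistoryState(lamA=V(2, 0), lamB=V(0, 0), lamD=V(0, 0))
    got = tc.predict_model2(V(10, 0), V(-5, 8.6603), state, 1, 1, 0.112)
    assert got.as_tuple() == pytest.approx((-5.224, -8.6603), abs=1e-4)


# --- Encoding-Error Model -------------------------------------------------

def test_eem_identity_encoding_is_ideal(equilateral):
    xA, xB, xC = tc.walk_template(equilateral)
    got = tc.predict_eem(xA, xB, k0=0, k1=1, w0=0, w1=1)
    assert got.as_tuple() == pytest.approx(xC.as_tuple(), abs=1e-9)


def test_eem_law_of_cosines_shrinks_sides():
    # A = B = 10, ∠ab = 60°, k1 = 0.9 → encoded equilateral with 9 m sides
    c_r, g2_r = tc.eem_return_path(10, 10, 60, k0=0, k1=0.9, w0=0, w1=1)
    assert c_r == pytest.approx(9.0, abs=1e-9)
    assert g2_r == pytest.approx(60.0, abs=1e-9)


def test_eem_degenerate_encodings_rejected():
    with pytest.raises(DegenerateEncodingError):
        tc.eem_return_path(10, 10, 60, k0=-15, k1=1, w0=0, w1=1)  # negative side
    with pytest.raises(DegenerateEncodingError):
        tc.eem_return_path(10, 10, 60, k0=0, k1=1, w0=150, w1=1)  # angle ≥ 180


def test_eem_mirror_symmetry():
    tpl = tc.TriangleTemplate.from_angles("t", (50, 75, 55), side_c=10, handedness="left")
    xAl, xBl, _ = tc.walk_template(tpl)
    xAr, xBr, _ = tc.walk_template(tpl.mirrored())
    left = tc.predict_eem(xAl, xBl, 0.3, 0.9, 2, 0.95)
    right = tc.predict_eem(xAr, xBr, 0.3, 0.9, 2, 0.95)
    assert right.as_tuple() == pytest.approx(left.mirrored().as_tuple(), abs=1e-9)


def test_eem_prediction_is_history_free(make_session):
    """EEM predictions depend only on the current trial's guided vectors."""
    session = make_session(tc.ParamSet.model1(1, 1, 0.1))
    preds = [tc.predict_eem(t.xA, t.xB, 0.2, 0.9, 1, 0.95) for t in session.trials]
    # identical templates (same label/handedness) get identical predictions
    by_key = {}
    for t, p in zip(session.trials, preds):
        key = (t.template.label, t.template.handedness)
        by_key.setdefault(key, []).append(p)
    for vals in by_key.values():
        for v in vals[1:]:
            assert v.as_tuple() == pytest.approx(vals[0].as_tuple(), abs=1e-12)


# --- ParamSet -------------------------------------------------------------

def test_paramset_validation_and_roundtrip():
    p = tc.ParamSet.model2(0.3, 0.8, 0.1, 0.5, 0.1)
    assert p.k == 5
    assert tc.ParamSet.from_json(p.to_json()) == p
    eem = tc.ParamSet.eem(k0=0.1, k1=0.9, w0=1.0, w1=0.95, sigma_tilde=0.1)
    assert eem.k == 10
    assert eem.hand_coeffs("left")["k1"] == 0.9
    with pytest.raises(ParameterError):
        tc.ParamSet.model2(0.3, 0.8, 0.1, 1.5, 0.1)  # alpha out of range
    with pytest.raises(ParameterError):
        tc.ParamSet.model1(0.3, 0.8, -0.1)  # negative noise
    with pytest.raises(ParameterError):
        tc.ParamSet("model1", {"beta_A": 1.0})  # missing names
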