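"""Generative models of the unguided return in triangle completion.

Three configural models map the guided-side vectors of a trial (and, for one
of them, the trial history) to a predicted return vector x̃D:

* **Model 1** — weighted vector addition, ``x̃D = −(βA·xA + βB·xB)``. With
  βA = βB = 1 this is the ideal homing vector.
* **Model 2** — Model 1 plus an exponentially decaying history term,
  ``x̃D = −(βA·xA + βB·xB + βλ·[λA + λB − λD])`` where each λ accumulates the
  corresponding vectors of past trials as ``λ ← x + α·λ`` (α in [0, 1]). This
  implements a regression-to-the-mean pull from previously walked paths.
* **Encoding-Error Model (EEM)** — the guided sides and the turn between them
  are each passed through a linear encoding (same function for both sides);
  the return distance follows from the law of cosines on the encoded triangle
  and the return turn from its encoded angle at G2. All systematic error is
  attributed to encoding; the model has no history term.

The walked response is the model prediction perturbed by isotropic Gaussian
noise whose standard deviation grows with the traversed path,
``σ = σ̃·sqrt(|xA|² + |xB|²)`` — scalar variability consistent with Weber's
law.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import DegenerateEncodingError, ParameterError
from .geometry import PlanarVector, wrap_angle

__all__ = [
    "MODEL_IDS",
    "PARAM_NAMES",
    "K_PARAMS",
    "ParamSet",
    "HistoryState",
    "noise_scale",
    "predict_model1",
    "predict_model2",
    "update_history",
    "eem_return_path",
    "predict_eem",
]

MODEL_IDS = ("model1", "model2", "eem")

_EEM_HAND_NAMES = ("k0", "k1", "w0", "w1", "sigma_tilde")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "model1": ("beta_A", "beta_B", "sigma_tilde"),
    "model2": ("beta_A", "beta_B", "beta_lambda", "alpha", "sigma_tilde"),
    # EEM coefficients are fitted separately per handedness; both sets live in
    # one ParamSet and both count toward k.
    "eem": tuple(f"{h}_{name}" for h in ("left", "right") for name in _EEM_HAND_NAMES),
}

K_PARAMS = {m: len(names) for m, names in PARAM_NAMES.items()}

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ParamSet:
    """Named parameters for one generative model.

    ``values`` holds exactly the names in ``PARAM_NAMES[model_id]``. For the
    EEM the names are prefixed ``left_``/``right_`` — one coefficient set per
    handedness.
    """

    model_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ParameterError(f"unknown model_id {self.model_id!r}")
        expected = PARAM_NAMES[self.model_id]
        got = tuple(self.values)
        if set(got) != set(expected):
            raise ParameterError(
                f"{self.model_id} requires parameters {expected}, got {got}"
            )
        object.__setattr__(
            self, "values", {name: float(self.values[name]) for name in expected}
        )
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ParameterError(f"parameter {name} is not finite")
            if name.endswith("alpha") and not (0.0 <= v <= 1.0):
                raise ParameterError(f"alpha must lie in [0, 1], got {v}")
            if name.endswith("sigma_tilde") and v < 0.0:
                raise ParameterError(f"sigma_tilde must be ≥ 0, got {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def k(self) -> int:
        """Number of free parameters (AIC/BIC count)."""
        return K_PARAMS[self.model_id]

    @classmethod
    def model1(cls, beta_A: float, beta_B: float, sigma_tilde: float) -> "ParamSet":
        return cls("model1", dict(beta_A=beta_A, beta_B=beta_B, sigma_tilde=sigma_tilde))

    @classmethod
    def model2(
        cls,
        beta_A: float,
        beta_B: float,
        beta_lambda: float,
        alpha: float,
        sigma_tilde: float,
    ) -> "ParamSet":
        return cls(
            "model2",
            dict(
                beta_A=beta_A,
                beta_B=beta_B,
                beta_lambda=beta_lambda,
                alpha=alpha,
                sigma_tilde=sigma_tilde,
            ),
        )

    @classmethod
    def eem(
        cls,
        k0: float = 0.0,
        k1: float = 1.0,
        w0: float = 0.0,
        w1: float = 1.0,
        sigma_tilde: float = 0.1,
        *,
        left: Mapping[str, float] | None = None,
        right: Mapping[str, float] | None = None,
    ) -> "ParamSet":
        """Build an EEM ParamSet; shared coefficients unless per-hand overrides given."""
        shared = dict(k0=k0, k1=k1, w0=w0, w1=w1, sigma_tilde=sigma_tilde)
        values: dict[str, float] = {}
        for hand, override in (("left", left), ("right", right)):
            coeffs = dict(shared, **(dict(override) if override else {}))
            for name in _EEM_HAND_NAMES:
                values[f"{hand}_{name}"] = coeffs[name]
        return cls("eem", values)

    def hand_coeffs(self, handedness: str) -> dict[str, float]:
        """EEM coefficient set for one handedness."""
        if self.model_id != "eem":
            raise ParameterError("hand_coeffs only applies to the EEM")
        return {name: self.values[f"{handedness}_{name}"] for name in _EEM_HAND_NAMES}

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "model_id": self.model_id,
                "values": self.values,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, doc: str) -> "ParamSet":
        data = json.loads(doc)
        return cls(data["model_id"], data["values"])


@dataclass(frozen=True)
class HistoryState:
    """Exponentially decaying accumulators of past trial vectors.

    All three accumulators are zero vectors before the first trial; λD is
    built from the vectors actually walked (or simulated), not from the ideal
    returns.
    """

    lamA: PlanarVector = field(default_factory=lambda: PlanarVector(0.0, 0.0))
    lamB: PlanarVector = field(default_factory=lambda: PlanarVector(0.0, 0.0))
    lamD: PlanarVector = field(default_factory=lambda: PlanarVector(0.0, 0.0))

    @classmethod
    def zero(cls) -> "HistoryState":
        return cls()


def noise_scale(sigma_tilde: float, xA: PlanarVector, xB: PlanarVector) -> float:
    """Weber-scaled response noise SD: σ = σ̃·sqrt(|xA|² + |xB|²), meters."""
    if sigma_tilde < 0:
        raise ParameterError(f"sigma_tilde must be ≥ 0, got {sigma_tilde}")
    return sigma_tilde * math.hypot(xA.magnitude, xB.magnitude)


def predict_model1(
    xA: PlanarVector, xB: PlanarVector, beta_A: float, beta_B: float
) -> PlanarVector:
    """Weighted vector-addition prediction −(βA·xA + βB·xB)."""
    return -(beta_A * xA + beta_B * xB)


def predict_model2(
    xA: PlanarVector,
    xB: PlanarVector,
    state: HistoryState,
    beta_A: float,
    beta_B: float,
    beta_lambda: float,
) -> PlanarVector:
    """History-augmented prediction −(βA·xA + βB·xB + βλ·[λA + λB − λD]).

    ``state`` must be the history through the previous trial; on the first
    trial (zero state) the prediction equals Model 1's for any βλ.
    """
    history = state.lamA + state.lamB - state.lamD
    return -(beta_A * xA + beta_B * xB + beta_lambda * history)


def update_history(
    state: HistoryState,
    xA: PlanarVector,
    xB: PlanarVector,
    xD: PlanarVector,
    alpha: float,
) -> HistoryState:
    """Fold one completed trial into the history: λ ← x + α·λ.

    Applied strictly after the trial's response is realized; α = 0 keeps only
    the immediately preceding trial, α = 1 sums all past trials undecayed.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    return HistoryState(
        lamA=xA + alpha * state.lamA,
        lamB=xB + alpha * state.lamB,
        lamD=xD + alpha * state.lamD,
    )


def eem_return_path(
    side_a: float,
    side_b: float,
    angle_ab: float,
    k0: float,
    k1: float,
    w0: float,
    w1: float,
) -> tuple[float, float]:
    """Encoded return distance and encoded interior angle at G2, per the EEM.

    The guided sides are encoded through the *same* linear function
    ``s_r = k0 + k1·s`` and the turn angle at G1 through ``∠ab_r = w0 +
    w1·∠ab``. The encoded return side is the law-of-cosines third side of
    (A_r, B_r, ∠ab_r); the encoded interior angle at G2 follows from the law
    of cosines on the encoded triangle (equivalent to the law of sines but
    unambiguous when the encoded angle at G2 is obtuse).

    Returns ``(C_r, angle_g2_r)`` in meters and degrees.
    """
    a_r = k0 + k1 * side_a
    b_r = k0 + k1 * side_b
    ang_r = w0 + w1 * angle_ab
    if a_r <= 0 or b_r <= 0:
        raise DegenerateEncodingError(
            f"encoded sides must be positive (A_r={a_r}, B_r={b_r})"
        )
    if not (0.0 < ang_r < 180.0):
        raise DegenerateEncodingError(f"encoded angle {ang_r}° outside (0°, 180°)")
    cos_ab = math.cos(math.radians(ang_r))
    c_r = math.sqrt(a_r * a_r + b_r * b_r - 2.0 * a_r * b_r * cos_ab)
    if c_r <= 1e-12:
        raise DegenerateEncodingError("encoded return side collapses to zero")
    cos_g2 = (b_r * b_r + c_r * c_r - a_r * a_r) / (2.0 * b_r * c_r)
    angle_g2_r = math.degrees(math.acos(min(1.0, max(-1.0, cos_g2))))
    return c_r, angle_g2_r


def predict_eem(
    xA: PlanarVector,
    xB: PlanarVector,
    k0: float,
    k1: float,
    w0: float,
    w1: float,
) -> PlanarVector:
    """EEM prediction of the return vector in the trial's frame.

    The interior angle at G1 and the handedness are read off the guided
    vectors themselves, so the prediction is frame-independent. With identity
    encoding (k0=0, k1=1, w0=0, w1=1) the output equals the ideal homing
    vector. The EEM is history-free: the prediction depends only on the
    current trial.
    """
    head_a = xA.heading_deg
    head_b = xB.heading_deg
    turn = wrap_angle(head_b - head_a)  # exterior turn at G1, signed
    if turn == 0.0 or abs(turn) == 180.0:
        raise DegenerateEncodingError("guided sides are collinear")
    sign = 1.0 if turn > 0 else -1.0  # +1 leftward (CCW) turns
    angle_ab = 180.0 - abs(turn)  # interior angle at G1
    c_r, angle_g2_r = eem_return_path(
        xA.magnitude, xB.magnitude, angle_ab, k0, k1, w0, w1
    )
    heading_d = head_b + sign * (180.0 - angle_g2_r)
    return PlanarVector.from_polar(c_r, heading_d)
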