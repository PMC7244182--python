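"""Domain types and error metrics for the triangle completion task.

A trial guides a walker along two sides of a triangle (side A from the origin
to corner G1, side B from G1 to G2); the walker then attempts the third,
unguided side back to the origin. The ideal return — the configural homing
vector — is ``xC = −(xA + xB)``. The walked return ``xD`` is scored by three
metrics:

* angle error: signed difference (degrees) between the executed turn at G2
  and the required turn, positive when the walker turns past the correct
  heading (overshoot);
* distance error: ``|xD| / |xC|`` (>1 overshoot, <1 undershoot);
* position error: ``|xA + xB + xD|``, the distance from the walker's final
  position to the origin, in meters.

Each trial is expressed in its own frame: origin at the start point, start
heading along +x. All metrics are invariant to a common rotation of the
trial's vectors, so the frame choice is presentation only. Angles are degrees
at every public interface; radians appear only inside function bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .exceptions import (
    MissingResponseError,
    TriangleError,
    UndefinedCircularMeanError,
    UndefinedDirectionError,
)

__all__ = [
    "PlanarVector",
    "TriangleTemplate",
    "Trial",
    "Session",
    "ideal_homing_vector",
    "walk_template",
    "angle_error",
    "distance_error",
    "position_error",
    "circular_mean",
    "wrap_angle",
]

_ANGLE_SUM_TOL = 1e-9  # degrees
_GEOM_TOL = 1e-9  # meters / relative


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to the half-open interval (−180, 180]."""
    w = angle % 360.0
    return w - 360.0 if w > 180.0 else w


@dataclass(frozen=True)
class PlanarVector:
    """A 2-D displacement in meters (x east, y north)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite vector components ({self.x}, {self.y})")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)

    @property
    def heading_deg(self) -> float:
        """Direction of the vector in degrees, in (−180, 180].

        Raises
        ------
        UndefinedDirectionError
            If the vector has zero magnitude.
        """
        if self.magnitude == 0.0:
            raise UndefinedDirectionError("zero-length vector has no heading")
        return wrap_angle(math.degrees(math.atan2(self.y, self.x)))

    def rotated(self, angle_deg: float) -> "PlanarVector":
        """Counterclockwise rotation by `angle_deg` degrees."""
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        return PlanarVector(c * self.x - s * self.y, s * self.x + c * self.y)

    def mirrored(self) -> "PlanarVector":
        """Reflection across the x-axis (the start-heading axis)."""
        return PlanarVector(self.x, -self.y)

    def __add__(self, other: "PlanarVector") -> "PlanarVector":
        return PlanarVector(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "PlanarVector") -> "PlanarVector":
        return PlanarVector(self.x - other.x, self.y - other.y)

    def __neg__(self) -> "PlanarVector":
        return PlanarVector(-self.x, -self.y)

    def __mul__(self, scalar: float) -> "PlanarVector":
        return PlanarVector(scalar * self.x, scalar * self.y)

    __rmul__ = __mul__

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)

    @staticmethod
    def from_polar(magnitude: float, heading_deg: float) -> "PlanarVector":
        a = math.radians(heading_deg)
        return PlanarVector(magnitude * math.cos(a), magnitude * math.sin(a))


@dataclass(frozen=True)
class TriangleTemplate:
    """Interior angles, side lengths and handedness of one guided path.

    Angles are listed at the origin, at G1 and at G2 (degrees). Side A runs
    origin→G1, side B runs G1→G2, side C is the unguided return G2→origin;
    each side faces the opposite corner, so the law of sines ties sides to
    angles. Handedness says whether the guided turns are leftward
    (counterclockwise) or rightward.
    """

    label: str
    angles: tuple[float, float, float]  # degrees at origin, G1, G2
    side_a: float
    side_b: float
    side_c: float
    handedness: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.handedness not in ("left", "right"):
            raise TriangleError(f"handedness must be left/right, got {self.handedness!r}")
        if abs(sum(self.angles) - 180.0) > _ANGLE_SUM_TOL:
            raise TriangleError(f"interior angles {self.angles} do not sum to 180°")
        if any(a <= 0 for a in self.angles):
            raise TriangleError(f"interior angles must be positive, got {self.angles}")
        sides = (self.side_a, self.side_b, self.side_c)
        if any(s <= 0 for s in sides):
            raise TriangleError(f"sides must be positive, got {sides}")
        a, b, c = sides
        if a + b <= c or b + c <= a or a + c <= b:
            raise TriangleError(f"triangle inequality violated for sides {sides}")
        # law of sines: side_a/sin(G2) = side_b/sin(origin) = side_c/sin(G1)
        ratios = [
            self.side_a / math.sin(math.radians(self.angles[2])),
            self.side_b / math.sin(math.radians(self.angles[0])),
            self.side_c / math.sin(math.radians(self.angles[1])),
        ]
        ref = ratios[0]
        for r in ratios[1:]:
            if abs(r - ref) > _GEOM_TOL * max(1.0, abs(ref)):
                raise TriangleError(
                    f"sides {sides} and angles {self.angles} violate the law of sines"
                )

    @property
    def perimeter(self) -> float:
        return self.side_a + self.side_b + self.side_c

    @classmethod
    def from_angles(
        cls,
        label: str,
        angles: Sequence[float],
        side_c: float = 10.0,
        handedness: str = "left",
    ) -> "TriangleTemplate":
        """Build a template from its interior angles with side C fixed.

        Sides A and B follow from the law of sines; this is how the
        constant-return-distance templates are defined.
        """
        o, g1, g2 = (float(a) for a in angles)
        if abs((o + g1 + g2) - 180.0) > _ANGLE_SUM_TOL:
            raise TriangleError(f"interior angles {angles} do not sum to 180°")
        scale = side_c / math.sin(math.radians(g1))
        return cls(
            label=label,
            angles=(o, g1, g2),
            side_a=scale * math.sin(math.radians(g2)),
            side_b=scale * math.sin(math.radians(o)),
            side_c=float(side_c),
            handedness=handedness,
        )

    @classmethod
    def from_angles_perimeter(
        cls,
        label: str,
        angles: Sequence[float],
        perimeter: float,
        handedness: str = "left",
    ) -> "TriangleTemplate":
        """Build a template from interior angles scaled to a total perimeter."""
        o, g1, g2 = (float(a) for a in angles)
        if abs((o + g1 + g2) - 180.0) > _ANGLE_SUM_TOL:
            raise TriangleError(f"interior angles {angles} do not sum to 180°")
        sines = [math.sin(math.radians(a)) for a in (g2, o, g1)]
        scale = perimeter / sum(sines)
        return cls(
            label=label,
            angles=(o, g1, g2),
            side_a=scale * sines[0],
            side_b=scale * sines[1],
            side_c=scale * sines[2],
            handedness=handedness,
        )

    def mirrored(self) -> "TriangleTemplate":
        """The same shape walked with the opposite handedness."""
        other = "right" if self.handedness == "left" else "left"
        return replace(self, handedness=other)


@dataclass(frozen=True)
class Trial:
    """One trial: guided vectors, ideal return, and (optionally) a response.

    ``index`` is the 1-based position within the session; it defines the order
    the history term sees. ``xC`` is always the ideal homing vector
    ``−(xA + xB)``; ``xD`` is the walked response and may be absent.
    """

    index: int
    template: TriangleTemplate
    xA: PlanarVector
    xB: PlanarVector
    xC: PlanarVector
    xD: Optional[PlanarVector] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"trial index must be ≥ 1, got {self.index}")
        closure = self.xA + self.xB + self.xC
        if abs(closure.x) > _GEOM_TOL or abs(closure.y) > _GEOM_TOL:
            raise TriangleError(f"xC is not −(xA+xB): closure residual {closure.as_tuple()}")
        for vec, side, name in (
            (self.xA, self.template.side_a, "A"),
            (self.xB, self.template.side_b, "B"),
        ):
            if abs(vec.magnitude - side) > _GEOM_TOL * max(1.0, side):
                raise TriangleError(
                    f"|x{name}| = {vec.magnitude} does not match template side {side}"
                )

    @property
    def has_response(self) -> bool:
        return self.xD is not None

    def with_response(self, xD: PlanarVector) -> "Trial":
        return replace(self, xD=xD)


@dataclass(frozen=True)
class Session:
    """An ordered run of trials for one subject."""

    subject_id: str
    design_id: str  # "exp1" | "exp2" | "custom"
    trials: tuple[Trial, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        for pos, trial in enumerate(self.trials, start=1):
            if trial.index != pos:
                raise ValueError(
                    f"trial indices must be 1..n consecutive; position {pos} holds index {trial.index}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def has_responses(self) -> bool:
        return all(t.has_response for t in self.trials)

    def with_responses(self, responses: Sequence[PlanarVector]) -> "Session":
        if len(responses) != len(self.trials):
            raise ValueError("one response per trial required")
        trials = tuple(t.with_response(r) for t, r in zip(self.trials, responses))
        return replace(self, trials=trials)


def ideal_homing_vector(xA: PlanarVector, xB: PlanarVector) -> PlanarVector:
    """The configural homing vector −(xA + xB).

    Walking it returns the walker exactly to the origin:
    ``xA + xB + result == (0, 0)`` up to floating round-off.
    """
    return -(xA + xB)


def _turn_sign(handedness: str) -> float:
    return 1.0 if handedness == "left" else -1.0


def walk_template(
    template: TriangleTemplate, start_heading: float = 0.0
) -> tuple[PlanarVector, PlanarVector, PlanarVector]:
    """Walk a template's guided path; return (xA, xB, xC) in the trial frame.

    Side A is walked along ``start_heading``; at G1 the walker makes an
    exterior turn of ``180° − interior angle at G1``, counterclockwise for
    left-handed templates and clockwise for right-handed ones.
    """
    s = _turn_sign(template.handedness)
    heading_a = start_heading
    heading_b = heading_a + s * (180.0 - template.angles[1])
    xA = PlanarVector.from_polar(template.side_a, heading_a)
    xB = PlanarVector.from_polar(template.side_b, heading_b)
    return xA, xB, ideal_homing_vector(xA, xB)


def angle_error(trial: Trial) -> float:
    """Signed angular error of the response heading, degrees in (−180, 180].

    Both the required and the executed turn at G2 are measured from the
    direction of side B, signed positive in the required turn direction, so a
    positive error always means the walker turned past the correct heading
    (overshoot) and a negative one that they stopped short (undershoot),
    independent of handedness.
    """
    if trial.xD is None:
        raise MissingResponseError("trial has no response")
    if trial.xD.magnitude == 0.0:
        raise UndefinedDirectionError("zero-length response has no heading")
    head_b = trial.xB.heading_deg
    required = wrap_angle(trial.xC.heading_deg - head_b)
    executed = wrap_angle(trial.xD.heading_deg - head_b)
    sign = 1.0 if required >= 0.0 else -1.0
    return wrap_angle(sign * (executed - required))


def distance_error(trial: Trial) -> float:
    """Ratio |xD| / |xC|: 1 is perfect, >1 overshoot, <1 undershoot."""
    if trial.xD is None:
        raise MissingResponseError("trial has no response")
    denom = trial.xC.magnitude
    if denom == 0.0:
        raise TriangleError("degenerate template: |xC| = 0")
    return trial.xD.magnitude / denom


def position_error(trial: Trial) -> float:
    """Distance (m) from the walked path's endpoint to the origin."""
    if trial.xD is None:
        raise MissingResponseError("trial has no response")
    return (trial.xA + trial.xB + trial.xD).magnitude


def circular_mean(angles: Iterable[float]) -> float:
    """Circular mean of angles in degrees, in (−180, 180].

    The mean is the argument of the mean resultant vector of unit vectors at
    the given angles. If the resultant length falls below 1e-12 (e.g. for
    {90°, −90°}) the mean direction is undefined.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("circular_mean of an empty sequence")
    sx = sum(math.cos(math.radians(a)) for a in angles) / len(angles)
    sy = sum(math.sin(math.radians(a)) for a in angles) / len(angles)
    if math.hypot(sx, sy) < 1e-12:
        raise UndefinedCircularMeanError("mean resultant length below 1e-12")
    return wrap_angle(math.degrees(math.atan2(sy, sx)))
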