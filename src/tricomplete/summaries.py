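"""Descriptive group summaries of triangle-completion sessions.

Reproduces the headline behavioral patterns from trial tables, real or
simulated: per-subject circular mean of angle error and mean distance error
(overall and per triangle template), the regression of walked return
distance on the correct return distance, and the two size-scaling fits —
the linear growth of response SD with return distance and the logarithmic
growth of systematic distance error ``1 − |xD|/|xC|`` with return distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .geometry import Session, angle_error, circular_mean, distance_error, position_error

__all__ = [
    "SubjectSummary",
    "subject_summary",
    "homing_regression",
    "sd_vs_distance",
    "systematic_error_log_fit",
]


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject error summary, overall and per template."""

    subject_id: str
    angle_error_deg: float  # circular mean
    distance_error: float  # arithmetic mean of |xD|/|xC|
    position_error_m: float
    per_template: pd.DataFrame  # index: template label

    def __repr__(self) -> str:  # compact, table elided
        return (
            f"SubjectSummary({self.subject_id!r}, angle={self.angle_error_deg:.2f}°, "
            f"distance={self.distance_error:.3f}, position={self.position_error_m:.2f} m)"
        )


def subject_summary(session: Session) -> SubjectSummary:
    """Circular-mean angle error, mean distance and position error.

    Computed over trials with responses only; grouped per template label and
    overall. An empty or response-free session is invalid.
    """
    trials = [t for t in session.trials if t.has_response]
    if not trials:
        raise ParameterError("session has no trials with responses")
    rows = [
        {
            "label": t.template.label,
            "angle": angle_error(t),
            "distance": distance_error(t),
            "position": position_error(t),
        }
        for t in trials
    ]
    df = pd.DataFrame(rows)
    per_template = (
        df.groupby("label")
        .agg(
            angle_error_deg=("angle", circular_mean),
            distance_error=("distance", "mean"),
            position_error_m=("position", "mean"),
            n_trials=("angle", "size"),
        )
        .sort_index()
    )
    return SubjectSummary(
        subject_id=session.subject_id,
        angle_error_deg=circular_mean(df["angle"]),
        distance_error=float(df["distance"].mean()),
        position_error_m=float(df["position"].mean()),
        per_template=per_template,
    )


def homing_regression(sessions: Sequence[Session]) -> pd.Series:
    """OLS slope of walked return distance |xD| on correct distance |xC|,
    one slope per subject (with intercept)."""
    slopes = {}
    for session in sessions:
        trials = [t for t in session.trials if t.has_response]
        x = np.array([t.xC.magnitude for t in trials])
        y = np.array([t.xD.magnitude for t in trials])
        if np.ptp(x) <= 1e-9 * max(1.0, float(np.abs(x).max())):
            raise ParameterError(
                f"subject {session.subject_id}: |xC| is constant; slope undefined"
            )
        slope, _ = np.polyfit(x, y, 1)
        slopes[session.subject_id] = float(slope)
    return pd.Series(slopes, name="slope")


def _size_groups(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for session in sessions:
        for t in session.trials:
            if t.has_response:
                rows.append(
                    {
                        "label": t.template.label,
                        "xC": t.xC.magnitude,
                        "xD": t.xD.magnitude,
                        "systematic": 1.0 - distance_error(t),
                    }
                )
    if not rows:
        raise ParameterError("no trials with responses")
    return pd.DataFrame(rows)


def sd_vs_distance(sessions: Sequence[Session]) -> tuple[float, float]:
    """Line (slope, intercept) of the SD of |xD| against |xC| across size
    groups.

    Trials are grouped by template label, pooled across subjects; groups with
    fewer than two trials cannot yield an SD and are dropped with a warning.
    """
    df = _size_groups(sessions)
    grouped = df.groupby("label").agg(
        xC=("xC", "mean"), sd=("xD", "std"), n=("xD", "size")
    )
    small = grouped[grouped["n"] < 2]
    if len(small):
        warnings.warn(
            f"excluding size groups with < 2 trials: {list(small.index)}", stacklevel=2
        )
        grouped = grouped[grouped["n"] >= 2]
    if len(grouped) < 2:
        raise ParameterError("need at least 2 size groups for the SD-vs-distance fit")
    slope, intercept = np.polyfit(grouped["xC"], grouped["sd"], 1)
    return float(slope), float(intercept)


def systematic_error_log_fit(
    sessions: Sequence[Session],
) -> tuple[float, float, float]:
    """Fit mean systematic distance error to ``a + b·ln(|xC|)`` across size
    groups.

    Systematic error is ``1 − |xD|/|xC|`` (positive = undershoot), averaged
    within each template-label size group. Returns ``(intercept a, log-slope
    b, R²)``.
    """
    df = _size_groups(sessions)
    grouped = df.groupby("label").agg(xC=("xC", "mean"), err=("systematic", "mean"))
    if len(grouped) < 3:
        raise ParameterError("need at least 3 size groups for the logarithmic fit")
    if (grouped["xC"] <= 0).any():
        raise ParameterError("return distances must be positive")
    x = np.log(grouped["xC"].to_numpy())
    y = grouped["err"].to_numpy()
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(a), float(b), r2
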