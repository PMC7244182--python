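"""Likelihood evaluation and per-subject maximum-likelihood fitting.

Each trial's response is modeled as an isotropic planar Gaussian around the
model's predicted return vector, with Weber-scaled SD σ_t = σ̃·sqrt(|xA|² +
|xB|²). The per-trial log density is

    −log(2π σ_t²) − |xD_t − x̃D_t|² / (2 σ_t²)

and the session log likelihood is the sum over trials. For Model 2, the
history accumulators are propagated from the *observed* responses
(one-step-ahead prediction). EEM coefficients are fitted separately for
left- and right-handed trials; the reported log likelihood is the sum of the
two halves and k counts both coefficient sets.

Fitting is bounded multi-start local optimization (L-BFGS-B): ``n_starts``
seeded random initial points inside the parameter box, plus, for the vector
models, one deterministic start at the weighted-least-squares solution with
the history weight zeroed. The best start by log likelihood wins; exact ties
break toward the smallest parameter-vector norm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

from ._rng import rng_from_seed
from .exceptions import FitFailureError, MissingResponseError, ParameterError
from .geometry import Session, wrap_angle
from .models import K_PARAMS, PARAM_NAMES, ParamSet

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "log_likelihood",
    "fit_mle",
    "simulate_fitted",
]

# Generous boxes around all reported parameter estimates.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta_A": (-2.0, 2.0),
    "beta_B": (-2.0, 2.0),
    "beta_lambda": (-2.0, 2.0),
    "alpha": (0.0, 1.0),
    "sigma_tilde": (1e-4, 2.0),
    "k0": (-5.0, 5.0),  # m
    "k1": (0.0, 2.0),
    "w0": (-30.0, 30.0),  # degrees
    "w1": (0.0, 2.0),
}

_PENALTY = 1e12  # objective value for degenerate parameter points
_FTOL = 1e-10  # optimizer tolerance on the (negative) log likelihood


@dataclass(frozen=True)
class _SessionArrays:
    """Stacked per-trial arrays for vectorized likelihood evaluation."""

    xA: np.ndarray  # (T, 2)
    xB: np.ndarray  # (T, 2)
    xD: np.ndarray  # (T, 2)
    path: np.ndarray  # (T,) sqrt(|xA|² + |xB|²)
    side_a: np.ndarray  # (T,)
    side_b: np.ndarray  # (T,)
    angle_ab: np.ndarray  # (T,) interior angle at G1, degrees
    head_b: np.ndarray  # (T,) heading of xB, degrees
    turn_sign: np.ndarray  # (T,) +1 leftward, −1 rightward
    is_left: np.ndarray  # (T,) bool

    @property
    def n(self) -> int:
        return self.xA.shape[0]


def _session_arrays(session: Session) -> _SessionArrays:
    if not session.has_responses:
        raise MissingResponseError("every trial needs a response for likelihood evaluation")
    xA = np.array([t.xA.as_tuple() for t in session.trials], float)
    xB = np.array([t.xB.as_tuple() for t in session.trials], float)
    xD = np.array([t.xD.as_tuple() for t in session.trials], float)
    head_a = np.degrees(np.arctan2(xA[:, 1], xA[:, 0]))
    head_b = np.degrees(np.arctan2(xB[:, 1], xB[:, 0]))
    turn = np.vectorize(wrap_angle)(head_b - head_a)
    return _SessionArrays(
        xA=xA,
        xB=xB,
        xD=xD,
        path=np.sqrt((xA**2).sum(1) + (xB**2).sum(1)),
        side_a=np.linalg.norm(xA, axis=1),
        side_b=np.linalg.norm(xB, axis=1),
        angle_ab=180.0 - np.abs(turn),
        head_b=head_b,
        turn_sign=np.where(turn > 0, 1.0, -1.0),
        is_left=np.array([t.template.handedness == "left" for t in session.trials]),
    )


def _vector_model_means(arr: _SessionArrays, theta: Mapping[str, float]) -> np.ndarray:
    """Mean predictions for model1/model2 (model1 when beta_lambda absent)."""
    mu = -(theta["beta_A"] * arr.xA + theta["beta_B"] * arr.xB)
    if "beta_lambda" in theta:
        z = arr.xA + arr.xB - arr.xD  # per-trial contribution to λA+λB−λD
        # λ_full[t] = z[t] + α λ_full[t−1]; prediction at t uses λ through t−1
        lam_full = lfilter([1.0], [1.0, -theta["alpha"]], z, axis=0)
        lam_prev = np.vstack([np.zeros((1, 2)), lam_full[:-1]])
        mu -= theta["beta_lambda"] * lam_prev
    return mu


def _eem_means(arr: _SessionArrays, theta: Mapping[str, float]) -> np.ndarray | None:
    """EEM mean predictions for all trials in `arr`; None when degenerate."""
    a_r = theta["k0"] + theta["k1"] * arr.side_a
    b_r = theta["k0"] + theta["k1"] * arr.side_b
    ang_r = theta["w0"] + theta["w1"] * arr.angle_ab
    if np.any(a_r <= 0) or np.any(b_r <= 0) or np.any(ang_r <= 0) or np.any(ang_r >= 180):
        return None
    c_sq = a_r**2 + b_r**2 - 2 * a_r * b_r * np.cos(np.radians(ang_r))
    c_r = np.sqrt(np.maximum(c_sq, 0.0))
    if np.any(c_r <= 1e-12):
        return None
    cos_g2 = np.clip((b_r**2 + c_r**2 - a_r**2) / (2 * b_r * c_r), -1.0, 1.0)
    g2_r = np.degrees(np.arccos(cos_g2))
    head_d = np.radians(arr.head_b + arr.turn_sign * (180.0 - g2_r))
    return c_r[:, None] * np.column_stack([np.cos(head_d), np.sin(head_d)])


def _gauss_ll(xD: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Sum of isotropic planar Gaussian log densities; −inf if any σ=0 with residual."""
    r_sq = ((xD - mu) ** 2).sum(1)
    if np.any(sigma == 0.0):
        return -math.inf if np.any(r_sq[sigma == 0.0] > 0) else math.inf
    return float(np.sum(-np.log(2 * np.pi * sigma**2) - r_sq / (2 * sigma**2)))


def _ll_arrays(arr: _SessionArrays, model_id: str, theta: Mapping[str, float]) -> float:
    sigma = theta["sigma_tilde"] * arr.path
    if model_id in ("model1", "model2"):
        mu = _vector_model_means(arr, theta)
    else:
        mu = _eem_means(arr, theta)
        if mu is None:
            return -math.inf
    return _gauss_ll(arr.xD, mu, sigma)


def _subset(arr: _SessionArrays, mask: np.ndarray) -> _SessionArrays:
    return _SessionArrays(
        xA=arr.xA[mask],
        xB=arr.xB[mask],
        xD=arr.xD[mask],
        path=arr.path[mask],
        side_a=arr.side_a[mask],
        side_b=arr.side_b[mask],
        angle_ab=arr.angle_ab[mask],
        head_b=arr.head_b[mask],
        turn_sign=arr.turn_sign[mask],
        is_left=arr.is_left[mask],
    )


def log_likelihood(session: Session, params: ParamSet) -> float:
    """Session log likelihood (nats) of the responses under one model.

    Sum over trials of ``−log(2πσ_t²) − |xD_t − x̃D_t|²/(2σ_t²)`` with
    σ_t = σ̃·sqrt(|xA|²+|xB|²). Degenerate cases (σ̃ = 0 with a nonzero
    residual, or an EEM encoding outside the valid triangle range) evaluate
    to −inf. Invariant under a common rotation of all trial vectors.
    """
    arr = _session_arrays(session)
    if params.model_id == "eem":
        total = 0.0
        for hand, mask in (("left", arr.is_left), ("right", ~arr.is_left)):
            if mask.any():
                total += _ll_arrays(_subset(arr, mask), "eem", params.hand_coeffs(hand))
        return total
    return _ll_arrays(arr, params.model_id, dict(params.values))


@dataclass(frozen=True)
class FitResult:
    """Per-subject maximum-likelihood fit of one model."""

    subject_id: str
    model_id: str
    params: ParamSet
    log_likelihood: float
    n_trials: int
    k_params: int
    n_starts: int
    converged: tuple[bool, ...]
    seed: int
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    start_diagnostics: tuple[dict, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "subject_id": self.subject_id,
                "model_id": self.model_id,
                "params": self.params.values,
                "log_likelihood": self.log_likelihood,
                "n_trials": self.n_trials,
                "k_params": self.k_params,
                "n_starts": self.n_starts,
                "converged": list(self.converged),
                "seed": self.seed,
                "bounds": {k: list(v) for k, v in self.bounds.items()},
                "start_diagnostics": list(self.start_diagnostics),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, doc: str) -> "FitResult":
        d = json.loads(doc)
        return cls(
            subject_id=d["subject_id"],
            model_id=d["model_id"],
            params=ParamSet(d["model_id"], d["params"]),
            log_likelihood=d["log_likelihood"],
            n_trials=d["n_trials"],
            k_params=d["k_params"],
            n_starts=d["n_starts"],
            converged=tuple(d["converged"]),
            seed=d["seed"],
            bounds={k: tuple(v) for k, v in d["bounds"].items()},
            start_diagnostics=tuple(d["start_diagnostics"]),
        )


def _profile_start(arr: _SessionArrays, names: Sequence[str]) -> np.ndarray | None:
    """Weighted-least-squares start for the vector models (βλ = 0)."""
    w = 1.0 / arr.path  # residuals scaled by per-trial σ ∝ path length
    y = (arr.xD * w[:, None]).ravel()
    A = np.column_stack([(-arr.xA * w[:, None]).ravel(), (-arr.xB * w[:, None]).ravel()])
    try:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    except np.linalg.LinAlgError:
        return None
    mu = -(beta[0] * arr.xA + beta[1] * arr.xB)
    r_sq = (((arr.xD - mu) / arr.path[:, None]) ** 2).sum()
    sigma_tilde = math.sqrt(max(r_sq / (2 * arr.n), 1e-8))
    theta = {"beta_A": beta[0], "beta_B": beta[1], "beta_lambda": 0.0, "alpha": 0.5,
             "sigma_tilde": sigma_tilde}
    return np.array([theta[n] for n in names])


def _fit_arrays(
    arr: _SessionArrays,
    model_id: str,
    names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    n_starts: int,
    seed: int,
) -> tuple[dict[str, float], float, list[bool], list[dict]]:
    # for the EEM, `names` are the bare per-hand coefficient names
    box = [bounds[n] for n in names]
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    def objective(x: np.ndarray) -> float:
        theta = dict(zip(names, x))
        ll = _ll_arrays(arr, model_id, theta)
        return _PENALTY if not math.isfinite(ll) else -ll

    rng = rng_from_seed(seed)
    starts = [lo + (hi - lo) * rng.random(len(names)) for _ in range(n_starts)]
    if model_id in ("model1", "model2"):
        x0 = _profile_start(arr, names)
        if x0 is not None:
            starts.append(np.clip(x0, lo, hi))

    best_x, best_fun = None, math.inf
    converged: list[bool] = []
    diagnostics: list[dict] = []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": _FTOL, "maxiter": 500},
        )
        converged.append(bool(res.success))
        diagnostics.append(
            {
                "x0": [float(v) for v in x0],
                "x": [float(v) for v in res.x],
                "neg_ll": float(res.fun),
                "success": bool(res.success),
            }
        )
        if res.fun < best_fun - 1e-12 or (
            abs(res.fun - best_fun) <= 1e-12
            and best_x is not None
            and np.linalg.norm(res.x) < np.linalg.norm(best_x)
        ):
            best_x, best_fun = res.x, float(res.fun)
    if best_x is None or not math.isfinite(best_fun) or best_fun >= _PENALTY:
        raise FitFailureError(
            f"no {model_id} start reached a finite likelihood ({len(starts)} starts)"
        )
    if not any(converged):
        raise FitFailureError(f"all {model_id} starts failed to converge")
    return dict(zip(names, (float(v) for v in best_x))), -best_fun, converged, diagnostics


def fit_mle(
    session: Session,
    model_id: str,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit one model to a session by bounded multi-start maximum likelihood.

    Deterministic given ``seed``. For the EEM the left- and right-handed
    trials are fitted separately (each with its own coefficient set and noise
    coefficient); the reported log likelihood is the sum of both halves.
    """
    if model_id not in K_PARAMS:
        raise ParameterError(f"unknown model_id {model_id!r}")
    arr = _session_arrays(session)
    if arr.n < K_PARAMS[model_id]:
        raise ParameterError(
            f"{model_id} needs at least {K_PARAMS[model_id]} trials with responses, got {arr.n}"
        )
    bnds = dict(DEFAULT_BOUNDS, **(bounds or {}))

    if model_id == "eem":
        values: dict[str, float] = {}
        total_ll = 0.0
        converged: list[bool] = []
        diagnostics: list[dict] = []
        per_hand_names = ("k0", "k1", "w0", "w1", "sigma_tilde")
        for i, (hand, mask) in enumerate((("left", arr.is_left), ("right", ~arr.is_left))):
            if not mask.any():
                raise ParameterError(f"EEM fit requires {hand}-handed trials")
            theta, ll, conv, diag = _fit_arrays(
                _subset(arr, mask), "eem", per_hand_names, bnds, n_starts, seed + i
            )
            total_ll += ll
            converged.extend(conv)
            for d in diag:
                diagnostics.append(dict(d, handedness=hand))
            for name, v in theta.items():
                values[f"{hand}_{name}"] = v
        params = ParamSet("eem", values)
        ll = total_ll
    else:
        names = PARAM_NAMES[model_id]
        theta, ll, converged, diagnostics = _fit_arrays(
            arr, model_id, names, bnds, n_starts, seed
        )
        params = ParamSet(model_id, theta)

    return FitResult(
        subject_id=session.subject_id,
        model_id=model_id,
        params=params,
        log_likelihood=ll,
        n_trials=arr.n,
        k_params=K_PARAMS[model_id],
        n_starts=n_starts,
        converged=tuple(converged),
        seed=seed,
        bounds={k: tuple(v) for k, v in bnds.items()},
        start_diagnostics=tuple(diagnostics),
    )


def simulate_fitted(design, fit_result: FitResult, seed: int, subject_id: str | None = None):
    """Regenerate a synthetic session from a fitted parameter set."""
    from .designs import build_session, simulate_responses

    session = build_session(
        design, seed=seed, subject_id=subject_id or fit_result.subject_id
    )
    return simulate_responses(session, fit_result.params, seed=seed + 1)
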