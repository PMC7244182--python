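"""Penalized model comparison, group-level selection, and model recovery.

Per subject × model, AIC = 2k − 2LL and BIC = k·ln(n) − 2LL (lower is
better), with n the number of trials. Group-level selection follows the
random-effects scheme of Stephan et al.: a variational Dirichlet posterior
over model frequencies is estimated from per-subject log evidences
(approximated as −BIC/2 by default), and each model's *exceedance
probability* — the probability that it is the most frequent generating model
in the population — is computed by Monte-Carlo sampling of that Dirichlet.

Model recovery validates the whole pipeline: each candidate model simulates
synthetic subjects at randomized parameters, every model is fitted back, and
confusion matrices tabulate how often each fitting model wins under AIC and
BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma

from ._rng import rng_from_seed, spawn_seeds
from .designs import DesignSpec, build_session, simulate_responses
from .exceptions import FitFailureError, ParameterError
from .inference import FitResult, fit_mle
from .models import ParamSet

__all__ = [
    "aic",
    "bic",
    "build_comparison_table",
    "exceedance_probabilities",
    "best_fit_counts",
    "default_param_sampler",
    "model_recovery",
]


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, 2k − 2LL."""
    if k < 0:
        raise ParameterError("k must be ≥ 0")
    return 2.0 * k - 2.0 * log_likelihood


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, k·ln(n) − 2LL.

    ``n`` counts trials (one behavioral response per trial), not response
    components.
    """
    if n < 1:
        raise ParameterError("n must be ≥ 1")
    if k < 0:
        raise ParameterError("k must be ≥ 0")
    return k * math.log(n) - 2.0 * log_likelihood


def build_comparison_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Long-form table: one row per subject × model with LL, k, n, AIC, BIC."""
    rows = [
        {
            "subject_id": f.subject_id,
            "model_id": f.model_id,
            "log_likelihood": f.log_likelihood,
            "k": f.k_params,
            "n": f.n_trials,
            "aic": aic(f.log_likelihood, f.k_params),
            "bic": bic(f.log_likelihood, f.k_params, f.n_trials),
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def exceedance_probabilities(
    log_evidence: np.ndarray,
    n_draws: int = 100_000,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Exceedance probability of each model from a subjects × models
    log-evidence matrix.

    Variational Dirichlet update under a uniform Dirichlet(1, …, 1) prior on
    model frequencies: iterate posterior model assignments and Dirichlet
    counts until the counts change by less than ``tol``, then estimate each
    model's probability of being the population's most frequent model by
    sampling the Dirichlet (``n_draws`` draws, seeded). Probabilities sum to
    one. Adding a constant to one subject's row leaves the result unchanged.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ParameterError("log_evidence must be (n_subjects, n_models≥2)")
    if not np.all(np.isfinite(L)):
        raise ParameterError("log evidences must be finite")
    n_subjects, n_models = L.shape
    alpha0 = np.ones(n_models)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        u = L + digamma(alpha) - digamma(alpha.sum())
        u -= u.max(axis=1, keepdims=True)
        g = np.exp(u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = rng_from_seed(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=n_models) / n_draws


def best_fit_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-criterion count of subjects best fitted by each model.

    Criteria: highest log likelihood, lowest AIC, lowest BIC. Exact ties are
    not assigned to any model; they are tallied in the ``(tie)`` row, so each
    column sums to the number of subjects.
    """
    models = sorted(table["model_id"].unique())
    counts = pd.DataFrame(
        0, index=models + ["(tie)"], columns=["log_likelihood", "aic", "bic"]
    )
    for criterion, better_high in (("log_likelihood", True), ("aic", False), ("bic", False)):
        for _, sub in table.groupby("subject_id"):
            vals = sub.set_index("model_id")[criterion]
            best = vals.max() if better_high else vals.min()
            winners = vals.index[np.isclose(vals, best, rtol=0, atol=1e-12)]
            if len(winners) == 1:
                counts.loc[winners[0], criterion] += 1
            else:
                counts.loc["(tie)", criterion] += 1
    return counts


def default_param_sampler(model_id: str, rng: np.random.Generator) -> ParamSet:
    """Randomized generating parameters for model recovery.

    Vector-model weights are uniform on [0, 1.2], α uniform on [0, 1] and the
    noise coefficient uniform on [0.05, 0.3]; EEM slopes uniform on
    [0.7, 1.1] with intercepts near zero, drawn independently per handedness.
    """
    u = rng.uniform
    if model_id == "model1":
        return ParamSet.model1(u(0, 1.2), u(0, 1.2), u(0.05, 0.3))
    if model_id == "model2":
        return ParamSet.model2(u(0, 1.2), u(0, 1.2), u(0, 1.2), u(0, 1), u(0.05, 0.3))
    if model_id == "eem":
        def hand() -> dict[str, float]:
            return dict(
                k0=u(-0.5, 0.5), k1=u(0.7, 1.1), w0=u(-5, 5), w1=u(0.7, 1.1),
                sigma_tilde=u(0.05, 0.3),
            )
        return ParamSet.eem(left=hand(), right=hand())
    raise ParameterError(f"unknown model_id {model_id!r}")


@dataclass(frozen=True)
class RecoveryResult:
    """Confusion matrices (rows: generating model, columns: fitting model)."""

    aic: pd.DataFrame
    bic: pd.DataFrame
    n_sims: int
    n_failures: pd.Series  # per generating model: sims where every fit failed


def model_recovery(
    design: DesignSpec,
    model_ids: Sequence[str],
    n_sims: int = 100,
    param_sampler: Callable[[str, np.random.Generator], ParamSet] | None = None,
    seed: int = 0,
    n_starts: int = 20,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> RecoveryResult:
    """Simulate-and-refit confusion matrices under AIC and BIC.

    For each generating model, ``n_sims`` synthetic subjects are simulated on
    ``design`` with parameters drawn from ``param_sampler``; every candidate
    model is fitted back and the winner (lowest criterion) tallied. Rows are
    normalized over the simulations where at least one model fitted; fully
    seeded and reproducible.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be ≥ 1")
    sampler = param_sampler or default_param_sampler
    model_ids = list(model_ids)
    aic_mat = pd.DataFrame(0.0, index=model_ids, columns=model_ids)
    bic_mat = pd.DataFrame(0.0, index=model_ids, columns=model_ids)
    failures = pd.Series(0, index=model_ids)
    seeds = spawn_seeds(seed, len(model_ids) * n_sims * 3)
    it = iter(seeds)
    for gen in model_ids:
        n_scored = 0
        for _ in range(n_sims):
            s_params, s_sim, s_fit = next(it), next(it), next(it)
            params = sampler(gen, rng_from_seed(s_params))
            session = build_session(design, seed=s_sim, subject_id=f"sim_{gen}")
            session = simulate_responses(session, params, seed=s_sim + 1)
            scores_aic: dict[str, float] = {}
            scores_bic: dict[str, float] = {}
            for fit_model in model_ids:
                try:
                    fr = fit_mle(
                        session, fit_model, bounds=bounds, n_starts=n_starts, seed=s_fit
                    )
                except FitFailureError:
                    continue
                scores_aic[fit_model] = aic(fr.log_likelihood, fr.k_params)
                scores_bic[fit_model] = bic(fr.log_likelihood, fr.k_params, fr.n_trials)
            if not scores_aic:
                failures[gen] += 1
                continue
            n_scored += 1
            aic_mat.loc[gen, min(scores_aic, key=scores_aic.get)] += 1
            bic_mat.loc[gen, min(scores_bic, key=scores_bic.get)] += 1
        if n_scored:
            aic_mat.loc[gen] /= n_scored
            bic_mat.loc[gen] /= n_scored
    return RecoveryResult(aic=aic_mat, bic=bic_mat, n_sims=n_sims, n_failures=failures)
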