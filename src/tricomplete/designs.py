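"""Experimental designs and synthetic session generation.

Two designs are emulated:

* **exp1** — seven triangle templates (3 scalene, 1 isosceles, 1 right,
  1 equilateral, 1 isosceles-right) sharing a fixed 10 m unguided side; 28
  trials, 14 left-handed and 14 right-handed (two of each handedness per
  template).
* **exp2** — one scalene shape at five sizes with perimeters 15.19, 25.32,
  126.60, 253.20 and 506.42 m; interior angles identical across sizes.
  Per-size trial counts are 10, 10, 8, 4 and 2 (34 trials, 17 per
  handedness); the larger sizes get fewer repetitions.

The equilateral (60-60-60), isosceles (30-120-30) and isosceles-right
(45-90-45) angle triples of exp1 are fixed by the design; the remaining
triples and the exp2 scalene shape are configurable defaults — only side C
and the perimeters are normative. Responses for a session are simulated from
any of the generative models under Weber-scaled isotropic Gaussian noise;
Model 2's history is fed by the vectors actually simulated on earlier trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from ._rng import rng_from_seed
from .exceptions import ParameterError
from .geometry import PlanarVector, Session, TriangleTemplate, Trial, walk_template
from .models import HistoryState, ParamSet, noise_scale, predict_eem, predict_model1, predict_model2, update_history

__all__ = [
    "DesignSpec",
    "EXP1_ANGLE_TRIPLES",
    "EXP2_ANGLE_TRIPLE",
    "EXP2_PERIMETERS",
    "exp1_templates",
    "exp2_templates",
    "exp1_design",
    "exp2_design",
    "build_session",
    "simulate_responses",
]

# Interior-angle triples (at origin, G1, G2) for the seven exp1 templates.
# The equilateral, isosceles and isosceles-right triples are part of the
# design; the right and scalene triples are documented placeholders and can
# be overridden.
EXP1_ANGLE_TRIPLES: dict[str, tuple[float, float, float]] = {
    "equilateral_60_60_60": (60.0, 60.0, 60.0),
    "isosceles_30_120_30": (30.0, 120.0, 30.0),
    "isosceles_right_45_90_45": (45.0, 90.0, 45.0),
    "right_60_90_30": (60.0, 90.0, 30.0),
    "scalene_50_75_55": (50.0, 75.0, 55.0),
    "scalene_40_105_35": (40.0, 105.0, 35.0),
    "scalene_70_65_45": (70.0, 65.0, 45.0),
}

EXP1_SIDE_C = 10.0  # m, the fixed unguided side

# One scalene shape at five perimeters; the triple is a configurable default,
# the perimeters are normative.
EXP2_ANGLE_TRIPLE: tuple[float, float, float] = (35.0, 100.0, 45.0)
EXP2_PERIMETERS: tuple[float, ...] = (15.19, 25.32, 126.60, 253.20, 506.42)
EXP2_TRIAL_COUNTS: tuple[int, ...] = (10, 10, 8, 4, 2)


@dataclass(frozen=True)
class DesignSpec:
    """Templates, repetition counts and handedness balance of one design.

    ``templates`` are left-handed prototypes; per-template counts give
    (left, right) repetitions and must sum to the design's handedness
    balance.
    """

    design_id: str
    templates: tuple[TriangleTemplate, ...]
    trial_counts: Mapping[str, tuple[int, int]]  # label -> (n_left, n_right)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        labels = [t.label for t in self.templates]
        if len(set(labels)) != len(labels):
            raise ParameterError(f"duplicate template labels in design: {labels}")
        if set(self.trial_counts) != set(labels):
            raise ParameterError("trial_counts keys must match template labels")
        for label, (nl, nr) in self.trial_counts.items():
            if nl < 0 or nr < 0:
                raise ParameterError(f"negative trial count for {label}")

    @property
    def n_trials(self) -> int:
        return sum(nl + nr for nl, nr in self.trial_counts.values())

    @property
    def handedness_balance(self) -> tuple[int, int]:
        n_left = sum(nl for nl, _ in self.trial_counts.values())
        n_right = sum(nr for _, nr in self.trial_counts.values())
        return n_left, n_right


def exp1_templates(
    angle_triples: Mapping[str, Sequence[float]] | None = None,
    side_c: float = EXP1_SIDE_C,
) -> list[TriangleTemplate]:
    """The seven constant-return-distance templates of the first design.

    Side C is fixed (10 m by default); sides A and B follow from the interior
    angles by the law of sines. Triples not summing to 180° raise
    ``TriangleError``.
    """
    triples = dict(EXP1_ANGLE_TRIPLES if angle_triples is None else angle_triples)
    return [
        TriangleTemplate.from_angles(label, triple, side_c=side_c, handedness="left")
        for label, triple in triples.items()
    ]


def exp2_templates(
    angle_triple: Sequence[float] | None = None,
    perimeters: Sequence[float] = EXP2_PERIMETERS,
) -> list[TriangleTemplate]:
    """Five similar triangles of one scalene shape at the design perimeters."""
    triple = tuple(EXP2_ANGLE_TRIPLE if angle_triple is None else angle_triple)
    if len(set(triple)) < 3:
        warnings.warn(
            f"exp2 shape {triple} is not scalene; proceeding anyway", stacklevel=2
        )
    return [
        TriangleTemplate.from_angles_perimeter(
            f"perimeter_{p:g}m", triple, perimeter=p, handedness="left"
        )
        for p in perimeters
    ]


def exp1_design(
    angle_triples: Mapping[str, Sequence[float]] | None = None, seed: int = 0
) -> DesignSpec:
    """28-trial design: 7 templates × (2 left + 2 right)."""
    templates = exp1_templates(angle_triples)
    counts = {t.label: (2, 2) for t in templates}
    return DesignSpec("exp1", tuple(templates), counts, seed=seed)


def exp2_design(
    angle_triple: Sequence[float] | None = None,
    trial_counts: Sequence[int] = EXP2_TRIAL_COUNTS,
    seed: int = 0,
) -> DesignSpec:
    """34-trial design over five sizes, counts split evenly by handedness."""
    templates = exp2_templates(angle_triple)
    if len(trial_counts) != len(templates):
        raise ParameterError("one trial count per perimeter required")
    counts = {}
    for tpl, n in zip(templates, trial_counts):
        if n % 2:
            raise ParameterError(
                f"per-size count {n} cannot be split evenly between handednesses"
            )
        counts[tpl.label] = (n // 2, n // 2)
    return DesignSpec("exp2", tuple(templates), counts, seed=seed)


def build_session(
    design: DesignSpec, seed: int, subject_id: str = "synthetic"
) -> Session:
    """Instantiate a session (responses absent) from a design.

    Trial order is a seeded permutation of the design's template ×
    handedness multiset; each trial is laid out in its own frame (start at
    the origin, side A along +x). Deterministic given ``(design, seed)``.
    """
    items: list[TriangleTemplate] = []
    for tpl in design.templates:
        n_left, n_right = design.trial_counts[tpl.label]
        items.extend([tpl] * n_left)
        items.extend([tpl.mirrored()] * n_right)
    rng = rng_from_seed(seed)
    order = rng.permutation(len(items))
    trials = []
    for pos, idx in enumerate(order, start=1):
        tpl = items[idx]
        xA, xB, xC = walk_template(tpl)
        trials.append(Trial(index=pos, template=tpl, xA=xA, xB=xB, xC=xC))
    return Session(
        subject_id=subject_id, design_id=design.design_id, trials=tuple(trials), seed=seed
    )


def simulate_responses(session: Session, params: ParamSet, seed: int) -> Session:
    """Fill a session's responses by forward simulation from one model.

    Trials are processed in order; the model's mean prediction is perturbed
    by isotropic Gaussian noise with SD ``σ = σ̃·sqrt(|xA|² + |xB|²)`` added
    independently to each component. For Model 2 the history accumulators are
    updated with the vectors actually simulated on earlier trials.
    Deterministic given ``seed``; the input session is not mutated.
    """
    rng = rng_from_seed(seed)
    state = HistoryState.zero()
    responses: list[PlanarVector] = []
    for trial in session.trials:
        if params.model_id == "model1":
            mean = predict_model1(
                trial.xA, trial.xB, params["beta_A"], params["beta_B"]
            )
        elif params.model_id == "model2":
            mean = predict_model2(
                trial.xA,
                trial.xB,
                state,
                params["beta_A"],
                params["beta_B"],
                params["beta_lambda"],
            )
        else:  # eem
            coeffs = params.hand_coeffs(trial.template.handedness)
            mean = predict_eem(
                trial.xA,
                trial.xB,
                coeffs["k0"],
                coeffs["k1"],
                coeffs["w0"],
                coeffs["w1"],
            )
        if params.model_id == "eem":
            sigma = noise_scale(
                params.hand_coeffs(trial.template.handedness)["sigma_tilde"],
                trial.xA,
                trial.xB,
            )
        else:
            sigma = noise_scale(params["sigma_tilde"], trial.xA, trial.xB)
        eps = rng.normal(0.0, 1.0, size=2) * sigma
        xD = PlanarVector(mean.x + eps[0], mean.y + eps[1])
        responses.append(xD)
        if params.model_id == "model2":
            state = update_history(state, trial.xA, trial.xB, xD, params["alpha"])
    return session.with_responses(responses)
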