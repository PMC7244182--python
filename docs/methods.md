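# Methods

This note documents the modeling choices behind `tricomplete`: the
generative models, the noise model, the synthetic designs, the fitting and
comparison machinery, and the numerical decisions that were genuinely open.

## Task geometry and conventions

Each trial is laid out in its own frame: origin at the start point, side A
walked along +x. All error metrics are invariant to a common rotation of a
trial's vectors (tested by property tests), so the frame is presentation
only. Angles are degrees at every public interface and radians internally;
wrapped angles live in (−180°, 180°], with ties at ±180° resolved to +180°.

A template is defined by its interior angles (at the origin, at the first
corner G1, and at the second corner G2), its side lengths, and a
*handedness*: left-handed paths make counterclockwise exterior turns,
right-handed paths clockwise. The two conventions are mirror images and all
metrics are mirror-symmetric, so the choice is inert. Walking a template
turns by the exterior angle `180° − ∠G1` at the first corner.

**Angle error.** The correct turn at G2 and the executed turn are both
measured from the direction of side B, signed positive in the *required*
turn direction. The reported error is (executed − required) under that sign
convention, so a positive value always means turning past the correct
heading (overshoot), independent of handedness. The original measurement
axis for this quantity is not fully specified by its source figure; this
operationalization is chosen because it reproduces the stated
overshoot/undershoot semantics for both handednesses.

**Distance error** is |xD|/|xC| (> 1 overshoot); **position error** is
|xA + xB + xD|, the final distance from the origin. Angle summaries use
circular statistics (mean resultant vector); a resultant length below 1e-12
makes the circular mean undefined and raises rather than returning noise.

## Generative models

* **Model 1**: `x̃D = −(βA·xA + βB·xB)`. βA = βB = 1 is the ideal homing
  vector; equal weights β scale the return distance by exactly β with zero
  angle error, a closed-form identity the tests exploit.
* **Model 2**: adds `−βλ·[λA + λB − λD]`, where each accumulator is updated
  *after* a trial completes as `λ ← x + α·λ` (α ∈ [0, 1]) and starts at the
  zero vector before trial 1, so the first prediction equals Model 1's for
  any βλ. λD accumulates the vectors actually walked (observed responses
  when fitting, simulated responses when simulating), not the ideal returns.
  The history only includes completed previous trials, never the current
  one.
* **Encoding-Error Model**: the two guided side lengths are encoded through
  the *same* linear function `s_r = k0 + k1·s` and the turn angle through
  `∠ab_r = w0 + w1·∠ab`; the encoded return distance C_r follows from the
  law of cosines and the encoded interior angle at G2 from the law of
  cosines on the encoded triangle. (A law-of-sines formulation is
  equivalent but ambiguous when the encoded angle at G2 is obtuse; the
  law-of-cosines form needs no case split.) The response vector has length
  C_r at the heading implied by the encoded return turn in the trial frame.
  The linear (intercept + slope) encoding family is isolated behind
  `eem_return_path` so alternatives (e.g. power laws) can be swapped in.
  Encodings producing a non-positive side, an angle outside (0°, 180°), or a
  collapsed return side are reported per trial as degenerate. The EEM is
  limited to two-segment paths by construction and has no history term.

EEM coefficients are fitted separately for left- and right-handed trials;
one parameter set stores both halves (10 parameters total, and k = 10 in the
information criteria). Model 1 has k = 3 and Model 2 k = 5.

## Noise model and likelihood

Responses are the model prediction plus isotropic Gaussian noise added
independently to each component with standard deviation
`σ = σ̃·sqrt(|xA|² + |xB|²)` — scalar (Weber) variability: doubling the
walked path doubles the response SD. The session log likelihood is the sum
of isotropic planar Gaussian log densities,

    LL = Σ_t [ −log(2π σ_t²) − |xD_t − x̃D_t|² / (2 σ_t²) ].

A published variant of this expression is typeset inconsistently with the
stated isotropic sampling model; the planar Gaussian density above is the
form consistent with how the noise is defined and simulated, and it is what
this package implements (verified against a per-trial `scipy.stats` density
product to 1e-9, and rotation-invariant by isotropy). σ̃ = 0 with a nonzero
residual yields −∞, flagged rather than masked.

## Synthetic designs

The generator's defaults are the study conditions, not tuning knobs:

* **Shape design (`exp1`)**: seven templates with side C = 10 m exactly,
  sides A and B derived by the law of sines from the interior angles; 28
  trials = 7 templates × (2 left + 2 right), order given by a seeded
  permutation. The equilateral (60-60-60), isosceles (30-120-30) and
  isosceles-right (45-90-45) triples are fixed; the right triangle
  (60-90-30) and three scalenes (50-75-55, 40-105-35, 70-65-45) are
  documented placeholder triples — the original per-template tables are not
  available — and are configurable data, not constants.
* **Size design (`exp2`)**: one scalene shape (default triple 35-100-45,
  configurable; a non-scalene override warns but proceeds) at perimeters
  15.19, 25.32, 126.60, 253.20 and 506.42 m (matched to 1e-6 m), with
  per-size trial counts 10, 10, 8, 4, 2 split evenly between handednesses —
  34 trials. The source description of this design is internally
  inconsistent (a stated total of 30 trials vs. per-size counts summing
  to 34); the per-size counts are taken as normative because they are the
  more specific statement.

Whether the original pseudorandomized trial sequences constrained
consecutive repeats is unknown; the seeded permutation imposes no such
constraint. All randomness flows through counter-based Philox generators
keyed by explicit integer seeds; identical (design, seed) pairs reproduce
byte-identical trial tables.

What the generator does **not** emulate: execution noise on the guided
sides, controller feedback dynamics, breaks/fatigue, trial exclusions, or
any vision manipulation. Passing recovery tests therefore show that the
estimation machinery is correct and well-calibrated *under the assumed
generative process*, not that the models are correct for real walkers.

## Fitting

Per-subject maximum likelihood with bounded multi-start local optimization
(L-BFGS-B, numerical gradients, `ftol` 1e-10, 500 iterations max). Default
bounds are generous boxes around all reported estimates: weights βA, βB, βλ
∈ [−2, 2], α ∈ [0, 1], σ̃ ∈ [1e-4, 2], EEM slopes ∈ [0, 2], intercepts ∈
[−5, 5] m and [−30°, 30°]. Default `n_starts` = 20 seeded uniform draws
inside the box; for the vector models one extra deterministic start is added
at the weighted-least-squares solution (weights 1/σ_t², βλ = 0, α = 0.5,
σ̃ profiled from the residuals). Ties between equal-likelihood starts break
toward the smallest parameter-vector norm. Degenerate parameter points
(e.g. EEM encodings outside the triangle range) receive a large finite
penalty so the optimizer retreats rather than aborts; a fit fails only if
every start is degenerate or non-convergent. Internally the likelihood is
vectorized over trials (the exponential history recursion is an IIR filter
evaluated with `scipy.signal.lfilter`, which is numerically stable for any
α ∈ [0, 1]); its equivalence to the scalar per-trial path is a tested
invariant, and the optimum is checked against a 21³ grid oracle.

Model 2 is fitted in one-step-ahead mode: λD is propagated from the
*observed* responses, matching how the history is defined.

## Model comparison

AIC = 2k − 2LL and BIC = k·ln(n) − 2LL with n = trials per subject (one
behavioral response per trial; using 2n for the two response components
would shift all BICs by a model-independent amount times k and is not
done — the choice is configurable at the call site by passing n). Group
selection uses the random-effects scheme of Stephan et al. (2009): a
variational Dirichlet posterior over model frequencies (uniform prior,
posterior assignment / count iteration to 1e-6), with log model evidence
approximated as −BIC/2 (common practice; the evidence approximation used by
the original group analysis is unstated, so BIC is the default and AIC-based
evidences are equally accepted). Exceedance probabilities are estimated from
10⁵ seeded Dirichlet draws. Known limits are tested: identical evidences
give (0.5, 0.5); a model dominant by ≥ 20 nats per subject exceeds 0.99.

Model recovery simulates each candidate model at randomized parameters
(weights uniform on [0, 1.2], α on [0, 1], σ̃ on [0.05, 0.3], EEM slopes on
[0.7, 1.1] with near-zero intercepts — the original randomization is
unspecified), refits all models, and tabulates AIC and BIC winners into
confusion matrices whose rows are normalized over scored simulations.

## Summaries

Group statistics use per-subject circular means for angle error and
arithmetic means for distance error; dispersion across subjects is the
natural next step but only the means are computed here. The distance
regressions are ordinary least squares with intercept (no
heteroskedasticity correction). The SD-vs-distance line pools trials within
a size group across subjects (a per-subject-then-pooled variant would also
be defensible; pooled is implemented and flagged here). The systematic-error
fit regresses mean `1 − |xD|/|xC|` per size group on ln|xC| and reports
intercept, slope and R².

## Problem sizes

The shipped test-suite and acceptance-script runs use the full design sizes
(28- and 34-trial sessions; cohorts of 22 and 17 subjects; 20 optimizer
starts). The model-recovery property checks use compact cohorts (8
simulations per generating model, 6 starts) — enough to exercise row
normalization, determinism and low-noise diagonal dominance of the nested
vector models, which are structural rather than asymptotic properties.
Larger recovery studies (e.g. 100 simulations per model including the EEM)
run through the same `model_recovery` API or the `recover` CLI subcommand.

## Known limitations

* The EEM's original encoding functions and parameter count are not fully
  specified by available sources; the linear family implemented here is the
  standard formulation but other families may fit differently.
* Vector directions are assumed encoded without systematic bias (only
  magnitudes are weighted); direction mis-encoding models are out of scope.
* No hierarchical (group-level) parameter estimation: fits are independent
  per subject, as in the original analyses.
* Exceedance probabilities depend on the −BIC/2 evidence approximation;
  with few subjects and nested models the Dirichlet scheme can be
  conservative.
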