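# tricomplete

Configural models of human path integration in the **triangle completion
task**: a walker is guided along two sides of a triangle (vectors xA, xB) and
must return, unguided, to the origin. The correct return is the *configural
homing vector*

```
xC = −(xA + xB)
```

and the walked return xD deviates from it systematically — people tend to
overshoot the turn angle and undershoot the return distance. `tricomplete`
implements, fits, simulates and formally compares three generative accounts
of those errors, for researchers modeling human (or animal) dead reckoning:

* **Model 1 — weighted vector addition.** The predicted return is
  `x̃D = −(βA·xA + βB·xB)`; under- or over-weighting a guided side (βA, βB ≠ 1)
  produces both angle and distance biases.
* **Model 2 — vector addition with trial history.** Adds a
  regression-to-the-mean pull from previously walked paths:
  `x̃D = −(βA·xA + βB·xB + βλ·[λA + λB − λD])`, where each accumulator decays
  exponentially, `λ ← x + α·λ` with α ∈ [0, 1]. Model 2 nests Model 1 (βλ = 0).
* **Encoding-Error Model (EEM).** Both guided side lengths pass through one
  linear encoding `s_r = k0 + k1·s` and the turn angle through
  `∠ab_r = w0 + w1·∠ab`; the return distance follows from the law of cosines
  on the encoded triangle and the return turn from its encoded angle at the
  second corner. Coefficients are fitted separately for left- and
  right-handed paths.

Responses are modeled as the prediction plus isotropic Gaussian noise whose
standard deviation scales with the traversed path — scalar variability
consistent with Weber's law:

```
σ = σ̃ · sqrt(|xA|² + |xB|²)
```

Fitting is per-subject maximum likelihood (bounded multi-start L-BFGS-B) of
the planar Gaussian log likelihood
`LL = Σ_t [ −log(2πσ_t²) − |xD_t − x̃D_t|² / (2σ_t²) ]`. Model comparison
offers AIC/BIC, best-fit counts, random-effects exceedance probabilities
(variational Dirichlet over model frequencies), and simulate-and-refit
model-recovery confusion matrices.

Because no participant data are distributed, the package ships first-class
synthetic designs: a 28-trial design with seven triangle shapes sharing a
10 m return side (14 left-/14 right-handed trials), and a 34-trial design
with one scalene shape at five perimeters (15.19–506.42 m).

## Worked example

```python
import tricomplete as tc

design = tc.exp1_design()                       # 7 shapes × 4 trials, |xC| = 10 m
truth = tc.ParamSet.model1(0.3, 0.813, 0.1)     # group-mean side weights
session = tc.simulate_responses(
    tc.build_session(design, seed=11, subject_id="S01"), truth, seed=12
)

print(tc.subject_summary(session))
# SubjectSummary('S01', angle=26.04°, distance=0.671, position=5.21 m)

fit1 = tc.fit_mle(session, "model1", n_starts=20, seed=0)
fit2 = tc.fit_mle(session, "model2", n_starts=20, seed=0)
print(fit1.params.values, round(fit1.log_likelihood, 2))
# {'beta_A': 0.288..., 'beta_B': 0.817..., 'sigma_tilde': 0.090...} -77.33
print(round(tc.aic(fit1.log_likelihood, 3), 2), round(tc.bic(fit1.log_likelihood, 3, 28), 2))
# 160.66 164.65
print(round(tc.aic(fit2.log_likelihood, 5), 2), round(tc.bic(fit2.log_likelihood, 5, 28), 2))
# 161.91 168.57
```

The simulated subject shows the signature biases — a positive (overshot)
mean turn angle of 26° and an undershot return distance (ratio 0.671 < 1) —
because side A is weighted far below side B. Refitting recovers the
generating weights (0.288 / 0.817 vs. 0.3 / 0.813), and both penalized
criteria prefer the 3-parameter Model 1 over the 5-parameter Model 2 on data
that contain no history effect.

A `tricomplete` command-line interface wraps the same functions
(`simulate`, `fit`, `compare`, `recover`, `summarize`, `validate`, and `run`
for a full seeded pipeline from a YAML config); trial data travel as a plain
CSV table of per-trial vectors.

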