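# circinf

Circular-inference modelling of bistable Necker-cube perception:
a generative attractor model of trial-by-trial percept reports under
intermittent stimulation, a simulation-based fitting procedure, a
synthetic longitudinal cohort generator, and the group-level statistical
pipeline that ties perceptual dynamics to questionnaire measures
(conspiracy-belief and political-distress scores).

## The model

An observer views a Necker cube intermittently and reports, at each
presentation, which 3-D interpretation they see: *seen from above* (SFA)
or *seen from below* (SFB). The belief is the log-odds `L` of SFA versus
SFB. Between presentations (OFF periods, 0.1–1.2 s) the belief evolves
without input:

    dL/dt = r_on (1 + e^{-L}) - r_off (1 + e^{L}) + a L

with `r_on = r b`, `r_off = r (1 - b)` the switching rates of the
generative model (volatility `r` = 10 Hz, bias `b` toward SFA), and
`a = L_St · r` the amplification of the current belief by descending
loops — the circular-inference term. For loop strength `L_St < 1` the
model is a leaky integrator that forgets its percept; for `L_St > 1` the
energy landscape becomes a double well and the percept is stabilized
across long blanks. At each presentation the ambiguous stimulus adds an
impulse `w·ε`, `ε ~ N(0,1)`; the report is the sign of `L`; and a
penalty `P` then shifts the belief along the reported percept's
direction (negative `P` destabilizes it, capturing reports of the less
likely interpretation at short blanks). The Bayes-optimal variant sets
`a = 0` and frees `r`.

Each subject is summarized by 28 pairwise response statistics (4 ordered
report pairs × 7 OFF-duration levels). Fitting minimizes the Euclidean
distance between these statistics and the model's prediction averaged
over many simulated runs with frozen noise (common random numbers),
using a bound-constrained multi-start compass pattern search over
`(b, w, L_St, P)`.

## Worked example

```python
import numpy as np
from circinf import CIParams, make_trial_sequence, simulate_run
from circinf import pairwise_stats, fit_stability_curve, fit_subject

seq = make_trial_sequence(seed=1)           # 10 blocks x 64 trials
subject = CIParams(b=0.59, w=1.70, loop_strength=1.85, penalty=-2.04)
run = simulate_run(subject, seq, seed=42)   # one session's reports

stats = pairwise_stats(run, seq)
fit = fit_stability_curve(stats.sp_by_delay, stats.delays)
print(f"overall SP by delay: {np.round(stats.sp_by_delay, 3)}")
print(f"stability score: {fit.stability_score:.3f}")

refit = fit_subject(stats, seq, n_restarts=20, n_runs=20, seed=0,
                    max_evals=400)
print(f"fitted (b, w, L_St, P) = ({refit.params.b:.2f}, "
      f"{refit.params.w:.2f}, {refit.params.loop_strength:.2f}, "
      f"{refit.params.penalty:.2f}); distance {refit.objective_value:.3f}")
```

prints

```
overall SP by delay: [0.578 0.5   0.556 0.533 0.567 0.522 0.567]
stability score: 0.550
fitted (b, w, L_St, P) = (0.73, 4.15, 2.43, -3.17); distance 0.178
```

This subject's stability probability hovers near 0.55 across blanks —
a moderately unstable observer, close to the population-mean stability
of ~0.57 — and the fitted stability score is the curve's value at the
longest blank. The refit matches the response statistics closely
(distance 0.178 over the 28-vector), while the parameter estimates
land elsewhere on the soft
trade-off surface between sensory gain and loop strength; see the
identifiability discussion in `docs/methods.md`.

A full synthetic study — cohort generation, quality filtering,
behavioral summaries, per-subject fits and group statistics — runs as

```
circinf run-all --n 30 --seed 0 --profile scaled_down out/run1
```

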