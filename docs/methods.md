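# Methods

## The generative model

The belief about the Necker cube's 3-D configuration is the log-odds
`L` of "seen from above" (SFA) against "seen from below" (SFB). During
the blank interval (OFF period) before each presentation the belief
follows the autonomous dynamics

    dL/dt = r_on (1 + e^{-L}) - r_off (1 + e^{L}) + a L ,

where `r_on = r b` and `r_off = r (1 - b)` are the switching rates of
the generative model (configuration volatility `r`, bias `b` toward
SFA) and `a` amplifies the current belief through descending loops.
The dimensionless loop strength `L_St = a / r` governs the phase
portrait: for `L_St < 1` the drift has a single stable zero near
indifference (leaky integrator); at `L_St = 1` (with `b = 0.5`) a
pitchfork bifurcation creates two stable fixed points — an energy
double well — and the percept is retained across arbitrarily long
blanks. Strong biases tilt the landscape until only the SFA well
survives. The associated potential, `U(L)` with `U' = -drift` and
`U(0) = 0`, is exposed for landscape inspection.

At presentation onset the ambiguous stimulus contributes an impulse
`w ε`, `ε ~ N(0, 1)` i.i.d. per trial, added to `L`; the model reports
SFA if `L > 0`, SFB if `L < 0` (an exactly zero belief — a measure-zero
event reachable only in degenerate parameter corners — is resolved by a
fair coin from the run's RNG stream). After the report, the belief is
shifted by the penalty `P` *along the reported percept's direction*
(`L += sign(report) · P`): negative `P` pushes against whatever was
just seen, which reproduces reports of the less likely configuration at
the shortest blanks; positive `P` entrenches the current percept. An
additive variant (`L += P`, independent of the report) is available via
`penalty_mode="additive"`. The response-relative form is the default
because, at the published population-mean parameters, it reproduces the
published stability moments (simulated cohort stability 0.59 ± 0.22
against the reported .572 ± .178) and SFA dominance, whereas the
additive form yields over-stable, SFB-dominated runs (0.76 ± 0.15,
SFA fraction 0.27).

Blocks are separated by a long gap intended to decouple them; the
belief is reset to `L = 0` at each block onset (configurable through
`block_start_l`). The circular variant fixes `r = 10` Hz — a 100 ms
sensory integration time constant — leaving `(b, w, L_St, P)` free;
the Bayes-optimal variant fixes `a = 0` and frees `(b, w, r, P)`.

## Numerics

The OFF drift grows like `e^{|L|}`, so explicit stepping in `L` is
stiff near the working cap `|L| = 12`. Integration is therefore
carried out in `u = tanh(L/2)`, where the identical dynamics read

    du/dt = r_on (1 - u) - r_off (1 + u) + a (1 - u^2) atanh(u)

and every term is bounded (rates ≤ ~40 s⁻¹ over the whole parameter
box). For `b = 0.5, a = 0` this is exactly `du/dt = -r u`, the
closed-form decay law `tanh(L(t)/2) = tanh(L0/2) e^{-rt}` used as the
integrator oracle; the fixed-step classical Runge-Kutta scheme at
`dt = 1 ms` matches it to ~1e-10 over `L0 ∈ [-3, 3]`, `t ≤ 1.2 s`.

Because the OFF dynamics are one-dimensional and autonomous, a single
integration of a grid of start values yields a flow map
`L_in -> L_out` per delay level (1201 nodes over `[-12, 12]` by
default); simulation then only interpolates the map linearly per
trial. The map is monotone (1-D flows preserve order), and the grid
contains `L = 0`, so interpolation never flips the side of the
unstable fixed point. Fitting uses a coarser profile (301 nodes,
`dt = 5 ms`) whose pairwise-frequency error (~0.009 in the 28-vector
norm) is far below the Monte-Carlo floor of a 20-run objective
(~0.067). Fixed points are located by a dense sign-change scan at 1e-3
resolution refined by Brent's method to 1e-9 and classified by the
drift's derivative.

## Behavioral summaries

Two successive reports within a block form an ordered pair attributed
to the OFF duration of the second report; 4 ordered pairs × 7 delay
levels give 28 conditional frequencies (each delay column sums to 1;
columns without pairs are flagged missing, never zero-filled). The
stability probability `SP(d)` is the column's repeat mass. Its curve
over delays typically drops then plateaus; the plateau portion — from
the empirical minimum through the last delay — is fitted with the
saturating exponential `SP(d) = A - B e^{-d/τ}` (bounded least squares,
`A, B ∈ [0, 1.05]`, `τ ∈ (0, 10]`, multi-start over
`τ ∈ {0.1, 0.3, 1.0}` s), and the fitted value at the longest delay is
the subject's stability score. When fewer than three defined points
remain, the raw last SP is used and flagged. Per-percept stabilities
(SFA and SFB separately) are computed and reported but feed nothing
downstream.

## Fitting

The objective is the Euclidean distance between a subject's observed
28-vector and the model's prediction averaged over `n_runs` simulated
runs on the subject's own OFF sequence. The noise streams of those
runs are frozen per fit (common random numbers), making the stochastic
objective deterministic in the parameters — a requirement for
derivative-free search. Optimization is a bound-constrained compass
pattern search in box-normalized coordinates: initial mesh 0.5,
opportunistic ± polls per coordinate, mesh doubling on success (capped
at 0.5) and halving after a full failed poll, terminating below mesh
1e-3 or at the evaluation budget. Each fit restarts from points drawn
uniformly in the box and keeps the best end point. Bounds:
`b ∈ [0.01, 0.99]`, `w ∈ [0, 6]`, `L_St ∈ [0, 6]`, `P ∈ [-8, 8]`,
`r ∈ [0.5, 50]` Hz (Bayes variant) — population means ± ~3 SD.

Two profiles ship: the full procedure (100 restarts × 40 runs, 2000
evaluations per restart) and a desk-scale one (20 × 20, 400
evaluations) used by the tests and the acceptance script. Flow maps
are memoized within a fit keyed by `(b, L_St, r)` — polls that move
only `w` or `P` reuse the incumbent's map.

Model comparison reports per-subject MSE (`distance²/28`), a paired
two-sided Wilcoxon signed-rank test, and BIC
(`n ln(RSS/n) + k ln n`, `n = 28`, `k = 4`, `RSS = distance²`) —
stated explicitly because printed aggregate BIC values cannot identify
the formula used on unavailable data.

### Identifiability at single-run scale

Parameter recovery simulates one 640-trial run per synthetic subject
and refits it. At this data volume the expected 28-vector moves along
a soft `(w, L_St, P)` ridge by less than the observation noise of a
single run (~0.05 per entry), so the minimum-distance estimator has an
information ceiling: a brute-force nearest-neighbour inversion against
a dense (24k-point) library of near-noiseless predicted statistics
reaches only ~0.4–0.7 Spearman for `w` and `L_St` on 20-subject
cohorts, with large cohort-to-cohort spread. Bias `b` fares better
(~0.65–0.85) because it controls the well asymmetry and the SFA
marginal directly. Rank recovery of `w` and `L_St` at high confidence
would require several runs per subject or informative priors; this is
a property of the design (7 delay levels, 90 pairs each), not of the
optimizer, and the pattern search attains objective values at or below
the value at the generating parameters.

## The synthetic cohort

No public dataset exists for the study design this package emulates,
so the generator is a first-class component. Defaults are the study
conditions: 10 blocks × 64 trials, 7 OFF levels linearly spaced over
[0.1, 1.2] s balanced within blocks (trial 1 of each block uniform),
10 s block gaps; two sessions per subject.

Baseline traits — sensory gain, loop strength, bias, penalty, distress
and conspiracy (GCB) score — are coupled through a Gaussian copula
(target Spearman correlations converted to latent Pearson via
`2 sin(πρ/6)`), with marginals imposed by inverse-CDF transforms:

* `w ~ 1.70 ± 0.85` (truncated ≥ 0), `L_St ~ 1.85 ± 0.91` (≥ 0),
  `b ~ 0.59 ± 0.07` (in (0,1)), `P ~ N(-2.04, 1.50)`. Truncated-normal
  parent parameters are solved numerically so the *truncated* moments
  hit the targets.
* GCB: scaled Beta on [15, 75], mean 33.8, sd 13.3 — skewed toward low
  scores, rounded to integers. Demographic gradients (age, education,
  country group means) enter as additive shifts with the base marginal
  deflated so overall moments stay on target; switchable off.
* Distress: scaled Beta on [0, 10], mean 5.35, sd 3.33. That sd
  exceeds what any truncated normal supports on [0, 10] (max ~2.9):
  the scale is polarized, hence U-shaped.
* Planted rank correlations: ρ(GCB, w) = +0.098,
  ρ(distress, GCB) = -0.094, and ρ(distress, L_St) = -0.18, the latter
  chosen once so that simulated stability (driven chiefly by loop
  strength) correlates with distress near -0.12 after the
  behavioral mapping.

Longitudinal structure: each subject is assigned a decreasing-distress
trajectory with probability 330/557 (the reported group split).
Distress moves strictly in the trajectory's direction; loop-strength
and GCB changes are drawn per group with the reported change moments
(Dec: +0.081 ± 1.11 and +1.29 ± 10.3; Inc: -0.121 ± 1.14 and
-0.305 ± 11.6) and rank correlation 0.116 within the decreasing group.
Because those published moments are *realized* moments on bounded
scales, the generator calibrates the pre-bounding draws by fixed-point
iteration until the post-bounding changes match them; the realized
Cohen's d then lands on 0.18 / 0.145 at large n. Reaction times are
lognormal (median 0.6 s, σ = 0.4); a configurable fraction of
subjects are implausibly fast (median 0.2 s, mean < 300 ms) to
exercise the quality filter.

What the generator does *not* emulate: item-level questionnaire
responses, a third session, attention-check content (only a pass/fail
flag), learning or attention drift across blocks, eye movements, and
any dependence of reaction times on the belief state. Passing tests
therefore demonstrate internal consistency of the pipeline under the
stated population model, not claims about real populations.

## Group analysis

Spearman correlations with Benjamini-Hochberg FDR within a declared
family (undefined pairs excluded from the family size); median splits
with ties to the low group; trajectory splits on the sign of the
change score with zeros excluded; Mann-Whitney, Welch t (one-sided
direction always an explicit argument), Wilcoxon signed-rank for
repeated measures, Welch ANOVA with classical η²; OLS with
treatment-coded categorical covariates, raising on rank deficiency
with the collinear columns named; Bland-Altman limits of agreement at
mean ± 1.96 SD. Cohen's d always uses the pooled SD, signed as
(first group - second group). A Shapiro-Wilk gate (α = 0.05) selects
parametric versus nonparametric defaults where no test is forced.

## Pipeline

`run_pipeline` executes simulate → exclude (mean RT < 300 ms or failed
attention flag) → summarize → fit (retained subjects only) → analyze,
writing every table as delimited text plus a manifest with the exact
configuration, derived seeds and SHA-256 content hashes; re-running a
configuration reproduces outputs byte for byte. All randomness derives
from named `SeedSequence` spawns per subject, session and stage.

## Problem sizes used by tests and the acceptance script

Structural and oracle checks run at full design size (640 trials,
1000-replicate brute-force comparisons). Persistence probabilities use
500 runs; trait-level cohort checks use n = 5000 (no response
simulation). Parameter recovery runs the desk-scale profile — 20
subjects, one run each, 20 restarts × 20 averaged runs, 400
evaluations per restart — the configuration whose identifiability
limits are discussed above. Pipeline integration tests use a reduced
task (4 blocks × 15 trials) and a 2-restart smoke profile.
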