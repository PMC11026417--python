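"""Circular-inference dynamics for bistable Necker-cube perception.

The observer's belief is the log-odds L of the "seen from above" (SFA)
interpretation against "seen from below" (SFB).  Between presentations
(OFF periods) the belief evolves autonomously,

    dL/dt = r_on (1 + e^{-L}) - r_off (1 + e^{L}) + a L + w S,

with S = 0 during OFF periods.  r_on = r b and r_off = r (1 - b) are the
switching rates of the generative model (volatility r, bias b toward SFA),
and a = L_St * r amplifies the current belief through descending loops.
For loop strength L_St < 1 the model is a leaky integrator with a single
stable state at indifference; for L_St > 1 and moderate bias it is
bistable, and the two wells of the associated energy landscape stabilize
the percept across long blank intervals.  The Bayes-optimal variant has
a = 0 (no amplification) and keeps r free.

At each presentation onset the sensory input instantaneously shifts L by
w * eps with eps ~ N(0, 1); the model reports SFA if L > 0, SFB if L < 0,
and the belief is then reset by a fixed penalty P before the next OFF
period starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernels, design
from .task import TrialSequence, make_trial_sequence

#: Belief magnitudes are capped here to keep e^{±L} finite; far beyond any
#: stable fixed point at sane parameters.
L_CAP = 12.0

#: Default fixed-step size of the RK4 integrator (seconds).
DEFAULT_DT = 1e-3

#: Flow-map grid for memoized OFF-period evolution.
FLOW_GRID_POINTS = 1201

MODEL_KINDS = ("circular", "bayes_optimal")

SFA, SFB = 1, -1
PERCEPT_LABELS = {SFA: "SFA", SFB: "SFB"}
PERCEPT_CODES = {"SFA": SFA, "SFB": SFB}


@dataclass(frozen=True)
class CIParams:
    """One subject's generative parameters.

    Parameters
    ----------
    b : float
        Bias toward the SFA configuration, in (0, 1).
    w : float
        Sensory gain (>= 0) applied to the unit-variance input impulse.
    loop_strength : float
        Prior amplification L_St = a / r (>= 0); 0 for the Bayes-optimal
        variant.
    penalty : float
        Signed log-odds shift applied to the belief after each response.
    r : float
        Mean volatility in Hz; fixed at 10 for the circular variant, free
        for the Bayes-optimal one.
    model_kind : {"circular", "bayes_optimal"}
    """

    b: float
    w: float
    loop_strength: float
    penalty: float
    r: float = design.VOLATILITY_HZ
    model_kind: str = "circular"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not (0.0 < self.b < 1.0):
            raise ValueError("bias b must lie strictly in (0, 1)")
        if self.w < 0.0:
            raise ValueError("sensory gain w must be >= 0")
        if self.loop_strength < 0.0:
            raise ValueError("loop_strength must be >= 0")
        if self.r <= 0.0:
            raise ValueError("volatility r must be > 0")
        if not np.isfinite([self.b, self.w, self.loop_strength, self.penalty, self.r]).all():
            raise ValueError("parameters must be finite")
        if self.model_kind == "bayes_optimal" and self.loop_strength != 0.0:
            raise ValueError("bayes_optimal requires loop_strength == 0")
        if self.model_kind == "circular" and self.r != design.VOLATILITY_HZ:
            raise ValueError(
                f"the circular variant fixes r at {design.VOLATILITY_HZ} Hz"
            )

    # derived rates are always recomputed, never stored
    @property
    def r_on(self) -> float:
        return self.r * self.b

    @property
    def r_off(self) -> float:
        return self.r * (1.0 - self.b)

    @property
    def a(self) -> float:
        return self.loop_strength * self.r


@dataclass(frozen=True)
class BeliefState:
    """Belief log-odds of SFA versus SFB at a time point; L > 0 favors SFA."""

    L: float
    t: float = 0.0


@dataclass(frozen=True)
class FixedPointSet:
    """Roots of the OFF-period drift, ascending, each labelled stable/unstable."""

    roots: tuple[tuple[float, bool], ...]

    @property
    def n_stable(self) -> int:
        return sum(1 for _, s in self.roots if s)

    def __len__(self) -> int:
        return len(self.roots)


def drift(L, params: CIParams, S=0.0):
    """Rate of change of the belief log-odds (1/s); vectorized in L and S."""
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(S))):
        raise ValueError("non-finite belief state or sensory input")
    out = (
        params.r_on * (1.0 + np.exp(-L))
        - params.r_off * (1.0 + np.exp(L))
        + params.a * L
        + params.w * S
    )
    return out if out.ndim else float(out)


def drift_jacobian(L, params: CIParams):
    """d(drift)/dL, used to classify fixed points."""
    L = np.asarray(L, dtype=float)
    out = -params.r_on * np.exp(-L) - params.r_off * np.exp(L) + params.a
    return out if out.ndim else float(out)


def potential(L, params: CIParams):
    """Energy landscape U(L) with dU/dL = -drift(L, S=0) and U(0) = 0.

    Minima of U are stable percept configurations; with b = 0.5 and no
    amplification U(L) = r cosh(L) - r, a single bowl centred on
    indifference.
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite belief state")
    antideriv = (
        params.r_on * (L - np.exp(-L))
        - params.r_off * (L + np.exp(L))
        + 0.5 * params.a * L**2
    )
    at_zero = -params.r_on - params.r_off
    out = -(antideriv - at_zero)
    return out if out.ndim else float(out)


def fixed_points(
    params: CIParams,
    interval: tuple[float, float] = (-L_CAP, L_CAP),
    scan_step: float = 1e-3,
    tol: float = 1e-9,
) -> FixedPointSet:
    """All roots of the OFF-period drift in `interval`.

    A dense sign-change scan brackets the roots, each refined by Brent's
    method; stability is the sign of the drift's derivative at the root.
    """
    lo, hi = interval
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("degenerate search interval")
    grid = np.arange(lo, hi + scan_step, scan_step)
    f = drift(grid, params)
    roots: list[float] = []
    exact = grid[f == 0.0]
    roots.extend(float(x) for x in exact)
    sign_change = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    for i in sign_change:
        roots.append(
            brentq(lambda x: drift(x, params), grid[i], grid[i + 1], xtol=tol)
        )
    roots = sorted(roots)
    # merge near-duplicates from exact hits adjacent to brackets
    merged: list[float] = []
    for x in roots:
        if not merged or abs(x - merged[-1]) > 10 * max(tol, scan_step * 1e-3):
            merged.append(x)
    labelled = tuple((x, bool(drift_jacobian(x, params) < 0)) for x in merged)
    return FixedPointSet(roots=labelled)


def evolve_off(L0, duration: float, params: CIParams, dt: float = DEFAULT_DT):
    """Evolve the belief through an OFF period of `duration` seconds (S = 0).

    Classical fixed-step RK4 with a shortened final step; duration 0
    returns L0 exactly.  Accepts a scalar or an array of initial log-odds.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    arr = np.atleast_1d(np.asarray(L0, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite belief state")
    if duration == 0:
        out = arr.copy()
    else:
        out = _kernels.rk4_evolve(
            arr, float(duration), dt, params.r_on, params.r_off, params.a, L_CAP
        )
    return out if np.ndim(L0) else float(out[0])


class FlowMap:
    """Memoized OFF-period evolution for the delay levels of a sequence.

    One RK4 pass over a grid of initial log-odds yields, for every delay
    level, a monotone map L_in -> L_out that simulation then interpolates
    linearly.  The OFF dynamics are autonomous and one-dimensional, so a
    single integration per grid node serves all trials.
    """

    def __init__(
        self,
        params: CIParams,
        delays: np.ndarray,
        dt: float = DEFAULT_DT,
        grid_points: int = FLOW_GRID_POINTS,
        l_cap: float = L_CAP,
    ):
        delays = np.asarray(delays, dtype=float)
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be ascending")
        self.params = params
        self.delays = delays
        self.grid = np.linspace(-l_cap, l_cap, grid_points)
        self.table = _kernels.rk4_flow_snapshots(
            self.grid, delays, dt, params.r_on, params.r_off, params.a, l_cap
        )
        self.grid_min = float(self.grid[0])
        self.inv_dgrid = (grid_points - 1) / (2 * l_cap)

    def __call__(self, L0, delay_index: int):
        """Interpolated end-of-OFF belief for initial log-odds L0."""
        return np.interp(L0, self.grid, self.table[delay_index])


def simulate_responses(
    params: CIParams,
    seq: TrialSequence,
    noise: np.ndarray,
    coins: np.ndarray,
    penalty_mode: str = "response_relative",
    block_start_l: float = 0.0,
    flow: FlowMap | None = None,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Simulate percept reports (+1 SFA / -1 SFB) for given noise draws.

    `noise` and `coins` have shape (n_runs, n_trials); passing them
    explicitly supports common-random-number fitting and the percept-swap
    symmetry (negating the noise with b = 0.5, P = 0 swaps every report).
    """
    if seq.n_trials == 0:
        raise ValueError("empty trial sequence")
    if penalty_mode not in ("additive", "response_relative"):
        raise ValueError(f"unknown penalty_mode {penalty_mode!r}")
    noise = np.ascontiguousarray(noise, dtype=float)
    coins = np.ascontiguousarray(coins, dtype=float)
    if noise.shape != coins.shape or noise.ndim != 2 or noise.shape[1] != seq.n_trials:
        raise ValueError("noise/coins must be (n_runs, n_trials) and aligned")
    if flow is None:
        flow = FlowMap(params, seq.delay_levels, dt=dt)
    return _kernels.simulate_responses(
        flow.table,
        flow.grid_min,
        flow.inv_dgrid,
        seq.level_idx,
        seq.is_block_first,
        params.w,
        params.penalty,
        penalty_mode == "response_relative",
        noise,
        coins,
        block_start_l,
        L_CAP,
    )


def draw_noise(
    seq_or_n, n_runs: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Sensory noise and tie-break coins for `n_runs` runs, one RNG stream."""
    n_trials = seq_or_n.n_trials if hasattr(seq_or_n, "n_trials") else int(seq_or_n)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_runs, n_trials))
    coins = rng.random((n_runs, n_trials))
    return noise, coins


def responses_to_table(
    responses: np.ndarray, seq: TrialSequence, rt_s: np.ndarray | None = None
) -> pd.DataFrame:
    """Format one run's reports as the delimited response-table layout."""
    responses = np.asarray(responses).ravel()
    if responses.size != seq.n_trials:
        raise ValueError("responses do not align with the sequence")
    return pd.DataFrame(
        {
            "block": seq.block_id + 1,
            "trial": np.tile(np.arange(1, seq.trials_per_block + 1), seq.n_blocks),
            "off_duration_s": seq.off_durations,
            "response": [PERCEPT_LABELS[int(r)] for r in responses],
            "rt_s": np.full(seq.n_trials, np.nan) if rt_s is None else rt_s,
        }
    )


def simulate_run(
    params: CIParams,
    seq: TrialSequence,
    seed,
    penalty_mode: str = "response_relative",
    block_start_l: float = 0.0,
    flow: FlowMap | None = None,
) -> pd.DataFrame:
    """Simulate one run and return a response table.

    Deterministic given the seed: the same seed yields a bit-identical
    table.  Columns: block (1-based), trial (1-based within block),
    off_duration_s, response in {SFA, SFB}, rt_s (NaN; reaction times are
    not part of the belief model).
    """
    noise, coins = draw_noise(seq, 1, seed)
    resp = simulate_responses(
        params, seq, noise, coins, penalty_mode=penalty_mode,
        block_start_l=block_start_l, flow=flow,
    )
    return responses_to_table(resp[0], seq)


def persistence_probability(
    params: CIParams,
    delays: Sequence[float],
    n_runs: int = 200,
    seed=0,
    seq: TrialSequence | None = None,
    penalty_mode: str = "response_relative",
    block_start_l: float = 0.0,
) -> pd.DataFrame:
    """Estimate the persistence probability PP(percept, delay).

    PP(X, d) = P(report_{t+1} = X | report_t = X, OFF duration of t+1 = d),
    pooled over `n_runs` simulated runs of a balanced sequence built on the
    given delay levels (or of `seq` if provided).  Cells with no
    conditioning events are NaN with n_pairs = 0, never 0.

    Returns a tidy frame with columns delay_s, percept, pp, n_pairs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    delays = np.sort(np.asarray(delays, dtype=float))
    if seq is None:
        n_lev = delays.size
        seq = make_trial_sequence(
            n_blocks=design.N_BLOCKS,
            trials_per_block=9 * n_lev + 1,
            delay_levels=delays,
            seed=np.random.default_rng(seed).integers(2**31),
        )
    noise, coins = draw_noise(seq, n_runs, seed)
    resp = simulate_responses(
        params, seq, noise, coins, penalty_mode=penalty_mode,
        block_start_l=block_start_l,
    )
    counts = _kernels.pair_counts(resp, seq.level_idx, seq.pair_mask, seq.n_levels)
    rows = []
    for percept, (stay, leave) in ((SFA, (0, 1)), (SFB, (3, 2))):
        n_cond = counts[stay] + counts[leave]
        with np.errstate(invalid="ignore"):
            pp = np.where(n_cond > 0, counts[stay] / np.maximum(n_cond, 1), np.nan)
        for j, d in enumerate(seq.delay_levels):
            rows.append(
                {
                    "delay_s": d,
                    "percept": PERCEPT_LABELS[percept],
                    "pp": pp[j],
                    "n_pairs": int(n_cond[j]),
                }
            )
    return pd.DataFrame(rows)
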