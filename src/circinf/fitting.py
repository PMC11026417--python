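"""Per-subject model inversion by simulation-based pattern search.

The objective is the Euclidean distance between a subject's observed
pairwise response statistics (4 ordered pairs x 7 delays = 28 conditional
frequencies) and the same statistics predicted by simulating the model on
the subject's own OFF-duration sequence, averaged over many runs.  The
sensory-noise streams of those runs are frozen per fit (common random
numbers), which makes the stochastic objective a deterministic function
of the parameters and the derivative-free search well-posed.

Free parameters: (b, w, L_St, P) for the circular model (volatility r
fixed at 10 Hz) and (b, w, r, P) for the Bayes-optimal variant (no prior
amplification, a = 0).  Each fit restarts a bound-constrained compass
pattern search from many uniform starting points and keeps the best end
point.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ci_model import CIParams, FlowMap, simulate_responses, design
from .summary_stats import PairwiseStats, counts_from_matrix, stats_from_counts
from .task import TrialSequence

#: Box bounds covering the population means +/- ~3 SD.
DEFAULT_BOUNDS = {
    "circular": {
        "b": (0.01, 0.99),
        "w": (0.0, 6.0),
        "loop_strength": (0.0, 6.0),
        "penalty": (-8.0, 8.0),
    },
    "bayes_optimal": {
        "b": (0.01, 0.99),
        "w": (0.0, 6.0),
        "r": (0.5, 50.0),
        "penalty": (-8.0, 8.0),
    },
}

FREE_PARAMS = {
    "circular": ("b", "w", "loop_strength", "penalty"),
    "bayes_optimal": ("b", "w", "r", "penalty"),
}

#: Flow-map resolution used inside fits; coarser than the public default but
#: with pairwise-frequency error well below the Monte-Carlo floor of the
#: averaged-run objective.
FIT_FLOW_DT = 5e-3
FIT_FLOW_GRID = 301

N_MEASURES = 28  # 4 ordered pairs x 7 delays


def vector_to_params(x: Sequence[float], model_kind: str) -> CIParams:
    """Free-parameter vector -> CIParams for the given model variant."""
    b, w, third, penalty = (float(v) for v in x)
    if model_kind == "circular":
        return CIParams(b=b, w=w, loop_strength=third, penalty=penalty,
                        r=design.VOLATILITY_HZ, model_kind="circular")
    return CIParams(b=b, w=w, loop_strength=0.0, penalty=penalty,
                    r=third, model_kind="bayes_optimal")


def params_to_vector(params: CIParams) -> np.ndarray:
    third = params.loop_strength if params.model_kind == "circular" else params.r
    return np.array([params.b, params.w, third, params.penalty])


def noise_from_seeds(noise_seeds: Sequence[int], n_trials: int):
    """One frozen (noise, coins) pair per run, one RNG stream per seed."""
    noise = np.empty((len(noise_seeds), n_trials))
    coins = np.empty((len(noise_seeds), n_trials))
    for i, s in enumerate(noise_seeds):
        rng = np.random.default_rng(s)
        noise[i] = rng.standard_normal(n_trials)
        coins[i] = rng.random(n_trials)
    return noise, coins


class _FlowCache:
    """LRU cache of flow maps keyed by the parameters they depend on.

    The OFF-period dynamics involve only (b, L_St, r); polling steps that
    move w or P reuse the incumbent's flow map for free.
    """

    def __init__(self, delays, dt, grid_points, maxsize=256):
        self.delays = delays
        self.dt = dt
        self.grid_points = grid_points
        self.maxsize = maxsize
        self._store: OrderedDict[tuple, FlowMap] = OrderedDict()

    def get(self, params: CIParams) -> FlowMap:
        key = (round(params.b, 12), round(params.loop_strength, 12),
               round(params.r, 12))
        hit = self._store.get(key)
        if hit is None:
            hit = FlowMap(params, self.delays, dt=self.dt,
                          grid_points=self.grid_points)
            self._store[key] = hit
            if len(self._store) > self.maxsize:
                self._store.popitem(last=False)
        else:
            self._store.move_to_end(key)
        return hit


class Objective:
    """Deterministic simulation objective with frozen noise streams."""

    def __init__(
        self,
        observed: PairwiseStats,
        seq: TrialSequence,
        n_runs: int,
        noise_seeds: Sequence[int],
        model_kind: str = "circular",
        penalty_mode: str = "response_relative",
        flow_dt: float = FIT_FLOW_DT,
        flow_grid_points: int = FIT_FLOW_GRID,
    ):
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if len(noise_seeds) != n_runs:
            raise ValueError("need exactly one noise seed per run")
        if observed.missing.all():
            raise ValueError("observed statistics have no defined delay column")
        self.observed = observed
        self.seq = seq
        self.n_runs = n_runs
        self.model_kind = model_kind
        self.penalty_mode = penalty_mode
        self.noise, self.coins = noise_from_seeds(noise_seeds, seq.n_trials)
        self._cache = _FlowCache(seq.delay_levels, flow_dt, flow_grid_points)
        self._col_n = seq.pair_level_counts.astype(float)
        self._use = ~observed.missing & (self._col_n > 0)
        self._obs_vec = observed.freqs[:, self._use].ravel()
        self.n_used = int(self._obs_vec.size)
        self.n_evals = 0

    def predicted_freqs(self, params: CIParams) -> np.ndarray:
        flow = self._cache.get(params)
        resp = simulate_responses(
            params, self.seq, self.noise, self.coins,
            penalty_mode=self.penalty_mode, flow=flow,
        )
        counts = counts_from_matrix(resp, self.seq)
        return counts / (self.n_runs * self._col_n)

    def __call__(self, x: Sequence[float]) -> float:
        params = vector_to_params(x, self.model_kind)
        pred = self.predicted_freqs(params)[:, self._use].ravel()
        self.n_evals += 1
        return float(np.linalg.norm(pred - self._obs_vec))


def objective(
    params: CIParams,
    observed: PairwiseStats,
    seq: TrialSequence,
    n_runs: int,
    noise_seeds: Sequence[int],
    **kwargs,
) -> float:
    """Euclidean distance between predicted and observed pairwise statistics.

    Simulates `n_runs` runs of the model on the subject's own OFF sequence
    with the given frozen noise seeds, averages the 4 x 7 conditional
    frequency arrays, and returns the Euclidean norm of the difference on
    the 28-vector (delay columns missing from the observation are
    excluded).  Deterministic given `noise_seeds`.
    """
    fn = Objective(observed, seq, n_runs, noise_seeds,
                   model_kind=params.model_kind, **kwargs)
    return fn(params_to_vector(params))


@dataclass
class PatternSearchResult:
    x: np.ndarray
    fun: float
    n_evals: int
    converged: bool          # mesh tolerance reached within the budget


def pattern_search(
    f: Callable[[np.ndarray], float],
    x0: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    max_evals: int = 2000,
    mesh_init: float = 0.5,
    mesh_tol: float = 1e-3,
    expansion: float = 2.0,
    contraction: float = 0.5,
) -> PatternSearchResult:
    """Bound-constrained compass (coordinate-polling) pattern search.

    Operates in box-normalized coordinates with an initial mesh of
    `mesh_init`; polls +/- mesh along each coordinate opportunistically,
    expanding the mesh on success and contracting it after a full
    unsuccessful poll, until the mesh falls below `mesh_tol` or the
    evaluation budget is exhausted.  Never evaluates outside the box and
    never accepts a worse point, so the returned value is <= f(x0).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with upper > lower")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < lo - 1e-12) or np.any(x0 > hi + 1e-12):
        raise ValueError("x0 must lie within bounds")
    span = hi - lo
    z = np.clip((x0 - lo) / span, 0.0, 1.0)
    f_best = float(f(lo + z * span))
    n_evals = 1
    mesh = mesh_init
    d = z.size
    while mesh >= mesh_tol and n_evals < max_evals:
        improved = False
        for i in range(d):
            for sign in (1.0, -1.0):
                if n_evals >= max_evals:
                    break
                z_new = z.copy()
                z_new[i] = np.clip(z[i] + sign * mesh, 0.0, 1.0)
                if z_new[i] == z[i]:
                    continue
                f_new = float(f(lo + z_new * span))
                n_evals += 1
                if f_new < f_best:
                    z, f_best = z_new, f_new
                    improved = True
                    break
            if improved:
                break
        if improved:
            mesh = min(mesh * expansion, mesh_init)
        else:
            mesh *= contraction
    return PatternSearchResult(
        x=lo + z * span, fun=f_best, n_evals=n_evals, converged=mesh < mesh_tol
    )


def bic(rss: float, n: int = N_MEASURES, k: int = 4) -> float:
    """Gaussian-residual Bayesian information criterion n ln(RSS/n) + k ln n."""
    rss = max(float(rss), 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class FitResult:
    """Best parameter set of a multi-start fit and its bookkeeping."""

    params: CIParams
    objective_value: float
    mse: float
    bic: float
    n_restarts: int
    seed: int
    restart_table: pd.DataFrame   # columns: start_*, end_*, objective, n_evals
    n_runs: int
    noise_seeds: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "model_kind": self.params.model_kind,
            "params": {k: getattr(self.params, k)
                       for k in ("b", "w", "loop_strength", "penalty", "r")},
            "objective_value": self.objective_value,
            "mse": self.mse,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "noise_seeds": list(self.noise_seeds),
        }


def fit_subject(
    observed: PairwiseStats,
    seq: TrialSequence,
    model_kind: str = "circular",
    n_restarts: int = 100,
    n_runs: int = 40,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    max_evals: int = 2000,
    mesh_tol: float = 1e-3,
    penalty_mode: str = "response_relative",
    flow_dt: float = FIT_FLOW_DT,
    flow_grid_points: int = FIT_FLOW_GRID,
) -> FitResult:
    """Fit one subject-session by repeated pattern search.

    `n_restarts` independent starts are drawn uniformly within the bounds;
    all objective evaluations of the fit share the same `n_runs` frozen
    noise streams, and the best end point over restarts is retained.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if model_kind not in FREE_PARAMS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    names = FREE_PARAMS[model_kind]
    bnds = dict(DEFAULT_BOUNDS[model_kind])
    if bounds:
        bnds.update(bounds)
    box = [bnds[k] for k in names]
    rng = np.random.default_rng(seed)
    noise_seeds = tuple(int(s) for s in rng.integers(2**31, size=n_runs))
    fn = Objective(
        observed, seq, n_runs, noise_seeds, model_kind=model_kind,
        penalty_mode=penalty_mode, flow_dt=flow_dt,
        flow_grid_points=flow_grid_points,
    )
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    starts = lo + rng.random((n_restarts, len(box))) * (hi - lo)
    rows = []
    best: PatternSearchResult | None = None
    for x0 in starts:
        res = pattern_search(fn, x0, box, max_evals=max_evals, mesh_tol=mesh_tol)
        rows.append(
            {**{f"start_{k}": v for k, v in zip(names, x0)},
             **{f"end_{k}": v for k, v in zip(names, res.x)},
             "objective": res.fun, "n_evals": res.n_evals}
        )
        if best is None or res.fun < best.fun:
            best = res
    restart_table = pd.DataFrame(rows)
    params = vector_to_params(best.x, model_kind)
    rss = best.fun**2
    return FitResult(
        params=params,
        objective_value=best.fun,
        mse=rss / fn.n_used,
        bic=bic(rss, n=fn.n_used, k=len(names)),
        n_restarts=n_restarts,
        seed=seed,
        restart_table=restart_table,
        n_runs=n_runs,
        noise_seeds=noise_seeds,
    )


@dataclass
class ModelComparison:
    """Paired per-subject comparison of circular vs Bayes-optimal fits."""

    mse_ci: np.ndarray
    mse_bayes: np.ndarray
    mean_mse_ci: float
    mean_mse_bayes: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    all_zero_differences: bool
    bic_ci: np.ndarray
    bic_bayes: np.ndarray
    mean_bic_ci: float
    mean_bic_bayes: float


def compare_models(
    fits_ci: Sequence[FitResult], fits_bayes: Sequence[FitResult]
) -> ModelComparison:
    """Group-level comparison of the two model variants on the same subjects.

    Reports per-subject MSE pairs, group means, a two-sided Wilcoxon
    signed-rank test on the paired MSE differences (flagged undefined when
    every difference is zero) and per-model BIC summaries.
    """
    if len(fits_ci) != len(fits_bayes):
        raise ValueError("fit lists must be paired and equal length")
    mse_ci = np.array([f.mse for f in fits_ci])
    mse_bayes = np.array([f.mse for f in fits_bayes])
    diffs = mse_ci - mse_bayes
    all_zero = bool(np.all(diffs == 0))
    if all_zero:
        stat, p = 0.0, float("nan")
    else:
        stat, p = stats.wilcoxon(mse_ci, mse_bayes)
    bic_ci = np.array([f.bic for f in fits_ci])
    bic_bayes = np.array([f.bic for f in fits_bayes])
    return ModelComparison(
        mse_ci=mse_ci, mse_bayes=mse_bayes,
        mean_mse_ci=float(mse_ci.mean()), mean_mse_bayes=float(mse_bayes.mean()),
        wilcoxon_statistic=float(stat), wilcoxon_p=float(p),
        all_zero_differences=all_zero,
        bic_ci=bic_ci, bic_bayes=bic_bayes,
        mean_bic_ci=float(bic_ci.mean()), mean_bic_bayes=float(bic_bayes.mean()),
    )


@dataclass
class RecoveryReport:
    """Simulate -> fit -> tabulate check of parameter identifiability."""

    true: pd.DataFrame
    recovered: pd.DataFrame
    spearman: dict[str, float]
    rmse: dict[str, float]
    settings: dict

    def __post_init__(self) -> None:
        assert len(self.true) == len(self.recovered)


def parameter_recovery(
    true_cohort: Sequence[CIParams],
    seq: TrialSequence,
    n_restarts: int = 20,
    n_runs: int = 20,
    seed: int = 0,
    max_evals: int = 2000,
    mesh_tol: float = 1e-3,
    penalty_mode: str = "response_relative",
) -> RecoveryReport:
    """Simulate one run per subject from known parameters, refit, tabulate.

    Returns per-parameter Spearman rank correlations between true and
    recovered values, and RMSEs.
    """
    if len(true_cohort) < 2:
        raise ValueError("need at least 2 subjects")
    kinds = {p.model_kind for p in true_cohort}
    if len(kinds) != 1:
        raise ValueError("true cohort mixes model kinds")
    model_kind = kinds.pop()
    names = FREE_PARAMS[model_kind]
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 * len(true_cohort))
    true_rows, rec_rows = [], []
    for i, params in enumerate(true_cohort):
        data_rng = np.random.default_rng(child[2 * i])
        noise = data_rng.standard_normal((1, seq.n_trials))
        coins = data_rng.random((1, seq.n_trials))
        resp = simulate_responses(params, seq, noise, coins,
                                  penalty_mode=penalty_mode)
        observed = stats_from_counts(counts_from_matrix(resp, seq),
                                     seq.delay_levels)
        fit = fit_subject(
            observed, seq, model_kind=model_kind, n_restarts=n_restarts,
            n_runs=n_runs,
            seed=int(np.random.default_rng(child[2 * i + 1]).integers(2**31)),
            max_evals=max_evals, mesh_tol=mesh_tol, penalty_mode=penalty_mode,
        )
        vec_t = params_to_vector(params)
        vec_r = params_to_vector(fit.params)
        true_rows.append(dict(zip(names, vec_t)))
        rec_rows.append(dict(zip(names, vec_r)))
    true_df = pd.DataFrame(true_rows)
    rec_df = pd.DataFrame(rec_rows)
    spearman = {
        k: float(stats.spearmanr(true_df[k], rec_df[k]).statistic) for k in names
    }
    rmse = {
        k: float(np.sqrt(np.mean((true_df[k] - rec_df[k]) ** 2))) for k in names
    }
    return RecoveryReport(
        true=true_df, recovered=rec_df, spearman=spearman, rmse=rmse,
        settings={
            "n_restarts": n_restarts, "n_runs": n_runs, "seed": seed,
            "max_evals": max_evals, "mesh_tol": mesh_tol,
            "model_kind": model_kind, "n_subjects": len(true_cohort),
        },
    )
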