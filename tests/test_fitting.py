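"""Pattern search, the simulation objective, per-subject fits and model
comparison."""

import numpy as np
import pandas as pd
import pytest

from circinf.ci_model import CIParams, FlowMap, simulate_responses
from circinf.fitting import (
    FIT_FLOW_DT,
    FIT_FLOW_GRID,
    Objective,
    bic,
    compare_models,
    fit_subject,
    noise_from_seeds,
    objective,
    params_to_vector,
    parameter_recovery,
    pattern_search,
    vector_to_params,
)
from circinf.summary_stats import counts_from_matrix, stats_from_counts


def observed_from(params, seq, seeds, penalty_mode="response_relative"):
    """Observed statistics generated through the fitting flow profile, so an
    objective sharing `seeds` sees exactly zero self-distance."""
    noise, coins = noise_from_seeds(seeds, seq.n_trials)
    flow = FlowMap(params, seq.delay_levels, dt=FIT_FLOW_DT,
                   grid_points=FIT_FLOW_GRID)
    resp = simulate_responses(params, seq, noise, coins, flow=flow,
                              penalty_mode=penalty_mode)
    return stats_from_counts(counts_from_matrix(resp, seq), seq.delay_levels)


class TestPatternSearch:
    def test_convex_quadratic_reaches_center(self):
        c = np.array([0.3, -0.2, 0.7])
        res = pattern_search(lambda x: float(((x - c) ** 2).sum()),
                             [0.9, 0.9, -0.9],
                             [(-1, 1)] * 3, mesh_tol=1e-4)
        assert np.allclose(res.x, c, atol=1e-3)

    def test_rosenbrock_smoke(self):
        f = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
        res = pattern_search(f, [-1.2, 1.0], [(-2, 2), (-2, 2)],
                             max_evals=5000)
        assert res.fun < 1e-2

    def test_never_worse_than_start_and_monotone(self):
        history = []

        def f(x):
            v = float((x**2).sum())
            history.append(v)
            return v

        res = pattern_search(f, [0.8, -0.6], [(-1, 1), (-1, 1)],
                             max_evals=200)
        assert res.fun <= history[0]
        best_so_far = np.minimum.accumulate(history)
        assert (np.diff(best_so_far) <= 0).all()

    def test_stays_within_bounds(self):
        seen = []

        def f(x):
            seen.append(x.copy())
            return float(-x.sum())  # pushes toward the upper corner

        res = pattern_search(f, [0.0, 0.0], [(-1, 2), (-1, 3)])
        seen = np.array(seen)
        assert (seen[:, 0] >= -1).all() and (seen[:, 0] <= 2).all()
        assert (seen[:, 1] >= -1).all() and (seen[:, 1] <= 3).all()
        assert np.allclose(res.x, [2, 3])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pattern_search(lambda x: 0.0, [0.0], [(1.0, 1.0)])
        with pytest.raises(ValueError):
            pattern_search(lambda x: 0.0, [5.0], [(0.0, 1.0)])


class TestObjective:
    def test_self_distance_zero(self, small_seq, mean_params):
        seeds = list(range(5))
        obs = observed_from(mean_params, small_seq, seeds)
        assert objective(mean_params, obs, small_seq, 5, seeds) == 0.0

    def test_deterministic_given_seeds(self, small_seq, mean_params):
        seeds = list(range(7, 12))
        obs = observed_from(mean_params, small_seq, seeds)
        fn = Objective(obs, small_seq, 5, seeds)
        x = params_to_vector(
            CIParams(b=0.45, w=1.0, loop_strength=1.2, penalty=-1.0))
        assert fn(x) == fn(x)

    def test_distance_bounded_for_frequency_tables(self, small_seq,
                                                   mean_params):
        seeds = list(range(5))
        obs = observed_from(mean_params, small_seq, seeds)
        fn = Objective(obs, small_seq, 5, seeds)
        far = params_to_vector(
            CIParams(b=0.98, w=6.0, loop_strength=6.0, penalty=8.0))
        # each delay column of each table lies on the probability simplex
        assert fn(far) <= np.sqrt(2 * 28)

    def test_seed_count_must_match_runs(self, small_seq, mean_params):
        obs = observed_from(mean_params, small_seq, list(range(5)))
        with pytest.raises(ValueError):
            Objective(obs, small_seq, 4, list(range(5)))


class TestFitSubject:
    def test_restart_bookkeeping(self, small_seq, mean_params):
        obs = observed_from(mean_params, small_seq, list(range(5)))
        fit = fit_subject(obs, small_seq, n_restarts=3, n_runs=5, seed=1,
                          max_evals=60)
        assert len(fit.restart_table) == 3
        assert fit.objective_value == fit.restart_table["objective"].min()
        assert fit.mse == pytest.approx(fit.objective_value**2 / 28)
        p = fit.params
        assert 0.01 <= p.b <= 0.99 and 0 <= p.w <= 6
        assert 0 <= p.loop_strength <= 6 and -8 <= p.penalty <= 8

    def test_invalid_restart_count(self, small_seq, mean_params):
        obs = observed_from(mean_params, small_seq, list(range(5)))
        with pytest.raises(ValueError):
            fit_subject(obs, small_seq, n_restarts=0)

    def test_all_sfa_responder_hits_stabilizing_regime(self, small_seq):
        locked = CIParams(b=0.95, w=0.05, loop_strength=4.0, penalty=2.0)
        obs = observed_from(locked, small_seq, list(range(5)))
        fit = fit_subject(obs, small_seq, n_restarts=5, n_runs=5, seed=3,
                          max_evals=150)
        # perfect persistence is matched nearly exactly
        assert fit.objective_value < 0.2
        assert fit.params.b > 0.5 or fit.params.loop_strength > 1.0

    def test_bayes_variant_frees_volatility(self, small_seq):
        gen = CIParams(b=0.6, w=1.5, loop_strength=0.0, penalty=-1.0, r=6.0,
                       model_kind="bayes_optimal")
        obs = observed_from(gen, small_seq, list(range(5)))
        fit = fit_subject(obs, small_seq, model_kind="bayes_optimal",
                          n_restarts=3, n_runs=5, seed=2, max_evals=60)
        assert fit.params.model_kind == "bayes_optimal"
        assert fit.params.loop_strength == 0.0
        assert 0.5 <= fit.params.r <= 50


class TestModelComparison:
    def _fits(self, small_seq, kind, seed):
        gen = CIParams(b=0.55, w=1.2, loop_strength=2.5, penalty=-1.5)
        obs = observed_from(gen, small_seq, [seed, seed + 1])
        return fit_subject(obs, small_seq, model_kind=kind, n_restarts=2,
                           n_runs=2, seed=seed, max_evals=40)

    def test_identical_lists_flagged(self, small_seq):
        fits = [self._fits(small_seq, "circular", s) for s in (1, 2)]
        cmp = compare_models(fits, fits)
        assert cmp.mean_mse_ci == cmp.mean_mse_bayes
        assert cmp.all_zero_differences
        assert np.isnan(cmp.wilcoxon_p)

    def test_length_mismatch_rejected(self, small_seq):
        fits = [self._fits(small_seq, "circular", 1)]
        with pytest.raises(ValueError):
            compare_models(fits, fits * 2)

    def test_bic_penalizes_extra_parameters(self):
        assert bic(0.5, n=28, k=5) > bic(0.5, n=28, k=4)

    def test_circular_data_favors_circular_model(self, default_seq):
        """Subjects generated from a strongly bistable circular model are fit
        better by the circular variant than by the Bayes-optimal one."""
        rng = np.random.default_rng(42)
        fits_ci, fits_bayes = [], []
        for i in range(4):
            gen = CIParams(b=float(rng.uniform(0.45, 0.7)), w=2.0,
                           loop_strength=3.0, penalty=0.0)
            noise, coins = noise_from_seeds([int(rng.integers(2**31))],
                                            default_seq.n_trials)
            resp = simulate_responses(gen, default_seq, noise, coins)
            obs = stats_from_counts(counts_from_matrix(resp, default_seq),
                                    default_seq.delay_levels)
            common = dict(n_restarts=6, n_runs=10, max_evals=200,
                          seed=100 + i)
            fits_ci.append(fit_subject(obs, default_seq,
                                       model_kind="circular", **common))
            fits_bayes.append(fit_subject(obs, default_seq,
                                          model_kind="bayes_optimal",
                                          **common))
        cmp = compare_models(fits_ci, fits_bayes)
        assert cmp.mean_mse_ci < cmp.mean_mse_bayes


class TestParameterRecovery:
    def test_report_shapes_and_ranges(self, small_seq):
        cohort = [
            CIParams(b=0.55, w=1.0, loop_strength=1.5, penalty=-1.0),
            CIParams(b=0.65, w=2.0, loop_strength=2.5, penalty=-3.0),
            CIParams(b=0.45, w=0.5, loop_strength=0.5, penalty=0.5),
        ]
        rep = parameter_recovery(cohort, small_seq, n_restarts=2, n_runs=3,
                                 seed=0, max_evals=40)
        assert len(rep.true) == len(rep.recovered) == 3
        for v in rep.spearman.values():
            assert np.isnan(v) or -1 <= v <= 1
        assert set(rep.rmse) == {"b", "w", "loop_strength", "penalty"}

    def test_requires_two_subjects(self, small_seq):
        with pytest.raises(ValueError):
            parameter_recovery(
                [CIParams(b=0.5, w=1, loop_strength=1, penalty=0)], small_seq)

    def test_rejects_mixed_model_kinds(self, small_seq):
        cohort = [
            CIParams(b=0.5, w=1, loop_strength=1, penalty=0),
            CIParams(b=0.5, w=1, loop_strength=0, penalty=0, r=5,
                     model_kind="bayes_optimal"),
        ]
        with pytest.raises(ValueError):
            parameter_recovery(cohort, small_seq)
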