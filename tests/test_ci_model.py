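"""Core dynamics: drift, energy landscape, fixed points, OFF evolution,
and trial-by-trial simulation."""

import math

import numpy as np
import pytest

from circinf import design
from circinf.ci_model import (
    CIParams,
    FlowMap,
    draw_noise,
    drift,
    evolve_off,
    fixed_points,
    persistence_probability,
    potential,
    simulate_responses,
    simulate_run,
)
from circinf.task import make_trial_sequence


def P(b=0.5, w=0.0, loop=0.0, pen=0.0, **kw):
    return CIParams(b=b, w=w, loop_strength=loop, penalty=pen, **kw)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"b": 0.0},
            {"b": 1.0},
            {"w": -0.1},
            {"loop": -1.0},
            {"pen": float("nan")},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            P(**kwargs)

    def test_derived_rates(self):
        p = P(b=0.59, loop=1.85)
        assert p.r_on == pytest.approx(5.9)
        assert p.r_off == pytest.approx(4.1)
        assert p.a == pytest.approx(18.5)

    def test_bayes_variant_constraints(self):
        with pytest.raises(ValueError):
            CIParams(b=0.5, w=1, loop_strength=1, penalty=0,
                     model_kind="bayes_optimal")
        p = CIParams(b=0.5, w=1, loop_strength=0, penalty=0, r=3.0,
                     model_kind="bayes_optimal")
        assert p.a == 0.0

    def test_circular_volatility_fixed(self):
        with pytest.raises(ValueError):
            CIParams(b=0.5, w=1, loop_strength=1, penalty=0, r=5.0)


class TestDrift:
    def test_symmetric_equilibrium(self):
        assert drift(0.0, P()) == 0.0

    def test_bias_drives_drift_at_origin(self):
        # 2r(2b - 1) at L = 0
        assert drift(0.0, P(b=0.59)) == pytest.approx(3.6)

    def test_reduces_to_minus_r_sinh(self):
        p = P()
        for L in (-2.0, -1.0, 1.0, 2.0):
            assert drift(L, p) == pytest.approx(-10 * math.sinh(L), rel=1e-12)
        assert drift(1.0, p) == pytest.approx(-11.752011936, rel=1e-8)

    def test_odd_symmetry_without_bias(self):
        p = P(loop=1.7)
        L = np.linspace(-4, 4, 41)
        np.testing.assert_allclose(drift(-L, p), -drift(L, p), atol=1e-12)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            drift(float("inf"), P())
        with pytest.raises(ValueError):
            drift(0.0, P(), S=float("nan"))


class TestPotential:
    def test_normalized_at_origin(self):
        assert potential(0.0, P(b=0.7, loop=2.0, pen=1.0)) == 0.0

    def test_symmetric_leak_is_cosh_bowl(self):
        p = P()
        L = np.linspace(-3, 3, 61)
        np.testing.assert_allclose(
            potential(L, p), 10 * np.cosh(L) - 10, rtol=1e-12
        )

    def test_gradient_is_minus_drift(self):
        p = P(b=0.62, loop=1.4, pen=0.0)
        L = np.linspace(-3, 3, 2001)
        num_grad = np.gradient(potential(L, p), L)
        np.testing.assert_allclose(num_grad[5:-5], -drift(L, p)[5:-5],
                                   atol=5e-3)

    def test_double_well_minima_positions(self):
        # sinh(L)/L = 2 has roots at +/- 2.177
        p = P(loop=2.0)
        L = np.linspace(-6, 6, 120001)
        U = potential(L, p)
        interior = (np.diff(np.sign(np.diff(U))) > 0).nonzero()[0] + 1
        assert len(interior) == 2
        np.testing.assert_allclose(sorted(L[interior]), [-2.177, 2.177],
                                   atol=1e-3)

    def test_single_minimum_below_critical_loop(self):
        for loop in (0.0, 0.5, 0.95):
            L = np.linspace(-6, 6, 12001)
            U = potential(L, P(loop=loop))
            interior = (np.diff(np.sign(np.diff(U))) > 0).nonzero()[0]
            assert len(interior) == 1


class TestFixedPoints:
    def test_subcritical_single_stable_root(self):
        fps = fixed_points(P(loop=0.9))
        assert len(fps) == 1
        root, stable = fps.roots[0]
        assert abs(root) < 1e-6 and stable

    def test_supercritical_three_roots_alternating(self):
        fps = fixed_points(P(loop=1.1))
        assert len(fps) == 3
        roots = [r for r, _ in fps.roots]
        stables = [s for _, s in fps.roots]
        assert roots[0] < 0 < roots[2]
        assert roots[0] == pytest.approx(-roots[2], abs=1e-8)
        assert stables == [True, False, True]

    def test_strong_bias_keeps_only_sfa(self):
        fps = fixed_points(CIParams(b=0.9, w=0, loop_strength=1.05, penalty=0))
        assert len(fps) == 1
        root, stable = fps.roots[0]
        assert root > 0 and stable

    @pytest.mark.parametrize("loop,n_roots", [(0.95, 1), (1.05, 3)])
    def test_pitchfork_at_unit_loop_strength(self, loop, n_roots):
        assert len(fixed_points(P(loop=loop))) == n_roots

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            fixed_points(P(), interval=(1.0, 1.0))


class TestEvolveOff:
    def test_zero_duration_identity(self, symmetric_leaky):
        assert evolve_off(1.2345, 0.0, symmetric_leaky) == 1.2345

    def test_negative_duration_rejected(self, symmetric_leaky):
        with pytest.raises(ValueError):
            evolve_off(1.0, -0.1, symmetric_leaky)

    def test_closed_form_decay_grid(self, symmetric_leaky):
        # tanh(L(t)/2) = tanh(L0/2) exp(-r t)
        r = symmetric_leaky.r
        for L0 in np.arange(-3.0, 3.5, 0.5):
            for t in (0.05, 0.1, 0.2, 0.4, 0.6, 0.9, 1.2):
                got = evolve_off(L0, t, symmetric_leaky)
                want = 2 * math.atanh(math.tanh(L0 / 2) * math.exp(-r * t))
                assert abs(got - want) < 1e-6

    def test_long_evolution_reaches_stable_fixed_point(self, bistable_params):
        target = max(r for r, s in fixed_points(bistable_params).roots if s)
        assert evolve_off(2.0, 5.0, bistable_params) == pytest.approx(
            target, abs=1e-3
        )

    def test_array_input(self, symmetric_leaky):
        out = evolve_off(np.array([-1.0, 0.0, 1.0]), 0.3, symmetric_leaky)
        assert out.shape == (3,)
        assert out[1] == 0.0
        assert out[0] == pytest.approx(-out[2])


class TestFlowMap:
    def test_matches_direct_integration(self, mean_params, default_seq):
        fm = FlowMap(mean_params, default_seq.delay_levels)
        for j, d in enumerate(default_seq.delay_levels):
            for L0 in (-5.0, -1.0, -0.3, 0.4, 2.0, 6.0):
                direct = evolve_off(L0, d, mean_params)
                assert fm(L0, j) == pytest.approx(direct, abs=2e-3)

    def test_maps_monotone_in_initial_state(self, mean_params, default_seq):
        fm = FlowMap(mean_params, default_seq.delay_levels)
        assert (np.diff(fm.table, axis=1) >= -1e-9).all()


class TestSimulateRun:
    def test_empty_sequence_rejected(self, mean_params, default_seq):
        noise, coins = draw_noise(default_seq, 1, 0)
        with pytest.raises(ValueError):
            simulate_responses(mean_params, default_seq, noise[:, :10], coins,
                               penalty_mode="additive")

    def test_bit_reproducible(self, mean_params, default_seq):
        t1 = simulate_run(mean_params, default_seq, seed=99)
        t2 = simulate_run(mean_params, default_seq, seed=99)
        assert t1.equals(t2)

    def test_attractor_locks_block_without_noise(self, default_seq):
        p = P(loop=3.0)
        table = simulate_run(p, default_seq, seed=0, block_start_l=0.1)
        assert (table["response"] == "SFA").all()

    def test_degenerate_coin_flips_near_half(self, default_seq):
        # w = 0, L_St = 0, block-start 0: every trial decided by the tie rule
        p = P()
        noise, coins = draw_noise(default_seq, 50, 123)
        resp = simulate_responses(p, default_seq, noise * 0.0, coins)
        frac = (resp == 1).mean()
        assert abs(frac - 0.5) < 0.01

    def test_noise_negation_swaps_percepts(self, default_seq):
        # with b = 0.5 and P = 0 the model is SFA/SFB symmetric
        p = P(w=1.5, loop=2.0)
        noise, coins = draw_noise(default_seq, 3, 7)
        a = simulate_responses(p, default_seq, noise, coins)
        b = simulate_responses(p, default_seq, -noise, 1 - coins)
        np.testing.assert_array_equal(a, -b)

    def test_mean_stability_near_cohort_value(self, mean_params, default_seq):
        # population-mean parameters, 40 runs: overall stability in a
        # plausible band around the cohort mean 0.57
        noise, coins = draw_noise(default_seq, 40, 11)
        resp = simulate_responses(mean_params, default_seq, noise, coins)
        same = (resp[:, :-1] == resp[:, 1:])[:, default_seq.pair_mask]
        assert abs(same.mean() - 0.57) < 0.15

    def test_response_relative_penalty_destabilizes(self, default_seq):
        p = CIParams(b=0.59, w=0.5, loop_strength=2.5, penalty=-3.0)
        noise, coins = draw_noise(default_seq, 20, 5)
        additive = simulate_responses(p, default_seq, noise, coins,
                                      penalty_mode="additive")
        relative = simulate_responses(p, default_seq, noise, coins,
                                      penalty_mode="response_relative")
        # the response-relative mode pushes against whichever percept was
        # just reported, so it cannot lock into the penalty's direction
        assert abs((relative == 1).mean() - 0.5) < abs(
            (additive == 1).mean() - 0.5
        ) + 0.2


class TestPersistenceProbability:
    def test_locked_attractor_gives_unit_pp(self):
        p = P(loop=3.0)
        delays = design.default_delay_levels()
        pp = persistence_probability(p, delays, n_runs=5, seed=0,
                                     block_start_l=0.1)
        sfa = pp[pp.percept == "SFA"]
        assert (sfa["pp"] == 1.0).all()
        sfb = pp[pp.percept == "SFB"]
        assert sfb["n_pairs"].sum() == 0
        assert sfb["pp"].isna().all()

    def test_bayes_pp_decays_toward_half(self):
        p = CIParams(b=0.5, w=2.0, loop_strength=0.0, penalty=0.0, r=10.0,
                     model_kind="bayes_optimal")
        delays = design.default_delay_levels()
        pp = persistence_probability(p, delays, n_runs=300, seed=1)
        sfa = pp[pp.percept == "SFA"].sort_values("delay_s")["pp"].to_numpy()
        assert sfa[0] > sfa[-1]
        assert abs(sfa[-1] - 0.5) < 0.05

    def test_circular_pp_exceeds_bayes_at_long_delay(self):
        delays = design.default_delay_levels()
        ci = persistence_probability(
            P(loop=3.0, w=2.0), delays, n_runs=300, seed=2)
        bayes = persistence_probability(
            CIParams(b=0.5, w=2.0, loop_strength=0.0, penalty=0.0, r=10.0,
                     model_kind="bayes_optimal"),
            delays, n_runs=300, seed=2)
        d_max = delays[-1]
        pp_ci = ci[(ci.percept == "SFA") & (ci.delay_s == d_max)]["pp"].iloc[0]
        pp_b = bayes[(bayes.percept == "SFA")
                     & (bayes.delay_s == d_max)]["pp"].iloc[0]
        assert pp_ci > pp_b

    def test_estimates_within_unit_interval(self, mean_params):
        pp = persistence_probability(mean_params,
                                     design.default_delay_levels(),
                                     n_runs=20, seed=3)
        vals = pp["pp"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_bayes_pp_matches_markov_chain_oracle(self):
        """Stationary PP of the symmetric Bayes-optimal model against a
        brute-force numerical propagation of the belief distribution."""
        w, r = 2.0, 10.0
        p = CIParams(b=0.5, w=w, loop_strength=0.0, penalty=0.0, r=r,
                     model_kind="bayes_optimal")
        from scipy.stats import norm

        for d in (0.1, 0.65, 1.2):
            # single-delay sequence; long blocks, stationary regime
            seq = make_trial_sequence(n_blocks=4, trials_per_block=201,
                                      delay_levels=np.array([d]), seed=0)
            n_runs = 400
            pp = persistence_probability(p, [d], n_runs=n_runs, seed=4,
                                         seq=seq)
            est = pp[pp.percept == "SFA"]["pp"].iloc[0]
            n_pairs = pp[pp.percept == "SFA"]["n_pairs"].iloc[0]

            # oracle: discretized belief distribution, exact decay map
            grid = np.linspace(-12, 12, 1601)
            decay = 2 * np.arctanh(np.tanh(grid / 2) * np.exp(-r * d))
            dens = norm.pdf(grid, 0, w)  # after the first impulse
            dens /= dens.sum()
            for _ in range(300):
                new = norm.pdf(grid[:, None] - decay[None, :], 0, w) @ dens
                dens = new / new.sum()
            stay = norm.sf(-decay / w)  # P(next L > 0 | current L)
            pos = grid > 0
            pp_oracle = float((dens[pos] * stay[pos]).sum() / dens[pos].sum())
            mc_se = math.sqrt(pp_oracle * (1 - pp_oracle) / n_pairs)
            assert abs(est - pp_oracle) < 3 * mc_se + 1e-3
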