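"""Synthetic longitudinal cohort emulating the study's data model.

No public dataset accompanies the study this package models, so every
downstream stage is exercised on generated data whose structure mirrors
what was actually measured: per-subject circular-inference parameters
with the published population moments, conspiracy-belief (GCB) and
political-distress scores with the published marginals and rank
correlations, demographic gradients, a two-session design in which
distress trajectories (decreasing vs increasing) carry small planted
effects on prior amplification and conspiracy scores, and simulated
Necker-cube response tables for every subject and session.

Latent traits are coupled through a Gaussian copula: target Spearman
correlations are converted to Pearson correlations of latent normals via
rho_P = 2 sin(pi rho_S / 6), and marginals are imposed by inverse-CDF
transforms, which controls rank correlations exactly regardless of the
marginal shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import design
from .ci_model import CIParams, FlowMap, draw_noise, responses_to_table, simulate_responses
from .task import TrialSequence, make_trial_sequence

COUNTRIES = ("US", "UK", "FR")
#: ISCED attainment levels and sampling weights (mean ~ 5.6, sd ~ 1.4).
ISCED_LEVELS = np.arange(2, 9)
ISCED_WEIGHTS = np.array([0.02, 0.06, 0.10, 0.20, 0.30, 0.22, 0.10])


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the study conditions."""

    # task
    n_blocks: int = design.N_BLOCKS
    trials_per_block: int = design.TRIALS_PER_BLOCK
    delay_levels: tuple[float, ...] = tuple(design.default_delay_levels())
    # baseline marginals: (mean, sd) per trait
    moments: dict = field(default_factory=lambda: dict(design.T1_MOMENTS))
    rank_correlations: dict = field(
        default_factory=lambda: dict(design.T1_RANK_CORRELATIONS)
    )
    # longitudinal structure
    dec_fraction: float = design.DEC_FRACTION
    delta_moments: dict = field(default_factory=lambda: dict(design.DELTA_MOMENTS))
    dec_delta_rank_correlation: float = design.DEC_DELTA_RANK_CORRELATION
    # demographic gradients on the conspiracy score
    gcb_gradients: bool = True
    # reaction times
    rt_median_s: float = 0.6
    rt_sigma: float = 0.4
    fast_responder_fraction: float = 0.0
    fast_rt_median_s: float = 0.2
    penalty_mode: str = "response_relative"

    def to_json(self) -> str:
        d = asdict(self)
        d["rank_correlations"] = {"|".join(k): v
                                  for k, v in d["rank_correlations"].items()}
        return json.dumps(d, sort_keys=True, indent=1)


def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    requested mean and sd; solved numerically, since truncation shifts both."""

    def moments(x):
        mu, log_sig = x
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        d = stats.truncnorm(a, b, loc=mu, scale=sig)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.fsolve(moments, [mean, np.log(sd)], full_output=True)
    x, _, ok, _ = sol
    if ok != 1:
        raise RuntimeError(f"truncated-normal moment matching failed for "
                           f"mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(x[0]), float(np.exp(x[1]))


def _truncnorm_dist(mean, sd, lo, hi):
    mu, sig = _truncnorm_parent(mean, sd, lo, hi)
    return stats.truncnorm((lo - mu) / sig, (hi - mu) / sig, loc=mu, scale=sig)


def _beta_on_range(mean: float, sd: float, lo: float, hi: float):
    """Beta distribution rescaled to [lo, hi] with the requested moments."""
    span = hi - lo
    m = (mean - lo) / span
    v = (sd / span) ** 2
    if not 0 < m < 1 or v >= m * (1 - m):
        raise ValueError("infeasible beta moments")
    nu = m * (1 - m) / v - 1
    return stats.beta(m * nu, (1 - m) * nu, loc=lo, scale=span)


def spearman_to_pearson(rho_s: float) -> float:
    """Latent-normal Pearson correlation reproducing a Spearman target."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


#: Order of copula-coupled baseline traits.
_COPULA_VARS = ("w", "loop_strength", "b", "penalty", "distress", "gcb")


def _copula_matrix(rank_correlations: dict) -> np.ndarray:
    k = len(_COPULA_VARS)
    corr = np.eye(k)
    pos = {v: i for i, v in enumerate(_COPULA_VARS)}
    for (a, b), rho in rank_correlations.items():
        if a not in pos or b not in pos:
            raise KeyError(f"unknown trait pair ({a}, {b})")
        corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = spearman_to_pearson(rho)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 0:
        # name the most implicated pair for the error message
        worst = max(rank_correlations.items(), key=lambda kv: abs(kv[1]))
        raise ValueError(
            f"correlation matrix not positive definite (min eigenvalue "
            f"{eigvals.min():.3g}); offending pair likely {worst[0]}"
        )
    return corr


def sample_cohort_traits(
    n: int, config: CohortConfig | None = None, seed=0
) -> pd.DataFrame:
    """Draw baseline (T1) subject records without responses.

    Latent traits (sensory gain w, loop strength, bias, penalty, distress,
    GCB) are coupled by the Gaussian copula with the configured rank
    correlations and given their marginal shapes by inverse-CDF transforms:
    truncated normals for the bounded parameters and a low-score-skewed
    scaled Beta for the GCB total.  Demographics are sampled independently;
    when `gcb_gradients` is on, age/education/country group shifts are
    added to the conspiracy score (and the base marginal is deflated so the
    overall moments stay on target).
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    mom = cfg.moments

    # demographics
    country = rng.choice(COUNTRIES, size=n)
    sex = rng.choice(["F", "M"], size=n)
    age = rng.integers(design.AGE_RANGE[0], design.AGE_RANGE[1] + 1, size=n)
    education = rng.choice(ISCED_LEVELS, size=n,
                           p=ISCED_WEIGHTS / ISCED_WEIGHTS.sum())

    gcb_mean, gcb_sd = mom["gcb"]
    shifts = np.zeros(n)
    if cfg.gcb_gradients:
        for (lo, hi), grp_mean in design.GCB_BY_AGE:
            shifts[(age >= lo) & (age <= hi)] += grp_mean - gcb_mean
        for (lo, hi), grp_mean in design.GCB_BY_EDUCATION:
            shifts[(education >= lo) & (education <= hi)] += grp_mean - gcb_mean
        for c, grp_mean in design.GCB_BY_COUNTRY.items():
            shifts[country == c] += grp_mean - gcb_mean
        base_mean = gcb_mean - shifts.mean()
        base_var = gcb_sd**2 - shifts.var()
        if base_var <= 0:
            raise ValueError("GCB gradients exceed the target variance")
        base_sd = np.sqrt(base_var)
    else:
        base_mean, base_sd = gcb_mean, gcb_sd

    marginals = {
        "w": _truncnorm_dist(*mom["w"], 0.0, np.inf),
        "loop_strength": _truncnorm_dist(*mom["loop_strength"], 0.0, np.inf),
        "b": _truncnorm_dist(*mom["b"], 1e-6, 1 - 1e-6),
        "penalty": stats.norm(*mom["penalty"]),
        # the distress sd exceeds what a truncated normal can carry on
        # [0, 10]; a scaled Beta (U-shaped here) matches the polarized scale
        "distress": _beta_on_range(*mom["distress"], *design.DISTRESS_RANGE),
        "gcb": _beta_on_range(base_mean, base_sd, *design.GCB_RANGE),
    }

    corr = _copula_matrix(cfg.rank_correlations)
    z = rng.multivariate_normal(np.zeros(len(_COPULA_VARS)), corr, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)
    draws = {v: marginals[v].ppf(u[:, i]) for i, v in enumerate(_COPULA_VARS)}

    gcb = np.clip(np.round(draws["gcb"] + shifts), *design.GCB_RANGE)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "country": country,
            "sex": sex,
            "age": age,
            "education": education,
            "w_t1": draws["w"],
            "loop_strength_t1": draws["loop_strength"],
            "b_t1": draws["b"],
            "penalty_t1": draws["penalty"],
            "distress_t1": draws["distress"],
            "gcb_t1": gcb,
        }
    )


def _calibrated_bounded_delta(
    t1: np.ndarray, z: np.ndarray, mean: float, sd: float,
    lo: float, hi: float, n_iter: int = 25,
) -> np.ndarray:
    """T2 - T1 changes with the requested *realized* moments on [lo, hi].

    The reported change moments were measured on bounded scales, so a raw
    normal draw that is afterwards clamped to the scale would come out
    attenuated.  Given standard-normal draws `z`, the affine map
    mu + sigma z is re-calibrated by fixed-point iteration until the
    post-clamping changes have the requested mean and sd.
    """
    mu, sig = mean, sd
    for _ in range(n_iter):
        t2 = np.clip(t1 + mu + sig * z, lo, hi)
        delta = t2 - t1
        got_sd = delta.std()
        if got_sd <= 0:
            break
        mu += mean - delta.mean()
        sig *= np.clip(sd / got_sd, 0.5, 2.0)
    return np.clip(t1 + mu + sig * z, lo, hi) - t1


def apply_longitudinal_effects(
    traits: pd.DataFrame, config: CohortConfig | None = None, seed=0
) -> pd.DataFrame:
    """Assign stress trajectories and draw session-2 traits.

    Each subject is assigned a decreasing- or increasing-distress
    trajectory (probability `dec_fraction` of decreasing).  Distress,
    loop-strength and GCB changes are drawn per group from the configured
    delta moments; within the decreasing group the loop-strength and GCB
    changes share the configured rank correlation (Gaussian copula on the
    two deltas).  T2 values stay within their valid ranges, and the
    change draws are calibrated so the realized (post-bounding) change
    moments match the configured ones.  Parameters without planted changes
    (w, b, penalty) carry over.
    """
    cfg = config or CohortConfig()
    need = {"distress_t1", "loop_strength_t1", "gcb_t1"}
    if not need.issubset(traits.columns):
        raise ValueError("traits table lacks T1 columns")
    out = traits.copy()
    n = len(out)
    rng = np.random.default_rng(seed)
    dec = rng.random(n) < cfg.dec_fraction
    rho = spearman_to_pearson(cfg.dec_delta_rank_correlation)

    d_loop = np.empty(n)
    d_gcb = np.empty(n)
    d_dis = np.empty(n)
    loop_t1 = out["loop_strength_t1"].to_numpy()
    gcb_t1 = out["gcb_t1"].to_numpy()
    for grp, mask in (("dec", dec), ("inc", ~dec)):
        m = int(mask.sum())
        mm = cfg.delta_moments[grp]
        rho_g = rho if grp == "dec" else 0.0
        cov = np.array([[1.0, rho_g], [rho_g, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=m, method="cholesky")
        d_loop[mask] = _calibrated_bounded_delta(
            loop_t1[mask], z[:, 0], *mm["loop_strength"], 0.0, np.inf)
        d_gcb[mask] = _calibrated_bounded_delta(
            gcb_t1[mask], z[:, 1], *mm["gcb"], *design.GCB_RANGE)
        # distress strictly moves in the trajectory's direction
        mag = np.abs(rng.normal(mm["distress"][0], mm["distress"][1], size=m))
        d_dis[mask] = -mag if grp == "dec" else mag

    out["trajectory"] = np.where(dec, "dec", "inc")
    out["distress_t2"] = np.clip(out["distress_t1"] + d_dis,
                                 *design.DISTRESS_RANGE)
    out["loop_strength_t2"] = loop_t1 + d_loop
    out["gcb_t2"] = np.round(gcb_t1 + d_gcb)
    for k in ("w", "b", "penalty"):
        out[f"{k}_t2"] = out[f"{k}_t1"]
    return out


def params_for(traits_row: pd.Series, session: str) -> CIParams:
    """The generative parameters of one subject at one session."""
    return CIParams(
        b=float(traits_row[f"b_{session}"]),
        w=float(traits_row[f"w_{session}"]),
        loop_strength=float(traits_row[f"loop_strength_{session}"]),
        penalty=float(traits_row[f"penalty_{session}"]),
    )


@dataclass
class CohortTable:
    """A generated cohort: traits plus per-subject-session response tables."""

    traits: pd.DataFrame
    responses: dict[tuple[str, str], pd.DataFrame]
    sequences: dict[tuple[str, str], TrialSequence]
    config: CohortConfig
    seed: int

    @property
    def sessions(self) -> tuple[str, ...]:
        return ("t1", "t2")

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        (path / "responses").mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(path / "traits.tsv", sep="\t", index=False,
                           float_format="%.10g")
        for (sid, ses), table in sorted(self.responses.items()):
            table.to_csv(path / "responses" / f"{sid}_{ses}.tsv", sep="\t",
                         index=False, float_format="%.10g")
        manifest = {
            "n_subjects": len(self.traits),
            "seed": self.seed,
            "config": json.loads(self.config.to_json()),
            "subjects": sorted(self.traits["subject_id"]),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                       sort_keys=True))


def generate_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> CohortTable:
    """Generate a full two-session cohort with simulated response tables.

    Every subject-session gets a fresh pseudorandom trial sequence and a
    run simulated from that session's true parameters.  Reaction times are
    drawn lognormal (configurable median); a configurable fraction of
    subjects respond implausibly fast (mean RT < 300 ms) to exercise the
    quality-control exclusion filter.  Regeneration from the same config
    and seed reproduces the cohort exactly.
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    s_traits, s_long, s_fast, s_runs = root.spawn(4)
    traits = sample_cohort_traits(n, cfg, seed=s_traits)
    traits = apply_longitudinal_effects(traits, cfg, seed=s_long)
    fast_rng = np.random.default_rng(s_fast)
    fast = fast_rng.random(n) < cfg.fast_responder_fraction
    traits["fast_responder"] = fast
    traits["attention_pass"] = True

    responses: dict[tuple[str, str], pd.DataFrame] = {}
    sequences: dict[tuple[str, str], TrialSequence] = {}
    run_streams = s_runs.spawn(n)
    mean_rts = np.zeros(n)
    for i, row in traits.iterrows():
        sid = row["subject_id"]
        per_session = run_streams[i].spawn(len(("t1", "t2")))
        rts_all = []
        for ses, stream in zip(("t1", "t2"), per_session):
            s_seq, s_noise, s_rt = stream.spawn(3)
            seq = make_trial_sequence(
                n_blocks=cfg.n_blocks,
                trials_per_block=cfg.trials_per_block,
                delay_levels=np.asarray(cfg.delay_levels),
                seed=s_seq,
            )
            noise, coins = draw_noise(seq, 1, s_noise)
            resp = simulate_responses(
                params_for(row, ses), seq, noise, coins,
                penalty_mode=cfg.penalty_mode,
            )
            rt_rng = np.random.default_rng(s_rt)
            median = cfg.fast_rt_median_s if fast[i] else cfg.rt_median_s
            rts = rt_rng.lognormal(np.log(median), cfg.rt_sigma, seq.n_trials)
            rts_all.append(rts)
            responses[(sid, ses)] = responses_to_table(resp[0], seq, rt_s=rts)
            sequences[(sid, ses)] = seq
        mean_rts[i] = np.concatenate(rts_all).mean()
    traits["mean_rt"] = mean_rts
    return CohortTable(traits=traits, responses=responses,
                       sequences=sequences, config=cfg, seed=seed)


def exclusion_filter(
    traits: pd.DataFrame, rt_threshold_s: float = design.MEAN_RT_EXCLUSION_S
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-control split: (retained, excluded) subject records.

    Subjects are excluded for an implausibly fast mean reaction time
    (below `rt_threshold_s`) or a failed attention check.
    """
    fast = traits["mean_rt"] < rt_threshold_s
    fail = ~traits["attention_pass"].astype(bool)
    excluded = traits[fast | fail].copy()
    reasons = np.where(fast[fast | fail], "fast_rt", "attention")
    excluded["exclusion_reason"] = reasons
    return traits[~(fast | fail)].copy(), excluded
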