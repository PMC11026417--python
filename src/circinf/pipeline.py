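"""End-to-end orchestration: simulate -> exclude -> summarize -> fit -> analyze.

A pipeline run writes a self-describing directory: the generated cohort,
the quality-control exclusion log, per-subject-session behavioral
summaries and model fits, the group-level analysis report, and a stage
manifest with the exact configuration, seeds and content hashes, so that
re-running the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design
from .fitting import FitResult, fit_subject
from .group_analysis import (
    correlate_fdr,
    fit_covariate_regression,
    paired_wilcoxon,
    split_and_compare,
)
from .summary_stats import (
    overall_stability,
    pairwise_stats,
    fit_stability_curve,
    stability_per_percept,
)
from .synthetic_cohort import CohortConfig, CohortTable, exclusion_filter, generate_cohort

logger = logging.getLogger("circinf")

#: Fitting profiles: the full-scale procedure and a desk-scale one.
PROFILES = {
    "paper": {"n_restarts": 100, "n_runs": 40, "max_evals": 2000},
    "scaled_down": {"n_restarts": 20, "n_runs": 20, "max_evals": 400},
    "smoke": {"n_restarts": 2, "n_runs": 5, "max_evals": 60},
}


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    out_dir: str
    n_subjects: int = 30
    seed: int = 0
    profile: str = "scaled_down"
    model_kind: str = "circular"
    analysis_family: str = "baseline"     # baseline | longitudinal | both
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit_overrides: dict = field(default_factory=dict)

    def fit_settings(self) -> dict:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        return {**PROFILES[self.profile], **self.fit_overrides}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = json.loads(self.cohort.to_json())
        return json.dumps(d, sort_keys=True, indent=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Behavioral summaries per subject and session."""
    rows = []
    for (sid, ses), table in sorted(cohort.responses.items()):
        seq = cohort.sequences[(sid, ses)]
        ps = pairwise_stats(table, seq)
        fit = fit_stability_curve(ps.sp_by_delay, ps.delays)
        per = stability_per_percept(table)
        rows.append({
            "subject_id": sid,
            "session": ses,
            "overall_stability": overall_stability(table),
            "stability_score": fit.stability_score,
            "sp_sfa": per["SFA"],
            "sp_sfb": per["SFB"],
            "curve_asymptote": fit.asymptote,
            "curve_depth": fit.depth,
            "curve_tau": fit.tau,
            "curve_fell_back": fit.fell_back,
        })
    return pd.DataFrame(rows)


def fit_cohort(
    cohort: CohortTable,
    retained: pd.DataFrame,
    model_kind: str = "circular",
    seed: int = 0,
    **fit_settings,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FitResult]]:
    """Fit every retained subject-session; returns a flat table and results."""
    root = np.random.SeedSequence(seed)
    ids = sorted(retained["subject_id"])
    streams = dict(zip(ids, root.spawn(len(ids))))
    rows, results = [], {}
    for sid in ids:
        per_session = streams[sid].spawn(2)
        for ses, stream in zip(("t1", "t2"), per_session):
            seq = cohort.sequences[(sid, ses)]
            observed = pairwise_stats(cohort.responses[(sid, ses)], seq)
            fit = fit_subject(
                observed, seq, model_kind=model_kind,
                seed=int(np.random.default_rng(stream).integers(2**31)),
                **fit_settings,
            )
            results[(sid, ses)] = fit
            rows.append({
                "subject_id": sid, "session": ses,
                "b": fit.params.b, "w": fit.params.w,
                "loop_strength": fit.params.loop_strength,
                "penalty": fit.params.penalty, "r": fit.params.r,
                "objective": fit.objective_value, "mse": fit.mse,
                "bic": fit.bic, "seed": fit.seed,
            })
            logger.info("fitted %s %s: objective %.4f", sid, ses,
                        fit.objective_value)
    return pd.DataFrame(rows), results


def _analysis_table(traits: pd.DataFrame, summaries: pd.DataFrame,
                    fits: pd.DataFrame) -> pd.DataFrame:
    wide = traits.copy()
    for ses in ("t1", "t2"):
        s = summaries[summaries.session == ses][
            ["subject_id", "overall_stability", "stability_score"]
        ].rename(columns={
            "overall_stability": f"overall_stability_{ses}",
            "stability_score": f"stability_{ses}",
        })
        wide = wide.merge(s, on="subject_id", how="left")
        f = fits[fits.session == ses][
            ["subject_id", "b", "w", "loop_strength", "penalty"]
        ].rename(columns={k: f"fit_{k}_{ses}"
                          for k in ("b", "w", "loop_strength", "penalty")})
        wide = wide.merge(f, on="subject_id", how="left")
    return wide


def analyze_cohort(table: pd.DataFrame, family: str = "baseline") -> dict:
    """The study's statistical pipeline on a merged cohort table.

    baseline: distress/GCB/stability/parameter correlations with FDR, the
    distress median split, and the covariate regression of GCB on distress.
    longitudinal: T2 - T1 change scores, the stress-trajectory split with
    an oriented Welch test on the conspiracy change, and the change-score
    correlation inside the decreasing-stress group.
    """
    report: dict = {"family": family, "n": int(len(table))}
    if family in ("baseline", "both"):
        corr = correlate_fdr(
            table,
            ["distress_t1", "gcb_t1", "stability_t1"],
            family="baseline_behavior",
        )
        par_pairs = [("gcb_t1", f"fit_{k}_t1")
                     for k in ("b", "w", "loop_strength", "penalty")
                     if f"fit_{k}_t1" in table.columns]
        par_corr = (correlate_fdr(table, [], family="baseline_parameters",
                                  pairs=par_pairs)
                    if par_pairs else pd.DataFrame())
        split = split_and_compare(
            table.dropna(subset=["distress_t1"]), "distress_t1",
            [c for c in ("stability_t1", "gcb_t1") if c in table.columns],
            split="median", test="mann_whitney",
        )
        try:
            reg = fit_covariate_regression(
                table.dropna(subset=["gcb_t1", "distress_t1"]),
                "gcb_t1", ["distress_t1", "age", "education", "country"],
            )
            regression = {
                "coefficients": reg["coefficients"].to_dict(orient="records"),
                "adj_r_squared": reg["adj_r_squared"],
                "n": reg["n"],
            }
        except ValueError as exc:
            # e.g. rank deficiency on very small cohorts
            logger.warning("covariate regression skipped: %s", exc)
            regression = {"skipped": str(exc)}
        report["baseline"] = {
            "correlations": corr.to_dict(orient="records"),
            "parameter_correlations": par_corr.to_dict(orient="records")
                                      if len(par_corr) else [],
            "median_split": [c.to_dict() for c in split],
            "regression": regression,
        }
    if family in ("longitudinal", "both"):
        tab = table.copy()
        tab["d_distress"] = tab["distress_t2"] - tab["distress_t1"]
        tab["d_gcb"] = tab["gcb_t2"] - tab["gcb_t1"]
        loop_cols = ("fit_loop_strength_t1", "fit_loop_strength_t2")
        if all(c in tab.columns for c in loop_cols):
            tab["d_loop"] = tab[loop_cols[1]] - tab[loop_cols[0]]
        else:
            tab["d_loop"] = tab["loop_strength_t2"] - tab["loop_strength_t1"]
        rep_meas = [
            paired_wilcoxon(tab["distress_t1"], tab["distress_t2"],
                            outcome="distress").to_dict(),
            paired_wilcoxon(tab["gcb_t1"], tab["gcb_t2"],
                            outcome="gcb").to_dict(),
        ]
        moving = tab[tab["d_distress"] != 0]
        split = split_and_compare(
            moving, "d_distress", ["d_loop"], split="delta_sign",
            test="welch_t",
        )
        oriented = split_and_compare(
            moving, "d_distress", ["d_gcb"], split="delta_sign",
            test="welch_t", alternative="greater",
        )
        dec = moving[moving["d_distress"] < 0]
        if len(dec.dropna(subset=["d_loop", "d_gcb"])) >= 3:
            dec_corr = correlate_fdr(dec, [], family="dec_deltas",
                                     pairs=[("d_loop", "d_gcb")])
        else:
            logger.warning("too few decreasing-stress subjects for the "
                           "change-score correlation")
            dec_corr = pd.DataFrame()
        report["longitudinal"] = {
            "repeated_measures": rep_meas,
            "trajectory_split": [c.to_dict() for c in split],
            "oriented_gcb": [c.to_dict() for c in oriented],
            "dec_delta_correlation": dec_corr.to_dict(orient="records"),
        }
    return report


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing outputs and manifests under `out_dir`.

    Stages: cohort generation, the mean-RT / attention quality filter,
    behavioral summaries, per-subject model fits (retained subjects only),
    and the group analysis.  Any stage failure aborts with the stage name;
    re-running the same configuration reproduces identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    manifest: dict = {"stages": {}}
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_fit = root.spawn(2)

    stage = "simulate"
    try:
        cohort = generate_cohort(
            config.n_subjects, config.cohort,
            seed=int(np.random.default_rng(s_cohort).integers(2**31)),
        )
        cohort.to_dir(out / "cohort")
        manifest["stages"][stage] = {
            "n_subjects": config.n_subjects,
            "traits": _sha256(out / "cohort" / "traits.tsv"),
        }

        stage = "exclude"
        retained, excluded = exclusion_filter(cohort.traits)
        retained.to_csv(out / "retained.tsv", sep="\t", index=False,
                        float_format="%.10g")
        excluded.to_csv(out / "excluded.tsv", sep="\t", index=False,
                        float_format="%.10g")
        manifest["stages"][stage] = {
            "n_retained": int(len(retained)),
            "n_excluded": int(len(excluded)),
            "excluded_ids": sorted(excluded["subject_id"]),
        }

        stage = "summarize"
        summaries = summarize_cohort(cohort)
        summaries.to_csv(out / "summaries.tsv", sep="\t", index=False,
                         float_format="%.10g")
        manifest["stages"][stage] = {"sha256": _sha256(out / "summaries.tsv")}

        stage = "fit"
        fit_seed = int(np.random.default_rng(s_fit).integers(2**31))
        fits, results = fit_cohort(
            cohort, retained, model_kind=config.model_kind, seed=fit_seed,
            **config.fit_settings(),
        )
        fits.to_csv(out / "fits.tsv", sep="\t", index=False,
                    float_format="%.10g")
        (out / "fits").mkdir(exist_ok=True)
        for (sid, ses), fit in sorted(results.items()):
            _write_json(out / "fits" / f"{sid}_{ses}.json", fit.to_dict())
        manifest["stages"][stage] = {
            "profile": config.profile, "seed": fit_seed,
            "sha256": _sha256(out / "fits.tsv"),
        }

        stage = "analyze"
        table = _analysis_table(retained, summaries, fits)
        table.to_csv(out / "analysis_table.tsv", sep="\t", index=False,
                     float_format="%.10g")
        report = analyze_cohort(table, family=config.analysis_family)
        _write_json(out / "analysis.json", report)
        manifest["stages"][stage] = {
            "family": config.analysis_family,
            "sha256": _sha256(out / "analysis.json"),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return out
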