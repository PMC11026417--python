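"""Behavioral summaries of intermittent bistable-perception runs.

Two successive reports within a block form an ordered pair attributed to
the OFF duration preceding the second report.  The 4 ordered pairs
(SFA->SFA, SFA->SFB, SFB->SFA, SFB->SFB) at each of the 7 delay levels
give the 28 pairwise measures used as the model-fitting target.  The
stability probability SP(d) — the chance that the percept repeats across
an OFF period of duration d — typically drops over short delays and then
plateaus; the plateau portion is fitted with a saturating ("reversed")
exponential and its value at the longest delay is the subject's stability
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import _kernels
from .ci_model import PERCEPT_CODES, PERCEPT_LABELS, SFA, SFB
from .task import TrialSequence

PAIR_LABELS = ("SFA->SFA", "SFA->SFB", "SFB->SFA", "SFB->SFB")


@dataclass(frozen=True)
class PairwiseStats:
    """Ordered-pair counts and conditional frequencies by delay level.

    `counts[k, j]` is the number of within-block consecutive pairs of kind
    ``PAIR_LABELS[k]`` whose second trial followed the j-th delay level;
    `freqs` divides each delay column by its total pair count, so defined
    columns sum to 1 and columns with no pairs are NaN (flagged missing,
    never 0).
    """

    delays: np.ndarray          # (n_levels,) ascending seconds
    counts: np.ndarray          # (4, n_levels) int
    freqs: np.ndarray           # (4, n_levels) float, NaN where no pairs

    @property
    def n_pairs_by_delay(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of delay columns with no conditioning pairs."""
        return self.n_pairs_by_delay == 0

    def flatten(self) -> np.ndarray:
        """The 28-vector, pair-major and delay-minor:
        [SFA->SFA at d1..d7, SFA->SFB at d1..d7, SFB->SFA ..., SFB->SFB ...]."""
        return self.freqs.ravel()

    @property
    def sp_by_delay(self) -> np.ndarray:
        """Per-delay stability probability: freq(SFA->SFA) + freq(SFB->SFB)."""
        return self.freqs[0] + self.freqs[3]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, lab in enumerate(PAIR_LABELS):
            for j, d in enumerate(self.delays):
                rows.append(
                    {"pair": lab, "delay_s": d,
                     "count": int(self.counts[k, j]), "freq": self.freqs[k, j]}
                )
        return pd.DataFrame(rows)


def _responses_to_codes(responses: pd.DataFrame) -> np.ndarray:
    try:
        return np.array([PERCEPT_CODES[r] for r in responses["response"]], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown percept label {exc.args[0]!r}") from None


def counts_from_matrix(resp: np.ndarray, seq: TrialSequence) -> np.ndarray:
    """Pooled (4, n_levels) pair counts for a (n_runs, n_trials) +/-1 matrix."""
    resp = np.ascontiguousarray(resp, dtype=np.int8)
    return _kernels.pair_counts(resp, seq.level_idx, seq.pair_mask, seq.n_levels)


def stats_from_counts(counts: np.ndarray, delays: np.ndarray) -> PairwiseStats:
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(col > 0, counts / np.maximum(col, 1), np.nan)
    return PairwiseStats(delays=np.asarray(delays, float), counts=counts, freqs=freqs)


def pairwise_stats(responses: pd.DataFrame, seq: TrialSequence) -> PairwiseStats:
    """Ordered-pair statistics of successive reports within blocks.

    `responses` is a response table aligned with `seq` (same length and
    OFF durations); a pair at delay d couples trial t with trial t+1 of the
    same block where trial t+1's OFF duration is d.
    """
    if len(responses) != seq.n_trials:
        raise ValueError(
            f"response table has {len(responses)} rows, sequence has "
            f"{seq.n_trials} trials"
        )
    if not np.allclose(responses["off_duration_s"].to_numpy(), seq.off_durations):
        raise ValueError("response table OFF durations do not match the sequence")
    codes = _responses_to_codes(responses)
    counts = counts_from_matrix(codes[None, :], seq)
    return stats_from_counts(counts, seq.delay_levels)


def overall_stability(responses: pd.DataFrame) -> float:
    """Mean same-percept indicator over within-block consecutive pairs.

    Each trial after the first of its block scores 1 if its report equals
    the previous one and 0 otherwise; the average over all such trials is
    the overall stability probability, in [0, 1].
    """
    codes = _responses_to_codes(responses)
    block = responses["block"].to_numpy()
    same_block = block[:-1] == block[1:]
    if not same_block.any():
        raise ValueError("need at least 2 trials in some block")
    return float((codes[:-1] == codes[1:])[same_block].mean())


def stability_per_percept(responses: pd.DataFrame) -> dict[str, float]:
    """Per-interpretation stability: P(repeat | previous percept), SFA and SFB.

    Reported for completeness alongside the overall probability; not used
    by downstream analyses.
    """
    codes = _responses_to_codes(responses)
    block = responses["block"].to_numpy()
    same_block = block[:-1] == block[1:]
    prev, nxt = codes[:-1][same_block], codes[1:][same_block]
    out = {}
    for percept in (SFA, SFB):
        mask = prev == percept
        out[PERCEPT_LABELS[percept]] = (
            float((nxt[mask] == percept).mean()) if mask.any() else float("nan")
        )
    return out


@dataclass(frozen=True)
class StabilityFit:
    """Stability curve fit SP(d) = A - B exp(-d / tau) on the plateau portion.

    `stability_score` is the fitted curve evaluated at the largest delay;
    `portion_start` indexes where the stabilization portion begins.  When
    fewer than 3 defined points are available for the fit, the raw SP at
    the longest delay is used and `fell_back` is True.
    """

    delays: np.ndarray
    sp_by_delay: np.ndarray
    asymptote: float
    depth: float
    tau: float
    stability_score: float
    portion_start: int
    fell_back: bool = False

    def curve(self, d) -> np.ndarray:
        return self.asymptote - self.depth * np.exp(-np.asarray(d, float) / self.tau)


def _reversed_exponential(d, A, B, tau):
    return A - B * np.exp(-d / tau)


def fit_stability_curve(
    sp_by_delay: np.ndarray, delays: np.ndarray
) -> StabilityFit:
    """Fit the stabilization portion of the stability curve.

    The portion runs from the delay achieving the minimum empirical SP
    through the last delay.  SP(d) = A - B exp(-d/tau) is fitted by
    bounded nonlinear least squares with a multi-start over tau; the
    stability score is the fitted value at the longest delay, in [0, 1].
    Missing (NaN) delay cells are excluded, not imputed.
    """
    delays = np.asarray(delays, dtype=float)
    sp = np.asarray(sp_by_delay, dtype=float)
    if delays.shape != sp.shape or delays.ndim != 1:
        raise ValueError("delays and sp_by_delay must be equal-length 1-D")
    defined = np.isfinite(sp)
    if defined.sum() < 3:
        raise ValueError("need >= 3 delays with defined SP")
    d_max = delays[defined][-1]
    start = int(np.nanargmin(sp))
    d_fit = delays[start:]
    sp_fit = sp[start:]
    keep = np.isfinite(sp_fit)
    d_fit, sp_fit = d_fit[keep], sp_fit[keep]
    if d_fit.size < 3:
        score = float(sp[defined][-1])
        return StabilityFit(
            delays=delays, sp_by_delay=sp, asymptote=score, depth=0.0,
            tau=1.0, stability_score=score, portion_start=start, fell_back=True,
        )
    best = None
    for tau0 in (0.1, 0.3, 1.0):
        try:
            popt, _ = curve_fit(
                _reversed_exponential,
                d_fit,
                sp_fit,
                p0=[np.clip(sp_fit[-1], 0, 1.05), 0.2, tau0],
                bounds=([0.0, 0.0, 1e-3], [1.05, 1.05, 10.0]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = sp_fit - _reversed_exponential(d_fit, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:  # pathological data; fall back to the raw endpoint
        score = float(sp_fit[-1])
        return StabilityFit(
            delays=delays, sp_by_delay=sp, asymptote=score, depth=0.0,
            tau=1.0, stability_score=score, portion_start=start, fell_back=True,
        )
    A, B, tau = best[1]
    score = float(np.clip(_reversed_exponential(d_max, A, B, tau), 0.0, 1.0))
    return StabilityFit(
        delays=delays, sp_by_delay=sp, asymptote=float(A), depth=float(B),
        tau=float(tau), stability_score=score, portion_start=start,
    )


def stability_fit_from_responses(
    responses: pd.DataFrame, seq: TrialSequence
) -> StabilityFit:
    """Convenience composition: pairwise stats -> SP(d) -> stability fit."""
    ps = pairwise_stats(responses, seq)
    return fit_stability_curve(ps.sp_by_delay, ps.delays)
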