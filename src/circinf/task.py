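"""Necker-cube task structure: blocks of intermittent presentations.

A run consists of consecutive blocks of trials.  Each trial is one cube
presentation preceded by an OFF period (blank interstimulus interval)
whose duration is drawn from a small set of discrete delay levels.  The
belief dynamics evolve without input during the OFF period, so the OFF
durations are the experimentally controlled variable of the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import design


@dataclass(frozen=True)
class TrialSequence:
    """Block/trial scaffold of one run with per-trial OFF durations.

    Attributes
    ----------
    off_durations : ndarray of float
        OFF (interstimulus) duration in seconds preceding each trial,
        concatenated over blocks.
    delay_levels : ndarray of float
        The distinct OFF-duration levels, ascending.
    n_blocks, trials_per_block : int
        Block structure; ``len(off_durations) == n_blocks * trials_per_block``.
    block_gap : float
        Blank gap between blocks in seconds (not part of any trial's OFF
        period; the belief is reset at block onset by default).
    """

    off_durations: np.ndarray
    delay_levels: np.ndarray
    n_blocks: int
    trials_per_block: int
    block_gap: float = design.BLOCK_GAP_S

    def __post_init__(self) -> None:
        off = np.asarray(self.off_durations, dtype=float)
        lev = np.asarray(self.delay_levels, dtype=float)
        object.__setattr__(self, "off_durations", off)
        object.__setattr__(self, "delay_levels", lev)
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if off.shape != (self.n_blocks * self.trials_per_block,):
            raise ValueError(
                f"off_durations has length {off.size}, expected "
                f"{self.n_blocks * self.trials_per_block}"
            )
        if lev.ndim != 1 or lev.size < 1 or np.any(np.diff(lev) <= 0):
            raise ValueError("delay_levels must be 1-D, distinct and ascending")
        if np.any(off <= 0):
            raise ValueError("OFF durations must be positive")
        # every trial's OFF duration must be one of the levels
        idx = np.searchsorted(lev, off)
        idx = np.clip(idx, 0, lev.size - 1)
        near = np.minimum(
            np.abs(lev[idx] - off), np.abs(lev[np.maximum(idx - 1, 0)] - off)
        )
        if np.any(near > 1e-9):
            raise ValueError("some off_durations are not in delay_levels")

    @property
    def n_trials(self) -> int:
        return self.off_durations.size

    @property
    def n_levels(self) -> int:
        return self.delay_levels.size

    @cached_property
    def block_id(self) -> np.ndarray:
        """0-based block index per trial."""
        return np.repeat(np.arange(self.n_blocks), self.trials_per_block)

    @cached_property
    def is_block_first(self) -> np.ndarray:
        first = np.zeros(self.n_trials, dtype=bool)
        first[:: self.trials_per_block] = True
        return first

    @cached_property
    def level_idx(self) -> np.ndarray:
        """Index into ``delay_levels`` per trial."""
        idx = np.abs(self.off_durations[:, None] - self.delay_levels[None, :])
        return np.argmin(idx, axis=1).astype(np.int64)

    @cached_property
    def pair_mask(self) -> np.ndarray:
        """True at t when trials (t, t+1) lie in the same block; length n_trials-1."""
        return self.block_id[:-1] == self.block_id[1:]

    @cached_property
    def pair_level_counts(self) -> np.ndarray:
        """Number of within-block consecutive pairs whose second trial sits at
        each delay level (one run)."""
        lvl = self.level_idx[1:][self.pair_mask]
        return np.bincount(lvl, minlength=self.n_levels)

    @property
    def n_pairs(self) -> int:
        return int(self.pair_mask.sum())


def make_trial_sequence(
    n_blocks: int = design.N_BLOCKS,
    trials_per_block: int = design.TRIALS_PER_BLOCK,
    delay_levels: np.ndarray | None = None,
    block_gap: float = design.BLOCK_GAP_S,
    balanced: bool = True,
    seed: int | np.random.SeedSequence = 0,
) -> TrialSequence:
    """Build a pseudorandom trial sequence.

    Within each block, trial 1 receives a delay level drawn uniformly and
    trials 2..trials_per_block carry a balanced assignment of the levels
    (each level appears ``(trials_per_block - 1) / n_levels`` times),
    independently permuted per block.  Deterministic for a given seed.

    Parameters
    ----------
    balanced : bool
        If True (default) require ``(trials_per_block - 1)`` to be divisible
        by the number of levels; otherwise draw every trial's level uniformly.
    """
    if delay_levels is None:
        delay_levels = design.default_delay_levels()
    lev = np.asarray(delay_levels, dtype=float)
    n_levels = lev.size
    rng = np.random.default_rng(seed)
    per_block = trials_per_block - 1
    if balanced and per_block % n_levels != 0:
        raise ValueError(
            f"trials_per_block - 1 = {per_block} not divisible by "
            f"{n_levels} levels; pass balanced=False to draw uniformly"
        )
    blocks = []
    for _ in range(n_blocks):
        first = rng.integers(n_levels)
        if balanced:
            rest = np.tile(np.arange(n_levels), per_block // n_levels)
            rng.shuffle(rest)
        else:
            rest = rng.integers(n_levels, size=per_block)
        blocks.append(np.concatenate(([first], rest)))
    idx = np.concatenate(blocks)
    return TrialSequence(
        off_durations=lev[idx],
        delay_levels=lev,
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        block_gap=block_gap,
    )
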