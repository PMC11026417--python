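"""Constants of the study design this package emulates.

These are the fixed quantities of the intermittent Necker-cube protocol
(block structure, OFF-duration range, volatility) and of the longitudinal
online study whose data model the synthetic cohort reproduces (recruitment
and exclusion counts, population moments of questionnaires and fitted
model parameters).
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------- task design
N_BLOCKS = 10
TRIALS_PER_BLOCK = 64
N_DELAY_LEVELS = 7
DELAY_RANGE_S = (0.1, 1.2)
BLOCK_GAP_S = 10.0

#: Mean volatility of the generative model, fixed for the circular variant.
VOLATILITY_HZ = 10.0


def default_delay_levels() -> np.ndarray:
    """Seven OFF-duration levels linearly spaced over the task's ISI range."""
    return np.linspace(*DELAY_RANGE_S, N_DELAY_LEVELS)


def sensory_integration_time_constant_s(r: float = VOLATILITY_HZ) -> float:
    """Mean sensory integration time constant implied by volatility r (1/r)."""
    if r <= 0:
        raise ValueError("volatility must be positive")
    return 1.0 / r


# ----------------------------------------------------- recruitment arithmetic
N_RECRUITED = 755
N_EXCLUDED_QC = 30          # failed attention checks or mean RT < 300 ms
N_LOST_FOLLOWUP = 102
PER_COUNTRY_ANALYZED = {"US": 212, "UK": 225, "FR": 186}
MEAN_RT_EXCLUSION_S = 0.300


def analyzed_sample_size() -> int:
    """Retained longitudinal sample implied by recruitment/exclusion counts."""
    return N_RECRUITED - N_EXCLUDED_QC - N_LOST_FOLLOWUP


# --------------------------------------------- population moments at baseline
#: (mean, sd) of the fitted model parameters and questionnaires at T1.
T1_MOMENTS = {
    "w": (1.70, 0.85),
    "loop_strength": (1.85, 0.91),
    "b": (0.59, 0.07),
    "penalty": (-2.04, 1.50),
    "distress": (5.35, 3.33),
    "gcb": (33.8, 13.3),
    "stability": (0.572, 0.178),
}

GCB_RANGE = (15.0, 75.0)
DISTRESS_RANGE = (0.0, 10.0)
AGE_RANGE = (18, 60)

#: Target Spearman rank correlations among baseline traits.
T1_RANK_CORRELATIONS = {
    ("gcb", "w"): 0.098,
    ("distress", "gcb"): -0.094,
    # chosen so that simulated perceptual stability correlates with distress
    # near -0.12 once the loop-strength -> stability mapping is applied
    ("distress", "loop_strength"): -0.18,
}

# -------------------------------------------------------- longitudinal change
#: Fraction of subjects whose distress decreases between sessions (Dec group).
DEC_FRACTION = 330 / 557

#: (mean, sd) of T2 - T1 changes by stress trajectory.
DELTA_MOMENTS = {
    "dec": {
        "distress": (-2.78, 2.45),
        "loop_strength": (0.081, 1.11),
        "gcb": (1.29, 10.3),
    },
    "inc": {
        "distress": (2.01, 2.14),
        "loop_strength": (-0.121, 1.14),
        "gcb": (-0.305, 11.6),
    },
}

#: Rank correlation between the loop-strength change and the conspiracy-score
#: change within the decreasing-stress group.
DEC_DELTA_RANK_CORRELATION = 0.116

# ------------------------------------------------- demographic GCB gradients
#: Mean conspiracy score by age band (years, inclusive bounds).
GCB_BY_AGE = [((18, 30), 35.0), ((31, 45), 33.1), ((46, 60), 31.5)]
#: Mean conspiracy score by education band (ISCED levels).
GCB_BY_EDUCATION = [((0, 3), 38.2), ((4, 6), 34.7), ((7, 8), 30.0)]
#: Mean conspiracy score by country.
GCB_BY_COUNTRY = {"US": 37.7, "UK": 33.3, "FR": 30.0}
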