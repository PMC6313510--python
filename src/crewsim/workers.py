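"""Worker agents: states, task decisions and violation outcomes.

A worker is either APPROACHING (walking toward workload), IMPLEMENTING
(working a cell) or STOPPED (recovering from an accident).  On entering a
cell with workload the worker runs the decision chain: situational check
(is a constraint present and not removed by management?), then safety check
(is the effective hazard below the worker's acceptable hazard AR_i?).  The
resulting task mode fixes the production speed; violating tasks run
``1 + production_incr`` times faster.  At completion a violating task rolls
one of three outcomes -- nothing, a near-miss, or an accident -- with
probabilities linear in the hazard at which the violation was committed.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from .config import ConfigurationError, OutcomeParams, WorkerParams, HAZARD_MAX

__all__ = [
    "WorkerState",
    "TaskMode",
    "Outcome",
    "task_duration",
    "roll_violation_outcome",
    "outcome_probabilities",
    "apply_outcome_to_ar",
]


class WorkerState(IntEnum):
    APPROACHING = 0
    IMPLEMENTING = 1
    STOPPED = 2


class TaskMode(IntEnum):
    NORMAL = 0
    ROUTINE_VIOLATION = 1
    SITUATIONAL_VIOLATION = 2


class Outcome(IntEnum):
    NONE = 0
    NEAR_MISS = 1
    ACCIDENT = 2


def task_duration(
    workload: float, production_speed: float, mode: TaskMode, production_incr: float
) -> float:
    """Days needed to complete ``workload`` in the given mode.

    Compliant tasks take ``workload / speed`` days; violating tasks trade
    safety for a temporary ``1 + production_incr`` speed-up.
    """
    if production_speed <= 0:
        raise ConfigurationError("production_speed must be positive")
    if workload <= 0:
        raise ValueError("task_duration requires positive workload")
    speed = production_speed
    if mode != TaskMode.NORMAL:
        speed *= 1.0 + production_incr
    return workload / speed


def outcome_probabilities(
    effective_hazard, params: OutcomeParams
) -> tuple[np.ndarray, np.ndarray]:
    """(accident, near-miss) probabilities for a violation at the given hazard.

    Both scale linearly with hazard -- a violation at hazard 0 is harmless
    -- and the near-miss channel is ``nearmiss_multiplier`` times the
    accident channel, so the expected near-miss : accident ratio equals the
    multiplier regardless of where violations happen.
    """
    h = np.asarray(effective_hazard, dtype=float)
    p_acc = params.p_accident_at_max * h / HAZARD_MAX
    return p_acc, params.nearmiss_multiplier * p_acc


def roll_violation_outcome(
    effective_hazard: float, params: OutcomeParams, rng: np.random.Generator
):
    """Draw the outcome of one violating task (vectorized over hazards)."""
    p_acc, p_nm = outcome_probabilities(effective_hazard, params)
    if np.any(p_acc + p_nm > 1.0):
        raise ConfigurationError("outcome probabilities exceed 1; rescale parameters")
    u = rng.random(np.shape(p_acc)) if np.ndim(p_acc) else rng.random()
    out = np.where(u < p_acc, Outcome.ACCIDENT, np.where(u < p_acc + p_nm, Outcome.NEAR_MISS, Outcome.NONE))
    return Outcome(int(out)) if np.ndim(out) == 0 else out


def apply_outcome_to_ar(ar: float, outcome: Outcome, params: WorkerParams) -> float:
    """Experiential learning: incidents lower the acceptable hazard.

    A near-miss nudges AR_i down by ``nearmiss_decrement``; an accident
    slashes it by ``accident_decrement``.  AR_i stays within [0, 200].
    """
    if outcome == Outcome.NEAR_MISS:
        ar -= params.nearmiss_decrement
    elif outcome == Outcome.ACCIDENT:
        ar -= params.accident_decrement
    return float(min(max(ar, 0.0), HAZARD_MAX))


def draw_initial_workers(
    n_workers: int,
    params: WorkerParams,
    median_contagion_pro: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial acceptable hazards and contagion probabilities.

    AR_i ~ U(ar_init_range); cp_i ~ U(contagion_pro_range) shifted so its
    median equals ``median_contagion_pro`` (the factorial-experiment handle)
    and clamped to (0.01, 0.99) to preserve heterogeneity at extreme
    medians.
    """
    ar = rng.uniform(*params.ar_init_range, size=n_workers)
    lo, hi = params.contagion_pro_range
    cp = rng.uniform(lo, hi, size=n_workers)
    shift = median_contagion_pro - 0.5 * (lo + hi)
    if shift:
        cp = np.clip(cp + shift, 0.01, 0.99)
    return ar, cp
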