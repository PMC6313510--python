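"""System-level feedback dynamics.

Worker and manager events (violations, feedback, improvements, near-misses,
accidents, completed workload) accumulate into trailing-window stocks; once
per day the stocks are condensed into the auxiliaries that re-parameterize
the agents:

* per-crew perceived safety-specific social support SS and perceived
  production pressure PP, combined into the attitudinal ambivalence w;
* a global safety-performance gap against the weekly safety goal, clamped
  into the safety control pressure SCP in [0, 1];
* the management outputs: safety-feedback rate, safety-improvement rate,
  inspection distance and tolerable hazard level TM.

Lower ``proacMan`` means more intensive proactive management (higher rates,
wider inspection, lower TM); SCP is the reactive channel that tightens the
same outputs after a bad week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, SDParams

__all__ = [
    "SDOutputs",
    "perceived_social_support",
    "perceived_production_pressure",
    "attitudinal_ambivalence",
    "safety_control_pressure",
    "management_outputs",
]


@dataclass(frozen=True)
class SDOutputs:
    """Daily management outputs consumed by the agents."""

    safety_feedback_rate: float
    safety_improvement_rate: float
    distance: float  # inspection radius, cells (Chebyshev)
    tolerable_hazard: float  # TM, hazard-units


def perceived_social_support(n_impr, n_fb, n_viol, scaling: float = 100.0):
    """SS = min(1, interventions-per-violation x scaling); 1 when violation-free.

    With no coworker violations in the window there is nothing to support
    against, so support is vacuously full.
    """
    n_impr = np.asarray(n_impr, dtype=float)
    n_fb = np.asarray(n_fb, dtype=float)
    n_viol = np.asarray(n_viol, dtype=float)
    ratio = np.divide(
        n_impr + n_fb, n_viol, out=np.full(np.broadcast(n_impr, n_viol).shape, np.inf),
        where=n_viol > 0,
    )
    return np.minimum(1.0, ratio * scaling)


def perceived_production_pressure(crew_prod, avg_prod, scaling: float = 100.0):
    """PP = min(1, relative productivity shortfall x scaling); 0 if not behind."""
    crew_prod = np.asarray(crew_prod, dtype=float)
    avg = float(avg_prod)
    if avg <= 0.0:
        return np.zeros_like(crew_prod)
    shortfall = np.maximum(0.0, (avg - crew_prod) / avg)
    return np.minimum(1.0, shortfall * scaling)


def attitudinal_ambivalence(pp, ss, pp_coeff: float = 0.68, ss_coeff: float = 0.13):
    """w = clamp(0.68 PP - 0.13 SS, 0, 1): pressure feeds ambivalence, support quells it."""
    raw = pp_coeff * np.asarray(pp, dtype=float) - ss_coeff * np.asarray(ss, dtype=float)
    return np.clip(raw, 0.0, 1.0)


def safety_control_pressure(
    near_misses: float, accidents: float, safe_goal: float, accident_weight: float = 10.0
) -> tuple[float, float]:
    """Safety-performance gap against the weekly goal, and its clamp SCP.

    ``gap = (near + 10 x accidents - safeGoal) / safeGoal``;
    ``SCP = clamp(gap, 0, 1)``.
    """
    if safe_goal <= 0:
        raise ConfigurationError("safe_goal must be positive")
    gap = (near_misses + accident_weight * accidents - safe_goal) / safe_goal
    return gap, float(np.clip(gap, 0.0, 1.0))


def management_outputs(
    proac_man: float, scp: float, distance_scale: float = 10.0
) -> SDOutputs:
    """Daily management outputs from proactive intensity and control pressure.

    Rates: ``max(1 - proacMan, SCP)``; inspection distance scales the same
    driver; tolerance: ``TM = min(100 proacMan, 100 (1 - SCP))``.
    """
    if not 0.0 <= proac_man <= 1.0 or not 0.0 <= scp <= 1.0:
        raise ConfigurationError("proac_man and scp must lie in [0, 1]")
    drive = max(1.0 - proac_man, scp)
    return SDOutputs(
        safety_feedback_rate=drive,
        safety_improvement_rate=drive,
        distance=distance_scale * drive,
        tolerable_hazard=min(100.0 * proac_man, 100.0 * (1.0 - scp)),
    )
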