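"""Social contagion of hazard tolerance within a crew.

Each worker carries an acceptable-hazard set point AR_i (risk homeostasis):
they violate a safety rule when the perceived cell hazard falls below it.
The set point drifts toward the hazard tolerance the worker perceives
around them, built from three ingredients updated once per simulated day:

* a crew tolerance TC_i, an exponentially weighted memory (capacity ``m``
  days) of an index summarizing each coworker's observable behaviour over
  the trailing memory window;
* the management tolerance TM, blended with TC_i through the worker's
  attitudinal ambivalence w_i (weight on crew norms versus formal rules);
* the worker's contagion probability cp_i, the per-day adaptation rate.

All three updates are convex combinations, so tolerances stay inside the
range spanned by their inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "coworker_hazard_index",
    "update_crew_tolerance",
    "perceived_tolerance",
    "adapt_acceptable_hazard",
]


def coworker_hazard_index(
    violation_hazard_sum: float, n_tasks: float, *, n_violations: float | None = None,
    mode: str = "violation_load",
) -> float:
    """Index of a coworker's behaviour over the trailing memory window.

    ``"violation_load"`` divides the summed hazards at the coworker's
    violations by their total completed tasks (a per-task violation-hazard
    load); ``"violation_mean"`` divides by the violation count instead.  A
    coworker with no completed tasks exposes no observable behaviour and
    scores 0.  The engine's default ``"exposure"`` index (mean hazard over
    all tasks) is computed in the engine from the exposure ring buffers.
    """
    if n_tasks <= 0:
        return 0.0
    if mode == "violation_load":
        return violation_hazard_sum / n_tasks
    if mode == "violation_mean":
        if not n_violations:
            return 0.0
        return violation_hazard_sum / n_violations
    raise ValueError(f"unknown coworker index mode: {mode!r}")


def update_crew_tolerance(tc_prev, coworker_indices, m: float):
    """One daily step of the crew-tolerance memory.

    ``TC(t) = (1 - 1/m) * TC(t-1) + (1/m) * mean(coworker indices)``.
    With ``m = 1`` the memory is erased each day; as ``m`` grows the crew
    norm responds ever more sluggishly.  Accepts scalars or arrays.
    """
    if m < 1:
        raise ValueError("memory capacity m must be >= 1")
    mean_index = np.mean(coworker_indices, axis=-1) if np.ndim(coworker_indices) else coworker_indices
    return (1.0 - 1.0 / m) * np.asarray(tc_prev) + (1.0 / m) * mean_index


def perceived_tolerance(tc, tm, w):
    """Blend crew and management tolerance by attitudinal ambivalence.

    ``TR = w * TC + (1 - w) * TM`` with ``w`` in [0, 1]: ambivalent workers
    (high w) weight the informal crew norm; resolute ones follow the rules.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("ambivalence weight w must lie in [0, 1]")
    return w * np.asarray(tc) + (1.0 - w) * np.asarray(tm)


def adapt_acceptable_hazard(ar_prev, tr, cp, clamp: tuple[float, float] = (0.0, 200.0)):
    """Daily adaptation of the acceptable-hazard set point.

    ``AR(t) = (1 - cp) * AR(t-1) + cp * TR(t)``, clamped to the hazard
    scale.  ``cp = 0`` leaves the worker untouched by social influence;
    ``cp = 1`` makes them fully determined by it.
    """
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0.0) or np.any(cp > 1.0):
        raise ValueError("contagion probability must lie in [0, 1]")
    out = (1.0 - cp) * np.asarray(ar_prev) + cp * np.asarray(tr)
    return np.clip(out, clamp[0], clamp[1])
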