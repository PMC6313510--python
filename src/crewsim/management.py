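"""Manager agents: patrol and tolerance-gated inspection.

One manager supervises each crew of 20.  Managers patrol by sampling: each
tick they relocate to the cell of a uniformly chosen non-stopped member of
their crew.  When a worker starts a task, the crew's manager may intervene
-- but only if the worker is within the inspection distance (Chebyshev
metric on the grid), the cell's effective hazard exceeds the management
tolerance TM, and a Bernoulli draw at the relevant rate succeeds.  A
successful safety improvement removes the cell's situational constraint; a
successful safety feedback turns a pending routine violation into compliant
work.  Both rates, the distance and TM are set daily by the system-level
dynamics.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["InspectionResult", "chebyshev", "position_managers", "inspect_worker"]


class InspectionResult(IntEnum):
    NONE = 0
    FEEDBACK_GIVEN = 1
    IMPROVEMENT_MADE = 2


def chebyshev(ax: int, ay: int, bx: int, by: int) -> int:
    """Grid distance: a radius-d inspection zone is a (2d+1)^2 square."""
    return max(abs(ax - bx), abs(ay - by))


def position_managers(
    manager_cells: np.ndarray,
    worker_cells: np.ndarray,
    crew_of_worker: np.ndarray,
    active: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relocate each manager to a uniformly chosen active member of their crew.

    Managers with no active crew member stay put.  ``manager_cells`` is
    modified in place and returned.
    """
    for crew_id in range(manager_cells.size):
        members = np.flatnonzero((crew_of_worker == crew_id) & active)
        if members.size:
            manager_cells[crew_id] = worker_cells[members[rng.integers(members.size)]]
    return manager_cells


def inspect_worker(
    distance_to_manager: float,
    inspection_distance: float,
    effective_hazard: float,
    tolerable_hazard: float,
    constraint_present: bool,
    pending_routine_violation: bool,
    improvement_rate: float,
    feedback_rate: float,
    rng: np.random.Generator,
) -> InspectionResult:
    """One inspection gate, evaluated when a worker starts a task.

    Out-of-range workers, and hazards at or below the management tolerance,
    draw no intervention at all -- managers do not act on situations they
    consider safe.  Within range and above tolerance, a situational
    constraint is removed with probability ``improvement_rate``; otherwise a
    pending routine violation is averted with probability ``feedback_rate``.
    """
    if distance_to_manager > inspection_distance:
        return InspectionResult.NONE
    if effective_hazard <= tolerable_hazard:
        return InspectionResult.NONE
    if constraint_present:
        if rng.random() < improvement_rate:
            return InspectionResult.IMPROVEMENT_MADE
        return InspectionResult.NONE
    if pending_routine_violation and rng.random() < feedback_rate:
        return InspectionResult.FEEDBACK_GIVEN
    return InspectionResult.NONE
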