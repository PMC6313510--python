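"""Simulation engine: daily system-dynamics / contagion updates wrapped
around a tick-level agent loop, plus the summary metrics of a run.

Each simulated day proceeds in three phases:

1. the system-level stocks of the trailing windows (violations, feedback,
   improvements, incidents, productivity) are condensed into the daily
   management outputs and per-crew ambivalence;
2. every worker's acceptable hazard adapts through the social-contagion
   update;
3. ``ticks_per_day`` agent ticks run: cranes rotate, managers patrol,
   stopped workers recover, implementing workers progress and complete
   tasks (rolling violation outcomes), approaching workers step toward
   workload and start new tasks through the inspection gate.

A run is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import management, sysdyn
from ._rand import BufferedUniform, DrawBuffer
from .config import HAZARD_MAX, SimulationConfig
from .site import SiteGrid, generate_site
from .workers import Outcome, TaskMode, WorkerState, draw_initial_workers

__all__ = ["RunResult", "MetricsReport", "run_simulation", "compute_metrics",
           "aggregate", "run_replicates"]

_EPS = 1e-9
# hot-loop integer aliases of the public enums
_APPROACHING = int(WorkerState.APPROACHING)
_IMPLEMENTING = int(WorkerState.IMPLEMENTING)
_STOPPED = int(WorkerState.STOPPED)
_NORMAL = int(TaskMode.NORMAL)
_ROUTINE = int(TaskMode.ROUTINE_VIOLATION)
_SITUATIONAL = int(TaskMode.SITUATIONAL_VIOLATION)
_NONE, _NEAR_MISS, _ACCIDENT = int(Outcome.NONE), int(Outcome.NEAR_MISS), int(Outcome.ACCIDENT)
_IMPROVEMENT_MADE = int(management.InspectionResult.IMPROVEMENT_MADE)
_FEEDBACK_GIVEN = int(management.InspectionResult.FEEDBACK_GIVEN)


@dataclass
class RunResult:
    """Raw output of one simulation run."""

    seed: Any
    totals: dict[str, float]
    # per-worker aggregates (for the validation regressions)
    crew_of_worker: np.ndarray
    ar_mean: np.ndarray
    own_violations: np.ndarray
    coworker_violations: np.ndarray
    ambivalence_mean: np.ndarray  # per crew
    pressure_mean: np.ndarray  # per crew
    # small daily series (diagnostics)
    daily: pd.DataFrame
    # optional detailed logs
    events: pd.DataFrame | None = None
    sd_trace: pd.DataFrame | None = None
    panel: pd.DataFrame | None = None


@dataclass(frozen=True)
class MetricsReport:
    """The summary statistics reported for a run.

    * ``ratio_safety_violations``: violations per worker per day;
    * ``prop_situational``: situational share of all violations;
    * ``rate_accidents`` / ``rate_near_misses``: incidents per 100
      full-time workers over the horizon (one work-year by default);
    * ``acc_to_nm_ratio``: near-misses per accident (NaN when no accident);
    * ``rate_productivity``: completed workload per active worker-day.
    """

    ratio_safety_violations: float
    prop_situational: float
    rate_accidents: float
    rate_near_misses: float
    acc_to_nm_ratio: float
    rate_productivity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ratio_safety_violations": self.ratio_safety_violations,
            "prop_situational": self.prop_situational,
            "rate_accidents": self.rate_accidents,
            "rate_near_misses": self.rate_near_misses,
            "acc_to_nm_ratio": self.acc_to_nm_ratio,
            "rate_productivity": self.rate_productivity,
        }


class _Simulation:
    """Mutable state of one run; array-of-fields layout for speed."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator,
                 collect_logs: bool):
        self.cfg = config
        self.rng = rng
        self.collect_logs = collect_logs
        self.site: SiteGrid = generate_site(config.site, rng)

        W, C = config.n_workers, config.n_crews
        self.W, self.C = W, C
        self.crew_size = config.crew_size
        self.crew = np.arange(W) // self.crew_size

        bidx = self.site.building_idx
        self.pos = bidx[rng.integers(bidx.size, size=W)]
        self.state = np.full(W, _APPROACHING, dtype=np.int8)
        self.remaining = np.zeros(W)
        self.tick_rate = np.zeros(W)  # workload-units per tick for current task
        self.task_mode = np.zeros(W, dtype=np.int8)
        self.task_haz = np.zeros(W)
        self.task_load = np.zeros(W, dtype=np.int64)
        self.stop_ticks = np.zeros(W, dtype=np.int64)

        self.ar, self.cp = draw_initial_workers(
            W, config.worker, config.median_contagion_pro, rng
        )
        # crew tolerance starts at the crew mean of initial acceptable hazards
        crew_mean_ar = np.bincount(self.crew, weights=self.ar, minlength=C) / self.crew_size
        self.tc = crew_mean_ar[self.crew].copy()

        self.base_tick_rate = config.worker.production_speed / config.ticks_per_day

        m = config.worker.memory_days
        self.mem = m
        self.tasks_ring = np.zeros((W, m))
        self.expo_ring = np.zeros((W, m))
        self.violc_ring = np.zeros((W, m))
        self.violh_ring = np.zeros((W, m))

        win = config.sd.incident_window_days
        self.sd_win = win
        self.crew_viol_ring = np.zeros((C, win))
        self.crew_fb_ring = np.zeros((C, win))
        self.crew_impr_ring = np.zeros((C, win))
        self.crew_prod_ring = np.zeros((C, win))
        self.near_ring = np.zeros(win)
        self.acc_ring = np.zeros(win)

        self.members = [np.flatnonzero(self.crew == k) for k in range(C)]
        self.mgr_cell = np.zeros(C, dtype=np.int64)
        management.position_managers(
            self.mgr_cell, self.pos, self.crew, np.ones(W, dtype=bool), rng
        )
        self._buf = DrawBuffer()
        self._bufrng = BufferedUniform(self._buf, rng)
        # daily management outputs (initialized on day 0 by the SD update)
        self.fb_rate = 0.0
        self.impr_rate = 0.0
        self.distance = 0.0
        self.tm = 0.0
        self.w_crew = np.zeros(C)

        # counters
        self.n_tasks = 0
        self.n_routine = 0
        self.n_situational = 0
        self.n_near = 0
        self.n_accidents = 0
        self.n_feedback = 0
        self.n_improvement = 0
        self.n_averted = 0
        self.stopped_ticks_total = 0
        self.work_done = np.zeros(W)
        self._work_snapshot = np.zeros(W)
        self.own_viol = np.zeros(W, dtype=np.int64)
        self.ar_day_sum = np.zeros(W)
        self.w_day_sum = np.zeros(C)
        self.pp_day_sum = np.zeros(C)

        self.daily_rows: list[tuple] = []
        self.event_rows: list[tuple] = [] if collect_logs else None  # type: ignore
        self.sd_rows: list[tuple] = [] if collect_logs else None  # type: ignore
        self.panel_rows: list[np.ndarray] = [] if collect_logs else None  # type: ignore

    # ------------------------------------------------------------------ daily

    def run(self) -> None:
        for day in range(self.cfg.horizon_days):
            self._begin_day(day)
            for _ in range(self.cfg.ticks_per_day):
                self._tick()
            self._end_day(day)

    def _begin_day(self, day: int) -> None:
        cfg = self.cfg
        # clear the ring slots that will accumulate today's events; the
        # remaining slots then hold exactly the trailing windows
        self.mcol = day % self.mem
        self.tasks_ring[:, self.mcol] = 0.0
        self.expo_ring[:, self.mcol] = 0.0
        self.violc_ring[:, self.mcol] = 0.0
        self.violh_ring[:, self.mcol] = 0.0
        self.scol = day % self.sd_win
        for ring in (self.crew_viol_ring, self.crew_fb_ring,
                     self.crew_impr_ring, self.crew_prod_ring):
            ring[:, self.scol] = 0.0
        self.near_ring[self.scol] = 0.0
        self.acc_ring[self.scol] = 0.0

        # ---- phase 1: system dynamics ----
        viol7 = self.crew_viol_ring.sum(axis=1)
        fb7 = self.crew_fb_ring.sum(axis=1)
        impr7 = self.crew_impr_ring.sum(axis=1)
        prod7 = self.crew_prod_ring.sum(axis=1) / self.crew_size
        ss = sysdyn.perceived_social_support(impr7, fb7, viol7, cfg.sd.support_scaling)
        pp = sysdyn.perceived_production_pressure(
            prod7, float(prod7.mean()), cfg.sd.pressure_scaling
        )
        self.w_crew = sysdyn.attitudinal_ambivalence(
            pp, ss, cfg.sd.ambivalence_pp_coeff, cfg.sd.ambivalence_ss_coeff
        )
        gap, scp = sysdyn.safety_control_pressure(
            float(self.near_ring.sum()), float(self.acc_ring.sum()),
            cfg.sd.safe_goal, cfg.sd.accident_weight,
        )
        out = sysdyn.management_outputs(cfg.sd.proac_man, scp, cfg.sd.distance_scale)
        self.fb_rate = out.safety_feedback_rate
        self.impr_rate = out.safety_improvement_rate
        self.distance = out.distance
        self.tm = out.tolerable_hazard
        self.w_day_sum += self.w_crew
        self.pp_day_sum += pp
        if self.sd_rows is not None:
            for k in range(self.C):
                self.sd_rows.append((day, k, viol7[k], fb7[k], impr7[k], prod7[k],
                                     ss[k], pp[k], self.w_crew[k], gap, scp,
                                     self.fb_rate, self.distance, self.tm))

        # ---- phase 2: social contagion ----
        tasks_m = self.tasks_ring.sum(axis=1)
        mode = cfg.coworker_index
        if mode == "exposure":
            num = self.expo_ring.sum(axis=1)
            den = tasks_m
        elif mode == "violation_load":
            num = self.violh_ring.sum(axis=1)
            den = tasks_m
        else:  # violation_mean
            num = self.violh_ring.sum(axis=1)
            den = self.violc_ring.sum(axis=1)
        idx = np.divide(num, den, out=np.zeros(self.W), where=den > 0)
        crew_idx_sum = np.bincount(self.crew, weights=idx, minlength=self.C)
        crew_tasks = np.bincount(self.crew, weights=tasks_m, minlength=self.C)
        cow_mean = (crew_idx_sum[self.crew] - idx) / (self.crew_size - 1)
        # no observable coworker behaviour yet (first day): hold tolerances
        observable = (crew_tasks[self.crew] - tasks_m) > 0
        m = self.cfg.worker.memory_days
        tc_new = (1.0 - 1.0 / m) * self.tc + (1.0 / m) * cow_mean
        self.tc = np.where(observable, tc_new, self.tc)
        tm_blend = (
            100.0 * cfg.sd.proac_man if cfg.sd.contagion_tm == "policy" else self.tm
        )
        tr = self.w_crew[self.crew] * self.tc + (1.0 - self.w_crew[self.crew]) * tm_blend
        ar_new = np.clip((1.0 - self.cp) * self.ar + self.cp * tr, 0.0, HAZARD_MAX)
        self.ar = np.where(observable, ar_new, self.ar)
        if self.panel_rows is not None:
            self.panel_rows.append(np.column_stack([
                np.full(self.W, day), np.arange(self.W), self.tc, tr, self.ar,
                self.w_crew[self.crew], np.full(self.W, self.tm),
            ]))
        self._today = day

    def _end_day(self, day: int) -> None:
        today_work = self.work_done - self._work_snapshot
        self._work_snapshot = self.work_done.copy()
        self.crew_prod_ring[:, self.scol] = np.bincount(
            self.crew, weights=today_work, minlength=self.C
        )
        self.ar_day_sum += self.ar
        self.daily_rows.append((
            day, float(self.ar.mean()), self.tm,
            self.n_routine + self.n_situational, self.n_accidents,
        ))

    # ------------------------------------------------------------------ ticks

    def _tick(self) -> None:
        rng = self.rng
        self.site.rotate_cranes(rng)

        stopped = np.flatnonzero(self.state == _STOPPED)
        if stopped.size == 0:
            # patrol-by-sampling fast path: every crew member is active
            buf, pos, members = self._buf, self.pos, self.members
            for k in range(self.C):
                mk = members[k]
                self.mgr_cell[k] = pos[mk[buf.integer(rng, mk.size)]]
        else:
            management.position_managers(
                self.mgr_cell, self.pos, self.crew, self.state != _STOPPED, rng
            )
        if stopped.size:
            self.stopped_ticks_total += stopped.size
            self.stop_ticks[stopped] -= 1
            resumed = stopped[self.stop_ticks[stopped] <= 0]
            if resumed.size:
                self.state[resumed] = _APPROACHING

        appr = np.flatnonzero(self.state == _APPROACHING)

        impl = np.flatnonzero(self.state == _IMPLEMENTING)
        if impl.size:
            before = self.remaining[impl]
            progress = np.minimum(self.tick_rate[impl], before)
            self.remaining[impl] = before - progress
            self.work_done[impl] += progress
            done_mask = self.remaining[impl] <= _EPS
            done = impl[done_mask]
            if done.size:
                leftover = self.tick_rate[done] - progress[done_mask]
                for j, i in enumerate(done):
                    self._finish_and_continue(int(i), float(leftover[j]))

        for i in appr:
            self._approach_step(int(i))

    def _approach_step(self, i: int) -> None:
        """One movement step; on reaching workload, start and work the task."""
        rng = self.rng
        nb = self.site.neighbors_building[self.pos[i]]
        if nb.size:
            cand = nb[self.site.workload[nb] > 0]
        else:
            cand = nb
        if cand.size:
            self.pos[i] = cand[self._buf.integer(rng, cand.size)]
            self._start_task(i)
            budget = self.tick_rate[i]
            p = min(budget, self.remaining[i])
            self.remaining[i] -= p
            self.work_done[i] += p
            if self.remaining[i] <= _EPS:
                self._finish_and_continue(i, budget - p)
        else:
            walk = self.site.neighbors_walkable[self.pos[i]]
            if walk.size:
                self.pos[i] = walk[self._buf.integer(rng, walk.size)]

    def _start_task(self, i: int) -> None:
        """Run the decision chain (situational check, inspection gate,
        safety check) and set up the task."""
        rng = self.rng
        cell = int(self.pos[i])
        h = float(self.site.effective_hazard[cell])
        constraint = bool(self.site.has_constraint[cell])
        pending_routine = h < self.ar[i]

        # cell indices are flat: x = idx % width, y = idx // width
        mgr = int(self.mgr_cell[self.crew[i]])
        dist = management.chebyshev(
            mgr % self.site.width, mgr // self.site.width,
            cell % self.site.width, cell // self.site.width,
        )
        res = management.inspect_worker(
            dist, self.distance, h, self.tm, constraint, pending_routine,
            self.impr_rate, self.fb_rate, self._bufrng,
        )
        crew_id = int(self.crew[i])
        if res == _IMPROVEMENT_MADE:
            constraint = False
            self.n_improvement += 1
            self.crew_impr_ring[crew_id, self.scol] += 1

        if constraint:
            mode = _SITUATIONAL
        elif pending_routine:
            if res == _FEEDBACK_GIVEN:
                self.n_feedback += 1
                self.n_averted += 1
                self.crew_fb_ring[crew_id, self.scol] += 1
                mode = _NORMAL
            else:
                mode = _ROUTINE
        else:
            mode = _NORMAL

        self.task_mode[i] = mode
        self.task_haz[i] = h
        load = int(self.site.workload[cell])
        self.task_load[i] = load
        self.remaining[i] = float(load)
        # claim the cell's workload up front so concurrent workers never
        # double-consume it; under replenishment the cell is redrawn at once
        self.site.consume(cell, float(load), rng)
        rate = self.base_tick_rate
        if mode != _NORMAL:
            rate *= 1.0 + self.cfg.worker.production_incr
        self.tick_rate[i] = rate
        self.state[i] = _IMPLEMENTING

    def _finish_and_continue(self, i: int, leftover: float) -> None:
        """Complete the current task; with residual-carry enabled, roll the
        unused fraction of the tick into the next task."""
        carry = self.cfg.worker.carry_residual_work
        self._complete_task(i)
        if not carry:
            return
        rng = self.rng
        while leftover > _EPS and self.state[i] == _APPROACHING:
            nb = self.site.neighbors_building[self.pos[i]]
            cand = nb[self.site.workload[nb] > 0] if nb.size else nb
            if not cand.size:
                break
            self.pos[i] = cand[self._buf.integer(rng, cand.size)]
            self._start_task(i)
            p = min(leftover, self.remaining[i])
            self.remaining[i] -= p
            self.work_done[i] += p
            leftover -= p
            if self.remaining[i] <= _EPS:
                self._complete_task(i)

    def _complete_task(self, i: int) -> None:
        rng = self.rng
        cfg = self.cfg
        cell = int(self.pos[i])
        mode = int(self.task_mode[i])
        h = float(self.task_haz[i])
        crew_id = int(self.crew[i])

        self.n_tasks += 1
        self.tasks_ring[i, self.mcol] += 1
        self.expo_ring[i, self.mcol] += h

        outcome = _NONE
        ar_before = self.ar[i]
        if mode != _NORMAL:
            self.violc_ring[i, self.mcol] += 1
            self.violh_ring[i, self.mcol] += h
            self.crew_viol_ring[crew_id, self.scol] += 1
            self.own_viol[i] += 1
            if mode == _ROUTINE:
                self.n_routine += 1
            else:
                self.n_situational += 1
            p_acc = cfg.outcome.p_accident_at_max * h / HAZARD_MAX
            u = self._buf.uniform(rng)
            if u < p_acc:
                outcome = _ACCIDENT
            elif u < p_acc * (1.0 + cfg.outcome.nearmiss_multiplier):
                outcome = _NEAR_MISS
            if outcome == _NEAR_MISS:
                self.n_near += 1
                self.near_ring[self.scol] += 1
                self.ar[i] = max(0.0, self.ar[i] - cfg.worker.nearmiss_decrement)
            elif outcome == _ACCIDENT:
                self.n_accidents += 1
                self.acc_ring[self.scol] += 1
                self.ar[i] = max(0.0, self.ar[i] - cfg.worker.accident_decrement)
                self.state[i] = _STOPPED
                self.stop_ticks[i] = cfg.worker.accident_stop_days * cfg.ticks_per_day

        if self.state[i] != _STOPPED:
            self.state[i] = _APPROACHING
        if self.event_rows is not None:
            self.event_rows.append((
                self._today, i, crew_id, cell % self.site.width,
                cell // self.site.width, h, int(mode), int(outcome),
                ar_before, self.ar[i],
            ))

    # ------------------------------------------------------------------ output

    def result(self, seed: Any) -> RunResult:
        cfg = self.cfg
        H = cfg.horizon_days
        crew_viol_total = np.bincount(self.crew, weights=self.own_viol, minlength=self.C)
        totals = {
            "n_tasks": self.n_tasks,
            "n_routine": self.n_routine,
            "n_situational": self.n_situational,
            "n_violations": self.n_routine + self.n_situational,
            "n_near_misses": self.n_near,
            "n_accidents": self.n_accidents,
            "n_feedback": self.n_feedback,
            "n_improvement": self.n_improvement,
            "n_averted": self.n_averted,
            "completed_workload": float(self.work_done.sum()),
            "stopped_worker_days": self.stopped_ticks_total / cfg.ticks_per_day,
            "worker_days": cfg.n_workers * H,
        }
        daily = pd.DataFrame(
            self.daily_rows,
            columns=["day", "mean_ar", "tolerable_hazard", "cum_violations", "cum_accidents"],
        )
        events = sd_trace = panel = None
        if self.event_rows is not None:
            events = pd.DataFrame(self.event_rows, columns=[
                "day", "worker", "crew", "x", "y", "hazard", "mode", "outcome",
                "ar_before", "ar_after",
            ])
            sd_trace = pd.DataFrame(self.sd_rows, columns=[
                "day", "crew", "violations_7d", "feedback_7d", "improvements_7d",
                "productivity_7d", "social_support", "production_pressure",
                "ambivalence", "performance_gap", "control_pressure",
                "feedback_rate", "distance", "tolerable_hazard",
            ])
            panel = pd.DataFrame(
                np.concatenate(self.panel_rows),
                columns=["day", "worker", "tc", "tr", "ar", "w", "tm"],
            )
        return RunResult(
            seed=seed,
            totals=totals,
            crew_of_worker=self.crew.copy(),
            ar_mean=self.ar_day_sum / H,
            own_violations=self.own_viol.copy(),
            coworker_violations=crew_viol_total[self.crew] - self.own_viol,
            ambivalence_mean=self.w_day_sum / H,
            pressure_mean=self.pp_day_sum / H,
            daily=daily,
            events=events,
            sd_trace=sd_trace,
            panel=panel,
        )


def run_simulation(
    config: SimulationConfig, seed: int | np.random.SeedSequence,
    collect_logs: bool = False,
) -> RunResult:
    """Execute one full run; fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    sim = _Simulation(config, rng, collect_logs)
    sim.run()
    return sim.result(seed)


def compute_metrics(result: RunResult, config: SimulationConfig) -> MetricsReport:
    """Condense a run into the standard summary metrics."""
    t = result.totals
    worker_days = t["worker_days"]
    violations = t["n_violations"]
    active_days = worker_days - t["stopped_worker_days"]
    per100 = 100.0 / config.n_workers
    return MetricsReport(
        ratio_safety_violations=violations / worker_days,
        prop_situational=(t["n_situational"] / violations) if violations else float("nan"),
        rate_accidents=t["n_accidents"] * per100,
        rate_near_misses=t["n_near_misses"] * per100,
        acc_to_nm_ratio=(t["n_near_misses"] / t["n_accidents"])
        if t["n_accidents"] else float("nan"),
        rate_productivity=t["completed_workload"] / active_days,
    )


def aggregate(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Across-replicate mean, SD and standard error for every metric.

    NaN entries (e.g. the near-miss : accident ratio of an accident-free
    run) are excluded metric-wise.
    """
    if len(reports) < 2:
        raise ValueError("aggregate requires at least two replicate reports")
    frame = pd.DataFrame([r.as_dict() for r in reports])
    out = pd.DataFrame({
        "mean": frame.mean(),
        "sd": frame.std(ddof=1),
    })
    out["se"] = out["sd"] / np.sqrt(frame.notna().sum())
    return out


def run_replicates(
    config: SimulationConfig, n_runs: int, seed: int | tuple[int, ...],
    collect_logs: bool = False,
) -> list[RunResult]:
    """Run ``n_runs`` independent replicates with seeds derived from ``seed``."""
    base = seed if isinstance(seed, tuple) else (seed,)
    return [
        run_simulation(config, np.random.SeedSequence((*base, k)), collect_logs)
        for k in range(n_runs)
    ]
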