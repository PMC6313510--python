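"""Configuration objects for the crew-safety contagion simulator.

Every tunable of the model lives here, grouped by the part of the model it
parameterizes: the virtual site, the worker agents, the violation-outcome
law, the system-level (management) dynamics, and the overall run.  Defaults
reproduce the baseline study conditions: a 92 x 84 m site with 3600 building
cells under a Triangular(0, 100, 200) hazard field, 100 workers in 5 crews
of 20, one manager per crew, and a 250 work-day horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

HAZARD_MAX = 200.0
WORKLOAD_MAX = 20

#: Calibrated violation-outcome constants.  ``ALPHA`` is the probability
#: that a violation committed at the maximum hazard (200) ends in an
#: accident; ``NEARMISS_MULT`` scales the near-miss probability relative to
#: the accident probability (the Heinrich-like pyramid ratio); ``KAPPA``
#: scales the workload-proportional probability that a task carries a
#: situational constraint.  See docs/methods.md for the calibration
#: procedure that produced these values.
ALPHA_DEFAULT = 1.9e-3
NEARMISS_MULT_DEFAULT = 8.18
KAPPA_DEFAULT = 0.036


class ConfigurationError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass(frozen=True)
class SiteConfig:
    """Geometry and hazard law of the cell-based virtual construction site.

    The site is a ``grid_width`` x ``grid_height`` grid of 1 m^2 cells of
    which exactly ``n_building_cells`` are buildings under construction,
    arranged as four 30 x 30 blocks separated by two road corridors.  Each
    building cell carries an integer workload in ``1..workload_max`` and a
    static hazard drawn from Triangular(0, hazard_mode, 200).  Three tower
    cranes sweep dynamic danger zones (hazard 160-200) under their jibs.
    """

    grid_width: int = 92
    grid_height: int = 84
    n_building_cells: int = 3600
    workload_max: int = WORKLOAD_MAX
    hazard_mode: float = 100.0  # triangular mode: 50 (low) / 100 (modest) / 150 (high)
    n_cranes: int = 3
    crane_hazard_low: float = 160.0
    crane_hazard_high: float = 200.0
    jib_length: float = 20.0
    crane_step_deg: float = 15.0
    replenish: bool = True
    #: probability that a freshly (re)drawn cell carries a situational
    #: constraint: ``constraint_coeff * workload / workload_max``.
    constraint_coeff: float = KAPPA_DEFAULT

    def __post_init__(self) -> None:
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if not 0.0 < self.hazard_mode < HAZARD_MAX:
            raise ConfigurationError(
                f"hazard_mode must lie strictly inside (0, {HAZARD_MAX})"
            )
        if self.n_building_cells != 3600:
            raise ConfigurationError("site layout provides exactly 3600 building cells")
        if not 0.0 <= self.constraint_coeff <= 1.0:
            raise ConfigurationError("constraint_coeff must be a probability scale in [0, 1]")
        if not (0.0 <= self.crane_hazard_low <= self.crane_hazard_high <= HAZARD_MAX):
            raise ConfigurationError("crane hazard range must lie within [0, 200]")
        if 360.0 % self.crane_step_deg != 0.0:
            raise ConfigurationError("crane_step_deg must divide 360")


@dataclass(frozen=True)
class WorkerParams:
    """Behavioural parameters shared by all worker agents.

    ``acceptable_hazard`` (the risk-homeostasis set point AR_i) is drawn
    uniformly on ``ar_init_range`` and the contagion probability on
    ``contagion_pro_range``; both express worker heterogeneity.  A compliant
    worker completes ``production_speed`` workload-units per day; a violating
    task runs ``1 + production_incr`` times faster.  Near-misses and
    accidents lower AR_i by ``nearmiss_decrement`` / ``accident_decrement``
    and an accident stops the worker for ``accident_stop_days``.
    """

    ar_init_range: tuple[float, float] = (20.0, 180.0)
    contagion_pro_range: tuple[float, float] = (0.1, 0.9)
    production_speed: float = 20.0  # workload-units per day
    production_incr: float = 0.2  # fractional speed gain while violating
    memory_days: int = 28
    nearmiss_decrement: float = 5.0
    accident_decrement: float = 50.0
    accident_stop_days: int = 3
    #: carry unused capacity of a task's completion tick into the next task.
    #: ``False`` (the default) loses the fractional remainder of the tick in
    #: which a task completes, mimicking discrete task hand-offs; ``True``
    #: models perfectly continuous work (per-worker daily output is then
    #: exactly ``production_speed`` under full compliance).
    carry_residual_work: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ar_init_range
        if not 0.0 <= lo <= hi <= HAZARD_MAX:
            raise ConfigurationError("ar_init_range must lie within [0, 200]")
        plo, phi = self.contagion_pro_range
        if not 0.0 <= plo <= phi <= 1.0:
            raise ConfigurationError("contagion_pro_range must lie within [0, 1]")
        if self.production_speed <= 0:
            raise ConfigurationError("production_speed must be positive")
        if self.production_incr < 0:
            raise ConfigurationError("production_incr must be non-negative")
        if self.memory_days < 1:
            raise ConfigurationError("memory_days must be >= 1")


@dataclass(frozen=True)
class OutcomeParams:
    """Probability law for the three outcomes of a committed violation.

    A violation at effective hazard ``h`` ends in an accident with
    probability ``p_accident_at_max * h / 200`` and in a near-miss with
    ``nearmiss_multiplier`` times that probability; otherwise the only
    consequence is the production gain already applied.  ``constraint_coeff``
    is the situational-constraint scale (mirrored into :class:`SiteConfig`).
    """

    p_accident_at_max: float = ALPHA_DEFAULT
    nearmiss_multiplier: float = NEARMISS_MULT_DEFAULT
    constraint_coeff: float = KAPPA_DEFAULT

    def __post_init__(self) -> None:
        total_at_max = self.p_accident_at_max * (1.0 + self.nearmiss_multiplier)
        if not 0.0 <= total_at_max <= 1.0:
            raise ConfigurationError(
                "accident + near-miss probability exceeds 1 at maximum hazard"
            )
        if not 0.0 <= self.constraint_coeff <= 1.0:
            raise ConfigurationError("constraint_coeff must lie in [0, 1]")


@dataclass(frozen=True)
class SDParams:
    """Inputs and constants of the system-level (management) dynamics.

    ``safe_goal`` is the weekly tolerable weighted incident count
    (near-misses + 10 x accidents) and ``proac_man`` the intensity of
    proactive management; together they set the safety-feedback rate, the
    safety-improvement rate, the inspection distance and the management
    hazard tolerance each day.  The 0.68 / 0.13 ambivalence weights come
    from an empirical path model of production pressure and safety-specific
    social support.
    """

    safe_goal: float = 1.25
    proac_man: float = 0.5
    support_scaling: float = 100.0
    pressure_scaling: float = 100.0
    distance_scale: float = 10.0  # inspection radius = scale * max(1-proacMan, SCP)
    incident_window_days: int = 7
    ambivalence_pp_coeff: float = 0.68
    ambivalence_ss_coeff: float = 0.13
    accident_weight: float = 10.0
    #: which management tolerance enters the worker-side tolerance blend:
    #: ``"policy"`` uses the standing proactive level (100 x proacMan) --
    #: workers perceive the formal rulebook; ``"dynamic"`` uses the daily
    #: SCP-modulated inspection tolerance.  Inspection always uses the
    #: dynamic value.  See docs/methods.md.
    contagion_tm: str = "policy"

    def __post_init__(self) -> None:
        if self.safe_goal <= 0:
            raise ConfigurationError("safe_goal must be positive")
        if not 0.0 <= self.proac_man <= 1.0:
            raise ConfigurationError("proac_man must lie in [0, 1]")
        if self.incident_window_days < 1:
            raise ConfigurationError("incident_window_days must be >= 1")
        if self.contagion_tm not in ("policy", "dynamic"):
            raise ConfigurationError("contagion_tm must be 'policy' or 'dynamic'")


#: How a worker summarizes a coworker's observable behaviour over the memory
#: window (the index averaged in the crew-tolerance update):
#:
#: ``"exposure"``       mean effective hazard over all completed tasks -- the
#:                      hazard coworkers are seen working under (default, see
#:                      docs/methods.md for why this reading is used);
#: ``"violation_load"`` sum of violation hazards divided by completed tasks;
#: ``"violation_mean"`` mean hazard over violations only.
COWORKER_INDEX_MODES = ("exposure", "violation_load", "violation_mean")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation run."""

    n_workers: int = 100
    n_crews: int = 5
    horizon_days: int = 250  # one work-year
    ticks_per_day: int = 10
    median_contagion_pro: float = 0.5
    coworker_index: str = "exposure"
    site: SiteConfig = field(default_factory=SiteConfig)
    worker: WorkerParams = field(default_factory=WorkerParams)
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    sd: SDParams = field(default_factory=SDParams)

    def __post_init__(self) -> None:
        if self.n_crews <= 0 or self.n_workers % self.n_crews != 0:
            raise ConfigurationError("n_workers must split evenly into n_crews")
        if self.crew_size < 2:
            raise ConfigurationError("crews need at least 2 workers for contagion")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be >= 1")
        if self.ticks_per_day < 1:
            raise ConfigurationError("ticks_per_day must be >= 1")
        if not 0.0 <= self.median_contagion_pro <= 1.0:
            raise ConfigurationError("median_contagion_pro must lie in [0, 1]")
        if self.coworker_index not in COWORKER_INDEX_MODES:
            raise ConfigurationError(
                f"coworker_index must be one of {COWORKER_INDEX_MODES}"
            )
        if self.site.constraint_coeff != self.outcome.constraint_coeff:
            # keep the single scientific constant in sync across both views
            object.__setattr__(
                self,
                "site",
                replace(self.site, constraint_coeff=self.outcome.constraint_coeff),
            )

    @property
    def crew_size(self) -> int:
        return self.n_workers // self.n_crews

    @property
    def n_managers(self) -> int:
        return self.n_crews

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def baseline_config(**overrides: Any) -> SimulationConfig:
    """The baseline study configuration, with optional field overrides.

    Top-level keys override :class:`SimulationConfig` fields; the
    convenience keys ``hazard_mode``, ``safe_goal``, ``proac_man`` and
    ``production_incr`` reach into the corresponding sub-configs.
    """
    site_kw: dict[str, Any] = {}
    worker_kw: dict[str, Any] = {}
    sd_kw: dict[str, Any] = {}
    if "hazard_mode" in overrides:
        site_kw["hazard_mode"] = overrides.pop("hazard_mode")
    if "production_incr" in overrides:
        worker_kw["production_incr"] = overrides.pop("production_incr")
    for key in ("safe_goal", "proac_man"):
        if key in overrides:
            sd_kw[key] = overrides.pop(key)
    site = replace(overrides.pop("site", SiteConfig()), **site_kw)
    worker = replace(overrides.pop("worker", WorkerParams()), **worker_kw)
    sd = replace(overrides.pop("sd", SDParams()), **sd_kw)
    return SimulationConfig(site=site, worker=worker, sd=sd, **overrides)
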