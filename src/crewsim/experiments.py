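"""Experiment drivers: baseline validation, one-at-a-time sensitivity and
the replicated 2^4 factorial experiment with standardized-effect analysis.

The four managed factors are the weekly safety goal (``safeGoal``), the
proactive-management intensity (``proacMan``), the median contagion
probability and the safety-productivity tradeoff (``productionIncr``).
Each factor takes a negative/positive level; the full factorial crosses all
sixteen combinations, each replicated with independent seeds, and the main
and interaction effects are ranked by their standardized (t) values against
the replicate-pooled error -- the tabular equivalent of a standardized
Pareto chart.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .config import SimulationConfig, baseline_config
from .engine import MetricsReport, aggregate, compute_metrics, run_replicates

__all__ = [
    "FactorLevels", "FEDDesign", "build_fed_design", "run_fed",
    "standardized_effects", "run_baseline_validation", "run_sensitivity",
    "RESPONSES",
]

FACTORS = ("safe_goal", "proac_man", "median_contagion_pro", "production_incr")
#: response variables tabulated per design point
RESPONSES = (
    "rate_accidents",
    "ratio_routine_violations",
    "ratio_situational_violations",
    "rate_productivity",
)


@dataclass(frozen=True)
class FactorLevels:
    """Negative / positive levels of the four factors."""

    safe_goal: tuple[float, float] = (0.5, 2.0)
    proac_man: tuple[float, float] = (0.2, 0.8)
    median_contagion_pro: tuple[float, float] = (0.2, 0.8)
    production_incr: tuple[float, float] = (0.08, 0.32)


@dataclass(frozen=True)
class FEDDesign:
    """The 16-point +/-1 coded full-factorial design matrix.

    Rows follow standard order: the first factor alternates fastest.
    """

    levels: FactorLevels = field(default_factory=FactorLevels)
    n_replicates: int = 50
    hazard_mode: float = 100.0

    @property
    def coded(self) -> np.ndarray:
        rows = [
            (a, b, c, d)
            for d, c, b, a in itertools.product((-1, 1), repeat=4)
        ]
        return np.asarray(rows, dtype=int)

    def point_config(self, row: np.ndarray, base: SimulationConfig | None = None
                     ) -> SimulationConfig:
        """Concrete simulation config for one coded design row."""
        lv = self.levels
        pick = lambda pair, code: pair[0] if code < 0 else pair[1]
        return baseline_config(
            hazard_mode=self.hazard_mode,
            safe_goal=pick(lv.safe_goal, row[0]),
            proac_man=pick(lv.proac_man, row[1]),
            median_contagion_pro=pick(lv.median_contagion_pro, row[2]),
            production_incr=pick(lv.production_incr, row[3]),
            **({} if base is None else {
                "horizon_days": base.horizon_days,
                "n_workers": base.n_workers,
                "n_crews": base.n_crews,
            }),
        )


def build_fed_design(n_replicates: int = 50, hazard_mode: float = 100.0) -> FEDDesign:
    """The published 16-row design in its printed order."""
    return FEDDesign(n_replicates=n_replicates, hazard_mode=hazard_mode)


def _metrics_row(rep: MetricsReport, totals: dict[str, float]) -> dict[str, float]:
    worker_days = totals["worker_days"]
    return {
        "rate_accidents": rep.rate_accidents,
        "ratio_routine_violations": totals["n_routine"] / worker_days,
        "ratio_situational_violations": totals["n_situational"] / worker_days,
        "rate_productivity": rep.rate_productivity,
    }


def run_fed(
    design: FEDDesign, seed: int = 0, base: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every design point.

    Returns ``(responses, raw)``: per-point mean responses in printed-table
    layout, and the per-replicate raw responses for the effects analysis.
    """
    raw_rows = []
    for p, row in enumerate(design.coded):
        cfg = design.point_config(row, base)
        for r, result in enumerate(
            run_replicates(cfg, design.n_replicates, seed=(seed, p))
        ):
            rep = compute_metrics(result, cfg)
            entry = {"design_point": p + 1, "replicate": r}
            entry.update({f: int(row[j]) for j, f in enumerate(FACTORS)})
            entry.update(_metrics_row(rep, result.totals))
            raw_rows.append(entry)
    raw = pd.DataFrame(raw_rows)
    responses = raw.groupby("design_point")[list(RESPONSES)].mean()
    return responses, raw


def standardized_effects(raw: pd.DataFrame, response: str) -> pd.DataFrame:
    """Main and interaction effects of the replicated 2^4 design.

    Fits the saturated factorial model by least squares on the +/-1 coded
    factors (all 15 orthogonal contrasts), pools the error variance from
    the within-point replicates, and reports each term's effect estimate
    (mean at +1 minus mean at -1 = twice the regression coefficient), its
    standard error, standardized effect (t value) and two-sided p value,
    sorted by |t| -- the Pareto ordering.
    """
    groups = raw.groupby("design_point")[response]
    if (groups.count() < 2).any():
        raise ValueError("standardized effects need >= 2 replicates per design point")

    X_cols: dict[str, np.ndarray] = {}
    codes = raw[list(FACTORS)].to_numpy(dtype=float)
    for order in range(1, len(FACTORS) + 1):
        for combo in itertools.combinations(range(len(FACTORS)), order):
            name = ":".join(FACTORS[j] for j in combo)
            X_cols[name] = np.prod(codes[:, combo], axis=1)
    X = sm.add_constant(pd.DataFrame(X_cols, index=raw.index))
    fit = sm.OLS(raw[response].to_numpy(), X).fit()

    terms = list(X_cols)
    table = pd.DataFrame({
        "term": terms,
        "effect": [2.0 * fit.params[t] for t in terms],
        "se": [2.0 * fit.bse[t] for t in terms],
        "standardized_effect": [fit.tvalues[t] for t in terms],
        "p_value": [fit.pvalues[t] for t in terms],
    })
    table["significant"] = table["p_value"] <= 0.05
    table["df_resid"] = int(fit.df_resid)
    return table.reindex(
        table["standardized_effect"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def run_baseline_validation(
    config: SimulationConfig | None = None, n_runs: int = 50, seed: int = 0,
    results: list | None = None,
) -> dict:
    """Replicated baseline runs plus the three validation regressions.

    Pools per-worker run output across replicates and regresses the mean
    acceptable hazard on (i) the worker's count of coworker violations,
    (ii) the crew's mean attitudinal ambivalence, and (iii) the crew's mean
    perceived production pressure; each relationship is expected to have a
    positive slope.  Pass ``results`` to reuse an existing replicate batch.
    """
    cfg = config or baseline_config()
    if results is None:
        results = run_replicates(cfg, n_runs, seed)
    reports = [compute_metrics(r, cfg) for r in results]
    summary = aggregate(reports)

    ar = np.concatenate([r.ar_mean for r in results])
    cow = np.concatenate([r.coworker_violations for r in results]).astype(float)
    amb = np.concatenate([r.ambivalence_mean[r.crew_of_worker] for r in results])
    pp = np.concatenate([r.pressure_mean[r.crew_of_worker] for r in results])
    regressions = {}
    for name, x in (
        ("coworker_violations", cow),
        ("ambivalence", amb),
        ("production_pressure", pp),
    ):
        reg = scipy.stats.linregress(x, ar)
        regressions[name] = {
            "slope": reg.slope,
            "r_squared": reg.rvalue ** 2,
            "p_value": reg.pvalue,
        }
    return {"summary": summary, "regressions": regressions,
            "reports": reports, "results": results}


SENSITIVITY_PARAMS = ("safe_goal", "proac_man", "median_contagion_pro", "production_incr")
SENSITIVITY_OUTPUTS = (
    "ratio_safety_violations", "rate_accidents", "rate_near_misses", "rate_productivity",
)


def run_sensitivity(
    config: SimulationConfig | None = None, n_runs: int = 50, seed: int = 0,
    factor: float = 1.5,
) -> dict:
    """One-at-a-time sensitivity: raise each parameter by 50% over base.

    Returns the base means and the percent change of each output against
    the base run set; replicate seeds are shared across scenarios (common
    random numbers).
    """
    cfg = config or baseline_config()

    def batch_means(c: SimulationConfig) -> pd.Series:
        reports = [compute_metrics(r, c) for r in run_replicates(c, n_runs, seed)]
        return pd.DataFrame([r.as_dict() for r in reports]).mean()

    base_means = batch_means(cfg)
    rows = {}
    for param in SENSITIVITY_PARAMS:
        if param == "median_contagion_pro":
            varied = baseline_config(
                hazard_mode=cfg.site.hazard_mode,
                safe_goal=cfg.sd.safe_goal, proac_man=cfg.sd.proac_man,
                production_incr=cfg.worker.production_incr,
                median_contagion_pro=cfg.median_contagion_pro * factor,
                horizon_days=cfg.horizon_days,
            )
        else:
            current = {
                "safe_goal": cfg.sd.safe_goal,
                "proac_man": cfg.sd.proac_man,
                "production_incr": cfg.worker.production_incr,
            }
            current[param] = current[param] * factor
            varied = baseline_config(
                hazard_mode=cfg.site.hazard_mode,
                median_contagion_pro=cfg.median_contagion_pro,
                horizon_days=cfg.horizon_days,
                **current,
            )
        means = batch_means(varied)
        rows[param] = {
            out: 100.0 * (means[out] - base_means[out]) / base_means[out]
            for out in SENSITIVITY_OUTPUTS
        }
    return {
        "base": base_means[list(SENSITIVITY_OUTPUTS)],
        "percent_change": pd.DataFrame(rows).T[list(SENSITIVITY_OUTPUTS)],
    }
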