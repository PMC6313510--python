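"""Engine-level behaviour: determinism, conservation, metrics arithmetic."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from crewsim import (
    MetricsReport,
    aggregate,
    baseline_config,
    compute_metrics,
    run_replicates,
    run_simulation,
)
from crewsim.engine import RunResult

from conftest import violations_disabled_config


def short_cfg(**kw):
    return baseline_config(horizon_days=kw.pop("horizon_days", 40), **kw)


def test_same_seed_reproduces_run_exactly():
    cfg = short_cfg()
    a = run_simulation(cfg, 12)
    b = run_simulation(cfg, 12)
    assert a.totals == b.totals
    np.testing.assert_array_equal(a.ar_mean, b.ar_mean)
    pd.testing.assert_frame_equal(a.daily, b.daily)


def test_totals_equal_event_log_aggregation():
    cfg = short_cfg(horizon_days=25)
    r = run_simulation(cfg, 8, collect_logs=True)
    ev = r.events
    assert len(ev) == r.totals["n_tasks"]
    assert (ev["mode"] > 0).sum() == r.totals["n_violations"]
    assert (ev["mode"] == 1).sum() == r.totals["n_routine"]
    assert (ev["mode"] == 2).sum() == r.totals["n_situational"]
    assert (ev["outcome"] == 1).sum() == r.totals["n_near_misses"]
    assert (ev["outcome"] == 2).sum() == r.totals["n_accidents"]
    # per-worker violation counts in the result match the log
    own = ev[ev["mode"] > 0].groupby("worker").size()
    for w, n in own.items():
        assert r.own_violations[w] == n


def test_conservation_and_bounds():
    cfg = short_cfg()
    r = run_simulation(cfg, 3)
    t = r.totals
    assert t["n_accidents"] <= t["n_violations"]
    assert t["n_near_misses"] <= t["n_violations"]
    assert t["n_feedback"] == t["n_averted"]
    # no worker can outproduce the violating speed ceiling
    ceiling = cfg.worker.production_speed * (1 + cfg.worker.production_incr)
    per_day = t["completed_workload"] / t["worker_days"]
    assert per_day <= ceiling + 1e-9
    # crew-level productivity sums to the total
    crew_work = np.bincount(
        r.crew_of_worker, weights=np.ones_like(r.ar_mean), minlength=5
    )
    assert crew_work.sum() == cfg.n_workers


def test_disabled_violations_mean_no_incidents():
    cfg = violations_disabled_config(horizon_days=20)
    r = run_simulation(cfg, 4)
    assert r.totals["n_violations"] == 0
    assert r.totals["n_accidents"] == 0
    assert r.totals["n_near_misses"] == 0


def test_accident_stoppage_removes_three_worker_days():
    """Drive the accident probability up and check stoppage accounting."""
    cfg = short_cfg(horizon_days=60)
    cfg = replace(
        cfg,
        outcome=replace(cfg.outcome, p_accident_at_max=0.05, nearmiss_multiplier=1.0),
    )
    r = run_simulation(cfg, 10)
    acc = r.totals["n_accidents"]
    assert acc > 0
    stop_days = cfg.worker.accident_stop_days
    assert r.totals["stopped_worker_days"] <= stop_days * acc + 1e-9
    # allow truncation only for accidents within the final stop window
    assert r.totals["stopped_worker_days"] >= stop_days * (acc - cfg.n_workers)
    m = compute_metrics(r, cfg)
    assert m.rate_accidents == pytest.approx(acc * 100 / cfg.n_workers)


def test_higher_proactive_value_worsens_safety():
    """Raising proacMan (laxer proactive management) increases violations
    under common random numbers."""
    lax = sum(
        r.totals["n_violations"]
        for r in run_replicates(short_cfg(proac_man=0.8, horizon_days=80), 3, 77)
    )
    strict = sum(
        r.totals["n_violations"]
        for r in run_replicates(short_cfg(proac_man=0.2, horizon_days=80), 3, 77)
    )
    assert lax > strict


def _fake_result(**totals):
    base = {
        "n_tasks": 0, "n_routine": 0, "n_situational": 0, "n_violations": 0,
        "n_near_misses": 0, "n_accidents": 0, "n_feedback": 0,
        "n_improvement": 0, "n_averted": 0, "completed_workload": 0.0,
        "stopped_worker_days": 0.0, "worker_days": 25000,
    }
    base.update(totals)
    z = np.zeros(1)
    return RunResult(seed=0, totals=base, crew_of_worker=z.astype(int), ar_mean=z,
                     own_violations=z, coworker_violations=z, ambivalence_mean=z,
                     pressure_mean=z, daily=pd.DataFrame())


def test_metric_arithmetic_from_counts():
    cfg = baseline_config()
    r = _fake_result(
        n_violations=8000, n_routine=7120, n_situational=880,
        n_near_misses=26, n_accidents=3, completed_workload=500000.0,
    )
    m = compute_metrics(r, cfg)
    assert m.ratio_safety_violations == pytest.approx(0.32)
    assert m.prop_situational == pytest.approx(0.11)
    assert m.acc_to_nm_ratio == pytest.approx(26 / 3)
    assert m.rate_accidents == pytest.approx(3.0)
    assert m.rate_productivity == pytest.approx(20.0)
    # zero accidents: the ratio is undefined, reported as missing
    m0 = compute_metrics(_fake_result(n_violations=10, n_routine=10), cfg)
    assert np.isnan(m0.acc_to_nm_ratio)


def test_aggregate_mean_and_standard_error():
    rep = lambda x: MetricsReport(x, 0.1, 3.0, 25.0, 8.0, 19.5)
    out = aggregate([rep(0.30), rep(0.34)])
    assert out.loc["ratio_safety_violations", "mean"] == pytest.approx(0.32)
    assert out.loc["rate_accidents", "sd"] == 0.0
    assert out.loc["rate_accidents", "se"] == 0.0
    with pytest.raises(ValueError):
        aggregate([rep(0.3)])
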