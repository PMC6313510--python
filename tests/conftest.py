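"""Shared fixtures.

The heavy replicate batches (baseline, sensitivity, factorial) are
session-scoped so the acceptance checks that share a batch only pay for it
once.  All seeds are fixed; every fixture is fully deterministic.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from crewsim import (
    baseline_config,
    build_fed_design,
    compute_metrics,
    run_fed,
    run_replicates,
    run_sensitivity,
)

BASELINE_SEED = 101
SENSITIVITY_SEED = 61
FED_SEED = 202


def violations_disabled_config(horizon_days: int = 30, carry: bool = False):
    """Baseline with every violation channel switched off.

    Acceptable hazard pinned at 0 (no routine violations), situational
    constraints disabled, and contagion frozen so tolerance cannot drift.
    """
    cfg = baseline_config(horizon_days=horizon_days, median_contagion_pro=0.0)
    return replace(
        cfg,
        worker=replace(
            cfg.worker,
            ar_init_range=(0.0, 0.0),
            contagion_pro_range=(0.0, 0.0),
            carry_residual_work=carry,
        ),
        outcome=replace(cfg.outcome, constraint_coeff=0.0),
    )


@pytest.fixture(scope="session")
def baseline_batch():
    """Ten baseline replicates plus their metric reports."""
    cfg = baseline_config()
    results = run_replicates(cfg, 10, seed=BASELINE_SEED)
    reports = [compute_metrics(r, cfg) for r in results]
    return cfg, results, reports


@pytest.fixture(scope="session")
def sensitivity_table():
    """+50% one-at-a-time sensitivity, 30 replicates per scenario."""
    return run_sensitivity(n_runs=30, seed=SENSITIVITY_SEED)


@pytest.fixture(scope="session")
def fed_batches():
    """Replicated 2^4 factorial at the three hazard conditions (10 reps)."""
    out = {}
    for label, mode in (("low", 50.0), ("modest", 100.0), ("high", 150.0)):
        design = build_fed_design(n_replicates=10, hazard_mode=mode)
        out[label] = run_fed(design, seed=FED_SEED)
    return out
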