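# crewsim

A hybrid system-dynamics / agent-based simulator of the **social contagion
of safety violations** within construction crews.

Construction workers break safety rules mostly intentionally — to save
time or effort — and such violations spread socially: workers who see
coworkers cut corners raise their own tolerance for hazard.  `crewsim`
models this on a cell-based virtual site (92 × 84 m, 3600 building cells
with workloads, a triangular hazard field, and rotating crane danger
zones): 100 workers in 5 crews decide per task whether to violate, one
manager per crew inspects within a limited distance and probability, and a
system-dynamics layer turns the week's violations, incidents and
productivity into the management parameters and crew ambivalence that
re-parameterize the agents each day.

The core of the model is risk homeostasis plus contagion.  Worker *i*
violates when the perceived hazard *h* of the current cell falls below
their acceptable hazard AR_i(t), which assimilates daily toward the
tolerance they perceive around them:

    TC_i(t) = (1 − 1/m) · TC_i(t−1) + (1/m) · mean_c HA_c(t)        (crew norm, memory m = 28 d)
    TR_i(t) = w_i(t) · TC_i(t) + (1 − w_i(t)) · TM                  (ambivalence blend)
    AR_i(t) = (1 − cp_i) · AR_i(t−1) + cp_i · TR_i(t)               (contagion probability cp_i)

Violating tasks run 20% faster (the safety–productivity tradeoff) but
draw an accident with probability α·h/200 and a near-miss with r·α·h/200.
Accidents stop the worker for 3 days and slash AR_i; the weekly incident
tally feeds back into safety control pressure, inspection intensity and
tolerance.  See `docs/methods.md` for the full model description and the
calibration of (α, r, κ).

## Worked example

```python
from crewsim import baseline_config, run_simulation, compute_metrics

cfg = baseline_config()              # 100 workers, modest hazard, one work-year
result = run_simulation(cfg, seed=0)
print(compute_metrics(result, cfg).as_dict())
```

```
{'ratio_safety_violations': 0.31104,
 'prop_situational': 0.10558127572016461,
 'rate_accidents': 2.0,
 'rate_near_misses': 26.0,
 'acc_to_nm_ratio': 13.0,
 'rate_productivity': 19.508650076018235}
```

Reading this run: workers committed 0.31 safety violations per worker per
day, about one-ninth of them driven by situational constraints rather than
deliberate corner-cutting; 2 accidents and 26 near-misses occurred per 100
full-time workers over the simulated work-year (the per-run incident ratio
is noisy at these counts — averaged over 50 replicates it settles near
1 : 8.2); and each worker completed ≈19.5 workload-units per day against a
nominal speed of 20.

The same entry points drive the studies: `run_baseline_validation`
(replicated baseline plus regressions of AR_i on coworker violations,
ambivalence and production pressure), `run_sensitivity` (+50%
one-at-a-time), and `build_fed_design` / `run_fed` /
`standardized_effects` (the replicated 2⁴ factorial with a
standardized-effect table per response).  A thin CLI wraps them:

```bash
crewsim run --seed 0 --out out/          # one run: events.csv, sd_trace.csv, metrics.json
crewsim baseline --runs 50 --seed 0
crewsim sensitivity --runs 50 --seed 0
crewsim fed --hazard-mode modest --runs 50 --seed 0 --out fed_out/
crewsim config                           # dump the baseline configuration
```

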