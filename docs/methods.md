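# Model and methods

`crewsim` simulates how safety violations spread through construction work
crews, coupling an agent-based layer (workers and safety managers on a
cell-based site) with a system-dynamics layer (daily stocks and management
feedback).  This note records the model, its parameters, the numerical
choices, and the known limitations — in particular which published
behaviours the model does and does not reproduce.

## The virtual site

The site is a 92 × 84 grid of 1 m² cells.  Exactly 3600 cells are buildings
under construction, laid out as four 30 × 30 blocks separated by two road
corridors (safety metrics aggregate over the site, so any layout with the
right cell count is equivalent).  Each building cell carries

* an integer workload in 1..20 (uniform), the work required to finish it;
* a static hazard drawn from Triangular(0, mode, 200) with mode 50 / 100 /
  150 for the low / modest / high hazard conditions;
* with probability `κ · workload/20`, a situational constraint — an
  unintentional block (missing equipment, adverse conditions) that makes
  compliant work impractical.

Three tower cranes rotate 15° per tick with a 20-cell jib; cells under the
jib sector carry a dynamic hazard drawn U(160, 200).  A cell's effective
hazard is the maximum of its static and crane hazard.  When a cell's
workload is claimed, the cell is immediately redrawn (workload, hazard,
constraint) so that a year-long run has a stationary supply of work; this
models a project in steady state rather than one burning down a fixed
scope.  Claiming happens when a task starts, so two workers sharing a cell
can never double-count its workload.

## Worker agents

100 workers form 5 crews of 20.  A worker is approaching (walking),
implementing (working a claimed cell) or stopped (recovering from an
accident).  Movement is one step per tick to a uniformly chosen 8-neighbour
building cell with workload (a random walk over walkable cells when none
exists); on arrival the worker starts a task in the same tick.

At task start the worker runs the decision chain:

1. **situational check** — a present constraint (not removed by a manager)
   forces a *situational violation*;
2. **safety check** (risk homeostasis) — otherwise, if the cell's effective
   hazard is below the worker's acceptable hazard AR_i, the worker commits
   a *routine violation* unless a manager's warning averts it;
3. otherwise the task is implemented normally.

Compliant work proceeds at 20 workload-units/day; violating tasks run
`1 + productionIncr` times faster (default 1.2×) — the safety–productivity
tradeoff.  A violating task, at completion, draws one of three outcomes:
accident with probability `α·h/200`, near-miss with probability `r·α·h/200`
(h the hazard at which the violation was committed), otherwise nothing but
the speed gain.  A near-miss lowers AR_i by 5; an accident lowers it by 50
and stops the worker for 3 days.  AR_i is clamped to [0, 200].

The outcome law is the simplest monotone law consistent with "hazard 0 is
perfectly safe", and makes the expected near-miss : accident ratio equal
`r` wherever violations occur.

## Social contagion

Once per day each worker's acceptable hazard assimilates toward the
tolerance they perceive around them:

    TC_i(t) = (1 − 1/m)·TC_i(t−1) + (1/m)·mean over coworkers of HA_c(t)
    TR_i(t) = w_i(t)·TC_i(t) + (1 − w_i(t))·TM
    AR_i(t) = (1 − cp_i)·AR_i(t−1) + cp_i·TR_i(t)

with m = 28 days of memory, w_i the crew's attitudinal ambivalence, TM the
management tolerance and cp_i ~ U(0.1, 0.9) the worker's contagion
probability.  Crews are cliques; there is no cross-crew influence.  TC_i
is initialized at the crew mean of the initial AR_i ~ U(20, 180).  On the
first day, before any coworker behaviour is observable, TC and AR are held
rather than updated against an empty window.

**The coworker index HA_c.**  Three definitions are implemented
(`SimulationConfig.coworker_index`):

* `"exposure"` (default): the mean effective hazard over all tasks the
  coworker completed in the trailing 28 days — the hazard they are seen
  working under;
* `"violation_load"`: the sum of hazards at the coworker's violations
  divided by their completed tasks;
* `"violation_mean"`: the mean hazard over violations only.

The exposure index is the default because it is the only reading under
which the model reproduces the published baseline jointly: under the
violation-based readings the crew-tolerance term is bounded by the (small)
per-task violation-hazard load, the baseline violation ratio falls well
below a third, and the ambivalence and production-pressure validation
regressions come out with *negative* slopes.  With the exposure index the
baseline statistics and all three regression slopes (R² ≈ 0.2–0.36) match
the published validation.

**The management tolerance in the blend** (`SDParams.contagion_tm`).  The
system-dynamics layer produces a reactive tolerable-hazard output that
drops to 0 while the weekly safety goal is blown.  If that reactive value
enters the worker-side blend (`"dynamic"`), every accident collapses
perceived tolerance for a week and acceptable hazards crash crew-wide; the
baseline then cannot show a violation ratio near one-third while accidents
sit near 3 per 100 worker-years.  The default `"policy"` reading blends
the standing formal-rule level (100 × proacMan): workers perceive the
organization's rulebook, while inspections always use the reactive value.
This is consistent with routing the reactive tolerance output to the
manager agents and the ambivalence output to the worker agents.

## Management agents

One manager per crew patrols by sampling: each tick they relocate to a
uniformly chosen non-stopped member of their crew.  When a worker starts a
task with the manager within the inspection distance (Chebyshev) *and* the
cell hazard above the management tolerance TM, the manager intervenes at
most once: a situational constraint is removed with the safety-improvement
rate; otherwise a pending routine violation is averted with the
safety-feedback rate.  Averted violations are not counted as violations;
feedback does not alter AR_i (persuasion acts through the tolerance blend,
not the warning).

## System dynamics

Stocks are event-driven daily tallies over trailing windows (7 days; the
safety goal is a weekly quantity).  Per crew: violations, feedback,
improvements, completed workload.  Global: near-misses and accidents.
Daily auxiliaries, as fixed algebraic rules with scaling 100 (which makes
the support and pressure terms effectively binary — implemented as
printed, a scaling of 1 would produce graded values):

* social support `SS = min(1, (improvements + feedback)/violations × 100)`
  (1 when the window is violation-free);
* production pressure `PP = min(1, shortfall vs crew-average × 100)` for
  crews behind the 7-day average, else 0;
* ambivalence `w = clamp(0.68·PP − 0.13·SS, 0, 1)` (empirical path
  coefficients);
* performance gap `(near + 10·accidents − safeGoal)/safeGoal`, clamped to
  [0, 1] as the safety control pressure SCP;
* outputs: feedback and improvement rates `max(1 − proacMan, SCP)`,
  inspection distance `10 × max(1 − proacMan, SCP)` (the scale of 10
  honours the documented baseline distance of 5 at proacMan 0.5), and
  tolerable hazard `min(100·proacMan, 100·(1 − SCP))`.

## Time stepping and accounting

A day has 10 ticks of 0.1 day; production is 2 units/tick.  Tasks complete
on the tick where cumulative progress reaches the workload.  By default the
unused remainder of the completion tick is lost (`carry_residual_work =
False`): discrete hand-offs between tasks cost on average a quarter-tick.
This reproduces the published productivity levels — ≈19.04 units/worker/day
at near-zero violations and ≈19.5 at baseline, against a nominal speed of
20.  With `carry_residual_work=True` work is perfectly continuous and a
fully compliant population produces exactly 20 units/worker/day — the
accounting identity used by the corresponding test.  Contagion and system
dynamics update once per day (in that order: outputs, then adaptation,
then the day's ticks); incident decrements apply at the events themselves.

Metrics: violations per worker per day and incident rates use all
worker-days (full-time equivalence, horizon 250 work-days ≈ one work-year);
productivity divides completed workload by active (non-stopped)
worker-days.  The near-miss : accident ratio is pooled over replicates
(per-run ratios are unstable at ~3 accidents/run).

## Calibration

The outcome constants are not stated in the source model and were
calibrated once against the published baseline averages: `r = 8.18` (it
equals the expected near-miss : accident ratio by construction), then a
grid search over (α, κ) to centre the accident rate (3.16 per 100
worker-years) and the situational share (0.11): `α = 1.9e-3`,
`κ = 0.036`.  At 50 replicates the baseline reproduces: violation ratio
≈ 0.30 (published 0.32), situational share 0.110, accidents ≈ 3.0,
near-misses per accident ≈ 8.2–9.0, near-miss rate ≈ 27 (published 33.56 —
a figure internally inconsistent with the published 1:8.18 ratio times
3.16 accidents = 25.8), productivity 19.48 (published 19.35).

## Experiments

* **Baseline validation**: 50 replicates (10 in the test suite) plus three
  pooled per-worker regressions of mean AR_i on coworker-violation count,
  crew ambivalence and crew production pressure — all slopes positive.
* **Sensitivity**: each of safeGoal, proacMan, median contagionPro,
  productionIncr raised 50% one at a time, common random numbers.
* **Factorial experiment**: the 2⁴ design over safeGoal {0.5, 2}, proacMan
  {0.2, 0.8}, median contagionPro {0.2, 0.8}, productionIncr {0.08, 0.32},
  replicated (50 by default, 10 in the tests) at each of the three hazard
  conditions.  The saturated model is fitted by least squares on the ±1
  codes; the standardized effect of a term is its estimate over the
  replicate-pooled standard error, and the table is sorted by |t| — the
  tabular form of a standardized Pareto chart, with significance at the
  computed α = 0.05 t threshold rather than any externally printed line.
  The median contagionPro manipulation shifts every worker's cp by
  (M − 0.5), clamped to (0.01, 0.99), preserving the baseline spread.

## What the model reproduces, and what it does not

Reproduced (test suite and acceptance script): the baseline violation,
situational, accident, near-miss and productivity statistics; the positive
validation-regression slopes; the dominance of proactive management on
accident and routine-violation responses in all hazard conditions; the
dominance of the safety–productivity tradeoff on productivity; the
positive safeGoal × proacMan interaction; the increase of routine
violations as the ambient hazard level falls; the all-low factor
configuration being the safest.

Not reproduced — left as failing tests rather than adjusted away:

* **The contagion-probability direction.**  In this formulation the
  equilibrium perceived tolerance (≈60–80 hazard units) lies *below* the
  mean initial acceptable hazard (100), so the contagion probability only
  sets how fast workers assimilate toward a safer norm; raising it is
  neutral-to-beneficial, not harmful.  This holds for every coworker-index
  reading, with and without a warm-up, and at the factorial contrast.  A
  strongly harmful contagion probability would require the crew norm to
  sit above the workers' current tolerance at baseline, which the printed
  tolerance blend (anchored by a management tolerance of 50) cannot
  produce.  Downstream casualties: the all-high factor configuration is
  not quite the worst (the configuration with contagion at its low level
  is), and the contagion effect on routine violations shows no
  modest-hazard maximum.
* **The reactive safety-goal magnitude.**  With the policy-tolerance
  reading needed for the baseline, a +50% safeGoal moves the safety
  outputs by only ≈1% (reported: ≈19%); the direction is positive but
  undetectable at desk-scale replication.
* **Dominance of proactive management on situational violations** is
  marginal: the safeGoal channel ties with it at the modest hazard level.

## Limitations

Homogeneous skill and productivity; no hazard-recognition error; no
penalties, incentives or technology-based monitoring; no cross-crew
contagion; no material logistics or congestion on the roads.  The
synthetic site is stationary by construction (replenishment), so the model
speaks to steady-state operation, not project ramp-up or close-out.
Passing tests show the decision rules and feedback structure behave as
specified on this synthetic site; they do not validate the model against
any real project's records.
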