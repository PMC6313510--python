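"""Crew-tolerance memory, ambivalence blending and hazard-set-point
adaptation: exact hand-computed values plus convexity/monotonicity laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crewsim.contagion import (
    adapt_acceptable_hazard,
    coworker_hazard_index,
    perceived_tolerance,
    update_crew_tolerance,
)

hazards = st.floats(min_value=0.0, max_value=200.0, allow_nan=False)
weights = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def test_coworker_index_hand_values():
    # 2 violations at hazards 40 and 60 over 10 completed tasks
    assert coworker_hazard_index(100.0, 10) == pytest.approx(10.0)
    assert coworker_hazard_index(0.0, 10) == 0.0
    assert coworker_hazard_index(0.0, 0) == 0.0  # no observable behaviour
    # every one of 10 tasks violated at hazard 80: index = mean violation hazard
    assert coworker_hazard_index(800.0, 10) == pytest.approx(80.0)
    assert coworker_hazard_index(
        100.0, 10, n_violations=2, mode="violation_mean"
    ) == pytest.approx(50.0)


def test_crew_tolerance_hand_values():
    assert update_crew_tolerance(50.0, [22.0], 1) == pytest.approx(22.0)  # memoryless
    assert update_crew_tolerance(50.0, [22.0], 28) == pytest.approx(
        (27 / 28) * 50 + 22 / 28
    )
    assert update_crew_tolerance(50.0, [10.0, 20.0, 30.0], 28) == pytest.approx(
        (27 / 28) * 50 + 20 / 28
    )
    with pytest.raises(ValueError):
        update_crew_tolerance(50.0, [22.0], 0)


def test_crew_tolerance_converges_geometrically():
    """Under a constant coworker index x the memory converges to x with
    ratio (1 - 1/m) per day -- checked against the closed form."""
    m, x, tc0 = 28, 42.0, 120.0
    tc = tc0
    for day in range(1, 101):
        tc = update_crew_tolerance(tc, [x], m)
        assert tc == pytest.approx(x + (tc0 - x) * (1 - 1 / m) ** day)


def test_perceived_tolerance_hand_values():
    assert perceived_tolerance(40.0, 60.0, 1.0) == 40.0
    assert perceived_tolerance(40.0, 60.0, 0.0) == 60.0
    assert perceived_tolerance(40.0, 60.0, 0.5) == 50.0
    with pytest.raises(ValueError):
        perceived_tolerance(40.0, 60.0, 1.2)


def test_adaptation_hand_values():
    assert adapt_acceptable_hazard(100.0, 60.0, 0.0) == 100.0
    assert adapt_acceptable_hazard(100.0, 60.0, 1.0) == 60.0
    assert adapt_acceptable_hazard(100.0, 60.0, 0.5) == 80.0
    with pytest.raises(ValueError):
        adapt_acceptable_hazard(100.0, 60.0, -0.1)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(tc_prev=hazards, indices=st.lists(hazards, min_size=1, max_size=19),
       m=st.integers(min_value=1, max_value=60))
def test_crew_tolerance_is_convex_combination(tc_prev, indices, m):
    out = float(update_crew_tolerance(tc_prev, indices, m))
    lo = min(tc_prev, min(indices))
    hi = max(tc_prev, max(indices))
    assert lo - 1e-9 <= out <= hi + 1e-9


@settings(max_examples=100, deadline=None, derandomize=True)
@given(tc=hazards, tm=hazards, w=weights, ar=hazards, cp=weights)
def test_blend_and_adaptation_stay_within_input_range(tc, tm, w, ar, cp):
    tr = float(perceived_tolerance(tc, tm, w))
    assert min(tc, tm) - 1e-9 <= tr <= max(tc, tm) + 1e-9
    ar_new = float(adapt_acceptable_hazard(ar, tr, cp))
    assert min(ar, tr) - 1e-9 <= ar_new <= max(ar, tr) + 1e-9
    assert 0.0 <= ar_new <= 200.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(tc_prev=hazards,
       indices=st.lists(hazards, min_size=1, max_size=10),
       bump=st.floats(min_value=0.0, max_value=50.0),
       m=st.integers(min_value=1, max_value=60),
       w=weights, tm=hazards, cp=weights, ar=hazards)
def test_raising_coworker_indices_weakly_raises_tolerances(
    tc_prev, indices, bump, m, w, tm, cp, ar
):
    """Monotonicity: uniformly higher coworker indices can only raise the
    crew tolerance and, downstream, the blended tolerance and next-day
    acceptable hazard."""
    raised = [min(x + bump, 200.0) for x in indices]
    tc_lo = float(update_crew_tolerance(tc_prev, indices, m))
    tc_hi = float(update_crew_tolerance(tc_prev, raised, m))
    assert tc_hi >= tc_lo - 1e-9
    tr_lo = float(perceived_tolerance(tc_lo, tm, w))
    tr_hi = float(perceived_tolerance(tc_hi, tm, w))
    assert tr_hi >= tr_lo - 1e-9
    assert float(adapt_acceptable_hazard(ar, tr_hi, cp)) >= \
        float(adapt_acceptable_hazard(ar, tr_lo, cp)) - 1e-9


def test_vectorized_updates_match_scalar():
    rng = np.random.default_rng(2)
    ar = rng.uniform(0, 200, 50)
    tr = rng.uniform(0, 200, 50)
    cp = rng.uniform(0, 1, 50)
    vec = adapt_acceptable_hazard(ar, tr, cp)
    for i in range(50):
        assert vec[i] == pytest.approx(adapt_acceptable_hazard(ar[i], tr[i], cp[i]))
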