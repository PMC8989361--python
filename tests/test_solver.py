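import math

import numpy as np
import pytest

from extrigger import (
    RateDistribution,
    SystemState,
    TerminalValues,
    ValueParams,
    brute_force_value,
    build_ex_situ_matrix,
    build_in_situ_matrix,
    enumerate_states,
    fixed_policy_value,
    solve,
    terminal_values,
)
from extrigger.solver import EX_SITU, IN_SITU, NONE


def random_instance(rng, tau):
    """One random stopping problem (matrices + terminal values)."""
    px = rng.uniform(0.0, 1.0)
    w2 = rng.uniform(0.2, 1.0)
    n0 = rng.uniform(20.0, 300.0)
    slope = -rng.uniform(0.5, 30.0)
    se = rng.uniform(0.0, 5.0)
    if se > 0:
        nodes = np.sort(rng.normal(slope, se, 5))
        rates = RateDistribution(nodes, np.full(5, 0.2))
    else:
        rates = RateDistribution.point_mass(slope)
    params = ValueParams(w1=math.log(20.0) / n0, w2=w2, px=px)
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, px)
    terminal = terminal_values(tau, rates, n0, params)
    return T_s, T_e, terminal


def test_zero_terminal_values_give_zero_everywhere():
    tau = 3
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, 0.5)
    terminal = TerminalValues(np.zeros(4 * (tau + 1)), tau)
    table = solve(T_s, T_e, terminal)
    assert np.all(table.values == 0.0)


def test_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(10):
        T_s, T_e, terminal = random_instance(rng, tau=3)
        table = solve(T_s, T_e, terminal)
        oracle = brute_force_value(T_s, T_e, terminal)
        assert table.values[0, 0] == pytest.approx(oracle, abs=1e-10)


def test_closed_form_single_decision():
    """tau = 1: the optimum is the better of the two one-shot actions."""
    rng = np.random.default_rng(11)
    T_s, T_e, terminal = random_instance(rng, tau=1)
    table = solve(T_s, T_e, terminal)
    q = 0.5  # uniform prior mean at n_u = 0
    v_in = q * terminal.value(SystemState(0, 0, 1)) \
        + (1 - q) * terminal.value(SystemState(1, 0, 0))
    px = T_e.row(SystemState(0, 0, 0))[2]
    v_ex = px * terminal.value(SystemState(0, 1, 0))
    assert table.values[0, 0] == pytest.approx(max(v_in, v_ex), abs=1e-12)
    assert brute_force_value(T_s, T_e, terminal) == pytest.approx(
        max(v_in, v_ex), abs=1e-12)


def test_certain_undiscounted_capture_dominates():
    """px = 1, w2 = 1: waiting only loses abundance, so capture is optimal
    at every live state below the horizon.

    Boundary cases tie instead of dominating strictly: an unresolved live
    state at the horizon is valued at the same elapsed time as a fresh
    capture, and the absorbing horizon state freezes elapsed time, so at the
    final decision stage and at n_u = tau - 1 the two actions are exactly
    equal and the tie-break keeps in situ.  Strict dominance therefore holds
    for n_u <= tau - 2 at stages t <= tau - 2.
    """
    tau = 3
    rates = RateDistribution.point_mass(-10.0)
    params = ValueParams(w1=math.log(20.0) / 100.0, w2=1.0, px=1.0)
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, 1.0)
    terminal = terminal_values(tau, rates, 100.0, params)
    table = solve(T_s, T_e, terminal)
    for t in range(tau - 1):
        for n_u in range(tau - 1):
            assert table.action(SystemState(n_u, 0, 0), t) == EX_SITU
    # final stage: exact tie between capturing now and one last in situ year
    for n_u in range(tau):
        state = SystemState(n_u, 0, 0)
        cont_s = T_s.row(state) @ terminal.values
        cont_e = T_e.row(state) @ terminal.values
        assert cont_s == pytest.approx(cont_e, abs=1e-12)
    # the oracle agrees that immediate capture achieves the optimum
    oracle = brute_force_value(T_s, T_e, terminal)
    assert table.values[0, 0] == pytest.approx(oracle, abs=1e-12)
    assert oracle == pytest.approx(terminal.value(SystemState(0, 1, 0)), abs=1e-12)


def test_worthless_capture_is_never_chosen():
    """px = 0 sends everything to the zero-valued sink: never capture."""
    rng = np.random.default_rng(13)
    tau = 3
    rates = RateDistribution.point_mass(-rng.uniform(1, 10))
    params = ValueParams(w1=0.02, w2=0.9, px=0.0)
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, 0.0)
    terminal = terminal_values(tau, rates, 150.0, params)
    table = solve(T_s, T_e, terminal)
    assert not np.any(table.actions == EX_SITU)
    assert brute_force_value(T_s, T_e, terminal) == pytest.approx(
        table.values[0, 0], abs=1e-12)


def test_optimal_value_dominates_fixed_policies():
    rng = np.random.default_rng(17)
    for _ in range(5):
        T_s, T_e, terminal = random_instance(rng, tau=4)
        table = solve(T_s, T_e, terminal)
        always_in = fixed_policy_value(T_s, terminal)
        always_ex = fixed_policy_value(T_e, terminal)
        assert np.all(table.values[0] >= always_in - 1e-12)
        assert np.all(table.values[0] >= always_ex - 1e-12)


def test_values_stay_in_unit_interval():
    rng = np.random.default_rng(19)
    T_s, T_e, terminal = random_instance(rng, tau=4)
    table = solve(T_s, T_e, terminal)
    assert table.values.min() >= 0.0 and table.values.max() <= 1.0


def test_capture_threshold_monotone_in_failures():
    """Once capture is optimal at some n_u it stays optimal for larger n_u."""
    tau = 8
    rates = RateDistribution.point_mass(-10.0)
    params = ValueParams(w1=math.log(20.0) / 100.0, w2=2 / 3, px=0.75)
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, params.px)
    terminal = terminal_values(tau, rates, 100.0, params)
    table = solve(T_s, T_e, terminal)
    for t in range(tau):
        # {tau,0,0} is excluded: its in situ self-loop retains terminal value
        acts = [table.action(SystemState(n_u, 0, 0), t) for n_u in range(tau)]
        seen_ex = False
        for a in acts:
            if a == EX_SITU:
                seen_ex = True
            elif seen_ex:
                assert a != IN_SITU, "capture region is not upward-closed in n_u"


def test_absorbing_states_have_no_action():
    rng = np.random.default_rng(23)
    T_s, T_e, terminal = random_instance(rng, tau=2)
    table = solve(T_s, T_e, terminal)
    for s_index, state in enumerate(enumerate_states(2), start=1):
        if not state.is_live:
            assert table.action(state, 0) == NONE
            # value propagates unchanged from the terminal stage
            assert table.values[0, s_index - 1] == pytest.approx(
                terminal.values[s_index - 1], abs=1e-12)


def test_dimension_mismatch_rejected():
    T_s = build_in_situ_matrix(2)
    T_e = build_ex_situ_matrix(3, 0.5)
    terminal = TerminalValues(np.zeros(12), 2)
    with pytest.raises(ValueError, match="inconsistent state space"):
        solve(T_s, T_e, terminal)


def test_oracle_scale_guard():
    tau = 5
    T_s = build_in_situ_matrix(tau)
    T_e = build_ex_situ_matrix(tau, 0.5)
    terminal = TerminalValues(np.zeros(4 * (tau + 1)), tau)
    with pytest.raises(ValueError, match="oracle scale exceeded"):
        brute_force_value(T_s, T_e, terminal)
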