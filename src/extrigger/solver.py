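"""Finite-horizon stochastic dynamic programming for the stopping problem.

Backward iteration of the Bellman equation

    V(S_i, t) = max_a  sum_j  T(a)_ij  V(S_j, t + 1),      t = tau-1, ..., 0

over the two actions (continue in situ, or trigger the ex situ capture) gives
the optimal value and action for every state and stage.  Ties are broken in
favour of staying in situ: delaying preserves the option value of the
irreversible capture and makes outputs deterministic.  A brute-force policy
enumerator over tiny horizons serves as an independent verification oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import TransitionMatrix, enumerate_states, state_legend
from .valuation import TerminalValues

__all__ = ["PolicyTable", "solve", "brute_force_value", "fixed_policy_value"]

IN_SITU = "in_situ"
EX_SITU = "ex_situ"
NONE = "none"

#: absolute tolerance on value comparisons before the in-situ tie-break
TIE_TOL = 1e-12


@dataclass(frozen=True)
class PolicyTable:
    """Optimal values and actions for every state index and stage.

    ``values`` has shape (tau + 1, R) with row t holding V(., t); ``actions``
    has shape (tau, R) (no action is taken at the terminal stage) with entries
    "in_situ", "ex_situ", or "none" for absorbing states.
    """

    values: np.ndarray
    actions: np.ndarray
    tau: int

    def value(self, state, t: int) -> float:
        return float(self.values[t, state.index - 1])

    def action(self, state, t: int) -> str:
        if t >= self.tau:
            return NONE
        return str(self.actions[t, state.index - 1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (t, state_index, n_u, a_e, a_s, action, value)."""
        legend = state_legend(self.tau)
        rows = []
        for t in range(self.tau + 1):
            block = legend.copy()
            block.insert(0, "t", t)
            block["action"] = self.actions[t] if t < self.tau else NONE
            block["value"] = self.values[t]
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


def solve(T_s: TransitionMatrix, T_e: TransitionMatrix,
          terminal: TerminalValues, tau: int | None = None) -> PolicyTable:
    """Backward induction of the Bellman equation over the full horizon."""
    tau = T_s.tau if tau is None else tau
    if T_s.tau != T_e.tau or T_e.tau != terminal.tau or tau != T_s.tau:
        raise ValueError("inconsistent state space: matrices and terminal values "
                         "must share one horizon")
    R = T_s.n_states
    live = np.array([s.is_live for s in enumerate_states(tau)])
    values = np.empty((tau + 1, R))
    actions = np.full((tau, R), NONE, dtype=object)
    values[tau] = terminal.values
    for t in range(tau - 1, -1, -1):
        cont_s = T_s.entries @ values[t + 1]
        cont_e = T_e.entries @ values[t + 1]
        take_ex = live & (cont_e > cont_s + TIE_TOL)
        values[t] = np.where(take_ex, cont_e, cont_s)
        actions[t, live] = IN_SITU
        actions[t, take_ex] = EX_SITU
    return PolicyTable(values=values, actions=actions, tau=tau)


def fixed_policy_value(matrix: TransitionMatrix, terminal: TerminalValues) -> np.ndarray:
    """Value at stage 0 of always applying one action (policy-evaluation bound)."""
    v = terminal.values.copy()
    for _ in range(matrix.tau):
        v = matrix.entries @ v
    return v


def brute_force_value(T_s: TransitionMatrix, T_e: TransitionMatrix,
                      terminal: TerminalValues, tau: int | None = None) -> float:
    """Optimal value at {0,0,0} by exhaustive deterministic-policy enumeration.

    Every assignment of an action to each (live state, stage) pair is
    evaluated by explicit probability-tree expansion from the initial state,
    and the maximum expected terminal value is returned.  Exponential in
    tau**2, hence the guard; this is a definitionally independent oracle for
    :func:`solve`, not a production path.
    """
    tau = T_s.tau if tau is None else tau
    if tau > 4:
        raise ValueError("oracle scale exceeded: brute force requires tau <= 4")
    if T_s.tau != T_e.tau or T_e.tau != terminal.tau or tau != T_s.tau:
        raise ValueError("inconsistent state space: matrices and terminal values "
                         "must share one horizon")
    states = enumerate_states(tau)
    live_idx = [s.index - 1 for s in states if s.is_live]
    rows = {IN_SITU: T_s.entries, EX_SITU: T_e.entries}
    term = terminal.values
    is_live = np.array([s.is_live for s in states])
    slots = [(i, t) for i in live_idx for t in range(tau)]

    def tree_value(i: int, t: int, policy: dict) -> float:
        if not is_live[i]:
            return float(term[i])  # absorbing: value fixed at the terminal stage
        if t == tau:
            return float(term[i])
        row = rows[policy[(i, t)]][i]
        total = 0.0
        for j in np.nonzero(row)[0]:
            total += row[j] * tree_value(int(j), t + 1, policy)
        return total

    best = -np.inf
    start = 0  # index of {0,0,0}
    for choice in itertools.product((IN_SITU, EX_SITU), repeat=len(slots)):
        policy = dict(zip(slots, choice))
        best = max(best, tree_value(start, 0, policy))
    return float(best)
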