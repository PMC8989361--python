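"""Markov state space and transition matrices for the stopping problem.

A system state is the triple {n_u, a_e, a_s}: the number of unsuccessful in
situ years so far (0..tau), whether the ex situ, in toto action has been taken
(binary a_e), and whether an in situ action has succeeded (binary a_s).  States
carry the canonical 1-based index i = a_s + 2 a_e + 4 n_u + 1, giving
R = 4 (tau + 1) states in total; the last state S_R = {tau, 1, 1} doubles as
the complete-extinction sink for failed ex situ attempts.

Two row-stochastic R x R matrices describe the dynamics: T(s) for a year of in
situ management (success with the current posterior mean of q, else one more
failure) and T(e) for the one-shot ex situ capture (establishment with
probability px, else extinction).  Any state with a_e = 1 or a_s = 1 is
absorbing, as is {tau, 0, 0}, where the horizon has run out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief import expected_success

__all__ = [
    "SystemState",
    "TransitionMatrix",
    "state_index",
    "state_from_index",
    "enumerate_states",
    "build_in_situ_matrix",
    "build_ex_situ_matrix",
]


@dataclass(frozen=True)
class SystemState:
    """One Markov state {n_u, a_e, a_s} of the decision problem."""

    n_u: int
    a_e: int
    a_s: int

    def __post_init__(self) -> None:
        if self.n_u < 0:
            raise ValueError("n_u must be non-negative")
        if self.a_e not in (0, 1) or self.a_s not in (0, 1):
            raise ValueError("a_e and a_s must be binary")

    @property
    def index(self) -> int:
        """Canonical 1-based index i = a_s + 2 a_e + 4 n_u + 1."""
        return state_index(self.n_u, self.a_e, self.a_s)

    @property
    def elapsed(self) -> int:
        """Years elapsed since management began: n_u + a_e + a_s."""
        return self.n_u + self.a_e + self.a_s

    @property
    def is_live(self) -> bool:
        """True if no action has yet resolved (a_e = a_s = 0)."""
        return self.a_e == 0 and self.a_s == 0


def state_index(n_u: int, a_e: int, a_s: int) -> int:
    return a_s + 2 * a_e + 4 * n_u + 1


def state_from_index(i: int) -> SystemState:
    """Invert the index formula (1-based)."""
    if i < 1:
        raise ValueError("state index is 1-based")
    rem = i - 1
    return SystemState(n_u=rem // 4, a_e=(rem % 4) // 2, a_s=rem % 2)


def enumerate_states(tau: int) -> list[SystemState]:
    """All R = 4 (tau + 1) states, listed in index order."""
    if tau < 1:
        raise ValueError("horizon too short: tau must be >= 1")
    return [state_from_index(i) for i in range(1, 4 * (tau + 1) + 1)]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over the tau-indexed state space."""

    entries: np.ndarray
    kind: str  # "in_situ" | "ex_situ"
    tau: int

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        R = 4 * (self.tau + 1)
        if entries.shape != (R, R):
            raise ValueError(f"expected {R}x{R} matrix, got {entries.shape}")
        if np.any(entries < 0) or np.any(entries > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(entries.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1")
        object.__setattr__(self, "entries", entries)

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]

    def row(self, state: SystemState) -> np.ndarray:
        return self.entries[state.index - 1]

    def to_frame(self) -> pd.DataFrame:
        idx = [s.index for s in enumerate_states(self.tau)]
        return pd.DataFrame(self.entries, index=idx, columns=idx)


def state_legend(tau: int) -> pd.DataFrame:
    """Sidecar table (index, n_u, a_e, a_s) describing the state enumeration."""
    states = enumerate_states(tau)
    return pd.DataFrame({
        "state_index": [s.index for s in states],
        "n_u": [s.n_u for s in states],
        "a_e": [s.a_e for s in states],
        "a_s": [s.a_s for s in states],
    })


def export_matrix(matrix: TransitionMatrix, path, legend_path=None) -> None:
    """Write a transition matrix as a dense R x R CSV.

    If ``legend_path`` is given, a sidecar table (state_index, n_u, a_e, a_s)
    describing the row/column enumeration is written next to it.
    """
    matrix.to_frame().to_csv(path, index_label="state_index")
    if legend_path is not None:
        state_legend(matrix.tau).to_csv(legend_path, index=False)


def build_in_situ_matrix(tau: int, belief_variant: str = "conjugate") -> TransitionMatrix:
    """Transition matrix T(s) for a year of in situ management.

    From a live state {n_u, 0, 0} with n_u < tau the action succeeds with the
    posterior mean E[q | n_u] (moving to {n_u, 0, 1}) and fails otherwise
    (moving to {n_u + 1, 0, 0}).  {tau, 0, 0} and every state with a_e = 1 or
    a_s = 1 self-loop with probability 1.
    """
    states = enumerate_states(tau)
    R = len(states)
    T = np.zeros((R, R))
    for s in states:
        i = s.index - 1
        if s.is_live and s.n_u < tau:
            q = expected_success(s.n_u, belief_variant)
            T[i, state_index(s.n_u, 0, 1) - 1] = q
            T[i, state_index(s.n_u + 1, 0, 0) - 1] = 1.0 - q
        else:  # absorbing: resolved states and the horizon state {tau,0,0}
            T[i, i] = 1.0
    return TransitionMatrix(T, kind="in_situ", tau=tau)


def build_ex_situ_matrix(tau: int, px: float) -> TransitionMatrix:
    """Transition matrix T(e) for the one-shot ex situ, in toto action.

    From any live state {n_u, 0, 0} the captive population establishes with
    probability ``px`` (moving to {n_u, 1, 0}); with probability 1 - px the
    attempt fails and the species is completely extinct, modelled as a jump to
    the last state S_R.  Resolved states self-loop.
    """
    if not 0.0 <= px <= 1.0:
        raise ValueError("invalid probability: px must lie in [0, 1]")
    states = enumerate_states(tau)
    R = len(states)
    T = np.zeros((R, R))
    for s in states:
        i = s.index - 1
        if s.is_live:
            T[i, state_index(s.n_u, 1, 0) - 1] += px
            T[i, R - 1] += 1.0 - px
        else:
            T[i, i] = 1.0
    return TransitionMatrix(T, kind="ex_situ", tau=tau)
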