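"""Expected abundance per state and the terminal value of each outcome.

The value of ending the horizon in a given state combines two preferences:
satisfaction saturates with abundance N as 1 - exp(-w1 N) (diminishing
marginal benefit, controlled by w1), and an established captive population is
worth only a fraction w2 of a wild one.  Expectations are taken over the
discretized decline-rate distribution, with the projected abundance
N0 + r * (elapsed years); by default negative projections are floored at zero
inside the integral so that extinct trajectories anchor the value scale at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decline import RateDistribution
from .states import SystemState, enumerate_states, state_legend

__all__ = [
    "ValueParams",
    "TerminalValues",
    "calibrated_w1",
    "expected_abundance",
    "terminal_value",
    "terminal_values",
]


def calibrated_w1(pre_decline_abundance: float, satisfaction: float = 0.95) -> float:
    """w1 such that managers are ``satisfaction``-satisfied at the given abundance.

    Solving 1 - exp(-w1 N) = s gives w1 = -ln(1 - s)/N; the default 95%
    satisfaction at the pre-decline abundance yields w1 = ln(20)/N.
    """
    if pre_decline_abundance <= 0:
        raise ValueError("pre-decline abundance must be positive")
    if not 0.0 < satisfaction < 1.0:
        raise ValueError("satisfaction must be in (0, 1)")
    return -math.log(1.0 - satisfaction) / pre_decline_abundance


@dataclass(frozen=True)
class ValueParams:
    """Value-function parameters.

    w1 : satisfaction saturation rate (1/individuals), > 0.
    w2 : preference discount for captive (ex situ) populations, in (0, 1].
    px : probability that the ex situ, in toto capture establishes, in [0, 1].
    """

    w1: float
    w2: float = 2.0 / 3.0
    px: float = 0.75

    def __post_init__(self) -> None:
        if self.w1 <= 0:
            raise ValueError("w1 must be positive")
        if not 0.0 < self.w2 <= 1.0:
            raise ValueError("w2 must lie in (0, 1]")
        if not 0.0 <= self.px <= 1.0:
            raise ValueError("invalid probability: px must lie in [0, 1]")


@dataclass(frozen=True)
class TerminalValues:
    """Terminal value V(S_i, tau) for every state index (extinction sink = 0)."""

    values: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (4 * (self.tau + 1),):
            raise ValueError("terminal values do not match the state space")
        object.__setattr__(self, "values", values)

    def value(self, state: SystemState) -> float:
        return float(self.values[state.index - 1])

    def to_frame(self):
        frame = state_legend(self.tau)
        frame["terminal_value"] = self.values
        return frame


def expected_abundance(state: SystemState, rates: RateDistribution,
                       n0: float) -> float:
    """Expected abundance N0 + r * (n_u + a_e + a_s) averaged over p(r).

    May be negative: the linear extrapolation is not floored here, the caller
    decides how to value extinct trajectories.
    """
    return float(rates.weights @ (n0 + rates.nodes * state.elapsed))


def _state_value(state: SystemState, rates: RateDistribution, n0: float,
                 params: ValueParams, clamp: str) -> float:
    projected = n0 + rates.nodes * state.elapsed
    if clamp == "floor":
        projected = np.maximum(0.0, projected)
    elif clamp != "raw":
        raise ValueError(f"unknown clamp mode {clamp!r}")
    sat = 1.0 - np.exp(-params.w1 * projected)
    return float((params.w2 ** state.a_e) * (rates.weights @ sat))


def terminal_value(state: SystemState, rates: RateDistribution, n0: float,
                   params: ValueParams, clamp: str = "floor",
                   tau: int | None = None) -> float:
    """Terminal value of one state (the extinction sink S_R is worth 0).

    With ``clamp='floor'`` (default) each rate node's projected abundance is
    floored at zero before the saturation transform, so trajectories that have
    crossed extinction contribute exactly the species-lost value 0;
    ``clamp='raw'`` evaluates the saturation on the raw linear projection.
    """
    if tau is not None and state.index == 4 * (tau + 1):
        return 0.0
    return _state_value(state, rates, n0, params, clamp)


def terminal_values(tau: int, rates: RateDistribution, n0: float,
                    params: ValueParams, clamp: str = "floor") -> TerminalValues:
    """Terminal value vector over the full state space for horizon ``tau``."""
    vals = np.array([
        terminal_value(s, rates, n0, params, clamp=clamp, tau=tau)
        for s in enumerate_states(tau)
    ])
    return TerminalValues(vals, tau=tau)
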