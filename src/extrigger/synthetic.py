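"""Synthetic declining-abundance timeseries with known ground truth.

Real single-population declines fall roughly into two regimes: near-
deterministic linear slides (the vaquita- and pipistrelle-style series) and
noisy declines with transient increases (the wombat- and turtle-style series).
The generator produces both from a handful of parameters so every stage of the
pipeline is testable against a known truth, with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import AbundanceSeries

__all__ = ["ScenarioSpec", "generate", "builtin_fixtures"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic decline scenario.

    The mean trajectory is N0 + slope * t; if ``recovery_year`` is set the
    slope flips sign from that calendar year onward (a managed or spontaneous
    recovery).  Gaussian noise of sd ``noise_sd`` is added, and abundances are
    floored at zero.
    """

    name: str
    n0: float
    slope: float
    noise_sd: float
    n_years: int
    recovery_year: int | None = None
    seed: int = 0
    start_year: int = 2000

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate(spec: ScenarioSpec) -> AbundanceSeries:
    """Deterministic-per-seed realization of a scenario."""
    rng = np.random.default_rng(spec.seed)
    years = spec.start_year + np.arange(spec.n_years)
    t = np.arange(spec.n_years, dtype=float)
    if spec.recovery_year is None:
        mean = spec.n0 + spec.slope * t
    else:
        t_rec = float(spec.recovery_year - spec.start_year)
        mean = spec.n0 + spec.slope * np.minimum(t, t_rec) \
            - spec.slope * np.maximum(0.0, t - t_rec)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_years) if spec.noise_sd > 0 \
        else np.zeros(spec.n_years)
    abund = np.maximum(0.0, mean + noise)
    return AbundanceSeries(years, abund, name=spec.name)


def builtin_fixtures() -> dict[str, ScenarioSpec]:
    """Four packaged scenarios shaped like the published case-study regimes.

    steady_long     — long, consistent, low-noise decline of a sizeable
                      population (vaquita-like).
    steady_to_zero  — shorter consistent decline that runs all the way to
                      zero (pipistrelle-like).
    noisy_upturn    — highly variable decline with a recovery in the final
                      years (wombat-like).
    noisy_shallow   — shallow, noisy decline of a small population
                      (turtle-like).

    All series are synthetic: magnitudes and shapes emulate the published
    regimes, they are not the historical observations.
    """
    specs = [
        ScenarioSpec("steady_long", n0=600.0, slope=-22.0, noise_sd=8.0,
                     n_years=25, seed=11, start_year=1990),
        ScenarioSpec("steady_to_zero", n0=120.0, slope=-9.0, noise_sd=2.0,
                     n_years=15, seed=12, start_year=1995),
        ScenarioSpec("noisy_upturn", n0=250.0, slope=-14.0, noise_sd=25.0,
                     n_years=20, recovery_year=2004, seed=13, start_year=1990),
        ScenarioSpec("noisy_shallow", n0=60.0, slope=-2.0, noise_sd=6.0,
                     n_years=25, seed=14, start_year=1985),
    ]
    return {s.name: s for s in specs}
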