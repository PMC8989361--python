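"""Bayesian belief about the annual in situ success probability q.

Each year of in situ management is a Bernoulli trial with unknown, constant
success probability q.  Starting from a uniform Beta(1, 1) prior, n_u observed
failures (and no successes) give the conjugate posterior Beta(1, n_u + 1):
repeated failures concentrate belief near q = 0, so managers grow increasingly
pessimistic about in situ action ever working.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["SuccessBelief", "posterior", "expected_success"]

_VARIANTS = ("conjugate", "as_printed")


@dataclass(frozen=True)
class SuccessBelief:
    """Beta posterior over q after ``n_failures`` unsuccessful years."""

    n_failures: int
    alpha: float
    beta: float

    @property
    def dist(self):
        """Frozen scipy Beta distribution."""
        return stats.beta(self.alpha, self.beta)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def posterior(n_u: int) -> SuccessBelief:
    """Posterior belief Beta(1, n_u + 1) after ``n_u`` in situ failures."""
    if n_u < 0 or int(n_u) != n_u:
        raise ValueError("invalid failure count: n_u must be a non-negative integer")
    return SuccessBelief(n_failures=int(n_u), alpha=1.0, beta=float(n_u) + 1.0)


def expected_success(n_u: int, variant: str = "conjugate") -> float:
    """Expected probability that next year's in situ action succeeds.

    ``conjugate`` (default) is the Beta(1, n_u+1) posterior mean 1/(n_u + 2),
    which decreases with every failure.  ``as_printed`` is the alternative
    closed form 1 - 1/(n_u + 2); it *increases* with failures and contradicts
    the conjugate posterior, but is kept available for literal reproduction of
    published analyses that may have used it.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    if n_u < 0 or int(n_u) != n_u:
        raise ValueError("invalid failure count: n_u must be a non-negative integer")
    mean = 1.0 / (n_u + 2.0)
    return mean if variant == "conjugate" else 1.0 - mean
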