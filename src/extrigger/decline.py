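"""Linear decline model: fit, decline-rate distribution, extinction forecast.

The observed abundance of a declining single-population threatened species is
modelled as a straight line in time plus Gaussian environmental/demographic
noise.  An ordinary least-squares fit yields the decline rate r (individuals
per year) together with its sampling distribution p(r); pushing p(r) through
the linear extrapolation N(t) = N0 + r t gives a distribution over the year in
which the population first crosses zero, and hence a finite planning horizon
tau beyond which extinction is treated as certain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .series import AbundanceSeries

__all__ = [
    "DeclineModel",
    "RateDistribution",
    "ExtinctionForecast",
    "DeclineTrend",
    "fit_decline",
    "rate_distribution",
    "extinction_forecast",
    "forecast_band",
]


@dataclass(frozen=True)
class DeclineModel:
    """Fitted linear decline with its sampling uncertainty.

    ``slope_mean``/``slope_se`` describe the OLS decline-rate estimate in
    individuals/year; ``intercept`` is the fitted abundance at ``first_year``.
    ``reference_abundance`` (N0) anchors every forward projection and is by
    default the last *observed* abundance.
    """

    slope_mean: float
    slope_se: float
    intercept: float
    n_obs: int
    reference_abundance: float
    reference_year: int
    residual_sd: float
    first_year: int
    first_abundance: float
    year_span: int
    slope_dist: str = "normal"

    def __post_init__(self) -> None:
        if self.n_obs < 3:
            raise ValueError("insufficient data: decline fit needs >= 3 observations")
        if self.slope_se < 0 or self.reference_abundance < 0:
            raise ValueError("slope_se and reference_abundance must be non-negative")

    def slope_distribution(self):
        """Frozen scipy distribution of the slope estimate (None if degenerate)."""
        if self.slope_se == 0:
            return None
        if self.slope_dist == "t":
            return stats.t(df=self.n_obs - 2, loc=self.slope_mean, scale=self.slope_se)
        return stats.norm(loc=self.slope_mean, scale=self.slope_se)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        dist = self.slope_distribution()
        if dist is None:
            return (self.slope_mean, self.slope_mean)
        lo = (1.0 - level) / 2.0
        return (float(dist.ppf(lo)), float(dist.ppf(1.0 - lo)))

    def predict(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.intercept + self.slope_mean * (years - self.first_year)


@dataclass(frozen=True)
class RateDistribution:
    """Discrete representation of the decline-rate distribution p(r).

    Nodes sit at equal-probability quantiles of the slope sampling
    distribution and carry uniform weights, so expectations over p(r) become
    plain weighted sums that are deterministic and reproducible.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-D and congruent")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.diff(nodes) < 0):
            raise ValueError("nodes must be sorted ascending")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def point_mass(cls, rate: float) -> "RateDistribution":
        return cls(np.array([float(rate)]), np.array([1.0]))

    @property
    def mean(self) -> float:
        return float(self.weights @ self.nodes)


@dataclass(frozen=True)
class ExtinctionForecast:
    """Distribution of the first year the linear extrapolation crosses zero.

    ``yearly_mass[k]`` is the probability that extinction first occurs in year
    k+1 (years run 1..tau); ``mass_beyond`` collects rate nodes that never
    cross zero within tau years (including all non-negative rates).
    """

    tau: int
    yearly_mass: np.ndarray
    mass_beyond: float
    percentile: float
    already_extinct: bool = False
    capped: bool = False

    def __post_init__(self) -> None:
        mass = np.asarray(self.yearly_mass, dtype=float)
        if np.any(mass < -1e-12):
            raise ValueError("yearly_mass must be non-negative")
        if not self.already_extinct and abs(mass.sum() + self.mass_beyond - 1.0) > 1e-9:
            raise ValueError("extinction forecast does not conserve probability")
        object.__setattr__(self, "yearly_mass", mass)

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.tau + 1)


def fit_decline(series: AbundanceSeries, slope_dist: str = "normal",
                reference: str = "last_observed") -> DeclineModel:
    """Ordinary least-squares fit of abundance against year.

    Parameters
    ----------
    series : AbundanceSeries
        At least three observations.
    slope_dist : {"normal", "t"}
        Family used for the slope sampling distribution p(r).
    reference : {"last_observed", "fitted"}
        Whether N0 is the raw last observation or the regression prediction at
        the last observed year (steadier for noisy series).
    """
    if len(series) < 3:
        raise ValueError("insufficient data: decline fit needs >= 3 observations")
    if slope_dist not in ("normal", "t"):
        raise ValueError(f"unknown slope_dist {slope_dist!r}")
    if reference not in ("last_observed", "fitted"):
        raise ValueError(f"unknown reference mode {reference!r}")
    t = series.years - series.first_year
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: no variance in years")
    res = stats.linregress(t.astype(float), series.abundances)
    n = len(series)
    fitted = res.intercept + res.slope * t
    resid = series.abundances - fitted
    residual_sd = float(np.sqrt((resid @ resid) / (n - 2))) if n > 2 else 0.0
    slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    if residual_sd < 1e-12:  # exact line: kill floating-point dust in the se
        slope_se = 0.0
    n0_fitted = float(res.intercept + res.slope * t[-1])
    n0 = series.last_abundance if reference == "last_observed" else max(0.0, n0_fitted)
    return DeclineModel(
        slope_mean=float(res.slope),
        slope_se=slope_se,
        intercept=float(res.intercept),
        n_obs=n,
        reference_abundance=n0,
        reference_year=series.last_year,
        residual_sd=residual_sd,
        first_year=series.first_year,
        first_abundance=series.first_abundance,
        year_span=series.last_year - series.first_year,
        slope_dist=slope_dist,
    )


def rate_distribution(model: DeclineModel, n_nodes: int = 201) -> RateDistribution:
    """Discretize p(r) into ``n_nodes`` equal-probability quantile nodes.

    Nodes are placed at the mid-quantiles (k - 1/2)/n of the slope sampling
    distribution with uniform weights 1/n; a degenerate fit (slope_se = 0)
    collapses to a single point mass at the estimated slope.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    dist = model.slope_distribution()
    if dist is None or n_nodes == 1:
        return RateDistribution.point_mass(model.slope_mean)
    probs = (np.arange(n_nodes) + 0.5) / n_nodes
    nodes = dist.ppf(probs)
    weights = np.full(n_nodes, 1.0 / n_nodes)
    return RateDistribution(nodes, weights)


def default_horizon_cap(model: DeclineModel) -> int:
    """Largest admissible horizon: max(5 x observed year span, 100)."""
    return max(5 * model.year_span, 100)


def extinction_time(rate: float, n0: float) -> float:
    """First integer year t with n0 + rate*t <= 0, or +inf for rate >= 0."""
    if n0 <= 0:
        return 0.0
    if rate >= 0:
        return math.inf
    return float(math.ceil(n0 / abs(rate)))


def extinction_forecast(model: DeclineModel, percentile: float = 0.99,
                        n_nodes: int = 201, cap: int | None = None,
                        rates: RateDistribution | None = None) -> ExtinctionForecast:
    """Forecast the extinction year distribution and the planning horizon tau.

    Each rate node r < 0 extinguishes the linear extrapolation in year
    ceil(N0/|r|); nodes with r >= 0 never do and contribute to ``mass_beyond``.
    tau is the smallest year whose cumulative extinction probability reaches
    ``percentile``, capped at ``cap`` (default: max(5 x observed span, 100)).
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    cap = default_horizon_cap(model) if cap is None else int(cap)
    n0 = model.reference_abundance
    if rates is None:
        rates = rate_distribution(model, n_nodes)
    if n0 <= 0:
        warnings.warn("reference abundance is 0: population already extinct",
                      stacklevel=2)
        return ExtinctionForecast(tau=0, yearly_mass=np.zeros(0), mass_beyond=0.0,
                                  percentile=percentile, already_extinct=True)
    t_ext = np.array([extinction_time(r, n0) for r in rates.nodes])
    finite = np.isfinite(t_ext)
    finite_mass = float(rates.weights[finite].sum())
    if finite_mass + 1e-12 < percentile:
        warnings.warn(
            f"slope distribution has mass {1 - finite_mass:.3f} at non-declining "
            f"rates; requested percentile {percentile} unreachable, horizon "
            f"capped at {cap}", stacklevel=2)
        tau, capped = cap, True
    else:
        order = np.argsort(t_ext[finite])
        cum = np.cumsum(rates.weights[finite][order])
        idx = int(np.searchsorted(cum, percentile - 1e-12))
        tau = int(t_ext[finite][order][idx])
        capped = tau > cap
        if capped:
            warnings.warn(f"forecast horizon {tau} exceeds cap, truncated to {cap}",
                          stacklevel=2)
            tau = cap
    yearly = np.zeros(tau)
    beyond = 0.0
    for t_e, w in zip(t_ext, rates.weights):
        if np.isfinite(t_e) and t_e <= tau:
            yearly[int(t_e) - 1] += w
        else:
            beyond += w
    return ExtinctionForecast(tau=tau, yearly_mass=yearly, mass_beyond=beyond,
                              percentile=percentile, capped=capped)


def forecast_band(model: DeclineModel, horizon: int, level: float = 0.95):
    """Per-year interval of projected abundance under slope uncertainty.

    For each future year t = 1..horizon the interval spans the two-sided
    ``level`` quantiles of N0 + r t under the slope sampling distribution,
    floored at zero.  Returns (years_ahead, lower, upper) arrays.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    t = np.arange(1, horizon + 1, dtype=float)
    dist = model.slope_distribution()
    n0 = model.reference_abundance
    if dist is None:
        line = np.maximum(0.0, n0 + model.slope_mean * t)
        return t.astype(int), line.copy(), line.copy()
    alpha = (1.0 - level) / 2.0
    r_lo, r_hi = dist.ppf(alpha), dist.ppf(1.0 - alpha)
    lower = np.maximum(0.0, n0 + r_lo * t)
    upper = np.maximum(0.0, n0 + r_hi * t)
    return t.astype(int), lower, upper


class DeclineTrend(BaseEstimator, RegressorMixin):
    """Scikit-learn style linear decline regressor for abundance timeseries.

    ``fit`` takes X = years (one column) and y = abundances and performs the
    same OLS fit as :func:`fit_decline`; the fitted decline model and its
    derived products (rate distribution, extinction forecast, forecast band)
    are exposed as methods so the estimator composes with sklearn tooling.

    Parameters
    ----------
    slope_dist : {"normal", "t"}, default "normal"
        Sampling distribution family for the decline rate.
    reference : {"last_observed", "fitted"}, default "last_observed"
        How the projection anchor N0 is chosen.
    n_rate_nodes : int, default 201
        Quantile nodes used when discretizing p(r).
    """

    def __init__(self, slope_dist: str = "normal", reference: str = "last_observed",
                 n_rate_nodes: int = 201):
        self.slope_dist = slope_dist
        self.reference = reference
        self.n_rate_nodes = n_rate_nodes

    def _to_series(self, X, y) -> AbundanceSeries:
        X = np.asarray(X)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of years")
            X = X[:, 0]
        return AbundanceSeries(X, np.asarray(y, dtype=float))

    def fit(self, X, y):
        series = self._to_series(X, y)
        model = fit_decline(series, slope_dist=self.slope_dist,
                            reference=self.reference)
        self.model_ = model
        self.slope_ = model.slope_mean
        self.slope_se_ = model.slope_se
        self.intercept_ = model.intercept
        self.n_obs_ = model.n_obs
        self.reference_abundance_ = model.reference_abundance
        self.residual_sd_ = model.residual_sd
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X)
        years = X[:, 0] if X.ndim == 2 else X
        return self.model_.predict(years)

    def rate_distribution(self, n_nodes: int | None = None) -> RateDistribution:
        check_is_fitted(self, "model_")
        return rate_distribution(self.model_, n_nodes or self.n_rate_nodes)

    def extinction_forecast(self, percentile: float = 0.99,
                            cap: int | None = None) -> ExtinctionForecast:
        check_is_fitted(self, "model_")
        return extinction_forecast(self.model_, percentile=percentile,
                                   n_nodes=self.n_rate_nodes, cap=cap)

    def forecast_band(self, horizon: int, level: float = 0.95):
        check_is_fitted(self, "model_")
        return forecast_band(self.model_, horizon, level)
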