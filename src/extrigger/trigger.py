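"""Receding-horizon replay: when would the method have triggered capture?

The case-study workflow replays a timeseries as if it were arriving in real
time.  Each year the decline is re-fitted on the data so far, the belief about
in situ success is updated (every elapsed management year without a declared
success counts as a failure), the horizon and value model are rebuilt, the
stopping problem is re-solved, and the optimal action at the current state is
read off.  The first year in which the recommendation is the ex situ, in toto
capture is the trigger year; if the population hits zero first, the method
"monitored the species to extinction" and the result records that instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .belief import expected_success
from .config import RunConfig
from .decline import DeclineModel, extinction_forecast, fit_decline, forecast_band, \
    rate_distribution
from .series import AbundanceSeries
from .solver import EX_SITU, PolicyTable, solve
from .states import SystemState, build_ex_situ_matrix, build_in_situ_matrix
from .valuation import ValueParams, calibrated_w1, terminal_values

__all__ = ["TriggerResult", "TriggerDecisionModel", "replay", "sensitivity_sweep"]

LOG_COLUMNS = ["year", "n_obs", "n_u", "slope", "slope_se", "N0", "tau",
               "expected_q", "action", "value"]


@dataclass(frozen=True)
class TriggerResult:
    """Outcome of a receding-horizon replay.

    ``trigger_year`` is the calendar year in which the capture was first
    recommended, or None ("never") if the series ended or the population hit
    zero before any recommendation.  ``yearly_log`` holds one row per decision
    year; ``band`` is the 95% projected-abundance envelope from the model
    fitted at the trigger (or at the final analysis if no trigger).
    """

    trigger_year: int | None
    n_failures_at_trigger: int | None
    extinction_year: int | None
    success_year: int | None
    yearly_log: pd.DataFrame
    band: pd.DataFrame
    final_model: DeclineModel | None
    final_policy: PolicyTable | None
    config: RunConfig

    @property
    def triggered(self) -> bool:
        return self.trigger_year is not None


def _resolve_params(series: AbundanceSeries, config: RunConfig) -> ValueParams:
    if isinstance(config.w1, str):  # "calibrated": 95% satisfied pre-decline
        w1 = calibrated_w1(series.first_abundance)
    else:
        w1 = float(config.w1)
    return ValueParams(w1=w1, w2=config.w2, px=config.px)


def analyse_year(series: AbundanceSeries, n_u: int, config: RunConfig,
                 params: ValueParams | None = None):
    """Single decision analysis on the data observed so far.

    Fits the decline, forecasts the horizon, builds and solves the stopping
    problem, and returns (model, forecast, policy, state, tau).  The queried
    stage equals ``n_u`` (state and stage stay consistent); the SDP horizon is
    the forecast tau, extended to n_u + 1 if the elapsed failures have already
    overtaken it so the query remains well-posed.
    """
    params = params or _resolve_params(series, config)
    model = fit_decline(series, slope_dist=config.slope_dist,
                        reference=config.reference)
    forecast = extinction_forecast(model, percentile=config.horizon_percentile,
                                   n_nodes=config.n_rate_nodes,
                                   cap=config.horizon_cap)
    tau = max(forecast.tau, n_u + 1)
    rates = rate_distribution(model, config.n_rate_nodes)
    T_s = build_in_situ_matrix(tau, belief_variant=config.belief_variant)
    T_e = build_ex_situ_matrix(tau, px=params.px)
    terminal = terminal_values(tau, rates, model.reference_abundance, params,
                               clamp=config.clamp)
    policy = solve(T_s, T_e, terminal)
    state = SystemState(n_u=n_u, a_e=0, a_s=0)
    return model, forecast, policy, state, tau


def replay(series: AbundanceSeries, params: ValueParams | None = None,
           config: RunConfig | None = None,
           success_detector=None) -> TriggerResult:
    """Receding-horizon yearly re-analysis of a timeseries.

    Management is assumed to start in the first observed year; by decision
    year y the number of in situ failures is the number of elapsed calendar
    years n_u = y - y0.  The first decision year is the first with
    ``config.fit_window`` observations.

    ``success_detector``, if given, is called as ``detector(sub_series)`` at
    each decision year and may declare the in situ action successful, ending
    the replay with ``success_year`` set.  The default detector never fires:
    the published case studies run to the trigger without an in situ success,
    and halting a decline is not reliably detectable from abundance alone.
    """
    config = config or RunConfig()
    if len(series) < config.fit_window:
        raise ValueError("insufficient data: series shorter than the fit window")
    params = params or _resolve_params(series, config)
    log_rows: list[dict] = []
    trigger_year = n_failures = extinction_year = success_year = None
    final_model = final_policy = None
    for k in range(config.fit_window - 1, len(series)):
        year = int(series.years[k])
        if series.abundances[k] <= 0:
            extinction_year = year
            break
        sub = series.truncate(year)
        if success_detector is not None and success_detector(sub):
            success_year = year
            break
        n_u = year - series.first_year
        model, forecast, policy, state, tau = analyse_year(sub, n_u, config, params)
        action = policy.action(state, n_u)
        log_rows.append({
            "year": year, "n_obs": len(sub), "n_u": n_u,
            "slope": model.slope_mean, "slope_se": model.slope_se,
            "N0": model.reference_abundance, "tau": tau,
            "expected_q": expected_success(n_u, config.belief_variant),
            "action": action, "value": policy.value(state, n_u),
        })
        final_model, final_policy = model, policy
        if action == EX_SITU:
            trigger_year, n_failures = year, n_u
            break
    yearly_log = pd.DataFrame(log_rows, columns=LOG_COLUMNS)
    if final_model is not None:
        horizon = max(1, final_policy.tau)
        years_ahead, lo, hi = forecast_band(final_model, horizon, level=0.95)
        band = pd.DataFrame({
            "year": final_model.reference_year + years_ahead,
            "lower": lo,
            "upper": hi,
        })
    else:
        band = pd.DataFrame(columns=["year", "lower", "upper"])
    return TriggerResult(
        trigger_year=trigger_year, n_failures_at_trigger=n_failures,
        extinction_year=extinction_year, success_year=success_year,
        yearly_log=yearly_log, band=band,
        final_model=final_model, final_policy=final_policy, config=config,
    )


def sensitivity_sweep(series: AbundanceSeries, param_name: str, grid,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Replay once per value of one value parameter, all else fixed.

    Returns a frame with columns (``param_name``, trigger_year, triggered,
    extinction_year); trigger_year is NaN when the capture is never
    recommended.
    """
    if param_name not in ("w1", "w2", "px"):
        raise ValueError("param_name must be one of 'w1', 'w2', 'px'")
    config = config or RunConfig()
    rows = []
    for value in grid:
        cfg = config.with_overrides(**{param_name: float(value)})
        result = replay(series, config=cfg)
        rows.append({
            param_name: float(value),
            "trigger_year": np.nan if result.trigger_year is None
            else result.trigger_year,
            "triggered": result.triggered,
            "extinction_year": np.nan if result.extinction_year is None
            else result.extinction_year,
        })
    return pd.DataFrame(rows)


class TriggerDecisionModel(BaseEstimator):
    """Scikit-learn style front end to the full trigger-point analysis.

    ``fit(X, y)`` takes X = years (single column) and y = abundances, runs the
    receding-horizon replay with the configured parameters, and exposes the
    outcome through fitted attributes (``trigger_year_``, ``yearly_log_``,
    ``result_``).  There is no predict step: the fitted object *is* the
    decision recommendation.

    Parameters mirror :class:`~extrigger.config.RunConfig`; see there for
    semantics and defaults.
    """

    def __init__(self, w1="calibrated", w2=2.0 / 3.0, px=0.75,
                 horizon_percentile=0.99, horizon_cap=None, n_rate_nodes=201,
                 slope_dist="normal", belief_variant="conjugate", clamp="floor",
                 reference="last_observed", fit_window=3):
        self.w1 = w1
        self.w2 = w2
        self.px = px
        self.horizon_percentile = horizon_percentile
        self.horizon_cap = horizon_cap
        self.n_rate_nodes = n_rate_nodes
        self.slope_dist = slope_dist
        self.belief_variant = belief_variant
        self.clamp = clamp
        self.reference = reference
        self.fit_window = fit_window

    def _config(self) -> RunConfig:
        return RunConfig(w1=self.w1, w2=self.w2, px=self.px,
                         horizon_percentile=self.horizon_percentile,
                         horizon_cap=self.horizon_cap,
                         n_rate_nodes=self.n_rate_nodes,
                         slope_dist=self.slope_dist,
                         belief_variant=self.belief_variant,
                         clamp=self.clamp, reference=self.reference,
                         fit_window=self.fit_window)

    def fit(self, X, y):
        X = np.asarray(X)
        years = X[:, 0] if X.ndim == 2 else X
        series = AbundanceSeries(years, np.asarray(y, dtype=float))
        result = replay(series, config=self._config())
        self.result_ = result
        self.trigger_year_ = result.trigger_year
        self.triggered_ = result.triggered
        self.n_failures_at_trigger_ = result.n_failures_at_trigger
        self.extinction_year_ = result.extinction_year
        self.yearly_log_ = result.yearly_log
        self.n_features_in_ = 1
        return self

    def sensitivity(self, X, y, param_name: str, grid) -> pd.DataFrame:
        X = np.asarray(X)
        years = X[:, 0] if X.ndim == 2 else X
        series = AbundanceSeries(years, np.asarray(y, dtype=float))
        return sensitivity_sweep(series, param_name, grid, config=self._config())

    def score(self, X=None, y=None):
        """Value of the initial live state at the last analysed year."""
        check_is_fitted(self, "result_")
        log = self.result_.yearly_log
        return float(log["value"].iloc[-1]) if len(log) else 0.0
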