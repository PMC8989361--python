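import warnings

import numpy as np
import pytest

from extrigger import (
    AbundanceSeries,
    RunConfig,
    ScenarioSpec,
    TriggerDecisionModel,
    builtin_fixtures,
    fit_decline,
    forecast_band,
    generate,
    replay,
    sensitivity_sweep,
)


@pytest.fixture
def upturn_pair():
    """The same decline with and without a late run of rising observations."""
    years = 2000 + np.arange(10)
    base = 100.0 - 5.0 * np.arange(10)
    upturn = base.copy()
    upturn[6:] = base[5] + 4.0 * np.arange(1, 5)
    return AbundanceSeries(years, base), AbundanceSeries(years, upturn)


class TestReplay:
    def test_certain_undiscounted_capture_triggers_immediately(self, steady_series):
        cfg = RunConfig(px=1.0, w2=1.0)
        result = replay(steady_series, config=cfg)
        first_decision_year = int(steady_series.years[cfg.fit_window - 1])
        assert result.trigger_year == first_decision_year
        assert result.n_failures_at_trigger == cfg.fit_window - 1

    def test_worthless_capture_never_triggers_and_logs_extinction(self):
        # 21 noiseless years: abundance reaches exactly 0 in the final year
        series = generate(ScenarioSpec("to_zero", n0=100.0, slope=-5.0,
                                       noise_sd=0.0, n_years=21))
        result = replay(series, config=RunConfig(px=0.0))
        assert not result.triggered
        assert result.extinction_year == int(series.years[-1])

    def test_upturn_postpones_the_trigger(self, upturn_pair):
        base, upturn = upturn_pair
        r_base = replay(base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flattened slope may hit the cap
            r_up = replay(upturn)
        base_trigger = r_base.trigger_year or np.inf
        up_trigger = r_up.trigger_year or np.inf
        assert base_trigger < up_trigger
        # the rising tail flattens the fitted slope and stretches the horizon
        year = base_trigger
        log_b = r_base.yearly_log.set_index("year")
        log_u = r_up.yearly_log.set_index("year")
        assert log_u.loc[year, "slope"] > log_b.loc[year, "slope"]
        assert log_u.loc[year, "tau"] > log_b.loc[year, "tau"]

    def test_replay_is_deterministic(self, steady_series):
        a = replay(steady_series)
        b = replay(steady_series)
        assert a.trigger_year == b.trigger_year
        assert a.yearly_log.equals(b.yearly_log)
        assert a.band.equals(b.band)

    def test_trailing_observations_do_not_change_trigger(self, steady_series):
        full = replay(steady_series)
        assert full.triggered
        truncated = replay(steady_series.truncate(full.trigger_year))
        assert truncated.trigger_year == full.trigger_year
        assert truncated.yearly_log.equals(full.yearly_log)

    def test_log_covers_every_decision_year(self, steady_series):
        result = replay(steady_series)
        cfg = result.config
        expected = list(steady_series.years[cfg.fit_window - 1:])
        logged = list(result.yearly_log["year"])
        stop = expected.index(result.trigger_year)
        assert logged == expected[:stop + 1]

    def test_belief_and_stage_advance_yearly(self, steady_series):
        log = replay(steady_series).yearly_log
        assert list(log["n_u"]) == list(log["year"] - steady_series.first_year)
        assert list(log["expected_q"]) == [
            pytest.approx(1.0 / (n + 2)) for n in log["n_u"]]

    def test_success_detector_ends_the_replay(self, upturn_pair):
        _, upturn = upturn_pair

        def two_rises(sub):
            a = sub.abundances
            return len(a) >= 3 and a[-1] > a[-2] > a[-3]

        result = replay(upturn, success_detector=two_rises)
        assert result.success_year == 2007  # second consecutive rise (75,79,83)
        assert not result.triggered and result.extinction_year is None

    def test_insufficient_series_rejected(self):
        short = AbundanceSeries([2000, 2001], [10.0, 8.0])
        with pytest.raises(ValueError, match="insufficient data"):
            replay(short)

    def test_builtin_fixtures_all_reach_a_decision(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for spec in builtin_fixtures().values():
                result = replay(generate(spec))
                assert result.triggered or result.extinction_year is not None \
                    or len(result.yearly_log) > 0


class TestSensitivity:
    def test_direction_of_each_parameter(self, steady_series):
        """Stronger capture odds or weaker wild preference -> act earlier;
        slower value saturation -> wait longer."""
        w1_cal = np.log(20.0) / steady_series.first_abundance
        sweeps = {
            "px": ([0.25, 0.5, 0.75, 1.0], "non_increasing"),
            "w2": ([1 / 3, 0.5, 2 / 3, 1.0], "non_increasing"),
            "w1": ([0.5 * w1_cal, w1_cal, 2 * w1_cal, 4 * w1_cal],
                   "non_decreasing"),
        }
        for name, (grid, direction) in sweeps.items():
            frame = sensitivity_sweep(steady_series, name, grid)
            years = frame["trigger_year"].fillna(np.inf).to_numpy()
            diffs = np.diff(years)
            if direction == "non_increasing":
                assert np.all(diffs <= 0), f"{name}: {years}"
            else:
                assert np.all(diffs >= 0), f"{name}: {years}"

    def test_unknown_parameter_rejected(self, steady_series):
        with pytest.raises(ValueError, match="param_name"):
            sensitivity_sweep(steady_series, "w3", [0.1])


class TestForecastBandCoverage:
    def test_band_covers_true_decline_rate_path(self):
        """The 95% band contains the projection along the true slope in at
        least 90% of 200 noisy replications."""
        hits = 0
        for seed in range(200):
            s = generate(ScenarioSpec("rep", n0=300.0, slope=-7.0, noise_sd=5.0,
                                      n_years=15, seed=seed))
            m = fit_decline(s, slope_dist="t")
            _, lo, hi = forecast_band(m, horizon=10)
            truth = m.reference_abundance - 7.0 * 10
            hits += bool(lo[-1] <= truth <= hi[-1])
        assert hits / 200 >= 0.90


class TestEstimator:
    def test_fit_exposes_replay_outcome(self, steady_series):
        est = TriggerDecisionModel()
        est.fit(steady_series.years.reshape(-1, 1), steady_series.abundances)
        reference = replay(steady_series)
        assert est.trigger_year_ == reference.trigger_year
        assert est.yearly_log_.equals(reference.yearly_log)
        assert est.score() == pytest.approx(
            reference.yearly_log["value"].iloc[-1])

    def test_sklearn_param_contract(self):
        est = TriggerDecisionModel(px=0.9, w2=0.5)
        params = est.get_params()
        assert params["px"] == 0.9
        clone = TriggerDecisionModel(**params)
        assert clone.get_params() == params
        est.set_params(px=0.2)
        assert est.get_params()["px"] == 0.2
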