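import numpy as np
import pytest

from growthpf import GrowthParams, SyntheticSpec, generate, make_do_profile
from growthpf.events import (CRITICAL_DO, HARVEST_BM, EventSpec, event_error,
                             event_loss, posthoc_event_time, predict_event)
from growthpf.growth_models import crossing_time, evaluate
from growthpf.preprocessing import TimeSeries
from growthpf.synthetic_data import crossing_of_backbone


class TestPredictEvent:
    def test_degenerate_gompertz_special_fraction(self):
        parts = np.tile([2.0, 3.0, 1.0], (10, 1))
        w = np.full(10, 0.1)
        spec = EventSpec("BM", float(np.exp(-1.0)), "max_of_signal")
        ev = predict_event(parts, w, "gompertz", spec)
        assert ev.tpred == pytest.approx(3.0, abs=1e-12)
        assert ev.noncrossing_fraction == 0.0

    def test_degenerate_logistic_midpoint(self):
        parts = np.tile([2.0, 3.0, 1.0], (5, 1))
        ev = predict_event(parts, np.full(5, 0.2), "logistic",
                           EventSpec("BM", 0.5, "max_of_signal"))
        assert ev.tpred == pytest.approx(3.0, abs=1e-12)

    def test_two_particle_weighted_average_vs_grid_oracle(self):
        parts = np.array([[2.0, 3.0, 1.0], [1.5, 4.0, 0.8]])
        w = np.array([0.3, 0.7])
        ev = predict_event(parts, w, "gompertz", HARVEST_BM)
        # dense-grid threshold search per curve
        grid = np.linspace(0, 50, 2_000_001)
        ts = []
        for k, b, c in parts:
            y = evaluate("gompertz", GrowthParams(k, b, c), grid)
            ts.append(grid[np.argmin(np.abs(y - 0.95 * k))])
        assert ev.tpred == pytest.approx(0.3 * ts[0] + 0.7 * ts[1], abs=1e-4)

    def test_all_noncrossing_flagged(self):
        parts = np.tile([2.0, 3.0, 0.0], (4, 1))  # c = 0: never crosses
        ev = predict_event(parts, np.full(4, 0.25), "gompertz", HARVEST_BM)
        assert not ev.crossed
        assert ev.noncrossing_fraction == 1.0


class TestPosthocEventTime:
    def test_bm_matches_closed_form_within_one_interval(self):
        spec = SyntheticSpec(regimes=[(0.0, GrowthParams(2.0, 4.5, 0.9))],
                             noise_sd=0.0, seed=0)
        series, _ = generate(spec)
        topt, crossed = posthoc_event_time(series, HARVEST_BM)
        # the smoothed max differs from k only by curve truncation at t_max
        t_true = crossing_of_backbone(spec, 0.95, "max_of_signal")
        assert crossed
        assert abs(topt - t_true) <= 0.2  # within ~one 0.1 h interval of target
        assert series.values.max() == pytest.approx(2.0, abs=0.02)

    def test_do_matches_20pct_of_initial_crossing(self):
        spec = SyntheticSpec(regimes=[(0.0, GrowthParams(2.0, -4.5, -0.9))],
                             noise_sd=0.0, channel="DO", seed=0)
        series, _ = make_do_profile(spec)
        topt, crossed = posthoc_event_time(series, CRITICAL_DO)
        t_true = crossing_of_backbone(spec, 0.20, "initial_value")
        assert crossed
        assert abs(topt - t_true) <= 0.15

    def test_never_reaching_threshold_flags_and_returns_boundary(self):
        t = np.linspace(0, 5, 30)
        series = TimeSeries(t, 1.0 + 0.01 * t)  # never drops to 20% of start
        topt, crossed = posthoc_event_time(series, CRITICAL_DO)
        assert not crossed
        assert topt in (t[0], t[-1])

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="window"):
            posthoc_event_time(TimeSeries(np.arange(10.0), np.zeros(10)),
                               HARVEST_BM)

    def test_convergence_with_sampling_density(self):
        p = GrowthParams(2.0, 4.5, 0.9)
        t_true = crossing_time("gompertz", p, 0.95)
        errs = []
        for interval in (0.2, 0.05):
            spec = SyntheticSpec(regimes=[(0.0, p)], noise_sd=0.0,
                                 mean_interval=interval, duration=14.0, seed=0)
            series, _ = generate(spec)
            topt, _ = posthoc_event_time(series, HARVEST_BM)
            errs.append(abs(topt - t_true))
        assert errs[1] <= errs[0] + 1e-9


class TestErrorAndLoss:
    def test_event_error_arithmetic(self):
        assert event_error(5.0, 5.0) == 0.0
        assert event_error(5.5, 5.0) == pytest.approx(0.5)
        assert np.isnan(event_error(np.nan, 5.0))

    def test_loss_zero_at_optimum(self, noiseless_series):
        series, _ = noiseless_series
        topt, _ = posthoc_event_time(series, HARVEST_BM)
        assert event_loss(series, topt, topt) == pytest.approx(0.0, abs=1e-12)

    def test_loss_matches_direct_smoothed_lookup(self, noiseless_series):
        # harvesting 30 min early: loss equals the smoothed-curve evaluation
        from growthpf.preprocessing import smooth
        series, _ = noiseless_series
        topt, _ = posthoc_event_time(series, HARVEST_BM)
        tpred = topt - 0.5
        got = event_loss(series, tpred, topt)
        sm = smooth(series)
        y_p = sm.values[np.argmin(np.abs(sm.times - tpred))]
        y_o = sm.values[np.argmin(np.abs(sm.times - topt))]
        assert got == pytest.approx((y_p - y_o) / y_o * 100.0, rel=1e-12)
        assert got < 0  # early harvest loses biomass

    def test_loss_ratio_value(self):
        t = np.arange(30.0)
        series = TimeSeries(t, np.full(30, 2.0))
        # constant series: y[tpred] = y[topt] for any times
        assert event_loss(series, 5.0, 20.0) == pytest.approx(0.0, abs=1e-9)

    def test_loss_outside_span_is_nan(self, noiseless_series):
        series, _ = noiseless_series
        assert np.isnan(event_loss(series, -5.0, 3.0))
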