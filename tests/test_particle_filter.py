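import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import gamma as gamma_dist

from growthpf import GrowthParams, GrowthParticleFilter, SyntheticSpec, generate
from growthpf.growth_models import evaluate
from growthpf.particle_filter import (gamma_mh_step, resample,
                                      systematic_resample_indices,
                                      weighted_quantile)


class TestResample:
    def test_uniform_weights_preserve_mean(self, rng):
        parts = rng.normal(size=(5000, 3))
        out, w, idx = resample(parts, np.full(5000, 1 / 5000), "systematic", rng)
        assert w == pytest.approx(np.full(5000, 1 / 5000))
        assert out.mean(0) == pytest.approx(parts.mean(0), abs=0.05)

    def test_degenerate_weight_copies_single_particle(self, rng):
        parts = np.arange(12.0).reshape(4, 3)
        w = np.array([0.0, 1.0, 0.0, 0.0])
        for scheme in ("systematic", "multinomial"):
            out, _, _ = resample(parts, w, scheme, rng)
            assert np.all(out == parts[1])

    def test_systematic_counts_within_one_of_expectation(self, rng):
        # stratified grid: counts can deviate from n*w by at most 1
        n = 100_000
        w = np.zeros(n)
        w[0], w[1] = 0.7, 0.3
        idx = systematic_resample_indices(w, rng)
        assert abs(np.sum(idx == 0) - 70_000) <= 1
        assert abs(np.sum(idx == 1) - 30_000) <= 1

    def test_negative_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(np.zeros((2, 3)), np.array([1.1, -0.1]), "systematic", rng)


class TestGammaMH:
    def test_long_run_mean_matches_analytic(self):
        # kernel validation: Gamma(3, 2) has mean 1.5
        rng = np.random.default_rng(0)
        x, total = 1.0, 0.0
        n = 100_000
        for _ in range(n):
            x = gamma_mh_step(x, 3.0, 2.0, 0.5, rng)
            total += x
        assert total / n == pytest.approx(1.5, rel=0.02)

    def test_invariance_under_target_draws(self):
        # starting at exact Gamma draws, one step keeps the distribution
        # (chi-square check on the pooled marginal)
        rng = np.random.default_rng(1)
        draws = rng.gamma(3.0, 1 / 2.0, size=20_000)
        stepped = np.array([gamma_mh_step(x, 3.0, 2.0, 0.9, rng) for x in draws])
        qs = gamma_dist.ppf(np.linspace(0.1, 0.9, 9), 3.0, scale=0.5)
        counts = np.histogram(stepped, bins=np.concatenate([[0], qs, [np.inf]]))[0]
        chi2 = np.sum((counts - 2000.0) ** 2 / 2000.0)
        assert chi2 < 30  # 9 dof, generous

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            gamma_mh_step(1.0, 1.0, 1.0, 1.5, np.random.default_rng(0))


class TestStateNoiseUpdate:
    def _pf(self, **kw):
        pf = GrowthParticleFilter(n_particles=10, random_state=0, **kw)
        pf.initialize(particles=np.tile([2.0, 3.0, 1.0], (10, 1)))
        return pf

    def test_zero_increments_shrink_state_noise(self):
        # all-zero increments: posterior rate = prior rate, so the precision
        # posterior mean is (shape + n/2) / rate — noise collapses
        pf = self._pf()
        for _ in range(5):
            pf.increment_history_.append((10, 0.0, 0.0, 0.0))
        pf.update_state_noise()
        g, h = pf.lambda_prior
        assert pf.lambda_ == pytest.approx((g + 25.0) / h, rel=1e-12)

    def test_conjugate_posterior_mean_formula(self):
        # shape 0.1 + 5, rate 1 + 0.5*2 -> mean 5.1/2 = 2.55, cross-checked
        # against numerical integration of the Gamma posterior density
        pf = self._pf()
        for _ in range(5):
            pf.increment_history_.append((2, 0.4, 0.0, 0.0))  # sum d^2 = 2
        pf.update_state_noise()
        assert pf.lambda_ == pytest.approx(5.1 / 2.0, rel=1e-12)
        xs = np.linspace(1e-9, 60, 400_001)
        dens = gamma_dist.pdf(xs, 5.1, scale=1 / 2.0)
        numeric = np.trapezoid(xs * dens, xs)
        assert pf.lambda_ == pytest.approx(numeric, rel=1e-6)

    def test_empty_history_is_noop(self):
        pf = self._pf()
        lam = pf.lambda_
        pf.update_state_noise()
        assert pf.lambda_ == lam


class TestFilter:
    def test_weights_normalized_after_every_update(self, default_series):
        series, _ = default_series
        pf = GrowthParticleFilter(n_particles=200, random_state=0)
        pf.initialize(prior_ranges=pf.default_prior_ranges(series.times,
                                                           series.values))
        for t, y in zip(series.times[:40], series.values[:40]):
            pf.partial_fit(t, y)
            assert abs(pf.weights_.sum() - 1.0) < 1e-12

    def test_identity_seeding(self):
        pf = GrowthParticleFilter(n_particles=50, random_state=0)
        pf.initialize(particles=np.tile([1.0, 2.0, 0.5], (50, 1)))
        assert np.all(pf.particles_ == [1.0, 2.0, 0.5])
        assert pf.weights_ == pytest.approx(np.full(50, 0.02))

    def test_identical_particles_keep_uniform_weights(self):
        pf = GrowthParticleFilter(n_particles=50, random_state=0,
                                  initial_state_noise=(1e12, 1e12, 1e12),
                                  adapt_state_noise=False)
        pf.initialize(particles=np.tile([2.0, 3.0, 1.0], (50, 1)))
        pf.partial_fit(1.0, evaluate("gompertz", GrowthParams(2, 3, 1), 1.0))
        assert pf.weights_ == pytest.approx(np.full(50, 0.02))

    def test_determinism_bit_identical(self, default_series):
        series, _ = default_series
        runs = []
        for _ in range(2):
            pf = GrowthParticleFilter(n_particles=300, random_state=7)
            pf.fit(series.times, series.values)
            runs.append((pf.particles_.copy(), pf.weights_.copy(),
                         pf.lambda_, pf.nu_, pf.gamma_))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
        assert runs[0][2:] == runs[1][2:]

    def test_prior_spec_seeding_deterministic(self):
        ranges = {"k": (1, 3), "b": (0, 6), "c": (0.1, 2)}
        a = GrowthParticleFilter(n_particles=100, random_state=3).initialize(ranges)
        b = GrowthParticleFilter(n_particles=100, random_state=3).initialize(ranges)
        assert np.array_equal(a.particles_, b.particles_)

    def test_non_increasing_time_rejected(self):
        pf = GrowthParticleFilter(n_particles=10, random_state=0)
        pf.initialize(particles=np.tile([1.0, 1.0, 1.0], (10, 1)))
        pf.partial_fit(1.0, 0.5)
        with pytest.raises(ValueError, match="not greater"):
            pf.partial_fit(1.0, 0.6)

    def test_posterior_tracks_truth_against_nls_oracle(self, default_series):
        # noisy single-regime data: the filtered posterior mean should land
        # near an independent nonlinear least-squares fit of the same points
        series, truth = default_series
        pf = GrowthParticleFilter(random_state=1)
        pf.fit(series.times, series.values)

        def gomp(t, k, b, c):
            return k * np.exp(-np.exp(b - c * t))

        popt, _ = curve_fit(gomp, series.times, series.values,
                            p0=[1.5, 4.0, 0.6], maxfev=10000)
        assert pf.posterior_mean_ == pytest.approx(popt, rel=0.07)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GrowthParticleFilter(n_particles=1).initialize({"k": (0, 1),
                                                            "b": (0, 1),
                                                            "c": (0, 1)})


class TestPredict:
    def _degenerate(self, theta, n=20):
        pf = GrowthParticleFilter(n_particles=n, random_state=0)
        pf.initialize(particles=np.tile(theta, (n, 1)))
        return pf

    def test_degenerate_ensemble_predicts_exact_curve(self):
        theta = [2.0, 3.0, 1.0]
        pf = self._degenerate(theta)
        ts = np.array([0.0, 2.0, 5.0])
        fc = pf.predict(ts, return_forecast=True)
        expect = evaluate("gompertz", GrowthParams(*theta), ts)
        assert fc.mean == pytest.approx(expect, rel=1e-12)
        assert fc.upper - fc.lower == pytest.approx(np.zeros(3), abs=1e-12)

    def test_two_particle_mean(self):
        pf = GrowthParticleFilter(n_particles=2, random_state=0)
        pf.initialize(particles=np.array([[2.0, 3.0, 1.0], [1.0, 2.0, 0.5]]))
        t = 4.0
        want = 0.5 * (evaluate("gompertz", GrowthParams(2, 3, 1), t)
                      + evaluate("gompertz", GrowthParams(1, 2, 0.5), t))
        assert pf.predict([t])[0] == pytest.approx(want, rel=1e-12)

    def test_empty_horizon(self):
        pf = self._degenerate([1.0, 1.0, 1.0])
        assert pf.predict([]).size == 0

    def test_forecast_beats_last_value_carried_forward(self):
        # stationary synthetic run, held-out tail
        series, _ = generate(SyntheticSpec(seed=3))
        n = len(series)
        cut = int(0.7 * n)
        pf = GrowthParticleFilter(random_state=2)
        pf.fit(series.times[:cut], series.values[:cut])
        pred = pf.predict(series.times[cut:])
        mse_pf = np.mean((pred - series.values[cut:]) ** 2)
        mse_naive = np.mean((series.values[cut - 1] - series.values[cut:]) ** 2)
        assert mse_pf < mse_naive

    def test_weighted_quantile_median(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([0.25, 0.25, 0.25, 0.25])
        assert 1.0 <= weighted_quantile(v, w, 0.5)[0] <= 4.0


class TestSerialization:
    def test_state_round_trip(self, default_series):
        import json
        series, _ = default_series
        pf = GrowthParticleFilter(n_particles=100, random_state=5)
        pf.fit(series.times[:50], series.values[:50])
        blob = json.dumps(pf.to_state())
        clone = GrowthParticleFilter(n_particles=100, random_state=5)
        clone.from_state(json.loads(blob))
        assert np.array_equal(clone.particles_, pf.particles_)
        assert clone.lambda_ == pf.lambda_
        assert clone.window_times_ == pf.window_times_

    def test_sklearn_get_set_params(self):
        pf = GrowthParticleFilter()
        params = pf.get_params()
        assert params["sample_window"] == 20
        pf.set_params(n_particles=123)
        assert pf.n_particles == 123
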