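"""Sequential importance resampling over growth-model parameters.

The filter represents the posterior over the Gompertz/Logistic coefficient
triple ``(k, b, c)`` by a weighted particle ensemble.  Between observations
each particle performs a Gaussian random walk whose per-parameter variances
``1/lambda`` (k), ``1/nu`` (b) and ``1/gamma`` (c) — the state-noise
precisions — are themselves inferred online from the random-walk increments
realized by the particles that survive resampling over the most recent
``state_noise_window`` updates.  ``lambda`` and ``nu`` receive conjugate
Gamma updates; ``gamma`` is refreshed by one Metropolis-Hastings step with a
multiplicative uniform proposal.  Large precisions give stationary accuracy;
when the data disagree with the ensemble the surviving increments grow, the
precisions drop and the filter switches to fast tracking.

The observation model is Gaussian on the transformed (log) signal scale with
a per-particle noise precision.  The sensor noise level is a static physical
property, so its conjugate Gamma statistics accumulate one-step-ahead
residuals over the whole run (carried through resampling) instead of being
re-estimated from the current window alone; a mid-culture level step then
cannot be explained away as a transient burst of observation noise and the
mismatch pressure reaches the state-noise adaptation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .growth_models import ModelFamily, evaluate_many

__all__ = [
    "GrowthParticleFilter",
    "Forecast",
    "resample",
    "systematic_resample_indices",
    "gamma_mh_step",
    "weighted_quantile",
]

_MIN_PRECISION = 1e-12
_MAX_PRECISION = 1e12


@dataclass
class Forecast:
    """Point forecasts with central credible intervals.

    ``mean`` is the weighted ensemble expectation of the curve value at each
    horizon time; ``lower``/``upper`` are weighted quantiles (default 5-95%).
    """

    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def systematic_resample_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic (stratified-grid) resampling indices.

    One uniform offset places ``n`` equally spaced pointers on the cumulative
    weight profile, so the copy count of particle ``i`` differs from
    ``n * w_i`` by at most 1.
    """
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=n - 1)


def resample(particles: np.ndarray, weights: np.ndarray, scheme: str,
             rng: np.random.Generator):
    """Draw ``n`` particles proportional to ``weights``; reset weights to 1/n.

    Returns ``(particles, weights, indices)`` so that ancillary per-particle
    state can be carried through the same selection.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("resample: negative weight")
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("resample: weights must have positive finite sum")
    w = weights / total
    n = len(w)
    if scheme == "systematic":
        idx = systematic_resample_indices(w, rng)
    elif scheme == "multinomial":
        idx = rng.choice(n, size=n, p=w)
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    return particles[idx], np.full(n, 1.0 / n), idx


def gamma_mh_step(x: float, shape: float, rate: float, delta: float,
                  rng: np.random.Generator) -> float:
    """One Metropolis-Hastings step targeting Gamma(shape, rate).

    Proposal: ``x' = x * u`` with ``u ~ Uniform(delta, 1/delta)``.  The
    Hastings correction for the multiplicative kernel contributes a factor
    ``x/x'``, giving ``log A = (shape - 2) log(x'/x) - rate (x' - x)``.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("gamma_mh_step: delta must lie in (0, 1)")
    u = rng.uniform(delta, 1.0 / delta)
    xp = x * u
    log_alpha = (shape - 2.0) * np.log(xp / x) - rate * (xp - x)
    if np.log(rng.random()) < log_alpha:
        return xp
    return x


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Weighted empirical quantiles (inverse-CDF convention)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.interp(np.atleast_1d(q), cdf, v)


class GrowthParticleFilter(BaseEstimator):
    """Online Bayesian inference of time-varying growth-model parameters.

    Parameters
    ----------
    family : {"gompertz", "logistic"}
        Growth law whose coefficients are tracked.
    n_particles : int, default 1000
        Ensemble size N.
    sample_window : int, default 20
        Number of most recent observations the likelihood sees (W).
    state_noise_window : int, default 10
        Number of most recent update steps whose realized random-walk
        increments drive the state-noise precisions (S).
    lambda_prior, nu_prior, gamma_prior : (shape, rate), default (0.1, 1.0)
        Gamma hyperpriors for the state-noise precisions of k, b and c.
    obs_precision_prior : (shape, rate), default (1e-3, 1e-3)
        Gamma prior for the observation-noise precision.  Deliberately
        vague (Jeffreys-type): with a rate of order 1 the windowed
        conjugate posterior mean would be capped near ``W/2`` regardless of
        how small the residuals are, flattening the likelihood on low-noise
        signals.
    mh_delta : float, default 0.9
        Multiplicative-proposal width for the Metropolis-Hastings update of
        the c-parameter precision gamma.
    initial_state_noise : (lambda, nu, gamma) or None, default (100, 100, 100)
        Starting values of the three precisions, i.e. the filter begins in
        stationary-accuracy mode (random-walk sd 0.1 per parameter).  The
        initial particle spread, not the random walk, does the cold-start
        exploration, and the adaptation can still drop the precisions by
        roughly an order of magnitude per buffer refresh when tracking
        demands it.  ``None`` starts at the Gamma-prior means (very diffuse).
    mh_steps : int, default 25
        Metropolis-Hastings kernel iterations per filter update.  Each
        proposal can move gamma by at most a factor 1/mh_delta, so a single
        iteration cannot track a posterior that concentrates far from the
        current value on short series; iterating the same kernel fixes the
        mobility without changing the target.
    resampling : {"systematic", "multinomial"}
        Resampling scheme; systematic by default for lower variance.
    adapt_state_noise : bool, default True
        Set False to pin the precisions at their initial values (static-like
        behaviour, used in tests).
    enforce_time_order : bool, default True
        Require strictly increasing update times.  The reshuffled-profile
        batch fit disables this.
    record_diagnostics : bool, default True
        Keep per-update traces (one-step-ahead prediction, state-noise sds,
        ensemble means) in ``diagnostics_``.
    random_state : int or numpy Generator, optional
        Seed for the single random stream driving all stochastic stages.

    Attributes (after ``initialize``/``fit``)
    ----------
    particles_ : (N, 3) array of (k, b, c) rows
    weights_ : (N,) normalized weights
    obs_precision_ : (N,) per-particle observation-noise precision
    lambda_, nu_, gamma_ : state-noise precisions for k, b, c
    window_times_, window_values_ : the current observation window
    n_updates_ : number of update steps performed
    """

    def __init__(self, family="gompertz", n_particles=1000, sample_window=20,
                 state_noise_window=10, lambda_prior=(0.1, 1.0),
                 nu_prior=(0.1, 1.0), gamma_prior=(0.1, 1.0),
                 obs_precision_prior=(1e-3, 1e-3), mh_delta=0.9,
                 mh_steps=25, initial_state_noise=(100.0, 100.0, 100.0),
                 resampling="systematic", adapt_state_noise=True,
                 enforce_time_order=True, record_diagnostics=True,
                 random_state=None):
        self.family = family
        self.n_particles = n_particles
        self.sample_window = sample_window
        self.state_noise_window = state_noise_window
        self.lambda_prior = lambda_prior
        self.nu_prior = nu_prior
        self.gamma_prior = gamma_prior
        self.obs_precision_prior = obs_precision_prior
        self.mh_delta = mh_delta
        self.mh_steps = mh_steps
        self.initial_state_noise = initial_state_noise
        self.resampling = resampling
        self.adapt_state_noise = adapt_state_noise
        self.enforce_time_order = enforce_time_order
        self.record_diagnostics = record_diagnostics
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _check_config(self):
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.sample_window < 2 or self.state_noise_window < 2:
            raise ValueError("sample_window and state_noise_window must be >= 2")
        if not (0.0 < self.mh_delta < 1.0):
            raise ValueError("mh_delta must lie in (0, 1)")
        if self.resampling not in ("systematic", "multinomial"):
            raise ValueError("resampling must be 'systematic' or 'multinomial'")
        ModelFamily(str(self.family).lower())

    def initialize(self, prior_ranges=None, particles=None, obs_precision=None,
                   state_noise=None):
        """Set up the ensemble, precisions and empty observation window.

        Either ``particles`` (an (N, 3) array, e.g. a static-fit posterior
        sample) or ``prior_ranges`` (dict with ``k``, ``b``, ``c`` mapping to
        (low, high) tuples for a uniform cold start) must be given.  Weights
        start uniform; state-noise precisions start at their Gamma-prior
        means unless ``state_noise`` (a (lambda, nu, gamma) triple) overrides
        them.
        """
        self._check_config()
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        self._rng = rng
        n = self.n_particles
        if particles is not None:
            particles = np.asarray(particles, dtype=float)
            if particles.ndim != 2 or particles.shape[1] != 3:
                raise ValueError("particles must be an (N, 3) array of (k, b, c)")
            if particles.shape[0] != n:
                idx = rng.integers(0, particles.shape[0], size=n)
                particles = particles[idx]
            self.particles_ = particles.copy()
        elif prior_ranges is not None:
            cols = []
            for name in ("k", "b", "c"):
                lo, hi = prior_ranges[name]
                cols.append(rng.uniform(lo, hi, size=n))
            self.particles_ = np.column_stack(cols)
        else:
            raise ValueError("initialize: provide particles or prior_ranges")

        self.weights_ = np.full(n, 1.0 / n)
        a0, b0 = self.obs_precision_prior
        if obs_precision is not None:
            op = np.asarray(obs_precision, dtype=float)
            self.obs_precision_ = (np.full(n, float(op)) if op.ndim == 0
                                   else op[:n].copy() if op.shape[0] >= n
                                   else np.resize(op, n))
            # encode the supplied precision as prior pseudo-observations so a
            # warm start retains the initializing culture's noise estimate
            self.obs_shape_ = np.full(n, a0 + 10.0)
            self.obs_rate_ = (a0 + 10.0) / np.maximum(self.obs_precision_, 1e-12)
        else:
            self.obs_precision_ = np.full(n, a0 / b0)
            self.obs_shape_ = np.full(n, a0)
            self.obs_rate_ = np.full(n, b0)
        if state_noise is None:
            state_noise = self.initial_state_noise
        if state_noise is not None:
            self.lambda_, self.nu_, self.gamma_ = map(float, state_noise)
        else:
            self.lambda_ = self.lambda_prior[0] / self.lambda_prior[1]
            self.nu_ = self.nu_prior[0] / self.nu_prior[1]
            self.gamma_ = self.gamma_prior[0] / self.gamma_prior[1]
        self.window_times_ = []
        self.window_values_ = []
        # per-step sufficient statistics of realized increments:
        # (count, sum d_k^2, sum d_b^2, sum d_c^2)
        self.increment_history_ = deque(maxlen=self.state_noise_window)
        self.n_updates_ = 0
        self.diagnostics_ = {key: [] for key in
                             ("time", "obs", "pred_one_step", "sd_k", "sd_b",
                              "sd_c", "mean_k", "mean_b", "mean_c")}
        return self

    @staticmethod
    def default_prior_ranges(times, values):
        """Heuristic uniform cold-start ranges bracketing the data.

        The asymptote range brackets the observed signal maximum; the rate
        magnitude spans roughly one to twenty transitions per observed time
        span, with the sign taken from the overall trend; the offset range
        covers transition midpoints anywhere in the observed span.
        """
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        vspan = max(values.max() - values.min(), 1e-3)
        tspan = max(times.max() - times.min(), 1e-6)
        increasing = values[-1] >= values[0]
        k_range = (values.max() - 0.1 * vspan, values.max() + vspan)
        c_lo, c_hi = 1.0 / tspan, 20.0 / tspan
        if increasing:
            c_range = (c_lo, c_hi)
            b_range = (c_lo * times.min() + 1e-6, c_hi * times.max())
        else:
            c_range = (-c_hi, -c_lo)
            b_range = (-c_hi * times.max(), -c_lo * times.min() - 1e-6)
        return {"k": k_range, "b": b_range, "c": c_range}

    # ------------------------------------------------------------------ update

    def _log_likelihood(self, particles, obs_precision):
        """Gaussian log-likelihood of the windowed values per particle."""
        t = np.asarray(self.window_times_, dtype=float)
        y = np.asarray(self.window_values_, dtype=float)
        curves = evaluate_many(self.family, particles[:, 0], particles[:, 1],
                               particles[:, 2], t)
        ss = np.square(curves - y[None, :]).sum(axis=1)
        m = len(y)
        r = obs_precision
        return 0.5 * m * (np.log(r) - np.log(2.0 * np.pi)) - 0.5 * r * ss, ss

    def partial_fit(self, times, values):
        """Assimilate one or more new observations, one update per point."""
        if not hasattr(self, "particles_"):
            raise RuntimeError("call initialize() or fit() before partial_fit()")
        times = np.atleast_1d(np.asarray(times, dtype=float))
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if times.shape != values.shape:
            raise ValueError("times and values must have matching shapes")
        for t, y in zip(times, values):
            self._update_one(float(t), float(y))
        return self

    def _update_one(self, t: float, y: float):
        if not (np.isfinite(t) and np.isfinite(y)):
            raise ValueError("update: time and value must be finite")
        if (self.enforce_time_order and self.window_times_
                and t <= self.window_times_[-1]):
            raise ValueError(
                f"update: time {t} not greater than last window time "
                f"{self.window_times_[-1]}")
        rng = self._rng
        n = self.n_particles

        if self.record_diagnostics:
            pred = float(np.dot(self.weights_, evaluate_many(
                self.family, self.particles_[:, 0], self.particles_[:, 1],
                self.particles_[:, 2], [t])[:, 0]))

        # (i) slide the observation window
        self.window_times_.append(t)
        self.window_values_.append(y)
        if len(self.window_times_) > self.sample_window:
            self.window_times_.pop(0)
            self.window_values_.pop(0)

        # (ii) random-walk propagation
        sds = np.array([self.lambda_, self.nu_, self.gamma_]) ** -0.5
        incr = rng.standard_normal((n, 3)) * sds[None, :]
        proposed = self.particles_ + incr

        # accumulate the obs-noise statistics with the one-step-ahead
        # residual of each proposed particle at the new point; a 3-sigma
        # gate keeps structural breaks (level steps, regime switches) from
        # being booked as sensor noise — the mismatch must be resolved by
        # the parameters, not absorbed into the noise estimate
        res_new = evaluate_many(self.family, proposed[:, 0], proposed[:, 1],
                                proposed[:, 2], [t])[:, 0] - y
        ok = res_new ** 2 <= 9.0 / np.maximum(self.obs_precision_, _MIN_PRECISION)
        self.obs_shape_ = self.obs_shape_ + 0.5 * ok
        self.obs_rate_ = self.obs_rate_ + 0.5 * ok * res_new ** 2
        # empirical-Bayes plug-in: the posterior mean, not a Gamma draw — a
        # sampled precision adds a spurious selection channel (low draws act
        # as likelihood tempering and out-compete parameter moves whenever
        # the whole ensemble misfits)
        self.obs_precision_ = np.clip(self.obs_shape_ / self.obs_rate_,
                                      _MIN_PRECISION, _MAX_PRECISION)

        # (iii) importance weights from the full window (log space, max-shifted)
        logw, _ = self._log_likelihood(proposed, self.obs_precision_)
        logw = logw + np.log(np.maximum(self.weights_, 1e-300)) + np.log(n)
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:  # full degeneracy guard
            w = np.full(n, 1.0 / n)
        else:
            w /= total

        # (iv) resample; carry increments and obs-noise state through selection
        _, self.weights_, idx = resample(proposed, w, self.resampling, rng)
        self.particles_ = proposed[idx]
        self.obs_precision_ = self.obs_precision_[idx]
        self.obs_shape_ = self.obs_shape_[idx]
        self.obs_rate_ = self.obs_rate_[idx]
        incr = incr[idx]

        # (v) state-noise adaptation from surviving increments
        self.increment_history_.append(
            (n, float(np.sum(incr[:, 0] ** 2)), float(np.sum(incr[:, 1] ** 2)),
             float(np.sum(incr[:, 2] ** 2))))
        if self.adapt_state_noise:
            self.update_state_noise()

        self.n_updates_ += 1
        if self.record_diagnostics:
            mean = self.weights_ @ self.particles_
            d = self.diagnostics_
            d["time"].append(t)
            d["obs"].append(y)
            d["pred_one_step"].append(pred)
            d["sd_k"].append(self.lambda_ ** -0.5)
            d["sd_b"].append(self.nu_ ** -0.5)
            d["sd_c"].append(self.gamma_ ** -0.5)
            d["mean_k"].append(mean[0])
            d["mean_b"].append(mean[1])
            d["mean_c"].append(mean[2])
        return self

    def update_state_noise(self):
        """Refresh lambda, nu (conjugate) and gamma (one MH step).

        The Gamma posterior for each precision has shape ``prior_shape +
        n_increments/2`` and rate ``prior_rate + sum(increments^2)/2``, with
        the increment statistics pooled over the history buffer.  lambda and
        nu are set to the posterior mean; gamma takes one Metropolis-Hastings
        step against the same posterior density.
        """
        if not self.increment_history_:
            return self
        counts = sum(h[0] for h in self.increment_history_)
        ss = [sum(h[j] for h in self.increment_history_) for j in (1, 2, 3)]
        g, h = self.lambda_prior
        self.lambda_ = float(np.clip((g + 0.5 * counts) / (h + 0.5 * ss[0]),
                                     _MIN_PRECISION, _MAX_PRECISION))
        alpha, beta = self.nu_prior
        self.nu_ = float(np.clip((alpha + 0.5 * counts) / (beta + 0.5 * ss[1]),
                                 _MIN_PRECISION, _MAX_PRECISION))
        a, b = self.gamma_prior
        gam = self.gamma_
        for _ in range(max(1, int(self.mh_steps))):
            gam = gamma_mh_step(gam, a + 0.5 * counts, b + 0.5 * ss[2],
                                self.mh_delta, self._rng)
        self.gamma_ = float(np.clip(gam, _MIN_PRECISION, _MAX_PRECISION))
        return self

    # ------------------------------------------------------------------ fit/predict

    def fit(self, times, values):
        """Cold-start from data-derived prior ranges and filter the series.

        ``times`` and ``values`` are equal-length 1-D arrays on the
        transformed signal scale.  For warm starts call :meth:`initialize`
        with a particle ensemble first and then :meth:`partial_fit`.
        """
        times = np.asarray(times, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if not hasattr(self, "particles_"):
            self.initialize(prior_ranges=self.default_prior_ranges(times, values))
        return self.partial_fit(times, values)

    def predict(self, times, interval=(0.05, 0.95), return_forecast=False):
        """Forecast the signal at ``times``.

        Point estimate = weighted ensemble mean of each particle's curve;
        intervals are weighted quantiles.  Returns the mean array, or a
        :class:`Forecast` when ``return_forecast`` is True.
        """
        if not hasattr(self, "particles_"):
            raise RuntimeError("predict: filter not initialized")
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if times.size == 0:
            empty = np.array([])
            return (Forecast(empty, empty, empty, empty) if return_forecast
                    else empty)
        curves = evaluate_many(self.family, self.particles_[:, 0],
                               self.particles_[:, 1], self.particles_[:, 2],
                               times)
        mean = self.weights_ @ curves
        if not return_forecast:
            return mean
        lo = np.empty_like(mean)
        hi = np.empty_like(mean)
        for j in range(len(times)):
            lo[j], hi[j] = weighted_quantile(curves[:, j], self.weights_,
                                             list(interval))
        return Forecast(times, mean, lo, hi)

    # ------------------------------------------------------------------ misc

    @property
    def posterior_mean_(self) -> np.ndarray:
        """Weighted ensemble mean of (k, b, c)."""
        return self.weights_ @ self.particles_

    def diagnostics_frame(self):
        """Per-update traces as a pandas DataFrame."""
        import pandas as pd
        return pd.DataFrame(self.diagnostics_)

    def to_state(self) -> dict:
        """JSON-serializable snapshot for checkpoint/restart."""
        return {
            "family": str(ModelFamily(str(self.family).lower()).value),
            "particles": self.particles_.tolist(),
            "weights": self.weights_.tolist(),
            "obs_precision": self.obs_precision_.tolist(),
            "obs_shape": self.obs_shape_.tolist(),
            "obs_rate": self.obs_rate_.tolist(),
            "state_noise": [self.lambda_, self.nu_, self.gamma_],
            "window_times": list(self.window_times_),
            "window_values": list(self.window_values_),
            "increment_history": [list(h) for h in self.increment_history_],
            "n_updates": self.n_updates_,
        }

    def from_state(self, state: dict):
        """Restore a snapshot produced by :meth:`to_state`."""
        self._check_config()
        self._rng = (self.random_state
                     if isinstance(self.random_state, np.random.Generator)
                     else np.random.default_rng(self.random_state))
        self.particles_ = np.asarray(state["particles"], dtype=float)
        self.weights_ = np.asarray(state["weights"], dtype=float)
        self.obs_precision_ = np.asarray(state["obs_precision"], dtype=float)
        a0, b0 = self.obs_precision_prior
        self.obs_shape_ = np.asarray(state.get("obs_shape",
                                               np.full(len(self.obs_precision_), a0)),
                                     dtype=float)
        self.obs_rate_ = np.asarray(state.get("obs_rate",
                                              np.full(len(self.obs_precision_), b0)),
                                    dtype=float)
        self.lambda_, self.nu_, self.gamma_ = map(float, state["state_noise"])
        self.window_times_ = list(state["window_times"])
        self.window_values_ = list(state["window_values"])
        self.increment_history_ = deque(
            (tuple(h) for h in state["increment_history"]),
            maxlen=self.state_noise_window)
        self.n_updates_ = int(state["n_updates"])
        self.diagnostics_ = {key: [] for key in
                             ("time", "obs", "pred_one_step", "sd_k", "sd_b",
                              "sd_c", "mean_k", "mean_b", "mean_c")}
        return self
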