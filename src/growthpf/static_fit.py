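"""Batch growth-model fitting by reshuffled-profile sequential resampling.

A static model (time-invariant parameters) is obtained by running the same
sequential-importance-resampling updates used for online filtering over a
randomly permuted copy of the complete profile, for several sweeps with a
fresh permutation each sweep.  Because the sliding sample window then always
spans points from the whole profile, the particle ensemble converges to a
posterior over one parameter set describing the entire curve.  The resulting
ensemble doubles as a warm-start initializer for the online filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .particle_filter import Forecast, GrowthParticleFilter

__all__ = ["StaticGrowthModel", "StaticFitResult", "fit_static"]


@dataclass
class StaticFitResult:
    """Posterior sample of (k, b, c) from a batch fit."""

    particles: np.ndarray
    weights: np.ndarray
    obs_precision: np.ndarray
    family: str
    n_sweeps: int
    source: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "particles": self.particles.tolist(),
            "weights": self.weights.tolist(),
            "obs_precision": self.obs_precision.tolist(),
            "n_sweeps": self.n_sweeps,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StaticFitResult":
        return cls(np.asarray(d["particles"], float),
                   np.asarray(d["weights"], float),
                   np.asarray(d["obs_precision"], float),
                   d["family"], int(d["n_sweeps"]), d.get("source", ""))


class StaticGrowthModel(BaseEstimator):
    """Static Gompertz/Logistic model fitted to one complete profile.

    Each sweep re-permutes the (time, value) pairs and applies the particle
    updates of :class:`~growthpf.particle_filter.GrowthParticleFilter` to the
    permuted stream; sweeps stop early when the posterior means of all three
    parameters change by less than ``tol`` relative between sweeps.

    Parameters mirror the filter's; ``n_sweeps`` (default 50) bounds the
    number of passes and ``prior_ranges`` optionally overrides the
    data-derived uniform cold-start ranges.
    """

    def __init__(self, family="gompertz", n_particles=1000, sample_window=20,
                 state_noise_window=10, n_sweeps=50, tol=1e-3,
                 prior_ranges=None, resampling="systematic", random_state=None):
        self.family = family
        self.n_particles = n_particles
        self.sample_window = sample_window
        self.state_noise_window = state_noise_window
        self.n_sweeps = n_sweeps
        self.tol = tol
        self.prior_ranges = prior_ranges
        self.resampling = resampling
        self.random_state = random_state

    def fit(self, times, values, source: str = ""):
        """Fit on a complete profile (transformed scale)."""
        times = np.asarray(times, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) < self.sample_window:
            raise ValueError(
                f"fit_static: series length {len(times)} shorter than the "
                f"sample window {self.sample_window}")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

        rng = np.random.default_rng(self.random_state)
        pf = GrowthParticleFilter(
            family=self.family, n_particles=self.n_particles,
            sample_window=self.sample_window,
            state_noise_window=self.state_noise_window,
            resampling=self.resampling, enforce_time_order=False,
            record_diagnostics=False, random_state=rng)
        ranges = self.prior_ranges or pf.default_prior_ranges(times, values)
        pf.initialize(prior_ranges=ranges)

        prev_mean = None
        sweeps_done = 0
        for sweep in range(self.n_sweeps):
            perm = rng.permutation(len(times))
            pf.partial_fit(times[perm], values[perm])
            sweeps_done = sweep + 1
            mean = pf.posterior_mean_
            if prev_mean is not None:
                rel = np.abs(mean - prev_mean) / np.maximum(np.abs(prev_mean), 1e-9)
                if np.max(rel) < self.tol:
                    break
            prev_mean = mean

        self.filter_ = pf
        self.result_ = StaticFitResult(
            particles=pf.particles_.copy(), weights=pf.weights_.copy(),
            obs_precision=pf.obs_precision_.copy(),
            family=str(self.family), n_sweeps=sweeps_done, source=source)
        return self

    @property
    def posterior_mean_(self) -> np.ndarray:
        return self.result_.posterior_mean

    def predict(self, times, interval=(0.05, 0.95), return_forecast=False):
        """Forecast with frozen parameters (same contract as the filter)."""
        if not hasattr(self, "filter_"):
            raise RuntimeError("predict: model not fitted")
        return self.filter_.predict(times, interval=interval,
                                    return_forecast=return_forecast)

    def to_ensemble(self) -> StaticFitResult:
        """The posterior sample, usable to warm-start an online filter."""
        return self.result_


def fit_static(times, values, family="gompertz", n_sweeps=50, source="",
               random_state=None, **kwargs) -> StaticFitResult:
    """Functional wrapper over :class:`StaticGrowthModel`."""
    model = StaticGrowthModel(family=family, n_sweeps=n_sweeps,
                              random_state=random_state, **kwargs)
    model.fit(times, values, source=source)
    return model.result_


def predict_static(fit: StaticFitResult, times, interval=(0.05, 0.95),
                   return_forecast=False):
    """Forecast from a stored :class:`StaticFitResult` (frozen parameters)."""
    from .growth_models import evaluate_many
    from .particle_filter import weighted_quantile

    times = np.atleast_1d(np.asarray(times, dtype=float))
    w = fit.weights / fit.weights.sum()
    if times.size == 0:
        empty = np.array([])
        return Forecast(empty, empty, empty, empty) if return_forecast else empty
    curves = evaluate_many(fit.family, fit.particles[:, 0], fit.particles[:, 1],
                           fit.particles[:, 2], times)
    mean = w @ curves
    if not return_forecast:
        return mean
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for j in range(len(times)):
        lo[j], hi[j] = weighted_quantile(curves[:, j], w, list(interval))
    return Forecast(times, mean, lo, hi)


__all__.append("predict_static")
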