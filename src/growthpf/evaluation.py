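"""Predictive-accuracy metrics and significance testing.

Forecasts are scored only on strictly-future observations.  Filter-vs-static
comparisons use the paired squared residuals per future time point; the
one-sided sign-flip permutation test asks whether the filter's residuals are
systematically smaller, and Benjamini-Hochberg step-up q-values control the
false discovery rate over the resulting family of p-values (significance is
declared at FDR < 0.05).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ssd",
    "mse",
    "squared_residuals",
    "paired_permutation_test",
    "bh_fdr",
    "windowed_one_step_mse",
]


def _pair(observed, predicted):
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def ssd(observed, predicted) -> float:
    """Sum of squared deviations over the evaluation points."""
    y, yhat = _pair(observed, predicted)
    if y.size == 0:
        raise ValueError("ssd: need at least one point")
    return float(np.sum((y - yhat) ** 2))


def mse(observed, predicted) -> float:
    """Mean squared error: ssd divided by the number of future points.

    Comparable across split fractions as the filter progresses through the
    series, unlike the raw sum.
    """
    y, yhat = _pair(observed, predicted)
    if y.size == 0:
        raise ValueError("mse: zero future points")
    return ssd(y, yhat) / y.size


def squared_residuals(observed, predicted) -> np.ndarray:
    """Per-time squared residuals, the paired test statistic inputs."""
    y, yhat = _pair(observed, predicted)
    return (y - yhat) ** 2


def paired_permutation_test(eps_a, eps_b, n_permutations: int = 100_000,
                            random_state=None, exhaustive_max: int = 0) -> float:
    """One-sided sign-flip permutation p-value for paired residuals.

    With ``s = eps_a - eps_b`` the null of exchangeable pairs is sampled by
    flipping the sign of each ``s`` independently; ``p = kappa / K`` where
    ``kappa`` counts replicates whose mean is *strictly* below the observed
    mean (alternative: E[s] < 0, i.e. model A more accurate).  Ties are not
    counted; with continuous residuals they have measure zero.  When
    ``n <= exhaustive_max`` all ``2^n`` sign assignments are enumerated
    instead of sampled.
    """
    s = np.asarray(eps_a, dtype=float).ravel() - np.asarray(eps_b, dtype=float).ravel()
    n = s.size
    if n == 0:
        raise ValueError("paired_permutation_test: empty input")
    if n_permutations < 1:
        raise ValueError("paired_permutation_test: n_permutations must be >= 1")
    observed = s.mean()
    if n <= exhaustive_max:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n),
                                     indexing="ij")).reshape(n, -1).T
        means = signs @ s / n
        return float(np.mean(means < observed))
    rng = np.random.default_rng(random_state)
    k = int(n_permutations)
    kappa = 0
    # chunked so K=1e5 at large n stays within modest memory
    chunk = max(1, min(k, 20_000_000 // max(n, 1)))
    done = 0
    while done < k:
        m = min(chunk, k - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n))
        kappa += int(np.sum(signs @ s / n < observed))
        done += m
    return kappa / k


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values, mapped
    back to the input order; element-wise >= input and <= 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def windowed_one_step_mse(errors, window: int = 15):
    """Rolling mean of squared one-step-ahead errors.

    ``errors`` are the one-step-ahead prediction errors aligned to the
    observations.  Returns ``(values, full_window)`` where ``values[i]`` is
    the mean of the squared errors over the trailing ``window`` samples
    (fewer at the start) and ``full_window[i]`` flags whether the full
    window was available.
    """
    e2 = np.square(np.asarray(errors, dtype=float).ravel())
    n = e2.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(e2)])
    for i in range(n):
        lo = max(0, i - window + 1)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    full = np.arange(n) >= window - 1
    return out, full
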