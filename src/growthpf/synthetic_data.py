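"""Synthetic shake-flask-like BM/DO signal generator with known ground truth.

The generator is phenomenological: it draws Gompertz/Logistic-shaped signals
on the transformed (log) scale with additive Gaussian observation noise and
mildly irregular sampling, and it can inject the two classes of
non-stationary events seen in real shake-flask cultures — abrupt step
changes in signal level (a sensor artefact) and mid-culture growth-rate
slowdowns (a metabolic response, modelled as a regime switch in the
parameters).  No mechanistic metabolism or oxygen-transfer simulation is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .growth_models import GrowthParams, evaluate, time_to_level
from .preprocessing import TimeSeries

__all__ = ["SyntheticSpec", "generate", "make_do_profile"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic culture signal.

    ``regimes`` is an ordered list of ``(start_time, GrowthParams)``; the
    active parameter triple switches at each boundary (first start must be
    0).  With ``continuous=True`` the offset ``b`` of each later regime is
    re-solved so the backbone stays continuous at the switch (slowdown
    scenario); otherwise switches may introduce genuine discontinuities.
    ``step_events`` adds abrupt additive offsets (log-units) at given times.
    Sampling times are jittered uniformly by ``±jitter * interval``.
    """

    family: str = "gompertz"
    regimes: List[Tuple[float, GrowthParams]] = field(
        default_factory=lambda: [(0.0, GrowthParams(2.0, 5.2, 0.8))])
    step_events: List[Tuple[float, float]] = field(default_factory=list)
    noise_sd: float = 0.05
    duration: float = 12.0
    mean_interval: float = 0.1
    jitter: float = 0.0
    continuous: bool = False
    channel: str = "BM"
    seed: int = 0

    def __post_init__(self):
        if not self.regimes or self.regimes[0][0] != 0.0:
            raise ValueError("regimes must start at time 0")
        starts = [r[0] for r in self.regimes]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("regime start times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0 or self.mean_interval <= 0:
            raise ValueError("duration and mean_interval must be > 0")
        if not (0.0 <= self.jitter < 0.5):
            raise ValueError("jitter must lie in [0, 0.5)")


def _effective_regimes(spec: SyntheticSpec):
    """Resolve regime parameters, enforcing backbone continuity if asked."""
    regimes = [(t0, p) for t0, p in spec.regimes]
    if not spec.continuous or len(regimes) == 1:
        return regimes
    out = [regimes[0]]
    for t0, p in regimes[1:]:
        prev_t0, prev_p = out[-1]
        v = evaluate(spec.family, prev_p, t0)
        # re-solve b so the new regime's curve passes through (t0, v)
        ratio = v / p.k
        if not (0.0 < ratio < 1.0):
            out.append((t0, p))
            continue
        if spec.family == "gompertz":
            b_new = p.c * t0 + np.log(-np.log(ratio))
        else:
            b_new = p.c * t0 + np.log(1.0 / ratio - 1.0)
        out.append((t0, GrowthParams(p.k, float(b_new), p.c)))
    return out


def _backbone(spec: SyntheticSpec, times: np.ndarray):
    regimes = _effective_regimes(spec)
    starts = np.array([r[0] for r in regimes])
    idx = np.searchsorted(starts, times, side="right") - 1
    values = np.empty_like(times)
    truth = []
    for i, (t, j) in enumerate(zip(times, idx)):
        p = regimes[j][1]
        values[i] = evaluate(spec.family, p, t)
        truth.append(p)
    # cumulative additive step offsets
    for t_s, offset in spec.step_events:
        values[times >= t_s] += offset
    return values, truth


def generate(spec: SyntheticSpec):
    """Generate one synthetic series plus its ground-truth trajectory.

    Returns ``(TimeSeries, truth)`` where ``truth`` is the list of active
    :class:`GrowthParams` per sample.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(2, int(round(spec.duration / spec.mean_interval)) + 1)
    times = np.linspace(0.0, spec.duration, n)
    if spec.jitter > 0:
        inner = times[1:-1] + rng.uniform(-spec.jitter, spec.jitter,
                                          n - 2) * spec.mean_interval
        times = np.concatenate([[times[0]], np.sort(inner), [times[-1]]])
    values, truth = _backbone(spec, times)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=len(times))
    series = TimeSeries(times, values, channel=spec.channel,
                        metadata={"synthetic": True, "seed": spec.seed})
    return series, truth


def make_do_profile(spec: SyntheticSpec, floor: float = None):
    """Monotone-declining DO-like profile (mirror sign convention).

    Requires regimes with ``b < 0`` and ``c < 0``; a warning is raised
    otherwise.  ``floor`` clips the backbone from below to mimic the
    near-zero DO tail of oxygen-exhausted cultures.
    """
    import warnings

    for _, p in spec.regimes:
        if not (p.b < 0 and p.c < 0):
            warnings.warn("make_do_profile expects declining-convention "
                          "parameters (b < 0 and c < 0)", stacklevel=2)
            break
    series, truth = generate(spec)
    if floor is not None:
        series = TimeSeries(series.times, np.maximum(series.values, floor),
                            channel=series.channel, metadata=series.metadata)
    return series, truth


def crossing_of_backbone(spec: SyntheticSpec, fraction: float,
                         reference: str = "max_of_signal") -> float:
    """Closed-form threshold crossing of a single-regime noiseless backbone.

    Oracle helper for event-time tests: for the first regime's parameters,
    the time at which the curve reaches ``fraction`` of its asymptote
    (``max_of_signal``) or of its value at t=0 (``initial_value``).
    """
    p = spec.regimes[0][1]
    if reference == "initial_value":
        level = fraction * evaluate(spec.family, p, 0.0)
    else:
        level = fraction * p.k
    return time_to_level(spec.family, p, level)


__all__.append("crossing_of_backbone")
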