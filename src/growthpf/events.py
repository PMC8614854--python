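"""Event-time prediction and post hoc assessment.

Two operational events are covered: the optimal harvest time, defined as the
moment the biomass signal reaches 95% of its maximum, and the critically-low
dissolved-oxygen event, reached when DO falls to 20% of its reference level
(initial value by default; the signal maximum is available as an
alternative reference since initial and maximum coincide for a declining DO
profile).  Forward-looking predictions come from the particle ensemble via
the closed-form threshold crossing of each particle's own curve; post hoc
target times come from the Savitzky-Golay-smoothed complete signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .growth_models import GrowthParams, time_to_level, evaluate_many
from .preprocessing import TimeSeries, smooth

__all__ = [
    "EventSpec",
    "EventPrediction",
    "predict_event",
    "posthoc_event_time",
    "event_error",
    "event_loss",
    "HARVEST_BM",
    "CRITICAL_DO",
]


@dataclass(frozen=True)
class EventSpec:
    """Definition of a threshold event.

    ``fraction`` of the ``reference`` level defines the threshold.  For BM
    the reference is the curve's own asymptote (prediction) or the smoothed
    signal maximum (post hoc); for DO the default reference is the initial
    value.
    """

    channel: str = "BM"
    fraction: float = 0.95
    reference: str = "max_of_signal"  # or "initial_value"

    def __post_init__(self):
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("EventSpec.fraction must lie in (0, 1)")
        if self.channel not in ("BM", "DO"):
            raise ValueError("EventSpec.channel must be 'BM' or 'DO'")
        if self.reference not in ("max_of_signal", "initial_value"):
            raise ValueError("EventSpec.reference must be 'max_of_signal' "
                             "or 'initial_value'")


HARVEST_BM = EventSpec(channel="BM", fraction=0.95, reference="max_of_signal")
CRITICAL_DO = EventSpec(channel="DO", fraction=0.20, reference="initial_value")


@dataclass
class EventPrediction:
    """Ensemble event-time forecast."""

    tpred: float
    spec: EventSpec
    crossing_times: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    noncrossing_fraction: float = 0.0

    @property
    def crossed(self) -> bool:
        return np.isfinite(self.tpred)


def predict_event(particles, weights, family, spec: EventSpec,
                  reference_time: Optional[float] = None) -> EventPrediction:
    """Ensemble forecast of the event time.

    For each particle the threshold is ``fraction`` of the particle's own
    asymptote ``k`` (``reference="max_of_signal"``) or of the particle's
    curve value at ``reference_time`` (``reference="initial_value"``, the DO
    convention; ``reference_time`` defaults to 0).  ``tpred`` is the weighted
    mean of the finite crossing times; particles whose curve never attains
    the threshold are excluded and reported via ``noncrossing_fraction``.
    """
    particles = np.asarray(particles, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    times = np.empty(len(particles))
    if spec.reference == "initial_value":
        t0 = 0.0 if reference_time is None else float(reference_time)
        refs = evaluate_many(family, particles[:, 0], particles[:, 1],
                             particles[:, 2], [t0])[:, 0]
    else:
        refs = particles[:, 0]
    for i, (k, b, c) in enumerate(particles):
        if c == 0:
            times[i] = np.nan
            continue
        times[i] = time_to_level(family, GrowthParams(k, b, c),
                                 spec.fraction * refs[i])
    finite = np.isfinite(times)
    noncross = float(weights[~finite].sum())
    if not finite.any():
        return EventPrediction(float("nan"), spec, times, weights, 1.0)
    w = weights[finite] / weights[finite].sum()
    tpred = float(w @ times[finite])
    return EventPrediction(tpred, spec, times, weights, noncross)


def posthoc_event_time(series: TimeSeries, spec: EventSpec,
                       polyorder: int = 6, window: int = 21):
    """Post hoc target event time from the smoothed complete signal.

    The series is Savitzky-Golay smoothed (order 6, window 21, mirror
    padding); the reference level is the smoothed maximum (BM convention) or
    the first smoothed value (DO convention); the returned time is the
    sample minimizing ``|smoothed - fraction * reference|``, ties broken
    toward the earliest time.  Returns ``(topt, crossed)`` where ``crossed``
    is False when the smoothed signal never brackets the threshold (the
    argmin then sits at a boundary sample).
    """
    if len(series) < window:
        raise ValueError(
            f"posthoc_event_time: series length {len(series)} < window {window}")
    sm = smooth(series, polyorder=polyorder, window=window)
    if spec.reference == "initial_value":
        ref = sm.values[0]
    else:
        ref = sm.values.max()
    target = spec.fraction * ref
    dist = np.abs(sm.values - target)
    idx = int(np.argmin(dist))  # argmin returns the first minimum: earliest tie
    lo, hi = sm.values.min(), sm.values.max()
    crossed = bool(lo <= target <= hi)
    return float(sm.times[idx]), crossed


def event_error(tpred: float, topt: float) -> float:
    """Signed event-time error ``td = tpred - topt`` in hours (positive = late)."""
    if not (np.isfinite(tpred) and np.isfinite(topt)):
        return float("nan")
    return float(tpred - topt)


def event_loss(series: TimeSeries, tpred: float, topt: float,
               polyorder: int = 6, window: int = 21) -> float:
    """Relative signal loss of acting at ``tpred`` instead of ``topt``.

    ``(y[tpred] - y[topt]) / y[topt] * 100`` evaluated on the smoothed
    signal, with each time mapped to its nearest sample.  Returns NaN when
    the smoothed signal at ``topt`` is zero (undefined loss) or either time
    falls outside the series span.
    """
    if not (np.isfinite(tpred) and np.isfinite(topt)):
        return float("nan")
    if not (series.times[0] <= tpred <= series.times[-1]
            and series.times[0] <= topt <= series.times[-1]):
        return float("nan")
    sm = smooth(series, polyorder=polyorder, window=window)
    y_pred = sm.values[int(np.argmin(np.abs(sm.times - tpred)))]
    y_opt = sm.values[int(np.argmin(np.abs(sm.times - topt)))]
    if y_opt == 0:
        return float("nan")
    return float((y_pred - y_opt) / y_opt * 100.0)
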