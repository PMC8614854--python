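"""Signal transforms and smoothing for shake-flask sensor series.

Raw back-scatter biomass (BM, Attenuation Units) and dissolved-oxygen
(DO, percent of maximum) signals are rescaled by constant factors (AU/1000,
DO/10) and mapped to a natural-log scale before any model fitting.  The
Savitzky-Golay smoother here (order 6, window 21, mirror padding) is used
for post hoc event-time estimation only, never inside the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "TimeSeries",
    "transform",
    "inverse_transform",
    "smooth",
    "read_series",
    "write_series",
]

# constant rescale factors applied before the log transform
_SCALE = {"BM": 1000.0, "DO": 10.0}


@dataclass
class TimeSeries:
    """A (time, value) sensor record on the transformed (log) scale.

    times are in hours and must be strictly increasing; irregular spacing is
    allowed.  ``channel`` is ``"BM"`` or ``"DO"``; free-form metadata (medium,
    flask size, shaking rate ...) rides along in ``metadata``.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = "BM"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.channel not in ("BM", "DO"):
            raise ValueError("channel must be 'BM' or 'DO'")

    def __len__(self) -> int:
        return len(self.times)


def transform(raw_values, channel: str = "BM") -> np.ndarray:
    """Map raw sensor units to the modelling scale: ``ln(raw / scale)``.

    ``scale`` is 1000 for BM (AU) and 10 for DO (percent).  Raw values must
    be strictly positive; the error names the first offending index.
    """
    raw = np.asarray(raw_values, dtype=float)
    if channel not in _SCALE:
        raise ValueError("channel must be 'BM' or 'DO'")
    bad = np.flatnonzero(~(raw > 0))
    if bad.size:
        raise ValueError(
            f"transform: non-positive raw value at index {bad[0]} "
            f"({raw.flat[bad[0]]!r}); {channel} signals must be > 0"
        )
    return np.log(raw / _SCALE[channel])


def inverse_transform(values, channel: str = "BM") -> np.ndarray:
    """Invert :func:`transform`: ``scale * exp(value)``."""
    if channel not in _SCALE:
        raise ValueError("channel must be 'BM' or 'DO'")
    return _SCALE[channel] * np.exp(np.asarray(values, dtype=float))


def smooth(series: TimeSeries, polyorder: int = 6, window: int = 21) -> TimeSeries:
    """Savitzky-Golay smoothing with mirror padding.

    Applied index-wise, which assumes approximately uniform sampling; a
    warning is emitted when the coefficient of variation of the time steps
    exceeds 10%.  Reproduces any polynomial of degree <= ``polyorder``
    exactly (on a uniform grid).
    """
    if window % 2 == 0:
        raise ValueError("smooth: window must be odd")
    if window <= polyorder:
        raise ValueError("smooth: window must exceed polyorder")
    if len(series) < window:
        raise ValueError(
            f"smooth: series length {len(series)} shorter than window {window}"
        )
    dt = np.diff(series.times)
    if len(dt) > 1 and dt.std() / dt.mean() > 0.10:
        warnings.warn(
            "time steps vary by >10%: Savitzky-Golay smoothing is applied "
            "index-wise and assumes near-uniform sampling",
            stacklevel=2,
        )
    sm = savgol_filter(series.values, window_length=window, polyorder=polyorder,
                       mode="mirror")
    return TimeSeries(series.times.copy(), sm, channel=series.channel,
                      metadata=dict(series.metadata))


def read_series(path, channel: str = "BM", **metadata) -> TimeSeries:
    """Read a one-channel CSV/TSV with header ``time_h,value``.

    Lines starting with ``#`` are ignored; the delimiter is sniffed from the
    header (comma or tab); decimal point ``.`` only.
    """
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    cols = {c.strip(): c for c in df.columns}
    if "time_h" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns 'time_h,value', got {list(df.columns)}")
    return TimeSeries(df[cols["time_h"]].to_numpy(float),
                      df[cols["value"]].to_numpy(float),
                      channel=channel, metadata=metadata)


def write_series(series: TimeSeries, path, sep: str = ",") -> None:
    """Write a series in the standard ``time_h,value`` layout."""
    pd.DataFrame({"time_h": series.times, "value": series.values}).to_csv(
        path, sep=sep, index=False)
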