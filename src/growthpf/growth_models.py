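"""Three-parameter Gompertz and Logistic growth laws.

Both families share the parameter triple ``(k, b, c)``: ``k`` is the limit
value (the asymptote on the transformed signal scale), while ``b`` (offset)
and ``c`` (rate, per hour) parameterize the transition dynamics.  With
``b > 0`` and ``c > 0`` the curves rise monotonically from 0 (Gompertz) or
towards ``k`` (both); flipping the signs of both ``b`` and ``c`` mirrors the
curve in time about the axis ``t = b/c`` and yields a monotone decline, which
is the convention used for dissolved-oxygen profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "ModelFamily",
    "GrowthParams",
    "evaluate",
    "crossing_time",
    "time_to_level",
    "check_monotone",
]


class ModelFamily(str, Enum):
    """Growth-law family: ``gompertz`` or ``logistic``."""

    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"


FamilyLike = Union[ModelFamily, str]


def _as_family(family: FamilyLike) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    return ModelFamily(str(family).lower())


@dataclass(frozen=True)
class GrowthParams:
    """One ``(k, b, c)`` coefficient triple.

    ``k`` may be any finite real (the filter operates on log-transformed
    signals whose asymptote can be non-positive).  A curve is monotone
    increasing for ``b > 0, c > 0`` and monotone decreasing for
    ``b < 0, c < 0``; mixed signs are mathematically valid but flagged by
    :func:`check_monotone` and :meth:`is_valid`.
    """

    k: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("k", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"GrowthParams.{name} must be finite")

    def is_valid(self) -> bool:
        """True when the (b, c) signs follow a monotone convention."""
        return (self.b > 0 and self.c > 0) or (self.b < 0 and self.c < 0)


def evaluate(family: FamilyLike, params: GrowthParams, t):
    """Evaluate the growth curve at time(s) ``t`` (hours).

    Gompertz: ``y = k * exp(-exp(b - c*t))``.
    Logistic: ``y = k / (1 + exp(b - c*t))``.

    Accepts scalar or array ``t``; returns the matching shape.  The inner
    exponent is clipped at 700 so the result is finite for all finite inputs.
    """
    fam = _as_family(family)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("evaluate: t must be finite")
    u = np.clip(params.b - params.c * t, -745.0, 700.0)
    if fam is ModelFamily.GOMPERTZ:
        out = params.k * np.exp(-np.exp(u))
    else:
        out = params.k / (1.0 + np.exp(u))
    return out if out.ndim else float(out)


def evaluate_many(family: FamilyLike, k, b, c, t):
    """Vectorized :func:`evaluate` over particle arrays.

    ``k, b, c`` with shape ``(n,)`` and ``t`` with shape ``(m,)`` give an
    ``(n, m)`` curve matrix.  Used by the particle filter's likelihood and
    prediction steps.
    """
    fam = _as_family(family)
    k = np.atleast_1d(np.asarray(k, dtype=float))[:, None]
    b = np.atleast_1d(np.asarray(b, dtype=float))[:, None]
    c = np.atleast_1d(np.asarray(c, dtype=float))[:, None]
    t = np.atleast_1d(np.asarray(t, dtype=float))[None, :]
    u = np.clip(b - c * t, -745.0, 700.0)
    if fam is ModelFamily.GOMPERTZ:
        return k * np.exp(-np.exp(u))
    return k / (1.0 + np.exp(u))


def time_to_level(family: FamilyLike, params: GrowthParams, level: float) -> float:
    """Time at which the curve passes ``level`` (closed-form inverse).

    Requires ``0 < level/k < 1`` and ``c != 0``; returns NaN when the level
    is outside the curve's open range (the curve never attains it).
    """
    fam = _as_family(family)
    if params.c == 0:
        raise ValueError("time_to_level: c must be non-zero")
    ratio = level / params.k if params.k != 0 else np.nan
    if not np.isfinite(ratio) or not (0.0 < ratio < 1.0):
        return float("nan")
    if fam is ModelFamily.GOMPERTZ:
        return (params.b - np.log(-np.log(ratio))) / params.c
    return (params.b - np.log(1.0 / ratio - 1.0)) / params.c


def crossing_time(family: FamilyLike, params: GrowthParams, fraction: float) -> float:
    """Time at which the curve reaches ``fraction * k``.

    Gompertz: ``t = (b - ln(-ln f)) / c``; Logistic: ``t = (b - ln(1/f - 1)) / c``.
    Exact inverse of :func:`evaluate` at ``fraction * k``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("crossing_time: fraction must lie in (0, 1)")
    if params.c == 0:
        raise ValueError("crossing_time: c must be non-zero")
    fam = _as_family(family)
    if fam is ModelFamily.GOMPERTZ:
        return (params.b - np.log(-np.log(fraction))) / params.c
    return (params.b - np.log(1.0 / fraction - 1.0)) / params.c


def check_monotone(family: FamilyLike, params: GrowthParams) -> str:
    """Classify the curve's direction from the sign of ``c``.

    Returns ``"increasing"`` (c > 0), ``"decreasing"`` (c < 0) or
    ``"invalid"`` (c == 0, a constant curve).  Mixed (b, c) signs trigger a
    warning but still classify by ``c``.
    """
    _as_family(family)
    if params.c == 0:
        return "invalid"
    if not params.is_valid():
        warnings.warn(
            "mixed signs of b and c: curve is monotone by c but outside the "
            "usual increasing/decreasing conventions",
            stacklevel=2,
        )
    return "increasing" if params.c > 0 else "decreasing"
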