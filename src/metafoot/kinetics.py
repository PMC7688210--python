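"""Closed-form mathematics of the four-parameter sigmoid used for substrate
depletion and metabolite appearance curves.

Depletion form:  y(x) = a / (1 + exp((x - t50) / w)) + o
Appearance form: y(x) = a / (1 + exp(-(x - t50) / w)) + o

with amplitude ``a`` (the span depleted or produced), midpoint ``t50`` (h),
width ``w`` (h) and offset ``o`` (the predicted final value for depletion,
the baseline for appearance).

The "90% usage window" is the interval over which the middle 80% of the
modelled utilization happens: the curve passes o + 0.9a at
``t10 = t50 - w ln 9`` and o + 0.1a at ``t90 = t50 + w ln 9``, so
``width90 = 2 ln(9) w`` exactly, for either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "LN9",
    "SigmoidParams",
    "UsageWindow",
    "MaxRate",
    "eval_sigmoid",
    "sigmoid_slope",
    "usage_window",
    "max_rate",
    "normalize_rate",
]

LN9 = float(np.log(9.0))

Direction = Literal["depletion", "appearance"]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the four-parameter sigmoid."""

    a: float
    t50: float
    w: float
    o: float
    direction: Direction = "depletion"

    @property
    def sign(self) -> float:
        # +1 in the exponent for depletion, -1 for appearance
        return 1.0 if self.direction == "depletion" else -1.0

    def mirrored(self) -> "SigmoidParams":
        other = "appearance" if self.direction == "depletion" else "depletion"
        return replace(self, direction=other)


@dataclass(frozen=True)
class UsageWindow:
    """The 10%->90% utilization interval of a fitted curve."""

    t10: float
    t90: float
    width90: float


@dataclass(frozen=True)
class MaxRate:
    """Maximum |dy/dx| within an observation window."""

    rate: float
    at_time: float
    clipped: bool          # True when the optimum t50 fell outside the window
    direction: Direction
    degenerate: bool = False  # a == 0: flat curve, rate 0 by convention


def _check_w(p: SigmoidParams) -> None:
    if not p.w > 0:
        raise ValueError(f"sigmoid width must be positive, got w={p.w}")


def eval_sigmoid(p: SigmoidParams, x):
    """Evaluate the sigmoid at time(s) ``x`` (hours)."""
    _check_w(p)
    x = np.asarray(x, dtype=float)
    u = p.sign * (x - p.t50) / p.w
    y = p.a * expit(-u) + p.o
    return float(y) if y.ndim == 0 else y


def sigmoid_slope(p: SigmoidParams, x):
    """Analytic derivative dy/dx at time(s) ``x``.

    Negative throughout for depletion, positive for appearance.
    """
    _check_w(p)
    x = np.asarray(x, dtype=float)
    u = p.sign * (x - p.t50) / p.w
    s = expit(-u)
    dy = -p.sign * p.a * s * (1.0 - s) / p.w
    return float(dy) if dy.ndim == 0 else dy


def usage_window(p: SigmoidParams) -> UsageWindow:
    """10%->90% utilization interval; identical for both directions."""
    _check_w(p)
    if not p.a > 0:
        raise ValueError("degenerate curve: zero amplitude has no usage window")
    half = p.w * LN9
    return UsageWindow(t10=p.t50 - half, t90=p.t50 + half, width90=2.0 * half)


def max_rate(p: SigmoidParams, t_min: float = 0.0, t_max: float = 24.0) -> MaxRate:
    """Maximum absolute depletion/appearance rate within ``[t_min, t_max]``.

    |dy/dx| = (a/w) s (1-s) peaks at a/(4w) at x = t50; when t50 lies
    outside the window the boundary nearer t50 carries the maximum (the
    derivative magnitude is monotone on either side of t50) and the result
    is flagged ``clipped``.
    """
    _check_w(p)
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    if p.a == 0:
        return MaxRate(0.0, t_min, clipped=False, direction=p.direction,
                       degenerate=True)
    if t_min <= p.t50 <= t_max:
        return MaxRate(p.a / (4.0 * p.w), p.t50, clipped=False,
                       direction=p.direction)
    t_star = t_min if p.t50 < t_min else t_max
    return MaxRate(abs(sigmoid_slope(p, t_star)), t_star, clipped=True,
                   direction=p.direction)


def normalize_rate(rate_uM_per_h: float, biomass_mg_per_L: float) -> float:
    """Biomass-normalised rate, mmol h^-1 g^-1 (dry weight).

    µmol L^-1 h^-1 divided by mg L^-1 is mmol g^-1 h^-1 — a pure unit
    identity, no extra factor.
    """
    if biomass_mg_per_L <= 0:
        raise ValueError("biomass must be positive")
    return rate_uM_per_h / biomass_mg_per_L
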