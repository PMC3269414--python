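"""One-dimensional deferral models: open loop, instantaneous, polyphasic.

Each model tracks a single regulator level X, starting from X0 = 1,
with the cell cycle as the time unit and continuous exponential
dilution at rate 1; deferral time T_D is when X first reaches the
threshold X_thr = 100.

open loop        dX/dt = b - X
                 T_D = ln((b - X0) / (b - X_thr)),    needs b > X_thr
instantaneous    dX/dt = b X - X
                 T_D = ln(X_thr / X0) / (b - 1),      needs b > 1
polyphasic       per-cycle map X_{n+1} = (1 + b) X_n e^{-1}
                 (production proportional to the cycle's pulse is
                 delivered after the pulse, then one cycle of dilution)
                 T_D = ln(X_thr / X0) / (ln(1 + b) - 1), needs ln(1+b) > 1

The minimal feedback strengths b0 that can reach the threshold are
therefore X_thr (open loop), 1 (instantaneous) and e - 1 (polyphasic).
The models' sensitivities S = |d ln T_D / d ln b| order strictly:
open loop > instantaneous > polyphasic at matched deferral times,
with the polyphasic time constant exponentially less sensitive to b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, FitError

__all__ = ["OneDModelParams", "ONED_VARIANTS", "oned_deferral_time",
           "oned_deferral_time_numeric", "oned_minimal_b", "oned_tune_b",
           "oned_sensitivity"]

ONED_VARIANTS = ("open_loop", "instantaneous", "polyphasic")


@dataclass(frozen=True)
class OneDModelParams:
    variant: str
    b: float
    x0: float = 1.0
    x_thr: float = 100.0

    def __post_init__(self) -> None:
        if self.variant not in ONED_VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.b <= 0:
            raise ConfigError("feedback strength b must be positive")
        if self.x_thr <= self.x0 or self.x0 <= 0:
            raise ConfigError("need 0 < x0 < x_thr")


def oned_deferral_time(params: OneDModelParams) -> float | None:
    """Closed-form deferral time in cell cycles; None if X never reaches X_thr."""
    b, x0, xt = params.b, params.x0, params.x_thr
    if params.variant == "open_loop":
        if b <= xt:
            return None
        return math.log((b - x0) / (b - xt))
    if params.variant == "instantaneous":
        if b <= 1:
            return None
        return math.log(xt / x0) / (b - 1)
    # polyphasic
    if math.log1p(b) <= 1:
        return None
    return math.log(xt / x0) / (math.log1p(b) - 1.0)


def oned_deferral_time_numeric(params: OneDModelParams, dt: float = 1e-4,
                               t_max: float = 200.0) -> float | None:
    """Deferral time by direct integration/iteration; cross-checks the closed form."""
    b, x0, xt = params.b, params.x0, params.x_thr
    if params.variant == "polyphasic":
        # iterate the per-cycle map; crossing interpolated on log X
        x = x0
        factor = (1.0 + b) * math.exp(-1.0)
        if factor <= 1.0:
            return None
        for n in range(100000):
            x_next = x * factor
            if x_next >= xt:
                return n + (math.log(xt) - math.log(x)) / math.log(factor)
            x = x_next
        return None
    if params.variant == "open_loop":
        deriv = lambda x: b - x
    else:
        deriv = lambda x: (b - 1.0) * x
    x, t = x0, 0.0
    while t < t_max:
        k1 = deriv(x)
        k2 = deriv(x + 0.5 * dt * k1)
        k3 = deriv(x + 0.5 * dt * k2)
        k4 = deriv(x + dt * k3)
        x_next = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if x_next >= xt:
            return t + dt * (xt - x) / (x_next - x)
        x, t = x_next, t + dt
    return None


def oned_minimal_b(variant: str, x0: float = 1.0, x_thr: float = 100.0,
                   rel_tol: float = 1e-9) -> float:
    """Minimal feedback strength b0 that can reach the threshold (bisection)."""

    def reachable(b: float) -> bool:
        return oned_deferral_time(OneDModelParams(variant, b, x0, x_thr)) is not None

    lo, hi = 1e-9, 1.0
    while not reachable(hi):
        hi *= 2.0
        if hi > 1e12:
            raise FitError("threshold unreachable for any feedback strength")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if reachable(mid):
            hi = mid
        else:
            lo = mid
    return hi


def oned_tune_b(variant: str, target_td: float, x0: float = 1.0,
                x_thr: float = 100.0, td_tol: float = 1e-9) -> float:
    """Feedback strength b giving the target deferral time (T_D decreasing in b)."""
    if target_td <= 0:
        raise ConfigError("target deferral time must be positive")
    b0 = oned_minimal_b(variant, x0, x_thr)
    lo = b0 * (1 + 1e-12)  # T_D -> infinity
    hi = max(2 * b0, 10.0)
    td = lambda b: oned_deferral_time(OneDModelParams(variant, b, x0, x_thr))
    while (t := td(hi)) is None or t > target_td:
        hi *= 2.0
        if hi > 1e15:
            raise FitError("target deferral time unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t = td(mid)
        if t is None or t > target_td:
            lo = mid
        else:
            hi = mid
        if t is not None and abs(t - target_td) < td_tol:
            return mid
    return 0.5 * (lo + hi)


def oned_sensitivity(variant: str, b: float, x0: float = 1.0,
                     x_thr: float = 100.0) -> float | None:
    """S = |d ln T_D / d ln b| from the closed-form deferral times.

    open loop      S = b (X_thr - X0) / ((b - X0)(b - X_thr) T_D)
    instantaneous  S = b / (b - 1)
    polyphasic     S = b / ((1 + b)(ln(1 + b) - 1))
    """
    td = oned_deferral_time(OneDModelParams(variant, b, x0, x_thr))
    if td is None:
        return None
    if variant == "open_loop":
        return b * (x_thr - x0) / ((b - x0) * (b - x_thr) * td)
    if variant == "instantaneous":
        return b / (b - 1.0)
    return b / ((1.0 + b) * (math.log1p(b) - 1.0))
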