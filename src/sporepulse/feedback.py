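"""Saturating feedback functions mapping one pulse amplitude to the next.

The pulse-to-pulse map ``g`` is a Hill-type saturating function

    g(p) = a0 + v * p**h / (K**h + p**h)

with basal amplitude ``a0``, maximal feedback gain ``v``, half-saturation
``K`` and Hill exponent ``h``.  Where ``g`` intersects the diagonal
``g(p) = p`` successive pulses are equal in size and amplitude growth
stops; that stable intersection is the fixed point ``p*`` of the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["SaturatingFeedback"]


@dataclass(frozen=True)
class SaturatingFeedback:
    """Hill-type saturating pulse-amplitude map ``g(p) = a0 + v p^h/(K^h + p^h)``."""

    a0: float = 1.0
    v: float = 12.0
    K: float = 3.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.v < 0 or self.K <= 0 or self.h <= 0 or self.a0 < 0:
            raise ConfigError(
                f"invalid feedback parameters a0={self.a0}, v={self.v}, "
                f"K={self.K}, h={self.h}"
            )

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        ph = np.power(np.clip(p, 0.0, None), self.h)
        out = self.a0 + self.v * ph / (self.K**self.h + ph)
        return float(out) if out.ndim == 0 else out

    def fixed_point(self, p_max: float | None = None, tol: float = 1e-12) -> float | None:
        """Stable fixed point of the map (largest root of g(p) - p), or None.

        Scans ``(0, p_max]`` for sign changes of ``g(p) - p`` and refines the
        largest one by bisection; the largest intersection of a saturating
        map with the diagonal is the stable one.
        """
        from scipy.optimize import brentq

        if p_max is None:
            p_max = 10.0 * (self.a0 + self.v + self.K)
        grid = np.linspace(1e-9, p_max, 4096)
        f = self(grid) - grid
        sign_changes = np.nonzero(np.diff(np.sign(f)) != 0)[0]
        if len(sign_changes) == 0:
            return None
        i = sign_changes[-1]
        return float(brentq(lambda p: self(p) - p, grid[i], grid[i + 1], xtol=tol))

    def iterate(self, p0: float, n: int) -> np.ndarray:
        """Deterministic amplitude staircase p0, g(p0), g(g(p0)), ... (n+1 values)."""
        out = np.empty(n + 1)
        out[0] = p0
        for k in range(n):
            out[k + 1] = self(out[k])
        return out
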