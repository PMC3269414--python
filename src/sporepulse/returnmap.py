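"""Pulse-amplitude return maps along lineages.

The return map plots the amplitude of each promoter-activity pulse
(p_{N+1}) against the amplitude of the pulse in the preceding cell
cycle (p_N).  Points above the diagonal indicate pulse growth; a
saturating positive feedback produces a map that rises above the
diagonal at small amplitudes and intersects it at the stable fixed
point p*, where successive pulses are equal in size and growth stops.

``FeedbackMapModel`` fits the saturating map
``p_{N+1} = a0 + v p_N^h / (K^h + p_N^h)`` to observed pairs by least
squares (optionally on log amplitudes, the natural scale for
multiplicative pulse noise) and reports the parameters, their
covariance and the fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .colony import Microcolony
from .errors import ConsistencyError, FitError, InsufficientDataError
from .feedback import SaturatingFeedback
from .pulses import Pulse

__all__ = ["ReturnMapPair", "DiagonalCounts", "build_return_map",
           "pairs_from_sequence", "diagonal_counts",
           "FeedbackMapModel", "FeedbackMapResults"]


@dataclass(frozen=True)
class ReturnMapPair:
    p_n: float
    p_n1: float
    lineage: str  # id of the cell contributing p_{N+1}


def pairs_from_sequence(amplitudes, lineage: str = "0") -> list[ReturnMapPair]:
    """Successive pairs from one cell's amplitude sequence over cycles."""
    amps = list(amplitudes)
    return [ReturnMapPair(float(a), float(b), lineage)
            for a, b in zip(amps[:-1], amps[1:])]


def build_return_map(pulses: list[Pulse], colony: Microcolony) -> list[ReturnMapPair]:
    """One (mother amplitude, daughter amplitude) pair per parent-child link.

    Each cell cycle is represented by its largest-amplitude pulse.  Both
    daughters of a division contribute a pair with the shared mother
    amplitude.  Pair order follows sorted daughter cell ids, so the
    construction is invariant to the input pulse ordering.
    """
    rep: dict[str, float] = {}
    for p in pulses:
        if p.cell_id not in colony.cells:
            raise ConsistencyError(f"pulse references unknown cell {p.cell_id!r}")
        if p.cell_id not in rep or p.amplitude > rep[p.cell_id]:
            rep[p.cell_id] = p.amplitude
    pairs = []
    for cell_id in sorted(rep):
        parent = colony.cells[cell_id].parent_id
        if parent is not None and parent in rep:
            pairs.append(ReturnMapPair(rep[parent], rep[cell_id], cell_id))
    return pairs


@dataclass
class DiagonalCounts:
    n_above: int
    n_below: int
    n_on: int
    pvalue: float | None  # two-sided exact binomial test vs 0.5; None if no off-diagonal pairs


def diagonal_counts(pairs, rel_tol: float = 1e-9) -> DiagonalCounts:
    """Partition pairs by the sign of p_{N+1} - p_N and test growth vs 0.5.

    Pairs within ``rel_tol`` (relative) of the diagonal count as
    on-diagonal and are excluded from the exact binomial test.  Accepts
    :class:`ReturnMapPair` lists or an (n, 2) array.
    """
    arr = np.asarray([(p.p_n, p.p_n1) if isinstance(p, ReturnMapPair) else tuple(p)
                      for p in pairs], dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no return-map pairs")
    diff = arr[:, 1] - arr[:, 0]
    scale = np.maximum(np.abs(arr[:, 0]), np.abs(arr[:, 1]))
    on = np.abs(diff) <= rel_tol * np.maximum(scale, 1e-300)
    n_above = int(np.sum(diff > 0) - np.sum(on & (diff > 0)))
    n_below = int(np.sum(diff < 0) - np.sum(on & (diff < 0)))
    n_on = int(on.sum())
    n_off = n_above + n_below
    pvalue = (float(stats.binomtest(n_above, n_off, 0.5).pvalue)
              if n_off > 0 else None)
    return DiagonalCounts(n_above, n_below, n_on, pvalue)


class FeedbackMapModel:
    """Saturating feedback map fitted to return-map pairs.

    Parameters
    ----------
    pairs : list of ReturnMapPair or (n, 2) array
        Observed (p_N, p_{N+1}) amplitude pairs.
    log_scale : bool
        Fit on log amplitudes (least squares on log p_{N+1}), the
        maximum-likelihood scale when pulse noise is multiplicative
        lognormal.  Default True.
    h_bounds : (float, float)
        Bounds on the Hill exponent; the default [0.5, 6] stabilizes
        the fit on small samples.
    """

    def __init__(self, pairs, log_scale: bool = True,
                 h_bounds: tuple[float, float] = (0.5, 6.0)):
        arr = np.asarray([(p.p_n, p.p_n1) if isinstance(p, ReturnMapPair) else tuple(p)
                          for p in pairs], dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 8:
            raise InsufficientDataError("feedback fit needs at least 8 pairs")
        if np.ptp(arr[:, 0]) <= 0:
            raise FitError("degenerate amplitude range: all p_N equal")
        self.x = arr[:, 0]
        self.y = arr[:, 1]
        self.log_scale = log_scale
        self.h_bounds = h_bounds

    @staticmethod
    def _g(x, a0, v, K, h):
        xh = np.power(np.clip(x, 1e-300, None), h)
        return a0 + v * xh / (K**h + xh)

    def fit(self) -> "FeedbackMapResults":
        x, y = self.x, self.y
        ymin, yptp = float(np.min(y)), float(np.ptp(y))
        lo = [0.0, 1e-12, 1e-12, self.h_bounds[0]]
        hi = [np.inf, np.inf, np.inf, self.h_bounds[1]]
        if self.log_scale:
            if np.any(y <= 0):
                raise FitError("log-scale fit requires positive amplitudes")
            model = lambda xx, a0, v, K, h: np.log(
                np.clip(self._g(xx, a0, v, K, h), 1e-300, None))
            target = np.log(y)
        else:
            model = self._g
            target = y
        best = None
        for h0 in (1.0, 2.0, 4.0):
            p_init = [max(ymin, 1e-6), max(yptp, 1e-6), float(np.median(x)), h0]
            try:
                popt, pcov = curve_fit(model, x, target, p0=p_init,
                                       bounds=(lo, hi), maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = model(x, *popt) - target
            ssr = float(resid @ resid)
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            raise FitError("feedback-function fit did not converge")
        popt, pcov, ssr = best
        fitted = SaturatingFeedback(*[float(v) for v in popt])
        p_star = fitted.fixed_point(p_max=10 * max(self.x.max(), self.y.max(),
                                                   fitted.a0 + fitted.v))
        return FeedbackMapResults(self, popt, pcov, ssr, fitted, p_star)


@dataclass
class FeedbackMapResults:
    """Fitted saturating feedback map: parameters, covariance, fixed point."""

    model: FeedbackMapModel
    params: np.ndarray         # a0, v, K, h
    cov: np.ndarray
    ssr: float
    feedback: SaturatingFeedback
    p_star: float | None       # stable diagonal intersection; None if absent

    param_names = ("a0", "v", "K", "h")

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, p):
        return self.feedback(p)

    def staircase(self, p0: float, n: int) -> np.ndarray:
        """Iterate the fitted map from a seed amplitude (cobweb sequence)."""
        return self.feedback.iterate(p0, n)

    def summary(self) -> str:
        lines = ["Saturating feedback map fit: p(N+1) = a0 + v p^h / (K^h + p^h)",
                 f"pairs: {self.model.x.size}   scale: "
                 f"{'log' if self.model.log_scale else 'linear'}   SSR: {self.ssr:.4g}",
                 f"{'param':>6} {'estimate':>12} {'std err':>12}"]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>6} {est:12.5g} {se:12.5g}")
        lines.append(f"fixed point p*: "
                     f"{self.p_star:.5g}" if self.p_star is not None
                     else "fixed point p*: absent (no diagonal intersection)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter the pairs, the fitted map, the diagonal and p*."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, ".", alpha=0.5, label="pulse pairs")
        grid = np.linspace(0, 1.1 * max(self.model.x.max(), self.model.y.max()), 200)
        ax.plot(grid, self.predict(grid), label="fitted feedback")
        ax.plot(grid, grid, "k--", lw=0.8, label="diagonal")
        if self.p_star is not None:
            ax.plot([self.p_star], [self.p_star], "o", label="p*")
        ax.set_xlabel("pulse amplitude $p_N$")
        ax.set_ylabel("pulse amplitude $p_{N+1}$")
        ax.legend()
        return ax
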