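"""Detection and characterization of promoter-activity pulses.

Pipeline, applied per cell trace:

1. nonlinear smoothing: each point is replaced by the mean of a fixed
   window around it after rejecting the single highest and single
   lowest point in the window (default window 7: 3 points either side);
2. candidate pulses are strict local maxima of the smoothed trace found
   with a sliding boxcar;
3. each pulse's width is the maximal contiguous run of frames around
   the maximum with negative discrete second derivative, its amplitude
   is the smoothed peak height, and its area is amplitude x width
   (trapezoidal integration over the width is available as an option);
4. candidates with area below a minimum pulse size are discarded to
   prevent spurious identification of noise as pulses.

Pulses are then assigned a cell-cycle phase (fraction of the cycle at
which the peak occurs) and a cycle index (generations since the movie
start).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .colony import Microcolony
from .errors import ConfigError, ConsistencyError, InsufficientDataError

__all__ = ["Pulse", "trimmed_window_smooth", "detect_pulses",
           "assign_cycle_phase", "pulses_per_cycle_stats",
           "detect_colony_pulses", "auto_min_size", "PulseCountStats"]


@dataclass(frozen=True)
class Pulse:
    """One detected promoter-activity pulse."""

    cell_id: str
    peak_frame: int          # global movie frame of the smoothed maximum
    amplitude: float         # smoothed peak height, rho units
    width: int               # frames with negative second derivative
    area: float              # rho units x frames
    phase: float = np.nan    # fraction of the cell cycle, [0, 1)
    cycle_index: int = -1    # generations since movie start
    edge_clipped: bool = False  # curvature run truncated by the trace boundary


def trimmed_window_smooth(series: np.ndarray, window: int = 7) -> np.ndarray:
    """Sliding trimmed-mean smoother (reject one max and one min per window).

    Interior points use the full window; near the edges the window
    shrinks symmetrically, and the two boundary points fall back to the
    three nearest points (whose trimmed mean is their median).
    """
    if window < 3 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 3")
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < window:
        raise InsufficientDataError(f"series of length {n} shorter than window {window}")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        if 2 * k + 1 >= 3:
            w = x[i - k:i + k + 1]
        else:  # boundary: three nearest points
            w = x[:3] if i == 0 else x[-3:]
        s = np.sort(w)
        out[i] = s[1:-1].mean()
    return out


def _strict_local_maxima(s: np.ndarray, boxcar_half_width: int) -> list[int]:
    """Indices that dominate a sliding boxcar; leftmost plateau point wins.

    The boxcar must fit inside the trace: points closer than the
    half-width to either end cannot be peaks (an extremum at a trace
    boundary is not a local maximum of the underlying signal).
    """
    n = s.size
    peaks = []
    for i in range(boxcar_half_width, n - boxcar_half_width):
        lo, hi = i - boxcar_half_width, i + boxcar_half_width + 1
        w = s[lo:hi]
        if s[i] < w.max():
            continue
        # tie-break: require strict dominance over earlier window points
        if np.any(s[lo:i] >= s[i]):
            continue
        peaks.append(i)
    return peaks


def detect_pulses(smoothed: np.ndarray, min_size: float = 0.0, *,
                  boxcar_half_width: int = 2, area_rule: str = "rectangle",
                  cell_id: str = "", frame_offset: int = 0) -> list[Pulse]:
    """Detect pulses in one smoothed trace; returns pulses in time order.

    ``min_size`` is the minimum pulse *area*; candidates below it are
    discarded.  ``frame_offset`` converts trace-local indices into global
    movie frames.
    """
    s = np.asarray(smoothed, dtype=float)
    if s.size == 0:
        return []
    if min_size < 0:
        raise ConfigError("min_size must be >= 0")
    if area_rule not in ("rectangle", "trapezoid"):
        raise ConfigError("area_rule must be 'rectangle' or 'trapezoid'")
    if s.size < 3:
        return []
    d2 = np.empty(s.size)
    d2[1:-1] = s[2:] - 2 * s[1:-1] + s[:-2]
    d2[0], d2[-1] = d2[1], d2[-2]  # extend curvature to the boundary frames
    pulses = []
    for i in _strict_local_maxima(s, boxcar_half_width):
        lo = i
        while lo - 1 >= 0 and d2[lo - 1] < 0:
            lo -= 1
        hi = i
        while hi + 1 <= s.size - 1 and d2[hi + 1] < 0:
            hi += 1
        if d2[i] >= 0:  # flat-top maximum with no negative curvature at peak
            lo = hi = i
        width = hi - lo + 1
        amplitude = float(s[i])
        if area_rule == "rectangle":
            area = amplitude * width
        else:
            area = float(np.trapezoid(s[lo:hi + 1])) if width > 1 else amplitude
        if area < min_size or area <= 0:
            continue
        pulses.append(Pulse(
            cell_id=cell_id, peak_frame=i + frame_offset,
            amplitude=amplitude, width=width, area=area,
            edge_clipped=(lo == 0 or hi == s.size - 1),
        ))
    return pulses


def auto_min_size(areas) -> float:
    """Default minimum pulse size: 10% of the 95th-percentile candidate area."""
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        return 0.0
    return 0.1 * float(np.percentile(areas, 95))


def assign_cycle_phase(pulses: list[Pulse], colony: Microcolony) -> list[Pulse]:
    """Attach cell-cycle phase and lineage cycle index to each pulse.

    phase = (peak_frame - birth_frame) / (end_frame - birth_frame);
    cycle_index = depth of the pulse's cell in the lineage tree (root 0).
    """
    out = []
    for p in pulses:
        if p.cell_id not in colony.cells:
            raise ConsistencyError(f"pulse references unknown cell {p.cell_id!r}")
        cell = colony.cells[p.cell_id]
        if not (cell.birth_frame <= p.peak_frame <= cell.end_frame):
            raise ConsistencyError(
                f"pulse peak frame {p.peak_frame} outside cell {p.cell_id!r} "
                f"interval [{cell.birth_frame}, {cell.end_frame}]")
        span = cell.end_frame - cell.birth_frame
        phase = (p.peak_frame - cell.birth_frame) / span if span > 0 else 0.0
        out.append(replace(p, phase=min(phase, np.nextafter(1.0, 0.0)),
                           cycle_index=colony.depth(p.cell_id)))
    return out


def detect_colony_pulses(activity: pd.DataFrame, colony: Microcolony, *,
                         window: int = 7, min_size: float | None = None,
                         boxcar_half_width: int = 2,
                         area_rule: str = "rectangle") -> list[Pulse]:
    """Full pipeline over a tidy activity table (cell_id, frame, rho).

    With ``min_size=None`` the threshold defaults to 10% of the
    colony-wide 95th-percentile candidate pulse area.
    """
    candidates: list[Pulse] = []
    for cell_id, g in activity.groupby("cell_id", sort=True):
        g = g.sort_values("frame")
        rho = g["rho"].to_numpy()
        if rho.size < window:
            continue
        smoothed = trimmed_window_smooth(rho, window)
        candidates.extend(detect_pulses(
            smoothed, 0.0, boxcar_half_width=boxcar_half_width,
            area_rule=area_rule, cell_id=str(cell_id),
            frame_offset=int(g["frame"].iloc[0])))
    if min_size is None:
        min_size = auto_min_size([p.area for p in candidates])
    kept = [p for p in candidates if p.area >= min_size]
    return assign_cycle_phase(kept, colony)


@dataclass
class PulseCountStats:
    """Observed pulses-per-cycle histogram vs a matched binomial null."""

    counts: np.ndarray          # pulse count per cell cycle
    observed: np.ndarray        # histogram over 0..n_null
    expected: np.ndarray        # binomial-null expectation, same support
    n_null: int                 # binomial n with matched mean
    p_null: float               # binomial p with matched mean
    chi2: float
    pvalue: float


def pulses_per_cycle_stats(pulses: list[Pulse], colony: Microcolony,
                           n_null: int | None = None) -> PulseCountStats:
    """Pulses-per-cell-cycle histogram and binomial goodness of fit.

    The null is a binomial with the same mean number of pulses per cell
    cycle; ``n_null`` defaults to the largest observed count (>= 1).
    Low-expectation support points are pooled before the chi-square
    test; one degree of freedom is spent on the matched mean.
    """
    if len(colony) == 0:
        raise InsufficientDataError("no cell cycles")
    counts = np.zeros(len(colony), dtype=int)
    order = {cid: k for k, cid in enumerate(sorted(colony.cells))}
    for p in pulses:
        counts[order[p.cell_id]] += 1
    mean = counts.mean()
    if n_null is None:
        n_null = max(int(counts.max()), 1)
    n_null = max(n_null, int(np.ceil(mean)))
    p_null = mean / n_null if n_null > 0 else 0.0
    support = np.arange(n_null + 1)
    observed = np.array([(counts == k).sum() for k in support], dtype=float)
    # histogram includes any counts beyond n_null in the top bin
    observed[-1] += (counts > n_null).sum()
    expected = stats.binom.pmf(support, n_null, p_null) * counts.size
    # pool bins with expectation < 5 into their left neighbor
    obs_b, exp_b = [], []
    for o, e in zip(observed, expected):
        if exp_b and (e < 5 or exp_b[-1] < 5):
            obs_b[-1] += o
            exp_b[-1] += e
        else:
            obs_b.append(o)
            exp_b.append(e)
    obs_b, exp_b = np.array(obs_b), np.array(exp_b)
    exp_b *= obs_b.sum() / exp_b.sum()
    dof = max(len(obs_b) - 2, 1)  # one df for the matched mean
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    pvalue = float(stats.chi2.sf(chi2, dof))
    return PulseCountStats(counts=counts, observed=observed, expected=expected,
                           n_null=n_null, p_null=p_null, chi2=chi2, pvalue=pvalue)
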