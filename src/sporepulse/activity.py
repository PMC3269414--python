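"""Promoter-activity inference from single-cell time-lapse traces.

Promoter activity is the protein production rate from a promoter.  For a
rod-shaped cell of essentially constant width, total fluorescence is
mean fluorescence times length (up to the constant width factor, which
is dropped), and the production rate per unit cell length — an
approximation to the rate per chromosomal equivalent — is

    rho(t) = mu(t) * M(t) + dM/dt + gamma_extra * M(t)

with instantaneous growth rate mu = (dL/dt)/L, mean fluorescence M, and
an optional extra first-order loss rate ``gamma_extra`` (maturation or
photobleaching; dilution is already the mu*M term and usually
dominates, so the default is 0).

Two limits make the estimator transparent: a growing cell with constant
M has rho = mu*M (production exactly balancing dilution), and a
non-growing cell has rho = dM/dt (production reflected in rising
concentration).

Derivatives use central differences in the interior and one-sided
differences at the boundaries; each cell's series is processed
independently, never across a division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colony import Microcolony
from .errors import AlignmentError, DomainError, InsufficientDataError

__all__ = ["TraceDerived", "growth_rate", "promoter_activity",
           "promoter_activity_euler", "colony_activity"]


@dataclass
class TraceDerived:
    """Per-frame growth rate and promoter activity for one cell."""

    cell_id: str
    mu: np.ndarray    # 1/min
    rho: np.ndarray   # fluorescence units / min


def growth_rate(length: np.ndarray, time_min: np.ndarray) -> np.ndarray:
    """Instantaneous relative growth rate mu(t) = (dL/dt) / L."""
    length = np.asarray(length, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if length.shape != time_min.shape:
        raise AlignmentError("length and time series differ in length")
    if length.size < 3:
        raise InsufficientDataError("growth rate needs at least 3 frames")
    if np.any(length <= 0):
        raise DomainError("cell length must be positive")
    return np.gradient(length, time_min) / length


def promoter_activity(mean_fluor: np.ndarray, length: np.ndarray,
                      time_min: np.ndarray, gamma_extra: float = 0.0) -> np.ndarray:
    """rho(t) = mu*M + dM/dt + gamma_extra*M.  Negative values are kept."""
    mean_fluor = np.asarray(mean_fluor, dtype=float)
    if mean_fluor.shape != np.shape(length):
        raise AlignmentError("mean fluorescence and length series differ in length")
    if gamma_extra < 0:
        raise DomainError("gamma_extra must be >= 0")
    mu = growth_rate(length, time_min)
    dm = np.gradient(mean_fluor, np.asarray(time_min, dtype=float))
    return mu * mean_fluor + dm + gamma_extra * mean_fluor


def promoter_activity_euler(total_fluor: np.ndarray, time_min: np.ndarray,
                            gamma: float = 0.0) -> np.ndarray:
    """Explicit-Euler production-rate estimate from total fluorescence.

    P(t) = (F(t + dt) - F(t)) / dt + gamma * F(t), one value per frame
    except the last.  ``gamma`` is the combined first-order loss rate of
    total fluorescence (photobleaching/maturation; dilution does not
    reduce total fluorescence).
    """
    total_fluor = np.asarray(total_fluor, dtype=float)
    time_min = np.asarray(time_min, dtype=float)
    if total_fluor.size < 2:
        raise InsufficientDataError("Euler estimate needs at least 2 frames")
    if total_fluor.shape != time_min.shape:
        raise AlignmentError("fluorescence and time series differ in length")
    dt = np.diff(time_min)
    return np.diff(total_fluor) / dt + gamma * total_fluor[:-1]


def colony_activity(colony: Microcolony, channel: str,
                    gamma_extra: float = 0.0) -> pd.DataFrame:
    """Tidy per-frame activity table for every cell of a colony.

    Columns: cell_id, frame, time_min, mu, rho.  Cells with fewer than
    3 frames are skipped (no derivative is defined for them).
    """
    rows = []
    for cell in sorted(colony, key=lambda c: c.cell_id):
        if cell.n_frames < 3:
            continue
        mu = growth_rate(cell.length, cell.time_min)
        rho = promoter_activity(cell.mean_fluor[channel], cell.length,
                                cell.time_min, gamma_extra)
        rows.append(pd.DataFrame({
            "cell_id": cell.cell_id,
            "frame": cell.frames,
            "time_min": cell.time_min,
            "mu": mu,
            "rho": rho,
        }))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "frame", "time_min", "mu", "rho"])
    return pd.concat(rows, ignore_index=True)
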