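"""Colony- and lineage-level sporulation deferral statistics.

T_50 scores a microcolony by the moment half of its objects (vegetative
cells plus phase-bright spores) are spores: T_50 = log2 of the total
object count at that moment.  In a binary tree with N leaves the mean
leaf-to-root path length is bounded below by log2(N), so T_50
underestimates the mean per-lineage deferral; it also ignores further
divisions of the not-yet-sporulated half.

Per-lineage deferral is the number of cell cycles from the start of
nutrient limitation to sporulation: a cell at lineage depth k (founder
= 0) that sporulates at the end of its cycle has deferred k + 1 cycles.

The per-cycle sporulation hazard is the fraction of the depth-k cohort
that sporulates rather than divides; censored branches are excluded
from numerator and denominator.

``HillSporulationModel`` fits the sporulated fraction versus induction
level to a Hill function f(x) = F_max x^n / (K^n + x^n) and reports the
Hill coefficient with covariance-based (and optionally bootstrap) 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .colony import FATE_SPORULATED, Microcolony
from .errors import FitError, InsufficientDataError

__all__ = ["DeferralSummary", "t50", "deferral_distribution",
           "sporulation_hazard", "distribution_from_hazard", "summarize_deferral",
           "HillSporulationModel", "HillFitResults"]


def _spore_and_cell_counts(colony: Microcolony, frame: int) -> tuple[int, int]:
    """(phase-bright spores, vegetative cells) present at a movie frame.

    A sporulated cell becomes a spore at its end frame and persists; a
    divided cell is replaced by its daughters at its end frame; a
    censored cell is counted through its last observed frame.
    """
    spores = cells = 0
    for c in colony:
        if c.fate == FATE_SPORULATED:
            if c.end_frame <= frame:
                spores += 1
            elif c.birth_frame <= frame:
                cells += 1
        elif c.fate == "divided":
            if c.birth_frame <= frame < c.end_frame:
                cells += 1
        else:  # censored
            if c.birth_frame <= frame <= c.end_frame:
                cells += 1
    return spores, cells


def t50(colony: Microcolony) -> float | None:
    """log2 of total objects at the earliest frame where >= 50% are spores.

    Returns None (censored) if the colony never reaches 50% sporulation.
    """
    if not any(c.fate == FATE_SPORULATED for c in colony):
        return None
    event_frames = sorted({c.end_frame for c in colony if c.fate == FATE_SPORULATED})
    for f in event_frames:
        spores, cells = _spore_and_cell_counts(colony, f)
        if spores > 0 and spores >= cells:
            return float(np.log2(spores + cells))
    return None


def deferral_distribution(colony: Microcolony) -> np.ndarray:
    """Per-lineage deferral times (cell cycles) of all sporulated cells.

    A sporulated cell at depth k completes k + 1 cycles before
    sporulating.  Returns an empty array (flagged by length 0) if no
    cell sporulated.
    """
    return np.array(sorted(
        colony.depth(c.cell_id) + 1
        for c in colony if c.fate == FATE_SPORULATED), dtype=float)


@dataclass
class DeferralSummary:
    """Deferral statistics of one colony."""

    t50: float | None
    deferral_times: np.ndarray
    hazard: np.ndarray           # per-depth sporulation probability
    hazard_se: np.ndarray
    cohort_sizes: np.ndarray

    @property
    def mean_deferral(self) -> float:
        return float(self.deferral_times.mean()) if self.deferral_times.size else np.nan


def sporulation_hazard(colony: Microcolony) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-depth sporulation hazard, its binomial SE, and cohort sizes.

    hazard[k] = sporulated cells at depth k / non-censored cells at
    depth k.  Depths with empty cohorts are truncated off the end (the
    sequence stops at the deepest populated cohort).
    """
    if len(colony) == 0:
        raise InsufficientDataError("empty colony")
    depth_total: dict[int, int] = {}
    depth_spore: dict[int, int] = {}
    for c in colony:
        k = colony.depth(c.cell_id)
        if c.fate == "censored":
            continue
        depth_total[k] = depth_total.get(k, 0) + 1
        if c.fate == FATE_SPORULATED:
            depth_spore[k] = depth_spore.get(k, 0) + 1
    if not depth_total:
        raise InsufficientDataError("all cells censored")
    kmax = max(depth_total)
    hazard, se, sizes = [], [], []
    for k in range(kmax + 1):
        n = depth_total.get(k, 0)
        if n == 0:
            hazard.append(np.nan)
            se.append(np.nan)
            sizes.append(0)
            continue
        q = depth_spore.get(k, 0) / n
        hazard.append(q)
        se.append(np.sqrt(q * (1 - q) / n))
        sizes.append(n)
    return np.array(hazard), np.array(se), np.array(sizes, dtype=int)


def distribution_from_hazard(hazard: np.ndarray) -> np.ndarray:
    """Expected deferral histogram implied by a hazard sequence.

    Accounts for cohort doubling: the expected number of cells
    sporulating after k + 1 cycles per founder is
    2^k h_k prod_{j<k} (1 - h_j).  Returns the normalized histogram
    over deferral times 1..len(hazard).
    """
    hazard = np.asarray(hazard, dtype=float)
    mass = np.empty(hazard.size)
    surv = 1.0
    for k, h in enumerate(hazard):
        mass[k] = (2.0**k) * h * surv
        surv *= (1 - h)
    total = mass.sum()
    return mass / total if total > 0 else mass


def summarize_deferral(colony: Microcolony) -> DeferralSummary:
    hazard, se, sizes = sporulation_hazard(colony)
    return DeferralSummary(
        t50=t50(colony),
        deferral_times=deferral_distribution(colony),
        hazard=hazard, hazard_se=se, cohort_sizes=sizes)


class HillSporulationModel:
    """Hill fit of sporulated fraction versus induction level.

    fraction(x) = F_max * x^n / (K^n + x^n), fitted by least squares.
    ``counts`` are per-level cohort sizes, used for the bootstrap CI.
    """

    param_names = ("n", "K", "fmax")

    def __init__(self, levels, fractions, counts=None):
        self.x = np.asarray(levels, dtype=float)
        self.f = np.asarray(fractions, dtype=float)
        if self.x.size < 4:
            raise InsufficientDataError("Hill fit needs at least 4 induction levels")
        if self.x.size != self.f.size:
            raise InsufficientDataError("levels and fractions differ in length")
        if np.all(self.f <= 0) or np.all(self.f >= 1):
            raise FitError("degenerate fractions (all 0 or all 1): Hill slope "
                           "is not identifiable")
        self.counts = (np.asarray(counts, dtype=float)
                       if counts is not None else None)

    @staticmethod
    def _hill(x, n, K, fmax):
        xn = np.power(np.clip(x, 1e-300, None), n)
        return fmax * xn / (K**n + xn)

    def _fit_arrays(self, x, f):
        K0 = float(np.interp(0.5 * f.max(), np.sort(f), x[np.argsort(f)]))
        p_init = [2.0, max(K0, 1e-9), min(max(f.max(), 1e-3), 1.0)]
        sigma = None
        absolute = False
        if self.counts is not None:
            # known binomial errors; clip fractions away from 0/1 so
            # saturated levels keep a finite weight
            pc = np.clip(f, 0.5 / self.counts, 1 - 0.5 / self.counts)
            sigma = np.sqrt(pc * (1 - pc) / self.counts)
            absolute = True
        popt, pcov = curve_fit(self._hill, x, f, p0=p_init, sigma=sigma,
                               absolute_sigma=absolute,
                               bounds=([1e-3, 1e-12, 1e-6], [50.0, np.inf, 1.0]),
                               maxfev=20000)
        return popt, pcov

    def fit(self, bootstrap: int = 0, seed: int = 0) -> "HillFitResults":
        popt, pcov = self._fit_arrays(self.x, self.f)
        boot_ci = None
        if bootstrap > 0:
            if self.counts is None:
                raise FitError("bootstrap CI requires cohort counts")
            rng = np.random.default_rng(seed)
            samples = []
            for _ in range(bootstrap):
                fb = rng.binomial(self.counts.astype(int),
                                  np.clip(self.f, 0, 1)) / self.counts
                try:
                    pb, _ = self._fit_arrays(self.x, fb)
                    samples.append(pb)
                except (RuntimeError, ValueError):
                    continue
            if samples:
                arr = np.array(samples)
                boot_ci = np.percentile(arr, [2.5, 97.5], axis=0).T
        return HillFitResults(self, popt, pcov, boot_ci)


@dataclass
class HillFitResults:
    """Hill-function fit of sporulation fraction vs induction level."""

    model: HillSporulationModel
    params: np.ndarray            # n, K, fmax
    cov: np.ndarray
    bootstrap_ci: np.ndarray | None  # (3, 2) percentiles, if requested

    @property
    def n(self) -> float:
        return float(self.params[0])

    @property
    def K(self) -> float:
        return float(self.params[1])

    @property
    def fmax(self) -> float:
        return float(self.params[2])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def conf_int(self) -> np.ndarray:
        """Covariance-based 95% confidence intervals, rows (n, K, fmax)."""
        half = 1.959963984540054 * self.bse
        return np.column_stack([self.params - half, self.params + half])

    def predict(self, x):
        return self.model._hill(np.asarray(x, dtype=float), *self.params)

    def summary(self) -> str:
        ci = self.conf_int
        lines = ["Hill fit: fraction = F_max x^n / (K^n + x^n)",
                 f"levels: {self.model.x.size}",
                 f"{'param':>6} {'estimate':>12} {'std err':>12} {'95% CI':>24}"]
        for k, name in enumerate(self.model.param_names):
            lines.append(f"{name:>6} {self.params[k]:12.4g} {self.bse[k]:12.4g} "
                         f"[{ci[k, 0]:10.4g}, {ci[k, 1]:10.4g}]")
        if self.bootstrap_ci is not None:
            lines.append("bootstrap 95% CI: " + ", ".join(
                f"{nm} [{lo:.4g}, {hi:.4g}]"
                for nm, (lo, hi) in zip(self.model.param_names, self.bootstrap_ci)))
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.f, "o", label="observed fractions")
        grid = np.geomspace(self.model.x.min(), self.model.x.max(), 200)
        ax.plot(grid, self.predict(grid), label=f"Hill fit (n = {self.n:.2f})")
        ax.set_xscale("log")
        ax.set_xlabel("induction level")
        ax.set_ylabel("fraction sporulated")
        ax.legend()
        return ax
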