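"""Synthetic microcolony generator.

Emulates time-lapse movies of a *B. subtilis* microcolony on a
nutrient-limited pad: rod-shaped cells grow exponentially in length,
divide symmetrically when they double, and carry two fluorescent
channels — a pulsed Spo0A-activity reporter (one promoter-activity pulse
per cell cycle, amplitudes ratcheting up under a saturating positive
feedback) and a constitutive reporter.  A cell sporulates the first
cycle its pulse amplitude reaches the threshold ``theta_sim``,
emulating the threshold requirement on phosphorylated Spo0A.

The generator emits already-segmented per-cell traces (frame time, cell
length, mean fluorescence per channel); there is no image synthesis.
Mean fluorescence is a concentration-like observable: within a cycle it
obeys dM/dt = rho(t) - (mu + gamma) * M with promoter activity rho and
growth rate mu, and daughters inherit the mother's final concentration.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .feedback import SaturatingFeedback

__all__ = [
    "CellRecord",
    "SimConfig",
    "Microcolony",
    "simulate_microcolony",
    "simulate_bypass_colony",
    "simulate_amplitude_pairs",
]

#: channel names: pulsed Spo0A-activity reporter and constitutive reporter
PULSED_CHANNEL = "yfp"
CONSTITUTIVE_CHANNEL = "rfp"

FATE_DIVIDED = "divided"
FATE_SPORULATED = "sporulated"
FATE_CENSORED = "censored"


@dataclass
class CellRecord:
    """One cell cycle's trace: per-frame time, length and mean fluorescence.

    ``frames`` run from ``birth_frame`` to ``end_frame`` inclusive on the
    global movie grid.  ``true_amplitude`` and ``true_pulse_time`` record
    the injected ground-truth pulse for recovery tests; they are carried
    through the table round trip.
    """

    cell_id: str
    parent_id: str | None
    birth_frame: int
    end_frame: int
    fate: str
    time_min: np.ndarray
    length: np.ndarray
    mean_fluor: dict[str, np.ndarray]
    true_amplitude: float = math.nan
    true_pulse_time: float = math.nan

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.birth_frame + 1

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.birth_frame, self.end_frame + 1)

    def __eq__(self, other) -> bool:  # value equality for round-trip checks
        if not isinstance(other, CellRecord):
            return NotImplemented
        same_truth = (
            (math.isnan(self.true_amplitude) and math.isnan(other.true_amplitude))
            or self.true_amplitude == other.true_amplitude
        ) and (
            (math.isnan(self.true_pulse_time) and math.isnan(other.true_pulse_time))
            or self.true_pulse_time == other.true_pulse_time
        )
        return (
            self.cell_id == other.cell_id
            and self.parent_id == other.parent_id
            and self.birth_frame == other.birth_frame
            and self.end_frame == other.end_frame
            and self.fate == other.fate
            and same_truth
            and np.array_equal(self.time_min, other.time_min)
            and np.array_equal(self.length, other.length)
            and set(self.mean_fluor) == set(other.mean_fluor)
            and all(
                np.array_equal(self.mean_fluor[c], other.mean_fluor[c])
                for c in self.mean_fluor
            )
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic microcolony run.

    Defaults emulate a nutrient-limited wild-type movie: 10-min frames,
    ~4-h cell cycles, one broad promoter-activity pulse per cycle at a
    reproducible cell-cycle phase, amplitudes following a saturating
    feedback map with lognormal cycle-to-cycle noise, and multiplicative
    per-frame measurement noise on fluorescence.
    """

    seed: int = 0
    frame_interval_min: float = 10.0
    mean_cycle_min: float = 240.0
    cycle_cv: float = 0.10
    p0: float = 1.0
    feedback: SaturatingFeedback = field(default_factory=SaturatingFeedback)
    amplitude_cv: float = 0.2
    theta_sim: float = 10.0
    measurement_cv: float = 0.05
    maturation_rate: float = 0.0  # extra first-order loss gamma, 1/min
    pulse_phase: float = 0.6
    pulse_width_frac: float = 0.6
    constitutive_rho: float = 2.0
    n_founders: int = 1
    max_frames: int = 240
    max_cells: int = 4096
    bypass_level: float | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be positive")
        if self.mean_cycle_min <= 0:
            raise ConfigError("mean_cycle_min must be positive")
        for name in ("cycle_cv", "amplitude_cv", "measurement_cv", "maturation_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.pulse_width_frac <= 1):
            raise ConfigError("pulse_width_frac must lie in (0, 1]")
        if not (0 <= self.pulse_phase < 1):
            raise ConfigError("pulse_phase must lie in [0, 1)")
        if self.theta_sim <= self.p0:
            raise ConfigError("theta_sim must exceed the initial amplitude p0")
        if self.n_founders < 1 or self.max_frames < 2 or self.max_cells < 1:
            raise ConfigError("n_founders >= 1, max_frames >= 2, max_cells >= 1 required")


class Microcolony:
    """A lineage forest of :class:`CellRecord` keyed by cell id.

    Lineage ids follow a path encoding: founders are "1", "2", ...; a
    division appends "0"/"1", so a cell's depth (generations since its
    founder) is recoverable from the id but is computed from parent
    links for robustness.
    """

    def __init__(self, cells: dict[str, CellRecord] | None = None,
                 config: SimConfig | None = None):
        self.cells: dict[str, CellRecord] = dict(cells or {})
        self.config = config
        self._children: dict[str, list[str]] | None = None

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.cells.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Microcolony):
            return NotImplemented
        return self.cells == other.cells

    def add(self, cell: CellRecord) -> None:
        self.cells[cell.cell_id] = cell
        self._children = None

    def roots(self) -> list[CellRecord]:
        return [c for c in self.cells.values() if c.parent_id is None]

    def children(self, cell_id: str) -> list[CellRecord]:
        if self._children is None:
            table: dict[str, list[str]] = {}
            for c in self.cells.values():
                if c.parent_id is not None:
                    table.setdefault(c.parent_id, []).append(c.cell_id)
            self._children = table
        return [self.cells[i] for i in sorted(self._children.get(cell_id, []))]

    def depth(self, cell_id: str) -> int:
        """Generations since the founder (founder depth = 0)."""
        d = 0
        cell = self.cells[cell_id]
        while cell.parent_id is not None:
            cell = self.cells[cell.parent_id]
            d += 1
        return d

    def max_frame(self) -> int:
        return max((c.end_frame for c in self.cells.values()), default=0)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal noise with unit mean and given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _raised_cosine(t: np.ndarray, amplitude: float, center: float,
                   half_width: float) -> np.ndarray:
    u = (t - center) / half_width
    out = np.where(np.abs(u) < 1.0,
                   0.5 * amplitude * (1.0 + np.cos(np.pi * u)), 0.0)
    return out


def _integrate_mean_fluor(m0: float, t: np.ndarray, rho, decay: float,
                          n_sub: int = 4) -> np.ndarray:
    """RK4 integration of dM/dt = rho(t) - decay * M on the frame grid."""
    out = np.empty_like(t)
    out[0] = m0
    m = m0
    for k in range(len(t) - 1):
        h = (t[k + 1] - t[k]) / n_sub
        tk = t[k]
        for _ in range(n_sub):
            k1 = rho(tk) - decay * m
            k2 = rho(tk + 0.5 * h) - decay * (m + 0.5 * h * k1)
            k3 = rho(tk + 0.5 * h) - decay * (m + 0.5 * h * k2)
            k4 = rho(tk + h) - decay * (m + h * k3)
            m = m + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tk += h
        out[k + 1] = m
    return out


def _next_amplitude_wildtype(p_parent: float, cfg: SimConfig,
                             rng: np.random.Generator) -> float:
    return cfg.feedback(p_parent) * _lognormal_factor(rng, cfg.amplitude_cv)


def _next_amplitude_bypass(p_parent: float, cfg: SimConfig,
                           rng: np.random.Generator) -> float:
    # constitutive kinase: amplitude relaxes to the set level with the
    # dilution timescale (ln2 per cycle), no transcriptional feedback
    c = cfg.bypass_level
    relaxed = c + (p_parent - c) * math.exp(-math.log(2.0))
    return relaxed * _lognormal_factor(rng, cfg.amplitude_cv)


def _simulate(cfg: SimConfig, next_amplitude, sporulate: bool) -> Microcolony:
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_min
    gamma = cfg.maturation_rate
    colony = Microcolony(config=cfg)
    # breadth-first so truncation at max_cells censors the deepest cells last
    queue: deque = deque()
    for i in range(cfg.n_founders):
        m0_const = cfg.constitutive_rho / (math.log(2.0) / cfg.mean_cycle_min + gamma)
        queue.append((str(i + 1), None, 0, 1.0, 0.0, m0_const, cfg.p0))

    while queue:
        cell_id, parent_id, birth_frame, l0, m0_pulse, m0_const, amplitude = queue.popleft()
        # realized cycle length in whole frames
        t_cycle = cfg.mean_cycle_min * _lognormal_factor(rng, cfg.cycle_cv)
        n_cycle = max(3, int(round(t_cycle / dt)))
        end_frame = birth_frame + n_cycle
        censored = False
        if end_frame > cfg.max_frames:
            end_frame = cfg.max_frames
            censored = True
        n = end_frame - birth_frame
        lam = math.log(2.0) / (n_cycle * dt)  # length doubles over the full cycle

        t = (birth_frame + np.arange(n + 1)) * dt
        length = l0 * np.exp(lam * (t - t[0]))

        # pulsed channel: one raised-cosine promoter-activity bump per cycle
        center = t[0] + cfg.pulse_phase * n_cycle * dt
        half_width = 0.5 * cfg.pulse_width_frac * n_cycle * dt

        def rho_pulse(tt, _a=amplitude, _c=center, _w=half_width):
            return float(_raised_cosine(np.asarray(tt, dtype=float), _a, _c, _w))

        m_pulse = _integrate_mean_fluor(m0_pulse, t, rho_pulse, lam + gamma)
        m_const = _integrate_mean_fluor(
            m0_const, t, lambda tt: cfg.constitutive_rho, lam + gamma)

        obs_pulse, obs_const = m_pulse, m_const
        if cfg.measurement_cv > 0:
            sig = math.sqrt(math.log1p(cfg.measurement_cv**2))
            obs_pulse = m_pulse * rng.lognormal(-0.5 * sig * sig, sig, size=m_pulse.shape)
            obs_const = m_const * rng.lognormal(-0.5 * sig * sig, sig, size=m_const.shape)

        will_sporulate = sporulate and amplitude >= cfg.theta_sim
        room_for_children = (
            not censored
            and end_frame < cfg.max_frames
            # created so far + this cell + pending + two daughters
            and len(colony) + 1 + len(queue) + 2 <= cfg.max_cells
        )
        if censored:
            fate = FATE_CENSORED
        elif will_sporulate:
            fate = FATE_SPORULATED
        elif room_for_children:
            fate = FATE_DIVIDED
        else:
            fate = FATE_CENSORED

        colony.add(CellRecord(
            cell_id=cell_id, parent_id=parent_id,
            birth_frame=birth_frame, end_frame=end_frame, fate=fate,
            time_min=t, length=length,
            mean_fluor={PULSED_CHANNEL: obs_pulse, CONSTITUTIVE_CHANNEL: obs_const},
            true_amplitude=amplitude, true_pulse_time=center,
        ))

        if fate == FATE_DIVIDED:
            l_final = float(length[-1])
            for suffix in ("0", "1"):
                child_amp = next_amplitude(amplitude, cfg, rng)
                queue.append((
                    cell_id + suffix, cell_id, end_frame,
                    0.5 * l_final,               # symmetric split of the mother
                    float(m_pulse[-1]),          # concentrations are inherited
                    float(m_const[-1]),
                    child_amp,
                ))
    return colony


def simulate_microcolony(config: SimConfig) -> Microcolony:
    """Simulate a wild-type-like microcolony with saturating pulse feedback.

    Each cell cycle carries one promoter-activity pulse; the amplitude of
    a daughter's pulse is ``g(p_mother)`` times lognormal noise, with
    ``g`` the configured saturating feedback map.  A cell whose amplitude
    reaches ``theta_sim`` sporulates instead of dividing.  The run is
    fully reproducible from ``config.seed``.
    """
    return _simulate(config, _next_amplitude_wildtype, sporulate=True)


def simulate_bypass_colony(config: SimConfig) -> Microcolony:
    """Simulate a feedback-bypass (constitutive kinase) microcolony.

    Pulse amplitudes relax to ``config.bypass_level`` with a one-cycle
    dilution timescale and show no systematic cycle-over-cycle growth.
    Cells never sporulate via the feedback threshold rule (amplitudes
    stay near the constitutive level); the threshold flag is ignored.
    """
    if config.bypass_level is None:
        config = replace(config, bypass_level=config.p0)
    return _simulate(config, _next_amplitude_bypass, sporulate=False)


def simulate_amplitude_pairs(
    feedback: SaturatingFeedback,
    p0: float,
    amplitude_cv: float,
    n_pairs: int,
    seed: int,
    n_generations: int = 8,
) -> np.ndarray:
    """Successive pulse-amplitude pairs from noisy lineage chains.

    Iterates ``p_{N+1} = g(p_N) * lognormal(cv)`` along independent
    chains of ``n_generations`` steps each, starting from ``p0``, until
    ``n_pairs`` (p_N, p_{N+1}) pairs are collected.  This samples the
    same amplitude process as :func:`simulate_microcolony` without
    building the full trace-level colony; used for feedback-function
    recovery studies.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n_pairs:
        p = p0
        for _ in range(n_generations):
            nxt = feedback(p) * _lognormal_factor(rng, amplitude_cv)
            pairs.append((p, nxt))
            p = nxt
            if len(pairs) >= n_pairs:
                break
    return np.asarray(pairs[:n_pairs])
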