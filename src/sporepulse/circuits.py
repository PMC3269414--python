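"""Two-component pulsed sporulation-initiation circuit models.

The phosphorelay is reduced to a direct kinase -> Spo0A phosphotransfer
with a constant phosphatase (Spo0E-like) activity.  Time is measured in
cell cycles; dilution acts on all species at rate lambda = ln 2 per
cycle.  Kinase autophosphorylation (and hence phosphotransfer to Spo0A)
is gated on during the first ``f_pulse`` of every cell cycle, producing
one Spo0A~P pulse per cycle.  States:

    dK/dt   = beta_K * u(t) - lambda K
    dA_P/dt = gate(t) k_t K A_u - k_E A_P - lambda A_P
    dA_u/dt = -gate(t) k_t K A_u + k_E A_P - lambda A_u + lambda A_tot

so total Spo0A (A_P + A_u) is conserved at A_tot (constitutive Spo0A
expression balancing dilution).  The kinase drive u(t) selects the
architecture:

    open loop        u = 1
    instantaneous    u = g_fb(A_P(t))
    polyphasic       u = g_fb(A_P(t - tau)), delayed feedback

with g_fb a saturating activation function (basal + Hill term).
Sporulation is deferred until A_P first crosses the threshold theta;
the deferral time T_D is that crossing in cell-cycle units.

Integration is explicit fixed-step RK4 (discontinuous gating argues
against adaptive steps); delayed values come from a dense history
buffer with linear interpolation.  Results are deterministic and
reproducible bit-for-bit at a fixed step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, FitError, SolverError
from .onedim import ONED_VARIANTS, oned_sensitivity, oned_tune_b

__all__ = ["CircuitParams", "DeferralResult", "FeedbackActivation",
           "simulate_circuit", "deferral_time", "envelope_deferral_time",
           "kinase_rise_during_vs_between", "tune_beta_for_deferral",
           "sensitivity", "sensitivity_curve", "MODES"]

MODES = ("open_loop", "instantaneous", "polyphasic")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FeedbackActivation:
    """Saturating kinase-promoter activation by Spo0A~P.

    g(A) = basal + (1 - basal) * A^h / (K^h + A^h); dimensionless in
    [basal, 1), multiplying the promoter strength beta_K.
    """

    basal: float = 0.05
    K: float = 0.25
    h: float = 2.0

    def __call__(self, a: float) -> float:
        if a <= 0:
            return self.basal
        ah = a**self.h
        return self.basal + (1.0 - self.basal) * ah / (self.K**self.h + ah)


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the pulsed two-component circuit (time unit: cell cycle)."""

    beta_k: float = 1.0            # kinase promoter strength
    mode: str = "polyphasic"
    tau: float = 0.5               # feedback delay, cycles (polyphasic only)
    f_pulse: float = 0.3           # fraction of each cycle with autophosphorylation on
    k_t: float = 10.0              # phosphotransfer rate
    k_e: float = 2.0               # phosphatase (Spo0E-like) rate
    lam: float = LN2               # dilution rate per cycle
    a_tot: float = 1.0             # total Spo0A pool
    g_fb: FeedbackActivation = field(default_factory=FeedbackActivation)
    theta: float = 0.5             # Spo0A~P sporulation threshold
    t_max: float = 30.0            # maximum simulated cycles
    dt: float = 1.0 / 500.0        # integration step, cycles

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("beta_k", "k_t", "k_e", "lam", "a_tot", "tau"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.f_pulse <= 1):
            raise ConfigError("f_pulse must lie in (0, 1]")
        if self.theta <= 0 or self.theta >= self.a_tot:
            raise ConfigError("theta must lie in (0, a_tot)")
        if self.dt > self.f_pulse / 10.0:
            raise ConfigError(
                f"step {self.dt} too coarse: must resolve the pulse window "
                f"(dt <= f_pulse/10 = {self.f_pulse / 10.0})")
        if self.mode == "polyphasic" and 0 < self.tau < self.dt:
            raise ConfigError("delay tau must be 0 or >= one integration step")


@dataclass
class DeferralResult:
    """Simulated trajectory and threshold crossing of one circuit run."""

    params: CircuitParams
    t: np.ndarray
    kinase: np.ndarray
    a_p: np.ndarray
    a_u: np.ndarray
    crossed: bool
    t_d: float | None       # first up-crossing of theta, cycles; None if never
    cycle_max: np.ndarray = None  # per-cycle maxima of A_P (the pulse envelope)

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.a_p + self.a_u - self.params.a_tot)))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.kinase, label="kinase")
        ax.plot(self.t, self.a_p, label="Spo0A~P")
        ax.axhline(self.params.theta, ls="--", c="gray", label="threshold")
        if self.t_d is not None:
            ax.axvline(self.t_d, ls=":", c="k")
        ax.set_xlabel("time (cell cycles)")
        ax.set_ylabel("concentration (a.u.)")
        ax.legend()
        return ax


def _gate(t: float, f_pulse: float) -> float:
    return 1.0 if (t - math.floor(t)) < f_pulse else 0.0


def simulate_circuit(params: CircuitParams, record_every: int = 1,
                     stop_at_crossing: bool = False) -> DeferralResult:
    """Integrate the circuit from (K, A_P) = (0, 0) until t_max.

    The full trajectory is recorded every ``record_every`` steps (the
    crossing itself is interpolated on the step grid regardless).  With
    ``stop_at_crossing`` the run ends one step after T_D, which speeds
    up tuning loops; the recorded trajectory is then truncated.
    """
    p = params
    dt = p.dt
    n_steps = int(round(p.t_max / dt))
    g = p.g_fb
    instantaneous = p.mode == "instantaneous" or (p.mode == "polyphasic" and p.tau == 0)
    delayed = p.mode == "polyphasic" and p.tau > 0
    lag = p.tau / dt if delayed else 0.0

    hist_ap = np.empty(n_steps + 1)
    k = 0.0
    a_p = 0.0
    a_u = p.a_tot
    hist_ap[0] = a_p

    def drive(step_time: float, ap_now: float, step_index_float: float) -> float:
        if p.mode == "open_loop":
            return 1.0
        if instantaneous:
            return g(ap_now)
        j = step_index_float - lag
        if j <= 0:
            return g(hist_ap[0])
        jf = math.floor(j)
        frac = j - jf
        a_del = hist_ap[int(jf)] if frac == 0 else (
            (1 - frac) * hist_ap[int(jf)] + frac * hist_ap[int(jf) + 1])
        return g(a_del)

    rec_t, rec_k, rec_ap, rec_au = [0.0], [k], [a_p], [a_u]
    crossed = False
    t_d = None
    cycle_max: list[float] = [a_p]

    def rhs(t, si, kk, ap, au):
        gate = _gate(t, p.f_pulse)
        u = drive(t, ap, si)
        dk = p.beta_k * u - p.lam * kk
        transfer = gate * p.k_t * kk * au
        dap = transfer - p.k_e * ap - p.lam * ap
        dau = -transfer + p.k_e * ap - p.lam * au + p.lam * p.a_tot
        return dk, dap, dau

    for i in range(n_steps):
        t = i * dt
        k1 = rhs(t, i, k, a_p, a_u)
        k2 = rhs(t + 0.5 * dt, i + 0.5, k + 0.5 * dt * k1[0],
                 a_p + 0.5 * dt * k1[1], a_u + 0.5 * dt * k1[2])
        k3 = rhs(t + 0.5 * dt, i + 0.5, k + 0.5 * dt * k2[0],
                 a_p + 0.5 * dt * k2[1], a_u + 0.5 * dt * k2[2])
        k4 = rhs(t + dt, i + 1.0, k + dt * k3[0],
                 a_p + dt * k3[1], a_u + dt * k3[2])
        k_new = k + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        ap_new = a_p + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        au_new = a_u + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if k_new < -1e-9 or ap_new < -1e-9 or math.isnan(ap_new):
            raise SolverError(f"integration blow-up at t = {t:.3f} "
                              f"(K = {k_new:.3g}, A_P = {ap_new:.3g})")
        if not crossed and a_p < p.theta <= ap_new:
            frac = (p.theta - a_p) / (ap_new - a_p)
            t_d = t + frac * dt
            crossed = True
        k, a_p, a_u = k_new, ap_new, au_new
        hist_ap[i + 1] = a_p
        cycle = int((i + 1) * dt * (1.0 - 1e-12))
        if cycle >= len(cycle_max):
            cycle_max.append(a_p)
        else:
            cycle_max[cycle] = max(cycle_max[cycle], a_p)
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            rec_t.append((i + 1) * dt)
            rec_k.append(k)
            rec_ap.append(a_p)
            rec_au.append(a_u)
        # after a crossing, finish the current cycle so its envelope
        # maximum is complete, then stop
        if crossed and stop_at_crossing and (i + 1) * dt >= math.floor(t_d) + 1.0:
            break

    return DeferralResult(params=p, t=np.array(rec_t), kinase=np.array(rec_k),
                          a_p=np.array(rec_ap), a_u=np.array(rec_au),
                          crossed=crossed, t_d=t_d, cycle_max=np.array(cycle_max))


def deferral_time(result_or_ap, theta: float | None = None,
                  t: np.ndarray | None = None) -> float | None:
    """First up-crossing of theta, linearly interpolated, in cycles.

    Accepts a :class:`DeferralResult` (theta taken from its params
    unless overridden) or an explicit trajectory ``(a_p array, theta,
    t array)``.  Absence of a crossing is a value (None), not an error.
    """
    if isinstance(result_or_ap, DeferralResult):
        ap = result_or_ap.a_p
        tt = result_or_ap.t
        theta = result_or_ap.params.theta if theta is None else theta
    else:
        ap = np.asarray(result_or_ap, dtype=float)
        if theta is None or t is None:
            raise ConfigError("explicit trajectories need theta and t")
        tt = np.asarray(t, dtype=float)
    above = ap >= theta
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(tt[0])
    frac = (theta - ap[i - 1]) / (ap[i] - ap[i - 1])
    return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]))


def envelope_deferral_time(result: DeferralResult) -> float | None:
    """Deferral time from the pulse-amplitude envelope, in cycles.

    Because phosphorylation is pulsed, the first up-crossing time is a
    near-staircase function of promoter strength: crossings cluster at
    the pulse peaks, so ``t_d`` jumps by ~1 cycle as beta_K varies.
    For tuning and differentiation a continuous surrogate is needed:
    interpolate the cycle index at which the per-cycle A_P maxima
    (the pulse envelope) cross theta, offset by the pulse window so
    the value approximates the actual crossing time.  Agrees with
    ``t_d`` to within a fraction of a cycle wherever both exist.
    """
    m = result.cycle_max
    th = result.params.theta
    above = np.nonzero(m >= th)[0]
    if above.size == 0:
        return None
    n = int(above[0])
    if n == 0:
        return result.t_d
    c = (n - 1) + (th - m[n - 1]) / (m[n] - m[n - 1])
    return float(c + result.params.f_pulse)


def kinase_rise_during_vs_between(result: DeferralResult,
                                  cycle: int) -> tuple[float, float]:
    """Kinase level change during vs between pulse windows of one cycle.

    Returns (rise during the autophosphorylation window, rise over the
    rest of the cycle); requires a densely recorded trajectory
    (record_every=1).
    """
    p = result.params
    t = result.t
    kin = result.kinase
    t0, t1, t2 = cycle, cycle + p.f_pulse, cycle + 1.0
    k_at = lambda tt: float(np.interp(tt, t, kin))
    return k_at(t1) - k_at(t0), k_at(t2) - k_at(t1)


def _td_of_beta(params: CircuitParams, beta: float,
                metric: str = "envelope") -> float | None:
    res = simulate_circuit(replace(params, beta_k=beta), record_every=10**9,
                           stop_at_crossing=True)
    return envelope_deferral_time(res) if metric == "envelope" else res.t_d


def tune_beta_for_deferral(params: CircuitParams, target_td: float,
                           bracket: tuple[float, float] | None = None,
                           td_tol: float = 0.01, max_iter: int = 200,
                           metric: str = "envelope") -> float:
    """Bisect beta_K so the circuit's deferral time hits the target.

    T_D decreases monotonically in beta_K (more kinase, faster Spo0A~P
    buildup); the bracket is auto-expanded if not supplied.  Raises
    :class:`FitError` if the target is below the minimum achievable
    deferral or the threshold is unreachable at any strength tried.

    ``metric`` selects the deferral measure: "envelope" (default, the
    continuous pulse-envelope crossing — the only measure a 0.01-cycle
    tolerance is meaningful for, since the raw first-crossing time is
    quantized by the pulse windows) or "first_crossing".
    """
    if target_td <= 0 or target_td >= params.t_max:
        raise ConfigError("target_td must lie in (0, t_max)")
    td = lambda b: _td_of_beta(params, b, metric)
    if bracket is not None:
        lo, hi = bracket
    else:
        lo = hi = params.beta_k
        # hi: strong enough to cross faster than the target
        for _ in range(60):
            t = td(hi)
            if t is not None and t <= target_td:
                break
            hi *= 2.0
        else:
            raise FitError("could not bracket: threshold unreachable from above")
        # lo: weak enough to cross slower than the target (or not at all)
        for _ in range(200):
            t = td(lo)
            if t is None or t > target_td:
                break
            lo *= 0.5
        else:
            raise FitError("target below the minimum achievable deferral time")
    best = None
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        t = td(mid)
        if t is not None and (best is None or abs(t - target_td) < best[0]):
            best = (abs(t - target_td), mid)
        if t is not None and abs(t - target_td) < td_tol:
            return mid
        if t is None or t > target_td:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-14 * hi:
            break
    if best is None or best[0] > 10 * td_tol:
        raise FitError(f"bisection did not reach target {target_td} "
                       f"(best |error| = {best[0] if best else 'n/a'})")
    return best[1]


def sensitivity(params: CircuitParams, delta: float = 0.01,
                min_delta: float = 1e-5, metric: str = "envelope") -> float | None:
    """S = |d ln T_D / d ln beta_K| by central log-log finite difference.

    If the crossing is lost at either perturbed strength the
    perturbation is shrunk (delta / 4, down to ``min_delta``) before
    the sensitivity is declared undefined (None).  Near-critical
    strengths — the open-loop circuit at long deferrals — need this:
    a 1% strength drop can make the threshold unreachable.
    """
    d = delta
    while d >= min_delta:
        t_hi = _td_of_beta(params, params.beta_k * math.exp(d), metric)
        t_lo = _td_of_beta(params, params.beta_k * math.exp(-d), metric)
        if t_hi is not None and t_lo is not None and t_hi > 0 and t_lo > 0:
            return abs(math.log(t_lo) - math.log(t_hi)) / (2 * d)
        d /= 4.0
    return None


def sensitivity_curve(family: str, td_grid, base_params: CircuitParams | None = None,
                      delta: float = 0.01):
    """S(T_D) per architecture, tuning the strength parameter at each target.

    ``family`` is "oned" (closed-form models) or "two_component".
    Unreachable targets are recorded as NaN.  Returns
    ``{variant: array aligned with td_grid}``.
    """
    td_grid = np.asarray(list(td_grid), dtype=float)
    curves: dict[str, np.ndarray] = {}
    if family == "oned":
        for variant in ONED_VARIANTS:
            out = np.full(td_grid.shape, np.nan)
            for i, td in enumerate(td_grid):
                try:
                    b = oned_tune_b(variant, float(td))
                except FitError:
                    continue
                s = oned_sensitivity(variant, b)
                out[i] = np.nan if s is None else s
            curves[variant] = out
        return curves
    if family != "two_component":
        raise ConfigError("family must be 'oned' or 'two_component'")
    if base_params is None:
        base_params = CircuitParams()
    for mode in MODES:
        params = replace(base_params, mode=mode)
        out = np.full(td_grid.shape, np.nan)
        for i, td in enumerate(td_grid):
            try:
                beta = tune_beta_for_deferral(params, float(td))
            except FitError:
                continue
            s = sensitivity(replace(params, beta_k=beta), delta=delta)
            out[i] = np.nan if s is None else s
        curves[mode] = out
    return curves
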