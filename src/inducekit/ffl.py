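"""Step- and ramp-response theory for feed-forward loops.

Because the input X is held at fixed concentration, Y's equation is linear
and relaxes exponentially between its pre- and post-step steady states, and
Z's equation is linear in Z with a time-dependent drive.  Writing the Z
production term as (a + b*Y)/(p + q*Y), the response to a step in the X
effector integrates in closed form:

    Z(t) = Z_i e^{-t} + Z_f (1 - e^{-t}) + Theta(t),
    Theta(t) = -(Phi dY / S^2) e^{-t} ln[(S e^t - q dY) / (S - q dY)],

with dY = Y_f - Y_i (in promoter-occupancy units), Phi = b p - a q the
rate/cooperativity coefficient, S = p + q Y_f the final-state partition sum
and q = 1 + omega X_f.  Theta is the offset from the matched simple-
regulation exponential; its time integral normalised by the output swing is
the average delay (< 0) or acceleration (> 0)

    <dt> = Phi / ((Z_f - Z_i) S q) * ln[(S - q dY)/S].

The same formulas cover the coherent loop (b = r1Z + omega r2Z X_f, so
Phi >= 0 for ordered rates: delay) and the incoherent loop (b = 0, so
Phi = -(r0Z + r1Z X_f)(1 + omega X_f) < 0: acceleration, with pulses when
the overshoot is large).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .allostery import p_active
from .circuits import (
    IncoherentFFLParams,
    cffl_rhs,
    iffl_rhs,
    y_steady_state,
    z_production,
    z_production_coefficients,
)
from .dynamics import Trajectory, integrate

__all__ = [
    "StepInput",
    "ContinuousInput",
    "DelayAnalytics",
    "PulseMetrics",
    "DEFAULT_STEP_ON",
    "DEFAULT_STEP_OFF",
    "ffl_steady_state",
    "simple_regulation_response",
    "ffl_step_response",
    "delay_analytics",
    "delay_sweep",
    "DelaySweep",
    "pulse_metrics",
    "continuous_response",
    "ContinuousResponse",
]


class DegenerateStepError(ValueError):
    pass


@dataclass(frozen=True)
class StepInput:
    """Step protocol for the X effector: cX jumps from ``c_initial`` to
    ``c_final`` at t = 0 while cY stays at ``c_Y``.

    The step is ON if the active fraction of X increases across the jump
    (for an inactivating effector that means cX *decreases*), OFF otherwise.
    """

    c_initial: float
    c_final: float
    c_Y: float = 1e-7
    t_step: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_initial", "c_final", "c_Y"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    def direction(self, tf) -> str:
        return "ON" if p_active(tf, self.c_final) > p_active(tf, self.c_initial) else "OFF"

    def reversed(self) -> "StepInput":
        return StepInput(self.c_final, self.c_initial, self.c_Y, self.t_step)


#: Default step protocol: cX between 1e-4 M and 1e-7 M, cY fixed at 1e-7 M.
#: With the default inactivating effector, dropping cX raises X activity (ON).
DEFAULT_STEP_ON = StepInput(c_initial=1e-4, c_final=1e-7)
DEFAULT_STEP_OFF = DEFAULT_STEP_ON.reversed()


def ffl_steady_state(p, cX: float, cY: float) -> tuple[float, float]:
    """Exact steady state (Ybar, Zbar) of a feed-forward loop at constant
    effector concentrations."""
    Y = y_steady_state(p, cX)
    Xs = p_active(p.tfX, cX) * p.Xbar / p.KXZ
    Ys = p_active(p.tfY, cY) * Y / p.KYZ
    return Y, float(z_production(p, Xs, Ys))


def _step_quantities(p, step: StepInput):
    pXi = p_active(p.tfX, step.c_initial)
    pXf = p_active(p.tfX, step.c_final)
    pY = p_active(p.tfY, step.c_Y)
    Xi = pXi * p.Xbar / p.KXZ
    Xf = pXf * p.Xbar / p.KXZ
    Yi = p.r0Y + p.r1Y * pXi * p.Xbar / (1.0 + pXi * p.Xbar)
    Yf = p.r0Y + p.r1Y * pXf * p.Xbar / (1.0 + pXf * p.Xbar)
    Ysi = pY * Yi / p.KYZ
    Ysf = pY * Yf / p.KYZ
    Zi = float(z_production(p, Xi, Ysi))
    Zf = float(z_production(p, Xf, Ysf))
    return Xi, Xf, Yi, Yf, Ysi, Ysf, Zi, Zf


def simple_regulation_response(
    p, step: StepInput, Ybar_fixed: float = 1.0, t_grid=None, ode_check: bool = False
) -> Trajectory:
    """Closed-form step response of the matched simple-regulation circuit.

    Y is pinned at ``Ybar_fixed`` (X no longer regulates Y), so after the
    step Z relaxes exponentially from Z_si to Z_sf with unit rate:
    ``Z_s(t) = Z_si e^{-t} + Z_sf (1 - e^{-t})``.  With ``ode_check`` the
    exponential is verified against direct integration.
    """
    if not Ybar_fixed > 0:
        raise ValueError("Ybar_fixed must be > 0")
    pY = p_active(p.tfY, step.c_Y)
    Ys = pY * Ybar_fixed / p.KYZ
    Xi = p_active(p.tfX, step.c_initial) * p.Xbar / p.KXZ
    Xf = p_active(p.tfX, step.c_final) * p.Xbar / p.KXZ
    Zsi = float(z_production(p, Xi, Ys))
    Zsf = float(z_production(p, Xf, Ys))
    if t_grid is None:
        t_grid = np.linspace(0.0, 30.0, 1200)
    t_grid = np.asarray(t_grid, dtype=float)
    Zs = Zsi * np.exp(-t_grid) + Zsf * (1.0 - np.exp(-t_grid))
    if ode_check:
        rhs = lambda t, y: np.array([-y[0] + Zsf])
        traj = integrate(rhs, [Zsi], float(t_grid[-1]), t_eval=t_grid,
                         rtol=1e-10, atol=1e-13)
        err = np.max(np.abs(traj.y[:, 0] - Zs))
        if err > 1e-7:
            raise RuntimeError(f"closed form disagrees with ODE by {err:.2e}")
    return Trajectory(
        t_grid, Zs[:, None],
        protocol={"kind": "simple_regulation", "step": step, "Zsi": Zsi, "Zsf": Zsf,
                  "Ybar_fixed": Ybar_fixed},
        converged=True, final_residual=abs(Zs[-1] - Zsf),
    )


def ffl_step_response(
    p, step: StepInput, t_grid=None, rtol: float = 1e-10, atol: float = 1e-13
) -> Trajectory:
    """Numeric (Ybar, Zbar) step response of a feed-forward loop.

    The system starts at its pre-step steady state (computed, not assumed);
    for t > 0 the effectors are (c_final, c_Y).
    """
    rhs_fn = iffl_rhs if isinstance(p, IncoherentFFLParams) else cffl_rhs
    Y0, Z0 = ffl_steady_state(p, step.c_initial, step.c_Y)
    if t_grid is None:
        t_grid = np.linspace(0.0, 30.0, 1200)
    t_grid = np.asarray(t_grid, dtype=float)
    rhs = lambda t, y: rhs_fn(np.clip(y, 0.0, None), p, (step.c_final, step.c_Y))
    traj = integrate(rhs, [Y0, Z0], float(t_grid[-1]), t_eval=t_grid,
                     rtol=rtol, atol=atol, protocol={"kind": "ffl_step", "step": step})
    return traj


@dataclass
class DelayAnalytics:
    """Closed-form step-response analytics of a feed-forward loop."""

    DeltaY: float
    Phi: float
    S: float
    Z_i: float
    Z_f: float
    avg_dt: float
    q: float
    t_grid: np.ndarray = field(repr=False)
    Theta: np.ndarray = field(repr=False)

    def theta(self, t):
        """Evaluate the analytic offset Theta at arbitrary times."""
        return _theta(t, self.Phi, self.DeltaY, self.S, self.q)


def _theta(t, Phi, DeltaY, S, q):
    t = np.asarray(t, dtype=float)
    if DeltaY == 0.0 or Phi == 0.0:
        return np.zeros_like(t)
    k = q * DeltaY
    # log written as t + log(S - k e^{-t}) to stay finite at large t
    val = -(Phi * DeltaY / S**2) * np.exp(-t) * (
        t + np.log(S - k * np.exp(-t)) - np.log(S - k)
    )
    return val


def _pulse_time_grid(t_end: float = 30.0, n: int = 1200) -> np.ndarray:
    """Time grid log-dense near zero, so that brief excursions immediately
    after the step are not missed by pulse detection."""
    return np.concatenate([[0.0], np.geomspace(1e-5, t_end, n - 1)])


def step_response_closed_form(p, step: StepInput, t_grid=None) -> Trajectory:
    """Exact output trajectory of a feed-forward loop under a step, from the
    closed form Z(t) = Z_i e^{-t} + Z_f (1 - e^{-t}) + Theta(t)."""
    Xi, Xf, Yi, Yf, Ysi, Ysf, Zi, Zf = _step_quantities(p, step)
    a, b, pden, q = z_production_coefficients(p, Xf)
    Phi = float(b * pden - a * q)
    S = float(pden + q * Ysf)
    if t_grid is None:
        t_grid = _pulse_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    Z = Zi * np.exp(-t_grid) + Zf * (1.0 - np.exp(-t_grid)) \
        + _theta(t_grid, Phi, Ysf - Ysi, S, q)
    return Trajectory(t_grid, Z[:, None],
                      protocol={"kind": "ffl_step_closed_form", "step": step,
                                "Z_i": Zi, "Z_f": Zf},
                      converged=True, final_residual=abs(Z[-1] - Zf))


def delay_analytics(
    p,
    step: StepInput,
    validate: bool = True,
    t_grid=None,
    check_tol: float = 1e-6,
) -> DelayAnalytics:
    """Analytic step-response offset Theta(t) and average delay <dt> of a
    feed-forward loop.

    With ``validate`` (default), two self-checks guard the closed forms:
    Theta must match the ODE response minus the rescaled exponential within
    ``check_tol`` in sup-norm, and the closed-form <dt> must match the
    numeric quadrature of Theta within ``check_tol`` relative.  Raises
    ``DegenerateStepError`` when the output swing Z_f - Z_i vanishes (the
    normalisation of <dt> is undefined).
    """
    Xi, Xf, Yi, Yf, Ysi, Ysf, Zi, Zf = _step_quantities(p, step)
    a, b, pden, q = z_production_coefficients(p, Xf)
    Phi = float(b * pden - a * q)
    DeltaY = Ysf - Ysi
    S = float(pden + q * Ysf)
    if abs(Zf - Zi) < 1e-13 * max(1.0, abs(Zf), abs(Zi)):
        raise DegenerateStepError("Z_f == Z_i: average delay normalisation undefined")

    if t_grid is None:
        t_grid = np.linspace(0.0, 30.0, 1200)
    t_grid = np.asarray(t_grid, dtype=float)
    Theta = _theta(t_grid, Phi, DeltaY, S, q)

    if DeltaY == 0.0 or Phi == 0.0:
        avg_dt = 0.0
    else:
        avg_dt = Phi / ((Zf - Zi) * S * q) * math.log((S - q * DeltaY) / S)

    result = DelayAnalytics(DeltaY, Phi, S, Zi, Zf, float(avg_dt), q, t_grid, Theta)

    if validate:
        traj = ffl_step_response(p, step, t_grid=t_grid)
        exponential = Zi * np.exp(-t_grid) + Zf * (1.0 - np.exp(-t_grid))
        theta_num = traj.y[:, 1] - exponential
        sup = float(np.max(np.abs(theta_num - Theta)))
        scale = max(1.0, float(np.max(np.abs(Theta))))
        if sup > check_tol * scale:
            raise RuntimeError(
                f"analytic Theta disagrees with ODE offset (sup-norm {sup:.2e})"
            )
        integral, _ = quad(lambda t: float(_theta(t, Phi, DeltaY, S, q)), 0.0, 50.0,
                           limit=200, epsabs=1e-12, epsrel=1e-12)
        avg_quad = integral / (Zf - Zi)
        denom = max(abs(avg_dt), 1e-12)
        if abs(avg_quad - avg_dt) > check_tol * denom:
            raise RuntimeError(
                f"closed-form <dt> {avg_dt:.6e} disagrees with quadrature {avg_quad:.6e}"
            )
        result.__dict__["theta_ode_supnorm"] = sup
    return result


# ---------------------------------------------------------------------------
# parameter sweeps (vectorised closed form; no per-cell ODE)
# ---------------------------------------------------------------------------

@dataclass
class DelaySweep:
    """Average delay over a (KXZ, KYZ) grid; ``avg_dt[i, j]`` refers to
    ``(KXZ_grid[i], KYZ_grid[j])``."""

    KXZ_grid: np.ndarray
    KYZ_grid: np.ndarray
    avg_dt: np.ndarray
    pulse_amplitude: np.ndarray | None = None
    strong_pulse: np.ndarray | None = None

    @property
    def max_abs_dt(self) -> float:
        return float(np.nanmax(np.abs(self.avg_dt)))

    @property
    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmax(np.abs(self.avg_dt)), self.avg_dt.shape)
        return float(self.KXZ_grid[i]), float(self.KYZ_grid[j])


def delay_sweep(
    p_base,
    KXZ_grid,
    KYZ_grid,
    step: StepInput,
    pulse_threshold: float = 0.05,
    t_grid=None,
) -> DelaySweep:
    """Vectorised closed-form <dt> over a grid of dimensionless dissociation
    constants; degenerate cells (zero output swing) are NaN.

    For incoherent parameter sets, the closed-form trajectory is also scanned
    for pulses; ``strong_pulse`` marks cells whose overshoot exceeds
    ``pulse_threshold`` of the output swing (those cells' <dt> values are
    still reported, but carry the caveat that the delay interpretation is
    ambiguous when a pulse exists).
    """
    KXZ = np.asarray(KXZ_grid, dtype=float)[:, None]
    KYZ = np.asarray(KYZ_grid, dtype=float)[None, :]
    pXi = p_active(p_base.tfX, step.c_initial)
    pXf = p_active(p_base.tfX, step.c_final)
    pY = p_active(p_base.tfY, step.c_Y)
    Yi = p_base.r0Y + p_base.r1Y * pXi * p_base.Xbar / (1.0 + pXi * p_base.Xbar)
    Yf = p_base.r0Y + p_base.r1Y * pXf * p_base.Xbar / (1.0 + pXf * p_base.Xbar)

    Xi = pXi * p_base.Xbar / KXZ
    Xf = pXf * p_base.Xbar / KXZ
    Ysi = pY * Yi / KYZ
    Ysf = pY * Yf / KYZ

    incoherent = isinstance(p_base, IncoherentFFLParams)
    a = p_base.r0Z + p_base.r1Z * Xf
    b = np.zeros_like(Xf) if incoherent else p_base.r1Z + p_base.omega * p_base.r2Z * Xf
    pden = 1.0 + Xf
    q = 1.0 + p_base.omega * Xf

    ai = p_base.r0Z + p_base.r1Z * Xi
    bi = np.zeros_like(Xi) if incoherent else p_base.r1Z + p_base.omega * p_base.r2Z * Xi
    Zi = (ai + bi * Ysi) / (1.0 + Xi + (1.0 + p_base.omega * Xi) * Ysi)
    Zf = (a + b * Ysf) / (pden + q * Ysf)

    Phi = b * pden - a * q
    DeltaY = Ysf - Ysi
    S = pden + q * Ysf
    swing = Zf - Zi
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = Phi / (swing * S * q) * np.log((S - q * DeltaY) / S)
    avg = np.where(np.abs(swing) < 1e-13, np.nan, avg)
    avg = np.where((DeltaY == 0) | (Phi == 0), np.where(np.isnan(avg), np.nan, 0.0), avg)

    pulse_amp = None
    strong = None
    if incoherent:
        if t_grid is None:
            t_grid = _pulse_time_grid(n=800)
        t = t_grid[:, None, None]
        k = q * DeltaY
        with np.errstate(divide="ignore", invalid="ignore"):
            Theta = -(Phi * DeltaY / S**2) * np.exp(-t) * (
                t + np.log(S - k * np.exp(-t)) - np.log(S - k)
            )
        Theta = np.nan_to_num(Theta)
        Z = Zi * np.exp(-t) + Zf * (1.0 - np.exp(-t)) + Theta
        hi, lo = np.maximum(Zi, Zf), np.minimum(Zi, Zf)
        up_excess = Z.max(axis=0) - hi
        dn_excess = lo - Z.min(axis=0)
        tol = 1e-8 * np.maximum.reduce([np.abs(Zi), np.abs(Zf),
                                        np.ones_like(np.broadcast_arrays(Zi, Zf)[0])])
        up = (up_excess >= dn_excess) & (up_excess > tol)
        dn = (dn_excess > up_excess) & (dn_excess > tol)
        pulse_amp = np.where(up, Z.max(axis=0) - Zf,
                             np.where(dn, Zf - Z.min(axis=0), 0.0))
        strong = pulse_amp > pulse_threshold * np.abs(swing)

    return DelaySweep(np.asarray(KXZ_grid, float), np.asarray(KYZ_grid, float),
                      avg, pulse_amp, strong)


# ---------------------------------------------------------------------------
# pulses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseMetrics:
    """Overshoot metrics of an output trajectory relative to its final state."""

    has_pulse: bool
    strong: bool
    amplitude: float
    t_peak: float


def pulse_metrics(
    traj: Trajectory,
    Z_f: float,
    Z_i: float,
    strong_threshold: float = 0.05,
    z_index: int = -1,
    abs_tol: float = 1e-8,
) -> PulseMetrics:
    """Detect a pulse: a transient excursion of Z(t) beyond its final steady
    state, in the direction of the response.

    A pulse is a transient excursion beyond the envelope
    ``[min(Z_i, Z_f), max(Z_i, Z_f)]``: above it for a rising excursion,
    below it for a falling one (for the generic monotone-net-change response
    this reduces to the overshoot-beyond-Z_f definition).  ``amplitude`` is
    the maximum deviation beyond Z_f in the excursion direction; the pulse
    is ``strong`` when the amplitude exceeds ``strong_threshold`` of the
    output swing |Z_f - Z_i|.
    """
    if not traj.converged and traj.final_residual > 1e-6:
        raise ValueError("trajectory has not converged; pulse metrics undefined")
    z = traj.y[:, z_index]
    scale = max(abs(Z_f), abs(Z_i), 1.0)
    hi, lo = max(Z_i, Z_f), min(Z_i, Z_f)
    up_excess = float(np.max(z) - hi)
    dn_excess = float(lo - np.min(z))
    tol = abs_tol * scale
    if up_excess >= dn_excess and up_excess > tol:
        k = int(np.argmax(z))
        has, amp = True, float(z[k] - Z_f)
    elif dn_excess > tol:
        k = int(np.argmin(z))
        has, amp = True, float(Z_f - z[k])
    else:
        has, amp, k = False, 0.0, -1
    swing = abs(Z_f - Z_i)
    strong = bool(has and swing > 0 and amp / swing > strong_threshold)
    return PulseMetrics(bool(has), strong, amp, float(traj.t[k]) if has else math.nan)


# ---------------------------------------------------------------------------
# continuous (ramped) signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousInput:
    """Piecewise log-linear effector schedule cX(t).

    ``times`` are knot times (dimensionless) and ``c_knots`` the molar
    concentrations at the knots; between knots log10(cX) is linear, outside
    the knots it is held constant.
    """

    times: tuple
    c_knots: tuple

    def __post_init__(self) -> None:
        if len(self.times) != len(self.c_knots) or len(self.times) < 2:
            raise ValueError("need matching times/c_knots with at least two knots")
        if any(c <= 0 for c in self.c_knots):
            raise ValueError("concentrations must be positive")
        if any(t1 <= t0 for t0, t1 in zip(self.times, self.times[1:])):
            raise ValueError("knot times must be strictly increasing")

    def c_of_t(self, t):
        logc = np.interp(np.asarray(t, dtype=float), self.times,
                         np.log10(self.c_knots))
        return 10.0 ** logc

    @classmethod
    def ramp(cls, c_from: float, c_to: float, t_start: float, duration: float):
        return cls((t_start, t_start + duration), (c_from, c_to))


@dataclass
class ContinuousResponse:
    """FFL and matched simple-regulation trajectories under a ramped input."""

    ffl: Trajectory
    simple: Trajectory
    t_c: float | None
    pact_trace: np.ndarray


def _pact_crossing(tf, ramp: ContinuousInput, level: float, t_lo, t_hi):
    from scipy.optimize import brentq

    f = lambda t: p_active(tf, float(ramp.c_of_t(t))) - level
    return brentq(f, t_lo, t_hi, xtol=1e-10)


def continuous_response(
    p,
    ramp: ContinuousInput,
    cY: float = 1e-7,
    Ybar_fixed: float = 1.0,
    t_end: float | None = None,
    n_eval: int = 2000,
) -> ContinuousResponse:
    """Integrate a feed-forward loop under a continuously varying cX(t),
    together with the fixed-Y simple-regulation reference.

    ``t_c``, the input timescale, is the time for the X activity to traverse
    [0.2, 0.8] (in either direction) during the first ramp segment; if the
    activity never covers that range ``t_c`` is None and a warning is issued
    (the trajectories are still returned).
    """
    rhs_fn = iffl_rhs if isinstance(p, IncoherentFFLParams) else cffl_rhs
    if t_end is None:
        t_end = ramp.times[-1] + 15.0
    t_eval = np.linspace(0.0, t_end, n_eval)

    Y0, Z0 = ffl_steady_state(p, float(ramp.c_of_t(0.0)), cY)
    rhs = lambda t, y: rhs_fn(np.clip(y, 0.0, None), p,
                              (float(ramp.c_of_t(t)), cY))
    ffl_traj = integrate(rhs, [Y0, Z0], t_end, t_eval=t_eval, rtol=1e-9, atol=1e-12,
                         protocol={"kind": "ffl_ramp", "ramp": ramp})

    pY = p_active(p.tfY, cY)
    Ys = pY * Ybar_fixed / p.KYZ

    def zs_prod(t):
        Xs = p_active(p.tfX, float(ramp.c_of_t(t))) * p.Xbar / p.KXZ
        return float(z_production(p, Xs, Ys))

    Zs0 = zs_prod(0.0)
    rhs_s = lambda t, y: np.array([-y[0] + zs_prod(t)])
    simple_traj = integrate(rhs_s, [Zs0], t_end, t_eval=t_eval, rtol=1e-9, atol=1e-12,
                            protocol={"kind": "simple_ramp", "ramp": ramp,
                                      "Ybar_fixed": Ybar_fixed})

    pact_trace = np.asarray(p_active(p.tfX, ramp.c_of_t(t_eval)))
    t_c = None
    lo, hi = float(np.min(pact_trace)), float(np.max(pact_trace))
    if lo < 0.2 and hi > 0.8:
        # restrict to the first ramp segment for a well-defined traversal
        t0, t1 = ramp.times[0], ramp.times[-1]
        try:
            ta = _pact_crossing(p.tfX, ramp, 0.2, t0, t1)
            tb = _pact_crossing(p.tfX, ramp, 0.8, t0, t1)
            t_c = abs(tb - ta)
        except ValueError:
            t_c = None
    if t_c is None:
        warnings.warn("X activity does not traverse [0.2, 0.8]; t_c undefined",
                      RuntimeWarning, stacklevel=2)
    return ContinuousResponse(ffl_traj, simple_traj, t_c, pact_trace)
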