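"""ODE integration, relaxation timescales, separatrices and basins.

All estimators here are deterministic.  Single trajectories use adaptive
integration (scipy ``solve_ivp``, rtol 1e-8 / atol 1e-12 by default) with an
optional steady-state stopping event; basin-of-attraction grids integrate
thousands of initial conditions simultaneously with a vectorised fixed-step
RK4 (basin membership only needs the attractor identity, not tight local
error control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .allostery import p_active
from .circuits import AutoActivationParams, MutualRepressionParams, auto_rhs, mr_rhs
from .steady_state import FixedPoint, auto_f_prime, auto_fixed_points, mr_fixed_points

__all__ = [
    "Trajectory",
    "RelaxationResult",
    "integrate",
    "linear_timescale",
    "relaxation_time_auto",
    "relaxation_time_mr",
    "mr_separatrix",
    "mr_basins",
]


class IntegrationFailure(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time grid and states from an ODE integration, with protocol metadata."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, n_states)
    protocol: dict = field(default_factory=dict)
    converged: bool = False
    final_residual: float = math.nan

    def final_state(self) -> np.ndarray:
        return self.y[-1]


def integrate(
    rhs,
    y0,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    steady_tol: float | None = None,
    t_eval=None,
    protocol: dict | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``dy/dt = rhs(t, y)`` from ``y0`` to ``t_end``.

    With ``steady_tol`` set, integration stops early once the right-hand-side
    norm falls below it (steady-state detection).  Raises
    ``IntegrationFailure`` on solver failure or non-finite states.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if np.any(y0 < 0):
        raise ValueError("initial state must be >= 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    events = None
    if steady_tol is not None:
        def _steady(t, y):
            return float(np.linalg.norm(rhs(t, y))) - steady_tol
        _steady.terminal = True
        _steady.direction = -1
        events = [_steady]

    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, rtol=rtol, atol=atol,
        t_eval=t_eval, events=events, dense_output=False,
    )
    if not sol.success:
        raise IntegrationFailure(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationFailure("non-finite state encountered during integration")
    y = sol.y.T
    resid = float(np.linalg.norm(rhs(sol.t[-1], y[-1])))
    converged = resid < (steady_tol if steady_tol is not None else 1e-9)
    return Trajectory(sol.t, y, protocol or {}, converged, resid)


# ---------------------------------------------------------------------------
# auto-activation relaxation
# ---------------------------------------------------------------------------

class MarginalPointError(ValueError):
    pass


def linear_timescale(p: AutoActivationParams, c: float, A_star: float) -> float:
    """Linearised relaxation timescale 1/|f'(A*)| at a fixed point.

    The sign of f'(A*) (negative at stable points) is available from
    ``steady_state.auto_f_prime``; raises ``MarginalPointError`` at
    saddle-node (|f'| < 1e-12) points where the linear timescale diverges.
    """
    fp = auto_f_prime(A_star, p, p_active(p.tf, c))
    if abs(fp) < 1e-12:
        raise MarginalPointError(f"|f'({A_star})| < 1e-12: marginal fixed point")
    return 1.0 / abs(fp)


@dataclass
class RelaxationResult:
    """Relaxation timescale estimate toward an attractor."""

    tau: float
    method: str
    target_state: np.ndarray
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def _auto_attractor(p, c, A0) -> tuple[float, list[FixedPoint]]:
    fps = auto_fixed_points(p, c)
    stable = [float(f.state[0]) for f in fps if f.is_stable]
    unstable = [float(f.state[0]) for f in fps if f.stability == "unstable"]
    for u in unstable:
        if abs(A0 - u) < 1e-12 * max(1.0, u):
            raise ValueError("initial condition sits exactly on an unstable fixed point")
    f0 = auto_rhs(A0, p, c)
    if abs(f0) < 1e-14:  # already at a fixed point
        target = min(stable, key=lambda s: abs(s - A0))
    elif f0 > 0:
        above = [A for A in stable if A >= A0]
        target = min(above) if above else max(stable)
    else:
        below = [A for A in stable if A <= A0]
        target = max(below) if below else min(stable)
    return target, fps


def relaxation_time_auto(
    p: AutoActivationParams,
    c: float,
    A0: float,
    method: str = "fit_exponential",
    n_samples: int = 600,
) -> RelaxationResult:
    """Relaxation timescale of the auto-activation switch from ``A0``.

    ``threshold_95``: first time the deviation |A - A_ss| shrinks to 5% of
    its initial value.  ``fit_exponential``: bounded least-squares fit of
    ``A(t) = B + C exp(-t/tau)`` over the dominant relaxation phase (sampled
    uniformly until the deviation has halved).  The free offset and the
    half-decay window make the fit characterise the bulk approach rather
    than the terminal linear regime: tau matches 1/|f'| for starts near a
    fixed point (where the whole transient is linear), grows without bound
    as the start approaches the unstable fixed point, and tends to the
    degradation timescale 1 for starts far above the high state (where
    production is nearly saturated and the decay is degradation-limited).
    The terminal-regime rate is available separately via
    ``linear_timescale``.
    """
    if A0 < 0:
        raise ValueError("A0 must be >= 0")
    if method not in ("fit_exponential", "threshold_95"):
        raise ValueError(f"unknown method {method!r}")
    A_ss, _ = _auto_attractor(p, c, A0)
    dev0 = abs(A0 - A_ss)
    if dev0 < 1e-12 * max(1.0, A_ss):
        # already at the attractor: report the linearised timescale
        tau = linear_timescale(p, c, A_ss)
        return RelaxationResult(tau, method, np.array([A_ss]),
                                diagnostics={"note": "initial condition at attractor"})

    rhs = lambda t, y: np.array([auto_rhs(max(y[0], 0.0), p, c)])
    t_end = 20.0
    for _ in range(12):
        traj = integrate(rhs, [A0], t_end, t_eval=np.linspace(0.0, t_end, n_samples))
        dev = np.abs(traj.y[:, 0] - A_ss)
        if dev[-1] <= 0.01 * dev0:
            break
        t_end *= 2.0
    else:
        return RelaxationResult(math.nan, method, np.array([A_ss]), converged=False,
                                diagnostics={"t_end": t_end})

    t, A = traj.t, traj.y[:, 0]
    dev = np.abs(A - A_ss)

    if method == "threshold_95":
        cross = np.flatnonzero(dev <= 0.05 * dev0)
        i = cross[0]
        if i == 0:
            tau = 0.0
        else:  # linear interpolation of the crossing time
            d0, d1 = dev[i - 1], dev[i]
            frac = (d0 - 0.05 * dev0) / (d0 - d1)
            tau = t[i - 1] + frac * (t[i] - t[i - 1])
        return RelaxationResult(float(tau), method, np.array([A_ss]),
                                diagnostics={"crossing_index": int(i)})

    below = np.flatnonzero(dev <= 0.5 * dev0)
    i_end = max(below[0] if below.size else len(t) - 1, 5)
    t_fit, A_fit = t[: i_end + 1], A[: i_end + 1]

    def resid(theta):
        B, C, log_tau = theta
        return B + C * np.exp(-t_fit / np.exp(log_tau)) - A_fit

    bound = 2.0 * max(A0, A_ss, 1.0)
    fit = least_squares(
        resid,
        np.array([A_ss, A0 - A_ss, 0.0]),
        bounds=([0.0, -2.0 * bound, -5.0], [bound, 2.0 * bound, 12.0]),
        max_nfev=4000,
    )
    tau = float(np.exp(fit.x[2]))
    return RelaxationResult(
        tau, method, np.array([A_ss]),
        diagnostics={"fit_cost": float(fit.cost), "offset": float(fit.x[0])},
    )


# ---------------------------------------------------------------------------
# mutual repression: relaxation, separatrix, basins
# ---------------------------------------------------------------------------

def relaxation_time_mr(
    p: MutualRepressionParams,
    c1: float,
    c2: float,
    R0,
    t_max: float = 200.0,
    threshold: float = 0.05,
) -> RelaxationResult:
    """Relaxation time of the toggle switch from initial condition ``R0``.

    Per-component times tau_i are the last times |R_i(t) - R_i*| exceeds
    ``threshold`` (default 5%) of the steady value R_i*; the global time is
    max(tau_1, tau_2).  A trajectory that has not settled by ``t_max`` is
    returned with ``converged=False`` (typically an initial condition on the
    separatrix, where the system can linger near the saddle indefinitely).
    """
    R0 = np.asarray(R0, dtype=float)
    rhs = lambda t, y: mr_rhs(np.clip(y, 0.0, None), p, (c1, c2))
    t_eval = np.linspace(0.0, t_max, 4000)
    traj = integrate(rhs, R0, t_max, t_eval=t_eval)
    fps = mr_fixed_points(p, c1, c2)
    stable = [f for f in fps if f.is_stable]
    if not stable:
        raise RuntimeError("no stable fixed point")
    end = traj.y[-1]
    target = min(stable, key=lambda f: np.linalg.norm(f.state - end))
    Rss = target.state
    if np.linalg.norm(end - Rss) > threshold * max(np.linalg.norm(Rss), 1e-12):
        return RelaxationResult(math.nan, "threshold_95", Rss, converged=False,
                                diagnostics={"note": "not converged by t_max (near separatrix?)"})
    taus = []
    for k in range(2):
        scale = max(abs(Rss[k]), 1e-12)
        outside = np.abs(traj.y[:, k] - Rss[k]) > threshold * scale
        taus.append(float(traj.t[np.flatnonzero(outside)[-1] + 1]) if outside.any() else 0.0)
    return RelaxationResult(max(taus), "threshold_95", Rss,
                            diagnostics={"tau1": taus[0], "tau2": taus[1]})


class NoSeparatrixError(RuntimeError):
    pass


def mr_separatrix(
    p: MutualRepressionParams,
    c1: float,
    c2: float,
    t_back: float = 40.0,
    seed_offset: float = 1e-7,
    box_margin: float = 2.0,
) -> np.ndarray:
    """Separatrix of a bistable toggle as an ordered (N, 2) polyline.

    The separatrix is the stable manifold of the saddle; it is traced by
    integrating the time-reversed flow from two seeds displaced off the
    saddle along its stable eigenvector.  Raises ``NoSeparatrixError`` for a
    monostable system.
    """
    fps = mr_fixed_points(p, c1, c2)
    saddles = [f for f in fps if f.stability == "saddle"]
    if not saddles:
        raise NoSeparatrixError("system has no saddle: not bistable at (c1, c2)")
    saddle = saddles[0]
    a1 = p_active(p.tf1, c1)
    a2 = p_active(p.tf2, c2)
    from .steady_state import mr_jacobian

    J = mr_jacobian(p, saddle.state[0], saddle.state[1], a1, a2)
    eigvals, eigvecs = np.linalg.eig(J)
    k = int(np.argmin(eigvals.real))  # stable direction (most negative eigenvalue)
    v = np.real(eigvecs[:, k])
    v /= np.linalg.norm(v)

    L = box_margin * p.rbar
    rhs_back = lambda t, y: -mr_rhs(np.clip(y, 0.0, None), p, (c1, c2))

    def _leave_box(t, y):
        return float(min(min(y), L - max(y)) + 1e-12)
    _leave_box.terminal = True
    _leave_box.direction = -1

    branches = []
    for sgn in (+1.0, -1.0):
        y0 = saddle.state + sgn * seed_offset * v
        sol = solve_ivp(rhs_back, (0.0, t_back), y0, method="LSODA",
                        rtol=1e-10, atol=1e-13, events=[_leave_box], max_step=0.1)
        branches.append(sol.y.T)
    poly = np.vstack([branches[0][::-1], saddle.state[None, :], branches[1]])
    return np.clip(poly, 0.0, None)


def _rk4_step(f, y, dt):
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def mr_basins(
    p: MutualRepressionParams,
    c1: float,
    c2: float,
    R1_grid,
    R2_grid,
    t_max: float = 200.0,
    dt: float = 0.05,
) -> np.ndarray:
    """Attractor-label matrix over a grid of initial conditions.

    ``labels[i, j]`` is the index (into the sorted stable-fixed-point list,
    ordered by R1) of the attractor reached from ``(R1_grid[i],
    R2_grid[j])``; -1 marks non-converged cells (on/near the separatrix).
    All grid points are integrated simultaneously with fixed-step RK4.
    """
    fps = mr_fixed_points(p, c1, c2)
    stable = sorted([f for f in fps if f.is_stable], key=lambda f: f.state[0])
    if len(stable) < 2:
        raise NoSeparatrixError("basin analysis requires a bistable system")
    attractors = np.array([f.state for f in stable])

    a1 = p_active(p.tf1, c1)
    a2 = p_active(p.tf2, c2)

    def f(Y):  # Y shape (n, 2), vectorised toggle RHS
        R1, R2 = Y[:, 0], Y[:, 1]
        x2 = a2 * R2
        P1 = p.rbar / (1.0 + 2.0 * x2 + p.omega2 * x2**2)
        x1 = a1 * R1 / p.Kratio
        P2 = p.rbar / (1.0 + 2.0 * x1 + p.omega1 * x1**2)
        return np.stack([-R1 + P1, -R2 + P2], axis=1)

    G1, G2 = np.meshgrid(np.asarray(R1_grid, float), np.asarray(R2_grid, float),
                         indexing="ij")
    Y = np.stack([G1.ravel(), G2.ravel()], axis=1)
    n_steps = int(t_max / dt)
    tol = 1e-3 * max(p.rbar, 1.0)
    for step in range(n_steps):
        Y = np.clip(_rk4_step(f, Y, dt), 0.0, None)
        if step % 200 == 199:
            d = np.linalg.norm(Y[:, None, :] - attractors[None, :, :], axis=2)
            if np.all(d.min(axis=1) < tol):
                break
    d = np.linalg.norm(Y[:, None, :] - attractors[None, :, :], axis=2)
    labels = np.where(d.min(axis=1) < 10 * tol, d.argmin(axis=1), -1)
    return labels.reshape(G1.shape)
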