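"""Fixed points, bifurcation diagrams and bistability analysis.

The auto-activation steady states are the non-negative real roots of a cubic
obtained by clearing the partition-sum denominator of the production term;
roots come from the companion matrix (numpy.roots) and are polished by Newton
iteration on the rational right-hand side.  The toggle-switch steady states
come from substituting one nullcline into the other, reducing the 2-D problem
to one scalar equation bracketed on a dense grid.  Stability is read off the
analytic derivative (1-D) or the 2x2 Jacobian eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .allostery import activity_limits, p_active
from .circuits import (
    AutoActivationParams,
    HillAutoParams,
    MutualRepressionParams,
    auto_production,
    auto_rhs,
    hill_auto_rhs,
    mr_production,
    mr_rhs,
)

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "BistabilityMap2D",
    "auto_fixed_points",
    "auto_f_prime",
    "auto_bifurcation",
    "necessary_conditions_auto",
    "AutoBistabilityConditions",
    "hysteresis",
    "HysteresisTrace",
    "compare_hill_thermo",
    "HillThermoComparison",
    "hill_fixed_points",
    "effective_hill_coefficient",
    "mr_fixed_points",
    "mr_jacobian",
    "mr_bistability_map",
    "mr_geometry_class",
    "mr_feasibility_boundary",
    "mr_diagonal_bistable_range",
    "mr_necessary_condition",
]

RESIDUAL_TOL = 1e-9
MARGINAL_TOL = 1e-8
DEDUP_RTOL = 1e-6


@dataclass(frozen=True)
class FixedPoint:
    """A steady state with its stability classification.

    ``state`` is the dimensionless concentration vector, ``stability`` one of
    ``{"stable", "unstable", "saddle", "marginal"}``, and ``linearization``
    the scalar derivative f'(A*) in 1-D or the Jacobian eigenvalues in 2-D.
    """

    state: np.ndarray
    stability: str
    linearization: np.ndarray

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BifurcationDiagram:
    """Fixed points of a 1-D motif swept over an effector-concentration grid."""

    c_grid: np.ndarray
    branches: list  # list (per c) of list[FixedPoint]
    bistable_intervals: list  # list of (c_lo, c_hi) molar

    def n_stable(self) -> np.ndarray:
        return np.array([sum(fp.is_stable for fp in fps) for fps in self.branches])


@dataclass
class BistabilityMap2D:
    """Boolean bistability map of the toggle switch over a (c1, c2) grid.

    ``bistable[i, j]`` refers to ``(c1_grid[i], c2_grid[j])``.
    """

    c1_grid: np.ndarray
    c2_grid: np.ndarray
    bistable: np.ndarray
    geometry_class: str = field(default="", compare=False)


# ---------------------------------------------------------------------------
# auto-activation fixed points
# ---------------------------------------------------------------------------

def auto_f_prime(A, p: AutoActivationParams, a: float):
    """Analytic derivative f'(A) of the auto-activation right-hand side,
    with a = p_act(c)."""
    A = np.asarray(A, dtype=float)
    x = a * A
    num = p.r0 + 2.0 * p.r1 * x + p.r2 * p.omega * x**2
    den = 1.0 + 2.0 * x + p.omega * x**2
    dnum = 2.0 * p.r1 * a + 2.0 * p.r2 * p.omega * a * x
    dden = 2.0 * a + 2.0 * p.omega * a * x
    out = -1.0 + (dnum * den - num * dden) / den**2
    return float(out) if out.ndim == 0 else out


def _classify_1d(fprime: float) -> str:
    if abs(fprime) < MARGINAL_TOL:
        return "marginal"
    return "stable" if fprime < 0 else "unstable"


def auto_fixed_points(p: AutoActivationParams, c: float) -> list[FixedPoint]:
    """All non-negative steady states of the auto-activation switch at
    effector concentration ``c``, sorted by concentration.

    Clearing the denominator of ``dA/dt = 0`` gives the cubic
    ``w a^2 A^3 + (2a - r2 w a^2) A^2 + (1 - 2 r1 a) A - r0 = 0``; real
    non-negative roots are polished by Newton iteration on the rational form,
    deduplicated at relative tolerance 1e-6, and classified by the sign of
    f'(A*).  Generic counts are 1 or 3 (2 at a saddle-node).
    """
    a = p_active(p.tf, c)
    coeffs = np.array([
        p.omega * a**2,
        2.0 * a - p.r2 * p.omega * a**2,
        1.0 - 2.0 * p.r1 * a,
        -p.r0,
    ])
    nz = np.flatnonzero(np.abs(coeffs) > 0)
    if len(nz) == 0:
        return []
    coeffs = coeffs[nz[0]:]
    if len(coeffs) == 1:
        roots = np.array([])
    else:
        roots = np.roots(coeffs)
    scale = max(1.0, p.r2)
    real = roots[np.abs(roots.imag) < 1e-7 * scale].real
    real = real[real > -1e-10 * scale]
    candidates = list(np.clip(real, 0.0, None))
    if p.r0 == 0.0 and not any(abs(r) < 1e-12 for r in candidates):
        candidates.append(0.0)

    polished = []
    for A0 in candidates:
        A = A0
        for _ in range(50):
            fa = -A + auto_production(A, p, a)
            fpa = auto_f_prime(A, p, a)
            if abs(fpa) < 1e-14:
                break
            step = fa / fpa
            A_new = A - step
            if A_new < 0:
                A_new = 0.0
            if abs(A_new - A) <= 1e-15 * max(1.0, abs(A)):
                A = A_new
                break
            A = A_new
        if A < 0 or not math.isfinite(A):
            continue
        if abs(-A + auto_production(A, p, a)) > RESIDUAL_TOL * max(1.0, A):
            continue
        polished.append(A)

    polished.sort()
    unique: list[float] = []
    for A in polished:
        if unique and abs(A - unique[-1]) <= DEDUP_RTOL * max(1.0, abs(unique[-1])):
            continue
        unique.append(A)

    out = []
    for A in unique:
        fp = auto_f_prime(A, p, a)
        out.append(FixedPoint(np.array([A]), _classify_1d(fp), np.array([fp])))
    return out


# ---------------------------------------------------------------------------
# bifurcation sweep and bistable interval
# ---------------------------------------------------------------------------

def _n_stable_auto(p: AutoActivationParams, c: float) -> int:
    return sum(fp.is_stable for fp in auto_fixed_points(p, c))


def _refine_boundary(is_bistable, c_in: float, c_out: float, rtol: float = 1e-4) -> float:
    """Bisect (in log c) between a bistable and a monostable concentration."""
    lo, hi = math.log(c_in), math.log(c_out)
    while abs(hi - lo) > rtol:
        mid = 0.5 * (lo + hi)
        if is_bistable(math.exp(mid)):
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def _bistable_intervals(c_grid, flags, is_bistable, refine: bool):
    intervals = []
    n = len(c_grid)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            lo = c_grid[i]
            hi = c_grid[j]
            if refine:
                if i > 0:
                    lo = _refine_boundary(is_bistable, c_grid[i], c_grid[i - 1])
                if j + 1 < n:
                    hi = _refine_boundary(is_bistable, c_grid[j], c_grid[j + 1])
            intervals.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return intervals


def auto_bifurcation(
    p: AutoActivationParams,
    c_grid,
    refine: bool = True,
) -> BifurcationDiagram:
    """Sweep the auto-activation fixed points over an effector grid and
    locate bistable interval(s), with saddle-node endpoints refined by
    bisection on log c to relative precision 1e-4."""
    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid.size == 0:
        raise ValueError("empty effector grid")
    if np.any(c_grid <= 0) or np.any(np.diff(c_grid) <= 0):
        raise ValueError("c_grid must be positive and strictly increasing")
    branches = [auto_fixed_points(p, c) for c in c_grid]
    flags = np.array([sum(fp.is_stable for fp in fps) >= 2 for fps in branches])
    intervals = _bistable_intervals(
        c_grid, flags, lambda c: _n_stable_auto(p, c) >= 2, refine
    )
    return BifurcationDiagram(c_grid, branches, intervals)


# ---------------------------------------------------------------------------
# necessary conditions (Descartes' rule on the steady-state cubic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutoBistabilityConditions:
    """The three inequalities that must all hold for the auto-activation
    switch to be bistable at *some* effector concentration.

    Three positive cubic roots require the sign pattern (+, -, +, -) of the
    steady-state polynomial's coefficients for some active fraction
    a in (pact_min, pact_max):

    * ``cooperative_drive``: omega * r2 / 2 > 1 + e^{-eps}; the doubly-bound
      production must beat degradation at full activity.  Implies the
      effective cooperativity omega_eff = omega*r2/2 > 1.
    * ``single_bound_rate``: 2 r1 < 1 + e^{-eps} (K_A/K_I)^n; the
      singly-bound production must not already saturate the switch at the
      leakiness floor.
    * ``rate_balance``: omega * r2 > 4 r1, so both windows in the active
      fraction overlap.

    None of the conditions involves the basal rate r0.
    """

    cooperative_drive: bool
    single_bound_rate: bool
    rate_balance: bool
    omega_eff: float

    @property
    def all_satisfied(self) -> bool:
        return self.cooperative_drive and self.single_bound_rate and self.rate_balance


def necessary_conditions_auto(p: AutoActivationParams) -> AutoBistabilityConditions:
    """Evaluate the three analytic necessary conditions for bistability of
    the auto-activation switch (see ``AutoBistabilityConditions``)."""
    e = math.exp(-p.tf.eps)
    kc_pow = (p.tf.K_A / p.tf.K_I) ** p.tf.n_sites
    return AutoBistabilityConditions(
        cooperative_drive=p.omega * p.r2 / 2.0 > 1.0 + e,
        single_bound_rate=2.0 * p.r1 < 1.0 + e * kc_pow,
        rate_balance=p.omega * p.r2 > 4.0 * p.r1,
        omega_eff=p.omega * p.r2 / 2.0,
    )


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

@dataclass
class HysteresisTrace:
    """Stable-branch trace along a monotone effector protocol."""

    c_path: np.ndarray
    A_trace: np.ndarray
    switch_thresholds: list  # concentrations at which the occupied branch jumps


def _attractor_of(p: AutoActivationParams, c: float, A0: float) -> float:
    """Stable fixed point reached from A0 by following the 1-D flow."""
    fps = auto_fixed_points(p, c)
    stable = [float(fp.state[0]) for fp in fps if fp.is_stable]
    if not stable:
        raise RuntimeError("no stable fixed point found")
    f0 = auto_rhs(A0, p, c)
    if f0 > 0:
        above = [A for A in stable if A >= A0 - 1e-12]
        return min(above) if above else max(stable)
    below = [A for A in stable if A <= A0 + 1e-12]
    return max(below) if below else min(stable)


def hysteresis(
    p: AutoActivationParams,
    c_path,
    A_init: float,
    jump_rtol: float = 0.25,
) -> HysteresisTrace:
    """Follow the occupied stable branch along a monotone effector sweep.

    The trace starts on the attractor of ``A_init`` at ``c_path[0]`` and at
    each subsequent concentration occupies the nearest stable fixed point; a
    relative jump larger than ``jump_rtol`` marks a saddle-node switching
    event and its concentration is recorded.  Upward and downward sweeps
    through a bistable window therefore switch at its opposite endpoints.
    """
    c_path = np.asarray(c_path, dtype=float)
    if A_init < 0:
        raise ValueError("A_init must be >= 0")
    d = np.diff(c_path)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("c_path must be strictly monotone")
    A = _attractor_of(p, c_path[0], A_init)
    trace = [A]
    thresholds = []
    c_prev = c_path[0]
    for c in c_path[1:]:
        stable = [float(fp.state[0]) for fp in auto_fixed_points(p, c) if fp.is_stable]
        A_new = min(stable, key=lambda s: abs(s - A))
        if abs(A_new - A) > jump_rtol * max(abs(A), 1e-12):
            # branch disappeared between c_prev and c: bisect (in log c) for
            # the saddle-node concentration where it is lost, following the
            # branch by continuity (the reference point tracks the branch,
            # which moves steeply near the saddle-node)
            lo, hi = math.log(c_prev), math.log(c)
            A_ref = A
            while abs(hi - lo) > 1e-5:
                mid = 0.5 * (lo + hi)
                stable_mid = [float(fp.state[0])
                              for fp in auto_fixed_points(p, math.exp(mid))
                              if fp.is_stable]
                nearest = min(stable_mid, key=lambda s: abs(s - A_ref))
                if abs(nearest - A_ref) <= jump_rtol * max(abs(A_ref), 1e-12):
                    lo = mid
                    A_ref = nearest
                else:
                    hi = mid
            thresholds.append(math.exp(0.5 * (lo + hi)))
        A = A_new
        trace.append(A)
        c_prev = c
    return HysteresisTrace(c_path, np.array(trace), thresholds)


# ---------------------------------------------------------------------------
# Hill vs thermodynamic comparison
# ---------------------------------------------------------------------------

def hill_fixed_points(p: HillAutoParams, c: float) -> list[FixedPoint]:
    """Steady states of the dimensional Hill-variant switch at effector
    concentration c, by dense-grid bracketing plus brentq (valid for any
    Hill coefficient, integer or not)."""
    a = p_active(p.tf, c)

    def f(A):
        return hill_auto_rhs(A, p, c)

    A_max = 1.05 * (p.r0 + p.r2) / p.gamma
    grid = np.concatenate([[0.0], np.geomspace(A_max * 1e-9, A_max, 2000)])
    vals = np.array([f(A) for A in grid])
    roots = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(grid[i])
        elif v0 * v1 < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-14))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    out = []
    h = 1e-7 * max(A_max, 1.0)
    prev = None
    for A in roots:
        if prev is not None and abs(A - prev) <= DEDUP_RTOL * max(abs(prev), 1e-30):
            continue
        prev = A
        fp = (f(A + h) - f(max(A - h, 0.0))) / (h + min(A, h))
        fp_scaled = fp / p.gamma  # dimensionless slope for classification
        out.append(FixedPoint(np.array([A]), _classify_1d(fp_scaled), np.array([fp])))
    return out


@dataclass
class HillThermoComparison:
    """Per-concentration bistability verdicts of the thermodynamic and the
    matched Hill model on a shared dimensional axis."""

    c_grid: np.ndarray
    thermo_bistable: np.ndarray
    hill_bistable: np.ndarray

    @property
    def disagreement(self) -> np.ndarray:
        return np.flatnonzero(self.thermo_bistable != self.hill_bistable)

    @property
    def agrees(self) -> bool:
        return len(self.disagreement) == 0


def compare_hill_thermo(
    p_thermo: AutoActivationParams,
    p_hill: HillAutoParams,
    c_grid,
    gamma: float,
    Kd: float,
) -> HillThermoComparison:
    """Compare bistability predictions of the thermodynamic switch (made
    dimensional with ``gamma``, ``Kd``) and a Hill-function switch on the
    same effector grid.

    Both parameter sets must share the degradation rate, basal and saturated
    rates, bare Kd and allosteric parameters; the matched high-cooperativity
    construction uses ``Kd_eff = Kd/sqrt(omega)`` so that the doubly-bound
    weight ``omega (a A/Kd)^2`` equals ``(a A/Kd_eff)^2``.
    """
    if p_hill.gamma != gamma:
        raise ValueError("Hill and thermodynamic models must share gamma")
    if p_hill.tf != p_thermo.tf:
        raise ValueError("Hill and thermodynamic models must share the allosteric TF")
    if not math.isclose(p_hill.r0, p_thermo.r0 * gamma * Kd, rel_tol=1e-9):
        raise ValueError("Hill r0 must equal the thermodynamic basal rate (dimensional)")
    if not math.isclose(p_hill.r2, p_thermo.r2 * gamma * Kd, rel_tol=1e-9):
        raise ValueError("Hill r2 must equal the thermodynamic saturated rate (dimensional)")

    c_grid = np.asarray(c_grid, dtype=float)
    thermo = np.array(
        [sum(fp.is_stable for fp in auto_fixed_points(p_thermo, c)) >= 2 for c in c_grid]
    )
    hill = np.array(
        [sum(fp.is_stable for fp in hill_fixed_points(p_hill, c)) >= 2 for c in c_grid]
    )
    return HillThermoComparison(c_grid, thermo, hill)


def matched_hill_params(
    p_thermo: AutoActivationParams, gamma: float, Kd: float, n: float = 2.0
) -> HillAutoParams:
    """Hill parameter set matched to a thermodynamic switch in the large-
    cooperativity limit: shared dimensional r0/r2 and ``Kd_eff = Kd/sqrt(omega)``."""
    if p_thermo.omega <= 0:
        raise ValueError("matched Hill construction requires omega > 0")
    return HillAutoParams(
        n=n,
        r0=p_thermo.r0 * gamma * Kd,
        r2=p_thermo.r2 * gamma * Kd,
        Kd_eff=Kd / math.sqrt(p_thermo.omega),
        gamma=gamma,
        tf=p_thermo.tf,
    )


def effective_hill_coefficient(
    p: AutoActivationParams, c: float, A_grid=None
) -> float:
    """Maximum logarithmic sensitivity of the open-loop production function.

    Defined here as ``max_A d log[(P(A) - P(0)) / (P(inf) - P(0))] /
    d log A`` at fixed effector concentration, computed by central
    differences on a log-spaced grid.  Bounded by the number of binding
    sites (2); bistability empirically requires a value above 1.
    """
    a = p_active(p.tf, c)
    if p.r2 == p.r0:
        return 0.0
    if A_grid is None:
        A_grid = np.geomspace(1e-6, 1e6, 2400)
    P = auto_production(A_grid, p, a)
    Pn = (P - p.r0) / (p.r2 - p.r0)
    with np.errstate(divide="ignore"):
        logPn = np.log(np.clip(Pn, 1e-300, None))
        logA = np.log(A_grid)
    slope = np.gradient(logPn, logA)
    return float(np.max(slope))


# ---------------------------------------------------------------------------
# mutual repression fixed points
# ---------------------------------------------------------------------------

def _mr_nullclines(p: MutualRepressionParams, a1: float, a2: float):
    def h1(R2):
        # R1 on its nullcline as a function of R2
        x = a2 * np.asarray(R2, dtype=float)
        return p.rbar / (1.0 + 2.0 * x + p.omega2 * x**2)

    def h2(R1):
        x = a1 * np.asarray(R1, dtype=float) / p.Kratio
        return p.rbar / (1.0 + 2.0 * x + p.omega1 * x**2)

    return h1, h2


def mr_jacobian(p: MutualRepressionParams, R1: float, R2: float, a1: float, a2: float):
    """Analytic 2x2 Jacobian of the toggle-switch right-hand side."""
    x2 = a2 * R2
    d2 = 1.0 + 2.0 * x2 + p.omega2 * x2**2
    dP1_dR2 = -p.rbar * (2.0 * a2 + 2.0 * p.omega2 * a2 * x2) / d2**2
    x1 = a1 * R1 / p.Kratio
    d1 = 1.0 + 2.0 * x1 + p.omega1 * x1**2
    k = a1 / p.Kratio
    dP2_dR1 = -p.rbar * (2.0 * k + 2.0 * p.omega1 * k * x1) / d1**2
    return np.array([[-1.0, dP1_dR2], [dP2_dR1, -1.0]])


def _classify_2d(eigs: np.ndarray) -> str:
    re = np.sort(eigs.real)
    if np.any(np.abs(re) < MARGINAL_TOL):
        return "marginal"
    if re[1] < 0:
        return "stable"
    if re[0] > 0:
        return "unstable"
    return "saddle"


def mr_fixed_points(
    p: MutualRepressionParams, c1: float, c2: float, n_grid: int = 1200
) -> list[FixedPoint]:
    """Steady states of the toggle switch at effector concentrations
    (c1, c2).

    On the R1 nullcline ``R1 = h1(R2)``; substituting into the R2 nullcline
    leaves ``g(R2) = R2 - h2(h1(R2)) = 0``, bracketed on a dense grid over
    [0, rbar] and solved by brentq.  Each root is classified by the Jacobian
    eigenvalues (stable / saddle / unstable).
    """
    a1 = p_active(p.tf1, c1)
    a2 = p_active(p.tf2, c2)
    h1, h2 = _mr_nullclines(p, a1, a2)

    def g(R2):
        return R2 - h2(h1(R2))

    hi = p.rbar * (1.0 + 1e-9)
    grid = np.concatenate([
        [0.0],
        np.geomspace(hi * 1e-9, hi, n_grid // 2),
        np.linspace(hi / n_grid, hi, n_grid // 2),
    ])
    grid = np.unique(grid)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-15))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    out = []
    prev = None
    for R2 in sorted(roots):
        if prev is not None and abs(R2 - prev) <= DEDUP_RTOL * max(abs(prev), 1e-30):
            continue
        prev = R2
        R1 = float(h1(R2))
        resid = mr_rhs((R1, R2), p, (c1, c2))
        if np.max(np.abs(resid)) > RESIDUAL_TOL * max(1.0, p.rbar):
            continue
        eigs = np.linalg.eigvals(mr_jacobian(p, R1, R2, a1, a2))
        out.append(FixedPoint(np.array([R1, R2]), _classify_2d(eigs), eigs))
    return out


def _mr_root_count_grid(
    p: MutualRepressionParams, c1_grid, c2_grid, n_r2: int = 600
) -> np.ndarray:
    """Vectorised count of nullcline intersections for every (c1, c2) cell.

    Counts sign changes of g(R2) on a dense shared R2 grid; >= 3 crossings
    means the generic bistable configuration (two stable nodes + saddle).
    """
    a1 = np.asarray(p_active(p.tf1, np.asarray(c1_grid, dtype=float)))
    a2 = np.asarray(p_active(p.tf2, np.asarray(c2_grid, dtype=float)))
    hi = p.rbar * (1.0 + 1e-9)
    R2 = np.unique(np.concatenate([
        [0.0], np.geomspace(hi * 1e-9, hi, n_r2 // 2), np.linspace(hi / n_r2, hi, n_r2 // 2)
    ]))
    counts = np.zeros((a1.size, a2.size), dtype=int)
    # chunk over c1 rows to bound memory
    for i, a1i in enumerate(a1):
        x2 = a2[:, None] * R2[None, :]                      # (nc2, nR2)
        R1 = p.rbar / (1.0 + 2.0 * x2 + p.omega2 * x2**2)
        x1 = a1i * R1 / p.Kratio
        h2v = p.rbar / (1.0 + 2.0 * x1 + p.omega1 * x1**2)
        gv = R2[None, :] - h2v
        counts[i, :] = np.sum(np.diff(np.sign(gv), axis=1) != 0, axis=1)
    return counts


def mr_bistability_map(
    p: MutualRepressionParams, c1_grid, c2_grid, n_r2: int = 600
) -> BistabilityMap2D:
    """Boolean bistability map of the toggle over a 2-D effector grid.

    For symmetric parameters (Kratio = 1, omega1 = omega2, tf1 = tf2 and
    transposed grids) the map is symmetric under (c1, c2) exchange.
    """
    c1_grid = np.asarray(c1_grid, dtype=float)
    c2_grid = np.asarray(c2_grid, dtype=float)
    if np.any(c1_grid <= 0) or np.any(c2_grid <= 0):
        raise ValueError("effector grids must be positive")
    counts = _mr_root_count_grid(p, c1_grid, c2_grid, n_r2=n_r2)
    m = BistabilityMap2D(c1_grid, c2_grid, counts >= 3)
    m.geometry_class = mr_geometry_class(m)
    return m


def mr_geometry_class(m: BistabilityMap2D) -> str:
    """Classify the shape of the bistable region in the (c1, c2) plane.

    ``BOTH_SMALL``: the low-concentration corner of the grid is bistable
    (bistability persists down to arbitrarily weak induction of both
    repressors).  ``C1_WINDOW``: at the weakest c2 supporting bistability,
    the bistable c1 values form a window excluding the grid minimum (c1 must
    be tuned into a finite interval); ``C2_WINDOW`` is the mirror case.
    ``NONE``: no bistable cell.
    """
    B = m.bistable
    if not B.any():
        return "NONE"
    if B[0, 0]:
        return "BOTH_SMALL"
    j0 = int(np.argmax(B.any(axis=0)))       # smallest c2 with any bistability
    if not B[0, j0]:
        return "C1_WINDOW"
    i0 = int(np.argmax(B.any(axis=1)))       # smallest c1 with any bistability
    if not B[i0, 0]:
        return "C2_WINDOW"
    return "BOTH_SMALL"


def mr_necessary_condition(p: MutualRepressionParams) -> tuple[bool, float]:
    """Analytic necessary condition for toggle bistability at any effector
    pair: ``rbar > 1 / (pact_max - pact_min + min(omega1, omega2) *
    pact_max / 2)``.

    Returns ``(satisfied, threshold)``.  Uses the shared allosteric limits
    of tf1 (the condition is derived for identical effector chemistries and
    equal DNA-binding affinities, Kratio = 1; for strongly asymmetric
    binding the bound does not apply).
    """
    pmin, pmax = activity_limits(p.tf1)
    threshold = 1.0 / (pmax - pmin + min(p.omega1, p.omega2) * pmax / 2.0)
    return p.rbar > threshold, threshold


def mr_feasibility_boundary(
    rbar: float,
    omega1_grid,
    omega2_grid,
    tf1=None,
    tf2=None,
    c1_grid=None,
    c2_grid=None,
    n_r2: int = 400,
):
    """Classify the (omega1, omega2) plane by whether the toggle (Kratio=1)
    is bistable for *any* effector pair in the scanned concentration window.

    Returns ``(feasible, boundary)`` where ``feasible[i, j]`` refers to
    ``(omega1_grid[i], omega2_grid[j])`` and ``boundary[i]`` is the smallest
    feasible omega2 for each omega1 (NaN if none).
    """
    from .allostery import DEFAULT_TF

    tf1 = tf1 or DEFAULT_TF
    tf2 = tf2 or DEFAULT_TF
    if c1_grid is None:
        c1_grid = np.geomspace(1e-7, 1e-4, 16)
    if c2_grid is None:
        c2_grid = np.geomspace(1e-7, 1e-4, 16)
    omega1_grid = np.asarray(omega1_grid, dtype=float)
    omega2_grid = np.asarray(omega2_grid, dtype=float)
    feasible = np.zeros((omega1_grid.size, omega2_grid.size), dtype=bool)
    for i, w1 in enumerate(omega1_grid):
        for j, w2 in enumerate(omega2_grid):
            p = MutualRepressionParams(rbar=rbar, omega1=w1, omega2=w2,
                                       Kratio=1.0, tf1=tf1, tf2=tf2)
            counts = _mr_root_count_grid(p, c1_grid, c2_grid, n_r2=n_r2)
            feasible[i, j] = bool((counts >= 3).any())
    boundary = np.full(omega1_grid.size, np.nan)
    for i in range(omega1_grid.size):
        idx = np.flatnonzero(feasible[i])
        if idx.size:
            boundary[i] = omega2_grid[idx[0]]
    return feasible, boundary


def mr_diagonal_bistable_range(
    p: MutualRepressionParams, c_grid, rtol: float = 1e-4
) -> tuple[float, float] | None:
    """Bistable window along the diagonal c1 = c2, endpoints refined by
    bisection in log c; None if the diagonal is never bistable.

    The upper endpoint is the pitchfork concentration at which the two
    symmetric stable states merge (for a symmetric toggle)."""
    c_grid = np.asarray(c_grid, dtype=float)

    def is_bi(c):
        return sum(fp.is_stable for fp in mr_fixed_points(p, c, c)) >= 2

    flags = np.array([is_bi(c) for c in c_grid])
    if not flags.any():
        return None
    i = int(np.argmax(flags))
    j = len(flags) - 1 - int(np.argmax(flags[::-1]))
    lo = c_grid[i]
    hi = c_grid[j]
    if i > 0:
        lo = _refine_boundary(is_bi, c_grid[i], c_grid[i - 1], rtol)
    if j + 1 < len(flags):
        hi = _refine_boundary(is_bi, c_grid[j], c_grid[j + 1], rtol)
    return lo, hi
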