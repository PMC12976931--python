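"""Dimensionless right-hand sides for the circuit motifs.

Every production term is thermodynamic: a promoter's occupancy states are
enumerated with Boltzmann weights, each state carries a production rate, and
the production is (sum of rate-weighted states) / (partition sum).  Time is
measured in units of the protein lifetime 1/gamma and concentrations in units
of the relevant dissociation constant, so each equation reads
``d x / dt = -x + production(x, ...)`` with dimensionless rates.

The one dimensional exception is the Hill-function variant of the
auto-activation switch, kept in physical units (molar, minutes) so the two
formulations can be compared on a common concentration axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .allostery import DEFAULT_TF, AllostericTF, p_active

__all__ = [
    "AutoActivationParams",
    "HillAutoParams",
    "MutualRepressionParams",
    "CoherentFFLParams",
    "IncoherentFFLParams",
    "auto_production",
    "auto_rhs",
    "hill_auto_rhs",
    "mr_rhs",
    "cffl_rhs",
    "iffl_rhs",
    "gate_preset",
    "z_production",
    "z_production_coefficients",
]


def _check_nonneg(name: str, value: float) -> None:
    if not (np.all(np.isfinite(value)) and np.all(np.asarray(value) >= 0)):
        raise ValueError(f"{name} must be finite and >= 0, got {value}")


def _check_pos(name: str, value: float) -> None:
    if not (np.all(np.isfinite(value)) and np.all(np.asarray(value) > 0)):
        raise ValueError(f"{name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class AutoActivationParams:
    """Auto-activation switch: a gene whose product activates its own promoter
    at two binding sites.

    Rates are dimensionless (units of gamma*Kd): ``r0`` basal, ``r1`` with one
    activator bound, ``r2`` with two.  ``omega = e^{-eps_int}`` is the
    cooperativity between the two bound activators.  The ordering
    ``r0 <= r1 <= r2`` makes the production term non-decreasing in activator
    concentration (a genuine activator); violations are rejected unless
    ``enforce_ordering=False``.
    """

    r0: float
    r1: float
    r2: float
    omega: float
    tf: AllostericTF = DEFAULT_TF
    enforce_ordering: bool = True

    def __post_init__(self) -> None:
        for name in ("r0", "r1", "r2", "omega"):
            _check_nonneg(name, getattr(self, name))
        if self.enforce_ordering and not (self.r0 <= self.r1 <= self.r2):
            raise ValueError(
                "auto-activation requires r0 <= r1 <= r2 "
                f"(got {self.r0}, {self.r1}, {self.r2}); "
                "pass enforce_ordering=False to override"
            )


@dataclass(frozen=True)
class HillAutoParams:
    """Hill-function variant of the auto-activation switch (dimensional).

    ``dA/dt = -gamma A + r0 + r2 u^n / (1 + u^n)`` with
    ``u = p_act(c) A / Kd_eff``.  Rates in molar/min, ``Kd_eff`` molar,
    ``gamma`` 1/min.  The single-activator state of the thermodynamic model
    has been approximated away, which is exact only in the high-cooperativity
    limit with ``Kd_eff = Kd / sqrt(omega)`` (for n = 2).
    """

    n: float
    r0: float
    r2: float
    Kd_eff: float
    gamma: float
    tf: AllostericTF = DEFAULT_TF

    def __post_init__(self) -> None:
        if self.n < 1 or not math.isfinite(self.n):
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        _check_nonneg("r0", self.r0)
        _check_pos("r2", self.r2)
        _check_pos("Kd_eff", self.Kd_eff)
        _check_pos("gamma", self.gamma)


@dataclass(frozen=True)
class MutualRepressionParams:
    """Toggle switch: two genes repressing each other at two operator sites.

    Both genes share the dimensionless production rate ``rbar`` (attributed
    to the repressor-free promoter state only).  ``omega1``/``omega2`` are
    the pairwise cooperativities of bound repressor 1 / repressor 2, and
    ``Kratio = K1/K2`` the ratio of their DNA dissociation constants
    (concentrations are non-dimensionalised by K2).  Each repressor i is
    inactivated by its own effector at concentration ``c_i`` through
    ``tf_i``.
    """

    rbar: float
    omega1: float
    omega2: float
    Kratio: float = 1.0
    tf1: AllostericTF = DEFAULT_TF
    tf2: AllostericTF = DEFAULT_TF

    def __post_init__(self) -> None:
        _check_pos("rbar", self.rbar)
        _check_nonneg("omega1", self.omega1)
        _check_nonneg("omega2", self.omega2)
        _check_pos("Kratio", self.Kratio)


@dataclass(frozen=True)
class CoherentFFLParams:
    """Type-I coherent feed-forward loop: X activates Y and Z; Y activates Z.

    The input X is held at fixed dimensionless concentration ``Xbar`` (in
    units of K_XY); its activity is tuned purely through the effector cX.
    Z's promoter binds X and Y with dimensionless dissociation constants
    ``KXZ = K_XZ/K_XY`` and ``KYZ = K_YZ/K_XY`` and cooperativity ``omega``;
    its rates are ``r0Z`` (empty), ``r1Z`` (either single activator) and
    ``r2Z`` (both).  Y's promoter has rates ``r0Y``, ``r1Y``.
    """

    r0Y: float
    r1Y: float
    r0Z: float
    r1Z: float
    r2Z: float
    omega: float
    KXZ: float = 1.0
    KYZ: float = 1.0
    Xbar: float = 1.0
    tfX: AllostericTF = DEFAULT_TF
    tfY: AllostericTF = DEFAULT_TF

    def __post_init__(self) -> None:
        for name in ("r0Y", "r1Y", "r0Z", "r1Z", "r2Z", "omega"):
            _check_nonneg(name, getattr(self, name))
        _check_pos("KXZ", self.KXZ)
        _check_pos("KYZ", self.KYZ)
        _check_pos("Xbar", self.Xbar)

    def with_kds(self, KXZ: float, KYZ: float) -> "CoherentFFLParams":
        return replace(self, KXZ=KXZ, KYZ=KYZ)


@dataclass(frozen=True)
class IncoherentFFLParams:
    """Type-I incoherent feed-forward loop: X activates Y and Z; Y represses Z.

    Same promoter states as the coherent loop, but only the states without
    bound repressor Y produce above basal level: Y appears in the partition
    sum alone, so Z production is non-increasing in Y.
    """

    r0Y: float
    r1Y: float
    r0Z: float
    r1Z: float
    omega: float
    KXZ: float = 1.0
    KYZ: float = 1.0
    Xbar: float = 1.0
    tfX: AllostericTF = DEFAULT_TF
    tfY: AllostericTF = DEFAULT_TF

    def __post_init__(self) -> None:
        for name in ("r0Y", "r1Y", "r0Z", "r1Z", "omega"):
            _check_nonneg(name, getattr(self, name))
        _check_pos("KXZ", self.KXZ)
        _check_pos("KYZ", self.KYZ)
        _check_pos("Xbar", self.Xbar)

    def with_kds(self, KXZ: float, KYZ: float) -> "IncoherentFFLParams":
        return replace(self, KXZ=KXZ, KYZ=KYZ)


# ---------------------------------------------------------------------------
# auto-activation
# ---------------------------------------------------------------------------

def auto_production(A, p: AutoActivationParams, a: float):
    """Thermodynamic production term of the auto-activation promoter at
    active fraction ``a = p_act(c)``; bounded by [r0, r2] when rates are
    ordered."""
    x = a * np.asarray(A, dtype=float)
    num = p.r0 + 2.0 * p.r1 * x + p.r2 * p.omega * x**2
    den = 1.0 + 2.0 * x + p.omega * x**2
    return num / den


def auto_rhs(A, p: AutoActivationParams, c: float):
    """dA/dt for the dimensionless auto-activation switch at effector
    concentration ``c`` (molar)."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or not np.all(np.isfinite(A)):
        raise ValueError("activator concentration must be finite and >= 0")
    a = p_active(p.tf, c)
    out = -A + auto_production(A, p, a)
    return float(out) if out.ndim == 0 else out


def hill_auto_rhs(A, p: HillAutoParams, c: float):
    """dA/dt (molar/min) for the Hill-function auto-activation variant."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or not np.all(np.isfinite(A)):
        raise ValueError("activator concentration must be finite and >= 0")
    u = (p_active(p.tf, c) * A / p.Kd_eff) ** p.n
    out = -p.gamma * A + p.r0 + p.r2 * u / (1.0 + u)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# mutual repression
# ---------------------------------------------------------------------------

def mr_production(R_other, p: MutualRepressionParams, which: int, a_other: float):
    """Production of repressor ``which`` (1 or 2) given the opposing
    repressor's concentration and active fraction.  Only the empty promoter
    state produces, so the term is ``rbar / partition sum``."""
    if which == 1:
        x = a_other * np.asarray(R_other, dtype=float)
        den = 1.0 + 2.0 * x + p.omega2 * x**2
    elif which == 2:
        x = a_other * np.asarray(R_other, dtype=float) / p.Kratio
        den = 1.0 + 2.0 * x + p.omega1 * x**2
    else:
        raise ValueError("which must be 1 or 2")
    return p.rbar / den


def mr_rhs(state, p: MutualRepressionParams, c: tuple[float, float]):
    """(dR1/dt, dR2/dt) for the dimensionless toggle switch.

    ``state = (R1, R2)`` in units of K2; ``c = (c1, c2)`` molar effector
    concentrations inactivating repressor 1 and 2 respectively.
    """
    R1, R2 = state
    if np.any(np.asarray(state) < 0):
        raise ValueError("repressor concentrations must be >= 0")
    c1, c2 = c
    a1 = p_active(p.tf1, c1)
    a2 = p_active(p.tf2, c2)
    dR1 = -R1 + mr_production(R2, p, 1, a2)
    dR2 = -R2 + mr_production(R1, p, 2, a1)
    return np.array([dR1, dR2])


# ---------------------------------------------------------------------------
# feed-forward loops
# ---------------------------------------------------------------------------

def z_production_coefficients(p, Xs):
    """Coefficients (a, b, pden, q) of the Z production term written as
    ``(a + b*Ys) / (pden + q*Ys)`` at regulatory strength ``Xs`` of the input.

    ``Xs = p_actX(cX) * Xbar / KXZ`` and ``Ys = p_actY(cY) * Ybar / KYZ`` are
    the dimensionless occupancy variables of X and Y on the Z promoter.  For
    the coherent loop ``b = r1Z + omega*r2Z*Xs``; for the incoherent loop Y
    only represses, so ``b = 0``.
    """
    a = p.r0Z + p.r1Z * Xs
    if isinstance(p, IncoherentFFLParams):
        b = np.zeros_like(np.asarray(Xs, dtype=float)) + 0.0
    else:
        b = p.r1Z + p.omega * p.r2Z * Xs
    pden = 1.0 + Xs
    q = 1.0 + p.omega * Xs
    return a, b, pden, q


def z_production(p, Xs, Ys):
    """Z production at occupancy variables (Xs, Ys); works for coherent and
    incoherent parameter sets."""
    a, b, pden, q = z_production_coefficients(p, Xs)
    return (a + b * Ys) / (pden + q * Ys)


def y_steady_state(p, cX: float) -> float:
    """Steady-state Y (units of K_XY) at input effector concentration cX;
    Y's equation is linear so this is exact."""
    px = p_active(p.tfX, cX)
    return p.r0Y + p.r1Y * px * p.Xbar / (1.0 + px * p.Xbar)


def _ffl_rhs(state, p, c):
    Y, Z = state
    if np.any(np.asarray(state) < 0):
        raise ValueError("state concentrations must be >= 0")
    cX, cY = c
    px = p_active(p.tfX, cX)
    Xs = px * p.Xbar / p.KXZ
    Ys = p_active(p.tfY, cY) * Y / p.KYZ
    dY = -Y + p.r0Y + p.r1Y * px * p.Xbar / (1.0 + px * p.Xbar)
    dZ = -Z + z_production(p, Xs, Ys)
    return np.array([dY, dZ])


def cffl_rhs(state, p: CoherentFFLParams, c: tuple[float, float]):
    """(dY/dt, dZ/dt) for the coherent feed-forward loop at effector
    concentrations ``c = (cX, cY)``."""
    return _ffl_rhs(state, p, c)


def iffl_rhs(state, p: IncoherentFFLParams, c: tuple[float, float]):
    """(dY/dt, dZ/dt) for the incoherent feed-forward loop."""
    return _ffl_rhs(state, p, c)


# ---------------------------------------------------------------------------
# logic-gate presets
# ---------------------------------------------------------------------------

_GATES = {
    # XOR: X and Y cannot bind simultaneously (omega = 0); single-bound
    # states activate.
    "XOR": dict(r0Y=0.0, r1Y=2.0, r0Z=0.0, r1Z=2.0, r2Z=0.0, omega=0.0),
    # AND: only the doubly-bound state activates.
    "AND": dict(r0Y=0.0, r1Y=2.0, r0Z=0.0, r1Z=0.0, r2Z=2.0, omega=10.0),
    # OR: any bound state activates.
    "OR": dict(r0Y=0.0, r1Y=2.0, r0Z=0.0, r1Z=2.0, r2Z=10.0, omega=1.0),
}


def gate_preset(gate: str, **overrides) -> CoherentFFLParams:
    """Coherent-FFL parameter set implementing an AND, OR, or XOR logic gate
    on the Z promoter.

    AND: ``omega > 0`` and ``r2Z > r1Z = r0Z`` (expression needs both X and
    Y bound).  XOR: ``omega = 0`` (mutually exclusive binding) with
    ``r1Z > r0Z``.  OR: ``r2Z >= r1Z > r0Z``.  ``overrides`` may adjust
    KXZ/KYZ/Xbar/tfX/tfY.
    """
    key = gate.upper()
    if key not in _GATES:
        raise ValueError(f"unknown gate {gate!r}; choose from {sorted(_GATES)}")
    params = CoherentFFLParams(**_GATES[key], **overrides)
    if key == "AND" and not (params.omega > 0 and params.r2Z > params.r1Z == params.r0Z):
        raise ValueError("AND gate requires omega > 0 and r2Z > r1Z == r0Z")
    if key == "XOR" and not (params.omega == 0 and params.r1Z > params.r0Z):
        raise ValueError("XOR gate requires omega == 0 and r1Z > r0Z")
    if key == "OR" and not (params.r2Z >= params.r1Z > params.r0Z):
        raise ValueError("OR gate requires r2Z >= r1Z > r0Z")
    return params
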