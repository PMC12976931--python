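"""Randomised parameter scans for bistability surveys.

Used to stress the analytic necessary conditions: no parameter set that an
exhaustive effector scan finds bistable may violate them.  Draws are
log-uniform over broad, biologically plausible ranges (cooperativities from
strongly destabilising to strongly stabilising interaction energies, rates
spanning several decades), with the auto-activation rate ordering
r0 <= r1 <= r2 imposed by sorting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allostery import DEFAULT_TF, AllostericTF, p_active
from .circuits import (
    AutoActivationParams,
    CoherentFFLParams,
    IncoherentFFLParams,
    MutualRepressionParams,
)
from .steady_state import _mr_root_count_grid

__all__ = [
    "draw_auto_params",
    "auto_bistable_anywhere",
    "auto_scan",
    "AutoScanResult",
    "draw_mr_params",
    "mr_bistable_anywhere",
    "mr_scan",
    "MRScanResult",
    "draw_coherent_ffl_params",
    "draw_incoherent_ffl_params",
]


def draw_auto_params(
    rng: np.random.Generator,
    tf: AllostericTF = DEFAULT_TF,
    rate_decades: tuple[float, float] = (-3.0, 2.5),
    omega_decades: tuple[float, float] = (-2.0, 3.0),
) -> AutoActivationParams:
    """One log-uniform auto-activation parameter draw with r0 <= r1 <= r2."""
    r0, r1, r2 = np.sort(10.0 ** rng.uniform(*rate_decades, size=3))
    omega = 10.0 ** rng.uniform(*omega_decades)
    return AutoActivationParams(r0=r0, r1=r1, r2=r2, omega=omega, tf=tf)


def _auto_root_count(p: AutoActivationParams, a: np.ndarray) -> np.ndarray:
    """Number of admissible cubic steady states per active fraction (vectorised)."""
    counts = np.empty(a.size, dtype=int)
    for i, ai in enumerate(a):
        coeffs = np.array([
            p.omega * ai**2,
            2.0 * ai - p.r2 * p.omega * ai**2,
            1.0 - 2.0 * p.r1 * ai,
            -p.r0,
        ])
        nz = np.flatnonzero(np.abs(coeffs) > 0)
        c = coeffs[nz[0]:]
        if len(c) <= 1:
            counts[i] = 0
            continue
        roots = np.roots(c)
        real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, p.r2)].real
        counts[i] = int(np.sum(real > 1e-12))
    return counts


def auto_bistable_anywhere(
    p: AutoActivationParams, c_grid=None
) -> bool:
    """Exhaustive effector scan: is the switch bistable at any concentration?

    Three distinct positive steady states at some grid concentration count
    as bistable (the generic two-stable + one-unstable configuration).
    """
    if c_grid is None:
        c_grid = np.geomspace(1e-9, 1e-2, 60)
    a = np.asarray(p_active(p.tf, np.asarray(c_grid, dtype=float)))
    return bool(np.any(_auto_root_count(p, a) >= 3))


@dataclass
class AutoScanResult:
    params: list
    bistable: np.ndarray
    omega_eff: np.ndarray


def auto_scan(n: int, seed: int, tf: AllostericTF = DEFAULT_TF, c_grid=None) -> AutoScanResult:
    """Draw ``n`` seeded auto-activation parameter sets and scan each for
    bistability over the effector grid."""
    rng = np.random.default_rng(seed)
    params = [draw_auto_params(rng, tf=tf) for _ in range(n)]
    bistable = np.array([auto_bistable_anywhere(p, c_grid) for p in params])
    omega_eff = np.array([p.omega * p.r2 / 2.0 for p in params])
    return AutoScanResult(params, bistable, omega_eff)


def draw_mr_params(
    rng: np.random.Generator,
    tf: AllostericTF = DEFAULT_TF,
    rbar_decades: tuple[float, float] = (-1.0, 1.5),
    omega_decades: tuple[float, float] = (-1.0, 2.0),
    kratio_decades: tuple[float, float] = (-1.0, 1.0),
) -> MutualRepressionParams:
    """One log-uniform toggle-switch parameter draw."""
    return MutualRepressionParams(
        rbar=10.0 ** rng.uniform(*rbar_decades),
        omega1=10.0 ** rng.uniform(*omega_decades),
        omega2=10.0 ** rng.uniform(*omega_decades),
        Kratio=10.0 ** rng.uniform(*kratio_decades),
        tf1=tf,
        tf2=tf,
    )


def mr_bistable_anywhere(
    p: MutualRepressionParams, c1_grid=None, c2_grid=None, n_r2: int = 400
) -> bool:
    """Scan the (c1, c2) plane for any bistable cell (vectorised root count)."""
    if c1_grid is None:
        c1_grid = np.geomspace(1e-8, 1e-3, 18)
    if c2_grid is None:
        c2_grid = np.geomspace(1e-8, 1e-3, 18)
    counts = _mr_root_count_grid(p, c1_grid, c2_grid, n_r2=n_r2)
    return bool((counts >= 3).any())


@dataclass
class MRScanResult:
    params: list
    bistable: np.ndarray


def mr_scan(
    n: int, seed: int, tf: AllostericTF = DEFAULT_TF, symmetric_kd: bool = True
) -> MRScanResult:
    """Draw ``n`` seeded toggle parameter sets and scan each for bistability.

    By default the draws have equal DNA-binding affinities (Kratio = 1), the
    domain in which the analytic production-rate bound is derived; pass
    ``symmetric_kd=False`` for fully general draws.
    """
    rng = np.random.default_rng(seed)
    kr = (0.0, 0.0) if symmetric_kd else (-1.0, 1.0)
    params = [draw_mr_params(rng, tf=tf, kratio_decades=kr) for _ in range(n)]
    bistable = np.array([mr_bistable_anywhere(p) for p in params])
    return MRScanResult(params, bistable)


def draw_coherent_ffl_params(rng: np.random.Generator) -> CoherentFFLParams:
    """Log-uniform coherent-loop draw with ordered Z rates (r0Z <= r1Z <=
    r2Z, a genuinely coherent activation hierarchy)."""
    r0Z, r1Z, r2Z = np.sort(10.0 ** rng.uniform(-2, 1.3, size=3))
    return CoherentFFLParams(
        r0Y=10.0 ** rng.uniform(-3, 0), r1Y=10.0 ** rng.uniform(-1, 1),
        r0Z=r0Z, r1Z=r1Z, r2Z=r2Z, omega=10.0 ** rng.uniform(-2, 2),
        KXZ=10.0 ** rng.uniform(-2, 2), KYZ=10.0 ** rng.uniform(-2, 2),
    )


def draw_incoherent_ffl_params(rng: np.random.Generator) -> IncoherentFFLParams:
    """Log-uniform incoherent-loop draw (Y production requires X)."""
    return IncoherentFFLParams(
        r0Y=0.0, r1Y=10.0 ** rng.uniform(-1, 1),
        r0Z=10.0 ** rng.uniform(-3, 0), r1Z=10.0 ** rng.uniform(-1, 1),
        omega=10.0 ** rng.uniform(-2, 2),
        KXZ=10.0 ** rng.uniform(-2, 2), KYZ=10.0 ** rng.uniform(-2, 2),
    )
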