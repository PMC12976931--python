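"""Monod-Wyman-Changeux (MWC) description of an allosteric transcription factor.

A two-conformation transcription factor (active / inactive, conformational
energy difference ``eps`` in units of k_B T, beta = 1 throughout) binds an
effector at ``n_sites`` identical sites with per-conformation dissociation
constants ``K_A`` (active) and ``K_I`` (inactive).  Summing the Boltzmann
weights of the 2^n binding configurations of each conformation gives the
probability that the factor is in its active conformation,

    p_act(c) = (1 + c/K_A)^n / [ (1 + c/K_A)^n + e^{-eps} (1 + c/K_I)^n ],

which is the experimentally accessible knob every circuit model in this
package is driven by.  All concentrations are molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "AllostericTF",
    "DEFAULT_TF",
    "p_active",
    "activity_limits",
    "effective_kd",
    "ec50",
]


@dataclass(frozen=True)
class AllostericTF:
    """MWC parameters of an effector-controlled transcription factor.

    Parameters
    ----------
    K_A : float
        Effector dissociation constant of the active conformation (molar).
    K_I : float
        Effector dissociation constant of the inactive conformation (molar).
    eps : float
        Conformational energy difference eps_inactive - eps_active, in k_B T.
        Positive values favour the active conformation at zero effector.
    n_sites : int
        Number of identical effector binding sites (>= 1).

    Notes
    -----
    With ``K_I < K_A`` the effector stabilises the inactive conformation, so
    activity decreases with effector concentration; ``K_I > K_A`` gives an
    activity that increases with concentration; ``K_I == K_A`` makes the
    effector irrelevant.
    """

    K_A: float
    K_I: float
    eps: float
    n_sites: int = 2

    def __post_init__(self) -> None:
        if not (self.K_A > 0 and math.isfinite(self.K_A)):
            raise ValueError(f"K_A must be positive and finite, got {self.K_A}")
        if not (self.K_I > 0 and math.isfinite(self.K_I)):
            raise ValueError(f"K_I must be positive and finite, got {self.K_I}")
        if not math.isfinite(self.eps):
            raise ValueError(f"eps must be finite, got {self.eps}")
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites}")


#: Allosteric parameters used by every preset unless overridden: a LacI-like
#: repressor whose effector (IPTG-like inducer) stabilises the inactive state.
DEFAULT_TF = AllostericTF(K_A=140e-6, K_I=530e-9, eps=4.5, n_sites=2)


def _validate_conc(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("effector concentration must be finite")
    if np.any(c < 0):
        raise ValueError("effector concentration must be >= 0")
    return c


def p_active(tf: AllostericTF, c) -> np.ndarray | float:
    """Probability that the transcription factor is active at effector
    concentration ``c`` (molar; scalar or array).

    Computed as a logistic in log-weight space,
    ``1 / (1 + exp(-eps + n [log(1+c/K_I) - log(1+c/K_A)]))``,
    which is the n-site MWC active fraction evaluated without overflow for
    any ``eps``.
    """
    c = _validate_conc(c)
    logit = tf.eps - tf.n_sites * (np.log1p(c / tf.K_I) - np.log1p(c / tf.K_A))
    out = expit(logit)
    return float(out) if out.ndim == 0 else out


def activity_limits(tf: AllostericTF) -> tuple[float, float]:
    """Return ``(pact_min, pact_max)``, the saturating- and zero-effector
    limits of the active fraction.

    ``pact_max = 1/(1 + e^{-eps})`` (c -> 0) and
    ``pact_min = 1/(1 + e^{-eps} (K_A/K_I)^n)`` (c -> infinity).  For an
    inactivating effector (``K_I < K_A``) these are the saturation and the
    leakiness of the induction curve; for an activating effector the two
    roles are swapped and ``pact_min`` exceeds ``pact_max``.
    """
    pact_max = float(expit(tf.eps))
    pact_min = float(expit(tf.eps - tf.n_sites * math.log(tf.K_A / tf.K_I)))
    return pact_min, pact_max


def effective_kd(Kd: float, tf: AllostericTF, c) -> np.ndarray | float:
    """Effective DNA dissociation constant ``Kd / p_act(c)`` (molar).

    Induction rescales the bare protein-DNA dissociation constant ``Kd``:
    only the active fraction of the factor competes for the operator, so the
    apparent constant is inflated by ``1/p_act``.  Over all effector
    concentrations the attainable range is exactly
    ``[Kd/pact_max, Kd/pact_min]``.
    """
    if not (Kd > 0 and math.isfinite(Kd)):
        raise ValueError(f"Kd must be positive and finite, got {Kd}")
    return Kd / p_active(tf, c)


def ec50(tf: AllostericTF, bracket: tuple[float, float] = (1e-15, 10.0)) -> float:
    """Effector concentration c* at which the activity is halfway between its
    two limits, ``p_act(c*) = (pact_min + pact_max) / 2``.

    Found by bracketed root finding on log10(c) over ``bracket`` (molar).
    Raises ``ValueError`` for the degenerate case ``K_A == K_I`` where the
    activity is constant in c.
    """
    if tf.K_A == tf.K_I:
        raise ValueError("ec50 undefined: K_A == K_I makes p_active constant in c")
    pmin, pmax = activity_limits(tf)
    target = 0.5 * (pmin + pmax)

    def resid(log10c: float) -> float:
        return p_active(tf, 10.0**log10c) - target

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    if resid(lo) * resid(hi) > 0:
        raise ValueError("ec50 bracket does not straddle the midpoint activity")
    log10c = brentq(resid, lo, hi, xtol=1e-13, rtol=1e-14)
    c_star = 10.0**log10c
    if abs(p_active(tf, c_star) - target) > 1e-10:
        raise RuntimeError("ec50 root did not converge to the midpoint")
    return c_star
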