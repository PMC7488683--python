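"""Equilibrium and local stability analysis of the scalar autorepressor.

The delayed autorepressor dx/dt = alpha/(1 + x(t-tau)**h) - x has exactly
one positive equilibrium x0, the root of x*(1 + x**h) = alpha.  Linearising
about x0 gives the feedback gain

    w = h * x0**h / (1 + x0**h),

which is the magnitude of the slope of the response at equilibrium divided
by the degradation rate.  For w <= 1 the equilibrium is stable for every
delay.  For w > 1, writing u = sqrt(w**2 - 1), the equilibrium loses
stability at the critical delay

    tau_star = (pi - arctan(u)) / u,

where a limit cycle of period T = 2*pi/u is born (delay-induced Hopf
bifurcation).  Without delay (tau = 0) the equilibrium is stable for all
(alpha, h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.optimize import brentq

__all__ = ["EquilibriumReport", "equilibrium", "hopf_report", "is_oscillatory"]


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibrium x0 and Hopf-threshold quantities of the autorepressor.

    ``u``, ``tau_star`` and ``T_hopf`` are None when w <= 1 (no delay can
    destabilise the equilibrium).
    """

    alpha: float
    h: float
    x0: float
    w: float
    u: float | None
    tau_star: float | None
    T_hopf: float | None
    oscillatory_possible: bool

    def to_dict(self) -> dict:
        return asdict(self)


def equilibrium(alpha: float, h: float) -> float:
    """Unique positive root of x*(1 + x**h) = alpha.

    The left side is strictly increasing from 0, so the root is unique and
    bracketed by (0, alpha]; solved with Brent's method to ~1e-14 relative.
    """
    if alpha <= 0 or h <= 0:
        raise ValueError("alpha and h must be > 0")

    def g(x: float) -> float:
        return x * (1.0 + x**h) - alpha

    hi = min(alpha, alpha ** (1.0 / (1.0 + h)) + 1.0)
    while g(hi) < 0:  # guard against rounding in the analytic bracket
        hi *= 2.0
    return brentq(g, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)


def hopf_report(alpha: float, h: float) -> EquilibriumReport:
    """Full linear-stability report for the scalar autorepressor."""
    x0 = equilibrium(alpha, h)
    xh = x0**h
    w = h * xh / (1.0 + xh)
    if w > 1.0:
        u = math.sqrt(w * w - 1.0)
        tau_star = (math.pi - math.atan(u)) / u
        T_hopf = 2.0 * math.pi / u
    else:
        u = tau_star = T_hopf = None
    return EquilibriumReport(
        alpha=float(alpha),
        h=float(h),
        x0=x0,
        w=w,
        u=u,
        tau_star=tau_star,
        T_hopf=T_hopf,
        oscillatory_possible=w > 1.0,
    )


def is_oscillatory(alpha: float, h: float, tau: float) -> bool:
    """True iff the equilibrium is unstable at delay *tau* (w > 1, tau >= tau*)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    rep = hopf_report(alpha, h)
    return rep.oscillatory_possible and tau >= rep.tau_star
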