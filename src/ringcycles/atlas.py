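"""Symmetric-cycle enumeration for the smooth Hill ring.

Every symmetric cycle of the n-gene ring with phase-shift numerator p
(consecutive genes lagged by pT/n) projects onto a periodic solution of the
scalar autorepressor with *effective delay* tau_eff = tau + (p/n) T.  The
scalar period function T(tau) — computed once on a grid, the single numeric
primitive here — therefore turns enumeration into one-dimensional
root-finding:

* cycles of the n-gene ring with system delay tau are fixed points of
  tau_eff = tau + (p/n) T(tau_eff);
* for tau = 0 this reduces to counting intersections of the line n/p with
  the ratio curve y(tau) = T(tau)/tau (only ratios above 2 can intersect,
  because T(tau) > 2 tau on the whole branch);
* a cycle is reducible exactly when gcd(n, p) > 1, in which case it is the
  lift of the cycle (s, q) = (n/g, p/g) of the smaller ring, and conversely
  any cycle of an s-gene ring lifts to every multiple n = s*ell;
* the numerically observed stability rule: the cycle is stable iff n is odd
  and p = (n-1)/2.

Records are verified by re-simulating the full n-gene system seeded with
the phase-shifted scalar profile and comparing periods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from math import gcd
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .dde_engine import IntegratorOptions, integrate, threshold_crossings
from .model_core import HillCircuitSpec, HistorySegment
from .stability import hopf_report

__all__ = [
    "CurveDomainError",
    "PeriodCurve",
    "SymmetricCycleRecord",
    "build_period_curve",
    "count_intersections",
    "algorithm1_enumerate",
    "algorithm2_lift",
    "classify_reducibility",
    "stability_class",
    "short_cycles",
    "census",
    "lifted_cycle_residual",
]


class CurveDomainError(RuntimeError):
    """The requested feature lies beyond the period curve's tau range."""


@dataclass
class PeriodCurve:
    """Sampled period function T(tau) of the scalar autorepressor.

    The first node is the analytic Hopf anchor (tau*, 2 pi / u); subsequent
    nodes are measured from simulations on a log-spaced grid.  Interpolation
    is shape-preserving (PCHIP), so the measured monotonicity of T(tau) is
    not distorted between nodes.
    """

    alpha: float
    h: float
    tau_star: float
    T_hopf: float
    tau_grid: np.ndarray
    T_values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.T_values = np.asarray(self.T_values, dtype=float)
        self._interp = PchipInterpolator(self.tau_grid, self.T_values)

    @property
    def tau_max(self) -> float:
        return float(self.tau_grid[-1])

    def T_at(self, tau):
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < self.tau_grid[0] - 1e-12) or np.any(tau > self.tau_max + 1e-12):
            raise CurveDomainError(
                f"tau outside curve domain [{self.tau_grid[0]:.6g}, {self.tau_max:.6g}]"
            )
        out = self._interp(np.clip(tau, self.tau_grid[0], self.tau_max))
        return float(out) if out.ndim == 0 else out

    def ratio_at(self, tau):
        return self.T_at(tau) / np.asarray(tau, dtype=float)

    def save(self, path) -> None:
        payload = {
            "alpha": self.alpha, "h": self.h,
            "tau_star": self.tau_star, "T_hopf": self.T_hopf,
            "tau_grid": self.tau_grid.tolist(),
            "T_values": self.T_values.tolist(),
            "meta": {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str))},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "PeriodCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha=d["alpha"], h=d["h"], tau_star=d["tau_star"], T_hopf=d["T_hopf"],
            tau_grid=np.array(d["tau_grid"]), T_values=np.array(d["T_values"]),
            meta=d.get("meta", {}),
        )


@dataclass(frozen=True)
class SymmetricCycleRecord:
    """One symmetric cycle of the n-gene smooth ring.

    ``tau_eff`` is the effective delay of the generating scalar cycle,
    ``T`` its period, ``phase_lag`` = p*T/n the lag between consecutive
    genes.  ``generator`` is (s, q) for reducible cycles (gcd(n, p) = g > 1,
    s = n/g, q = p/g).  ``T_measured`` is filled by verification.
    """

    n: int
    p: int
    k: int
    tau_eff: float
    T: float
    phase_lag: float
    reducible: bool
    generator: tuple[int, int] | None
    stability: str
    tangent: bool = False
    verified: bool | None = None
    T_measured: float | None = None


# ---------------------------------------------------------------------------
# period curve


def _measure_scalar_period(alpha, h, tau, T_est, rel_tol=1e-7):
    """Period of the scalar autorepressor at delay tau (must oscillate)."""
    options = IntegratorOptions(
        rel_tol=rel_tol, abs_tol=1e-10, max_step=min(0.05, max(T_est / 40.0, 1e-3))
    )
    transient = max(60.0, 6.0 * T_est)
    for t_end in (transient + 14.0 * T_est, 2.0 * (transient + 14.0 * T_est)):
        traj = integrate(
            HillCircuitSpec(1, alpha=alpha, h=h, tau=tau), 1.0, t_end, options
        )
        x = traj.component(0)
        sel = traj.times >= transient
        level = 0.5 * (x[sel].max() + x[sel].min())
        ups = threshold_crossings(traj, 0, level, "up")
        ups = ups[ups >= transient]
        if len(ups) >= 9:
            intervals = np.diff(ups)[-12:]
            spread = (intervals.max() - intervals.min()) / intervals.mean()
            if spread < 1e-3:
                return float(intervals.mean())
        transient *= 2.0
    raise RuntimeError(
        f"no converged oscillation at tau={tau:.6g} (alpha={alpha}, h={h})"
    )


def build_period_curve(
    alpha: float,
    h: float,
    tau_max: float | None = None,
    n_points: int = 160,
    cache_dir=None,
) -> PeriodCurve:
    """Measure T(tau) on a log-spaced grid above the Hopf threshold.

    The grid spans (1.02 tau*, tau_max]; the analytic anchor (tau*, 2pi/u)
    is prepended.  With *cache_dir* set, the curve is stored as JSON keyed
    by (alpha, h, grid) and reloaded on repeat calls.
    """
    rep = hopf_report(alpha, h)
    if not rep.oscillatory_possible:
        raise ValueError(
            f"(alpha={alpha}, h={h}) has w={rep.w:.4f} <= 1: no delay can "
            "destabilise the equilibrium, no period curve exists"
        )
    if tau_max is None:
        tau_max = 20.0 * rep.tau_star
    if tau_max <= 1.05 * rep.tau_star:
        raise ValueError("tau_max must exceed the Hopf threshold comfortably")

    cache_path = None
    if cache_dir is not None:
        key = hashlib.sha256(
            json.dumps([alpha, h, tau_max, n_points]).encode()
        ).hexdigest()[:16]
        cache_path = Path(cache_dir) / f"period_curve_{key}.json"
        if cache_path.exists():
            return PeriodCurve.load(cache_path)

    grid = np.geomspace(1.02 * rep.tau_star, tau_max, n_points)
    T_vals = []
    T_est = rep.T_hopf
    for tau in grid:
        T_est = _measure_scalar_period(alpha, h, tau, T_est)
        T_vals.append(T_est)

    curve = PeriodCurve(
        alpha=float(alpha), h=float(h),
        tau_star=rep.tau_star, T_hopf=rep.T_hopf,
        tau_grid=np.concatenate([[rep.tau_star], grid]),
        T_values=np.concatenate([[rep.T_hopf], T_vals]),
        meta={"n_points": n_points},
    )
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        curve.save(cache_path)
    return curve


# ---------------------------------------------------------------------------
# intersection counting / fixed points


def _fine_tau(curve: PeriodCurve, n_fine: int = 4000) -> np.ndarray:
    return np.geomspace(curve.tau_grid[0], curve.tau_max, n_fine)


def _fixed_point_roots(curve: PeriodCurve, tau: float, frac: float) -> list[float]:
    """Roots tau_eff of tau_eff = tau + frac*T(tau_eff) inside the domain."""
    taus = _fine_tau(curve)
    g = taus - tau - frac * curve.T_at(taus)
    roots = []
    for j in range(len(taus) - 1):
        if g[j] == 0.0:
            roots.append(float(taus[j]))
        elif g[j] * g[j + 1] < 0.0:
            f = lambda te: te - tau - frac * curve.T_at(te)
            roots.append(float(brentq(f, taus[j], taus[j + 1], xtol=1e-12)))
    return roots


def count_intersections(
    curve: PeriodCurve, ratio: float, tangent_tol: float = 0.005,
    with_flags: bool = False,
):
    """Number of solutions of T(tau)/tau = ratio on the curve's domain.

    Ratios <= 2 never intersect (T > 2 tau on the whole branch) and return 0
    without consulting the curve.  A ratio within *tangent_tol* (relative)
    of a local extremum of the ratio curve counts once and is flagged
    tangent.  A ratio that the descending tail has not yet reached at
    tau_max raises :class:`CurveDomainError` (extend tau_max).
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if ratio <= 2.0:
        return (0, False) if with_flags else 0
    taus = _fine_tau(curve)
    y = curve.T_at(taus) / taus
    y_end = y[-1]
    y_max = float(y.max())
    if 2.0 < ratio <= y_end:
        raise CurveDomainError(
            f"ratio {ratio} not yet reached by the descending tail at "
            f"tau_max={curve.tau_max:.4g} (y there = {y_end:.4f}); extend tau_max"
        )
    tangent = abs(ratio - y_max) <= tangent_tol * y_max
    if ratio > y_max:
        result = 1 if tangent else 0
        return (result, tangent) if with_flags else result
    s = y - ratio
    count = 0
    for j in range(len(taus) - 1):
        if s[j] == 0.0 or s[j] * s[j + 1] < 0.0:
            count += 1
    if tangent:
        count = 1
    return (count, tangent) if with_flags else count


def classify_reducibility(n: int, p: int):
    """gcd test: irreducible iff gcd(n, p) = 1, else the generating (s, q)."""
    if not 1 <= p < n:
        raise ValueError(f"p must satisfy 1 <= p < n, got p={p}, n={n}")
    g = gcd(n, p)
    if g == 1:
        return None
    return (n // g, p // g)


def stability_class(n: int, p: int) -> str:
    """Numerically observed rule: stable iff n odd and p = (n-1)/2."""
    if not 1 <= p < n:
        raise ValueError(f"p must satisfy 1 <= p < n, got p={p}, n={n}")
    return "stable" if (n % 2 == 1 and p == (n - 1) // 2) else "unstable"


def _make_record(n, p, tau_eff, T, tau, tangent=False) -> SymmetricCycleRecord:
    gen = classify_reducibility(n, p)
    return SymmetricCycleRecord(
        n=n, p=p, k=0, tau_eff=tau_eff, T=T, phase_lag=p * T / n,
        reducible=gen is not None, generator=gen,
        stability=stability_class(n, p), tangent=tangent,
    )


# ---------------------------------------------------------------------------
# verification by n-dimensional simulation


def _scalar_profile(alpha, h, tau_eff, rel_tol=1e-8, T_hint=None):
    """Converged scalar cycle at delay tau_eff: (trajectory, period, t_ref).

    ``t_ref`` is an upward mid-level crossing late in the trajectory, used
    as the phase origin of the profile.  ``T_hint`` sizes the integration
    window when the expected period is already known.
    """
    rep = hopf_report(alpha, h)
    T_est = T_hint if T_hint else max(2.0 * tau_eff, rep.T_hopf)
    options = IntegratorOptions(
        rel_tol=rel_tol, abs_tol=1e-11, max_step=min(0.05, max(T_est / 60.0, 1e-3))
    )
    transient = max(80.0, 8.0 * T_est)
    t_end = transient + 14.0 * T_est
    spec = HillCircuitSpec(1, alpha=alpha, h=h, tau=tau_eff)
    traj = integrate(spec, 1.0, t_end, options)
    x = traj.component(0)
    sel = traj.times >= transient
    level = 0.5 * (x[sel].max() + x[sel].min())
    ups = threshold_crossings(traj, 0, level, "up")
    ups = ups[ups >= transient]
    if len(ups) < 6:
        raise RuntimeError(f"scalar cycle did not converge at tau_eff={tau_eff:.6g}")
    T = float(np.diff(ups)[-10:].mean())
    t_ref = float(ups[2])  # leave >= 2 periods of profile on either side
    return traj, T, t_ref


def _seeded_period(alpha, h, tau, n, p, tau_eff, profile_tol, T_hint=None):
    """Seed the n-gene ring on the phase-shifted scalar cycle and measure the
    period over the earliest clean revolutions (unstable cycles hold the
    orbit only for a few periods).  Returns the measured period or None."""
    traj, T_s, t_ref = _scalar_profile(alpha, h, tau_eff, rel_tol=profile_tol,
                                       T_hint=T_hint)

    def prof(u):
        # phase u relative to t_ref, reduced into the converged window
        return float(traj.at(t_ref + (u % T_s))[0])

    theta = [(i * p * T_s / n) % T_s for i in range(n)]
    spec = HillCircuitSpec(n, alpha=alpha, h=h, tau=tau)
    if tau == 0.0:
        hist = HistorySegment(0.0, tuple(prof(th) for th in theta))
    else:
        hist = HistorySegment(
            tau, lambda t: np.array([prof(th + t) for th in theta])
        )
    options = IntegratorOptions(rel_tol=1e-9, abs_tol=1e-12,
                                max_step=min(0.05, T_s / 40.0))
    full = integrate(spec, hist, 6.0 * T_s, options)
    early = full.states[full.times <= 2.0 * T_s, 0]
    level = 0.5 * (float(early.max()) + float(early.min()))
    ups = threshold_crossings(full, 0, level, "up")
    ups = ups[ups >= 0.2 * T_s]
    if len(ups) < 2:
        return None
    return float(np.diff(ups)[:3].mean())


def verify_record(
    alpha: float, h: float, tau: float, record: SymmetricCycleRecord,
    rel_period_tol: float = 0.01,
) -> SymmetricCycleRecord:
    """Integrate the full n-gene ring seeded on the implied orbit and check
    that the measured period matches the record's to *rel_period_tol*.

    If the first attempt (effective delay from the interpolated curve)
    fails, the fixed point is polished against simulated periods and the
    seeding retried — strongly unstable cycles tolerate only a tiny
    inconsistency in the seed before escaping.
    """
    n, p = record.n, record.p
    T_meas = _seeded_period(alpha, h, tau, n, p, record.tau_eff, 1e-8,
                            T_hint=record.T)
    ok = T_meas is not None and abs(T_meas - record.T) <= rel_period_tol * record.T
    if not ok:
        te = refine_tau_eff(alpha, h, tau, p, n, record.tau_eff, rel_tol=1e-9)
        T_meas = _seeded_period(alpha, h, tau, n, p, te, 1e-9, T_hint=record.T)
        ok = T_meas is not None and abs(T_meas - record.T) <= rel_period_tol * record.T
    return replace(record, verified=bool(ok), T_measured=T_meas)


def algorithm1_enumerate(
    alpha: float, h: float, tau: float, n: int,
    curve: PeriodCurve, verify: bool = True,
) -> list[SymmetricCycleRecord]:
    """All symmetric cycles of the n-gene ring found on the period curve.

    For each p = 1..n-1, solves tau_eff = tau + (p/n) T(tau_eff) on the
    curve; each root becomes a record (with reducibility and stability
    classification), optionally verified by full n-dimensional simulation.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    records = []
    for p in range(1, n):
        frac = p / n
        if tau == 0.0:
            # guard: the ratio formulation also reports tangency and domain
            # exhaustion; count_intersections raises if tau_max is too small
            cnt, tangent = count_intersections(curve, n / p if frac else 0.0,
                                               with_flags=True)
            if cnt == 0:
                continue
        else:
            tangent = False
        roots = _fixed_point_roots(curve, tau, frac)
        if tau == 0.0 and tangent and not roots:
            # the line grazes the ratio curve: take the extremum itself
            taus = _fine_tau(curve)
            y = curve.T_at(taus) / taus
            roots = [float(taus[np.argmax(y)])]
        for te in roots:
            rec = _make_record(n, p, te, float(curve.T_at(te)), tau, tangent)
            if verify:
                rec = verify_record(alpha, h, tau, rec)
            records.append(rec)
    return records


def algorithm2_lift(record: SymmetricCycleRecord, ell: int) -> SymmetricCycleRecord:
    """Lift a symmetric cycle of an s-gene ring to the (s*ell)-gene ring.

    The lifted orbit repeats the generator's coordinate functions around the
    larger ring: same period, same phase lag q*T_s/s, shift numerator scaled
    to p = q*ell.  ``ell = 1`` returns the record unchanged.
    """
    if ell < 1:
        raise ValueError("ell must be >= 1")
    if ell == 1:
        return record
    s, q = record.n, record.p
    n2, p2 = s * ell, q * ell
    return SymmetricCycleRecord(
        n=n2, p=p2, k=record.k, tau_eff=record.tau_eff, T=record.T,
        phase_lag=record.phase_lag, reducible=True, generator=(s, q),
        stability=stability_class(n2, p2), tangent=record.tangent,
        verified=None, T_measured=record.T_measured,
    )


def refine_tau_eff(
    alpha: float, h: float, tau: float, p: int, n: int, tau_eff0: float,
    rel_tol: float = 1e-10, max_iter: int = 6,
) -> float:
    """Secant-polish the fixed point tau_eff = tau + (p/n) T(tau_eff) using
    simulated periods instead of the interpolated curve."""
    frac = p / n

    def phi(te):
        return te - tau - frac * _measure_scalar_period(
            alpha, h, te, max(2.0 * te, 1.0), rel_tol=rel_tol
        )

    a, b = tau_eff0, tau_eff0 * (1.0 + 1e-4)
    fa, fb = phi(a), phi(b)
    for _ in range(max_iter):
        if fb == fa:
            break
        c = b - fb * (b - a) / (fb - fa)
        a, fa, b, fb = b, fb, c, phi(c)
        if abs(fb) < 1e-11 * max(1.0, b):
            break
    return b


def lifted_cycle_residual(
    alpha: float, h: float, tau: float, record: SymmetricCycleRecord,
    rel_tol: float = 1e-10,
) -> float:
    """Max-norm residual of the phase-shifted orbit in the full n-gene ring.

    Substitutes x_i(t) = x(t + i p T / n) (x = the converged scalar cycle at
    the simulator-refined effective delay, T its measured period) into the
    n-dimensional equations and returns
    max |dx_i/dt - f(x_{i-1}(t - tau)) + x_i(t)| over one period.  The
    derivative comes from the integration itself (which used the true,
    unwrapped past), while the regulator value wraps the profile
    periodically, so the residual genuinely probes periodic closure and the
    fixed-point consistency of the lift.
    """
    n, p = record.n, record.p
    g = gcd(n, p)
    te = refine_tau_eff(alpha, h, tau, p // g, n // g, record.tau_eff,
                        rel_tol=rel_tol)
    traj, T_s, t_ref = _scalar_profile(alpha, h, te, rel_tol=rel_tol,
                                       T_hint=record.T)
    derivs = traj.meta["derivs"][:, 0]
    times = traj.times
    xvals = traj.component(0)

    def prof(u):
        return float(traj.at(t_ref + (u % T_s))[0])

    # by cyclic symmetry the residual of gene i at time t equals that of
    # gene 0 at time t + i*shift, so one dense sweep over a period covers
    # the whole ring
    worst = 0.0
    shift = p * T_s / n
    sel = np.where((times >= t_ref) & (times <= t_ref + T_s))[0]
    for k in sel:
        u = times[k] - t_ref
        xi, dxi = xvals[k], derivs[k]
        xreg = prof(u - shift - tau)
        rhs = alpha / (1.0 + xreg**h) - xi
        worst = max(worst, abs(dxi - rhs))
    return worst


def short_cycles(
    alpha: float, h: float, tau: float, curve: PeriodCurve
) -> list[tuple[int, float, float]]:
    """Short-period cycles coexisting with the main one at a large delay.

    For each m >= 1 with tau* + m*T_hopf <= tau there is a cycle whose
    parameters solve S_m(tau') = tau' + m*T(tau') = tau (unique: S_m grows
    monotonically).  Returns (m, tau'_m, T(tau'_m)); each period is < tau.
    """
    if tau <= curve.tau_star:
        raise ValueError("tau must exceed the Hopf threshold")
    out = []
    m = 1
    while curve.tau_star + m * curve.T_hopf <= tau:
        roots = _fixed_point_roots(curve, tau, -float(m))
        if not roots:
            raise CurveDomainError(
                f"S_{m}(tau') = tau has no root inside the curve domain"
            )
        te = roots[0]
        out.append((m, te, float(curve.T_at(te))))
        m += 1
    return out


def census(
    alpha: float, h: float, n_values, curve: PeriodCurve, verify: bool = True,
) -> dict[int, list[SymmetricCycleRecord]]:
    """Symmetric-cycle census of the delay-free rings for each n."""
    return {
        int(n): algorithm1_enumerate(alpha, h, 0.0, int(n), curve, verify=verify)
        for n in n_values
    }
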