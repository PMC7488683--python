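"""Exact machinery for the step-function (Glass) limit of the ring model.

In the infinite-cooperativity limit the repression response is an on/off
switch at threshold 1 and trajectories are concatenations of exponential
relaxations toward ``alpha_i`` (production on) or ``0`` (production off).
Switching happens exactly ``tau_i`` after the regulator crosses the
threshold, so the whole trajectory can be generated event by event with
every switching instant solved in closed form (logarithms) — there is no
time-stepping error.

For the symmetric case (all alphas equal, beta = 1) the cycle geometry is
closed-form.  A symmetric cycle with period T and effective delay
``tau_eff`` starts at its minimum x(0) = exp(-tau_eff), rises and crosses
the threshold at t1, peaks at t2 = t1 + tau_eff, decays crossing the
threshold again at t3 = T - tau_eff, and returns to its minimum at T.
The period satisfies

    T(tau) = ln[ (alpha e^tau - alpha + 1)(alpha e^tau - 1) / (alpha - 1) ]

and the map tau -> T is invertible in closed form.  Families of further
cycles (shorter periods, and phase-lagged cycles of the n-gene ring) are
roots of fixed-point equations in T built from the same period function.
"""

from __future__ import annotations

import heapq
import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    HistorySegment,
    SpecValidationError,
    StepCircuitSpec,
    Trajectory,
)

__all__ = [
    "PiecewiseCycle",
    "FamilyEntry",
    "StepEvent",
    "exact_step_trajectory",
    "period_from_delay",
    "delay_from_period",
    "cycle_schedule",
    "countable_family",
    "symmetric_family_nd",
    "symmetric_cycle_seed",
]

MAX_EVENTS = 1_000_000


@dataclass(frozen=True)
class StepEvent:
    """A threshold crossing of one component of the exact trajectory."""

    time: float
    gene: int
    direction: str  # "up" or "down"


@dataclass(frozen=True)
class PiecewiseCycle:
    """Closed-form symmetric cycle of the scalar step system (beta = 1).

    Schedule within one period: up-crossing at t1, maximum at t2 = t1 +
    tau_eff, down-crossing at t3 = T - tau_eff, minimum x_min = e^{-tau_eff}
    at 0 and T; maximum x_max = (alpha e^tau - alpha + 1)/e^tau.
    """

    alpha: float
    tau_eff: float
    T: float
    t1: float
    t2: float
    t3: float
    x_min: float
    x_max: float

    def profile(self, u: float) -> float:
        """Cycle value at phase u (any real; reduced mod T)."""
        u = u % self.T
        if u < self.t2:  # production on: relax toward alpha
            return self.alpha + (self.x_min - self.alpha) * math.exp(-u)
        return self.x_max * math.exp(-(u - self.t2))


@dataclass
class FamilyEntry:
    """One member of a countable cycle family.

    ``p`` is the cyclic phase-shift numerator (1 for scalar families), ``k``
    the period-winding index; ``tau_k`` the effective delay of the reduced
    scalar cycle, ``T_k`` its period.  ``validated`` is True when an exact
    event-driven simulation seeded on the implied orbit confirmed a
    persistent periodic orbit with the predicted period (None = not checked).
    """

    k: int
    p: int
    tau_k: float
    T_k: float
    validated: bool | None = None


# ---------------------------------------------------------------------------
# closed forms


def _require_supercritical(alpha: float) -> None:
    if alpha <= 1.0:
        raise SpecValidationError(
            f"alpha must exceed 1 for a step-limit cycle (got {alpha})"
        )


def period_from_delay(alpha: float, tau: float) -> float:
    """Cycle period of the scalar step system at effective delay tau."""
    _require_supercritical(alpha)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    et = math.exp(tau)
    return math.log((alpha * et - alpha + 1.0) * (alpha * et - 1.0) / (alpha - 1.0))


def delay_from_period(alpha: float, T: float) -> float:
    """Unique delay in (0, T/2) producing a cycle of period T."""
    _require_supercritical(alpha)
    if T <= 0:
        raise ValueError("T must be > 0")
    disc = alpha * alpha + 4.0 * math.expm1(T) * (alpha - 1.0)
    return math.log((alpha + math.sqrt(disc)) / (2.0 * alpha))


def cycle_schedule(alpha: float, tau: float) -> PiecewiseCycle:
    """Full closed-form schedule of the scalar symmetric cycle."""
    _require_supercritical(alpha)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    T = period_from_delay(alpha, tau)
    emt = math.exp(-tau)
    et = math.exp(tau)
    t1 = math.log((alpha - emt) / (alpha - 1.0))
    t2 = math.log((alpha * et - 1.0) / (alpha - 1.0))
    t3 = T - tau
    x_min = emt
    x_max = (et * alpha - alpha + 1.0) / et
    return PiecewiseCycle(
        alpha=alpha, tau_eff=tau, T=T, t1=t1, t2=t2, t3=t3,
        x_min=x_min, x_max=x_max,
    )


# ---------------------------------------------------------------------------
# event-driven exact simulation


def _segment_crossing(t0: float, v: float, target: float, beta: float):
    """Crossing time of level 1 within x(t)=target+(v-target)e^{-beta(t-t0)},
    or None. The segment is monotone, so at most one crossing exists."""
    if v == 1.0 or (v - 1.0) * (target - 1.0) >= 0.0:
        return None
    # E = (target-1)/(target-v) in (0,1) exactly when 1 is between v, target
    e = (target - 1.0) / (target - v)
    return t0 + math.log(1.0 / e) / beta


def simulate_step_network(
    spec: StepCircuitSpec,
    x0,
    on0,
    pending,
    t_end: float,
    sample_dt: float | None = None,
):
    """Exact event-driven simulation from an explicit switching state.

    *x0*: initial concentrations; *on0*: per-gene production flags at t=0;
    *pending*: iterable of (time, gene, new_on) production toggles already
    committed by pre-t=0 regulator crossings (0 < time <= tau_gene).
    Returns (Trajectory, [StepEvent...]).
    """
    n = spec.n
    beta = spec.beta
    alpha = spec.alpha
    tau = spec.tau

    t0 = [0.0] * n
    val = [float(v) for v in x0]
    on = [bool(o) for o in on0]
    version = [0] * n
    segments = [[(0.0, val[i], alpha[i] if on[i] else 0.0)] for i in range(n)]
    events: list[StepEvent] = []
    degenerate = False

    heap: list[tuple] = []
    counter = 0

    def push(t, kind, gene, payload):
        nonlocal counter
        heapq.heappush(heap, (t, counter, kind, gene, payload))
        counter += 1

    def value_at(i, t):
        tgt = alpha[i] if on[i] else 0.0
        return tgt + (val[i] - tgt) * math.exp(-beta[i] * (t - t0[i]))

    def schedule_crossing(i):
        tgt = alpha[i] if on[i] else 0.0
        tc = _segment_crossing(t0[i], val[i], tgt, beta[i])
        if tc is not None and tc <= t_end + spec.max_delay:
            push(tc, "cross", i, version[i])

    for t, gene, new_on in pending:
        push(float(t), "toggle", int(gene), bool(new_on))
    for i in range(n):
        if val[i] == 1.0 and (alpha[i] if on[i] else 0.0) == 1.0:
            degenerate = True
        schedule_crossing(i)

    n_processed = 0
    while heap:
        t, _, kind, i, payload = heapq.heappop(heap)
        if t > t_end:
            break
        n_processed += 1
        if n_processed > MAX_EVENTS:
            raise RuntimeError(f"event accumulation: >{MAX_EVENTS} events by t={t:.6g}")
        if kind == "cross":
            if payload != version[i]:
                continue  # stale: the segment changed before the crossing
            tgt = alpha[i] if on[i] else 0.0
            direction = "down" if tgt < 1.0 else "up"
            events.append(StepEvent(time=t, gene=i, direction=direction))
            j = (i + 1) % n  # the gene this one represses
            push(t + tau[j], "toggle", j, direction == "down")
        else:  # toggle of production
            new_on = payload
            if new_on == on[i]:
                continue
            val[i] = value_at(i, t)
            t0[i] = t
            on[i] = new_on
            version[i] += 1
            tgt = alpha[i] if on[i] else 0.0
            if val[i] == 1.0 and tgt == 1.0:
                degenerate = True
            segments[i].append((t, val[i], tgt))
            schedule_crossing(i)

    if sample_dt is None:
        sample_dt = t_end / 2000.0
    times = np.linspace(0.0, t_end, max(int(round(t_end / sample_dt)) + 1, 9))
    states = np.empty((times.size, n))
    derivs = np.empty((times.size, n))
    for i in range(n):
        seg = segments[i]
        starts = [s[0] for s in seg]
        for j, t in enumerate(times):
            k = bisect_right(starts, t) - 1
            ts_, v_, tgt_ = seg[k]
            x = tgt_ + (v_ - tgt_) * math.exp(-beta[i] * (t - ts_))
            states[j, i] = x
            derivs[j, i] = beta[i] * (tgt_ - x)
    meta = {
        "solver": "event-driven-exact",
        "segments": segments,
        "events": events,
        "n_events": len(events),
        "degenerate": degenerate,
        "derivs": derivs,
    }
    return Trajectory(times=times, states=states, meta=meta), events


def exact_step_trajectory(
    spec: StepCircuitSpec,
    history,
    t_end: float,
    sample_dt: float | None = None,
):
    """Exact trajectory of the step system from an initial history.

    Returns (Trajectory, [StepEvent...]); the event schedule lists every
    threshold crossing with its exact time.
    """
    if not isinstance(history, HistorySegment):
        history = HistorySegment(spec.max_delay, history)
    history = history.for_spec(spec)
    n = spec.n

    x0 = [float(v) for v in np.atleast_1d(history(0.0))]
    on0 = []
    pending = []
    for i in range(n):
        r = (i - 1) % n
        ti = spec.tau[i]
        xr = float(np.atleast_1d(history(-ti))[r])
        on0.append(xr <= 1.0)
        if ti > 0.0 and not history.is_constant:
            # regulator crossings inside (-tau_i, 0] commit future toggles
            grid = np.linspace(-ti, 0.0, 512)
            vals = np.array([float(np.atleast_1d(history(t))[r]) for t in grid]) - 1.0
            for j in range(len(grid) - 1):
                a, b = vals[j], vals[j + 1]
                if a == 0.0 or a * b >= 0.0:
                    continue
                f = lambda t: float(np.atleast_1d(history(t))[r]) - 1.0
                tc = brentq(f, grid[j], grid[j + 1], xtol=1e-14)
                pending.append((tc + ti, i, b < 0.0))
    return simulate_step_network(spec, x0, on0, pending, t_end, sample_dt)


# ---------------------------------------------------------------------------
# cycle families


def _solve_family_T(alpha: float, tau: float, coeff: float):
    """Root T > 0 of T = period_from_delay(alpha, tau + coeff*T) with
    tau + coeff*T > 0, or None.  coeff = p/n - k (0 for the main branch)."""
    def g(T: float) -> float:
        te = tau + coeff * T
        if te <= 0.0:
            return math.inf  # outside the admissible region
        return T - period_from_delay(alpha, te)

    if coeff < 0.0:
        if tau <= 0.0:
            return None
        hi = tau / (-coeff)  # tau_eff -> 0+ there, g -> hi > 0
        lo = hi * 1e-14
        if g(lo) >= 0.0:
            return None
        return brentq(g, lo, hi * (1.0 - 1e-13), xtol=1e-13, rtol=8.9e-16)

    # coeff >= 0: need 1 - 2*coeff > 0 for any root (since T > 2*tau_eff)
    if coeff >= 0.5:
        return None
    c_inf = math.log(alpha * alpha / (alpha - 1.0))
    hi = (2.0 * tau + c_inf + 10.0) / (1.0 - 2.0 * coeff)
    # scan a log grid for the sign change (g(0+) <= 0 can be degenerate at
    # tau = 0, where g(0) = 0 and the root is interior); the 1e-6 floor
    # rejects rounding-level sign flips at the degenerate origin
    grid = np.geomspace(1e-6, hi, 400)
    gv = [g(T) for T in grid]
    for j in range(len(grid) - 1):
        if gv[j] < 0.0 <= gv[j + 1]:
            root = brentq(g, grid[j], grid[j + 1], xtol=1e-13, rtol=8.9e-16)
            if root > 1e-5:
                return root
    return None


def countable_family(alpha: float, tau: float, k_max: int = 10) -> list[FamilyEntry]:
    """Scalar cycle family: for each k, the cycle whose effective delay
    tau_k = tau - k*T_k is positive.

    k = 0 is the main cycle (period ``period_from_delay(alpha, tau)``); each
    k >= 1 wraps the delay k extra periods.  In the step limit a root exists
    for every k (periods shrink like tau/k), so enumeration is capped at
    *k_max*.
    """
    _require_supercritical(alpha)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    out = []
    for k in range(k_max + 1):
        T = _solve_family_T(alpha, tau, -float(k)) if k else period_from_delay(alpha, tau)
        if T is None:
            break
        out.append(FamilyEntry(k=k, p=1, tau_k=tau - k * T, T_k=T))
    return out


def symmetric_cycle_seed(spec: StepCircuitSpec, entry: FamilyEntry):
    """Exact on-cycle switching state for a symmetric family entry.

    Returns (x0, on0, pending, cycle): the phase-shifted profile
    x_i(t) = x(t + i*p*T/n mod T) of the reduced scalar cycle, with the
    production flags and the pre-committed toggles implied by regulator
    crossings during (-tau, 0].
    """
    if any(b != 1.0 for b in spec.beta):
        raise SpecValidationError("closed-form seeding requires beta = 1")
    n = spec.n
    tau = spec.tau[0]
    cyc = cycle_schedule(spec.alpha[0], entry.tau_k)
    T = cyc.T
    theta = [(i * entry.p * T / n) % T for i in range(n)]
    x0 = [cyc.profile(th) for th in theta]
    # production of gene i is on exactly while phase(t + theta_i) is in (0, t2)
    on0 = [th < cyc.t2 for th in theta]
    pending = []
    if tau > 0.0:
        eps = 1e-9 * T  # a crossing at (numerically) t=0 still commits its toggle
        for i in range(n):
            r = (i - 1) % n
            for phase_c, direction in ((cyc.t1, "up"), (cyc.t3, "down")):
                # absolute times when the regulator crossed the threshold
                base = (phase_c - theta[r]) % T
                m = 0
                while True:
                    tc = base - m * T
                    if tc <= -tau:
                        break
                    if tc <= eps:
                        pending.append((tc + tau, i, direction == "down"))
                    m += 1
    return x0, on0, pending, cyc


def _validate_entry(spec: StepCircuitSpec, entry: FamilyEntry,
                    n_periods: int = 5, rel_tol: float = 1e-6) -> bool:
    """Seed the exact simulator on the implied orbit and confirm that the
    switching pattern persists with the predicted period."""
    try:
        x0, on0, pending, cyc = symmetric_cycle_seed(spec, entry)
    except (SpecValidationError, ValueError):
        return False
    T = cyc.T
    t_end = n_periods * T
    try:
        _, events = simulate_step_network(spec, x0, on0, pending, t_end,
                                          sample_dt=t_end / 10.0)
    except RuntimeError:
        return False
    for i in range(spec.n):
        ups = [e.time for e in events if e.gene == i and e.direction == "up"]
        downs = [e.time for e in events if e.gene == i and e.direction == "down"]
        if len(ups) < n_periods - 1 or len(downs) < n_periods - 1:
            return False
        for seq in (ups, downs):
            intervals = np.diff(seq)
            if np.any(np.abs(intervals - T) > rel_tol * T):
                return False
    return True


def symmetric_family_nd(
    alpha: float,
    tau: float,
    n: int,
    k_max: int = 3,
    validate: bool = True,
) -> list[FamilyEntry]:
    """Symmetric cycle candidates of the n-gene step ring (beta = 1).

    For each phase-shift numerator p = 1..n-1 and winding k >= 0, solves the
    fixed-point equation T = T_period(tau + (p/n - k) T); every root is then
    (optionally) validated by exact simulation seeded on the implied
    phase-shifted orbit.  Entries are returned validated and not.
    """
    _require_supercritical(alpha)
    if n < 2:
        raise ValueError("n must be >= 2")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    spec = StepCircuitSpec(n, alpha=alpha, beta=1.0, tau=tau)
    out = []
    for p in range(1, n):
        for k in range(k_max + 1):
            T = _solve_family_T(alpha, tau, p / n - k)
            if T is None:
                continue
            entry = FamilyEntry(k=k, p=p, tau_k=tau + (p / n - k) * T, T_k=T)
            if validate:
                entry.validated = _validate_entry(spec, entry)
            out.append(entry)
    return out
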