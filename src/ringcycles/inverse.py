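"""Closed-form parameter identification from switching times.

The delay-free 3-gene step ring (beta = 1, thresholds 1)

    dx/dt = L1(z) - x,   dy/dt = L2(x) - y,   dz/dt = L3(y) - z,

with all alpha_i > 1 has a unique limit cycle.  Along it each coordinate
alternates between exponential rise toward its alpha and exponential decay,
so one period is fully described by six switching times

    0 < t1 < t5 < t2 < t3 < t4 < T,

with the phase origin at x's *downward* crossing of the threshold:
x(0) = x(t2) = 1 (t2 upward), y(t1) = y(t3) = 1 (up, down),
z(t5) = z(t4) = 1 (down, up).  Chaining the exponential pieces between
these instants yields nine relations that can be solved in closed form for
the three production parameters alpha_1..alpha_3 and the six cycle extrema
— identification requires no iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .model_core import Trajectory
from .piecewise import StepEvent

__all__ = [
    "SwitchTimes3D",
    "RecoveredParams",
    "InfeasibleObservationError",
    "recover_parameters",
    "extract_switch_times",
    "switch_times_from_events",
    "perturb_observation",
    "recover_parameters_nd",
]


class InfeasibleObservationError(ValueError):
    """The switching times do not correspond to a valid cycle."""


@dataclass(frozen=True)
class SwitchTimes3D:
    """One period of switching times, in the fixed phase convention above."""

    t1: float
    t5: float
    t2: float
    t3: float
    t4: float
    T: float

    def __post_init__(self):
        seq = (0.0, self.t1, self.t5, self.t2, self.t3, self.t4, self.T)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise InfeasibleObservationError(
                f"switching times must satisfy 0 < t1 < t5 < t2 < t3 < t4 < T, got {seq[1:]}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveredParams:
    """Closed-form solution: production parameters and cycle extrema.

    Maxima (z1, y2, x4) exceed 1; minima (z3, y0, x5) lie in (0, 1); all
    alpha_i exceed 1 for a feasible observation.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    z1: float
    y2: float
    x4: float
    z3: float
    y0: float
    x5: float

    @property
    def alphas(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    def to_dict(self) -> dict:
        return asdict(self)


def recover_parameters(times: SwitchTimes3D) -> RecoveredParams:
    """Identify alpha_1..alpha_3 and the cycle extrema from switching times.

    Purely closed-form; raises :class:`InfeasibleObservationError` naming
    the violated relation when the observation cannot come from a cycle.
    """
    t1, t5, t2, t3, t4, T = times.t1, times.t5, times.t2, times.t3, times.t4, times.T

    z1 = math.exp(t5 - t1)
    z3 = math.exp(t5 - t3)
    alpha3 = -math.expm1(-(t4 - t5)) / -math.expm1(-(t4 - t3))

    y2 = math.exp(t3 - t2)
    y0 = y2 * math.exp(-(T - t2))
    alpha2 = (1.0 - y0 * math.exp(-t1)) / -math.expm1(-t1)

    x4 = math.exp(T - t4)
    x5 = x4 * math.exp(-(T - t4) - t5)  # = exp(-t5)
    alpha1 = (1.0 - x5 * math.exp(-(t2 - t5))) / -math.expm1(-(t2 - t5))

    checks = [
        ("z1 > 1 (maximum of z)", z1 > 1.0),
        ("z3 < 1 (minimum of z)", z3 < 1.0),
        ("y2 > 1 (maximum of y)", y2 > 1.0),
        ("y0 < 1 (minimum of y)", y0 < 1.0),
        ("x4 > 1 (maximum of x)", x4 > 1.0),
        ("x5 < 1 (minimum of x)", x5 < 1.0),
        ("alpha1 > 1", alpha1 > 1.0),
        ("alpha2 > 1", alpha2 > 1.0),
        ("alpha3 > 1", alpha3 > 1.0),
    ]
    for name, ok in checks:
        if not ok:
            raise InfeasibleObservationError(f"infeasible observation: {name} violated")
    return RecoveredParams(
        alpha1=alpha1, alpha2=alpha2, alpha3=alpha3,
        z1=z1, y2=y2, x4=x4, z3=z3, y0=y0, x5=x5,
    )


def switch_times_from_events(events: list[StepEvent], t_min: float = 0.0) -> SwitchTimes3D:
    """Cut one period out of an exact event schedule of the 3-gene ring.

    Uses the latest complete period before the end of the schedule (so the
    transient toward the unique cycle has died out when *t_min* is inside
    the converged regime).  Genes are (x, y, z) = (0, 1, 2).
    """
    ev = [e for e in events if e.time >= t_min]
    x_down = [e.time for e in ev if e.gene == 0 and e.direction == "down"]
    if len(x_down) < 3:
        raise InfeasibleObservationError(
            "trajectory has not settled on a cycle (too few x down-crossings)"
        )
    start, end = x_down[-3], x_down[-2]
    T = end - start
    window = [e for e in ev if start < e.time <= end]

    def one(gene, direction, what):
        hits = [e.time - start for e in window
                if e.gene == gene and e.direction == direction]
        if len(hits) != 1:
            raise InfeasibleObservationError(
                f"crossing pattern mismatch: expected one {what}, got {len(hits)}"
            )
        return hits[0]

    t1 = one(1, "up", "upward crossing of y")
    t5 = one(2, "down", "downward crossing of z")
    t2 = one(0, "up", "upward crossing of x")
    t3 = one(1, "down", "downward crossing of y")
    t4 = one(2, "up", "upward crossing of z")
    return SwitchTimes3D(t1=t1, t5=t5, t2=t2, t3=t3, t4=t4, T=T)


def extract_switch_times(traj: Trajectory) -> SwitchTimes3D:
    """Extract the six switching times from a converged 3-component trajectory.

    Works from the sampled trajectory (interpolated crossings); if the
    trajectory carries the exact event schedule of the event-driven solver
    the exact times are used instead.
    """
    from .dde_engine import threshold_crossings

    if traj.n != 3:
        raise ValueError(f"inverse problem needs a 3-component trajectory, got n={traj.n}")
    events = traj.meta.get("events")
    if events is not None:
        return switch_times_from_events(events)

    collected = []
    for gene in range(3):
        for direction in ("up", "down"):
            for t in threshold_crossings(traj, gene, 1.0, direction):
                collected.append(StepEvent(time=float(t), gene=gene, direction=direction))
    collected.sort(key=lambda e: e.time)
    return switch_times_from_events(collected)


def perturb_observation(times: SwitchTimes3D, noise_scale: float, seed: int) -> SwitchTimes3D:
    """Multiplicative jitter on the switching times, preserving the ordering.

    Each time is multiplied by (1 + noise_scale * u), u uniform on [-1, 1];
    draws violating the ordering are resampled (up to 100 tries).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.array([times.t1, times.t5, times.t2, times.t3, times.t4, times.T])
    for _ in range(100):
        jittered = base * (1.0 + noise_scale * rng.uniform(-1.0, 1.0, size=6))
        try:
            return SwitchTimes3D(*jittered)
        except InfeasibleObservationError:
            continue
    raise InfeasibleObservationError(
        "could not draw an ordering-preserving perturbation in 100 tries"
    )


def recover_parameters_nd(times, n: int):
    """Inverse problem for rings with n > 3 genes (not implemented).

    The block-transition combinatorics grows quickly with n; only the
    3-gene closed form is provided.
    """
    raise NotImplementedError("parameter identification is implemented for n=3 only")
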