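"""Model families and shared data structures for circular gene networks.

Two model families are supported, both describing a ring of ``n`` genetic
elements in which each element represses the next (and the last represses
the first), with a transcription/translation delay on every regulatory arm:

* the smooth Hill-type model, with repression response
  ``f_i(x) = alpha_i / (1 + x**h_i)``, and
* its infinite-cooperativity (Glass / step-function) limit, where repression
  becomes an on/off switch at the dimensionless threshold 1:
  ``L_i(x) = beta_i * alpha_i`` for ``x <= 1`` and ``0`` for ``x > 1``.

All quantities are dimensionless; time is normalised so that degradation
rates are O(1) (the closed-form machinery additionally assumes beta = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpecValidationError",
    "LengthMismatchError",
    "PositivityError",
    "NegativeDelayError",
    "HillCircuitSpec",
    "StepCircuitSpec",
    "HistorySegment",
    "Trajectory",
    "hill_response",
    "step_response",
    "validate_spec",
]


class SpecValidationError(ValueError):
    """Base class for model-specification validation failures."""


class LengthMismatchError(SpecValidationError):
    """A parameter list does not have length n."""


class PositivityError(SpecValidationError):
    """A parameter that must be strictly positive is not."""


class NegativeDelayError(SpecValidationError):
    """A regulatory delay is negative."""


def _as_tuple(x, n: int, name: str) -> tuple[float, ...]:
    if np.isscalar(x):
        return (float(x),) * n
    t = tuple(float(v) for v in x)
    if len(t) != n:
        raise LengthMismatchError(
            f"{name} has length {len(t)}, expected n={n}"
        )
    return t


@dataclass(frozen=True)
class HillCircuitSpec:
    """Parameters of the smooth ring model.

    dx_1/dt = alpha_1/(1 + x_n(t - tau_1)**h_n) - beta_1 x_1,
    dx_i/dt = alpha_i/(1 + x_{i-1}(t - tau_i)**h_{i-1}) - beta_i x_i.

    ``n = 1`` is the scalar autorepressor. Scalars passed for the per-gene
    lists are broadcast to length ``n``.
    """

    n: int
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    h: tuple[float, ...]
    tau: tuple[float, ...]

    def __init__(self, n, alpha, beta=1.0, h=1.0, tau=0.0):
        n = int(n)
        if n < 1:
            raise SpecValidationError(f"n must be a positive integer, got {n}")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "alpha", _as_tuple(alpha, n, "alpha"))
        object.__setattr__(self, "beta", _as_tuple(beta, n, "beta"))
        object.__setattr__(self, "h", _as_tuple(h, n, "h"))
        object.__setattr__(self, "tau", _as_tuple(tau, n, "tau"))
        _check_positive(self.alpha, "alpha")
        _check_positive(self.beta, "beta")
        _check_positive(self.h, "h")
        _check_delays(self.tau)

    @property
    def symmetric(self) -> bool:
        """True iff all genes share identical (alpha, beta, h, tau)."""
        return all(
            len(set(v)) == 1 for v in (self.alpha, self.beta, self.h, self.tau)
        )

    @property
    def max_delay(self) -> float:
        return max(self.tau)


@dataclass(frozen=True)
class StepCircuitSpec:
    """Parameters of the step-function (Glass) limit of the ring model.

    dx_i/dt = L_i(x_{i-1}(t - tau_i)) - beta_i x_i,  with
    L_i(x) = beta_i alpha_i for 0 <= x <= 1 and 0 for x > 1.

    The switching threshold is fixed at 1 (dimensionless); rescale states
    rather than the threshold.
    """

    n: int
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    tau: tuple[float, ...]

    threshold: float = field(default=1.0, init=False)

    def __init__(self, n, alpha, beta=1.0, tau=0.0):
        n = int(n)
        if n < 1:
            raise SpecValidationError(f"n must be a positive integer, got {n}")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "alpha", _as_tuple(alpha, n, "alpha"))
        object.__setattr__(self, "beta", _as_tuple(beta, n, "beta"))
        object.__setattr__(self, "tau", _as_tuple(tau, n, "tau"))
        object.__setattr__(self, "threshold", 1.0)
        _check_positive(self.alpha, "alpha")
        _check_positive(self.beta, "beta")
        _check_delays(self.tau)

    @property
    def symmetric(self) -> bool:
        return all(len(set(v)) == 1 for v in (self.alpha, self.beta, self.tau))

    @property
    def max_delay(self) -> float:
        return max(self.tau)


def _check_positive(values: Sequence[float], name: str) -> None:
    for i, v in enumerate(values):
        if not np.isfinite(v) or v <= 0:
            raise PositivityError(f"{name}[{i}] must be > 0, got {v}")


def _check_delays(values: Sequence[float]) -> None:
    for i, v in enumerate(values):
        if not np.isfinite(v) or v < 0:
            raise NegativeDelayError(f"tau[{i}] must be >= 0, got {v}")


@dataclass(frozen=True)
class HistorySegment:
    """Initial history x(t) for t in [-duration, 0].

    ``values`` is either a constant state vector (the common case) or a
    callable t -> state vector defined on [-duration, 0]. The duration must
    cover the largest delay of the spec the history is paired with.
    """

    duration: float
    values: tuple[float, ...] | Callable[[float], np.ndarray]

    def __init__(self, duration, values):
        duration = float(duration)
        if duration < 0:
            raise SpecValidationError("history duration must be >= 0")
        if not callable(values):
            values = tuple(float(v) for v in np.atleast_1d(values))
            if any(v < 0 or not np.isfinite(v) for v in values):
                raise SpecValidationError("history values must be finite and >= 0")
        object.__setattr__(self, "duration", duration)
        object.__setattr__(self, "values", values)

    @property
    def is_constant(self) -> bool:
        return not callable(self.values)

    def __call__(self, t: float) -> np.ndarray:
        if callable(self.values):
            return np.asarray(self.values(t), dtype=float)
        return np.asarray(self.values, dtype=float)

    def for_spec(self, spec) -> "HistorySegment":
        """Check compatibility with *spec* (dimension, delay coverage)."""
        if self.duration < spec.max_delay:
            raise SpecValidationError(
                f"history duration {self.duration} does not cover "
                f"max delay {spec.max_delay}"
            )
        if self.is_constant and len(self.values) not in (1, spec.n):
            raise SpecValidationError(
                f"history has {len(self.values)} components, spec has n={spec.n}"
            )
        if self.is_constant and len(self.values) == 1 and spec.n > 1:
            return HistorySegment(self.duration, self.values * spec.n)
        return self


@dataclass
class Trajectory:
    """A sampled solution: time grid, per-gene states, solver metadata."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states lengths differ")

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def component(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n:
            raise IndexError(f"component {i} out of range for n={self.n}")
        return self.states[:, i]

    def at(self, t: float) -> np.ndarray:
        """State vector at time t, cubic-Hermite interpolated when the solver
        stored derivatives (``meta["derivs"]``), else linearly."""
        t = float(t)
        if not self.times[0] <= t <= self.times[-1]:
            raise ValueError(f"t={t} outside trajectory span")
        derivs = self.meta.get("derivs")
        j = int(np.searchsorted(self.times, t, side="right")) - 1
        if j >= len(self.times) - 1:
            return self.states[-1].copy()
        if derivs is None:
            s = (t - self.times[j]) / (self.times[j + 1] - self.times[j])
            return (1 - s) * self.states[j] + s * self.states[j + 1]
        t0, t1 = self.times[j], self.times[j + 1]
        dt = t1 - t0
        s = (t - t0) / dt
        s2, s3 = s * s, s * s * s
        return (
            (2 * s3 - 3 * s2 + 1) * self.states[j]
            + (s3 - 2 * s2 + s) * dt * derivs[j]
            + (-2 * s3 + 3 * s2) * self.states[j + 1]
            + (s3 - s2) * dt * derivs[j + 1]
        )

    def write_tsv(self, path) -> None:
        header = "time\t" + "\t".join(f"x{i + 1}" for i in range(self.n))
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")

    @classmethod
    def read_tsv(cls, path) -> "Trajectory":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        data = np.atleast_2d(data)
        return cls(times=data[:, 0], states=data[:, 1:])


def hill_response(alpha: float, h: float, x: float):
    """Repression response f(x) = alpha / (1 + x**h).

    Strictly decreasing in x, with range (0, alpha].
    """
    if alpha <= 0 or h <= 0:
        raise PositivityError("alpha and h must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("x must be finite and >= 0")
    with np.errstate(over="ignore"):  # x**h overflow correctly yields f -> 0
        out = alpha / (1.0 + x**h)
    return float(out) if out.ndim == 0 else out


def step_response(alpha: float, beta: float, x: float) -> float:
    """Glass-limit response L(x) = beta*alpha for x <= 1, else 0.

    The value at the threshold x = 1 itself is beta*alpha (the "on" branch
    is closed on the right); trajectories sit on the threshold only at
    isolated instants, so the convention never affects integrals.
    """
    if alpha <= 0 or beta <= 0:
        raise PositivityError("alpha and beta must be > 0")
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise ValueError("x must be finite and >= 0")
    return beta * alpha if x <= 1.0 else 0.0


def validate_spec(spec):
    """Return *spec* with all invariants re-checked; idempotent.

    Construction already validates, so this re-runs the constructor checks
    (catching mutated or hand-built instances) and returns the spec.
    """
    if isinstance(spec, HillCircuitSpec):
        return HillCircuitSpec(spec.n, spec.alpha, spec.beta, spec.h, spec.tau)
    if isinstance(spec, StepCircuitSpec):
        return StepCircuitSpec(spec.n, spec.alpha, spec.beta, spec.tau)
    raise TypeError(f"not a circuit spec: {type(spec).__name__}")
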