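"""Leaky-integrator ("toy model") neurons and their simulation.

The basic unit is a non-spiking rate neuron, a dynamical extension of the
perceptron:

    tau * dy/dt = -y + f(sum_i w_i x_i + b)

with ``tau`` a timescale (higher = slower) and ``f`` a bounded monotone
activation.  All quantities, including time, are de-dimensionalized.  The
discrete-time counterpart obtained from a backward-difference discretization
with step ``Ts`` is

    y[n+1] = (1 - alpha) * y[n] + alpha * f(...),   alpha = (1 + tau/Ts)^-1

so ``alpha`` in (0, 1] plays the role of a per-unit leak rate; ``alpha = 1``
recovers the memoryless (static) perceptron.

This module provides the network containers, pulse-train stimuli, forward
Euler and exact discrete-time simulation, piecewise-exact fixed-point
enumeration, and threshold-event detection used by every model downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError, InvalidInputError, UnsupportedOperationError

DEFAULT_DT = 0.01
"""Default forward-Euler step, in de-dimensionalized time units."""

_ACT_CODES = {"piecewise_symmetric": 0, "piecewise_positive": 1, "logistic": 2}

try:  # optional JIT fast path; semantics identical to the numpy fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


# ---------------------------------------------------------------------------
# Activation functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationFunction:
    """A bounded, monotone non-decreasing activation.

    kind:
        ``piecewise_symmetric`` -- clips to [-1, 1], identity in between
        (a piecewise-linear stand-in for tanh);
        ``piecewise_positive`` -- clips to [0, 1], identity in between;
        ``logistic`` -- 1 / (1 + exp(-x)), range (0, 1).
    """

    kind: Literal["piecewise_symmetric", "piecewise_positive", "logistic"]

    def __post_init__(self):
        if self.kind not in _ACT_CODES:
            raise InvalidInputError(f"unknown activation kind: {self.kind!r}")

    @property
    def bounds(self) -> tuple[float, float]:
        """(min, max) of the function's range (closure for logistic)."""
        return (-1.0, 1.0) if self.kind == "piecewise_symmetric" else (0.0, 1.0)

    @property
    def code(self) -> int:
        return _ACT_CODES[self.kind]

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "piecewise_symmetric":
            return np.clip(x, -1.0, 1.0)
        if self.kind == "piecewise_positive":
            return np.clip(x, 0.0, 1.0)
        return 1.0 / (1.0 + np.exp(-x))

    def pieces(self) -> list[tuple[float, float, float, float]]:
        """Linear pieces as (z_lo, z_hi, intercept, slope) over the argument.

        Only defined for the piecewise kinds; used by the fixed-point
        enumerator, where on each piece f(z) = intercept + slope * z.
        """
        if self.kind == "piecewise_symmetric":
            return [(-np.inf, -1.0, -1.0, 0.0), (-1.0, 1.0, 0.0, 1.0),
                    (1.0, np.inf, 1.0, 0.0)]
        if self.kind == "piecewise_positive":
            return [(-np.inf, 0.0, 0.0, 0.0), (0.0, 1.0, 0.0, 1.0),
                    (1.0, np.inf, 1.0, 0.0)]
        raise UnsupportedOperationError("logistic activation has no linear pieces")


PIECEWISE_SYMMETRIC = ActivationFunction("piecewise_symmetric")
PIECEWISE_POSITIVE = ActivationFunction("piecewise_positive")
LOGISTIC = ActivationFunction("logistic")


def eval_activation(f: ActivationFunction, x: float) -> float:
    """Evaluate an activation at a scalar; rejects non-finite input."""
    if not np.isfinite(x):
        raise InvalidInputError(f"activation argument must be finite, got {x}")
    return float(f(x))


def tau_to_alpha(tau: float, ts: float) -> float:
    """Leak rate alpha = (1 + tau/Ts)^-1 of the discretized neuron.

    ``tau = 0`` gives alpha = 1 (the static perceptron limit); larger tau
    gives a slower, more persistent unit.
    """
    if ts <= 0:
        raise InvalidInputError(f"timestep Ts must be positive, got {ts}")
    if tau < 0:
        raise InvalidInputError(f"timescale tau must be >= 0, got {tau}")
    return 1.0 / (1.0 + tau / ts)


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseStimulus:
    """A rectangular pulse on one input channel, active on [onset, onset+duration)."""

    channel: int
    onset: float
    duration: float
    amplitude: float

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidInputError(f"pulse duration must be > 0, got {self.duration}")
        if self.channel < 0:
            raise InvalidInputError(f"channel must be >= 0, got {self.channel}")


@dataclass
class StimulusSchedule:
    """A set of pulses over ``n_channels`` input channels.

    The stimulus value on a channel at time t is the *sum* of the amplitudes
    of all pulses covering t (overlaps add), which is what amplitude-ratio
    scans rely on.
    """

    n_channels: int
    pulses: list[PulseStimulus] = field(default_factory=list)

    def __post_init__(self):
        for p in self.pulses:
            if p.channel >= self.n_channels:
                raise InvalidInputError(
                    f"pulse channel {p.channel} out of range for {self.n_channels} channels")

    def at(self, t: float) -> np.ndarray:
        u = np.zeros(self.n_channels)
        for p in self.pulses:
            if p.onset <= t < p.onset + p.duration:
                u[p.channel] += p.amplitude
        return u

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Evaluate on a grid of times; returns a (T, n_channels) array."""
        times = np.asarray(times, dtype=float)
        u = np.zeros((times.size, self.n_channels))
        for p in self.pulses:
            mask = (times >= p.onset) & (times < p.onset + p.duration)
            u[mask, p.channel] += p.amplitude
        return u

    @property
    def end_time(self) -> float:
        return max((p.onset + p.duration for p in self.pulses), default=0.0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_channels": self.n_channels,
                       "pulses": [vars(p) for p in self.pulses]}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StimulusSchedule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(n_channels=d["n_channels"],
                   pulses=[PulseStimulus(**p) for p in d["pulses"]])


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _check_matrix(name: str, a: np.ndarray, shape: tuple[int, ...]):
    if a.shape != shape:
        raise InvalidInputError(f"{name} must have shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} contains non-finite entries")


@dataclass
class ContinuousNetwork:
    """A coupled set of leaky-integrator neurons.

    ``W[j, i]`` is the weight from unit i onto unit j (rows index targets),
    so the recurrent drive on the state vector y is ``W @ y``.  ``W_in`` maps
    the m input channels into the units the same way.
    """

    W: np.ndarray
    W_in: np.ndarray
    b: np.ndarray
    tau: np.ndarray
    activation: ActivationFunction
    unit_names: list[str] | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        n = self.W.shape[0]
        _check_matrix("W", self.W, (n, n))
        _check_matrix("W_in", self.W_in, (n, self.W_in.shape[1]))
        _check_matrix("b", self.b, (n,))
        _check_matrix("tau", self.tau, (n,))
        if np.any(self.tau <= 0):
            raise InvalidInputError("all timescales tau must be strictly positive")
        if self.unit_names is not None and len(self.unit_names) != n:
            raise InvalidInputError("unit_names length must match n_units")

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    def names(self) -> list[str]:
        return self.unit_names or [f"y{i}" for i in range(self.n_units)]


@dataclass
class DiscreteNetwork:
    """Discrete-time counterpart with per-unit leak rates alpha in (0, 1]."""

    W: np.ndarray
    W_in: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    activation: ActivationFunction
    unit_names: list[str] | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        n = self.W.shape[0]
        _check_matrix("W", self.W, (n, n))
        _check_matrix("W_in", self.W_in, (n, self.W_in.shape[1]))
        _check_matrix("b", self.b, (n,))
        _check_matrix("alpha", self.alpha, (n,))
        if np.any(self.alpha <= 0) or np.any(self.alpha > 1):
            raise InvalidInputError("leak rates alpha must lie in (0, 1]")

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def names(self) -> list[str]:
        return self.unit_names or [f"x{i}" for i in range(self.n_units)]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A uniform time grid plus the per-unit state series on it."""

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray | None = None
    unit_names: list[str] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise InvalidInputError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise InvalidInputError("states rows must match times length")

    @property
    def n_units(self) -> int:
        return self.states.shape[1]

    def names(self) -> list[str]:
        return self.unit_names or [f"y{i}" for i in range(self.n_units)]

    def unit(self, idx: int) -> np.ndarray:
        return self.states[:, idx]

    def to_csv(self, path) -> None:
        cols = {"time": self.times}
        for i, name in enumerate(self.names()):
            cols[name] = self.states[:, i]
        if self.inputs is not None:
            for j in range(self.inputs.shape[1]):
                cols[f"u{j}"] = self.inputs[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        state_cols = [c for c in df.columns if c != "time" and not c.startswith("u")]
        in_cols = [c for c in df.columns if c.startswith("u")]
        return cls(times=df["time"].to_numpy(),
                   states=df[state_cols].to_numpy(),
                   inputs=df[in_cols].to_numpy() if in_cols else None,
                   unit_names=state_cols)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _euler_loop_py(W, W_in, b, tau, act_code, u, y0, dt):
    n_steps = u.shape[0]
    states = np.empty((n_steps + 1, y0.size))
    states[0] = y0
    y = y0.copy()
    for k in range(n_steps):
        z = W @ y + W_in @ u[k] + b
        if act_code == 0:
            fz = np.minimum(np.maximum(z, -1.0), 1.0)
        elif act_code == 1:
            fz = np.minimum(np.maximum(z, 0.0), 1.0)
        else:
            fz = 1.0 / (1.0 + np.exp(-z))
        y = y + dt * (-y + fz) / tau
        states[k + 1] = y
    return states


def _discrete_loop_py(W, W_in, b, alpha, act_code, u, x0):
    n_steps = u.shape[0]
    states = np.empty((n_steps + 1, x0.size))
    states[0] = x0
    x = x0.copy()
    for k in range(n_steps):
        z = W @ x + W_in @ u[k] + b
        if act_code == 0:
            fz = np.minimum(np.maximum(z, -1.0), 1.0)
        elif act_code == 1:
            fz = np.minimum(np.maximum(z, 0.0), 1.0)
        else:
            fz = 1.0 / (1.0 + np.exp(-z))
        x = (1.0 - alpha) * x + alpha * fz
        states[k + 1] = x
    return states


if _njit is not None:
    _euler_loop = _njit(_euler_loop_py)
    _discrete_loop = _njit(_discrete_loop_py)
else:  # pragma: no cover
    _euler_loop = _euler_loop_py
    _discrete_loop = _discrete_loop_py


def _first_bad_step(states: np.ndarray) -> int | None:
    bad = ~np.all(np.isfinite(states), axis=1)
    if bad.any():
        return int(np.argmax(bad))
    return None


def simulate_continuous(net: ContinuousNetwork,
                        stim: StimulusSchedule | None,
                        t_end: float,
                        dt: float = DEFAULT_DT,
                        y0: np.ndarray | None = None) -> Trajectory:
    """Forward-Euler integration of the coupled leaky-integrator ODEs.

    The input at each step is the schedule evaluated at the step's left
    endpoint.  Initial state defaults to all zeros.  Raises
    :class:`DivergenceError` naming the first step at which a state became
    non-finite.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be positive, got {dt}")
    if t_end <= 0:
        raise InvalidInputError(f"t_end must be positive, got {t_end}")
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    if stim is None:
        stim = StimulusSchedule(n_channels=net.n_inputs)
    if stim.n_channels != net.n_inputs:
        raise InvalidInputError(
            f"schedule has {stim.n_channels} channels, network expects {net.n_inputs}")
    u = stim.sample(times[:-1])
    if y0 is None:
        y0 = np.zeros(net.n_units)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (net.n_units,):
        raise InvalidInputError(f"y0 must have length {net.n_units}")
    states = _euler_loop(net.W, net.W_in, net.b, net.tau,
                         net.activation.code, u, y0, dt)
    bad = _first_bad_step(states)
    if bad is not None:
        raise DivergenceError(f"non-finite state at step {bad} (t={bad * dt:g})", step=bad)
    full_inputs = np.vstack([u, u[-1]]) if n_steps else np.zeros((1, net.n_inputs))
    return Trajectory(times=times, states=states, inputs=full_inputs,
                      unit_names=net.unit_names)


def simulate_discrete(net: DiscreteNetwork,
                      inputs: np.ndarray,
                      x0: np.ndarray | None = None) -> Trajectory:
    """Iterate x[n+1] = (I - A) x[n] + A f(W x[n] + W_in u[n] + b) exactly.

    ``inputs`` is a (T, m) series; the returned trajectory has T+1 rows
    (the initial state plus one per input step), indexed by step number.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[1] != net.W_in.shape[1]:
        raise InvalidInputError(
            f"inputs have {inputs.shape[1]} channels, network expects {net.W_in.shape[1]}")
    if not np.all(np.isfinite(inputs)):
        raise InvalidInputError("inputs contain non-finite values")
    if x0 is None:
        x0 = np.zeros(net.n_units)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n_units,):
        raise InvalidInputError(f"x0 must have length {net.n_units}")
    states = _discrete_loop(net.W, net.W_in, net.b, net.alpha,
                            net.activation.code, inputs, x0)
    bad = _first_bad_step(states)
    if bad is not None:
        raise DivergenceError(f"non-finite state at step {bad}", step=bad)
    return Trajectory(times=np.arange(states.shape[0], dtype=float),
                      states=states, unit_names=net.unit_names)


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    state: np.ndarray
    stability: Literal["stable", "unstable"]


def _classify(net: ContinuousNetwork, y: np.ndarray, const_input: np.ndarray,
              slope_fn) -> str:
    z = net.W @ y + net.W_in @ const_input + net.b
    D = np.diag(slope_fn(z))
    J = np.diag(1.0 / net.tau) @ (-np.eye(net.n_units) + D @ net.W)
    return "stable" if np.max(np.linalg.eigvals(J).real) < 0 else "unstable"


def find_fixed_points(net: ContinuousNetwork,
                      const_input: np.ndarray | Sequence[float] | None = None,
                      ) -> list[FixedPoint]:
    """Enumerate equilibria y = f(W y + W_in x + b) under constant input x.

    For the piecewise-linear activations the solutions are found exactly by
    solving the affine system on every combination of linear pieces and
    keeping the self-consistent ones.  For the logistic activation only a
    single unit is supported (dense grid bracketing + root refinement).
    Stability follows the eigenvalues of the local Jacobian (the sign of the
    local slope of the flow in 1-D).
    """
    if const_input is None:
        const_input = np.zeros(net.n_inputs)
    const_input = np.asarray(const_input, dtype=float)
    if const_input.shape != (net.n_inputs,):
        raise InvalidInputError(f"const_input must have length {net.n_inputs}")
    drive = net.W_in @ const_input + net.b
    act = net.activation

    if act.kind == "logistic":
        if net.n_units != 1:
            raise UnsupportedOperationError(
                "logistic fixed points supported for single units only")
        from scipy.optimize import brentq

        def g(y):
            return -y + float(act(net.W[0, 0] * y + drive[0]))

        lo, hi = act.bounds
        grid = np.linspace(lo - 0.5, hi + 0.5, 2001)
        vals = np.array([g(y) for y in grid])
        roots = []
        for i in range(grid.size - 1):
            if vals[i] == 0.0:
                roots.append(grid[i])
            elif vals[i] * vals[i + 1] < 0:
                roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
        def slope(z):
            s = 1.0 / (1.0 + np.exp(-z))
            return s * (1.0 - s)
        out = []
        for r in roots:
            y = np.array([r])
            out.append(FixedPoint(y, _classify(net, y, const_input, slope)))
        return out

    if net.n_units > 4:
        raise UnsupportedOperationError(
            "piecewise fixed-point enumeration supports at most 4 units")

    pieces = act.pieces()
    n = net.n_units
    tol = 1e-9
    found: list[FixedPoint] = []
    seen: set[tuple] = set()

    def piece_slope(z):
        # derivative of the piecewise activation (1 on the identity segment)
        lo_z, hi_z = pieces[1][0], pieces[1][1]
        return ((z > lo_z) & (z < hi_z)).astype(float)

    for assign in np.ndindex(*(len(pieces),) * n):
        c = np.array([pieces[a][2] for a in assign])
        d = np.array([pieces[a][3] for a in assign])
        A = np.eye(n) - d[:, None] * net.W
        rhs = c + d * drive
        try:
            y = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue  # continuum/degenerate piece combination
        z = net.W @ y + drive
        ok = all(pieces[a][0] - tol <= z[i] <= pieces[a][1] + tol
                 for i, a in enumerate(assign))
        if not ok:
            continue
        key = tuple(np.round(y, 8))
        if key in seen:
            continue
        seen.add(key)
        found.append(FixedPoint(y, _classify(net, y, const_input, piece_slope)))
    found.sort(key=lambda fp: tuple(fp.state))
    return found


# ---------------------------------------------------------------------------
# Threshold events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdEvent:
    unit: int
    time: float
    direction: Literal["up", "down"]
    threshold: float


def detect_threshold_events(traj: Trajectory, unit: int,
                            threshold: float) -> list[ThresholdEvent]:
    """Threshold crossings of one unit, times linearly interpolated.

    A sample exactly at threshold counts as a crossing in the direction of
    the next movement; a flat run at threshold produces no event.
    """
    y = traj.unit(unit)
    t = traj.times
    d = y - threshold
    events: list[ThresholdEvent] = []
    i = 0
    n = d.size
    while i < n - 1:
        if d[i] == 0.0:
            j = i
            while j < n and d[j] == 0.0:
                j += 1
            run = j - i
            if run == 1 and j < n:
                direction = "up" if d[j] > 0 else "down"
                events.append(ThresholdEvent(unit, float(t[i]), direction, threshold))
            i = j
            continue
        if d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            tc = t[i] + frac * (t[i + 1] - t[i])
            direction = "up" if d[i + 1] > d[i] else "down"
            events.append(ThresholdEvent(unit, float(tc), direction, threshold))
        i += 1
    return events


def first_crossing(traj: Trajectory, unit: int, threshold: float,
                   direction: str = "up") -> float | None:
    """Time of the first crossing in the given direction, or None."""
    for ev in detect_threshold_events(traj, unit, threshold):
        if ev.direction == direction:
            return ev.time
    return None
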