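"""Echo state network (ESN) construction, training, and the color-phi probe.

The ESN is a reservoir of N randomly connected discrete-time leaky
sigmoidal units,

    x[n+1] = (I - A) x[n] + A f(W_res x[n] + W_in u[n] + b),

with a trained linear readout Y = X W_out, where each row of X is the
state at one timestep with a constant 1 appended.  The reservoir weights
are drawn once at random (sparse normal, rescaled to a target spectral
radius below 1 so the network has fading memory) and never trained; only
W_out is fitted, by least squares, to a supervised protocol.

The task emulates a three-pixel, two-color visual display: 6 input
channels (3 positions x 2 colors) and 5 outputs (3 position + 2 color
indicators).  Training contains *valid* conditions (exactly one input
active; the matching position and color outputs should go high, with a
20-step allowance for the network to respond) and, in a later segment,
*invalid* conditions (several inputs at once; all outputs should stay
low).  Crucially, valid-condition transitions that jump left<->right while
changing color -- the stimulus pattern of the color phi illusion -- are
excluded from training, so any color-phi response of the trained network
is untrained, emergent behavior.

The color-phi probe alternates left-red and right-blue pulses with
shrinking gaps.  A network "shows the color phi phenomenon" (CPP) when,
inside a window after a jump, the *middle* position output rises above
threshold while the destination position output is still below it and the
destination color output is already above it: a ghost percept in the
middle carrying the new color before the second stimulus is itself
perceived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dynamics_core import tau_to_alpha  # noqa: F401  (re-exported companion)
from .errors import DivergenceError, InvalidInputError, ValidationError

logger = logging.getLogger("phidyn.esn")

INPUT_CHANNELS = ["left-red", "middle-red", "right-red",
                  "left-blue", "middle-blue", "right-blue"]
OUTPUT_CHANNELS = ["left", "middle", "right", "red", "blue"]
POSITIONS = ["left", "middle", "right"]
COLORS = ["red", "blue"]

#: valid condition -> (position-output index, color-output index)
def _condition_outputs(channel: int) -> tuple[int, int]:
    return channel % 3, 3 + channel // 3


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _esn_loop_py(W, proj, alpha, x0):
    n_steps, n = proj.shape
    X = np.empty((n_steps, n + 1))
    x = x0.copy()
    for k in range(n_steps):
        z = W @ x + proj[k]
        x = (1.0 - alpha) * x + alpha / (1.0 + np.exp(-z))
        X[k, :n] = x
        X[k, n] = 1.0
    return X


_esn_loop = _njit(_esn_loop_py) if _njit is not None else _esn_loop_py


# ---------------------------------------------------------------------------
# Configuration and model
# ---------------------------------------------------------------------------

@dataclass
class ESNConfig:
    """Reservoir hyperparameters.

    Defaults: N = 200 units; reservoir drawn N(0, 1) with 80% of entries
    zeroed and rescaled to spectral radius 0.9; input weights N(0, 0.5)
    with sparsity 0.8; leak rates alpha_i ~ U(0.1, 0.3); bias N(0, 0.5).
    """

    n_reservoir: int = 200
    res_sparsity: float = 0.8
    spectral_radius: float = 0.9
    res_sigma: float = 1.0
    in_sigma: float = 0.5
    in_sparsity: float = 0.8
    alpha_low: float = 0.1
    alpha_high: float = 0.3
    bias_sigma: float = 0.5
    n_in: int = 6
    n_out: int = 5
    seed: int = 0

    def __post_init__(self):
        for key in ("res_sparsity", "in_sparsity"):
            v = getattr(self, key)
            if not 0 <= v < 1:
                raise ValidationError(f"{key} must be in [0, 1), got {v}", key=key)
        if not 0 < self.alpha_low <= self.alpha_high <= 1:
            raise ValidationError(
                f"need 0 < alpha_low <= alpha_high <= 1, got "
                f"({self.alpha_low}, {self.alpha_high})", key="alpha_low")
        if self.spectral_radius <= 0:
            raise ValidationError("spectral_radius must be > 0", key="spectral_radius")
        if self.n_reservoir < 1:
            raise ValidationError("n_reservoir must be >= 1", key="n_reservoir")
        for key in ("res_sigma", "in_sigma", "bias_sigma"):
            if getattr(self, key) < 0:
                raise ValidationError(f"{key} must be >= 0", key=key)


@dataclass
class ESNModel:
    """A built (and possibly trained) echo state network."""

    W_res: np.ndarray
    W_in: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    config: ESNConfig
    W_out: np.ndarray | None = None
    eig_magnitudes: np.ndarray | None = None  # |eigenvalues| of W_res, post-scaling

    @property
    def n_reservoir(self) -> int:
        return self.W_res.shape[0]

    @property
    def trained(self) -> bool:
        return self.W_out is not None


def build_esn(cfg: ESNConfig) -> ESNModel:
    """Draw a reservoir from the config; fully reproducible from cfg.seed.

    Independent substreams (spawned from one seed sequence) drive the
    reservoir, input, leak-rate and bias draws, so each component is
    reproducible on its own.  A degenerate all-zero reservoir draw (which
    cannot be rescaled) is redrawn from the next substream.
    """
    ss = np.random.SeedSequence(cfg.seed)
    ss_res, ss_in, ss_alpha, ss_bias, ss_retry = ss.spawn(5)

    n = cfg.n_reservoir
    rng_res = np.random.default_rng(ss_res)
    W_res = rng_res.normal(0.0, cfg.res_sigma, (n, n))
    W_res[rng_res.random((n, n)) < cfg.res_sparsity] = 0.0
    eig = np.abs(np.linalg.eigvals(W_res))
    retries = 0
    while eig.max() == 0.0:  # degenerate draw; try the retry substream
        retries += 1
        logger.warning("degenerate zero reservoir for seed %s; redrawing (%d)",
                       cfg.seed, retries)
        rng_retry = np.random.default_rng(ss_retry.spawn(1)[0])
        W_res = rng_retry.normal(0.0, cfg.res_sigma, (n, n))
        W_res[rng_retry.random((n, n)) < cfg.res_sparsity] = 0.0
        eig = np.abs(np.linalg.eigvals(W_res))
        ss_retry = ss_retry.spawn(1)[0]
    scale = cfg.spectral_radius / eig.max()
    W_res *= scale

    rng_in = np.random.default_rng(ss_in)
    W_in = rng_in.normal(0.0, cfg.in_sigma, (n, cfg.n_in))
    W_in[rng_in.random((n, cfg.n_in)) < cfg.in_sparsity] = 0.0

    alpha = np.random.default_rng(ss_alpha).uniform(cfg.alpha_low, cfg.alpha_high, n)
    b = np.random.default_rng(ss_bias).normal(0.0, cfg.bias_sigma, n)
    return ESNModel(W_res=W_res, W_in=W_in, b=b, alpha=alpha, config=cfg,
                    eig_magnitudes=eig * scale)


# ---------------------------------------------------------------------------
# Running and training
# ---------------------------------------------------------------------------

@dataclass
class StateRecord:
    """Collected reservoir states (and outputs, once a readout exists).

    ``X`` is K x (N+1) with a constant-1 last column; row k is the state
    after input step k.  ``Y = X @ W_out`` is K x 5 when the model is
    trained.
    """

    X: np.ndarray
    Y: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return self.X.shape[0]


def run_esn(model: ESNModel, inputs: np.ndarray,
            x0: np.ndarray | None = None) -> StateRecord:
    """Drive the reservoir with a (K, 6) input series from state x0 (default 0)."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != model.config.n_in:
        raise InvalidInputError(
            f"inputs must be (K, {model.config.n_in}), got {inputs.shape}")
    if x0 is None:
        x0 = np.zeros(model.n_reservoir)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_reservoir,):
        raise InvalidInputError(f"x0 must have length {model.n_reservoir}")
    proj = inputs @ model.W_in.T + model.b
    X = _esn_loop(model.W_res, proj, model.alpha, x0)
    if not np.all(np.isfinite(X)):
        bad = int(np.argmax(~np.all(np.isfinite(X), axis=1)))
        raise DivergenceError(f"non-finite reservoir state at step {bad}", step=bad)
    Y = X @ model.W_out if model.trained else None
    return StateRecord(X=X, Y=Y)


def train_readout(model: ESNModel,
                  record: StateRecord | np.ndarray,
                  y_desired: np.ndarray,
                  washout: int = 200) -> ESNModel:
    """Fit the readout by least squares; returns a trained copy of the model.

    The minimum-norm least-squares solution of X W = Y_desired is used
    (falling back to ridge-stabilized normal equations if the direct solve
    fails); ``washout`` initial steps are excluded from the regression
    (pass 0 for the plain textbook normal-equations fit over all rows).
    """
    X = record.X if isinstance(record, StateRecord) else np.asarray(record, float)
    y_desired = np.asarray(y_desired, dtype=float)
    if y_desired.shape[0] != X.shape[0]:
        raise InvalidInputError("X and y_desired must have the same number of rows")
    if not 0 <= washout < X.shape[0]:
        raise InvalidInputError(f"washout must be in [0, K), got {washout}")
    Xw, Yw = X[washout:], y_desired[washout:]
    try:
        W_out, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
        if rank < X.shape[1]:
            logger.info("rank-deficient state matrix (rank %d < %d); "
                        "minimum-norm solution returned", rank, X.shape[1])
    except np.linalg.LinAlgError:  # pragma: no cover - numerical fallback
        G = Xw.T @ Xw + 1e-8 * np.eye(X.shape[1])
        W_out = np.linalg.solve(G, Xw.T @ Yw)
    return replace(model, W_out=W_out)


# ---------------------------------------------------------------------------
# Model persistence (directory of CSV matrices + JSON manifest)
# ---------------------------------------------------------------------------

def save_esn(model: ESNModel, directory) -> None:
    """Persist a model as plain CSV matrices plus a JSON manifest."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "W_res.csv", model.W_res, delimiter=",")
    np.savetxt(d / "W_in.csv", model.W_in, delimiter=",")
    np.savetxt(d / "b.csv", model.b, delimiter=",")
    np.savetxt(d / "alpha.csv", model.alpha, delimiter=",")
    if model.W_out is not None:
        np.savetxt(d / "W_out.csv", model.W_out, delimiter=",")
    manifest = {"config": vars(model.config),
                "trained": model.trained,
                "spectral_radius_achieved":
                    float(np.abs(np.linalg.eigvals(model.W_res)).max())}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_esn(directory) -> ESNModel:
    import json
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = ESNConfig(**manifest["config"])
    W_out = None
    if manifest.get("trained") and (d / "W_out.csv").exists():
        W_out = np.loadtxt(d / "W_out.csv", delimiter=",")
    return ESNModel(W_res=np.loadtxt(d / "W_res.csv", delimiter=","),
                    W_in=np.loadtxt(d / "W_in.csv", delimiter=","),
                    b=np.loadtxt(d / "b.csv", delimiter=","),
                    alpha=np.loadtxt(d / "alpha.csv", delimiter=","),
                    config=cfg, W_out=W_out)


# ---------------------------------------------------------------------------
# Training protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Timing and layout of the supervised training sequence.

    Pulses last ``pulse_len`` steps, separated by ``gap`` quiet steps so
    the reservoir settles between conditions; the desired output mirrors
    the input with a ``shift``-step onset delay.  Valid single-channel
    conditions run up to ``invalid_start``; invalid multi-channel
    conditions (all 15 channel pairs plus the all-on condition, cycled)
    fill the rest of the ``k_total`` steps with all-zero desired output.
    """

    pulse_len: int = 120
    gap: int = 180
    shift: int = 20
    k_total: int = 20000
    invalid_start: int = 13000
    amplitude: float = 1.0

    def __post_init__(self):
        if self.pulse_len < 1 or self.gap < 0:
            raise ValidationError("pulse_len must be >= 1 and gap >= 0",
                                  key="pulse_len")
        if not 0 <= self.shift < self.gap + self.pulse_len:
            raise ValidationError("shift must be shorter than one condition slot",
                                  key="shift")
        if not 0 < self.invalid_start <= self.k_total:
            raise ValidationError("need 0 < invalid_start <= k_total",
                                  key="invalid_start")


@dataclass(frozen=True)
class Segment:
    """One condition: input channels active on [start, start+pulse_len)."""

    start: int
    pulse_len: int
    channels: tuple[int, ...]
    valid: bool

    @property
    def end(self) -> int:
        return self.start + self.pulse_len


@dataclass
class LabelledSequence:
    inputs: np.ndarray    # K x 6
    desired: np.ndarray   # K x 5
    segments: list[Segment]


def _forbidden_transition(prev_channel: int, next_channel: int) -> bool:
    """True for left<->right jumps of opposite color (the CPP stimulus)."""
    p_pos, p_col = prev_channel % 3, prev_channel // 3
    n_pos, n_col = next_channel % 3, next_channel // 3
    return {p_pos, n_pos} == {0, 2} and p_col != n_col


def validate_condition_order(channels: Sequence[int]) -> None:
    """Raise if consecutive valid conditions form a CPP-inducing transition."""
    for prev, nxt in zip(channels[:-1], channels[1:]):
        if _forbidden_transition(prev, nxt):
            raise ValidationError(
                f"forbidden opposite-color left<->right transition: "
                f"{INPUT_CHANNELS[prev]} -> {INPUT_CHANNELS[nxt]}")


def invalid_condition_catalogue(n_in: int = 6) -> list[tuple[int, ...]]:
    """All unordered channel pairs plus the all-on condition."""
    pairs = [(i, j) for i in range(n_in) for j in range(i + 1, n_in)]
    return pairs + [tuple(range(n_in))]


def make_training_sequence(protocol: ProtocolSpec | None = None,
                           seed: int = 0) -> LabelledSequence:
    """Generate the valid/invalid supervised protocol.

    Valid conditions are drawn uniformly from the six single-channel
    stimuli, rejecting any draw that would form a forbidden opposite-color
    left<->right transition with the previous condition.  The desired
    output raises the condition's position and color channels to 1, shifted
    ``protocol.shift`` steps after stimulus onset, and is identically zero
    for invalid conditions.
    """
    p = protocol or ProtocolSpec()
    rng = np.random.default_rng(seed)
    K = p.k_total
    inputs = np.zeros((K, len(INPUT_CHANNELS)))
    desired = np.zeros((K, len(OUTPUT_CHANNELS)))
    segments: list[Segment] = []

    slot = p.pulse_len + p.gap
    start = p.gap  # lead-in gap before the first pulse
    prev: int | None = None
    while start + p.pulse_len <= p.invalid_start:
        while True:
            ch = int(rng.integers(0, len(INPUT_CHANNELS)))
            if prev is None or not _forbidden_transition(prev, ch):
                break
        inputs[start:start + p.pulse_len, ch] = p.amplitude
        pos, col = _condition_outputs(ch)
        d0 = start + p.shift
        d1 = min(start + p.pulse_len + p.shift, K)
        desired[d0:d1, pos] = 1.0
        desired[d0:d1, col] = 1.0
        segments.append(Segment(start, p.pulse_len, (ch,), valid=True))
        prev = ch
        start += slot

    catalogue = invalid_condition_catalogue(len(INPUT_CHANNELS))
    start = max(start, p.invalid_start + p.gap)
    i = 0
    while start + p.pulse_len <= K:
        chans = catalogue[i % len(catalogue)]
        for ch in chans:
            inputs[start:start + p.pulse_len, ch] = p.amplitude
        segments.append(Segment(start, p.pulse_len, tuple(chans), valid=False))
        i += 1
        start += slot

    validate_condition_order([s.channels[0] for s in segments if s.valid])
    return LabelledSequence(inputs=inputs, desired=desired, segments=segments)


# ---------------------------------------------------------------------------
# CPP probe and detection
# ---------------------------------------------------------------------------

@dataclass
class CPPProbeSpec:
    """Alternating left-red / right-blue pulses with shrinking gaps.

    ``gaps[i]`` is the quiet interval between pulse i and pulse i+1; the
    default shrinks from 150 steps to 0 in steps of 10.  Pulses never
    overlap (gaps must be non-negative and non-increasing).
    """

    pulse_len: int = 120
    gaps: tuple[int, ...] = tuple(range(150, -1, -10))
    lead_in: int = 200
    amplitude: float = 1.0
    start_channel: int = 0   # left-red
    jump_channel: int = 5    # right-blue

    def __post_init__(self):
        g = np.asarray(self.gaps)
        if g.size and np.any(g < 0):
            raise ValidationError("probe gaps must be non-negative "
                                  "(pulses may not overlap)", key="gaps")
        if g.size and np.any(np.diff(g) > 0):
            raise ValidationError("probe gaps must be non-increasing", key="gaps")


@dataclass(frozen=True)
class Transition:
    """One probe jump: the destination pulse starts at ``step``."""

    index: int
    step: int
    gap: int
    from_channel: int
    to_channel: int


def make_cpp_probe(spec: CPPProbeSpec | None = None
                   ) -> tuple[np.ndarray, list[Transition]]:
    """Build the probe input series and its per-jump annotations."""
    s = spec or CPPProbeSpec()
    n_pulses = len(s.gaps) + 1 if s.gaps else 0
    length = s.lead_in + n_pulses * s.pulse_len + int(np.sum(s.gaps))
    inputs = np.zeros((max(length, 1), len(INPUT_CHANNELS)))
    transitions: list[Transition] = []
    if n_pulses == 0:
        return inputs[:max(s.lead_in, 1)], transitions
    pos = s.lead_in
    ch = s.start_channel
    for i in range(n_pulses):
        inputs[pos:pos + s.pulse_len, ch] = s.amplitude
        if i < len(s.gaps):
            nxt = s.jump_channel if ch == s.start_channel else s.start_channel
            step = pos + s.pulse_len + s.gaps[i]
            transitions.append(Transition(index=i, step=step, gap=int(s.gaps[i]),
                                          from_channel=ch, to_channel=nxt))
            pos = step
            ch = nxt
    return inputs, transitions


@dataclass
class CPPDetection:
    detected: bool
    first_step: int | None = None
    transition_index: int | None = None
    outputs_at_detection: np.ndarray | None = None


def detect_cpp(record: StateRecord,
               transitions: Sequence[Transition],
               threshold: float = 0.5,
               window: int = 200,
               require_color: bool = True) -> CPPDetection:
    """Scan post-jump windows for the color-phi output signature.

    Detected at the first step, inside [jump, jump + window), where the
    middle output exceeds ``threshold`` while the destination-position
    output is still below it and (if ``require_color``) the
    destination-color output is already above it.  Direction-agnostic: the
    destination channels follow each transition's annotation.
    """
    if record.Y is None:
        raise InvalidInputError("record has no outputs; train the model first")
    Y = record.Y
    mid = OUTPUT_CHANNELS.index("middle")
    for tr in transitions:
        dest_pos, dest_col = _condition_outputs(tr.to_channel)
        if dest_pos == mid:
            continue  # a jump into the middle cannot define a middle ghost
        lo = tr.step
        hi = min(tr.step + window, Y.shape[0])
        if lo >= hi:
            continue
        seg = Y[lo:hi]
        cond = (seg[:, mid] > threshold) & (seg[:, dest_pos] < threshold)
        if require_color:
            cond &= seg[:, dest_col] > threshold
        if cond.any():
            k = int(np.argmax(cond))
            return CPPDetection(detected=True, first_step=lo + k,
                                transition_index=tr.index,
                                outputs_at_detection=seg[k].copy())
    return CPPDetection(detected=False)
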