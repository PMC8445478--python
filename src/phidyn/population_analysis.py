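"""Monte-Carlo screening of random ESNs for the color phi phenomenon.

Builds, trains and probes many independently seeded reservoirs, records
which ones show the CPP output signature, and summarizes network
characteristics (leak rates, reservoir eigenvalue magnitudes, the ratio of
excitatory to inhibitory synapses, and positive long-distance feedforward
motif counts) for the networks that do and do not show the effect.
Fractions carry binomial Wald confidence intervals, p +- z sqrt(p(1-p)/n).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .esn import (
    CPPProbeSpec,
    ESNConfig,
    ProtocolSpec,
    build_esn,
    detect_cpp,
    make_cpp_probe,
    make_training_sequence,
    run_esn,
    train_readout,
)

logger = logging.getLogger("phidyn.population")


# ---------------------------------------------------------------------------
# Network characteristics
# ---------------------------------------------------------------------------

def count_ldff(W: np.ndarray, mode: str = "two_hop") -> int:
    """Count positive long-distance feedforward (LDFF) connections.

    An ordered pair (i, j), i != j, is counted when unit i positively
    influences unit j both directly (W[j, i] > 0) and indirectly.
    ``mode="two_hop"`` (default) requires a two-step all-positive path
    i -> k -> j with k distinct from both; ``mode="reachability"`` accepts
    any all-positive path of length >= 2 (computed on the positive-weight
    digraph with the direct edge removed only in length, i.e. via transitive
    closure of paths of length >= 2).
    """
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidInputError(f"W must be square, got shape {W.shape}")
    P = (W > 0).astype(np.int64)
    np.fill_diagonal(P, 0)  # self-loops are neither direct nor valid hops
    if mode == "two_hop":
        indirect = (P @ P) > 0
    elif mode == "reachability":
        n = P.shape[0]
        step = (P @ P) > 0  # paths of length exactly 2
        reach = step.copy()
        for _ in range(n):  # longer simple paths cannot exceed n edges
            step = (step.astype(np.int64) @ P) > 0
            new = reach | step
            if (new == reach).all():
                break
            reach = new
        indirect = reach
    else:
        raise InvalidInputError(f"unknown LDFF mode: {mode!r}")
    direct = P.astype(bool)
    np.fill_diagonal(indirect, False)
    return int(np.sum(direct & indirect))


def excitatory_inhibitory_ratio(W: np.ndarray) -> float:
    """count(positive entries) / count(negative entries); NaN if no negatives.

    Structural zeros (sparsified-away synapses) are absences, not
    zero-strength synapses, and are excluded from both counts.
    """
    W = np.asarray(W)
    n_pos = int(np.sum(W > 0))
    n_neg = int(np.sum(W < 0))
    if n_neg == 0:
        logger.info("no inhibitory synapses; E/I ratio undefined")
        return float("nan")
    return n_pos / n_neg


def wald_interval(p: float, n: int, z: float = 1.96) -> float:
    """Half-width of the Wald binomial confidence interval, z*sqrt(p(1-p)/n)."""
    if not 0 <= p <= 1:
        raise InvalidInputError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    return z * float(np.sqrt(p * (1.0 - p) / n))


@dataclass
class NetworkCharacteristics:
    alphas: np.ndarray
    eig_magnitudes: np.ndarray
    ei_ratio: float
    ldff_count: int


def network_characteristics(model, ldff_mode: str = "two_hop") -> NetworkCharacteristics:
    """Characteristics of one built ESN (eigenvalues reuse the build-time ones)."""
    eig = model.eig_magnitudes
    if eig is None:
        eig = np.abs(np.linalg.eigvals(model.W_res))
    return NetworkCharacteristics(
        alphas=model.alpha.copy(),
        eig_magnitudes=np.sort(eig)[::-1],
        ei_ratio=excitatory_inhibitory_ratio(model.W_res),
        ldff_count=count_ldff(model.W_res, mode=ldff_mode))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-network rows plus the population CPP fraction and its Wald CI."""

    table: pd.DataFrame
    n_total: int
    n_with: int
    n_failed: int = 0
    z: float = 1.96
    alphas_with: list | None = None
    alphas_without: list | None = None
    eigs_with: list | None = None
    eigs_without: list | None = None

    @property
    def n_without(self) -> int:
        return self.n_total - self.n_with

    @property
    def fraction(self) -> float:
        return self.n_with / self.n_total

    @property
    def ci_halfwidth(self) -> float:
        return wald_interval(self.fraction, self.n_total, self.z)


def derive_network_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-network seeds derived from one master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def screen_population(cfg: ESNConfig,
                      n_networks: int,
                      master_seed: int = 0,
                      protocol: ProtocolSpec | None = None,
                      probe: CPPProbeSpec | None = None,
                      detection_threshold: float = 0.5,
                      detection_window: int = 200,
                      require_color: bool = True,
                      keep_vectors: bool = False,
                      out_csv=None,
                      progress: bool = False) -> ScreenResult:
    """Build -> train -> probe -> detect for ``n_networks`` random ESNs.

    All networks share one training sequence and probe (the experimental
    protocol); only the network draws differ, each from a seed derived
    deterministically from ``master_seed``.  Per-network characteristics
    are recorded alongside the CPP flag.  Rows are streamed to ``out_csv``
    (if given) as they are produced.  Networks whose simulation diverges
    are logged and excluded from the fraction's denominator; if they exceed
    0.1% of the population the screen aborts.
    """
    if n_networks < 1:
        raise InvalidInputError("n_networks must be >= 1")
    protocol = protocol or ProtocolSpec()
    probe = probe or CPPProbeSpec()
    seq = make_training_sequence(protocol, seed=master_seed)
    probe_inputs, transitions = make_cpp_probe(probe)
    seeds = derive_network_seeds(master_seed, n_networks)
    logger.debug("screen master_seed=%s -> first seeds %s", master_seed, seeds[:5])

    writer = None
    fh = None
    fieldnames = ["seed", "cpp_detected", "first_step", "transition_index",
                  "alpha_mean", "alpha_min", "alpha_max", "ei_ratio",
                  "ldff_count", "max_eig"]
    if out_csv is not None:
        fh = open(out_csv, "w", newline="")
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()

    rows = []
    n_failed = 0
    alphas_with, alphas_without, eigs_with, eigs_without = [], [], [], []
    iterator = range(n_networks)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="screening")
        except ImportError:  # pragma: no cover
            pass
    try:
        for i in iterator:
            seed = int(seeds[i])
            model = build_esn(replace(cfg, seed=seed))
            try:
                trained = train_readout(model, run_esn(model, seq.inputs),
                                        seq.desired)
                record = run_esn(trained, probe_inputs)
            except Exception as exc:  # divergence etc.; counted, not fatal
                n_failed += 1
                logger.warning("network seed %s failed: %s", seed, exc)
                if n_failed > max(1, 0.001 * n_networks):
                    raise RuntimeError(
                        f"{n_failed} network failures exceed 0.1% of the "
                        f"population; aborting") from exc
                continue
            det = detect_cpp(record, transitions, threshold=detection_threshold,
                             window=detection_window, require_color=require_color)
            chars = network_characteristics(model)
            row = {"seed": seed, "cpp_detected": bool(det.detected),
                   "first_step": det.first_step,
                   "transition_index": det.transition_index,
                   "alpha_mean": float(chars.alphas.mean()),
                   "alpha_min": float(chars.alphas.min()),
                   "alpha_max": float(chars.alphas.max()),
                   "ei_ratio": chars.ei_ratio,
                   "ldff_count": chars.ldff_count,
                   "max_eig": float(chars.eig_magnitudes.max())}
            rows.append(row)
            if writer is not None:
                writer.writerow(row)
                fh.flush()
            if keep_vectors:
                (alphas_with if det.detected else alphas_without).append(chars.alphas)
                (eigs_with if det.detected else eigs_without).append(chars.eig_magnitudes)
    finally:
        if fh is not None:
            fh.close()

    table = pd.DataFrame(rows, columns=fieldnames)
    return ScreenResult(table=table, n_total=len(rows),
                        n_with=int(table["cpp_detected"].sum()) if len(rows) else 0,
                        n_failed=n_failed,
                        alphas_with=alphas_with if keep_vectors else None,
                        alphas_without=alphas_without if keep_vectors else None,
                        eigs_with=eigs_with if keep_vectors else None,
                        eigs_without=eigs_without if keep_vectors else None)


# ---------------------------------------------------------------------------
# Characteristic comparison (descriptive, no inferential claim)
# ---------------------------------------------------------------------------

def _hist_pair(with_vals: np.ndarray, without_vals: np.ndarray, bins: int = 50):
    pooled = np.concatenate([with_vals, without_vals])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    h_with, _ = np.histogram(with_vals, bins=edges, density=True)
    h_without, _ = np.histogram(without_vals, bins=edges, density=True)
    # total-variation distance between the binned densities
    width = edges[1] - edges[0]
    tv = 0.5 * float(np.sum(np.abs(h_with - h_without)) * width)
    return {"edges": edges, "with": h_with, "without": h_without, "tv_distance": tv}


def compare_characteristics(result: ScreenResult, bins: int = 50) -> dict:
    """Pooled histograms of each characteristic split by CPP flag.

    Returns, per characteristic, fixed-bin histograms for both groups and a
    descriptive total-variation distance.  If a group is empty, only the
    other group's summary is returned, flagged under ``"empty_group"``.
    """
    t = result.table
    flag = t["cpp_detected"].astype(bool)
    out: dict = {"n_with": int(flag.sum()), "n_without": int((~flag).sum())}
    if out["n_with"] == 0 or out["n_without"] == 0:
        out["empty_group"] = "with" if out["n_with"] == 0 else "without"
        return out

    scalar_chars = ["ei_ratio", "ldff_count"]
    for name in scalar_chars:
        out[name] = _hist_pair(t.loc[flag, name].to_numpy(dtype=float),
                               t.loc[~flag, name].to_numpy(dtype=float), bins)
    if result.alphas_with and result.alphas_without:
        out["alphas"] = _hist_pair(np.concatenate(result.alphas_with),
                                   np.concatenate(result.alphas_without), bins)
        out["eig_magnitudes"] = _hist_pair(np.concatenate(result.eigs_with),
                                           np.concatenate(result.eigs_without), bins)
    return out


# ---------------------------------------------------------------------------
# Hyperparameter sweep
# ---------------------------------------------------------------------------

SWEEPABLE = ("res_sparsity", "in_sparsity", "spectral_radius", "in_sigma")


@dataclass
class SweepResult:
    parameter: str
    grid: list
    table: pd.DataFrame  # columns: value, n, p, ci_halfwidth


def hyperparameter_sweep(base_cfg: ESNConfig,
                         parameter: str,
                         grid: Sequence[float],
                         n_per_point: int = 200,
                         master_seed: int = 0,
                         protocol: ProtocolSpec | None = None,
                         probe: CPPProbeSpec | None = None,
                         progress: bool = False) -> SweepResult:
    """CPP fraction (with Wald CI) as a function of one network parameter.

    Each grid point is an independent screen of ``n_per_point`` networks
    with only that parameter changed from ``base_cfg``.
    """
    if parameter not in SWEEPABLE:
        raise InvalidInputError(
            f"parameter must be one of {SWEEPABLE}, got {parameter!r}")
    rows = []
    for value in grid:
        cfg = replace(base_cfg, **{parameter: value})
        res = screen_population(cfg, n_per_point, master_seed=master_seed,
                                protocol=protocol, probe=probe, progress=progress)
        rows.append({"value": value, "n": res.n_total, "p": res.fraction,
                     "ci_halfwidth": res.ci_halfwidth})
    return SweepResult(parameter=parameter, grid=list(grid),
                       table=pd.DataFrame(rows))
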