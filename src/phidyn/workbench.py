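"""Run configuration, result bundles, and named demonstration fixtures.

Ties the circuit models and the ESN screening into a reproducible tool:
a :class:`RunConfig` captures every tunable (JSON round-trippable, unknown
keys rejected), a :class:`ResultsBundle` stores output tables next to a
manifest whose hashes make tampering detectable, and the demo-fixture
registry packages the headline scenarios (masking onset-asynchrony flip,
the order-reversal region, the phi ghost) as small fast runs with recorded
qualitative assertions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .errors import CorruptionError, ValidationError
from .esn import CPPProbeSpec, ESNConfig, ProtocolSpec
from .microcircuits import MaskingModel, default_phi_params

logger = logging.getLogger("phidyn.workbench")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class MaskingParams:
    w1: float = 1.5
    w2: float = 1.5
    tau: float = 1.0

    def model(self) -> MaskingModel:
        return MaskingModel(w1=self.w1, w2=self.w2, tau=self.tau)


@dataclass
class ReversalParams:
    w_self_first: float = 2.0
    w_self_second: float = 2.0
    width: float = 10.0
    amp_a: float = 1.0
    amp_b: float = 1.0


@dataclass
class RunConfig:
    """All module parameters, defaulted to the packaged values."""

    seed: int = 0
    out_dir: str = "phidyn-results"
    log_level: str = "INFO"
    module: str = "esn"
    masking: MaskingParams = field(default_factory=MaskingParams)
    reversal: ReversalParams = field(default_factory=ReversalParams)
    phi: dict = field(default_factory=default_phi_params)
    esn: ESNConfig = field(default_factory=ESNConfig)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    probe: CPPProbeSpec = field(default_factory=CPPProbeSpec)

    def __post_init__(self):
        levels = {"DEBUG", "INFO", "WARNING", "ERROR"}
        if self.log_level not in levels:
            raise ValidationError(f"log_level must be one of {sorted(levels)}",
                                  key="log_level")


_NESTED = {"masking": MaskingParams, "reversal": ReversalParams,
           "esn": ESNConfig, "protocol": ProtocolSpec, "probe": CPPProbeSpec}


def _from_dict(cls, d: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in d.items():
        here = f"{path}{key}"
        if key not in fields:
            raise ValidationError(f"unknown config key: {here!r}", key=here)
        if key in _NESTED and cls is RunConfig:
            if not isinstance(value, dict):
                raise ValidationError(f"{here!r} must be an object", key=here)
            kwargs[key] = _from_dict(_NESTED[key], value, path=f"{here}.")
        elif key == "phi" and cls is RunConfig:
            defaults = default_phi_params()
            unknown = set(value) - set(defaults)
            if unknown:
                raise ValidationError(
                    f"unknown config key: 'phi.{sorted(unknown)[0]}'",
                    key=f"phi.{sorted(unknown)[0]}")
            defaults.update(value)
            kwargs[key] = defaults
        else:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    try:
        return cls(**kwargs)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"invalid config near {path or 'top level'}: {exc}") from exc


def config_to_dict(cfg: RunConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg)))


def load_config(path) -> RunConfig:
    """Read a JSON config; missing keys take the packaged defaults."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValidationError("config root must be a JSON object")
    return _from_dict(RunConfig, data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=1))


# ---------------------------------------------------------------------------
# Results bundles
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class ResultsBundle:
    """Output tables plus the manifest needed to reproduce them."""

    config: dict
    seed: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def save_bundle(bundle: ResultsBundle, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table_meta = {}
    for name, df in bundle.tables.items():
        p = d / f"{name}.csv"
        df.to_csv(p, index=False)
        table_meta[name] = {"path": p.name, "sha256": _sha256(p)}
    manifest = {"version": __version__,
                "created": datetime.now(timezone.utc).isoformat(),
                "seed": bundle.seed,
                "config": bundle.config,
                "summary": bundle.summary,
                "tables": table_meta}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return d


def load_bundle(directory) -> ResultsBundle:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    tables = {}
    for name, meta in manifest["tables"].items():
        p = d / meta["path"]
        digest = _sha256(p)
        if digest != meta["sha256"]:
            raise CorruptionError(
                f"table {name!r} hash mismatch: manifest {meta['sha256'][:12]}..., "
                f"file {digest[:12]}...")
        tables[name] = pd.read_csv(p)
    return ResultsBundle(config=manifest["config"], seed=manifest["seed"],
                         tables=tables, summary=manifest.get("summary", {}))


# ---------------------------------------------------------------------------
# Demo fixtures
# ---------------------------------------------------------------------------

@dataclass
class DemoFixture:
    """A named fast scenario with recorded qualitative assertions.

    ``run()`` executes the scenario and returns its outcomes; ``verify()``
    re-runs it and returns a list of violated assertions (empty = pass).
    """

    name: str
    description: str
    runner: Callable[[], dict]
    checker: Callable[[dict], list[str]]

    def run(self) -> dict:
        return self.runner()

    def verify(self) -> list[str]:
        return self.checker(self.run())


def _masking_soa_fixture() -> dict:
    from .microcircuits import masking_delay_scan
    table = masking_delay_scan(MaskingModel(), delays=np.arange(0.5, 6.1, 0.5))
    return {"outcomes": table["outcome"].tolist()}


def _masking_soa_check(out: dict) -> list[str]:
    flips = int(np.sum(np.diff(out["outcomes"]) != 0))
    problems = []
    if flips != 1:
        problems.append(f"expected exactly one outcome flip along the delay "
                        f"grid, found {flips}")
    if out["outcomes"][0] != -1 or out["outcomes"][-1] != 1:
        problems.append("expected masked (-1) at short delays and surviving "
                        "prime (+1) at long delays")
    return problems


def _reversal_scan_fixture() -> dict:
    from .microcircuits import build_reversal_circuit, reversal_interval_scan
    circ = build_reversal_circuit()
    _, bounds = reversal_interval_scan(circ, np.arange(-20.0, 20.5, 4.0))
    return {"bounds": bounds}


def _reversal_scan_check(out: dict) -> list[str]:
    lo, hi = out["bounds"]
    problems = []
    if lo is None or hi is None:
        problems.append("reversal region not found")
    elif not (lo < 0 < hi):
        problems.append(f"reversal region {out['bounds']} does not straddle 0")
    return problems


def _phi_ghost_fixture() -> dict:
    from .microcircuits import build_phi_circuit, run_phi_experiment
    circ = build_phi_circuit()
    fast = run_phi_experiment(circ, interval=15.0)
    slow = run_phi_experiment(circ, interval=60.0)
    return {"fast_ghost": fast.ghost_present, "fast_ordering": fast.ordering_ok,
            "slow_ghost": slow.ghost_present}


def _phi_ghost_check(out: dict) -> list[str]:
    problems = []
    if not out["fast_ghost"]:
        problems.append("no ghost for the fast stimulus interval")
    if not out["fast_ordering"]:
        problems.append("ghost not ordered between y_a and y_c crossings")
    if out["slow_ghost"]:
        problems.append("ghost appeared for the slow stimulus interval")
    return problems


_REGISTRY: dict[str, DemoFixture] = {}
for _name, _desc, _run, _check in [
    ("masking-soa", "backward masking flips outcome once along the "
     "prime-to-mask delay grid", _masking_soa_fixture, _masking_soa_check),
    ("reversal-scan", "order-reversal region is a finite interval "
     "straddling zero", _reversal_scan_fixture, _reversal_scan_check),
    ("phi-ghost", "middle-output ghost for fast but not slow outer-pixel "
     "stimulation", _phi_ghost_fixture, _phi_ghost_check),
]:
    _REGISTRY[_name] = DemoFixture(_name, _desc, _run, _check)


def make_demo_fixture(name: str) -> DemoFixture:
    """Look up a demo fixture by name; lists the registry on a miss."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(_REGISTRY)}")
    return _REGISTRY[name]


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)
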