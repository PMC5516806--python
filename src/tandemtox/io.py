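"""Parameter files, stable CSV output and run records.

Parameter sets are flat YAML mappings (uM / min units, matching the
dataclass field names); unknown keys are rejected so typos fail loudly.
CSV output uses 9 significant digits, '.' decimal and UTF-8, which makes
repeat runs byte-identical and diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Any, Type

import pandas as pd
import yaml

from tandemtox.models.glutathione import GshParams
from tandemtox.models.glycogen import GlycogenParams
from tandemtox.models.ppp import PppParams

__all__ = [
    "load_params",
    "save_params",
    "reference_params_path",
    "write_csv",
    "RunRecord",
]

PARAM_CLASSES: dict[str, type] = {
    "glycogen": GlycogenParams,
    "ppp": PppParams,
    "gsh": GshParams,
}

_FLOAT_FORMAT = "%.9g"


def load_params(model: str, path: str | Path | None = None):
    """Load a model parameter set; defaults to the packaged reference file."""
    cls = _param_class(model)
    if path is None:
        path = reference_params_path(model)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {model} parameters in {path}: {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in raw.items()})


def save_params(params: Any, path: str | Path) -> None:
    """Write a parameter dataclass as a flat YAML mapping."""
    data = {f.name: getattr(params, f.name) for f in dataclasses.fields(params)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def reference_params_path(model: str) -> Path:
    """Path of the packaged reference parameter file for `model`."""
    _param_class(model)
    return Path(str(resources.files("tandemtox").joinpath(f"data/{model}_reference.yaml")))


def _param_class(model: str) -> Type:
    if model not in PARAM_CLASSES:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(PARAM_CLASSES)}")
    return PARAM_CLASSES[model]


def load_chain(path: str | Path | None = None):
    """Build a TandemChain (plus its drug grid) from a chain config YAML.

    Returns ``(chain, drug_grid, vite_pool)``.  Paths inside the config are
    resolved relative to the config file's directory.
    """
    from tandemtox.tandem import InterfaceSpec, TandemChain

    if path is None:
        path = Path(str(resources.files("tandemtox").joinpath("data/tandem_reference.yaml")))
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    params = {}
    for model in PARAM_CLASSES:
        entry = (cfg.get("models") or {}).get(model)
        if entry is None:
            params[model] = _param_class(model)()
        else:
            entry_path = Path(entry)
            if not entry_path.is_absolute():
                entry_path = path.parent / entry_path
            params[model] = load_params(model, entry_path)

    interfaces = tuple(
        InterfaceSpec(
            upstream_model=spec["upstream"],
            downstream_model=spec["downstream"],
            species_map=tuple((k, v) for k, v in spec["map"].items()),
            coupling_mode=spec.get("mode", "fold-change"),
        )
        for spec in cfg["interfaces"]
    )
    grid = [float(d) for d in cfg["drug_grid_uM"]]
    vite = float(cfg.get("vite_pool_uM", 0.0))
    if vite > 0:
        params["gsh"] = dataclasses.replace(params["gsh"], vite_pool=vite)
    chain = TandemChain(
        glycogen=params["glycogen"], ppp=params["ppp"], gsh=params["gsh"],
        interfaces=interfaces,
    )
    return chain, grid, vite


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a frame with the package's stable CSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT, encoding="utf-8")
    return path


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunRecord:
    """Reproducibility record emitted next to every CLI run's outputs."""

    stage: str
    config: dict
    version: str
    status: str = "ok"
    started: str = ""
    finished: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)

    def start(self) -> "RunRecord":
        self.started = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        return self

    def finish(self, status: str = "ok") -> "RunRecord":
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        self.status = status
        return self

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
        return path
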