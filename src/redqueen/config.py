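"""Run configuration: validated specs, YAML loading, shipped presets."""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discrete_time import DT_MODELS
from .reaction_systems import MODEL_NAMES, ModelParams

__all__ = ["RunSpec", "load_config", "load_preset", "list_presets", "write_output"]

KINDS = ("simulate", "ensemble", "exact-dt", "ode", "sweep", "diversity")

_PARAM_KEYS = (
    "w_H",
    "w_P",
    "alpha",
    "beta",
    "b_H",
    "d_P",
    "lam",
    "lam0",
    "comp_rate",
    "K",
    "mut_H",
    "mut_P",
)
_SPEC_KEYS = {
    "kind",
    "model",
    "n",
    "N_H",
    "N_P",
    "seed",
    "n_reps",
    "t_max",
    "max_steps",
    "n_max",
    "with_mutation",
    "sweep",
    "out",
    *_PARAM_KEYS,
}


@dataclass
class RunSpec:
    """A fully validated experiment specification.

    Derived parameters (``lam`` from ``lam0 / K``, ``comp_rate`` from
    ``b_H / K``) are resolved at construction and echoed back by
    :meth:`to_dict`, so any output is re-runnable from its own
    metadata.  A seed is always required (reproducibility contract).
    """

    kind: str
    model: str
    n: int
    params: ModelParams
    seed: int
    N_H: int = 0
    N_P: int = 0
    n_reps: int = 1
    t_max: float = math.inf
    max_steps: float = math.inf
    n_max: float = math.inf
    with_mutation: bool = False
    sweep: dict | None = None
    out: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; choose from {KINDS}")
        known = MODEL_NAMES + DT_MODELS
        if self.model and self.model not in known:
            raise ValueError(f"unknown model {self.model!r}; choose from {known}")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "model": self.model,
            "n": self.n,
            "N_H": self.N_H,
            "N_P": self.N_P,
            "seed": self.seed,
            "n_reps": self.n_reps,
            "with_mutation": self.with_mutation,
        }
        for key in ("t_max", "max_steps", "n_max"):
            v = getattr(self, key)
            if math.isfinite(v):
                d[key] = v
        if self.sweep is not None:
            d["sweep"] = self.sweep
        if self.out is not None:
            d["out"] = self.out
        d.update({k: v for k, v in self.params.as_dict().items() if v is not None})
        return d


def _spec_from_dict(raw: dict, source: str) -> RunSpec:
    unknown = set(raw) - _SPEC_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    if "seed" not in raw or raw["seed"] is None:
        raise ValueError(f"{source}: an explicit seed is required")
    params = ModelParams(**{k: raw[k] for k in _PARAM_KEYS if k in raw})
    return RunSpec(
        kind=raw.get("kind", "simulate"),
        model=raw.get("model", ""),
        n=int(raw.get("n", 2)),
        params=params,
        seed=raw["seed"],
        N_H=int(raw.get("N_H", 0)),
        N_P=int(raw.get("N_P", 0)),
        n_reps=int(raw.get("n_reps", 1)),
        t_max=float(raw.get("t_max", math.inf)),
        max_steps=float(raw.get("max_steps", math.inf)),
        n_max=float(raw.get("n_max", math.inf)),
        with_mutation=bool(raw.get("with_mutation", False)),
        sweep=raw.get("sweep"),
        out=raw.get("out"),
    )


def load_config(path: str | Path) -> RunSpec:
    """Load and validate a YAML run specification.

    Unknown keys are rejected; derived parameters are resolved
    (explicit ``lam`` wins over ``lam0 / K``; inconsistent combinations
    raise).  ``serialize -> load`` round-trips to an equivalent spec.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _spec_from_dict(raw, str(path))


def save_config(spec: RunSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def list_presets() -> list[str]:
    res = importlib.resources.files("redqueen.presets")
    return sorted(p.name[: -len(".yaml")] for p in res.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a shipped parameter preset (``fig1``, ``fig3``, ``fig4``).

    Returns a dict with resolved ``params`` (a :class:`ModelParams`),
    the genotype count ``n``, initial sizes where defined, and for the
    sweep preset the per-model sweep axes.
    """
    res = importlib.resources.files("redqueen.presets")
    try:
        raw = yaml.safe_load((res / f"{name}.yaml").read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}; available: {list_presets()}") from None
    params = ModelParams(**{k: raw[k] for k in _PARAM_KEYS if k in raw})
    out = {
        "name": name,
        "params": params,
        "n": int(raw.get("n", 2)),
        "N_H": int(raw["N_H"]) if "N_H" in raw else None,
        "N_P": int(raw["N_P"]) if "N_P" in raw else None,
        "model": raw.get("model"),
        "sweep": raw.get("sweep"),
    }
    return out


def write_output(frame: pd.DataFrame, out: str | Path, spec: RunSpec | dict) -> Path:
    """Write a tidy CSV plus a JSON sidecar embedding the resolved spec."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    meta = spec.to_dict() if isinstance(spec, RunSpec) else dict(spec)
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default) + "\n")
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
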