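"""Run-configuration parsing and result serialization.

A single YAML (or JSON) config file fully determines an experiment:
lattice geometry, rule timescales, initial damage, replica count, seed,
horizon, optional parameter axes for sweeps and optional perturbation
schedule.  Validation happens before any simulation starts and names the
offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .core import Parameters
from .init_conditions import InitSpec, init_pericentral
from .lattice import Lattice, build_chain, build_hex_lobule, build_hex_stack
from .perturb import Perturbation

__all__ = [
    "load_config",
    "lattice_from_config",
    "params_from_config",
    "init_from_config",
    "perturbations_from_config",
    "axis_from_config",
]


class ConfigError(ValueError):
    """Invalid or missing configuration field."""


def _require(mapping: dict, field: str, where: str):
    if field not in mapping:
        raise ConfigError(f"missing required field '{where}.{field}'")
    return mapping[field]


def load_config(path) -> dict:
    """Read a YAML/JSON config file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return cfg


def lattice_from_config(cfg: dict) -> Lattice:
    geo = _require(cfg, "geometry", "config")
    kind = _require(geo, "kind", "geometry")
    if kind == "chain":
        return build_chain(_require(geo, "n", "geometry"))
    if kind == "hex_lobule":
        return build_hex_lobule(_require(geo, "nl", "geometry"))
    if kind == "hex_stack":
        return build_hex_stack(
            _require(geo, "nl", "geometry"), _require(geo, "planes", "geometry")
        )
    raise ConfigError(f"unknown geometry.kind: {kind!r}")


def params_from_config(cfg: dict) -> Parameters:
    p = _require(cfg, "params", "config")
    try:
        return Parameters(
            alpha=float(_require(p, "alpha", "params")),
            beta=float(_require(p, "beta", "params")),
            gamma=float(_require(p, "gamma", "params")),
            dt=float(p.get("dt", 0.25)),
            epsilon=float(p.get("epsilon", 0.0)),
            neighbor_order=p.get("neighbor_order", "first"),
            division_cap=p.get("division_cap"),
            update_order=p.get("update_order", "conversion_first"),
            same_step_vacancies=bool(p.get("same_step_vacancies", True)),
            t_norm=p.get("t_norm", "auto"),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid params: {exc}") from exc


def init_from_config(cfg: dict) -> InitSpec:
    ini = _require(cfg, "init", "config")
    mode = _require(ini, "mode", "init")
    try:
        return InitSpec(
            mode=mode,
            stressed_count=int(ini.get("stressed_count", 0)),
            stressed_layers=int(ini.get("stressed_layers", 0)),
            stress_probability=float(ini.get("stress_probability", 0.8)),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid init: {exc}") from exc


def perturbations_from_config(cfg: dict, base_params: Parameters) -> list[Perturbation]:
    out = []
    for i, p in enumerate(cfg.get("perturbations", []) or []):
        kind = _require(p, "kind", f"perturbations[{i}]")
        if kind == "state_convert":
            out.append(
                Perturbation(
                    at_time=float(_require(p, "at_time", f"perturbations[{i}]")),
                    kind=kind,
                    from_state=_require(p, "from", f"perturbations[{i}]"),
                    to_state=_require(p, "to", f"perturbations[{i}]"),
                    fraction=p.get("fraction", 1.0),
                )
            )
        elif kind == "param_switch":
            new = _require(p, "params", f"perturbations[{i}]")
            merged = {
                "alpha": new.get("alpha", base_params.alpha),
                "beta": new.get("beta", base_params.beta),
                "gamma": new.get("gamma", base_params.gamma),
            }
            out.append(
                Perturbation(
                    at_time=float(_require(p, "at_time", f"perturbations[{i}]")),
                    kind=kind,
                    new_params=base_params.with_ratios(**merged),
                )
            )
        else:
            raise ConfigError(f"unknown perturbation kind: {kind!r}")
    return out


def axis_from_config(ax: dict, where: str) -> tuple[str, np.ndarray]:
    """Parse a sweep axis: {param, start, stop, step} -> (name, values)."""
    param = _require(ax, "param", where)
    if param not in ("alpha", "beta", "gamma"):
        raise ConfigError(f"{where}.param must be alpha/beta/gamma, got {param!r}")
    start = float(_require(ax, "start", where))
    stop = float(_require(ax, "stop", where))
    step = float(_require(ax, "step", where))
    if step <= 0 or stop < start:
        raise ConfigError(f"{where}: need step > 0 and stop >= start")
    values = np.arange(start, stop + step / 2, step)
    if values.size == 0:
        raise ConfigError(f"{where}: empty axis")
    return param, values


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def build_initial(lattice: Lattice, spec: InitSpec, master_seed):
    """Initial state or per-replica initializer for randomized modes."""
    if spec.mode == "asymmetric_layers":
        return lambda lat, rng: init_pericentral(lat, spec, rng)
    return init_pericentral(lattice, spec)
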