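"""Structured YAML configuration for the command-line tool.

A config file has up to four blocks::

    geometry:
      units: cm          # "cm" (lengths cm, areas cm^2, default) or "m"
      d1: 10
      d2: 6
      d3: 6
      dd: 33
      S1: 1.0
      S2: 0.9
      S3: 0.9
      Sd: 1.0
      n_cells: 10
    mixture:
      kind: deb          # "deb" (with optional enrichment), "species",
      enrichment: 0      #   or "fractions"
    scan:
      f_start: 0.5
      f_stop: 3000
      step: 0.05
    sweep:
      parameter: d2
      values: [5.8, 6.0, 6.5, 7.0]   # in geometry units

Configs written in cm and in m that denote the same physical sensor resolve
to identical SI geometries and hence byte-identical outputs.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

from .gases import (GasMixture, builtin_species, deb_mixture)
from .sweeps import SweepSpec
from .tmm import SensorGeometry, initial_geometry, optimized_geometry

__all__ = ["load_config", "parse_geometry", "parse_mixture", "parse_scan",
           "parse_sweep", "fixture_configs", "dump_config"]

_GEOM_KEYS = ("d1", "d2", "d3", "dd", "S1", "S2", "S3", "Sd")


class ConfigError(ValueError):
    pass


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError("config root must be a mapping")
    return dict(cfg)


def _unit_factors(units: str) -> tuple[float, float]:
    if units == "cm":
        return 1e-2, 1e-4
    if units == "m":
        return 1.0, 1.0
    raise ConfigError(f"geometry units must be 'cm' or 'm', got {units!r}")


def parse_geometry(block: Mapping[str, Any]) -> SensorGeometry:
    units = str(block.get("units", "cm"))
    flen, farea = _unit_factors(units)
    missing = [k for k in _GEOM_KEYS if k not in block]
    if missing:
        raise ConfigError(f"geometry block missing keys: {missing}")
    kw = {k: float(block[k]) * (flen if k.startswith("d") else farea)
          for k in _GEOM_KEYS}
    return SensorGeometry(**kw, n_cells=int(block.get("n_cells", 10)))


def parse_mixture(block: Mapping[str, Any] | None) -> GasMixture:
    if block is None:
        return deb_mixture(0)
    kind = str(block.get("kind", "deb")).lower()
    if kind == "deb":
        return deb_mixture(float(block.get("enrichment", 0)))
    if kind == "species":
        name = block["name"]
        table = builtin_species()
        if name not in table:
            raise ConfigError(f"unknown species {name!r}")
        return GasMixture([(table[name], 1.0)])
    if kind == "fractions":
        return GasMixture.from_volumes(dict(block["fractions"]))
    raise ConfigError(f"unknown mixture kind {kind!r}")


def parse_scan(block: Mapping[str, Any] | None) -> dict[str, float]:
    block = block or {}
    scan = {"f_start": float(block.get("f_start", 0.5)),
            "f_stop": float(block.get("f_stop", 3000.0)),
            "step": float(block.get("step", 0.05))}
    if not (0 < scan["f_start"] < scan["f_stop"]):
        raise ConfigError("scan requires 0 < f_start < f_stop")
    if scan["step"] <= 0:
        raise ConfigError("scan step must be positive")
    return scan


def parse_sweep(block: Mapping[str, Any], geometry_block: Mapping[str, Any],
                mixture_block: Mapping[str, Any] | None = None) -> SweepSpec:
    base = parse_geometry(geometry_block)
    units = str(geometry_block.get("units", "cm"))
    flen, farea = _unit_factors(units)
    param = str(block["parameter"])
    factor = flen if param.startswith("d") else farea
    values = tuple(float(v) * factor for v in block["values"])
    lo = parse_mixture(mixture_block)
    hi = parse_mixture({**(mixture_block or {"kind": "deb"}),
                        "enrichment": float(block.get("enrichment_high", 100))}) \
        if (mixture_block is None or mixture_block.get("kind", "deb") == "deb") \
        else parse_mixture(block.get("mixture_high"))
    return SweepSpec(param, values, base, lo, hi)


def _geometry_block(geom: SensorGeometry) -> dict[str, Any]:
    return {"units": "cm",
            "d1": geom.d1 * 100, "d2": geom.d2 * 100,
            "d3": geom.d3 * 100, "dd": geom.dd * 100,
            "S1": geom.S1 * 1e4, "S2": geom.S2 * 1e4,
            "S3": geom.S3 * 1e4, "Sd": geom.Sd * 1e4,
            "n_cells": geom.n_cells}


def fixture_configs() -> dict[str, dict[str, Any]]:
    """Named ready-to-run configs for the two reference designs.

    ``initial``/``optimized`` use baseline dry exhaled breath; the ``*_air``
    variants fill the sensor with pure air.
    """
    out: dict[str, dict[str, Any]] = {}
    for name, geom in (("initial", initial_geometry()),
                       ("optimized", optimized_geometry())):
        out[name] = {"geometry": _geometry_block(geom),
                     "mixture": {"kind": "deb", "enrichment": 0},
                     "scan": {"f_start": 0.5, "f_stop": 3000, "step": 0.05}}
        out[name + "_air"] = {"geometry": _geometry_block(geom),
                              "mixture": {"kind": "species", "name": "Air"},
                              "scan": {"f_start": 0.5, "f_stop": 3000,
                                       "step": 0.05}}
    return out


def dump_config(cfg: Mapping[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
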