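"""Configuration files, trace/field CSV formats and provenance records.

Configuration documents (YAML or JSON) use experimentalist-friendly units —
micrometres, milliseconds, millivolts — with unit-suffixed field names, and
are converted to the internal unit system at this boundary:

    cable:
      length_um: 600.0
      diameter_um: 1.0
      soma_area_um2: 1963.5
      c_m: 1.0          # uF/cm^2
      g_L: 0.05         # mS/cm^2
      r_a: 0.1          # kOhm*cm
      eps_E: 70.0       # mV above rest
      eps_I: -10.0
    inputs:
      - {kind: E, strength: 0.02, location_um: 200, onset_ms: 0,
         rise_ms: 5.0, decay_ms: 7.8}
    grid: {t_end_ms: 100.0, dx_um: 2.0, dt_ms: 0.05}
    seed: 0

Traces are CSV with header ``time_ms,v_mV``; fields are long-form CSV with
``time_ms,x_um,v_mV``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fd import Grid, VoltageField, VoltageTrace
from .model import CM_PER_UM, CableParams, StimulusSet, SynapticInput

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_config",
    "write_trace",
    "read_trace",
    "write_field",
    "write_provenance",
]


class ConfigError(ValueError):
    """Schema violation with a field-level message."""


_CABLE_FIELDS = (
    "length_um", "diameter_um", "soma_area_um2",
    "c_m", "g_L", "r_a", "eps_E", "eps_I",
)
_INPUT_FIELDS = ("kind", "strength", "location_um", "onset_ms",
                 "rise_ms", "decay_ms")


@dataclass
class RunConfig:
    params: CableParams
    stimuli: StimulusSet
    t_end: float                 # ms
    dx_um: float = 2.0
    dt: float = 0.05             # ms
    solver: str = "fd"           # fd | green | asymptotic
    seed: int = 0
    n_modes: int = 80
    noise_sd: float = 0.0        # mV
    raw: dict = field(default_factory=dict)

    def grid(self) -> Grid:
        return Grid.for_cable(self.params, self.t_end, self.dx_um, self.dt)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required field '{key}' in {where}")
    return mapping[key]


def read_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")

    cable = _require(doc, "cable", "document")
    for f_name in _CABLE_FIELDS:
        _require(cable, f_name, "cable")
    extra = set(cable) - set(_CABLE_FIELDS)
    if extra:
        raise ConfigError(f"unknown cable fields {sorted(extra)}; "
                          "unit suffixes are part of the field names")
    params = CableParams.from_micrometers(
        length_um=float(cable["length_um"]),
        diameter_um=float(cable["diameter_um"]),
        soma_area_um2=float(cable["soma_area_um2"]),
        c_m=float(cable["c_m"]),
        g_L=float(cable["g_L"]),
        r_a=float(cable["r_a"]),
        eps_E=float(cable["eps_E"]),
        eps_I=float(cable["eps_I"]),
    )

    inputs = []
    for i, entry in enumerate(doc.get("inputs", [])):
        for f_name in _INPUT_FIELDS:
            _require(entry, f_name, f"inputs[{i}]")
        if entry["kind"] not in ("E", "I"):
            raise ConfigError(f"inputs[{i}].kind must be 'E' or 'I'")
        inputs.append(
            SynapticInput(
                kind=entry["kind"],
                strength=float(entry["strength"]),
                location=float(entry["location_um"]) * CM_PER_UM,
                onset=float(entry["onset_ms"]),
                sigma_r=float(entry["rise_ms"]),
                sigma_d=float(entry["decay_ms"]),
                site_id=entry.get("site_id"),
            )
        )
    stimuli = StimulusSet(inputs)
    stimuli.validate_locations(params)

    grid = doc.get("grid", {})
    cfg = RunConfig(
        params=params,
        stimuli=stimuli,
        t_end=float(grid.get("t_end_ms", 100.0)),
        dx_um=float(grid.get("dx_um", 2.0)),
        dt=float(grid.get("dt_ms", 0.05)),
        solver=doc.get("solver", "fd"),
        seed=int(doc.get("seed", 0)),
        n_modes=int(doc.get("n_modes", 80)),
        noise_sd=float(doc.get("noise_sd", 0.0)),
        raw=doc,
    )
    if cfg.solver not in ("fd", "green", "asymptotic"):
        raise ConfigError("solver must be one of fd, green, asymptotic")
    return cfg


def write_trace(path: str | Path, trace: VoltageTrace) -> None:
    pd.DataFrame({"time_ms": trace.times, "v_mV": trace.values}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path) -> VoltageTrace:
    df = pd.read_csv(path)
    for col in ("time_ms", "v_mV"):
        if col not in df.columns:
            raise ConfigError(f"trace file missing column '{col}'")
    return VoltageTrace(df["time_ms"].to_numpy(), df["v_mV"].to_numpy())


def write_field(path: str | Path, fld: VoltageField) -> None:
    t = np.repeat(fld.times, len(fld.positions))
    x = np.tile(fld.positions / CM_PER_UM, len(fld.times))
    pd.DataFrame(
        {"time_ms": t, "x_um": x, "v_mV": fld.values.ravel()}
    ).to_csv(path, index=False)


def write_provenance(out_dir: str | Path, cfg: RunConfig, command: str) -> None:
    from . import __version__

    Path(out_dir).mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
    }
    (Path(out_dir) / "provenance.json").write_text(json.dumps(record, indent=1))
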