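"""Configuration parsing, bundled fixtures and output writing.

Run configurations are single YAML files with explicitly unit-suffixed keys
(``G_kPa``, ``height_mm``, ``ramp_s``, ...).  All values are converted to SI
at the parsing boundary and validated into the package's domain objects
before any computation starts; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .constitutive import (
    HydrogelMaterial,
    ModelVariant,
    material_from_block,
    table1_materials,
)
from .errors import ConfigError, ValidationError
from .poro1d import LoadingProtocol, SolverSettings, StressHistory

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "write_outputs",
    "read_history_csv",
    "load_protocol_blocks",
    "resolve_material",
    "resolve_protocol",
]

#: exact CSV header of simulation outputs (compressive stresses positive)
CSV_COLUMNS = (
    "time_s",
    "sigma_total_kPa",
    "p_bottom_kPa",
    "sigma_eff_bottom_kPa",
    "outflow_mm",
)

_SOLVER_KEYS = {
    "n_elements": "n_elements",
    "dt_ramp_s": "dt_ramp",
    "dt_hold_s": "dt_hold",
    "newton_tol": "newton_tol",
    "max_newton_iter": "max_newton_iter",
    "permeability_frame": "permeability_frame",
}

_PROTOCOL_KEYS = {"label", "strain", "ramp_s", "hold_s", "height_mm"}


def _protocol_from_block(block: dict, default_label: str = "protocol") -> LoadingProtocol:
    unknown = set(block) - _PROTOCOL_KEYS
    if unknown:
        raise ConfigError(f"unknown protocol keys: {sorted(unknown)}")
    missing = {"strain", "ramp_s", "hold_s", "height_mm"} - set(block)
    if missing:
        raise ConfigError(f"missing protocol keys: {sorted(missing)}")
    try:
        return LoadingProtocol(
            label=str(block.get("label", default_label)),
            ramp_duration=float(block["ramp_s"]),
            hold_duration=float(block["hold_s"]),
            applied_strain=float(block["strain"]),
            height=float(block["height_mm"]) * 1e-3,
        )
    except ValidationError as exc:
        raise ConfigError(f"invalid protocol block: {exc}") from exc


def load_protocol_blocks() -> dict[str, LoadingProtocol]:
    """The bundled ramp-hold protocols keyed by their short names."""
    text = resources.files("porogel.data").joinpath("protocols.yaml").read_text()
    blocks = yaml.safe_load(text)
    return {key: _protocol_from_block(blk, key) for key, blk in blocks.items()}


def resolve_material(selector: str | dict) -> HydrogelMaterial:
    """A material from a bundled key ('c020'/'c030'/'c040'), a YAML file
    path containing one material block, or an inline block dict."""
    if isinstance(selector, dict):
        try:
            return material_from_block(selector)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc
    keys = ("c020", "c030", "c040")
    if selector in keys:
        return dict(zip(keys, table1_materials()))[selector]
    path = Path(selector)
    if not path.exists():
        raise ConfigError(
            f"material {selector!r} is neither a bundled key {keys} nor a file"
        )
    block = yaml.safe_load(path.read_text())
    if not isinstance(block, dict):
        raise ConfigError(f"material file {path} must contain a mapping")
    try:
        return material_from_block(block)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def resolve_protocol(selector: str | dict) -> LoadingProtocol:
    """A protocol from a bundled key ('busby'/'chandran'), a YAML file path,
    or an inline block dict."""
    if isinstance(selector, dict):
        return _protocol_from_block(selector)
    bundled = load_protocol_blocks()
    if selector in bundled:
        return bundled[selector]
    path = Path(selector)
    if not path.exists():
        raise ConfigError(
            f"protocol {selector!r} is neither a bundled key "
            f"{sorted(bundled)} nor a file"
        )
    block = yaml.safe_load(path.read_text())
    if not isinstance(block, dict):
        raise ConfigError(f"protocol file {path} must contain a mapping")
    return _protocol_from_block(block, default_label=path.stem)


def _settings_from_block(block: dict) -> SolverSettings:
    unknown = set(block) - set(_SOLVER_KEYS)
    if unknown:
        raise ConfigError(f"unknown solver keys: {sorted(unknown)}")
    kwargs = {_SOLVER_KEYS[k]: v for k, v in block.items()}
    try:
        return SolverSettings(**kwargs)
    except ValidationError as exc:
        raise ConfigError(f"invalid solver settings: {exc}") from exc


@dataclass
class RunConfig:
    """A fully validated simulation run: material, protocol, variant,
    solver settings, output prefix and verbosity."""

    material: HydrogelMaterial
    protocol: LoadingProtocol
    variant: ModelVariant
    settings: SolverSettings = field(default_factory=SolverSettings)
    output_prefix: str = "porogel_run"
    verbose: bool = False


_TOP_KEYS = {"material", "protocol", "variant", "solver", "output_prefix", "verbose"}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a single-file YAML run configuration.

    Raises :class:`ConfigError` naming the offending key on parse failure,
    unknown keys or invariant violations.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    for key in ("material", "protocol", "variant"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    try:
        variant = ModelVariant.coerce(raw["variant"])
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig(
        material=resolve_material(raw["material"]),
        protocol=resolve_protocol(raw["protocol"]),
        variant=variant,
        settings=_settings_from_block(raw.get("solver", {}) or {}),
        output_prefix=str(raw.get("output_prefix", "porogel_run")),
        verbose=bool(raw.get("verbose", False)),
    )


def dump_config(config: RunConfig) -> dict:
    """Config as a plain dict that :func:`load_config` round-trips."""
    mat, prot, st = config.material, config.protocol, config.settings
    solver = {
        "n_elements": st.n_elements,
        "newton_tol": st.newton_tol,
        "max_newton_iter": st.max_newton_iter,
        "permeability_frame": st.permeability_frame,
    }
    if st.dt_ramp is not None:
        solver["dt_ramp_s"] = st.dt_ramp
    if st.dt_hold is not None:
        solver["dt_hold_s"] = st.dt_hold
    return {
        "material": {
            "label": mat.label,
            "G_kPa": mat.G / 1e3,
            "K_kPa": mat.K / 1e3,
            "C10_kPa": mat.C10 / 1e3,
            "D1_per_kPa": mat.D1 * 1e3,
            "k0_m4_per_Ns": mat.k0,
            "M": mat.M,
            "nu": mat.nu,
        },
        "protocol": {
            "label": prot.label,
            "strain": prot.applied_strain,
            "ramp_s": prot.ramp_duration,
            "hold_s": prot.hold_duration,
            "height_mm": prot.height * 1e3,
        },
        "variant": config.variant.value,
        "solver": solver,
        "output_prefix": config.output_prefix,
        "verbose": config.verbose,
    }


def history_frame(history: StressHistory) -> pd.DataFrame:
    """Reporting-sign data frame of a stress history (kPa / mm columns).

    Compressive stresses are reported positive, matching how relaxation
    curves are conventionally plotted.
    """
    return pd.DataFrame(
        {
            "time_s": history.times,
            "sigma_total_kPa": -history.total_stress / 1e3,
            "p_bottom_kPa": history.bottom_pressure / 1e3,
            "sigma_eff_bottom_kPa": history.bottom_effective_stress / 1e3,
            "outflow_mm": history.cumulative_outflow * 1e3,
        }
    )


def write_outputs(history: StressHistory, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` and ``<prefix>.summary.json`` for one run.

    The CSV stores 15 significant digits so a re-read reproduces the series
    to full written precision.  Returns the two paths.
    """
    if history.times.size == 0:
        raise ValidationError("cannot write an empty stress history")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    frame = history_frame(history)
    frame.to_csv(csv_path, index=False, float_format="%.15g")
    summary = {
        "peak_effective_kPa": history.peak_effective / 1e3,
        "end_effective_kPa": history.end_effective / 1e3,
        "n_newton_total": history.n_newton_total,
        "converged": history.converged,
    }
    json_path = Path(str(prefix) + ".summary.json")
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    return csv_path, json_path


def read_history_csv(path: str | Path) -> pd.DataFrame:
    """Read a simulation CSV back, checking the exact column schema."""
    frame = pd.read_csv(path)
    if tuple(frame.columns) != CSV_COLUMNS:
        raise ConfigError(
            f"{path}: unexpected columns {tuple(frame.columns)!r}; "
            f"expected {CSV_COLUMNS!r}"
        )
    return frame
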