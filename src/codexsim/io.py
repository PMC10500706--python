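"""Curve-table serialization and run-configuration loading.

Curve files are plain delimited text: ``#``-prefixed metadata lines
(``# key: value``), a tab-separated header naming the columns present
(``tau_m_ms``, ``cos``, ``cos_err``, ``sin``, ``sin_err``) and one row per
mixing time.  Round trips are lossless to 12 significant digits.

Run configurations are YAML documents validated against a closed schema:
unknown keys are rejected, a seed is mandatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError, FormatError
from .experiment import ISpecies, MixingCurve, SequenceConfig
from .spin_system import CsaTensor, DipolarCoupling
from .stochastic_dynamics import ExchangeModel, FlipProcess

__all__ = ["read_curve", "write_curve", "RunConfig", "load_config",
           "dump_config"]

_COLUMNS = ("tau_m_ms", "cos", "cos_err", "sin", "sin_err")


def write_curve(curve: MixingCurve, path) -> None:
    """Write a mixing-time curve as delimited text with metadata comments."""
    path = Path(path)
    cols = ["tau_m_ms"]
    data = [curve.tau_m]
    for name in ("cos", "cos_err", "sin", "sin_err"):
        arr = getattr(curve, name)
        if arr is not None:
            cols.append(name)
            data.append(arr)
    lines = []
    for key, value in curve.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("\t".join(cols))
    for row in zip(*data):
        lines.append("\t".join(f"{v:.12g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_curve(path) -> MixingCurve:
    """Read a curve file; malformed rows are reported with line numbers."""
    path = Path(path)
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            continue
        if header is None:
            header = [c.strip() for c in line.split("\t")]
            if header[0] != "tau_m_ms":
                raise FormatError(
                    f"{path}:{lineno}: missing header (first column must be "
                    f"tau_m_ms, got {header[0]!r})"
                )
            unknown = [c for c in header if c not in _COLUMNS]
            if unknown:
                raise FormatError(
                    f"{path}:{lineno}: unknown column(s) {unknown}"
                )
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataError(
                f"{path}:{lineno}: expected {len(header)} fields, "
                f"got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from exc
        if len(rows) >= 2 and rows[-1][0] <= rows[-2][0]:
            raise DataError(
                f"{path}:{lineno}: mixing times must be strictly "
                f"increasing (tau_m {rows[-1][0]} after {rows[-2][0]})"
            )
    if header is None:
        raise FormatError(f"{path}: missing header line")
    if not rows:
        raise DataError(f"{path}: no data rows")
    table = np.array(rows)
    kwargs = {}
    for i, col in enumerate(header):
        if col == "tau_m_ms":
            continue
        kwargs[col.replace("_ms", "")] = table[:, i]
    return MixingCurve(table[:, 0], metadata=metadata, **kwargs)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """A sequence configuration plus analysis options."""

    sequence: SequenceConfig
    analysis: dict = field(default_factory=dict)


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_grid(node) -> tuple[float, ...]:
    if isinstance(node, dict):
        _check_keys(node, {"start", "stop", "num", "spacing"}, "tau_m_grid")
        start, stop = float(node["start"]), float(node["stop"])
        num = int(node["num"])
        spacing = node.get("spacing", "log")
        if spacing == "log":
            return tuple(np.geomspace(start, stop, num))
        if spacing == "linear":
            return tuple(np.linspace(start, stop, num))
        raise ConfigError(f"unknown grid spacing {spacing!r}")
    return tuple(float(v) for v in node)


def _parse_csa(node) -> CsaTensor:
    _check_keys(node, {"anisotropy", "asymmetry", "euler_angles"}, "csa")
    return CsaTensor(
        anisotropy=float(node["anisotropy"]),
        asymmetry=float(node.get("asymmetry", 0.0)),
        euler_angles=tuple(node.get("euler_angles", (0.0, 0.0, 0.0))),
    )


def _parse_species(node) -> ISpecies:
    _check_keys(
        node,
        {"label", "coupling", "flips", "cp_partner", "on_pulse_channel"},
        "species entry",
    )
    cspec = node["coupling"]
    _check_keys(
        cspec, {"coupling_constant", "polar_angles", "residual_scale"},
        "coupling",
    )
    coupling = DipolarCoupling(
        coupling_constant=float(cspec["coupling_constant"]),
        polar_angles=tuple(cspec.get("polar_angles", (0.0, 0.0))),
        residual_scale=float(cspec.get("residual_scale", 1.0)),
    )
    fspec = node["flips"]
    _check_keys(
        fspec, {"spin_I", "t1_flip_time", "flipflop_time", "seed"}, "flips"
    )
    flips = FlipProcess(
        spin_I=float(fspec.get("spin_I", 0.5)),
        t1_flip_time=float(fspec.get("t1_flip_time", math.inf)),
        flipflop_time=float(fspec.get("flipflop_time", math.inf)),
    )
    return ISpecies(
        coupling=coupling,
        flips=flips,
        label=str(node.get("label", "I")),
        cp_partner=bool(node.get("cp_partner", False)),
        on_pulse_channel=bool(node.get("on_pulse_channel", True)),
    )


def _parse_exchange(node) -> ExchangeModel:
    if node.get("type") == "symmetric_two_site":
        _check_keys(node, {"type", "rate", "reorientation"}, "exchange")
        return ExchangeModel.symmetric_two_site(
            float(node["rate"]),
            reorientation=tuple(node.get("reorientation", (0, 0, 0))),
        )
    _check_keys(
        node, {"type", "populations", "rate_matrix", "site_orientations"},
        "exchange",
    )
    return ExchangeModel(
        populations=tuple(float(p) for p in node["populations"]),
        rate_matrix=np.asarray(node["rate_matrix"], dtype=float),
        site_orientations=(
            tuple(tuple(float(a) for a in row)
                  for row in node["site_orientations"])
            if "site_orientations" in node else None
        ),
    )


_SEQUENCE_KEYS = {
    "tau_m_grid", "seed", "variant", "component", "csa", "species",
    "exchange", "anti_phase_fraction", "z_filter_delay", "t1_s", "t2_s",
    "tau_sd", "tau_r", "mas_period", "n_rotor_cycles", "orientation_count",
    "orientation_scheme", "mc_draws", "flips_within_periods",
}


def parse_config(doc: dict, seed_override: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML document."""
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(doc, _SEQUENCE_KEYS | {"analysis"}, "config")
    if "seed" not in doc and seed_override is None:
        raise ConfigError("config must declare a seed")
    kwargs: dict = {}
    for key in _SEQUENCE_KEYS:
        if key not in doc:
            continue
        value = doc[key]
        if key == "tau_m_grid":
            value = _parse_grid(value)
        elif key == "csa" and value is not None:
            value = _parse_csa(value)
        elif key == "species":
            value = tuple(_parse_species(s) for s in value)
        elif key == "exchange" and value is not None:
            value = _parse_exchange(value)
        kwargs[key] = value
    if seed_override is not None:
        kwargs["seed"] = int(seed_override)
    analysis = doc.get("analysis", {}) or {}
    _check_keys(
        analysis, {"n_components", "tolerance_z", "component"}, "analysis"
    )
    return RunConfig(sequence=SequenceConfig(**kwargs), analysis=dict(analysis))


def load_config(path, seed_override: int | None = None) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc, seed_override=seed_override)


def dump_config(config: SequenceConfig, analysis: dict | None = None) -> str:
    """Serialize a sequence configuration back to YAML."""
    doc: dict = {
        "seed": config.seed,
        "variant": config.variant,
        "component": config.component,
        "tau_m_grid": [float(t) for t in config.tau_m_grid],
        "anti_phase_fraction": config.anti_phase_fraction,
        "z_filter_delay": config.z_filter_delay,
        "t1_s": config.t1_s,
        "t2_s": config.t2_s,
        "tau_r": config.tau_r,
        "mas_period": config.mas_period,
        "n_rotor_cycles": config.n_rotor_cycles,
        "orientation_count": config.orientation_count,
        "orientation_scheme": config.orientation_scheme,
        "mc_draws": config.mc_draws,
        "flips_within_periods": config.flips_within_periods,
    }
    if config.tau_sd is not None:
        doc["tau_sd"] = config.tau_sd
    if config.csa is not None:
        doc["csa"] = {
            "anisotropy": config.csa.anisotropy,
            "asymmetry": config.csa.asymmetry,
            "euler_angles": [float(a) for a in config.csa.euler_angles],
        }
    if config.species:
        doc["species"] = [
            {
                "label": sp.label,
                "cp_partner": sp.cp_partner,
                "on_pulse_channel": sp.on_pulse_channel,
                "coupling": {
                    "coupling_constant": sp.coupling.coupling_constant,
                    "polar_angles": [float(a) for a in sp.coupling.polar_angles],
                    "residual_scale": sp.coupling.residual_scale,
                },
                "flips": {
                    "spin_I": sp.flips.spin_I,
                    "t1_flip_time": float(sp.flips.t1_flip_time),
                    "flipflop_time": float(sp.flips.flipflop_time),
                },
            }
            for sp in config.species
        ]
    if config.exchange is not None:
        doc["exchange"] = {
            "populations": [float(p) for p in config.exchange.populations],
            "rate_matrix": [
                [float(v) for v in row] for row in config.exchange.rate_matrix
            ],
            "site_orientations": (
                [[float(a) for a in row]
                 for row in config.exchange.site_orientations]
                if config.exchange.site_orientations is not None else None
            ),
        }
    if analysis:
        doc["analysis"] = analysis
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
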