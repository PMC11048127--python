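"""File I/O and run configuration: Touchstone .s1p sweeps, measurement
and permittivity CSV tables, calibration-curve JSON, and the structured
run config consumed by the CLI.

Touchstone support follows the version 1.1 convention for one-port files:
``!`` comment lines, a ``#`` option line declaring frequency unit,
parameter type, data format (RI / MA / DB) and reference impedance, and
three-column data rows.  Files are written in RI format and GHz by default.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from evapcyte.calibration import CONC_COL, FREQ_COL, REP_COL, CalibrationCurve
from evapcyte.circuit_model import SParamSweep

__all__ = [
    "read_touchstone",
    "write_touchstone",
    "read_measurement_table",
    "write_measurement_table",
    "read_permittivity_table",
    "write_permittivity_table",
    "load_curve",
    "save_curve",
    "RunConfig",
]

_UNIT_FACTORS = {"hz": 1.0, "khz": 1e3, "mhz": 1e6, "ghz": 1e9}


def _parse_option_line(line: str) -> tuple[float, str, str, float]:
    """Parse a Touchstone option line into (unit factor, parameter,
    format, reference impedance)."""
    tokens = line[1:].split()
    unit, param, fmt, z0 = 1e9, "S", "MA", 50.0
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok in _UNIT_FACTORS:
            unit = _UNIT_FACTORS[tok]
        elif tok in ("s", "y", "z", "g", "h"):
            param = tok.upper()
        elif tok in ("ri", "ma", "db"):
            fmt = tok.upper()
        elif tok == "r":
            if i + 1 >= len(tokens):
                raise ValueError("Touchstone option line: 'R' without impedance")
            z0 = float(tokens[i + 1])
            i += 1
        else:
            raise ValueError(f"unrecognised Touchstone option token: {tokens[i]!r}")
        i += 1
    return unit, param, fmt, z0


def _decode(fmt: str, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    if fmt == "RI":
        return v1 + 1j * v2
    if fmt == "MA":
        return v1 * np.exp(1j * np.deg2rad(v2))
    if fmt == "DB":
        return 10.0 ** (v1 / 20.0) * np.exp(1j * np.deg2rad(v2))
    raise ValueError(f"unknown Touchstone format: {fmt}")


def read_touchstone(path: str | Path) -> SParamSweep:
    """Read a one-port Touchstone (.s1p) file into an :class:`SParamSweep`.

    Supports RI, MA and DB data formats and Hz/kHz/MHz/GHz frequency
    units.  Raises ``ValueError`` for multi-port data, an empty data
    section, or a non-monotone frequency column.
    """
    path = Path(path)
    unit, param, fmt, z0 = 1e9, "S", "MA", 50.0
    rows: list[list[float]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                unit, param, fmt, z0 = _parse_option_line(line)
                continue
            values = [float(tok) for tok in line.split()]
            rows.append(values)
    if param != "S":
        raise ValueError(f"expected S-parameters, file declares {param!r}")
    if not rows:
        raise ValueError(f"{path}: empty Touchstone data section")
    widths = {len(r) for r in rows}
    if widths != {3}:
        raise ValueError(
            f"{path}: expected one-port data (3 columns per row), "
            f"found rows of width {sorted(widths)}"
        )
    data = np.asarray(rows, dtype=float)
    freqs = data[:, 0] * unit
    if np.any(np.diff(freqs) <= 0):
        raise ValueError(f"{path}: frequency column is not strictly increasing")
    s11 = _decode(fmt, data[:, 1], data[:, 2])
    return SParamSweep(frequencies=freqs, s11=s11, z0=z0)


def write_touchstone(
    path: str | Path, sweep: SParamSweep, fmt: str = "RI", unit: str = "GHz"
) -> None:
    """Write a one-port sweep as Touchstone 1.1 (.s1p)."""
    fmt = fmt.upper()
    factor = _UNIT_FACTORS[unit.lower()]
    lines = [f"! one-port S11 sweep, {sweep.frequencies.size} points",
             f"# {unit} S {fmt} R {sweep.z0:g}"]
    mag = np.abs(sweep.s11)
    ang = np.rad2deg(np.angle(sweep.s11))
    for i, f in enumerate(sweep.frequencies):
        if fmt == "RI":
            a, b = sweep.s11[i].real, sweep.s11[i].imag
        elif fmt == "MA":
            a, b = mag[i], ang[i]
        elif fmt == "DB":
            a, b = 20.0 * np.log10(max(mag[i], 1e-30)), ang[i]
        else:
            raise ValueError(f"unknown Touchstone format: {fmt}")
        lines.append(f"{f / factor:.12g} {a:.16e} {b:.16e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV with columns (concentration_cells_per_mL,
    f_res_GHz[, replicate])."""
    table = pd.read_csv(path)
    missing = {CONC_COL, FREQ_COL} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if REP_COL not in table.columns:
        table[REP_COL] = 0
    return table[[CONC_COL, FREQ_COL, REP_COL]]


def write_measurement_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_permittivity_table(path: str | Path) -> pd.DataFrame:
    """Read a permittivity CSV (frequency_Hz, eps_real, eps_imag)."""
    table = pd.read_csv(path)
    required = {"frequency_Hz", "eps_real", "eps_imag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_permittivity_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def save_curve(path: str | Path, curve: CalibrationCurve) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2) + "\n")


def load_curve(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(json.loads(Path(path).read_text()))


_CONFIG_SECTIONS = ("geometry", "circuit", "dielectrics", "sample", "simulation")


@dataclass
class RunConfig:
    """Structured run configuration.

    Sections: ``geometry`` (resonator layout/substrate), ``circuit``
    (parasitics), ``dielectrics``, ``sample`` (droplet/chip), and
    ``simulation`` (endpoint / trace generator settings), plus a global
    ``seed`` and optional ``output`` directory.  Loadable from TOML or
    JSON; load -> serialize -> load is idempotent.
    """

    geometry: dict = field(default_factory=dict)
    circuit: dict = field(default_factory=dict)
    dielectrics: dict = field(default_factory=dict)
    sample: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    output: str | None = None

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = set(_CONFIG_SECTIONS) | {"seed", "output"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section in _CONFIG_SECTIONS:
            if section in data and not isinstance(data[section], dict):
                raise ValueError(f"config section {section!r} must be a table")
        if "seed" in data and not isinstance(data["seed"], int):
            raise ValueError("config 'seed' must be an integer")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            with path.open("rb") as fh:
                data = tomllib.load(fh)
        else:
            data = json.loads(path.read_text())
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        data = {s: getattr(self, s) for s in _CONFIG_SECTIONS if getattr(self, s)}
        data["seed"] = self.seed
        if self.output is not None:
            data["output"] = self.output
        return data

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_mapping(), indent=2) + "\n")

    def digest(self) -> str:
        """SHA-256 hash of the resolved config, for run logging."""
        blob = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
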