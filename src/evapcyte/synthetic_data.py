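"""Seeded generators for endpoint calibration datasets and full
evaporation S11 time courses.

Endpoint datasets
-----------------
:func:`simulate_endpoint_dataset` draws replicate endpoint frequencies from
a configured calibration line with additive Gaussian noise.  The noise SD
is specified *relative to the magnitude of the mean frequency shift*
``|slope| * mean(concentrations)`` — the scale on which the assay's
replicate scatter is quoted (< 3.8%) — so the default configuration
reproduces the dispersion a calibration experiment at the six-step doubling
ladder would show.

Evaporation traces
------------------
:func:`simulate_evaporation_trace` renders the qualitative trajectory the
assay relies on: while the droplet evaporates, solvent loss concentrates
the suspended cells, the effective surface permittivity rises (via
Maxwell–Garnett mixing of a high-permittivity solute phase in the aqueous
host), the loading capacitance grows and the resonant dip drifts *down*;
when the solvent is gone the wet loading disappears, the frequency jumps
*up* to a stable dry-residue plateau whose level decreases with
concentration.  The residue left by pure PBS sits between the residues of
the 1e6 and 2e6 cells/mL samples.  Each time point is rendered as a full
one-port S11 sweep and the dip is re-extracted from it, so the generator
exercises the same signal path a VNA measurement would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from evapcyte.calibration import make_measurement_table
from evapcyte.circuit_model import (
    CircuitParams,
    SParamSweep,
    extract_resonance,
    resonant_frequency,
    synth_s11,
    vna_grid,
)
from evapcyte.dielectrics import ComplexPermittivity, effective_medium_mixture
from evapcyte.sample_geometry import concentration_ladder

__all__ = [
    "EndpointSimConfig",
    "EvaporationSimConfig",
    "TracePoint",
    "EvaporationTrace",
    "default_circuit",
    "simulate_endpoint_dataset",
    "simulate_evaporation_trace",
    "endpoint_from_traces",
]

#: Random-close-packing cap on the solute volume fraction.
_PHI_CAP = 0.74


@dataclass(frozen=True)
class EndpointSimConfig:
    """Configuration of the endpoint-dataset generator.

    Defaults are the assay's study conditions: the reported calibration
    line (slope -0.02506e-6 GHz per cells/mL, intercept -1.65475 GHz), the
    six-step doubling ladder 0.25–8 x 10^6 cells/mL, three replicates per
    concentration, and a relative replicate SD of 3.8% of the mean shift.
    """

    true_slope: float = -0.02506e-6
    true_intercept: float = -1.65475
    concentrations: tuple[float, ...] = tuple(concentration_ladder())
    replicates: int = 3
    noise_sd: float = 0.038
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.concentrations) < 1:
            raise ValueError("at least one concentration required")

    @property
    def noise_sd_ghz(self) -> float:
        """Absolute noise SD in GHz: noise_sd x |slope| x mean(conc)."""
        return self.noise_sd * abs(self.true_slope) * float(
            np.mean(self.concentrations)
        )


def simulate_endpoint_dataset(
    cfg: EndpointSimConfig, antithetic: bool = False
) -> pd.DataFrame:
    """Draw a replicate endpoint measurement table from the configured line.

    Returns a DataFrame with columns (concentration_cells_per_mL,
    f_res_GHz, replicate), exactly ``len(concentrations) * replicates``
    rows, bit-reproducible for a fixed seed.

    ``antithetic=True`` returns the noise-negated companion of the same
    seed.  Averaging a statistic over seed/antithetic pairs cancels its
    first-order random error while preserving any systematic bias, which
    makes paired datasets the preferred design for bias checks on
    calibration estimators.
    """
    rng = np.random.default_rng(cfg.seed)
    conc = np.repeat(np.asarray(cfg.concentrations, dtype=float), cfg.replicates)
    reps = np.tile(np.arange(cfg.replicates), len(cfg.concentrations))
    line = cfg.true_slope * conc + cfg.true_intercept
    noise = rng.normal(0.0, cfg.noise_sd_ghz, size=conc.size)
    if antithetic:
        noise = -noise
    return make_measurement_table(conc, line + noise, reps)


def default_circuit(f0: float = 1.28e9, L_total: float = 5e-9) -> CircuitParams:
    """A bare-chip equivalent circuit resonating at ``f0`` (default the
    1.28 GHz design point) with the given total inductance."""
    C = 1.0 / ((2.0 * math.pi * f0) ** 2 * L_total)
    return CircuitParams(L_total=L_total, C_total=C)


@dataclass(frozen=True)
class EvaporationSimConfig:
    """Configuration of the evaporation time-course generator.

    Units: volumes in uL, times in s, concentrations in cells/mL,
    permittivities relative.  ``dry_time`` defaults to 600 s (a 1 uL
    droplet evaporates in about ten minutes); the droplet volume decays
    exponentially to 1% of its initial value at ``dry_time`` (or linearly
    with ``volume_decay="linear"``).  ``kappa`` is the capacitance-loading
    coefficient mapping surface permittivity to added capacitance,
    C(eps) = C_total * (1 + kappa*(eps - 1)); it is an instrument-scale
    knob, not derived physics.  The dry-residue permittivity is
    ``dry_residue_eps_base + dry_residue_eps_per_conc * concentration``;
    pure PBS (concentration 0) leaves ``pbs_residue_eps``, which must lie
    strictly between the residues of the 1e6 and 2e6 cells/mL cases.
    ``plateau_line`` optionally pins the dry plateau directly to an affine
    map of concentration (slope GHz per cells/mL, intercept GHz).
    """

    concentration: float = 1e6
    initial_volume_ul: float = 1.0
    dry_time: float = 600.0
    sample_interval: float = 5.0
    plateau_duration: float = 120.0
    wet_medium_eps: float = 78.0
    solute_eps: float = 100.0
    dry_residue_eps_base: float = 1.05
    dry_residue_eps_per_conc: float = 2.5e-7
    pbs_residue_eps: float = 1.425
    cell_diameter: float = 15e-6
    kappa: float = 0.002
    q_loaded: float = 80.0
    coupling: float = 0.9
    trace_noise_sd: float = 1e-4
    noise_mode: str = "multiplicative"
    volume_decay: str = "exponential"
    plateau_line: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.dry_time <= self.sample_interval:
            raise ValueError("dry_time must exceed sample_interval")
        if self.initial_volume_ul <= 0 or self.plateau_duration < 0:
            raise ValueError("volumes and durations must be positive")
        if self.trace_noise_sd < 0:
            raise ValueError("trace_noise_sd must be >= 0")
        if self.noise_mode not in ("multiplicative", "additive"):
            raise ValueError("noise_mode must be 'multiplicative' or 'additive'")
        if self.volume_decay not in ("exponential", "linear"):
            raise ValueError("volume_decay must be 'exponential' or 'linear'")
        if self.solute_eps < self.wet_medium_eps:
            raise ValueError(
                "inconsistent permittivity endpoints: solute_eps must be >= "
                "wet_medium_eps for the wet-segment permittivity to rise"
            )
        if self.plateau_line is None:
            if self.dry_residue_eps(self.concentration) >= self.wet_medium_eps:
                raise ValueError(
                    "inconsistent permittivity endpoints: dry residue must be "
                    "less permittive than the wet medium"
                )
            lo = self.dry_residue_eps(1e6)
            hi = self.dry_residue_eps(2e6)
            if not lo < self.pbs_residue_eps < hi:
                raise ValueError(
                    "pbs_residue_eps must lie strictly between the dry-residue "
                    "permittivities of the 1e6 and 2e6 cells/mL cases"
                )

    def dry_residue_eps(self, concentration: float) -> float:
        """Dry-residue surface permittivity left by a given concentration."""
        if concentration == 0:
            return self.pbs_residue_eps
        return (
            self.dry_residue_eps_base
            + self.dry_residue_eps_per_conc * concentration
        )

    @property
    def initial_volume_fraction(self) -> float:
        """Initial cell volume fraction of the droplet."""
        cell_vol_ml = (4.0 / 3.0) * math.pi * (self.cell_diameter / 2.0) ** 3 * 1e6
        return min(self.concentration * cell_vol_ml, _PHI_CAP)


@dataclass(frozen=True)
class TracePoint:
    """One VNA snapshot of the evaporation: elapsed time (s), the rendered
    S11 sweep, the dip frequency re-extracted from it (Hz), and the model
    frequency that was rendered (``f0_model``, Hz, including trace noise)."""

    time: float
    sweep: SParamSweep
    f0: float
    f0_model: float


@dataclass(frozen=True)
class EvaporationTrace:
    """A time-ordered evaporation trace with its generating concentration."""

    points: tuple[TracePoint, ...]
    concentration: float

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.points])

    @property
    def f0_series(self) -> np.ndarray:
        return np.array([p.f0 for p in self.points])

    @property
    def f0_model_series(self) -> np.ndarray:
        return np.array([p.f0_model for p in self.points])


def _loaded_frequency(circuit: CircuitParams, eps_surface: float, kappa: float) -> float:
    c_loaded = circuit.C_total * (1.0 + kappa * (eps_surface - 1.0))
    return resonant_frequency(circuit.L_total, c_loaded)


def simulate_evaporation_trace(
    cfg: EvaporationSimConfig,
    circuit: CircuitParams | None = None,
    grid: np.ndarray | None = None,
    total_time: float | None = None,
) -> EvaporationTrace:
    """Simulate one droplet's evaporation as a sequence of S11 sweeps.

    Samples every ``cfg.sample_interval`` seconds from t = 0 to
    ``total_time`` (default ``dry_time + plateau_duration``).  See the
    module docstring for the trajectory model.
    """
    if circuit is None:
        circuit = default_circuit()
    if grid is None:
        grid = vna_grid()
    if total_time is None:
        total_time = cfg.dry_time + cfg.plateau_duration
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, total_time + 1e-9, cfg.sample_interval)

    phi0 = cfg.initial_volume_fraction
    host = ComplexPermittivity(cfg.wet_medium_eps)
    incl = ComplexPermittivity(cfg.solute_eps)

    points: list[TracePoint] = []
    for t in times:
        if t < cfg.dry_time:
            if cfg.volume_decay == "exponential":
                v_frac = math.exp(-math.log(100.0) * t / cfg.dry_time)
            else:
                v_frac = max(1.0 - 0.99 * t / cfg.dry_time, 0.01)
            phi = min(phi0 / v_frac, _PHI_CAP) if phi0 > 0 else 0.0
            eps_s = effective_medium_mixture(incl, host, phi).eps_real
            f0_true = _loaded_frequency(circuit, eps_s, cfg.kappa)
        else:
            if cfg.plateau_line is not None:
                slope, intercept = cfg.plateau_line
                f0_true = (slope * cfg.concentration + intercept) * 1e9
            else:
                eps_dry = cfg.dry_residue_eps(cfg.concentration)
                f0_true = _loaded_frequency(circuit, eps_dry, cfg.kappa)
        if cfg.trace_noise_sd > 0:
            if cfg.noise_mode == "multiplicative":
                f0_true *= 1.0 + rng.normal(0.0, cfg.trace_noise_sd)
            else:
                f0_true += rng.normal(0.0, cfg.trace_noise_sd)
        sweep = synth_s11(grid, f0_true, cfg.q_loaded, cfg.coupling)
        f0_extracted = extract_resonance(sweep).f0
        points.append(
            TracePoint(time=float(t), sweep=sweep, f0=f0_extracted, f0_model=f0_true)
        )
    return EvaporationTrace(points=tuple(points), concentration=cfg.concentration)


#: Minimum number of post-jump samples for a plateau to be declared.
MIN_PLATEAU_SAMPLES = 3
#: The jump must exceed this multiple of the largest other frequency step.
_JUMP_PROMINENCE = 3.0


def detect_plateau(trace: EvaporationTrace) -> int:
    """Index of the first plateau sample (the point right after the upward
    dry-out jump).

    Raises
    ------
    ValueError
        If no sufficiently prominent upward jump exists or fewer than
        ``MIN_PLATEAU_SAMPLES`` samples follow it (e.g. a truncated trace).
    """
    f0 = trace.f0_series
    if f0.size < MIN_PLATEAU_SAMPLES + 2:
        raise ValueError("trace too short to contain a plateau")
    diffs = np.diff(f0)
    j = int(np.argmax(diffs))
    others = np.abs(np.delete(diffs, j))
    floor = max(1e-9 * abs(f0[0]), 1e-3)
    if diffs[j] <= 0 or diffs[j] <= _JUMP_PROMINENCE * max(others.max(), floor):
        raise ValueError("no dry-out jump detected in trace")
    if f0.size - (j + 1) < MIN_PLATEAU_SAMPLES:
        raise ValueError(
            f"plateau has fewer than {MIN_PLATEAU_SAMPLES} samples "
            "(trace may be truncated)"
        )
    return j + 1


def endpoint_from_traces(traces) -> pd.DataFrame:
    """Reduce evaporation traces to an endpoint measurement table.

    The endpoint frequency of each trace is the mean of its post-jump
    plateau samples, reported in GHz; replicate ids count traces sharing a
    concentration.  The output feeds :func:`evapcyte.calibration.fit_line`
    unchanged.
    """
    conc, f_res, reps = [], [], []
    seen: dict[float, int] = {}
    for trace in traces:
        start = detect_plateau(trace)
        endpoint_hz = float(trace.f0_series[start:].mean())
        rep = seen.get(trace.concentration, 0)
        seen[trace.concentration] = rep + 1
        conc.append(trace.concentration)
        f_res.append(endpoint_hz / 1e9)
        reps.append(rep)
    return make_measurement_table(conc, f_res, reps)
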