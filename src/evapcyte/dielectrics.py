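"""Dielectric models: complex permittivity, penetration depth, the
single-shell spherical cell model, effective-medium mixing, and the
frequency-regime classification of the cell equivalent circuit.

Conventions
-----------
Complex relative permittivity is written eps = eps' - j*eps'' with
eps'' >= 0 (lossy media dissipate).  The loss tangent is eps''/eps'.

The penetration depth follows the standard lossy-dielectric closed form

    Dp = lambda0 / (2*pi*sqrt(2*eps')) * [sqrt(1 + (eps''/eps')^2) - 1]^(-1/2)

with lambda0 = c/f the free-space wavelength.  In the low-loss limit
(tan d -> 0) this reduces to lambda0*sqrt(eps')/(2*pi*eps'').  A lossless
medium (eps'' = 0) has unbounded penetration; the function returns
``math.inf`` explicitly in that case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from evapcyte.constants import CONSTANTS, PhysicalConstants

__all__ = [
    "ComplexPermittivity",
    "ShelledCell",
    "CellCircuitElements",
    "Regime",
    "RegimeLabel",
    "penetration_depth",
    "single_shell_permittivity",
    "effective_medium_mixture",
    "dispersion_regime",
]


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative complex permittivity eps' - j*eps''."""

    eps_real: float
    eps_imag: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_imag < 0:
            raise ValueError("eps_imag must be >= 0 (eps = eps' - j*eps'')")

    @property
    def loss_tangent(self) -> float:
        if self.eps_real <= 0:
            raise ValueError("loss tangent undefined for eps_real <= 0")
        return self.eps_imag / self.eps_real

    def as_complex(self) -> complex:
        return complex(self.eps_real, -self.eps_imag)

    @classmethod
    def from_complex(cls, value: complex) -> "ComplexPermittivity":
        return cls(eps_real=value.real, eps_imag=(-value.imag) + 0.0)


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell spherical cell: cytoplasm sphere of radius ``R`` coated
    by a membrane of thickness ``d``, with membrane and cytoplasm
    permittivities ``eps_mem`` and ``eps_cyto``."""

    radius: float
    membrane_thickness: float
    eps_mem: ComplexPermittivity
    eps_cyto: ComplexPermittivity

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0 <= self.membrane_thickness < self.radius:
            raise ValueError("membrane thickness must satisfy 0 <= d < R")

    @property
    def gamma(self) -> float:
        """Shell ratio gamma = R / (R - d) >= 1."""
        return self.radius / (self.radius - self.membrane_thickness)


@dataclass(frozen=True)
class CellCircuitElements:
    """Element values of the cell-in-medium equivalent circuit: membrane
    capacitance, electric-double-layer capacitance, cytoplasm resistance,
    and the parallel R-C of the suspending medium."""

    c_mem: float
    c_dl: float
    r_cyto: float
    r_medium: float
    c_medium: float

    def __post_init__(self) -> None:
        for name in ("c_mem", "c_dl", "r_cyto", "r_medium", "c_medium"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class Regime(str, Enum):
    """Frequency regimes of the cell equivalent circuit."""

    EDL_DOMINATED = "EDL_DOMINATED"
    MEMBRANE_POLARIZATION = "MEMBRANE_POLARIZATION"
    MEMBRANE_CHARGING = "MEMBRANE_CHARGING"
    CYTOPLASM_SENSITIVE = "CYTOPLASM_SENSITIVE"


@dataclass(frozen=True)
class RegimeLabel:
    """A regime name with its band edges (Hz); bands are half-open
    [f_low, f_high) and partition (0, inf)."""

    name: Regime
    f_low: float
    f_high: float


# Band edges of the equivalent-circuit regimes.  Below 1 kHz the electric
# double layer takes most of the voltage; below 1 MHz the membrane
# polarises and current stays extracellular; between 1 and 100 MHz the
# membrane reactance falls and intracellular current grows; above 100 MHz
# the membrane is effectively short-circuited and the field probes the
# cytoplasm.
_BANDS = (
    RegimeLabel(Regime.EDL_DOMINATED, 0.0, 1e3),
    RegimeLabel(Regime.MEMBRANE_POLARIZATION, 1e3, 1e6),
    RegimeLabel(Regime.MEMBRANE_CHARGING, 1e6, 100e6),
    RegimeLabel(Regime.CYTOPLASM_SENSITIVE, 100e6, math.inf),
)


def penetration_depth(
    eps: ComplexPermittivity,
    f: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Field penetration depth (m) in a lossy dielectric at frequency ``f``.

    Returns ``math.inf`` for a lossless medium (eps'' = 0).
    """
    if eps.eps_real <= 0:
        raise ValueError("eps_real must be > 0")
    if f <= 0:
        raise ValueError("frequency must be > 0")
    if eps.eps_imag == 0:
        return math.inf
    lam0 = constants.c_light / f
    tan_d = eps.eps_imag / eps.eps_real
    radicand = math.sqrt(1.0 + tan_d * tan_d) - 1.0
    return lam0 / (2.0 * math.pi * math.sqrt(2.0 * eps.eps_real)) * radicand**-0.5


_SHELL_SINGULARITY_TOL = 1e-12


def single_shell_permittivity(cell: ShelledCell) -> ComplexPermittivity:
    """Equivalent homogeneous permittivity eps_P of a single-shell cell.

    With gamma = R/(R-d) and h = (eps_i - eps_mem)/(eps_i + 2*eps_mem):

        eps_P = eps_mem * (gamma^3 + 2h) / (gamma^3 - h)

    Complex arithmetic throughout.  d = 0 or eps_mem = eps_i collapse to
    eps_P = eps_i exactly (no shell / homogeneous sphere).
    """
    em = cell.eps_mem.as_complex()
    ei = cell.eps_cyto.as_complex()
    g3 = cell.gamma**3
    inner = ei + 2.0 * em
    if abs(inner) < _SHELL_SINGULARITY_TOL:
        raise ZeroDivisionError("single-shell model singular: eps_i + 2*eps_mem ~ 0")
    h = (ei - em) / inner
    denom = g3 - h
    if abs(denom) < _SHELL_SINGULARITY_TOL * max(abs(g3), 1.0):
        raise ZeroDivisionError("single-shell model singular: gamma^3 - h ~ 0")
    return ComplexPermittivity.from_complex(em * (g3 + 2.0 * h) / denom)


def effective_medium_mixture(
    eps_incl: ComplexPermittivity,
    eps_host: ComplexPermittivity,
    phi: float,
    rule: str = "maxwell-garnett",
) -> ComplexPermittivity:
    """Effective permittivity of spherical inclusions in a host medium.

    The default is the Maxwell–Garnett rule

        eps_eff = eps_h * [eps_i + 2*eps_h + 2*phi*(eps_i - eps_h)]
                        / [eps_i + 2*eps_h -   phi*(eps_i - eps_h)]

    which interpolates between the host (phi = 0) and the pure inclusion
    phase (phi = 1) and is monotone in phi for real permittivities.  A
    linear volume-weighted rule (``rule="linear"``) is available for
    sensitivity analysis.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("volume fraction phi must lie in [0, 1]")
    ei = eps_incl.as_complex()
    eh = eps_host.as_complex()
    if rule == "maxwell-garnett":
        diff = ei - eh
        eff = eh * (ei + 2.0 * eh + 2.0 * phi * diff) / (ei + 2.0 * eh - phi * diff)
    elif rule == "linear":
        eff = phi * ei + (1.0 - phi) * eh
    else:
        raise ValueError(f"unknown mixing rule: {rule!r}")
    return ComplexPermittivity.from_complex(eff)


def dispersion_regime(f: float) -> RegimeLabel:
    """Classify frequency ``f`` (Hz) into the equivalent-circuit regime.

    Bands are half-open: a frequency exactly at a band edge belongs to the
    higher band.
    """
    if f <= 0:
        raise ValueError("frequency must be > 0")
    for band in _BANDS:
        if band.f_low <= f < band.f_high:
            return band
    return _BANDS[-1]  # unreachable: last band is unbounded
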