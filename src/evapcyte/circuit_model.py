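"""Equivalent-circuit forward model of the LC-resonator biosensor.

The sensor is a planar spiral inductor wrapped around a circular
interdigital ("circinate") capacitor, fabricated on a GaAs substrate.  This
module provides the closed-form design equations for the two lumped
elements, the resonant frequency of their parallel combination, a one-port
reflection (S11) forward model, and dip localisation / Q extraction from a
measured or synthesised sweep.

Capacitance parse
-----------------
The interdigital capacitance is computed by conformal mapping with complete
elliptic integrals of the first kind.  With the inner and outer radius
parameters ``a < b``, modulus ``k = a/b`` and complement ``k' = sqrt(1-k^2)``,
the capacitance per unit finger length is

    C / L_C = eps0 * (1 + eps_sub) / 2 * K(k') / K(k)  +  eps0 * t / a

i.e. the standard coplanar half-space result for a substrate of relative
permittivity ``eps_sub`` plus a thin-film correction proportional to the
SiNx passivation thickness ``t`` normalised by the inner radius ``a``.  The
total capacitance is linear in the circular finger length ``L_C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipk

from evapcyte.constants import CONSTANTS, PhysicalConstants

__all__ = [
    "LayoutCoefficients",
    "CIRCULAR_LAYOUT",
    "ResonatorGeometry",
    "CircuitParams",
    "SParamSweep",
    "ResonancePoint",
    "fill_ratio",
    "spiral_inductance",
    "circinate_capacitance",
    "resonant_frequency",
    "synth_s11",
    "extract_resonance",
    "vna_grid",
]


@dataclass(frozen=True)
class LayoutCoefficients:
    """Dimensionless layout coefficients of the current-sheet inductance
    approximation.  The circular-spiral preset is (1.00, 2.16, 0.00, 0.20)."""

    c1: float = 1.00
    c2: float = 2.16
    c3: float = 0.00
    c4: float = 0.20


#: Current-sheet coefficients for a circular spiral.
CIRCULAR_LAYOUT = LayoutCoefficients()


@dataclass(frozen=True)
class ResonatorGeometry:
    """Layout and substrate parameters of the resonator.

    Lengths are in metres.  ``n`` is the spiral turn count, ``d_out`` /
    ``d_in`` / ``d_avg`` the outer, inner and average spiral diameters,
    ``finger_length`` the total circular finger length L_C of the central
    capacitor, ``a`` and ``b`` the inner/outer conductor radius parameters
    of the conformal map, and ``nitride_thickness`` the SiNx passivation
    thickness.  Substrate defaults are the GaAs values: relative
    permittivity 12.85, loss tangent 2.8e-4, height 200 um.
    """

    n: int
    d_out: float
    d_in: float
    finger_length: float
    a: float
    b: float
    d_avg: float | None = None
    nitride_thickness: float = 0.2e-6
    substrate_eps: float = 12.85
    substrate_tand: float = 0.00028
    substrate_height: float = 200e-6

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("turn count n must be >= 1")
        if not self.d_out > self.d_in >= 0:
            raise ValueError("require d_out > d_in >= 0")
        if not 0 < self.a < self.b:
            raise ValueError("require 0 < a < b")
        if self.finger_length <= 0:
            raise ValueError("finger_length must be > 0")
        if self.nitride_thickness <= 0 or self.substrate_height <= 0:
            raise ValueError("thicknesses must be > 0")
        if self.substrate_eps < 1:
            raise ValueError("substrate_eps must be >= 1")
        if self.d_avg is None:
            object.__setattr__(self, "d_avg", 0.5 * (self.d_out + self.d_in))


@dataclass(frozen=True)
class CircuitParams:
    """Lumped equivalent-circuit values.

    ``C_SiNx`` (passivation capacitance), ``C_ab`` (inter-turn fringing),
    ``C_sub``/``R_sub`` (trace-to-substrate shunt) are parasitics supplied
    as configuration and folded into the totals; they are not derived from
    geometry.
    """

    L_total: float
    C_total: float
    C_SiNx: float = 0.0
    C_ab: float = 0.0
    C_sub: float = 0.0
    R_sub: float = 0.0

    def __post_init__(self) -> None:
        if self.L_total <= 0 or self.C_total <= 0:
            raise ValueError("L_total and C_total must be > 0")
        for name in ("C_SiNx", "C_ab", "C_sub", "R_sub"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def f0(self) -> float:
        """Resonant frequency (Hz) of the total L-C pair."""
        return resonant_frequency(self.L_total, self.C_total)


@dataclass(frozen=True)
class SParamSweep:
    """One-port S-parameter sweep: a uniform frequency grid (Hz) with a
    complex reflection coefficient per point."""

    frequencies: np.ndarray
    s11: np.ndarray
    z0: float = 50.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        s = np.asarray(self.s11, dtype=complex)
        if f.ndim != 1 or f.size < 3:
            raise ValueError("frequency grid must be 1-D with >= 3 points")
        if s.shape != f.shape:
            raise ValueError("s11 and frequencies must have equal length")
        steps = np.diff(f)
        if np.any(steps <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        if np.any(np.abs(s) > 1.0 + 1e-9):
            raise ValueError("|S11| > 1: sweep is not passive")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "s11", s)

    @property
    def step(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def magnitude_db(self) -> np.ndarray:
        """|S11| in dB, floored to avoid log(0) at a perfect null."""
        mag = np.abs(self.s11)
        return 20.0 * np.log10(np.maximum(mag, 1e-30))


@dataclass(frozen=True)
class ResonancePoint:
    """Extracted resonance: dip frequency, loaded Q, and dip depth (dB)."""

    f0: float
    q_loaded: float
    depth: float

    def __post_init__(self) -> None:
        if self.q_loaded <= 0:
            raise ValueError("q_loaded must be > 0")
        if self.depth > 0:
            raise ValueError("dip depth must be <= 0 dB")


def vna_grid(
    f_start: float = 1e5, f_stop: float = 3.0001e9, n_points: int = 10_001
) -> np.ndarray:
    """Default VNA frequency grid: 10 001 points, 0.0001–3.0001 GHz in
    steps of 0.0003 GHz."""
    return np.linspace(f_start, f_stop, n_points)


def fill_ratio(d_out: float, d_in: float) -> float:
    """Spiral fill ratio rho = (d_out - d_in) / (d_out + d_in).

    Scale-invariant: multiplying both diameters by any positive factor
    leaves rho unchanged.  rho = 1 for a filled disc (d_in = 0) and -> 0 as
    the annulus thins.
    """
    if not d_out > d_in >= 0:
        raise ValueError("require d_out > d_in >= 0 for a physical layout")
    return (d_out - d_in) / (d_out + d_in)


def spiral_inductance(
    n: int,
    d_avg: float,
    rho: float,
    coeffs: LayoutCoefficients = CIRCULAR_LAYOUT,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Current-sheet inductance of a planar spiral (H).

    L = mu0 * n^2 * d_avg * (c1 / 2) * [ln(c2 / rho) + c3*rho + c4*rho^2]

    with turn count ``n``, average diameter ``d_avg`` (m) and fill ratio
    ``rho``.  The logarithm diverges as rho -> 0, so rho must be positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if d_avg <= 0:
        raise ValueError("d_avg must be > 0")
    if not 0 < rho <= 1:
        raise ValueError("fill ratio must satisfy 0 < rho <= 1")
    bracket = math.log(coeffs.c2 / rho) + coeffs.c3 * rho + coeffs.c4 * rho**2
    return constants.mu0 * n**2 * d_avg * (coeffs.c1 / 2.0) * bracket


def circinate_capacitance(
    geom: ResonatorGeometry, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Capacitance (F) of the circular interdigital capacitor.

    Conformal-mapping form (see module docstring): with k = a/b,

        C = L_C * [ eps0 * (1 + eps_sub)/2 * K(k')/K(k) + eps0 * t / a ]

    where K is the complete elliptic integral of the first kind and
    k' = sqrt(1 - k^2).  Linear in the finger length L_C.
    """
    if not 0 < geom.a < geom.b:
        raise ValueError("require 0 < a < b so that 0 < k < 1")
    k = geom.a / geom.b
    m = k * k  # scipy's ellipk takes the parameter m = k^2
    ratio = ellipk(1.0 - m) / ellipk(m)
    per_length = (
        constants.eps0 * (1.0 + geom.substrate_eps) / 2.0 * ratio
        + constants.eps0 * geom.nitride_thickness / geom.a
    )
    return per_length * geom.finger_length


def resonant_frequency(L: float, C: float) -> float:
    """Resonant frequency f = 1 / (2*pi*sqrt(L*C)) in Hz."""
    if L <= 0 or C <= 0:
        raise ValueError("L and C must be > 0")
    return 1.0 / (2.0 * math.pi * math.sqrt(L * C))


def synth_s11(
    grid: np.ndarray,
    f0: float,
    q_loaded: float,
    coupling: float,
    z0: float = 50.0,
) -> SParamSweep:
    """Synthesise the one-port reflection of a resonator on ``grid``.

    Standard reflection of a single resonance coupled to a matched line
    with coupling factor beta:

        S11(f) = [(1 - beta) + j*Q0*x] / [(1 + beta) + j*Q0*x]

    where x = f/f0 - f0/f is the fractional detuning and Q0 = q_loaded *
    (1 + beta) is the unloaded Q.  |S11| <= 1 everywhere, -> 1 far from
    resonance, and vanishes at f0 for critical coupling (beta = 1).
    """
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= f0 <= grid[-1]:
        raise ValueError("f0 must lie within the sweep span")
    if q_loaded <= 0 or coupling <= 0:
        raise ValueError("q_loaded and coupling must be > 0")
    q0 = q_loaded * (1.0 + coupling)
    x = grid / f0 - f0 / grid
    jqx = 1j * q0 * x
    s11 = ((1.0 - coupling) + jqx) / ((1.0 + coupling) + jqx)
    return SParamSweep(frequencies=grid, s11=s11, z0=z0)


# Minimum dip prominence (relative drop of |S11| below its sweep maximum)
# for a resonance to be declared present.
_MIN_DIP_PROMINENCE = 1e-3


def extract_resonance(sweep: SParamSweep) -> ResonancePoint:
    """Locate the S11 dip and estimate f0, loaded Q, and depth.

    f0 is refined by parabolic interpolation of the log-magnitude through
    the grid minimum and its two neighbours (ties between equal adjacent
    minima break toward lower frequency).  The loaded Q is the refined f0
    divided by the full width at half maximum of the absorbed power
    1 - |S11|^2, with the half-level crossings located by linear
    interpolation.

    Raises
    ------
    ValueError
        If the sweep has no interior dip (monotone or flat magnitude) or
        the half-power bandwidth is not resolved within the span.
    """
    mag = np.abs(sweep.s11)
    i = int(np.argmin(mag))  # argmin breaks ties toward lower frequency
    if i == 0 or i == mag.size - 1:
        raise ValueError("no resonance found: |S11| minimum lies on the span edge")
    if mag.max() - mag[i] < _MIN_DIP_PROMINENCE * max(mag.max(), 1e-30):
        raise ValueError("no resonance found: sweep magnitude is flat")

    db = sweep.magnitude_db()
    y0, y1, y2 = db[i - 1], db[i], db[i + 1]
    denom = y0 - 2.0 * y1 + y2
    # Degenerate (collinear) neighbourhood: keep the grid point itself.
    shift = 0.0 if denom <= 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    f0 = float(sweep.frequencies[i] + shift * sweep.step)
    depth = float(y1)

    # Loaded Q from the FWHM of the absorbed power 1 - |S11|^2.
    absorbed = 1.0 - mag**2
    half = 0.5 * absorbed[i]
    below = absorbed < half

    def _crossing(direction: int) -> float:
        j = i
        while 0 < j < absorbed.size - 1 and not below[j]:
            j += direction
        if not below[j]:
            raise ValueError("half-power bandwidth not resolved within the span")
        # linear interpolation between j-direction (above half) and j (below)
        a_hi, a_lo = absorbed[j - direction], absorbed[j]
        frac = (a_hi - half) / (a_hi - a_lo)
        return float(
            sweep.frequencies[j - direction]
            + direction * frac * sweep.step
        )

    f_lo = _crossing(-1)
    f_hi = _crossing(+1)
    q_loaded = f0 / (f_hi - f_lo)
    return ResonancePoint(f0=f0, q_loaded=q_loaded, depth=depth)
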