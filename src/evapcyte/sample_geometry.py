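"""Deterministic arithmetic linking droplet concentration and volume to
deposited cell counts, the monolayer capacity of the chip surface, and
stacked-layer height bounds.

The assay pipettes a 1 uL droplet of cell suspension onto a ~1 mm x 1 mm
sensing chip; after evaporation the cells remain.  For K562 white blood
cells the mean diameter is about 15 um, giving a maximum cross-section of
~1.8e-10 m^2, so a monolayer saturates at roughly 5660 cells — deposited
counts across the standard doubling ladder (250–8000 cells per droplet)
stay below one monolayer, and stacking adds at most a few cell diameters
of height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SampleSpec",
    "ChipSurface",
    "concentration_ladder",
    "droplet_cell_count",
    "max_cross_section",
    "monolayer_capacity",
    "stack_height_range",
    "round_to_sig_figs",
]

#: Default K562 cell diameter (m).
DEFAULT_CELL_DIAMETER = 15e-6
#: Default membrane thickness (m), the stacking floor per membrane.
DEFAULT_MEMBRANE_THICKNESS = 10e-9


@dataclass(frozen=True)
class SampleSpec:
    """A droplet sample: concentration (cells/mL), volume (uL), and the
    cell dimensions used in geometry arithmetic."""

    concentration: float
    volume_ul: float = 1.0
    cell_diameter: float = DEFAULT_CELL_DIAMETER
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.volume_ul <= 0:
            raise ValueError("volume must be > 0")
        if self.cell_diameter <= 0:
            raise ValueError("cell diameter must be > 0")
        if self.membrane_thickness < 0:
            raise ValueError("membrane thickness must be >= 0")


@dataclass(frozen=True)
class ChipSurface:
    """Rectangular sensing surface; defaults to 1 mm x 1 mm."""

    width: float = 1e-3
    height: float = 1e-3

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("chip dimensions must be > 0")

    @property
    def area(self) -> float:
        return self.width * self.height


def concentration_ladder(
    base: float = 0.25e6, steps: int = 6, factor: float = 2.0
) -> list[float]:
    """The doubling concentration ladder, by default the six standard
    values 0.25, 0.5, 1, 2, 4, 8 x 10^6 cells/mL."""
    if base <= 0 or steps < 1 or factor <= 0:
        raise ValueError("base > 0, steps >= 1, factor > 0 required")
    return [base * factor**i for i in range(steps)]


def droplet_cell_count(spec: SampleSpec) -> float:
    """Expected number of cells deposited by one droplet.

    count = concentration [cells/mL] x volume [uL] x 1e-3 [mL/uL];
    exact for the standard ladder (250 ... 8000 cells at 1 uL).
    """
    return spec.concentration * spec.volume_ul * 1e-3


def max_cross_section(cell_diameter: float) -> float:
    """Maximum (equatorial) cross-sectional area of a spherical cell, m^2."""
    if cell_diameter <= 0:
        raise ValueError("cell diameter must be > 0")
    return math.pi * (cell_diameter / 2.0) ** 2


def round_to_sig_figs(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


def monolayer_capacity(
    chip: ChipSurface, cell_diameter: float = DEFAULT_CELL_DIAMETER
) -> tuple[float, float]:
    """Number of cells needed to tile the chip surface with one layer.

    Returns ``(raw, rounded)``: the raw ratio chip_area / cross-section and
    its 3-significant-figure report.  For the default 1 mm x 1 mm chip and
    15 um cells this is (5658.8..., 5660).  The value is a lower bound on
    the true capacity — deformable cells squeeze together, so the real
    count is somewhat larger.
    """
    raw = chip.area / max_cross_section(cell_diameter)
    return raw, round_to_sig_figs(raw, 3)


def stack_height_range(
    count: float,
    capacity: float,
    cell_diameter: float = DEFAULT_CELL_DIAMETER,
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS,
    max_layers: int | None = None,
) -> tuple[float, float]:
    """Bounds (m) on the height of the deposited cell stack.

    ``layers = ceil(count / capacity)`` (optionally capped at
    ``max_layers``).  The lower bound takes stacked cells as collapsed down
    to their membranes — ``h_min = min(layers, 2) * membrane_thickness`` —
    and the upper bound as intact spheres, ``h_max = layers *
    cell_diameter``.  The canonical two-layer case with 15 um cells and
    10 nm membranes gives (0.02 um, 30 um).  ``count = 0`` gives (0, 0).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    if count == 0:
        return 0.0, 0.0
    layers = math.ceil(count / capacity)
    if max_layers is not None:
        layers = min(layers, max_layers)
    h_min = min(layers, 2) * membrane_thickness
    h_max = layers * cell_diameter
    return h_min, h_max
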