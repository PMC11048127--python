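"""Physical constants used by the circuit and dielectric models."""

from dataclasses import dataclass

import scipy.constants


@dataclass(frozen=True)
class PhysicalConstants:
    """Vacuum constants.

    ``eps0`` defaults to 8.854e-12 F/m, the four-significant-figure value
    conventionally quoted in microwave design work; ``mu0`` and ``c_light``
    are CODATA values from :mod:`scipy.constants`.
    """

    mu0: float = scipy.constants.mu_0  # H/m
    eps0: float = 8.854e-12  # F/m
    c_light: float = scipy.constants.c  # m/s


CONSTANTS = PhysicalConstants()
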