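"""Circuit model: design equations, S11 synthesis and dip extraction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ellipk

from evapcyte.circuit_model import (
    CIRCULAR_LAYOUT,
    ResonatorGeometry,
    SParamSweep,
    circinate_capacitance,
    extract_resonance,
    fill_ratio,
    resonant_frequency,
    spiral_inductance,
    synth_s11,
    vna_grid,
)

# Frozen oracle values (sympy, 50-digit evaluation of the same algebra).
L_SPIRAL_REF = 1.9016128216419554e-10  # n=1, d_avg=200um, rho=0.5, circular
C_CIRC_REF = 7.8613660011700532e-14  # L_C=1mm, a=10um, b=20um, eps=12.85, t=0.2um
F_1NH_1PF = 5.03292121044870e9


class TestFillRatio:
    @pytest.mark.parametrize(
        "d_out, d_in, expected",
        [(300e-6, 100e-6, 0.5), (1e-3, 0.0, 1.0), (5.0, 3.0, 0.25)],
    )
    def test_values(self, d_out, d_in, expected):
        assert fill_ratio(d_out, d_in) == pytest.approx(expected, rel=1e-15)

    def test_degenerate_annulus_limit(self):
        d = 1e-4
        assert fill_ratio(d, d * (1 - 1e-12)) == pytest.approx(0.0, abs=1e-11)

    @pytest.mark.parametrize("d_out, d_in", [(1e-4, 1e-4), (1e-4, 2e-4), (1e-4, -1e-6)])
    def test_nonphysical_layout_rejected(self, d_out, d_in):
        with pytest.raises(ValueError):
            fill_ratio(d_out, d_in)

    @given(
        d_out=st.floats(1e-6, 1e-2),
        ratio=st.floats(0.0, 0.999),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, d_out, ratio, scale):
        d_in = d_out * ratio
        assert fill_ratio(d_out * scale, d_in * scale) == pytest.approx(
            fill_ratio(d_out, d_in), rel=1e-12
        )


class TestSpiralInductance:
    def test_frozen_reference_value(self):
        L = spiral_inductance(1, 200e-6, 0.5, CIRCULAR_LAYOUT)
        assert L == pytest.approx(L_SPIRAL_REF, rel=1e-12)

    def test_turn_count_squared_proportionality(self):
        L1 = spiral_inductance(1, 200e-6, 0.5)
        L2 = spiral_inductance(2, 200e-6, 0.5)
        assert L2 / L1 == pytest.approx(4.0, rel=1e-15)

    def test_circular_preset_coefficients(self):
        assert (
            CIRCULAR_LAYOUT.c1,
            CIRCULAR_LAYOUT.c2,
            CIRCULAR_LAYOUT.c3,
            CIRCULAR_LAYOUT.c4,
        ) == (1.00, 2.16, 0.00, 0.20)

    def test_zero_fill_ratio_rejected(self):
        with pytest.raises(ValueError):
            spiral_inductance(1, 200e-6, 0.0)

    def test_matches_arbitrary_precision_evaluation(self):
        """Independent 50-digit sympy evaluation agrees to >= 10 digits."""
        import sympy as sp

        from evapcyte.constants import CONSTANTS

        rng = np.random.default_rng(7)
        mu0 = sp.Float(CONSTANTS.mu0, 50)
        c1, c2, c3, c4 = (sp.Float(c, 50) for c in
                          (CIRCULAR_LAYOUT.c1, CIRCULAR_LAYOUT.c2,
                           CIRCULAR_LAYOUT.c3, CIRCULAR_LAYOUT.c4))
        for _ in range(20):
            n = int(rng.integers(1, 10))
            d_avg = float(rng.uniform(1e-5, 1e-2))
            rho = float(rng.uniform(1e-3, 1.0))
            expected = float(
                mu0 * n**2 * sp.Float(d_avg, 50) * (c1 / 2)
                * (sp.log(c2 / sp.Float(rho, 50))
                   + c3 * sp.Float(rho, 50) + c4 * sp.Float(rho, 50) ** 2)
            )
            assert spiral_inductance(n, d_avg, rho) == pytest.approx(
                expected, rel=1e-10
            )


class TestCircinateCapacitance:
    @staticmethod
    def geom(**kw):
        base = dict(n=1, d_out=300e-6, d_in=100e-6, finger_length=1e-3,
                    a=10e-6, b=20e-6)
        base.update(kw)
        return ResonatorGeometry(**base)

    def test_frozen_reference_value(self):
        assert circinate_capacitance(self.geom()) == pytest.approx(
            C_CIRC_REF, rel=1e-12
        )

    def test_linear_in_finger_length(self):
        c1 = circinate_capacitance(self.geom(finger_length=1e-3))
        c2 = circinate_capacitance(self.geom(finger_length=2e-3))
        assert c2 / c1 == pytest.approx(2.0, rel=1e-14)

    def test_elliptic_integral_closed_form(self):
        # K(0) = pi/2 to >= 12 significant digits
        assert ellipk(0.0) == pytest.approx(math.pi / 2, rel=1e-13)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            self.geom(a=20e-6, b=10e-6)


class TestResonantFrequency:
    def test_unit_inputs(self):
        assert resonant_frequency(1.0, 1.0) == pytest.approx(
            1.0 / (2 * math.pi), rel=1e-15
        )

    def test_nanohenry_picofarad(self):
        assert resonant_frequency(1e-9, 1e-12) == pytest.approx(F_1NH_1PF, rel=1e-13)

    def test_square_root_scaling(self):
        f1 = resonant_frequency(2e-9, 3e-12)
        f2 = resonant_frequency(4e-9, 6e-12)
        assert f1 / f2 == pytest.approx(2.0, rel=1e-14)

    @pytest.mark.parametrize("L, C", [(0.0, 1e-12), (1e-9, -1e-12)])
    def test_nonpositive_rejected(self, L, C):
        with pytest.raises(ValueError):
            resonant_frequency(L, C)

    def test_monotone_in_l_and_c(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            L = rng.uniform(1e-10, 1e-7)
            C = rng.uniform(1e-14, 1e-11)
            assert resonant_frequency(L * 1.1, C) < resonant_frequency(L, C)
            assert resonant_frequency(L, C * 1.1) < resonant_frequency(L, C)


class TestSynthS11:
    def test_dip_at_grid_point_nearest_f0(self, grid):
        sweep = synth_s11(grid, 1.28e9, q_loaded=80, coupling=0.9)
        dip = grid[np.argmin(np.abs(sweep.s11))]
        assert dip == pytest.approx(1.2799e9, rel=1e-12)

    def test_critical_coupling_null(self, grid):
        f0 = float(grid[4266])  # exactly on the grid
        sweep = synth_s11(grid, f0, q_loaded=80, coupling=1.0)
        assert sweep.magnitude_db().min() < -60.0

    @given(
        f0=st.floats(1e8, 2.9e9),
        q=st.floats(5, 500),
        beta=st.floats(0.05, 5.0),
    )
    def test_passivity(self, f0, q, beta):
        sweep = synth_s11(vna_grid(), f0, q, beta)
        assert np.max(np.abs(sweep.s11)) <= 1.0 + 1e-12

    def test_f0_outside_span_rejected(self, grid):
        with pytest.raises(ValueError):
            synth_s11(grid, 5e9, 80, 0.9)


class TestExtractResonance:
    def test_round_trip_f0(self, grid):
        point = extract_resonance(synth_s11(grid, 1.28e9, 80, 0.9))
        assert abs(point.f0 - 1.28e9) < 0.00015e9

    def test_round_trip_many_f0(self, grid):
        step = grid[1] - grid[0]
        rng = np.random.default_rng(5)
        for f0 in rng.uniform(0.05e9, 2.95e9, size=10):
            est = extract_resonance(synth_s11(grid, f0, 80, 0.9)).f0
            assert abs(est - f0) <= step / 2

    @pytest.mark.parametrize("q_true", [20.0, 80.0, 200.0])
    def test_q_recovery_within_5_percent(self, grid, q_true):
        point = extract_resonance(synth_s11(grid, 1.28e9, q_true, 0.9))
        assert point.q_loaded == pytest.approx(q_true, rel=0.05)

    def test_flat_sweep_rejected(self, grid):
        sweep = SParamSweep(grid, np.full(grid.size, 0.9 + 0j))
        with pytest.raises(ValueError, match="no resonance"):
            extract_resonance(sweep)

    def test_monotone_sweep_rejected(self, grid):
        mags = np.linspace(1.0, 0.5, grid.size)
        with pytest.raises(ValueError, match="no resonance"):
            extract_resonance(SParamSweep(grid, mags.astype(complex)))

    def test_depth_is_negative_db(self, grid):
        point = extract_resonance(synth_s11(grid, 1.28e9, 80, 0.9))
        assert point.depth < 0


class TestSParamSweep:
    def test_nonuniform_grid_rejected(self):
        freqs = np.array([1e6, 2e6, 4e6, 8e6])
        with pytest.raises(ValueError, match="uniform"):
            SParamSweep(freqs, np.zeros(4, dtype=complex))

    def test_active_sweep_rejected(self, grid):
        with pytest.raises(ValueError, match="passive"):
            SParamSweep(grid, np.full(grid.size, 1.5 + 0j))
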