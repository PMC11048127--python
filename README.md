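# evapcyte

Modelling and calibration toolkit for **evaporation-endpoint microwave
resonator cytometry** — counting white blood cells (WBCs) from the
resonant-frequency shift of a planar LC-resonator biosensor measured after a
cell droplet has fully evaporated on the chip.

## The problem

Live WBCs suspended in PBS are nearly invisible to a microwave sensor: the
cells maintain isotonicity with the buffer, so suspension and buffer have
almost the same permittivity regardless of cell count. The
evaporation-endpoint protocol sidesteps this: a 1 µL droplet is pipetted
onto the chip, the solvent evaporates (~10 min), and only the deposited
cells remain. Dry cells in air are dielectrically very different from air,
so the endpoint resonance shift tracks the deposited count — and because a
1 µL droplet at concentration *x* cells/mL deposits *x*·10⁻³ cells, it
tracks concentration linearly.

The package is aimed at sensor designers and assay developers who need the
full computational chain — resonator design equations, dielectric models,
sample-geometry arithmetic, calibration, and synthetic data for pipeline
validation — without access to a fabrication line or a VNA.

## Models

**Resonator.** The sensor is a spiral inductor around a circular
interdigital capacitor on GaAs (εsub = 12.85, tan δ = 2.8·10⁻⁴, 200 µm).
Current-sheet inductance with fill ratio ρ = (d_out − d_in)/(d_out + d_in):

    L = μ₀ n² d_avg (c₁/2) [ln(c₂/ρ) + c₃ρ + c₄ρ²],   (c₁..c₄) = (1.00, 2.16, 0.00, 0.20)

Interdigital capacitance by conformal mapping with complete elliptic
integrals, k = a/b, k′ = √(1 − k²):

    C = L_C [ ε₀(1 + εsub)/2 · K(k′)/K(k) + ε₀ t/a ],

and f₀ = 1/(2π√(L_total C_total)). A one-port reflection model
renders S11 dips; dips are re-extracted by parabolic interpolation with
loaded Q from the half-power bandwidth.

**Dielectrics.** Penetration depth
Dp = λ₀/(2π√(2ε′)) · [√(1 + (ε″/ε′)²) − 1]^(−1/2); the single-shell
spherical cell model εP = εmem(γ³ + 2h)/(γ³ − h) with γ = R/(R − d),
h = (εi − εmem)/(εi + 2εmem); Maxwell–Garnett effective-medium mixing; and
the standard frequency-regime classification of the cell equivalent circuit
(EDL < 1 kHz < membrane polarisation < 1 MHz < membrane charging <
100 MHz < cytoplasm-sensitive).

**Calibration.** Endpoint frequency vs concentration is fitted by OLS,
y = slope·x + intercept (GHz; cells/mL). Sensitivity is |slope| in Hz per
cells/mL — the reference line y = −0.02506·10⁻⁶ x − 1.65475 gives
25.06 Hz/(cells·mL⁻¹). Concentration is recovered by inverse prediction
with a first-order t-interval.

## Worked example

```python
from evapcyte import *
from evapcyte.synthetic_data import EndpointSimConfig, simulate_endpoint_dataset

table = simulate_endpoint_dataset(EndpointSimConfig(seed=1))   # 6 conc x 3 reps
curve = fit_line(table)
print(curve.slope, curve.r_squared, curve.sensitivity_hz)
est = invert_concentration(curve, predict_frequency(curve, 1.5e6))
print(est.estimate, est.ci_low, est.ci_high)
```

prints

```
slope     = -2.515299e-08 GHz per cells/mL
r^2       = 0.99958
sensitivity = 25.15 Hz per cells/mL
estimate  = 1.500e+06 cells/mL  95% CI [1.371e+06, 1.629e+06]
```

i.e. a calibration run at the six-step doubling ladder (0.25–8 ×10⁶
cells/mL, 3 replicates, 3.8% relative scatter) recovers the generating
sensitivity to 0.4%, and an observed endpoint frequency inverts to its true
concentration with a ±9% interval.

The CLI exposes the same chain (`evapcyte design | geometry | simulate |
fit | invert`):

```bash
evapcyte geometry                       # monolayer capacity, ladder, stack heights
evapcyte simulate --kind endpoint --seed 7 --out run/
evapcyte fit --input run/endpoint_table.csv --out run/curve.json
evapcyte invert --curve run/curve.json -- -1.70
```

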