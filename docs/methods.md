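# Methods

## Scope and modelling stance

`evapcyte` models the computational chain of an evaporation-endpoint
microwave cytometry assay: lumped-element design equations for the
resonator, dielectric models for cells and deposited layers, deterministic
sample-geometry arithmetic, linear calibration with inverse prediction, and
a synthetic-data layer that emulates both the endpoint measurement tables
and the full evaporation time course. It deliberately contains no
full-wave electromagnetics: the fabricated device's exact layout is not
public, so the 1.28 GHz design point is used only as a synthetic operating
frequency (`default_circuit`), never derived from geometry.

## Circuit model

Inductance uses the current-sheet approximation with the circular-layout
coefficients (1.00, 2.16, 0.00, 0.20). The interdigital capacitance uses
the conformal-mapping form

    C/L_C = ε₀(1 + εsub)/2 · K(k′)/K(k) + ε₀·t/a,  k = a/b, k′ = √(1−k²),

the standard coplanar half-space result plus a thin-film correction for the
SiNx passivation (thickness t, normalised by the inner radius a). The
correction term is this package's documented reading of an ambiguous
printed source form; it is small (≲0.3% at the reference geometry) and the
whole expression is pinned by a 50-digit arbitrary-precision regression
value in the tests. Parasitics (C_SiNx, C_ab, C_sub, R_sub) have no
published closed forms and are carried as user-supplied configuration
folded into C_total.

The one-port reflection model is the canonical coupled-resonance form
S11 = [(1−β) + jQ₀x]/[(1+β) + jQ₀x] with detuning x = f/f₀ − f₀/f,
coupling β, and unloaded Q₀ = Q_L(1+β). It is passive by construction,
nulls at critical coupling, and has the useful exact property that the full
width at half maximum of the absorbed power 1 − |S11|² equals f₀/Q_L, which
is how `extract_resonance` estimates Q. Dip localisation uses parabolic
interpolation of the dB magnitude through the grid minimum; ties between
equal adjacent minima break toward lower frequency, and the interpolation
shift is clipped to ±half a grid step. Frequencies are Hz internally, GHz
at user surfaces; the default VNA grid is exactly 10 001 points from 10⁵ to
3.0001·10⁹ Hz (0.3 MHz step).

## Dielectrics

Penetration depth implements the standard lossy-dielectric closed form
(the only dimensionally consistent reading of the usual shorthand); its
low-loss limit λ₀√ε′/(2πε″) is the pinning test, and a lossless medium
returns an explicit `math.inf` sentinel so downstream code never has to
guess at "a large number". The single-shell cell model is evaluated in
complex arithmetic with explicit singularity guards (tolerance 10⁻¹² on
the two denominators). Effective-medium mixing defaults to
Maxwell–Garnett for spherical inclusions — chosen because the assay's
narrative (permittivity rises monotonically with deposited load) needs a
monotone, endpoint-respecting rule — with a linear volume-weighted rule
behind a switch for sensitivity analysis. Regime classification uses
half-open bands [low, high): 1 kHz, 1 MHz and 100 MHz belong to the higher
regime, making classification deterministic at the printed thresholds.

No Debye/Cole–Cole dispersion and no temperature dependence are modelled.
Membrane and cytoplasm permittivities for K562 cells are not established
values; the defaults used in examples (εmem = 6, εi = 60) are placeholders
typical of mammalian cells, not measurements.

## Sample geometry

Counts are concentration × volume with the mL/µL conversion; the default
chip (1 mm²) and cell (15 µm) give a raw monolayer capacity of 5658.8,
reported alongside its 3-significant-figure rounding 5660. Note an
internal inconsistency of the conventional figures: the raw capacity
follows from the unrounded cross-section π(7.5 µm)² = 1.767·10⁻¹⁰ m²,
whereas the 2-s.f. area 1.8·10⁻¹⁰ m² would give ≈5556; the module returns
both raw and rounded values so callers can choose. The capacity is a lower
bound — deformable cells pack tighter.

Stack heights generalise a two-layer estimate: with `layers =
ceil(count/capacity)`, the lower bound treats stacked cells as collapsed to
their membranes, h_min = min(layers, 2)·(10 nm), and the upper bound as
intact spheres, h_max = layers·(15 µm); the two-layer case reproduces the
canonical (0.02 µm, 30 µm). The 10 nm membrane default is back-derived
from that 0.02 µm floor and is overridable. No packing-fraction or droplet
spreading physics is attempted.

## Calibration

`fit_line` is ordinary least squares of endpoint frequency on
concentration, replicates entering individually (a mean-per-concentration
flag exists for comparison); r² is the squared Pearson correlation of
fitted vs observed, which for a simple line equals the coefficient of
determination. Sensitivity is |slope|·10⁹ Hz per cells/mL. The curve is
treated as an abstract affine map: the reference intercept is negative and
no sign convention for "shift" is imposed.

Inverse prediction uses the first-order (delta-method) interval for a new
observation, x̂ ± t_{n−2}·(s/|m|)·√(1 + 1/n + (x̂−x̄)²/Sxx) — the smallest
defensible method for a 6-concentration calibration; no Fieller or Bayesian
variant. Negative estimates are clipped to zero and flagged, never
silently returned. Slopes below 10⁻¹⁵ GHz per cells/mL raise a
non-invertible-calibration error.

## Synthetic data

**Endpoint datasets.** Replicate endpoint frequencies are the configured
line plus additive Gaussian noise with SD = `noise_sd` × |slope| ×
mean(concentrations), i.e. relative to the *mean frequency shift* across
the design. This is the scale on which the assay's replicate scatter
(< 3.8%) is quoted; scaling the same percentage by the absolute resonant
frequency (~1.7 GHz) would imply ~65 MHz scatter, an order of magnitude
larger than the total concentration-induced shift span and inconsistent
with the near-unity r² the assay reports. Defaults are the study
conditions: six doubling concentrations 0.25–8·10⁶ cells/mL, 3 replicates,
noise_sd = 0.038. An `antithetic=True` companion dataset negates the noise
draws of the same seed; averaging statistics over seed/antithetic pairs
cancels their first-order Monte-Carlo error while preserving any systematic
bias, which is why the bias checks use paired datasets.

**Evaporation traces.** Droplet volume decays exponentially to 1% of its
initial value at `dry_time` (default 600 s — a 1 µL droplet dries in about
ten minutes; a linear law is available). Solvent loss concentrates the
suspended cells: the volume fraction φ(t) = φ₀·V₀/V(t) (capped at random
close packing, 0.74) feeds Maxwell–Garnett mixing of a high-permittivity
solute phase (default ε = 100) in the aqueous host (default ε = 78), and
the resulting surface permittivity loads the resonator through a single
capacitance-loading coefficient κ: C(ε) = C_total(1 + κ(ε − 1)), default
κ = 0.002 so traces span a plausible band below the 1.28 GHz bare-chip
point. κ is an instrument-scale knob, not derived physics. At `dry_time`
the wet loading disappears instantaneously between samples (the real
transition is too fast to record manually) and the frequency jumps up to a
dry-residue plateau with permittivity 1.05 + 2.5·10⁻⁷·(concentration) —
a monotone placeholder constrained only by the qualitative orderings the
assay reports: higher concentration → lower plateau, and the pure-PBS
residue (default ε = 1.425) strictly between the 1·10⁶ and 2·10⁶ cells/mL
cases (enforced at config validation). An optional `plateau_line` pins the
plateau directly to an affine map of concentration for end-to-end
calibration recovery tests. Trace noise is multiplicative Gaussian on f₀
(additive available). Every time point is rendered as a full S11 sweep on
the VNA grid and the dip re-extracted from it, so traces exercise the same
signal path as measured data; `TracePoint.f0_model` retains the rendered
model frequency so shape invariants can be tested exactly, separately from
extraction jitter (≤ half a grid step).

What the generator does **not** emulate: evaporation physics (diffusion,
humidity, contact-line dynamics), coffee-ring deposition patterns, cell
viability, electrode polarisation drift, or VNA trace noise correlated
across frequency. Passing tests therefore demonstrate the pipeline's
statistical and numerical correctness under the stated noise model, not
robustness to those real-data effects.

**Plateau detection** (`detect_plateau`): the largest positive frequency
step must be upward, exceed 3× the largest other absolute step, and leave
at least 3 samples after it; otherwise the trace is rejected (this is what
flags truncated traces).

## Problem sizes and runtime choices

The test suite and the acceptance script use: 100-point random parameter
sweeps for the inductance cross-check against a 50-digit sympy evaluation
(agreement required to 10 significant digits); 50 random dips for the
resonance round trip on the full 10 001-point grid; 100 seed pairs (200
datasets) for the slope-bias check; 1000 simulations for the
inverse-prediction coverage study (nominal 95%, accepted 93–97%); and
traces sampled every 30–60 s in tests (5 s default in the API). These
sizes give Monte-Carlo standard errors comfortably below the margins being
tested while keeping a full run to a few seconds.

## Known limitations

- The fabricated resonator geometry is not public, so design equations are
  validated against arbitrary-precision evaluation of themselves and
  printed-value spot checks, not against a measured device.
- The dry-residue permittivity map and κ are qualitative placeholders; the
  simulator's absolute frequency shifts should not be read as predictions.
- The inverse-prediction interval assumes homoscedastic Gaussian residuals
  and a high slope signal-to-noise ratio; both hold under the default
  generator but should be re-checked for sparser designs.
- The coplanar capacitance parse is a documented choice among plausible
  readings of a corrupted printed formula; alternative readings change C by
  an overall factor but not its scaling in L_C, k or εsub.
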