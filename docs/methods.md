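# Methods

This note records the model behind `zandry`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real drying data.

## Transport model

The pericarp is treated as a rigid, homogeneous, isotropic porous medium —
no shrinkage, no explicit gas phase, local thermal equilibrium between
phases. On a 1-D domain (sphere of radius R for a single berry, slab of
half-thickness L for a bulk layer; coordinate 0 at the center/midplane,
the exposed surface at R or L) the solver advances

    ρ_m C_p ∂T/∂t = ∇·(k_p ∇T) + Q_mode − L_v G_evap
    ∂C_w/∂t       = ∇·(D_w ∇C_w) − G_evap

where T is in °C, C_w (kg/m³) is liquid-water concentration, related to
dry-basis moisture by C_w = M·ρ_dry with ρ_dry = C_w0/M₀ fixed by the
initial state (707.61/2.03 ≈ 348.6 kg/m³).

**Evaporation sink.** G_evap = K_evap·C_w·max(0, p_sat(T) − p_opp)/p_atm,
zero once M falls to the equilibrium moisture (a 0.02 kg/kg ramp smooths
the cut-off for the implicit solver). p_sat comes from an Antoine
correlation log₁₀(p_kPa) = A − B/(C + T_K) with the tissue-specific
constants (A = 7.8087, B = 1007.839, C = −166.3583); the correlation reads
low against steam tables at low temperatures, which is tolerable because
the sink magnitude is rescaled by the calibrated K_evap anyway. The
opposing pressure p_opp is the chamber **total** pressure for the vacuum
modes (the chamber gas there is essentially water vapor) but the ambient
**vapor partial pressure** for hot air (default 1.57 kPa, from the stated
9.8 g/kg ambient humidity): using the 101.325 kPa total there would make
hot-air evaporation impossible below 100 °C. Water leaving through the
surface boundary evaporates at the surface, so the thermal boundary
carries the matching latent sink.

**Diffusivity.** D_w = r²·(−39.41·ln M − 8.247)/T_K with the calibration
scalar r² = 1e−9 m²·K by default, clamped below at 1e−12 m²/s. The printed
correlation is negative for M > exp(−8.247/39.41) ≈ 0.811 kg/kg — i.e.
through the entire wet stage of a run starting at M₀ = 2.03 — so liquid
transport is effectively frozen until the late stage. This is the model's
single most consequential limitation (see *Known limitations*).

**Sources.** MVD: a spatially uniform volumetric source
η·P_mw·1000·ρ_m (8 W/g nominal); the dielectric field itself is never
solved — the rated power density is its macroscopic surrogate. PVD:
Beer–Lambert deposition of the infrared flux κ·l_i (κ = 0.9,
l_i = 6540 W/m²) with decay length δ; on the slab the planar form
q(z) = η·κ·l_i/δ·e^(−z/δ) (plus the transmitted tail from the opposite
face of the symmetric layer), on the sphere the spherically convergent
form q(r) ∝ (R/r)²·e^(−(R−r)/δ), which conserves the absorbed flux
exactly on any mesh (cell-averaged analytically) and concentrates
deposition toward the center — the geometric origin of core-focused
infrared heating. δ defaults to 2 mm (the order of the berry radius) at
berry scale; a loosely packed layer is far more transparent than tissue,
so the bulk-layer scenario uses a layer-scale decay length of one slab
half-thickness. HAD has no volumetric source.

**Thermostatted source.** Both vacuum dryers regulate to a set
*temperature*, not a power, and the monitored surface temperature
plateaus at the set point; an unregulated constant source instead
diverges once evaporation wanes. The source is therefore modulated in
time: full power below the set temperature, ramping linearly to zero over
a `source_control_band` (default 2 °C) above it. Spatial uniformity of
the deposition profile is unaffected. The band is linearized inside the
implicit solve (the regulation feedback is stiff).

**Boundaries and pressure schedule.** Convective heat
(−k_p ∂T/∂n = h_t(T_s − T_a), h_t = 25 W/(m²·°C)) and moisture
(h_m = 0.025 m/s against the equilibrium moisture 0.01 kg/kg) exchange at
the exposed surface; symmetry at the center. T_a is the drying-air (HAD)
or chamber-gas set temperature (PVD/MVD). The pulsed-vacuum schedule
alternates a 900 s hold at 10 kPa with a 300 s hold at 101.325 kPa,
joined by quintic (C²-continuous) ramps spanning 0.08 of the 1200 s
period; MVD holds 10 kPa continuously and the vacuum enters only through
the evaporation driving force, not the thermal boundary.

## Discretization and numerics

Cell-centered finite volumes (default 40 cells), harmonic-mean interface
diffusivities, implicit Euler with a maximum step of 60 s and Picard
iteration; the iteration stops when the successive-iterate change falls
below abs 0.001 + rel 0.01 of the step change (temperature scale; the
concentration test is scaled by C_w0). Non-convergence or a negative
concentration halves the step down to 1 s before raising a solver error
with the offending state. The strongly stabilizing terms — the latent
sink's temperature sensitivity and the thermostat ramp — are linearized
into the diagonal of the implicit temperature solve.

Energy and mass ledgers are assembled each accepted step from exactly the
coefficient arrays and solutions of that step's linear systems, so the
discrete balances close to machine precision on every run (the tests
assert ≤ 1e−3 relative; observed ~1e−14). The conduction-only limit is
verified against the separation-of-variables slab series to < 0.1 °C.

A run terminates at `t_end` or when the volume-mean moisture reaches the
0.11 kg/kg safe level, whichever comes first; the crossing time is
interpolated linearly. Core/surface summaries are volume-weighted means
over normalized coordinate ≤ 0.5 (core) and ≥ 0.9 (surface shell); the
reported surface temperature is the boundary-face value from the discrete
flux balance, the core temperature the innermost cell.

## Calibration

`calibrate_source_fraction` fits the absorbed fraction η (and a K_evap
multiplier) to a reference drying curve: coordinate descent with a
log-spaced bracket scan plus golden-section refinement (≤ 3 sweeps),
initialized from an energy balance (η from the latent demand of the
reference's moisture loss over its duration) and a rate balance (K from
the first-order sink rate the reference implies at the set temperature).
The objective is the MR RMSE at the reference time points; when the
reference carries a surface-temperature trace and the mode has a tunable
source, a temperature RMSE normalized by the heating span is added —
along the MR curve alone, η and K are mutually degenerate (a weaker
source with a stronger sink dries identically but runs colder), while the
(MR, temperature) pair pins both, which is also the dual-series protocol
used to validate such models. Hot air has no tunable source, so only the
evaporation multiplier is searched there, against MR alone. A bracket
whose objective is monotone *and still improving more than 1% at the
boundary* raises a calibration error advising wider bounds; a
monotone-then-flat profile (hot air saturating at its wet-bulb-limited
drying rate) is accepted at the plateau.

## Synthetic data

The generator emulates the study's measurement structure so every stage is
testable offline: Page-form drying curves MR = exp(−k tⁿ) with additive
Gaussian noise (σ = 0.01 default) clipped to [0, 1], truncated at the
target moisture ratio 0.11/2.03; first-order-lag surface-temperature
traces T_set − (T_set − 20)·e^(−t/τ) with σ_T = 0.5 °C; a 3-method ×
4-temperature quality table with Gaussian replicate scatter (n = 3
indicators, n = 5 CIELAB readings) around the published treatment means,
with an optional planted color outlier. Per-method kinetic defaults
anchor k(T) through an Arrhenius pair to the printed study conditions:
activation energies 25.3/32.1/38.7 kJ/mol and 40 °C drying times
150/640/480 min for MVD/PVD/HAD, Page exponents 1.10/0.95/1.15 (typical
thin-layer range), gravimetric sampling every 5/10/10 min, heating time
constants 2.5/8/5 min (the microwave mode heats fastest, reaching its set
point within minutes). All generators are pure functions of (spec, seed).

What passing tests show: the estimators invert their own forward models
(exactly without noise; to ~10% in k and 0.05 in n at σ = 0.01), the
solver conserves energy and mass, and the pipeline is deterministic. What
they do not show: the noise model is homoscedastic Gaussian on MR, there
is no weighing-interval irregularity, no replicate-level correlation
between indicators, and no drift — real gravimetric data are messier, and
goodness-of-fit numbers on synthetic references are upper bounds. With
four temperatures over a 30 K span and the realistic sampling intervals
above, the σ = 0.01 chain recovers the activation energy with a median
error near 9% for the fastest-drying method (15–32 points per curve) and
near 5% for the slower ones — denser weighing, not a better estimator,
is what would tighten this.

## Quality scoring

ΔE is the CIE76 Euclidean distance against the fresh-sample reference
(31.82, −21.23, 19.51). Chauvenet screening is single-pass — reject x when
n·erfc(|x − mean|/(σ√2)) < 0.5 — with at least two values always retained
and no re-iteration. Min–max normalization treats ΔE as a cost and
dehiscence, volatile oil and amide as benefits. Entropy weights use
p_ij = d_ij/Σd_ij, E_j = −(ln m)⁻¹Σp ln p, W_j ∝ 1 − E_j, with all-zero
columns assigned zero weight. Scoring defaults to the published weight
vector (0.21, 0.18, 0.22, 0.39) for reproducing the study's rankings —
the replicate-level matrix behind those weights was never released, so
they are shipped as constants and never silently mixed with self-computed
entropy weights. F is reported both raw (Σ d·W ∈ [0, 1]) and on the 0–10
display scale the study uses.

## Known limitations

- **Frozen wet-stage diffusivity.** Because the printed D_w correlation is
  non-positive above M ≈ 0.811 kg/kg, liquid water cannot redistribute
  during the wet stage; with a near-uniform microwave temperature field
  the sink then depletes all depths proportionally and the simulated
  core–surface moisture-ratio difference stays near 0.01–0.06 where
  berry-scale observations report 0.2–0.4. Reproducing such gradients
  would need a positive wet-stage diffusivity (or an explicit vapor
  phase), which the adopted closure does not provide.
- **Wet-bulb-limited hot air.** A 10 mm bulk layer cannot match
  berry-level drying times by convective supply alone; calibration then
  drives the evaporation constant to a plateau where the evaporation zone
  collapses into a thin subsurface layer, the interior rests at the
  evaporation-onset temperature, and the surface–core gradient is a few
  tenths of a degree rather than several degrees.
- **Berry-scale conduction evens gradients.** At Bi ≈ 0.11 a 2.5 mm
  sphere cannot sustain multi-degree internal gradients; the
  core-focused infrared signature appears with the correct sign but a
  magnitude of order 0.5 °C.
- No electromagnetic cavity solve, no shrinkage or porosity dynamics, no
  2-D/3-D geometry, dielectric properties are metadata only, and the
  ANOVA/post-hoc layer of assay statistics is out of scope (correlation
  analysis is provided without multiplicity correction).
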