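# Methods

`mwablate` predicts the necrotic zone produced by a multi-slot 2.45 GHz
coaxial microwave-ablation (MWA) antenna inserted in a liver tumor, and uses
that prediction to plan treatment: the smallest input power that completely
necroses the tumor within a time budget, the ablation time as a function of
power, and the collateral damage to surrounding healthy tissue. This note
records the model, its assumptions, the numerical choices, and what the
synthetic phantoms do and do not represent.

## Model

### Electromagnetic source

The antenna (10 slots of width 0.6 mm separated by 0.8 mm gaps, driven
through a coaxial feed) is geometrically axisymmetric, so the time-harmonic
field is solved as the azimuthal-magnetic TM mode on an (r, z) half-plane:

    d/dz[(1/ε̃) ∂H/∂z] + d/dr[(1/(ε̃ r)) ∂(rH)/∂r] + k₀²H = 0,
    ε̃ = ε_r − jσ/(ωε₀),

with perfect-conductor behavior obtained by assigning metal a conductivity of
10⁷ S/m, the analytic coax TEM 1/r profile imposed on the feed dielectric at
the domain top, first-order absorbing conditions on the outer boundaries, and
axis regularity H ∝ r at r = 0. The finite-difference grid (default
0.15 mm) resolves the slot width with four cells. E_r and E_z follow by
differentiation and the deposition density is q = ½σ|E|².

Two deliberate reductions:

* **Axisymmetric EM, heterogeneous thermal.** Tissue heterogeneity enters the
  EM solve through an angle-averaged radial property profile; the full 3D
  heterogeneity is retained in the thermal solve. The axisymmetric deposition
  is rotated onto the voxel grid by bilinear interpolation.
* **Power normalization.** The port amplitude is arbitrary; the mapped
  deposition is rescaled so its volume integral equals η·P_in exactly. The
  single scalar η (the *efficiency*) absorbs everything the reduced model
  does not resolve — the impedance π-matching network, exact conductor radii
  (defaults are a standard MWA coax: 0.135/0.47/0.595/0.895 mm), reflection
  losses. η is fixed by one calibration (below) and never varied afterwards.

A purely analytic backend (`slot_source_model`, superposed exponentially
attenuated spherical kernels per slot) shares the normalization and symmetry
contracts and serves for fast smoke runs and backend cross-checks; the
full-wave backend is the default.

Because the tissue dielectric depends on temperature, the EM problem is
re-solved whenever any voxel has drifted more than 10 °C (configurable) since
the last solve.

### Bioheat equation

Temperature obeys the Pennes equation with evaporation-corrected heat
capacity,

    ρ c_eff(T) ∂T/∂t = ∇·(k∇T) + ρ_b W_b c_b (T_b − T) + Q_ext + Q_m,

on the labeled voxel grid: initial temperature 37 °C, zero-flux outer
boundaries and antenna surface, antenna-interior voxels excluded from the
solve, and Q_m = 0 by default. Temperatures are not capped at 100 °C; the
latent-heat term in c_eff is the physical sink that arrests the rise near the
boiling band.

### Material models

Baselines (37 °C): healthy liver ρ=1079 kg/m³, ε_r=44.3, σ=1.8 S/m,
k=0.52 W/(m·°C), c=3540 J/(kg·°C); tumor 1040, 54.8, 2.0, 0.57, 3960; blood
ρ_b=1060 kg/m³, c_b=3600 J/(kg·°C), k=0.5 W/(m·°C), T_b=37 °C. Latent heat
α = 2.26 MJ/kg, baseline water mass fraction W₀ = 0.78.

The temperature/damage dependencies are standard functional forms whose exact
shapes are open choices; each is a config key:

* **Water content** W(T) = W₀/(1 + exp((T − T_w)/s_w)) with T_w = 102 °C,
  s_w = 1.5 °C — flat at 78 % below boiling, smooth drop across the boiling
  band. Its derivative feeds c_eff = c − α·dW/dT (mass form; the printed
  "αρ∂W/∂T" variant is dimensionally inconsistent for α in J/kg, so a
  density-scaled alternative is retained only as a sensitivity option).
  The peak latent contribution is α·W₀/(4 s_w) ≈ 2.9·10⁵ J/(kg·°C).
* **Dielectric decline**: (ε_r, σ) scale with W(T)/W₀, floored at 10 % of
  baseline — desiccated tissue keeps a residual loss.
* **Perfusion**: baseline W_b = 0.0064 s⁻¹ (standard liver value; not printed
  in the source table) until the local damage fraction θ = 1 − e^(−Ω) exceeds
  0.8, then zero — coagulation shuts the microvasculature.

### Damage

The Arrhenius integral Ω(t) = ∫A·exp(−ΔE/(R·T_K))dt with liver constants
A = 7.39·10³⁹ s⁻¹, ΔE = 2.577·10⁵ J/mol accumulates trapezoidally each step.
"Complete necrosis" means θ ≥ 0.99 (Ω ≥ 4.6) in every tumor voxel; a 60 °C
peak-temperature isotherm criterion is available as an alternative lesion
definition. With these constants tissue held near 55 °C for a few minutes
necroses, so the Arrhenius zone is systematically *larger* than the 60 °C
isotherm zone (measured union overlap ≈ 0.5 at the calibration anchor) —
users comparing to isotherm-based lesion sizes should select the isotherm
criterion explicitly. Note also that at body temperature these constants
accumulate Ω ≈ 0.18 over 600 s — a known artifact of the parameter set, far
below the necrosis threshold but not the "zero" one might expect.

## Numerics

* **Grid**: uniform Cartesian voxels (default 0.8 mm, 15 mm healthy-tissue
  margin); tumor labels by a vertical-ray parity (point-in-polyhedron) test
  at voxel centers; the antenna is a metal/dielectric cylinder along +z that
  overrides tissue labels, with the axis and slot-array midpoint snapped to
  voxel centers. Degenerate grazing columns are retried with a sub-voxel
  jitter.
* **Time stepping**: conservative flux form with harmonic-mean face
  conductivities — total enthalpy is conserved to round-off without
  perfusion — and explicit time integration with automatic sub-stepping
  under the stability bound dt < ρc·h²/Σk_face (≈ 0.78 s at 0.8 mm). The
  default dt = 0.25 s is therefore stable outright; explicit stepping was
  chosen over an implicit solve because at these Fourier numbers it is
  equally accurate, strictly monotone, and an order of magnitude cheaper in
  pure-numpy form. Damage accumulates with a trapezoidal rule per step.
* **Ablation time**: Ω is monotone in time, so completeness is monitored
  every step inside a single run; the reported time is accurate to one time
  step (well inside the ±5 s contract).
* **Calibration**: bisection on η ∈ (0.05, 1.5] until the anchor scenario
  (ircad-1.07 phantom, 10 W) completes at 600 ± 5 s; each probe run is capped
  at 620 s since "not complete by then" already fixes the bisection sign.
  Calibrated η ≈ 0.50 at 0.8 mm spacing, moving < 2 % when the grid is
  coarsened to 1 mm.
* **Degenerate inputs**: non-watertight meshes are rejected after a repair
  attempt; antenna axes that miss the tumor are rejected; σ = 0 media skip
  power normalization (nothing absorbs); diverging temperature fields abort
  with a diagnostic.

## Synthetic phantoms

The two presets emulate the study tumors only through their published
bounding boxes (1.74 × 1.53 × 2.10 cm and 1.78 × 1.97 × 2.27 cm): they are
triangulated ellipsoids with those extents, optionally modulated radially by
a seeded low-order spherical-harmonic field (amplitude ≤ 0.3, box restored
exactly after perturbation). They reproduce the *scale* of the real segmented
tumors, not their actual shapes; paper-comparison runs use amplitude 0. What
passing tests show is that the coupled solver and the planning logic behave
correctly on realistic geometry scales — not that predictions transfer to a
specific patient's anatomy, which requires loading the real segmented mesh.

## Problem sizes

Reference runs use the 0.8 mm grid (≈ 2·10⁵ voxels, ~60³ domain), dt =
0.25 s, EM grid 0.15 mm on a 20 × 40 mm (r, z) domain re-solved every 10 °C
of drift. The test suite's pipeline checks run at 1 mm / dt = 0.5 s; these
desk-scale resolutions were chosen as the package's own working point, with
grid-convergence checks (volume, fixed-probe temperature, EM pattern) bounding
the discretization sensitivity at a few percent.

## Known limitations

* The ablation-zone *shape* at high power: the paper's full-3D FEM predicts
  elongated, unpredictable zones at 20–25 W; in this reduced model the zone
  aspect ratio is nearly power-independent (≈ 1.5 at the ablation time) and
  tends toward spherical at fixed long durations. The elongation flag
  machinery exists, but elongation does not emerge from the axisymmetric,
  power-normalized deposition. Relatedly, the predicted ablation-time gap
  between the two phantoms stays ≈ 29 % at 25 W rather than closing to ≈ 8 %.
* Single antenna, rigid tissue, no vapor transport or tissue shrinkage, no
  porous-media two-temperature heat transfer, single-frequency dielectrics
  (no Cole–Cole dispersion).
* The model is calibrated, not validated: one printed operating point fixes
  η, and all other comparisons are out-of-sample model predictions, not
  measurements.
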