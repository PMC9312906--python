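# mwablate

Microwave-ablation (MWA) treatment planning for liver tumors by coupled
electromagnetic / bioheat / thermal-damage simulation.

MWA destroys a tumor by inserting a thin coaxial antenna and heating the
tissue dielectrically at 2.45 GHz until coagulative necrosis. Planning the
procedure means choosing the input power and duration so that *every* part of
the tumor is necrosed while as little healthy liver as possible is damaged —
and because real tumors are irregular 3D shapes, a planning model has to
resolve the actual geometry, not a textbook sphere. `mwablate` is a compact,
fully scriptable pipeline for exactly that question, aimed at researchers in
computational biomedical physics who want a transparent, testable alternative
to monolithic FEM packages.

## Model

Three coupled pieces, stepped together on a labeled voxel grid:

1. **EM source.** The azimuthally symmetric TM mode of the Helmholtz equation
   around a 10-slot coaxial antenna, ∇²**E** − μ_r k₀²(ε_r − jσ/(ωε₀))**E** = 0,
   solved in (r, z) by finite differences with a coax TEM port, PEC conductors
   and first-order absorbing boundaries; the deposition Q_ext = ½σ|E|² is
   rotated onto the 3D grid and normalized to η·P_in.
2. **Bioheat.** The Pennes equation
   ρc_eff ∂T/∂t = ∇·(k∇T) + ρ_b W_b c_b (T_b − T) + Q_ext + Q_m, with the
   evaporation-corrected heat capacity c_eff = c − α·∂W/∂T, temperature-
   dependent dielectrics, and perfusion that ceases once local damage passes
   the coagulation threshold.
3. **Damage.** The Arrhenius integral Ω(t) = ∫A·e^(−ΔE/RT)dt; necrosis where
   the damage fraction θ = 1 − e^(−Ω) ≥ 0.99 (or, alternatively, inside the
   60 °C isotherm).

On top sits the planning layer: tumor coverage / healthy-damage / safety-
margin metrics, the ablation-time curve t_abl(P), minimal-power selection,
and a single-scalar efficiency calibration η that anchors the reduced model
to one known operating point (10 W just ablating the smaller study phantom at
600 s). Two phantom presets (`ircad-1.07`, `ircad-1.03`) reproduce the
bounding boxes of two public-database liver tumors; arbitrary watertight
STL/PLY tumor surfaces can be loaded instead. See `docs/methods.md` for
assumptions, parameter defaults and limitations.

## Worked example

Generate a phantom and inspect it:

```sh
$ mwablate phantom --preset ircad-1.07 --out tumor.stl
wrote tumor.stl: bounding box 1.740 x 1.530 x 2.100 cm, volume 2.921 cm^3
```

The box matches the preset's published extents; the volume is the ellipsoid
volume (π/6 · abc). Calibrate the efficiency and sweep powers from Python:

```python
import mwablate as mw
from mwablate.planning import SimOptions, calibrate_efficiency, ablation_time

mesh = mw.generate_tumor_phantom(preset="ircad-1.07")
antenna = mw.AntennaSpec()                      # 10 slots, 2.45 GHz
grid = mw.voxelize(mesh, antenna, spacing=0.8e-3)

cal = calibrate_efficiency(grid, antenna)       # anchor: 10 W -> 600 s
print(cal.efficiency)                           # 0.4975
ant = antenna.with_efficiency(cal.efficiency)
print(ablation_time(grid, ant, 15.0))           # 333.5  (seconds)
```

η ≈ 0.50 means half the port power reaches the tissue once matching and
unmodeled antenna details are absorbed; with the calibrated model, raising
the power from 10 W to 15 W shortens the predicted complete-necrosis time
from 600 s to ≈ 334 s. The `run` and `sweep` subcommands write VTK field
snapshots, necrosis isosurface STLs, center-point temperature CSVs and JSON
summaries for whole scenarios (`mwablate run --help`).

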