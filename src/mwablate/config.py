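"""Run configuration: validated schema, defaults, object builders.

A fully-defaulted :class:`RunConfig` reproduces the reference planning
scenario: the ``ircad-1.07`` ellipsoid phantom on a 0.8 mm grid with 15 mm
healthy margin, the 10-slot 2.45 GHz antenna driven at 10 W for 600 s, the
full-wave EM backend, Arrhenius completeness, and the 10 W / 600 s
calibration anchor.  Unknown keys anywhere in the config are rejected.
"""

from __future__ import annotations

from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import em as em_mod
from .damage import DamageParams
from .materials import BloodProperties, PropertySet, TissueProperties
from .phantoms import (TumorMesh, generate_tumor_phantom, load_tumor_mesh,
                       place_antenna, voxelize)
from .planning import SimOptions


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueConfig(_Section):
    density: float
    rel_permittivity: float
    conductivity: float
    thermal_conductivity: float
    specific_heat: float


class BloodConfig(_Section):
    density: float = 1060.0
    thermal_conductivity: float = 0.5
    specific_heat: float = 3600.0
    temperature: float = 37.0
    perfusion_rate: float = 0.0064


class MaterialsConfig(_Section):
    healthy: TissueConfig = TissueConfig(
        density=1079.0, rel_permittivity=44.3, conductivity=1.8,
        thermal_conductivity=0.52, specific_heat=3540.0)
    tumor: TissueConfig = TissueConfig(
        density=1040.0, rel_permittivity=54.8, conductivity=2.0,
        thermal_conductivity=0.57, specific_heat=3960.0)
    blood: BloodConfig = BloodConfig()
    latent_heat: float = 2.260e6
    water_fraction: float = 0.78
    metabolic_heat: float = 0.0
    evaporation_midpoint: float = 102.0
    evaporation_width: float = 1.5
    dielectric_floor: float = 0.1
    perfusion_cutoff: float = 0.8
    latent_form: Literal["mass", "density-scaled"] = "mass"


class AntennaConfig(_Section):
    n_slots: int = 10
    slot_width: float = 0.6e-3
    slot_gap: float = 0.8e-3
    inner_radius: float = 0.135e-3
    dielectric_radius: float = 0.47e-3
    outer_radius: float = 0.595e-3
    catheter_radius: float = 0.895e-3
    feed_permittivity: float = 2.03
    catheter_permittivity: float = 2.6
    frequency: float = 2.45e9
    power: float = 10.0
    efficiency: float = 1.0


class EMConfig(_Section):
    backend: Literal["fdfd", "slots"] = "fdfd"
    dr: float = 1.5e-4
    dz: float = 1.5e-4
    r_max: float = 0.02
    z_pad: float = 0.02
    resolve_delta_T: float = 10.0


class PhantomConfig(_Section):
    preset: Optional[str] = "ircad-1.07"
    mesh_path: Optional[str] = None
    mesh_units: str = "auto"
    perturbation_amplitude: float = 0.0
    subdivisions: int = 4


class GridConfig(_Section):
    spacing: float = 0.8e-3
    margin: float = 15e-3
    tip_extension: float = 1.0e-3


class SimulationConfig(_Section):
    duration: float = 600.0
    dt: float = 0.25
    snapshot_times: List[float] = Field(default_factory=lambda: [200.0, 400.0, 600.0])


class DamageConfig(_Section):
    frequency_factor: float = 7.39e39
    activation_energy: float = 2.577e5
    necrosis_threshold: float = 0.99
    isotherm_threshold: float = 60.0


class PlanningConfig(_Section):
    powers: List[float] = Field(default_factory=lambda: [float(p) for p in range(8, 26)])
    criterion: Literal["arrhenius", "isotherm"] = "arrhenius"
    t_max: float = 900.0
    anchor_preset: str = "ircad-1.07"
    anchor_power: float = 10.0
    anchor_time: float = 600.0
    calibration_tolerance: float = 5.0
    elongation_limit: float = 1.6


class OutputConfig(_Section):
    directory: str = "out"
    vtk: bool = True
    csv: bool = True


class RunConfig(_Section):
    materials: MaterialsConfig = MaterialsConfig()
    antenna: AntennaConfig = AntennaConfig()
    em: EMConfig = EMConfig()
    phantom: PhantomConfig = PhantomConfig()
    grid: GridConfig = GridConfig()
    simulation: SimulationConfig = SimulationConfig()
    damage: DamageConfig = DamageConfig()
    planning: PlanningConfig = PlanningConfig()
    output: OutputConfig = OutputConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# builders


def build_materials(cfg: RunConfig) -> PropertySet:
    m = cfg.materials
    return PropertySet(
        healthy=TissueProperties(**m.healthy.model_dump()),
        tumor=TissueProperties(**m.tumor.model_dump()),
        blood=BloodProperties(**m.blood.model_dump()),
        latent_heat=m.latent_heat, water_fraction=m.water_fraction,
        metabolic_heat=m.metabolic_heat,
        evaporation_midpoint=m.evaporation_midpoint,
        evaporation_width=m.evaporation_width,
        dielectric_floor=m.dielectric_floor,
        perfusion_cutoff=m.perfusion_cutoff,
        latent_form=m.latent_form)


def build_antenna(cfg: RunConfig, power: Optional[float] = None,
                  efficiency: Optional[float] = None) -> em_mod.AntennaSpec:
    kw = cfg.antenna.model_dump()
    if power is not None:
        kw["power"] = power
    if efficiency is not None:
        kw["efficiency"] = efficiency
    return em_mod.AntennaSpec(**kw)


def build_phantom(cfg: RunConfig, preset: Optional[str] = None,
                  seed: Optional[int] = None) -> TumorMesh:
    p = cfg.phantom
    if p.mesh_path is not None:
        return load_tumor_mesh(p.mesh_path, units=p.mesh_units)
    return generate_tumor_phantom(
        preset=preset or p.preset,
        perturbation_amplitude=p.perturbation_amplitude,
        seed=cfg.seed if seed is None else seed,
        subdivisions=p.subdivisions)


def build_grid(cfg: RunConfig, mesh: TumorMesh,
               antenna: Optional[em_mod.AntennaSpec] = None):
    antenna = antenna or build_antenna(cfg)
    placement = place_antenna(mesh)
    return voxelize(mesh, antenna, spacing=cfg.grid.spacing,
                    margin=cfg.grid.margin, placement=placement,
                    tip_extension=cfg.grid.tip_extension)


def build_damage(cfg: RunConfig) -> DamageParams:
    return DamageParams(**cfg.damage.model_dump())


def build_sim_options(cfg: RunConfig) -> SimOptions:
    return SimOptions(
        dt=cfg.simulation.dt,
        em_backend=cfg.em.backend,
        em_options={"dr": cfg.em.dr, "dz": cfg.em.dz,
                    "r_max": cfg.em.r_max, "z_pad": cfg.em.z_pad},
        em_resolve_delta_T=cfg.em.resolve_delta_T)
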