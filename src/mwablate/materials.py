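"""Tissue, blood and physical constants, with temperature/damage-dependent models.

Baseline constants are the standard literature values for healthy liver,
hepatic tumor and blood at 2.45 GHz and 37 °C.  On top of the baselines this
module provides the property *curves* that drive the coupled simulation:

* ``water_content`` — tissue water mass fraction W(T), a smooth logistic that
  stays at its baseline (~78 %) up to the boiling band and drops to zero above
  it, representing evaporation;
* ``effective_specific_heat`` — specific heat augmented by the latent heat of
  the evaporating tissue water, c_eff = c − α·dW/dT (the dominant heat sink
  that arrests the temperature rise near ~100 °C);
* ``dielectric_at`` — relative permittivity and electric conductivity scaled
  down with the water content (microwaves penetrate desiccated tissue much
  more deeply), floored at a residual fraction of the baseline;
* ``perfusion_at`` — blood perfusion that shuts off once coagulative damage
  exceeds a cessation threshold.

All curves are deterministic pure functions of (T, Ω, tissue class) and accept
scalars or numpy arrays in °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.special import expit

#: Latent heat of vaporization of tissue water, J/kg.
WATER_LATENT_HEAT = 2.260e6

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314

TissueClass = Literal["healthy", "tumor"]


@dataclass(frozen=True)
class TissueProperties:
    """Baseline (37 °C, undamaged) bulk properties of one tissue class."""

    density: float                # kg/m^3
    rel_permittivity: float       # dimensionless, at 2.45 GHz
    conductivity: float           # S/m, at 2.45 GHz
    thermal_conductivity: float   # W/(m °C)
    specific_heat: float          # J/(kg °C)

    def __post_init__(self) -> None:
        for name in ("density", "rel_permittivity", "conductivity",
                     "thermal_conductivity", "specific_heat"):
            if not getattr(self, name) > 0:
                raise ValueError(f"tissue property {name!r} must be positive")


@dataclass(frozen=True)
class BloodProperties:
    """Blood constants entering the perfusion sink of the bioheat equation."""

    density: float = 1060.0             # kg/m^3
    thermal_conductivity: float = 0.5   # W/(m °C)
    specific_heat: float = 3600.0       # J/(kg °C)
    temperature: float = 37.0           # °C, arterial
    perfusion_rate: float = 0.0064      # 1/s, baseline volumetric rate for liver

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_heat <= 0:
            raise ValueError("blood density and specific heat must be positive")
        if self.perfusion_rate < 0:
            raise ValueError("perfusion rate must be non-negative")


def _default_healthy() -> TissueProperties:
    return TissueProperties(1079.0, 44.3, 1.8, 0.52, 3540.0)


def _default_tumor() -> TissueProperties:
    return TissueProperties(1040.0, 54.8, 2.0, 0.57, 3960.0)


@dataclass(frozen=True)
class PropertySet:
    """All material constants and curve parameters used by the pipeline.

    Defaults reproduce the standard liver/tumor/blood table used for MWA
    modeling at 2.45 GHz.  Curve parameters (evaporation midpoint/width,
    dielectric floor, perfusion cutoff) are model choices exposed in the
    ``materials:`` config section.
    """

    healthy: TissueProperties = field(default_factory=_default_healthy)
    tumor: TissueProperties = field(default_factory=_default_tumor)
    blood: BloodProperties = field(default_factory=BloodProperties)

    latent_heat: float = WATER_LATENT_HEAT   # α, J/kg
    water_fraction: float = 0.78             # W0, baseline water mass fraction
    metabolic_heat: float = 0.0              # Q_m, W/m^3 (neglected by default)

    evaporation_midpoint: float = 102.0      # T_w, °C: center of the W(T) drop
    evaporation_width: float = 1.5           # s_w, °C: width of the drop
    dielectric_floor: float = 0.1            # residual fraction of (eps_r, sigma)
    perfusion_cutoff: float = 0.8            # damage fraction θ above which W_b = 0
    latent_form: Literal["mass", "density-scaled"] = "mass"

    def __post_init__(self) -> None:
        if not 0.0 < self.water_fraction < 1.0:
            raise ValueError("baseline water fraction must lie in (0, 1)")
        if self.evaporation_width <= 0:
            raise ValueError("evaporation width must be positive")
        if not 0.0 < self.dielectric_floor < 1.0:
            raise ValueError("dielectric floor must lie in (0, 1)")
        if not 0.0 < self.perfusion_cutoff < 1.0:
            raise ValueError("perfusion cutoff must lie in (0, 1)")

    def tissue(self, tissue_class: TissueClass) -> TissueProperties:
        if tissue_class == "healthy":
            return self.healthy
        if tissue_class == "tumor":
            return self.tumor
        raise ValueError(f"unknown tissue class {tissue_class!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PropertySet":
        d = dict(d)
        for key, sub in (("healthy", TissueProperties),
                         ("tumor", TissueProperties),
                         ("blood", BloodProperties)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def water_content(T, props: PropertySet):
    """Tissue water mass fraction W(T) ∈ (0, W0].

    Logistic in temperature: W = W0 · sigmoid(−(T − T_w)/s_w).  Flat at W0 for
    body temperatures, smooth monotone drop across the boiling band, → 0 well
    above 100 °C.  Continuously differentiable (its derivative feeds the
    effective specific heat).
    """
    T = np.asarray(T, dtype=float)
    x = (T - props.evaporation_midpoint) / props.evaporation_width
    return props.water_fraction * expit(-x)


def water_content_derivative(T, props: PropertySet):
    """dW/dT in 1/°C; non-positive everywhere."""
    T = np.asarray(T, dtype=float)
    x = (T - props.evaporation_midpoint) / props.evaporation_width
    s = expit(-x)
    return -props.water_fraction * s * (1.0 - s) / props.evaporation_width


def latent_heat_capacity(T, props: PropertySet, density=None):
    """Additive latent-heat term of c_eff, i.e. −α·dW/dT ≥ 0, in J/(kg °C).

    With ``latent_form == "density-scaled"`` the term is multiplied by
    ρ_water/ρ (a sensitivity variant of the evaporation sink).
    """
    term = -props.latent_heat * water_content_derivative(T, props)
    if props.latent_form == "density-scaled":
        if density is None:
            raise ValueError("density required for the density-scaled form")
        term = term * (1000.0 / np.asarray(density, dtype=float))
    return term


def effective_specific_heat(T, props: PropertySet,
                            tissue_class: TissueClass = "tumor"):
    """Evaporation-corrected specific heat c_eff(T) = c − α·dW/dT, J/(kg °C).

    Equals the baseline c away from the evaporation band and exceeds it inside
    the band (dW/dT ≤ 0), modeling the latent heat absorbed by boiling tissue
    water.
    """
    tp = props.tissue(tissue_class)
    return tp.specific_heat + latent_heat_capacity(T, props, density=tp.density)


def dielectric_at(T, tissue_class: TissueClass, props: PropertySet):
    """(relative permittivity, conductivity) of a tissue class at temperature T.

    Both baseline values are scaled by the relative water content
    max(W(T)/W0, floor): dielectric properties fall as tissue desiccates, but
    never below the configured residual fraction of baseline.
    """
    tp = props.tissue(tissue_class)  # validates the class
    scale = np.maximum(water_content(T, props) / props.water_fraction,
                       props.dielectric_floor)
    return tp.rel_permittivity * scale, tp.conductivity * scale


def perfusion_at(T, omega, props: PropertySet):
    """Blood perfusion rate (1/s) given temperature and damage integral Ω.

    Baseline W_b while the damage fraction θ = 1 − exp(−Ω) is at or below the
    cessation threshold; zero once the microvasculature has coagulated
    (θ strictly above threshold).  Monotone non-increasing in Ω.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("damage integral must be non-negative")
    theta = -np.expm1(-omega)
    wb = np.where(theta <= props.perfusion_cutoff, props.blood.perfusion_rate, 0.0)
    if wb.ndim == 0:
        return float(wb)
    return wb
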