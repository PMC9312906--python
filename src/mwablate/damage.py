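"""Arrhenius thermal-damage accumulation and necrosis criteria.

Cell death under hyperthermia is modeled as a first-order rate process: the
damage integral Ω(t) = ∫ A·exp(−ΔE/(R·T_K)) dt accumulates at every point, and
the surviving-cell fraction is exp(−Ω), so the damage (necrosis) fraction is
θ = 1 − exp(−Ω).  Ω ≈ 4.6 corresponds to 99 % cell death, the default
"complete necrosis" threshold.  A second, simpler lesion criterion — the 60 °C
isotherm, taken as instantly lethal — is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import GAS_CONSTANT


@dataclass(frozen=True)
class DamageParams:
    """Arrhenius kinetics and lesion-threshold parameters for liver tissue."""

    frequency_factor: float = 7.39e39     # A, 1/s
    activation_energy: float = 2.577e5    # ΔE, J/mol
    necrosis_threshold: float = 0.99      # θ*: damage fraction counted as dead
    isotherm_threshold: float = 60.0      # °C, instantly-lethal isotherm

    def __post_init__(self) -> None:
        if self.frequency_factor <= 0 or self.activation_energy <= 0:
            raise ValueError("Arrhenius parameters must be positive")
        if not 0.0 < self.necrosis_threshold < 1.0:
            raise ValueError("necrosis threshold must lie in (0, 1)")

    @property
    def omega_threshold(self) -> float:
        """Damage-integral value equivalent to θ*: Ω* = −ln(1 − θ*)."""
        return float(-np.log1p(-self.necrosis_threshold))


def arrhenius_rate(T, params: DamageParams):
    """Instantaneous damage rate A·exp(−ΔE/(R·T_K)) in 1/s, T in °C."""
    T_K = np.asarray(T, dtype=float) + 273.15
    return params.frequency_factor * np.exp(
        -params.activation_energy / (GAS_CONSTANT * T_K))


def arrhenius_increment(omega, T_start, T_end, dt: float, params: DamageParams):
    """Advance the damage integral over one time step of length ``dt``.

    Trapezoidal rule across the step: Ω += dt/2·(rate(T_start) + rate(T_end)).
    With dt = 0 the field is returned unchanged.  Ω is non-decreasing.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return np.asarray(omega, dtype=float)
    rate = 0.5 * (arrhenius_rate(T_start, params) + arrhenius_rate(T_end, params))
    return np.asarray(omega, dtype=float) + dt * rate


def damage_fraction(omega):
    """Necrosis fraction θ = 1 − exp(−Ω) ∈ [0, 1), monotone in Ω."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("damage integral must be non-negative")
    return -np.expm1(-omega)


def necrosis_mask(field, params: DamageParams, mode: str = "arrhenius"):
    """Boolean necrosis mask from a damage-fraction or temperature field.

    ``mode="arrhenius"``: ``field`` is θ; necrotic where θ ≥ θ*.
    ``mode="isotherm"``:  ``field`` is T (°C, typically the running maximum);
    necrotic where T ≥ the isotherm threshold.
    """
    field = np.asarray(field, dtype=float)
    if mode == "arrhenius":
        return field >= params.necrosis_threshold
    if mode == "isotherm":
        return field >= params.isotherm_threshold
    raise ValueError(f"unknown necrosis mode {mode!r}")


def necrosis_isosurface(field, params: DamageParams, spacing: float,
                        origin, mode: str = "arrhenius"):
    """Triangulated boundary of the necrotic zone (marching cubes).

    Returns a :class:`trimesh.Trimesh` in the grid's physical coordinates, or
    ``None`` if the level set is empty.
    """
    import trimesh
    from skimage.measure import marching_cubes

    field = np.asarray(field, dtype=float)
    if mode == "arrhenius":
        level = params.necrosis_threshold
    elif mode == "isotherm":
        level = params.isotherm_threshold
    else:
        raise ValueError(f"unknown necrosis mode {mode!r}")
    if field.max() < level or field.min() > level:
        return None
    verts, faces, _, _ = marching_cubes(field, level=level,
                                        spacing=(spacing,) * 3)
    verts = verts + np.asarray(origin, dtype=float)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)
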