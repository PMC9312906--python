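"""Electromagnetic source: multi-slot coaxial antenna at 2.45 GHz.

The antenna is geometrically axisymmetric, so the time-harmonic field is
solved as the azimuthally symmetric transverse-magnetic mode on an (r, z)
plane.  The working unknown is the azimuthal magnetic field H_phi; with the
complex permittivity eps_t = eps_r − j·sigma/(omega·eps0) it satisfies

    d/dz[(1/eps_t) dH/dz] + d/dr[(1/(eps_t r)) d(r H)/dr] + k0^2 H = 0,

from which E_r and E_z follow by differentiation and the volumetric heat
source is q = 1/2 · sigma · |E|^2.  Metal is modeled as a high-conductivity
material (PEC limit), the coax port is excited with the analytic TEM 1/r
profile at the domain top, and first-order absorbing conditions terminate the
outer boundaries.  The resulting axisymmetric deposition map is rotated onto
the 3D voxel grid and renormalized so the total deposited power equals
eta · P_in exactly.

A purely analytic fallback backend (:func:`slot_source_model`) superposes
spherically spreading, exponentially attenuated kernels centered on the slots;
it shares the normalization and symmetry contracts of the full-wave backend
and is useful for fast smoke runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates
from scipy.interpolate import RegularGridInterpolator

from .materials import PropertySet, dielectric_at
from .phantoms import Label, LabelGrid

SPEED_OF_LIGHT = 2.99792458e8
EPS0 = 8.8541878128e-12
METAL_CONDUCTIVITY = 1.0e7  # S/m; effectively PEC at 2.45 GHz


@dataclass(frozen=True)
class AntennaSpec:
    """Geometry and drive of the multi-slot coaxial MWA antenna.

    Defaults describe a compact 10-slot antenna: 0.6 mm slots separated by
    0.8 mm gaps, operating at 2.45 GHz.  ``efficiency`` is the single
    calibration factor absorbing unmodeled details (matching network, exact
    conductor radii); the deposited power is ``efficiency * power``.
    """

    n_slots: int = 10
    slot_width: float = 0.6e-3        # m
    slot_gap: float = 0.8e-3          # m, gap between adjacent slots
    inner_radius: float = 0.135e-3    # m, inner conductor
    dielectric_radius: float = 0.47e-3  # m, outer radius of feed dielectric
    outer_radius: float = 0.595e-3    # m, outer conductor (outer radius)
    catheter_radius: float = 0.895e-3  # m, insulating sleeve
    feed_permittivity: float = 2.03   # PTFE
    catheter_permittivity: float = 2.6
    frequency: float = 2.45e9         # Hz
    power: float = 10.0               # W at the port
    efficiency: float = 1.0           # eta, calibrated

    def __post_init__(self) -> None:
        radii = (self.inner_radius, self.dielectric_radius,
                 self.outer_radius, self.catheter_radius)
        if not all(b > a for a, b in zip(radii, radii[1:])):
            raise ValueError("antenna radii must be strictly increasing")
        if self.n_slots < 1:
            raise ValueError("need at least one slot")
        if self.slot_width <= 0 or self.slot_gap < 0:
            raise ValueError("slot dimensions must be positive")
        if self.frequency <= 0 or self.power <= 0:
            raise ValueError("frequency and power must be positive")
        if not 0.0 < self.efficiency <= 1.5:
            raise ValueError("efficiency must lie in (0, 1.5]")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def slot_array_length(self) -> float:
        """Axial extent from first slot start to last slot end."""
        return self.n_slots * self.slot_width + (self.n_slots - 1) * self.slot_gap

    def slot_centers(self, slot_center_z: float) -> np.ndarray:
        """Absolute z of each slot center given the array midpoint."""
        period = self.slot_width + self.slot_gap
        k = np.arange(self.n_slots)
        return slot_center_z + (k - (self.n_slots - 1) / 2.0) * period

    def with_power(self, power: float) -> "AntennaSpec":
        return replace(self, power=power)

    def with_efficiency(self, efficiency: float) -> "AntennaSpec":
        return replace(self, efficiency=efficiency)


@dataclass
class EMSolution:
    """Axisymmetric field solution and derived volumetric heat source."""

    r: np.ndarray                 # cell-center radii (m)
    z: np.ndarray                 # cell-center heights (m), absolute
    H_phi: np.ndarray             # complex, (nr, nz)
    E_r: np.ndarray
    E_z: np.ndarray
    q_rz: np.ndarray              # W/m^3 on the (r, z) grid, tissue only
    dissipated_power: float       # W, integral of q_rz over the solid of revolution
    omega: float
    k0: float
    eps0: float = EPS0
    mu_r: float = 1.0
    region: Optional[np.ndarray] = None  # 0 tissue, 1 metal, 2 feed, 3 catheter


# region codes for the 2D material map
_TISSUE, _METAL, _FEED, _CATHETER = 0, 1, 2, 3


def antenna_region_map(antenna: AntennaSpec, r: np.ndarray, z: np.ndarray,
                       slot_center_z: float, tip_z: float) -> np.ndarray:
    """Classify (r, z) cells as tissue / metal / feed dielectric / catheter."""
    region = np.full((len(r), len(z)), _TISSUE, dtype=np.int8)
    zz = z[None, :]
    rr = r[:, None]
    on_antenna = zz >= tip_z
    region[(rr <= antenna.inner_radius) & on_antenna] = _METAL
    region[(rr > antenna.inner_radius)
           & (rr <= antenna.dielectric_radius) & on_antenna] = _FEED
    outer = (rr > antenna.dielectric_radius) & (rr <= antenna.outer_radius)
    region[outer & on_antenna] = _METAL
    # slots: interruptions of the outer conductor, filled with feed dielectric
    for zc in antenna.slot_centers(slot_center_z):
        in_slot = np.abs(zz - zc) <= antenna.slot_width / 2.0
        region[outer & in_slot & on_antenna] = _FEED
    region[(rr > antenna.outer_radius)
           & (rr <= antenna.catheter_radius) & on_antenna] = _CATHETER
    return region


def solve_axisym_field(antenna: AntennaSpec,
                       tissue_profile: Callable,
                       *,
                       slot_center_z: float = 0.0,
                       tip_z: Optional[float] = None,
                       dr: float = 1.5e-4,
                       dz: float = 1.5e-4,
                       r_max: float = 0.02,
                       z_pad: float = 0.02,
                       z_min: Optional[float] = None,
                       z_max: Optional[float] = None) -> EMSolution:
    """Solve the axisymmetric TM mode around the antenna.

    ``tissue_profile(r2d, z2d) -> (eps_r, sigma)`` supplies angle-averaged
    tissue properties at the 2D cell centers (antenna regions are overridden
    internally).  The port (top row of the feed dielectric) is driven with the
    analytic coax TEM profile; amplitude is arbitrary because the deposition
    is renormalized to ``eta * P_in`` when mapped to the voxel grid.
    """
    if dr > antenna.slot_width / 3.0 or dz > antenna.slot_width / 3.0:
        raise ValueError(
            f"EM grid must resolve the slot width with >= 3 cells; "
            f"need dr, dz <= {antenna.slot_width / 3.0:.2e} m")
    if tip_z is None:
        tip_z = slot_center_z - antenna.slot_array_length / 2.0 - 1.0e-3
    if z_min is None:
        z_min = slot_center_z - z_pad
    if z_max is None:
        z_max = slot_center_z + z_pad

    nr = int(round(r_max / dr))
    nz = int(round((z_max - z_min) / dz))
    r = (np.arange(nr) + 0.5) * dr
    z = z_min + (np.arange(nz) + 0.5) * dz

    region = antenna_region_map(antenna, r, z, slot_center_z, tip_z)
    eps_t, sig_t = tissue_profile(*np.meshgrid(r, z, indexing="ij"))
    eps_r = np.asarray(eps_t, dtype=float).copy()
    sigma = np.asarray(sig_t, dtype=float).copy()
    eps_r[region == _METAL] = 1.0
    sigma[region == _METAL] = METAL_CONDUCTIVITY
    eps_r[region == _FEED] = antenna.feed_permittivity
    sigma[region == _FEED] = 0.0
    eps_r[region == _CATHETER] = antenna.catheter_permittivity
    sigma[region == _CATHETER] = 0.0

    omega = antenna.omega
    k0 = omega / SPEED_OF_LIGHT
    eps_c = eps_r - 1j * sigma / (omega * EPS0)
    inv_eps = 1.0 / eps_c

    n = nr * nz

    def idx(i, j):
        return i * nz + j

    rows, cols, vals = [], [], []
    diag = np.full((nr, nz), k0 ** 2, dtype=complex)

    r_face = np.arange(1, nr) * dr          # interior radial faces
    # radial coupling between (i, j) and (i+1, j)
    inv_face_r = 0.5 * (inv_eps[:-1, :] + inv_eps[1:, :])
    cR = inv_face_r / (r_face[:, None] * dr * dr)       # (nr-1, nz)
    I, J = np.meshgrid(np.arange(nr - 1), np.arange(nz), indexing="ij")
    # equation of cell i: +cR*(v_{i+1} - v_i);  cell i+1: -cR*(v_{i+1} - v_i)
    rows.append(idx(I, J).ravel()); cols.append(idx(I + 1, J).ravel())
    vals.append((cR * r[1:, None]).ravel())
    diag[:-1, :] += -cR * r[:-1, None]
    rows.append(idx(I + 1, J).ravel()); cols.append(idx(I, J).ravel())
    vals.append((cR * r[:-1, None]).ravel())
    diag[1:, :] += -cR * r[1:, None]

    # axis face (r = 0): regularity H ~ C r gives flux 2C/eps = 2 u0/(eps r0)
    diag[0, :] += -inv_eps[0, :] * 2.0 / (r[0] * dr)

    k_local = k0 * np.sqrt(eps_c)
    # outer radial boundary: first-order absorbing via decaying ghost cell
    ghost = (r[-1] + dr) * np.exp(-1j * k_local[-1, :] * dr)
    diag[-1, :] += inv_eps[-1, :] * (ghost - r[-1]) / (nr * dr * dr * dr)

    # axial coupling between (i, j) and (i, j+1)
    inv_face_z = 0.5 * (inv_eps[:, :-1] + inv_eps[:, 1:])
    cZ = inv_face_z / (dz * dz)
    I, J = np.meshgrid(np.arange(nr), np.arange(nz - 1), indexing="ij")
    rows.append(idx(I, J).ravel()); cols.append(idx(I, J + 1).ravel())
    vals.append(cZ.ravel())
    diag[:, :-1] += -cZ
    rows.append(idx(I, J + 1).ravel()); cols.append(idx(I, J).ravel())
    vals.append(cZ.ravel())
    diag[:, 1:] += -cZ

    # axial boundaries: absorbing ghosts (port row overridden below)
    diag[:, 0] += inv_eps[:, 0] * (np.exp(-1j * k_local[:, 0] * dz) - 1.0) / dz ** 2
    diag[:, -1] += inv_eps[:, -1] * (np.exp(-1j * k_local[:, -1] * dz) - 1.0) / dz ** 2

    rows.append(np.arange(n)); cols.append(np.arange(n))
    vals.append(diag.ravel())

    A = sp.csr_matrix((np.concatenate([np.asarray(v, dtype=complex)
                                       for v in vals]),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))

    # port: Dirichlet TEM profile H = 1/r on the top row of the feed dielectric
    port = np.zeros((nr, nz), dtype=bool)
    port[:, -1] = region[:, -1] == _FEED
    if not port.any():
        raise ValueError("no feed-dielectric cells on the port row; "
                         "extend the EM domain to the antenna shaft")
    b = np.zeros(n, dtype=complex)
    port_flat = np.flatnonzero(port.ravel())
    mask = np.ones(n, dtype=bool)
    mask[port_flat] = False
    A = sp.lil_matrix(A)
    for p in port_flat:
        A.rows[p] = [p]
        A.data[p] = [1.0 + 0j]
    b[port_flat] = 1.0 / r[(port_flat // nz)]
    A = sp.csc_matrix(A)

    u = spla.spsolve(A, b).reshape(nr, nz)

    # derived fields
    jwe = 1j * omega * EPS0 * eps_c
    dH_dz = np.gradient(u, dz, axis=1)
    rv = r[:, None] * u
    drv_dr = np.gradient(rv, dr, axis=0)
    E_r = -dH_dz / jwe
    E_z = drv_dr / (jwe * r[:, None])

    sigma_tissue = np.where(region == _TISSUE, sigma, 0.0)
    q_rz = 0.5 * sigma_tissue * (np.abs(E_r) ** 2 + np.abs(E_z) ** 2)
    power = float(np.sum(q_rz * 2.0 * np.pi * r[:, None]) * dr * dz)

    return EMSolution(r=r, z=z, H_phi=u, E_r=E_r, E_z=E_z, q_rz=q_rz,
                      dissipated_power=power, omega=omega, k0=k0,
                      region=region)


def sar_to_grid(sol: EMSolution, grid: LabelGrid,
                power: Optional[float] = None,
                efficiency: Optional[float] = None) -> np.ndarray:
    """Rotate the axisymmetric deposition onto the 3D grid and renormalize.

    Q_ext(x, y, z) = q(r = hypot(x − x0, y − y0), z) by bilinear interpolation,
    zero inside the antenna, scaled so that sum(Q_ext) * voxel_volume equals
    ``efficiency * power`` exactly (taken from ``grid.antenna`` if omitted).
    """
    antenna = grid.antenna
    if power is None:
        power = antenna.power
    if efficiency is None:
        efficiency = antenna.efficiency
    x0, y0 = grid.placement.axis_xy
    interp = RegularGridInterpolator((sol.r, sol.z), sol.q_rz,
                                     bounds_error=False, fill_value=0.0)
    X, Y = np.meshgrid(grid.x - x0, grid.y - y0, indexing="ij")
    R = np.hypot(X, Y)
    pts_r = np.broadcast_to(R[:, :, None], grid.shape).ravel()
    pts_z = np.broadcast_to(grid.z[None, None, :], grid.shape).ravel()
    q3d = interp(np.column_stack([pts_r, pts_z])).reshape(grid.shape)
    q3d[~grid.active_mask] = 0.0
    total = q3d.sum() * grid.voxel_volume
    if total > 0:
        q3d *= efficiency * power / total
    return q3d


def plane_wave_attenuation(eps_r, sigma, frequency: float):
    """Field attenuation constant (1/m) of a plane wave in lossy tissue."""
    omega = 2.0 * np.pi * frequency
    tan_d = np.asarray(sigma, dtype=float) / (omega * EPS0 *
                                              np.asarray(eps_r, dtype=float))
    k0 = omega / SPEED_OF_LIGHT
    return k0 * np.sqrt(np.asarray(eps_r, dtype=float) / 2.0
                        * (np.sqrt(1.0 + tan_d ** 2) - 1.0))


def slot_source_model(antenna: AntennaSpec, grid: LabelGrid,
                      materials: PropertySet,
                      T=None) -> np.ndarray:
    """Analytic fallback deposition: attenuated spherical kernels per slot.

    Each slot radiates a spherically spreading wave whose power density decays
    as exp(−2 α d)/d², with the attenuation constant α evaluated from the
    local (temperature-dependent) tissue dielectric properties.  The sum over
    slots is zeroed inside the antenna and normalized to ``eta * P_in``.
    """
    if T is None:
        T = np.full(grid.shape, 37.0)
    eps = np.empty(grid.shape)
    sig = np.empty(grid.shape)
    for cls, mask in (("healthy", grid.healthy_mask),
                      ("tumor", grid.tumor_mask)):
        e, s = dielectric_at(np.asarray(T)[mask], cls, materials)
        eps[mask], sig[mask] = e, s
    eps[~grid.active_mask] = 1.0
    sig[~grid.active_mask] = 0.0
    alpha = plane_wave_attenuation(eps, sig, antenna.frequency)

    x0, y0 = grid.placement.axis_xy
    X, Y = np.meshgrid(grid.x - x0, grid.y - y0, indexing="ij")
    R2 = (X ** 2 + Y ** 2)[:, :, None]
    q = np.zeros(grid.shape)
    d_min = antenna.catheter_radius
    for zc in antenna.slot_centers(grid.placement.slot_center_z):
        d = np.sqrt(R2 + (grid.z[None, None, :] - zc) ** 2)
        d = np.maximum(d, d_min)
        q += np.exp(-2.0 * alpha * d) / d ** 2
    q[~grid.active_mask] = 0.0
    total = q.sum() * grid.voxel_volume
    if total > 0:
        q *= antenna.efficiency * antenna.power / total
    return q


def tissue_profile_from_grid(grid: LabelGrid, T, materials: PropertySet,
                             n_azimuth: int = 8) -> Callable:
    """Angle-averaged (eps_r, sigma) profile for the axisymmetric EM solve.

    For each requested (r, z) point, samples ``n_azimuth`` points on the
    circle of radius r about the antenna axis, looks up the per-voxel
    temperature-dependent properties (nearest voxel), and averages.  Points
    outside the voxel grid clamp to the boundary.
    """
    T = np.asarray(T, dtype=float)
    eps_vox = np.empty(grid.shape)
    sig_vox = np.empty(grid.shape)
    for cls, mask in (("healthy", grid.healthy_mask),
                      ("tumor", grid.tumor_mask)):
        e, s = dielectric_at(T[mask], cls, materials)
        eps_vox[mask], sig_vox[mask] = e, s
    # antenna voxels are overridden by the solver's own region map; fill with
    # healthy baseline so azimuthal averages near the shaft stay sane
    inactive = ~grid.active_mask
    eps_vox[inactive] = materials.healthy.rel_permittivity
    sig_vox[inactive] = materials.healthy.conductivity

    x0, y0 = grid.placement.axis_xy
    h = grid.spacing
    origin = grid.origin

    def profile(r2d, z2d):
        phis = (np.arange(n_azimuth) + 0.5) * (2.0 * np.pi / n_azimuth)
        eps_acc = np.zeros_like(r2d, dtype=float)
        sig_acc = np.zeros_like(r2d, dtype=float)
        kz = (z2d - origin[2]) / h
        for phi in phis:
            ix = (x0 + r2d * np.cos(phi) - origin[0]) / h
            iy = (y0 + r2d * np.sin(phi) - origin[1]) / h
            coords = np.stack([ix.ravel(), iy.ravel(), kz.ravel()])
            eps_acc += map_coordinates(eps_vox, coords, order=0,
                                       mode="nearest").reshape(r2d.shape)
            sig_acc += map_coordinates(sig_vox, coords, order=0,
                                       mode="nearest").reshape(r2d.shape)
        return eps_acc / n_azimuth, sig_acc / n_azimuth

    return profile


def homogeneous_profile(eps_r: float, sigma: float) -> Callable:
    """Constant-property profile, mainly for tests and verification runs."""
    def profile(r2d, z2d):
        return (np.full_like(r2d, float(eps_r)),
                np.full_like(r2d, float(sigma)))
    return profile
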