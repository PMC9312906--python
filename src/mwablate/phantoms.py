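"""Tumor geometry: synthetic phantoms, mesh I/O, antenna placement, voxelization.

Two phantom presets emulate the study tumors via their published axis-aligned
bounding boxes:

* ``ircad-1.07`` — 1.74 cm × 1.53 cm × 2.10 cm
* ``ircad-1.03`` — 1.78 cm × 1.97 cm × 2.27 cm

A preset phantom is a triangulated ellipsoid with those extents; an optional
smooth random radial modulation (low-order spherical harmonics, seeded) stands
in for the irregular shapes of real segmented tumors.  The original database
meshes are not redistributed here; users supply their own STL/PLY via
:func:`load_tumor_mesh`.

The simulation domain is a uniform Cartesian voxel grid (``LabelGrid``)
labeling healthy tissue, tumor, antenna metal and antenna dielectric, with the
antenna inserted along +z through a configurable axis.  All coordinates are
meters internally; millimeters are accepted at I/O with explicit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
import trimesh
from scipy.special import sph_harm_y

__all__ = [
    "PRESETS", "Label", "TumorMesh", "AntennaPlacement", "LabelGrid",
    "MeshError", "generate_tumor_phantom", "load_tumor_mesh",
    "place_antenna", "voxelize",
]

#: Preset full bounding-box extents (m): x, y, z.
PRESETS = {
    "ircad-1.07": (1.74e-2, 1.53e-2, 2.10e-2),
    "ircad-1.03": (1.78e-2, 1.97e-2, 2.27e-2),
}


class MeshError(ValueError):
    """Raised for unusable tumor surface meshes."""


class Label(IntEnum):
    HEALTHY = 0
    TUMOR = 1
    ANTENNA_METAL = 2
    ANTENNA_DIELECTRIC = 3


@dataclass(frozen=True)
class TumorMesh:
    """A closed triangulated tumor surface plus its provenance."""

    mesh: trimesh.Trimesh
    provenance: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        m = self.mesh
        if len(m.faces) == 0:
            raise MeshError("empty mesh")
        if not m.is_watertight:
            raise MeshError("tumor surface is not watertight (open boundary)")
        if m.volume <= 0:
            raise MeshError("tumor surface has non-positive enclosed volume")

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    @property
    def extents(self) -> np.ndarray:
        """Axis-aligned bounding-box edge lengths (m)."""
        return self.mesh.extents

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.mesh.center_mass)

    def export(self, path) -> None:
        self.mesh.export(path)


@dataclass(frozen=True)
class AntennaPlacement:
    """Insertion axis (vertical, +z) and slot-array midpoint height."""

    axis_xy: tuple
    slot_center_z: float


def _harmonic_modulation(directions: np.ndarray, seed: int) -> np.ndarray:
    """Smooth random function on the unit sphere, normalized to max |f| = 1.

    Random combination of real spherical harmonics of degree 2 and 3 (degree
    0 would rescale, degree 1 mostly translates), so perturbed phantoms stay
    smooth and convex-ish.
    """
    z = np.clip(directions[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    rng = np.random.default_rng(seed)
    f = np.zeros(len(directions))
    for degree in (2, 3):
        for order in range(-degree, degree + 1):
            coeff = rng.standard_normal()
            ylm = sph_harm_y(degree, abs(order), theta, phi)
            f += coeff * (ylm.real if order >= 0 else ylm.imag)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_tumor_phantom(preset: Optional[str] = None,
                           semi_axes=None,
                           perturbation_amplitude: float = 0.0,
                           seed: Optional[int] = None,
                           subdivisions: int = 4) -> TumorMesh:
    """Generate a synthetic tumor phantom mesh.

    Parameters
    ----------
    preset:
        One of ``PRESETS`` (mutually exclusive with ``semi_axes``).
    semi_axes:
        Explicit ellipsoid semi-axes in meters.
    perturbation_amplitude:
        Relative amplitude (0–0.3) of a smooth seeded radial modulation.
        Zero yields an exact triangulated ellipsoid.  After perturbation the
        mesh is rescaled per axis so its bounding box matches the requested
        extents exactly.
    seed:
        Seed for the perturbation; required reproducibility handle.
    """
    if (preset is None) == (semi_axes is None):
        raise ValueError("specify exactly one of preset / semi_axes")
    if not 0.0 <= perturbation_amplitude <= 0.3:
        raise ValueError("perturbation amplitude must lie in [0, 0.3]")
    if preset is not None:
        try:
            extents = np.asarray(PRESETS[preset])
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
        provenance = preset
    else:
        extents = 2.0 * np.asarray(semi_axes, dtype=float)
        if extents.shape != (3,) or np.any(extents <= 0):
            raise ValueError("semi_axes must be three positive lengths")
        provenance = "ellipsoid"

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    directions = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1,
                                                  keepdims=True)
    radii = np.ones(len(directions))
    if perturbation_amplitude > 0:
        if seed is None:
            raise ValueError("a seed is required for a perturbed phantom")
        radii = 1.0 + perturbation_amplitude * _harmonic_modulation(directions,
                                                                    seed)
    vertices = directions * radii[:, None] * (extents / 2.0)
    mesh = trimesh.Trimesh(vertices=vertices, faces=sphere.faces,
                           process=False)
    # Restore the exact requested bounding box (the modulation shrinks/grows
    # the hull slightly), then center on the origin.
    scale = extents / mesh.extents
    mesh.vertices = (mesh.vertices - mesh.bounds.mean(axis=0)) * scale
    return TumorMesh(mesh=mesh, provenance=provenance, seed=seed)


def load_tumor_mesh(path, units: str = "auto") -> TumorMesh:
    """Load an STL/PLY tumor surface, repair orientation, validate, convert units.

    ``units``: ``"m"``, ``"mm"`` or ``"auto"`` (bounding-box heuristic: any
    extent above 0.5 is implausible in meters for a tumor and is read as mm).
    """
    mesh = trimesh.load_mesh(path)
    if isinstance(mesh, trimesh.Scene):  # pragma: no cover - loader dependent
        mesh = mesh.to_mesh()
    if mesh.is_empty or len(mesh.faces) == 0:
        raise MeshError(f"no triangles found in {path}")
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        mesh.fill_holes()
    if not mesh.is_watertight:
        raise MeshError(
            f"mesh {path} is not watertight after repair (open boundary or "
            "non-manifold edges); re-export a closed surface")
    if mesh.volume < 0:
        mesh.invert()
    if units == "auto":
        units = "mm" if mesh.extents.max() > 0.5 else "m"
    if units == "mm":
        mesh.apply_scale(1e-3)
    elif units != "m":
        raise ValueError(f"unknown units {units!r}")
    return TumorMesh(mesh=mesh, provenance=str(path))


def place_antenna(mesh: TumorMesh, strategy: str = "centroid-z",
                  axis_xy=None, slot_center_z=None) -> AntennaPlacement:
    """Choose the antenna insertion axis for a tumor.

    ``centroid-z`` (default): vertical axis through the volume centroid with
    the slot-array midpoint at the centroid height.  ``explicit``: caller
    supplies ``axis_xy`` and ``slot_center_z``; the axis must traverse the
    tumor.
    """
    if strategy == "centroid-z":
        c = mesh.centroid
        return AntennaPlacement(axis_xy=(float(c[0]), float(c[1])),
                                slot_center_z=float(c[2]))
    if strategy == "explicit":
        if axis_xy is None or slot_center_z is None:
            raise ValueError("explicit placement needs axis_xy and slot_center_z")
        placement = AntennaPlacement(axis_xy=(float(axis_xy[0]),
                                              float(axis_xy[1])),
                                     slot_center_z=float(slot_center_z))
        if not _axis_intersects(mesh, placement):
            raise ValueError("explicit antenna axis does not intersect the tumor")
        return placement
    raise ValueError(f"unknown placement strategy {strategy!r}")


def _vertical_crossings(triangles: np.ndarray, px: float, py: float):
    """z of every crossing of the vertical line (px, py) with a triangle soup.

    Barycentric point-in-triangle test on the (x, y) projection; triangles
    with (near-)zero projected area are ignored — a vertical line meets them
    on a measure-zero set, and grazing columns are retried with a jitter by
    the caller.
    """
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    d = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
         + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))
    ok = np.abs(d) > 1e-300
    w1 = np.where(ok, ((b[:, 1] - c[:, 1]) * (px - c[:, 0])
                       + (c[:, 0] - b[:, 0]) * (py - c[:, 1])) / np.where(ok, d, 1.0), -1.0)
    w2 = np.where(ok, ((c[:, 1] - a[:, 1]) * (px - a[:, 0])
                       + (a[:, 0] - c[:, 0]) * (py - a[:, 1])) / np.where(ok, d, 1.0), -1.0)
    w3 = 1.0 - w1 - w2
    hit = (w1 >= 0.0) & (w2 >= 0.0) & (w3 >= 0.0) & ok
    if not hit.any():
        return np.empty(0)
    return (w1[hit] * a[hit, 2] + w2[hit] * b[hit, 2] + w3[hit] * c[hit, 2])


def _column_intervals(triangles: np.ndarray, px: float, py: float,
                      jitter: float) -> np.ndarray:
    """(z_in, z_out) interval pairs of the solid along a vertical column."""
    for dx, dy in ((0.0, 0.0), (jitter, jitter), (-jitter, jitter)):
        zs = np.unique(np.round(np.sort(
            _vertical_crossings(triangles, px + dx, py + dy)), 12))
        if len(zs) % 2 == 0:
            return zs.reshape(-1, 2)
    return np.empty((0, 2))


def _axis_intersects(mesh: TumorMesh, placement: AntennaPlacement) -> bool:
    tri = mesh.mesh.triangles
    intervals = _column_intervals(tri, placement.axis_xy[0],
                                  placement.axis_xy[1], jitter=1e-7)
    return len(intervals) > 0


@dataclass
class LabelGrid:
    """Uniform voxel grid labeling tissue and antenna regions.

    ``labels`` is (nx, ny, nz) of :class:`Label`; voxel centers are
    ``origin + (i, j, k) * spacing``.  The antenna axis passes exactly through
    the voxel-center column ``axis_index`` and the slot-array midpoint lies at
    z-index ``slot_z_index``.
    """

    origin: np.ndarray
    spacing: float
    labels: np.ndarray
    mesh: TumorMesh
    placement: AntennaPlacement
    axis_index: tuple
    slot_z_index: int
    antenna: object = None  # AntennaSpec; kept loose to avoid a cycle

    # -- coordinates -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    @property
    def x(self) -> np.ndarray:
        return self.coords(0)

    @property
    def y(self) -> np.ndarray:
        return self.coords(1)

    @property
    def z(self) -> np.ndarray:
        return self.coords(2)

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    # -- masks -------------------------------------------------------------
    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == Label.TUMOR

    @property
    def healthy_mask(self) -> np.ndarray:
        return self.labels == Label.HEALTHY

    @property
    def antenna_mask(self) -> np.ndarray:
        return self.labels >= Label.ANTENNA_METAL

    @property
    def active_mask(self) -> np.ndarray:
        """Voxels participating in the thermal solve (tissue, not antenna)."""
        return self.labels <= Label.TUMOR

    def tumor_volume(self) -> float:
        return float(self.tumor_mask.sum()) * self.voxel_volume

    def center_heating_index(self) -> tuple:
        """Grid index of the antenna-surface point at the slot-array midpoint.

        Defined as the first non-antenna voxel in +x from the axis at the
        slot-center height — the probe point for "center of the heating zone"
        temperature traces.
        """
        i, j = self.axis_index
        k = self.slot_z_index
        while self.labels[i, j, k] >= Label.ANTENNA_METAL:
            i += 1
        return (i, j, k)


def _column_fill(mesh: trimesh.Trimesh, x, y, z, inside_cols, spacing):
    """Parity-fill tumor occupancy per vertical column of voxel centers."""
    occupancy = np.zeros((len(x), len(y), len(z)), dtype=bool)
    cols = np.argwhere(inside_cols)
    if len(cols) == 0:
        return occupancy
    tri = mesh.triangles
    jitter = 1e-4 * spacing
    for i, j in cols:
        for z_in, z_out in _column_intervals(tri, x[i], y[j], jitter):
            occupancy[i, j, (z >= z_in) & (z <= z_out)] = True
    return occupancy


def voxelize(mesh: TumorMesh, antenna, spacing: float = 0.5e-3,
             margin: float = 15e-3,
             placement: Optional[AntennaPlacement] = None,
             tip_extension: float = 1.0e-3) -> LabelGrid:
    """Voxelize a tumor mesh plus inserted antenna into a labeled grid.

    Tumor voxels are assigned by a point-in-polyhedron parity test at voxel
    centers (vertical-ray casting per column).  The antenna — a cylinder of
    metal radius / dielectric annulus taken from ``antenna`` — runs along +z
    from the grid top down to ``tip_extension`` below the slot array and
    overrides tissue labels (pass ``antenna=None`` for a tissue-only grid,
    e.g. geometry convergence studies).  The grid spans the mesh bounding box plus
    ``margin`` of healthy tissue on all sides, with the axis and slot center
    aligned to voxel centers.
    """
    if spacing <= 0 or spacing > 1.0001e-3:
        raise ValueError("voxel spacing must be positive and at most 1 mm")
    if placement is None:
        placement = place_antenna(mesh)
    if not _axis_intersects(mesh, placement):
        raise ValueError("antenna axis does not traverse the tumor; "
                         "choose another placement")
    x0, y0 = placement.axis_xy
    zc = placement.slot_center_z
    bmin, bmax = mesh.mesh.bounds

    def axis_coords(center: float, lo: float, hi: float):
        below = math.ceil((center - (lo - margin)) / spacing - 1e-9)
        above = math.ceil(((hi + margin) - center) / spacing - 1e-9)
        start = center - below * spacing
        return start + spacing * np.arange(below + above + 1), below

    x, ix0 = axis_coords(x0, bmin[0], bmax[0])
    y, iy0 = axis_coords(y0, bmin[1], bmax[1])
    z, iz0 = axis_coords(zc, bmin[2], bmax[2])

    in_x = (x >= bmin[0] - spacing) & (x <= bmax[0] + spacing)
    in_y = (y >= bmin[1] - spacing) & (y <= bmax[1] + spacing)
    inside_cols = np.outer(in_x, in_y)
    occupancy = _column_fill(mesh.mesh, x, y, z, inside_cols, spacing)

    labels = np.where(occupancy, np.uint8(Label.TUMOR),
                      np.uint8(Label.HEALTHY))

    if antenna is not None:
        # Antenna cylinder: metal core and dielectric (catheter) annulus.
        r_metal = antenna.outer_radius
        r_diel = antenna.catheter_radius
        rr = np.hypot(x[:, None] - x0, y[None, :] - y0)
        z_tip = zc - (antenna.slot_array_length / 2.0 + tip_extension)
        zmask = z >= z_tip - 1e-12
        metal_cols = rr <= r_metal + 1e-12
        diel_cols = (rr > r_metal + 1e-12) & (rr <= r_diel + 1e-12)
        labels[metal_cols[:, :, None] & zmask[None, None, :]] = np.uint8(
            Label.ANTENNA_METAL)
        labels[diel_cols[:, :, None] & zmask[None, None, :]] = np.uint8(
            Label.ANTENNA_DIELECTRIC)

    origin = np.array([x[0], y[0], z[0]])
    return LabelGrid(origin=origin, spacing=spacing, labels=labels,
                     mesh=mesh, placement=placement,
                     axis_index=(ix0, iy0), slot_z_index=iz0,
                     antenna=antenna)
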