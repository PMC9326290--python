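"""Voxelized body-and-environment models.

A measured body surface (point cloud) or an analytic phantom is turned into
a labelled cubic grid: body cubes (tissue, optionally an adipose shell and
a clothing shell), air, a substrate slab under the body, and a clamped
outer boundary that acts as an infinite ambient reservoir.  Temperature
loggers placed on the skin are snapped to the nearest surface body cube so
that measured and simulated temperatures refer to the same place.

Coordinate convention: grid indices are 0-based and cube ``(i, j, k)``
occupies the half-open box ``[origin + i*dx, origin + (i+1)*dx)`` per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, LocalizationError, VoxelizationError

# material label codes stored in VoxelGrid.labels
AIR = 0
TISSUE = 1
ADIPOSE = 2
SUBSTRATE = 3
CLOTHING = 4

LABEL_NAMES = {AIR: "air", TISSUE: "tissue", ADIPOSE: "adipose",
               SUBSTRATE: "substrate", CLOTHING: "clothing"}

BODY_LABELS = (TISSUE, ADIPOSE)

#: 6-connected structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PointCloud:
    """A body-surface point cloud with named logger positions (metres)."""

    points: np.ndarray
    logger_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.logger_sites = {k: np.asarray(v, dtype=float).reshape(3)
                             for k, v in self.logger_sites.items()}


@dataclass
class VoxelGrid:
    """Labelled cubic lattice representing the body and its environment.

    ``labels`` holds the material code of every cube; ``clamped`` marks
    cubes whose temperature is reset to the ambient value every time step
    (the outermost layer plus far-field air).  ``body_mask`` is derived
    from the labels.
    """

    dims: tuple[int, int, int]
    cube_size: float
    origin: np.ndarray
    labels: np.ndarray
    clamped: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not self.cube_size > 0:
            raise InvalidInputError("cube_size must be positive")

    @property
    def body_mask(self) -> np.ndarray:
        return np.isin(self.labels, BODY_LABELS)

    def label_name(self, index: tuple[int, int, int]) -> str:
        if self.clamped[index]:
            return "clamped-ambient"
        return LABEL_NAMES[int(self.labels[index])]

    def cell_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of cube centres for an (n, 3) index array."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.cube_size

    def index_of(self, position: np.ndarray) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(position, float) - self.origin) / self.cube_size + 1e-9)
        return tuple(int(v) for v in idx)

    def surface_body_mask(self) -> np.ndarray:
        """Body cubes with at least one non-body 6-neighbour."""
        body = self.body_mask
        interior = ndimage.binary_erosion(body, structure=_STRUCT6)
        return body & ~interior

    def body_volume(self) -> float:
        """Body volume estimate in m^3 (cube count times cube volume)."""
        return float(self.body_mask.sum()) * self.cube_size ** 3


@dataclass(frozen=True)
class LoggerSite:
    """A temperature-logger location co-registered with the grid."""

    name: str
    world_position: np.ndarray
    grid_index: tuple[int, int, int]


def voxelize_surface(cloud: PointCloud, cube_size: float = 0.01,
                     padding: float = 0.04,
                     substrate_thickness: float = 0.05) -> VoxelGrid:
    """Turn a surface point cloud into a labelled voxel grid.

    Surface cubes are those containing at least one point.  The solid
    interior is recovered by flood-filling the 6-connected complement from
    the domain boundary: cubes unreachable from outside become body.  A
    substrate slab of ``substrate_thickness`` is added directly beneath
    the body's lowest extent (spanning the horizontal domain), and the
    outermost cube layer is marked clamped-ambient.

    Raises
    ------
    InvalidInputError
        Empty or too-sparse cloud (< 100 points), or bad geometry args.
    VoxelizationError
        The sampled surface is not watertight at this cube size (the
        interior leaks to the domain boundary).
    """
    pts = np.asarray(cloud.points, dtype=float)
    if pts.size == 0:
        raise InvalidInputError("empty point cloud")
    if len(pts) < 100:
        raise InvalidInputError(f"point cloud too sparse for voxelization ({len(pts)} < 100 points)")
    if not cube_size > 0:
        raise InvalidInputError("cube_size must be positive")
    if padding < 2 * cube_size:
        raise InvalidInputError("padding must be at least two cube lengths")
    n_pad = int(math.ceil(padding / cube_size))
    n_sub = int(round(substrate_thickness / cube_size))

    pmin = pts.min(axis=0)
    origin = pmin - n_pad * cube_size
    origin[2] -= n_sub * cube_size
    # 1e-9-cube guard keeps points that sit on a cell boundary up to
    # floating-point jitter in the upper (half-open) cell
    idx = np.floor((pts - origin) / cube_size + 1e-9).astype(int)
    dims = tuple(int(d) for d in idx.max(axis=0) + n_pad + 1)

    surface = np.zeros(dims, dtype=bool)
    surface[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    free, _ = ndimage.label(~surface, structure=_STRUCT6)
    boundary_labels = set()
    for axis in range(3):
        boundary_labels |= set(np.unique(np.take(free, [0, -1], axis=axis)))
    boundary_labels.discard(0)
    outside = np.isin(free, sorted(boundary_labels))
    interior = ~surface & ~outside
    if not interior.any():
        raise VoxelizationError(
            "interior flood fill leaked to the domain boundary; the sampled "
            "surface is not watertight at cube_size "
            f"{cube_size} m — densify the cloud or coarsen the grid")

    labels = np.full(dims, AIR, dtype=np.uint8)
    labels[surface | interior] = TISSUE

    body = np.isin(labels, BODY_LABELS)
    zb = int(np.flatnonzero(body.any(axis=(0, 1)))[0])
    z_lo = max(zb - n_sub, 1)
    slab = np.zeros(dims, dtype=bool)
    slab[1:-1, 1:-1, z_lo:zb] = True
    labels[slab & (labels == AIR)] = SUBSTRATE

    clamped = np.zeros(dims, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = 0
        clamped[tuple(sl)] = True
        sl[axis] = dims[axis] - 1
        clamped[tuple(sl)] = True

    return VoxelGrid(dims=dims, cube_size=cube_size, origin=origin,
                     labels=labels, clamped=clamped)


# default logger placements on a prone phantom: (polar angle from +z,
# azimuth from +x), degrees.  Chest/abdomen/thigh on top, arm on the side.
DEFAULT_LOGGER_SPEC = [
    ("chest", 25.0, 0.0),
    ("abdomen", 10.0, 180.0),
    ("thigh", 40.0, 180.0),
    ("arm", 75.0, 20.0),
]


def _ellipsoid_surface(semi_axes: np.ndarray, spacing: float) -> np.ndarray:
    a, b, c = semi_axes
    r = float(max(semi_axes))
    n_u = max(int(math.ceil(math.pi * r / spacing)), 16)
    n_v = max(int(math.ceil(2 * math.pi * r / spacing)), 32)
    u = np.linspace(0.0, math.pi, n_u)
    v = np.linspace(0.0, 2 * math.pi, n_v, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.stack([a * np.sin(uu) * np.cos(vv),
                    b * np.sin(uu) * np.sin(vv),
                    c * np.cos(uu)], axis=-1)
    return pts.reshape(-1, 3)


def _capped_cylinder_surface(radius: float, length: float, spacing: float) -> np.ndarray:
    """Cylinder along x of given body length with hemispherical end caps."""
    half = length / 2.0
    n_x = max(int(math.ceil(length / spacing)), 8)
    n_v = max(int(math.ceil(2 * math.pi * radius / spacing)), 32)
    x = np.linspace(-half, half, n_x)
    v = np.linspace(0.0, 2 * math.pi, n_v, endpoint=False)
    xx, vv = np.meshgrid(x, v, indexing="ij")
    lateral = np.stack([xx, radius * np.cos(vv), radius * np.sin(vv)], axis=-1).reshape(-1, 3)
    caps = []
    n_u = max(int(math.ceil(math.pi / 2 * radius / spacing)), 8)
    u = np.linspace(0.0, math.pi / 2, n_u)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    for sign in (-1.0, 1.0):
        cap = np.stack([sign * (half + radius * np.cos(uu)),
                        radius * np.sin(uu) * np.cos(vv),
                        radius * np.sin(uu) * np.sin(vv)], axis=-1).reshape(-1, 3)
        caps.append(cap)
    return np.concatenate([lateral] + caps, axis=0)


def _ellipsoid_point(semi_axes: np.ndarray, polar_deg: float, azimuth_deg: float) -> np.ndarray:
    u = math.radians(polar_deg)
    v = math.radians(azimuth_deg)
    a, b, c = semi_axes
    return np.array([a * math.sin(u) * math.cos(v),
                     b * math.sin(u) * math.sin(v),
                     c * math.cos(u)])


def generate_phantom(shape: str = "ellipsoid",
                     dimensions: tuple[float, ...] = (0.3, 0.15, 0.1),
                     composition: str = "uniform-tissue",
                     shell_thickness: float = 0.02,
                     logger_spec: list[tuple[str, float, float]] | None = None,
                     cube_size: float = 0.01,
                     padding: float = 0.04,
                     substrate_thickness: float = 0.05) -> tuple[PointCloud, VoxelGrid]:
    """Build a deterministic analytic body phantom and its voxel grid.

    ``shape`` is ``"ellipsoid"`` (dimensions = semi-axes a, b, c in m) or
    ``"cylinder-with-caps"`` (dimensions = radius, lateral length in m).
    ``composition`` is ``"uniform-tissue"`` or ``"tissue-with-adipose-shell"``
    (subcutaneous shell of ``shell_thickness``).  Loggers are placed on the
    surface at the requested (polar, azimuth) angles in degrees; the
    default emulates chest, abdomen, thigh and upper-arm placements.
    """
    dims_arr = np.asarray(dimensions, dtype=float)
    if not np.all(dims_arr > 0):
        raise InvalidInputError("phantom dimensions must be positive")
    spacing = cube_size / 2.5
    if shape == "ellipsoid":
        if dims_arr.size != 3:
            raise InvalidInputError("ellipsoid needs three semi-axes")
        pts = _ellipsoid_surface(dims_arr, spacing)
        min_half_extent = float(dims_arr.min())
        def on_surface(polar, azimuth):
            return _ellipsoid_point(dims_arr, polar, azimuth)
    elif shape == "cylinder-with-caps":
        if dims_arr.size != 2:
            raise InvalidInputError("cylinder-with-caps needs (radius, length)")
        radius, length = dims_arr
        pts = _capped_cylinder_surface(radius, length, spacing)
        min_half_extent = float(radius)
        def on_surface(polar, azimuth):
            # place loggers on the lateral surface, axial position from polar
            u = math.radians(polar)
            v = math.radians(azimuth)
            xpos = (length / 2.0) * math.cos(u)
            return np.array([xpos, radius * math.sin(v), radius * math.cos(v)])
    else:
        raise InvalidInputError(f"unknown phantom shape {shape!r}")

    if composition == "tissue-with-adipose-shell":
        if not shell_thickness < min_half_extent:
            raise InvalidInputError("adipose shell must be thinner than the smallest semi-axis")
    elif composition != "uniform-tissue":
        raise InvalidInputError(f"unknown composition {composition!r}")

    spec = DEFAULT_LOGGER_SPEC if logger_spec is None else logger_spec
    sites = {name: on_surface(polar, azimuth) for name, polar, azimuth in spec}
    cloud = PointCloud(points=pts, logger_sites=sites)
    grid = voxelize_surface(cloud, cube_size=cube_size, padding=padding,
                            substrate_thickness=substrate_thickness)

    if composition == "tissue-with-adipose-shell":
        body = grid.body_mask
        # distance (in metres) from each body cube centre to the nearest
        # non-body cube centre; shallow cubes become subcutaneous fat
        dist = ndimage.distance_transform_edt(body, sampling=grid.cube_size)
        grid.labels[body & (dist <= shell_thickness)] = ADIPOSE

    return cloud, grid


def locate_logger_voxel(grid: VoxelGrid, site_position: np.ndarray,
                        name: str = "logger",
                        snap_radius: float = 0.05) -> LoggerSite:
    """Snap a world-space logger position to the nearest surface body cube.

    Distance is Euclidean between the position and cube centres; exact
    ties are broken toward the lexicographically smaller grid index.
    Positions farther than ``snap_radius`` from every surface cube raise
    :class:`LocalizationError`.
    """
    pos = np.asarray(site_position, dtype=float).reshape(3)
    surf_idx = np.argwhere(grid.surface_body_mask())
    if surf_idx.size == 0:
        raise LocalizationError("grid has no surface body cubes")
    centers = grid.cell_centers(surf_idx)
    d2 = np.einsum("ij,ij->i", centers - pos, centers - pos)
    dmin = d2.min()
    if math.sqrt(dmin) > snap_radius:
        raise LocalizationError(
            f"logger {name!r} at {pos.tolist()} is {math.sqrt(dmin):.3f} m from the "
            f"nearest surface cube (snap radius {snap_radius} m)")
    ties = surf_idx[d2 <= dmin + 1e-18]
    order = np.lexsort((ties[:, 2], ties[:, 1], ties[:, 0]))
    best = ties[order[0]]
    return LoggerSite(name=name, world_position=pos, grid_index=tuple(int(v) for v in best))
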