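"""Voxelized phantoms: synthetic neck anatomy, water calibration phantom, surface meshes.

Coordinate convention (used throughout the package): right-handed patient-like
axes with x toward the patient's left, y anterior, z superior, in millimeters.
For a supine patient gravity points along -y.  Voxel indices are 0-based and
positions address voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Tissue/material labels used on the voxel lattice."""

    AIR = 0
    SKIN = 1
    ADIPOSE = 2
    MUSCLE = 3
    BONE = 4
    TUMOR = 5
    WATER = 6


#: nominal mass densities, g/cm^3
DEFAULT_DENSITIES: dict[Tissue, float] = {
    Tissue.AIR: 0.0012,
    Tissue.SKIN: 1.09,
    Tissue.ADIPOSE: 0.95,
    Tissue.MUSCLE: 1.05,
    Tissue.BONE: 1.85,
    Tissue.TUMOR: 1.04,
    Tissue.WATER: 1.00,
}

#: default density -> tissue calibration: ordered (upper threshold, label) pairs.
#: A density d maps to the first interval with d <= threshold; a value exactly
#: on a threshold therefore belongs to the lower interval.
DEFAULT_DENSITY_CALIBRATION: list[tuple[float, Tissue]] = [
    (0.05, Tissue.AIR),
    (0.95, Tissue.ADIPOSE),
    (1.2, Tissue.MUSCLE),
    (np.inf, Tissue.BONE),
]


class GeometryError(ValueError):
    """Raised when a requested phantom geometry is inconsistent."""


@dataclass
class VoxelGrid:
    """Tissue labels and mass densities on a regular 3D lattice.

    Attributes
    ----------
    tissue : (nx, ny, nz) uint8 array of :class:`Tissue` labels.
    density : (nx, ny, nz) float array, g/cm^3.
    spacing : voxel edge lengths (dx, dy, dz), mm.
    origin : position of the center of voxel (0, 0, 0), mm.
    """

    tissue: np.ndarray
    density: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.tissue = np.ascontiguousarray(self.tissue, dtype=np.uint8)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.tissue.shape != self.density.shape:
            raise ValueError("tissue and density shapes differ")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.tissue.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 * 1e-3

    def voxel_mass_kg(self) -> np.ndarray:
        """Per-voxel mass in kg (density g/cm^3 x volume cm^3 x 1e-3)."""
        return self.density * self.voxel_volume_cm3 * 1e-3

    def voxel_center(self, idx) -> np.ndarray:
        """Position (mm) of the center of voxel ``idx``."""
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def index_of(self, position) -> tuple[int, int, int]:
        """Voxel index containing ``position`` (mm); may fall outside the grid."""
        rel = (np.asarray(position) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return tuple(int(np.floor(r + 0.5)) for r in rel)

    def extent_mm(self) -> np.ndarray:
        """(3, 2) array of lower/upper domain edges (voxel faces), mm."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.dims)
        return np.stack([o - 0.5 * sp, o + (n - 0.5) * sp], axis=1)


@dataclass
class NeckGeometry:
    """Descriptor of the synthetic neck anatomy (all lengths mm).

    The phantom is a vertical cylinder of soft tissue wrapped in an adipose
    layer and a skin shell, with a central air lumen (airway), a posterior
    bone cylinder (vertebral column stand-in) and a tumor ellipsoid lateral
    to the lumen, embedded in surrounding air.
    """

    neck_radius: float = 50.0
    skin_thickness: float = 2.0
    adipose_thickness: float = 4.0
    airway_radius: float = 8.0
    airway_center: tuple[float, float] = (0.0, 14.0)
    vertebra_radius: float = 12.0
    vertebra_center: tuple[float, float] = (0.0, -26.0)
    tumor_center: tuple[float, float, float] = (14.0, 14.0, 0.0)
    tumor_semi_axes: tuple[float, float, float] = (8.0, 8.0, 10.0)
    height: float = 60.0
    air_margin: float = 8.0

    def __post_init__(self) -> None:
        for name in ("neck_radius", "skin_thickness", "adipose_thickness",
                     "airway_radius", "vertebra_radius", "height"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if any(a <= 0 for a in self.tumor_semi_axes):
            raise GeometryError("tumor semi-axes must be positive")


def generate_neck_phantom(
    geometry: NeckGeometry | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.3),
    seed: int = 0,
    densities: dict[Tissue, float] | None = None,
    density_jitter: float = 0.02,
) -> VoxelGrid:
    """Generate the synthetic voxelized neck anatomy.

    Densities are drawn per voxel as tissue mean +/- Gaussian jitter
    (standard deviation ``density_jitter`` g/cm^3, seeded); labels are
    deterministic functions of the geometry only.
    """
    geo = geometry or NeckGeometry()
    dens = dict(DEFAULT_DENSITIES)
    if densities:
        dens.update(densities)

    half_xy = geo.neck_radius + geo.air_margin
    nx = int(np.ceil(2 * half_xy / spacing[0]))
    ny = int(np.ceil(2 * half_xy / spacing[1]))
    nz = int(np.ceil(geo.height / spacing[2]))
    origin = (-(nx - 1) / 2 * spacing[0], -(ny - 1) / 2 * spacing[1], -(nz - 1) / 2 * spacing[2])

    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    R = np.hypot(X, Y)

    tissue = np.full((nx, ny, nz), Tissue.AIR, dtype=np.uint8)
    tissue[R <= geo.neck_radius] = Tissue.SKIN
    tissue[R <= geo.neck_radius - geo.skin_thickness] = Tissue.ADIPOSE
    tissue[R <= geo.neck_radius - geo.skin_thickness - geo.adipose_thickness] = Tissue.MUSCLE

    body = tissue != Tissue.AIR
    muscle = tissue == Tissue.MUSCLE

    vx, vy = geo.vertebra_center
    vert = (np.hypot(X - vx, Y - vy) <= geo.vertebra_radius) & muscle
    tissue[vert] = Tissue.BONE

    tx, ty, tz = geo.tumor_center
    ax_, ay_, az_ = geo.tumor_semi_axes
    tum = ((X - tx) / ax_) ** 2 + ((Y - ty) / ay_) ** 2 + ((Z - tz) / az_) ** 2 <= 1.0
    if not np.any(tum & body):
        raise GeometryError("tumor ellipsoid lies entirely outside the body")
    if not np.any(tum & (tissue == Tissue.MUSCLE)):
        raise GeometryError("tumor ellipsoid does not intersect the muscle region")
    tissue[tum & body] = Tissue.TUMOR

    # airway carved last so it punches through any overlapping structure
    ax0, ay0 = geo.airway_center
    lumen = (np.hypot(X - ax0, Y - ay0) <= geo.airway_radius) & body
    tissue[lumen] = Tissue.AIR

    rng = np.random.default_rng(seed)
    density = np.empty_like(tissue, dtype=np.float64)
    for lab in Tissue:
        mask = tissue == lab
        if not np.any(mask):
            continue
        mean = dens[lab]
        if lab == Tissue.AIR or density_jitter == 0:
            density[mask] = mean
        else:
            vals = mean + density_jitter * rng.standard_normal(int(mask.sum()))
            density[mask] = np.clip(vals, 0.1 * mean, None)

    return VoxelGrid(tissue=tissue, density=density, spacing=spacing, origin=origin)


def compact_neck_geometry() -> NeckGeometry:
    """The shipped compact neck fixture used by the demonstration analyses.

    A reduced-height, reduced-radius neck that keeps every anatomical
    structure (skin/adipose/muscle shells, airway, vertebra, lateral tumor)
    while keeping photon-transport budgets desk scale.
    """
    return NeckGeometry(
        neck_radius=40.0,
        skin_thickness=2.0,
        adipose_thickness=4.0,
        airway_radius=7.0,
        airway_center=(0.0, 12.0),
        vertebra_radius=10.0,
        vertebra_center=(0.0, -22.0),
        tumor_center=(12.0, 12.0, 0.0),
        tumor_semi_axes=(7.0, 7.0, 8.0),
        height=40.0,
        air_margin=6.0,
    )


def generate_water_phantom(
    dims_cm: tuple[float, float, float] = (30.0, 30.0, 50.0),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> VoxelGrid:
    """Uniform water block for monitor-unit calibration.

    ``dims_cm`` is the physical size in cm; the default matches the
    30 x 30 x 50 cm calibration sample with the beam along +z starting at the
    z=0 face (origin places voxel (0,0,0) centered at half a spacing inside).
    """
    if any(d <= 0 for d in dims_cm):
        raise ValueError("dims must be positive")
    dims_mm = np.asarray(dims_cm, dtype=float) * 10.0
    n = tuple(int(round(d / s)) for d, s in zip(dims_mm, spacing))
    tissue = np.full(n, Tissue.WATER, dtype=np.uint8)
    density = np.full(n, 1.0)
    origin = (
        -(n[0] - 1) / 2 * spacing[0],
        -(n[1] - 1) / 2 * spacing[1],
        spacing[2] / 2,
    )
    return VoxelGrid(tissue=tissue, density=density, spacing=spacing, origin=origin)


def density_to_tissue(
    density: float,
    calibration: list[tuple[float, Tissue]] | None = None,
) -> Tissue:
    """Map a mass density (g/cm^3) to a tissue label via the calibration table.

    The table is an ordered list of (upper threshold, label); the first
    interval whose upper threshold is >= density wins, so a density exactly on
    a threshold takes the lower interval's label.
    """
    if density < 0:
        raise ValueError("density must be nonnegative")
    table = calibration if calibration is not None else DEFAULT_DENSITY_CALIBRATION
    thresholds = [t for t, _ in table]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("calibration thresholds must be strictly increasing")
    for threshold, label in table:
        if density <= threshold:
            return label
    return table[-1][1]


# ---------------------------------------------------------------------------
# surface mesh

_AXIS_SIDES = [(a, s) for a in range(3) for s in (-1, +1)]


@dataclass
class SurfaceMesh:
    """Axis-aligned exposed-face mesh of the tissue-air boundary.

    One element per voxel face separating a non-air voxel from air (or from
    outside the domain).  Element i belongs to voxel ``voxel_idx[i]``, points
    along ``normals[i]`` (unit, outward) and has area ``areas[i]`` equal to
    the product of the two transverse spacings.
    """

    centers: np.ndarray          # (M, 3) mm
    normals: np.ndarray          # (M, 3)
    areas: np.ndarray            # (M,) mm^2
    voxel_idx: np.ndarray        # (M, 3) int
    axis: np.ndarray             # (M,) face axis 0/1/2
    side: np.ndarray             # (M,) -1 or +1
    spacing: tuple[float, float, float]
    face_lookup: np.ndarray = field(repr=False, default=None)  # (6, nx, ny, nz) int32, -1 = none
    _neighbor_cache: dict = field(repr=False, default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def neighbor_lists(self, radius_factor: float = 1.5) -> list[np.ndarray]:
        """Indices of face-adjacent surface neighbors of each element.

        Neighbors are elements whose centers lie within
        ``radius_factor * max(spacing)`` — on a flat patch this is the 3x3
        block around the element, the default median-filter stencil.
        """
        if radius_factor in self._neighbor_cache:
            return self._neighbor_cache[radius_factor]
        from scipy.spatial import cKDTree

        tree = cKDTree(self.centers)
        r = radius_factor * max(self.spacing)
        lists = [np.asarray(lst, dtype=np.intp) for lst in tree.query_ball_point(self.centers, r)]
        self._neighbor_cache[radius_factor] = lists
        return lists

    def to_trimesh(self):
        """Quad faces split into triangles, for PLY/STL export (visualization)."""
        import trimesh

        sp = np.asarray(self.spacing)
        verts = []
        faces = []
        for i in range(len(self)):
            a = int(self.axis[i])
            t1, t2 = [(1, 2), (0, 2), (0, 1)][a]
            e1 = np.zeros(3)
            e2 = np.zeros(3)
            e1[t1] = sp[t1] / 2
            e2[t2] = sp[t2] / 2
            c = self.centers[i]
            base = len(verts)
            verts.extend([c - e1 - e2, c + e1 - e2, c + e1 + e2, c - e1 + e2])
            faces.append([base, base + 1, base + 2])
            faces.append([base, base + 2, base + 3])
        return trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces), process=False)


def extract_surface_mesh(grid: VoxelGrid) -> SurfaceMesh:
    """Extract the exposed-face mesh of all non-air voxels.

    A face is exposed when its owning voxel is non-air and the neighbor across
    the face is air or outside the domain.  Every tissue-air boundary face
    appears exactly once (it is owned by the tissue voxel).
    """
    nonair = grid.tissue != Tissue.AIR
    if not np.any(nonair):
        raise ValueError("grid contains no non-air voxels")
    nx, ny, nz = grid.dims
    sp = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)

    face_lookup = np.full((6, nx, ny, nz), -1, dtype=np.int32)
    centers, normals, areas, voxels, axes, sides = [], [], [], [], [], []

    air = ~nonair
    for fi, (a, s) in enumerate(_AXIS_SIDES):
        # neighbor-is-air (or out of domain) mask, same shape as grid
        exposed = nonair.copy()
        shifted = np.ones_like(air)  # out-of-domain counts as air
        sl_src = [slice(None)] * 3
        sl_dst = [slice(None)] * 3
        if s == +1:
            sl_dst[a] = slice(0, -1)
            sl_src[a] = slice(1, None)
        else:
            sl_dst[a] = slice(1, None)
            sl_src[a] = slice(0, -1)
        shifted[tuple(sl_dst)] = air[tuple(sl_src)]
        exposed &= shifted

        idx = np.argwhere(exposed)
        if len(idx) == 0:
            continue
        start = sum(len(v) for v in voxels)
        face_lookup[fi][tuple(idx.T)] = np.arange(start, start + len(idx), dtype=np.int32)
        c = origin + idx * sp
        c[:, a] += s * sp[a] / 2
        n = np.zeros((len(idx), 3))
        n[:, a] = s
        t1, t2 = [(1, 2), (0, 2), (0, 1)][a]
        centers.append(c)
        normals.append(n)
        areas.append(np.full(len(idx), sp[t1] * sp[t2]))
        voxels.append(idx)
        axes.append(np.full(len(idx), a, dtype=np.int8))
        sides.append(np.full(len(idx), s, dtype=np.int8))

    return SurfaceMesh(
        centers=np.concatenate(centers),
        normals=np.concatenate(normals),
        areas=np.concatenate(areas),
        voxel_idx=np.concatenate(voxels),
        axis=np.concatenate(axes),
        side=np.concatenate(sides),
        spacing=grid.spacing,
        face_lookup=face_lookup,
    )
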