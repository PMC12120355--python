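"""Optical photon transport through the heterogeneous voxel grid.

Analog (single-photon, unweighted) transport: exponential free paths over
the accumulated optical depth with 3D DDA voxel traversal, Henyey-Greenstein
scattering, absorption chosen with probability mu_a/mu_t at each
interaction, and unpolarized Fresnel reflection/refraction at tissue-air
boundaries (internal tissue-tissue interfaces are index matched).  Each
photon carries its birth position so the origin of surface light is
computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cherensim import _kernels
from cherensim.phantom import SurfaceMesh, Tissue, VoxelGrid
from cherensim.properties import OpticalTables

DEFAULT_MAX_EVENTS = 1_000_000

STATUS_ALIVE = _kernels.ALIVE
STATUS_ABSORBED = _kernels.ABSORBED
STATUS_EXITED = _kernels.EXITED
STATUS_CAPPED = _kernels.CAPPED


@dataclass
class OpticalPhoton:
    """A Cherenkov photon in flight (positions mm, wavelength nm)."""

    birth_position: np.ndarray
    position: np.ndarray
    direction: np.ndarray
    wavelength: float
    birth_voxel: tuple[int, int, int] | None = None
    born_in_tumor: bool = False
    status: int = STATUS_ALIVE

    def __post_init__(self) -> None:
        self.birth_position = np.asarray(self.birth_position, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if not 500.0 <= self.wavelength <= 1200.0:
            raise ValueError("wavelength outside the 500-1200 nm band")
        if not np.isclose(np.linalg.norm(self.direction), 1.0, atol=1e-6):
            raise ValueError("direction must be unit length")


@dataclass
class SurfaceExitRecord:
    """A photon that crossed the tissue-air boundary, with its provenance."""

    element_id: int
    exit_position: np.ndarray
    exit_direction: np.ndarray
    wavelength: float
    birth_position: np.ndarray
    born_in_tumor: bool


@dataclass
class ExitRecords:
    """Columnar bank of surface-exit records (one row per exited photon)."""

    element_id: np.ndarray
    exit_position: np.ndarray
    exit_direction: np.ndarray
    wavelength: np.ndarray
    birth_position: np.ndarray
    born_in_tumor: np.ndarray

    def __len__(self) -> int:
        return len(self.element_id)

    def select_band(self, lam_lo: float, lam_hi: float) -> "ExitRecords":
        m = (self.wavelength >= lam_lo) & (self.wavelength <= lam_hi)
        return self.subset(m)

    def subset(self, mask) -> "ExitRecords":
        return ExitRecords(
            element_id=self.element_id[mask],
            exit_position=self.exit_position[mask],
            exit_direction=self.exit_direction[mask],
            wavelength=self.wavelength[mask],
            birth_position=self.birth_position[mask],
            born_in_tumor=self.born_in_tumor[mask],
        )

    def __getitem__(self, i: int) -> SurfaceExitRecord:
        return SurfaceExitRecord(
            element_id=int(self.element_id[i]),
            exit_position=self.exit_position[i],
            exit_direction=self.exit_direction[i],
            wavelength=float(self.wavelength[i]),
            birth_position=self.birth_position[i],
            born_in_tumor=bool(self.born_in_tumor[i]),
        )


@dataclass
class TraceResult:
    """Fates of a traced photon bank; births = absorbed + exited + capped."""

    status: np.ndarray
    exits: ExitRecords
    absorbed_voxels: np.ndarray        # (N, 3), valid where status is ABSORBED/CAPPED
    fluence_mm: np.ndarray | None = None  # track length per voxel, if scored

    @property
    def n_absorbed(self) -> int:
        return int(np.sum(self.status == STATUS_ABSORBED))

    @property
    def n_exited(self) -> int:
        return int(np.sum(self.status == STATUS_EXITED))

    @property
    def n_capped(self) -> int:
        return int(np.sum(self.status == STATUS_CAPPED))


def sample_free_path(mu_t: float, u: float) -> float:
    """Exponential free path -ln(u)/mu_t (mm); infinite when mu_t = 0."""
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    if mu_t < 0:
        raise ValueError("mu_t must be nonnegative")
    if mu_t == 0.0:
        return np.inf
    return -np.log(u) / mu_t


def hg_inverse_cdf(g: float, u):
    """Henyey-Greenstein deflection cosine for uniform variate(s) ``u``.

    Closed-form inverse CDF; g = 0 degenerates to the isotropic 2u - 1.
    """
    if abs(g) >= 1:
        raise ValueError("anisotropy g must be in (-1, 1)")
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-9:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = np.clip((1.0 + g * g - frac**2) / (2.0 * g), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def scatter_hg(g: float, rng: np.random.Generator) -> float:
    """Sample a Henyey-Greenstein deflection cosine."""
    return float(hg_inverse_cdf(g, rng.random()))


def fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance at incidence cosine ``cos_i``."""
    return float(_kernels._fresnel_unpolarized(cos_i, n_in, n_out))


def boundary_interaction(direction, normal, n_in: float, n_out: float, rng: np.random.Generator):
    """Reflect or refract at an interface; returns (new direction, exited?).

    Unpolarized Fresnel reflectance decides reflection; otherwise Snell
    refraction.  Total internal reflection beyond the critical angle.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("refractive indices must be >= 1")
    d = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    cos_i = float(np.dot(d, nrm))
    if cos_i < 0:
        nrm = -nrm
        cos_i = -cos_i
    if n_in == n_out:
        return d.copy(), True
    refl = fresnel_reflectance(cos_i, n_in, n_out)
    if rng.random() < refl:
        return d - 2.0 * cos_i * nrm, False
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = (n_in / n_out) ** 2 * sin_i2
    cos_t = np.sqrt(max(0.0, 1.0 - sin_t2))
    tangential = d - cos_i * nrm
    out = (n_in / n_out) * tangential + cos_t * nrm
    return out / np.linalg.norm(out), True


def trace_photon_bank(
    positions,
    directions,
    wavelengths,
    grid: VoxelGrid,
    tables: OpticalTables,
    mesh: SurfaceMesh,
    rng_seed: int = 0,
    fresnel: bool = True,
    max_events: int = DEFAULT_MAX_EVENTS,
    born_in_tumor: np.ndarray | None = None,
    score_fluence: bool = False,
) -> TraceResult:
    """Trace a bank of photons; returns per-photon fates and exit records."""
    pos = np.ascontiguousarray(np.atleast_2d(positions), dtype=np.float64)
    dirs = np.ascontiguousarray(np.atleast_2d(directions), dtype=np.float64)
    lam = np.ascontiguousarray(np.atleast_1d(wavelengths), dtype=np.float64)
    n = len(lam)

    # starting voxel must be inside the grid and non-air
    rel = (pos - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    idx = np.floor(rel + 0.5).astype(np.int64)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.dims)):
        raise ValueError("photon starts outside the grid")
    if np.any(grid.tissue[idx[:, 0], idx[:, 1], idx[:, 2]] == Tissue.AIR):
        raise ValueError("photon starts in an air voxel")

    mua, mus, g_tab, n_tab = tables.as_arrays(max(int(t) for t in Tissue) + 1)
    lam0 = float(tables.wavelengths_nm[0])
    dlam = float(tables.wavelengths_nm[1] - tables.wavelengths_nm[0])

    status = np.zeros(n, dtype=np.uint8)
    exit_elem = np.full(n, -1, dtype=np.int32)
    exit_pos = np.zeros((n, 3))
    exit_dir = np.zeros((n, 3))
    absorb_voxel = np.full((n, 3), -1, dtype=np.int32)
    fluence = np.zeros(grid.dims) if score_fluence else np.zeros((1, 1, 1))

    _kernels.run_optics_batch(
        int(rng_seed) % 2**31,
        pos, dirs, lam,
        grid.tissue, np.asarray(grid.origin, dtype=float), np.asarray(grid.spacing, dtype=float),
        mua, mus, g_tab, n_tab, lam0, dlam,
        fresnel, int(max_events),
        mesh.face_lookup,
        status, exit_elem, exit_pos, exit_dir, absorb_voxel,
        fluence, score_fluence,
        int(Tissue.AIR),
    )

    bit = (born_in_tumor if born_in_tumor is not None
           else grid.tissue[idx[:, 0], idx[:, 1], idx[:, 2]] == Tissue.TUMOR)
    exited = status == STATUS_EXITED
    exits = ExitRecords(
        element_id=exit_elem[exited],
        exit_position=exit_pos[exited],
        exit_direction=exit_dir[exited],
        wavelength=lam[exited],
        birth_position=pos[exited],
        born_in_tumor=np.asarray(bit)[exited],
    )
    return TraceResult(
        status=status,
        exits=exits,
        absorbed_voxels=absorb_voxel,
        fluence_mm=fluence if score_fluence else None,
    )


def trace_optical_photon(
    photon: OpticalPhoton,
    grid: VoxelGrid,
    tables: OpticalTables,
    mesh: SurfaceMesh,
    rng_seed: int = 0,
    fresnel: bool = True,
    max_events: int = DEFAULT_MAX_EVENTS,
):
    """Trace one photon; returns a SurfaceExitRecord or the absorbed voxel index."""
    res = trace_photon_bank(
        photon.position[None, :], photon.direction[None, :],
        np.array([photon.wavelength]), grid, tables, mesh,
        rng_seed=rng_seed, fresnel=fresnel, max_events=max_events,
    )
    photon.status = int(res.status[0])
    if res.status[0] == STATUS_EXITED:
        rec = res.exits[0]
        return SurfaceExitRecord(
            element_id=rec.element_id,
            exit_position=rec.exit_position,
            exit_direction=rec.exit_direction,
            wavelength=rec.wavelength,
            birth_position=photon.birth_position,
            born_in_tumor=photon.born_in_tumor,
        )
    return tuple(int(v) for v in res.absorbed_voxels[0])
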