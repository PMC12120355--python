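"""Radiation transport: X-ray photons, secondary electrons, dose, Cherenkov yield.

Physics scope: Compton scattering (Klein-Nishina) and photoelectric
absorption for megavoltage photons; straight-line continuous-slowing-down
(CSDA) electron transport without multiple scattering or bremsstrahlung.
Electrons above the local Cherenkov threshold emit photons along their track
at the Frank-Tamm rate integrated over the 500-1200 nm band.

The functions here are the reference implementations (plain numpy, one
particle at a time, np.random.Generator driven); the batch entry points
delegate to the numba kernels in :mod:`cherensim._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cherensim import _kernels
from cherensim.phantom import Tissue, VoxelGrid
from cherensim.plan import XRayPhoton
from cherensim.properties import (
    ELECTRON_REST_MEV,
    OpticalTables,
    RadiologicalTables,
    WAVELENGTH_MAX_NM,
    WAVELENGTH_MIN_NM,
)

MEV_TO_JOULE = 1.602176634e-13
FINE_STRUCTURE_INV = 137.036
#: sentinel returned by cherenkov_threshold_energy when n <= 1
NO_THRESHOLD = np.inf

DEFAULT_ELECTRON_STEP_MM = 0.1
DEFAULT_ELECTRON_CUTOFF_MEV = 0.01
DEFAULT_XRAY_CUTOFF_MEV = 0.01


def beta_from_energy(e_kin_mev: float) -> float:
    """Speed ratio beta = v/c of an electron with kinetic energy E (MeV)."""
    if e_kin_mev < 0:
        raise ValueError("kinetic energy must be nonnegative")
    gamma_inv = ELECTRON_REST_MEV / (e_kin_mev + ELECTRON_REST_MEV)
    return float(np.sqrt(1.0 - gamma_inv**2))


def cherenkov_threshold_energy(n: float) -> float:
    """Kinetic energy (MeV) at which an electron starts emitting, beta*n = 1.

    For n <= 1 no threshold exists (returns inf).  At n = 1.4 this is
    ~0.219 MeV, the ~0.2 MeV soft-tissue threshold.
    """
    if n <= 0:
        raise ValueError("refractive index must be positive")
    if n <= 1:
        return NO_THRESHOLD
    return ELECTRON_REST_MEV * (1.0 / np.sqrt(1.0 - n**-2) - 1.0)


def frank_tamm_yield(beta: float, n: float, z: float, lam1_nm: float, lam2_nm: float) -> float:
    """Expected Cherenkov photons per mm of path in the band [lam1, lam2] nm.

    Closed-form integral of the Frank-Tamm spectral density
    d2N/dx dlam = (2 pi z^2 / 137.036) (1 - 1/(beta^2 n^2)) / lam^2
    over wavelength; zero below the emission condition beta*n > 1.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must be in (0, 1)")
    if lam1_nm >= lam2_nm:
        raise ValueError("lam1 must be < lam2")
    if beta * n <= 1.0:
        return 0.0
    factor = 1.0 - 1.0 / (beta * beta * n * n)
    inv_band = (1.0 / lam1_nm - 1.0 / lam2_nm) * 1.0e6  # nm^-1 -> mm^-1
    return float(2.0 * np.pi * z * z / FINE_STRUCTURE_INV * factor * inv_band)


def sample_cherenkov_wavelength(u: float, lam1_nm: float, lam2_nm: float) -> float:
    """Inverse-CDF sample of the 1/lam^2 spectral density on [lam1, lam2]."""
    if lam1_nm >= lam2_nm:
        raise ValueError("lam1 must be < lam2")
    return 1.0 / (1.0 / lam1_nm - u * (1.0 / lam1_nm - 1.0 / lam2_nm))


def sample_cherenkov_photon(
    beta: float,
    n: float,
    lam1_nm: float,
    lam2_nm: float,
    parent_direction,
    rng: np.random.Generator,
):
    """Draw (direction, wavelength) of one Cherenkov photon.

    The direction lies on the cone of half-angle arccos(1/(beta n)) about the
    parent electron direction with uniform azimuth; the wavelength follows
    the 1/lam^2 law on the band.
    """
    if beta * n <= 1.0:
        raise ValueError("no Cherenkov emission: beta * n <= 1")
    lam = sample_cherenkov_wavelength(rng.random(), lam1_nm, lam2_nm)
    cos_c = 1.0 / (beta * n)
    phi = 2.0 * np.pi * rng.random()
    d = np.asarray(parent_direction, dtype=float)
    d = d / np.linalg.norm(d)
    direction = np.array(_kernels._rotate(d[0], d[1], d[2], cos_c, phi))
    return direction, lam


def klein_nishina_pdf(e_mev: float, cos_theta) -> np.ndarray:
    """Unnormalized Klein-Nishina angular density d sigma / d cos(theta)."""
    c = np.asarray(cos_theta, dtype=float)
    k = e_mev / ELECTRON_REST_MEV
    ratio = 1.0 / (1.0 + k * (1.0 - c))
    return 0.5 * ratio**2 * (1.0 / ratio + ratio - (1.0 - c**2))


def compton_scatter(photon: XRayPhoton, rng: np.random.Generator):
    """Compton-scatter a photon; returns (scattered photon, electron track).

    The scattering angle follows the Klein-Nishina cross-section (rejection
    sampling); the electron receives the energy difference along the
    momentum-balancing direction.
    """
    e = photon.energy
    k = e / ELECTRON_REST_MEV
    while True:
        c = 2.0 * rng.random() - 1.0
        if rng.random() < klein_nishina_pdf(e, c):  # max value (theta=0) is 1
            break
    e_sc = e / (1.0 + k * (1.0 - c))
    e_el = e - e_sc
    phi = 2.0 * np.pi * rng.random()
    d = photon.direction
    sin_t = np.sqrt(max(0.0, 1.0 - c * c))
    new_dir = np.array(_kernels._rotate(d[0], d[1], d[2], c, phi))
    scattered = XRayPhoton(position=photon.position.copy(), direction=new_dir,
                           energy=e_sc, weight=photon.weight)
    # electron angle: tan(phi_el) = 1 / ((1+k) tan(theta/2))
    if sin_t < 1e-12:
        el_dir = d.copy()
        cos_el = 1.0
    else:
        half_tan = sin_t / (1.0 + c)
        tan_el = 1.0 / ((1.0 + k) * half_tan)
        cos_el = 1.0 / np.sqrt(1.0 + tan_el**2)
        el_dir = np.array(_kernels._rotate(d[0], d[1], d[2], cos_el, phi + np.pi))
    electron = ElectronTrack(position=photon.position.copy(), direction=el_dir,
                             kinetic_energy=e_el)
    return scattered, electron


def compton_scattered_energy(e_mev: float, theta_rad: float) -> float:
    """E' = E / (1 + (E / m_e c^2)(1 - cos theta)) — Compton kinematics."""
    return e_mev / (1.0 + (e_mev / ELECTRON_REST_MEV) * (1.0 - np.cos(theta_rad)))


@dataclass
class ElectronTrack:
    """A secondary electron: position (mm), unit direction, kinetic energy (MeV)."""

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be nonnegative")
        if not np.isclose(np.linalg.norm(self.direction), 1.0, atol=1e-9):
            raise ValueError("direction must be unit length")

    @property
    def beta(self) -> float:
        return beta_from_energy(self.kinetic_energy)


@dataclass
class DoseGrid:
    """Per-voxel deposited energy (MeV) and derived dose.

    ``units`` is "per-particle" until scaled to physical units by the MU
    calibration.
    """

    energy_mev: np.ndarray
    grid: VoxelGrid
    n_particles: int = 1
    units: str = "per-particle"

    @property
    def dose_gy(self) -> np.ndarray:
        """Dose = deposited energy x 1.602e-13 J/MeV / voxel mass (kg)."""
        mass = self.grid.voxel_mass_kg()
        if np.any((mass <= 0) & (self.energy_mev > 0)):
            raise ValueError("energy deposited in a zero-density voxel")
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(mass > 0, self.energy_mev * MEV_TO_JOULE / np.where(mass > 0, mass, 1.0), 0.0)
        return d

    @property
    def dose_per_particle_gy(self) -> np.ndarray:
        return self.dose_gy / self.n_particles

    @property
    def total_energy_mev(self) -> float:
        return float(self.energy_mev.sum())


@dataclass
class EmissionGrid:
    """Per-voxel Cherenkov photon counts, optionally wavelength resolved."""

    counts: np.ndarray
    grid: VoxelGrid
    spectral_counts: np.ndarray | None = None   # (n_bins, nx, ny, nz)
    band_edges_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.spectral_counts is not None:
            marg = self.spectral_counts.sum(axis=0)
            if not np.allclose(marg, self.counts):
                raise ValueError("spectral marginal must equal the unresolved grid")

    @property
    def photons_per_mm3(self) -> np.ndarray:
        return self.counts / self.grid.voxel_volume_mm3

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def score_dose(deposits: np.ndarray, grid: VoxelGrid, n_particles: int = 1) -> DoseGrid:
    """Wrap a per-voxel energy deposit array (MeV) into a DoseGrid."""
    deposits = np.asarray(deposits, dtype=float)
    if deposits.shape != grid.dims:
        raise ValueError("deposit array shape must match the grid")
    if np.any(deposits < 0):
        raise ValueError("deposits must be nonnegative")
    dg = DoseGrid(energy_mev=deposits, grid=grid, n_particles=n_particles)
    dg.dose_gy  # trigger the zero-mass check
    return dg


# ---------------------------------------------------------------------------
# batch transport


@dataclass
class TransportResult:
    """Output of a radiation-transport batch."""

    dose: DoseGrid
    emission: EmissionGrid
    photon_bank: dict = field(default_factory=dict)
    n_banked: int = 0
    n_generated: int = 0
    escaped_energy_mev: float = 0.0
    history_deposits_mev: np.ndarray | None = None
    history_escapes_mev: np.ndarray | None = None

    @property
    def deposited_energy_mev(self) -> float:
        return self.dose.total_energy_mev


def _kernel_tables(rad: RadiologicalTables, opt: OpticalTables):
    n_t = max(int(t) for t in Tissue) + 1
    mc, mp, sp, rho = rad.as_arrays(n_t)
    e0_log = float(np.log(rad.energies_mev[0]))
    de_log = float(np.log(rad.energies_mev[1]) - np.log(rad.energies_mev[0]))
    n_ref = np.ones(n_t)
    for t in opt.n:
        n_ref[int(t)] = opt.band_mean_n(t)
    n_ref[int(Tissue.AIR)] = 1.0
    return mc, mp, sp, rho, e0_log, de_log, n_ref


def transport_xray(
    photons,
    grid: VoxelGrid,
    rad: RadiologicalTables,
    opt: OpticalTables,
    rng_seed: int = 0,
    electron_step_mm: float = DEFAULT_ELECTRON_STEP_MM,
    electron_cutoff_mev: float = DEFAULT_ELECTRON_CUTOFF_MEV,
    xray_cutoff_mev: float = DEFAULT_XRAY_CUTOFF_MEV,
    band_nm: tuple[float, float] = (WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM),
    emission_fraction: float = 1.0,
    bank_capacity: int = 2_000_000,
) -> TransportResult:
    """Transport X-ray photons through the grid; dose, emission, photon bank.

    ``photons`` is a single :class:`XRayPhoton` or a (positions, directions,
    energies) array triple.  ``emission_fraction`` thins the stored analog
    Cherenkov bank (the emission grid still counts every generated photon).
    """
    if isinstance(photons, XRayPhoton):
        pos = photons.position[None, :]
        dirs = photons.direction[None, :]
        energies = np.array([photons.energy])
    else:
        pos, dirs, energies = photons
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        energies = np.atleast_1d(np.asarray(energies, dtype=float))
    n = len(energies)
    mc, mp, sp, rho, e0_log, de_log, n_ref = _kernel_tables(rad, opt)
    ft_const = 2.0 * np.pi * rad.z_charge**2 / FINE_STRUCTURE_INV

    edep = np.zeros(grid.dims)
    emission = np.zeros(grid.dims, dtype=np.int64)
    bank_pos = np.zeros((bank_capacity, 3), dtype=np.float32)
    bank_dir = np.zeros((bank_capacity, 3), dtype=np.float32)
    bank_lam = np.zeros(bank_capacity, dtype=np.float32)
    bank_tis = np.zeros(bank_capacity, dtype=np.uint8)
    hist_dep = np.zeros(n)
    hist_esc = np.zeros(n)

    n_banked, n_generated, escaped = _kernels.run_xray_batch(
        int(rng_seed) % 2**31,
        np.ascontiguousarray(pos), np.ascontiguousarray(dirs),
        np.ascontiguousarray(energies),
        grid.tissue, grid.density,
        np.asarray(grid.origin, dtype=float), np.asarray(grid.spacing, dtype=float),
        mc, mp, sp, rho, e0_log, de_log,
        n_ref, ft_const, float(band_nm[0]), float(band_nm[1]),
        electron_step_mm, electron_cutoff_mev, xray_cutoff_mev, emission_fraction,
        edep, emission,
        bank_pos, bank_dir, bank_lam, bank_tis,
        hist_dep, hist_esc,
        int(Tissue.AIR),
    )
    bank = {
        "position": bank_pos[:n_banked].astype(np.float64),
        "direction": bank_dir[:n_banked].astype(np.float64),
        "wavelength": bank_lam[:n_banked].astype(np.float64),
        "birth_tissue": bank_tis[:n_banked].copy(),
    }
    return TransportResult(
        dose=score_dose(edep, grid, n_particles=n),
        emission=EmissionGrid(counts=emission, grid=grid),
        photon_bank=bank,
        n_banked=int(n_banked),
        n_generated=int(n_generated),
        escaped_energy_mev=float(escaped),
        history_deposits_mev=hist_dep,
        history_escapes_mev=hist_esc,
    )


def transport_electron(
    electrons,
    grid: VoxelGrid,
    opt: OpticalTables,
    rad: RadiologicalTables,
    rng_seed: int = 0,
    step_mm: float = DEFAULT_ELECTRON_STEP_MM,
    cutoff_mev: float = DEFAULT_ELECTRON_CUTOFF_MEV,
    band_nm: tuple[float, float] = (WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM),
    emission_fraction: float = 1.0,
    bank_capacity: int = 1_000_000,
) -> TransportResult:
    """Transport primary electrons (CSDA steps + Cherenkov emission)."""
    if isinstance(electrons, ElectronTrack):
        pos = electrons.position[None, :]
        dirs = electrons.direction[None, :]
        energies = np.array([electrons.kinetic_energy])
    else:
        pos, dirs, energies = electrons
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        energies = np.atleast_1d(np.asarray(energies, dtype=float))
    n = len(energies)
    mc, mp, sp, rho, e0_log, de_log, n_ref = _kernel_tables(rad, opt)
    ft_const = 2.0 * np.pi * rad.z_charge**2 / FINE_STRUCTURE_INV

    edep = np.zeros(grid.dims)
    emission = np.zeros(grid.dims, dtype=np.int64)
    bank_pos = np.zeros((bank_capacity, 3), dtype=np.float32)
    bank_dir = np.zeros((bank_capacity, 3), dtype=np.float32)
    bank_lam = np.zeros(bank_capacity, dtype=np.float32)
    bank_tis = np.zeros(bank_capacity, dtype=np.uint8)
    hist_dep = np.zeros(n)
    hist_esc = np.zeros(n)

    n_banked, n_generated = _kernels.run_electron_batch(
        int(rng_seed) % 2**31,
        np.ascontiguousarray(pos), np.ascontiguousarray(dirs),
        np.ascontiguousarray(energies),
        grid.tissue, grid.density,
        np.asarray(grid.origin, dtype=float), np.asarray(grid.spacing, dtype=float),
        sp, rho, e0_log, de_log,
        n_ref, ft_const, float(band_nm[0]), float(band_nm[1]),
        step_mm, cutoff_mev, emission_fraction,
        edep, emission,
        bank_pos, bank_dir, bank_lam, bank_tis,
        hist_dep, hist_esc,
        int(Tissue.AIR),
    )
    bank = {
        "position": bank_pos[:n_banked].astype(np.float64),
        "direction": bank_dir[:n_banked].astype(np.float64),
        "wavelength": bank_lam[:n_banked].astype(np.float64),
        "birth_tissue": bank_tis[:n_banked].copy(),
    }
    return TransportResult(
        dose=score_dose(edep, grid, n_particles=n),
        emission=EmissionGrid(counts=emission, grid=grid),
        photon_bank=bank,
        n_banked=int(n_banked),
        n_generated=int(n_generated),
        escaped_energy_mev=float(hist_esc.sum()),
        history_deposits_mev=hist_dep,
        history_escapes_mev=hist_esc,
    )


def expected_cherenkov_yield(
    e0_mev: float,
    tissue: Tissue,
    opt: OpticalTables,
    rad: RadiologicalTables,
    density_g_cm3: float | None = None,
    step_mm: float = DEFAULT_ELECTRON_STEP_MM,
    cutoff_mev: float = DEFAULT_ELECTRON_CUTOFF_MEV,
    band_nm: tuple[float, float] = (WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM),
) -> float:
    """Deterministic step-sum of the Frank-Tamm yield along a CSDA slowdown.

    Independent of the Monte Carlo path: marches the same CSDA energy grid
    and sums expected (not sampled) photon numbers per step.  Serves as the
    oracle for the stochastic electron transport.
    """
    n_med = opt.band_mean_n(tissue)
    rho = density_g_cm3 if density_g_cm3 is not None else rad.nominal_density[tissue]
    rho_scale = rho / rad.nominal_density[tissue]
    loge = np.log(rad.energies_mev)
    e0_log, de_log = float(loge[0]), float(loge[1] - loge[0])
    sp_tab = rad.stopping_power[tissue]
    e = e0_mev
    total = 0.0
    while e > cutoff_mev:
        f = (np.log(e) - e0_log) / de_log
        i = int(np.clip(f, 0, len(sp_tab) - 2))
        w = np.clip(f - i, 0.0, 1.0)
        s_loc = ((1 - w) * sp_tab[i] + w * sp_tab[i + 1]) * rho_scale
        de = min(s_loc * step_mm, e)
        e_mid = e - de / 2
        beta = beta_from_energy(e_mid)
        if beta * n_med > 1.0:
            total += frank_tamm_yield(beta, n_med, rad.z_charge, *band_nm) * step_mm
        e -= de
    return total
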