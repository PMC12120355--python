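"""End-to-end drivers: water-phantom MU calibration and treatment simulation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cherensim.analysis import CalibrationResult, calibrate_mu
from cherensim.optics import TraceResult, ExitRecords, trace_photon_bank
from cherensim.phantom import (
    SurfaceMesh,
    Tissue,
    VoxelGrid,
    extract_surface_mesh,
    generate_water_phantom,
)
from cherensim.plan import BeamControlPoint, Mv6Spectrum, TreatmentPlan, gantry_transform
from cherensim.properties import (
    OpticalTables,
    RadiologicalTables,
    default_optical_tables,
    default_radiological_tables,
)
from cherensim.radtransport import TransportResult, transport_xray


def sample_calibration_photons(
    n: int,
    spectrum: Mv6Spectrum,
    rng: np.random.Generator,
    ssd_mm: float = 1000.0,
    field_mm: float = 100.0,
):
    """Photon states for the calibration geometry: point source on the +z
    beam axis at SSD above the water surface (z = 0), 10x10 cm field at the
    surface."""
    source = np.array([0.0, 0.0, -ssd_mm])
    xy = (rng.random((n, 2)) - 0.5) * field_mm
    targets = np.column_stack([xy, np.zeros(n)])
    dirs = targets - source
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos = np.tile(source, (n, 1))
    energies = spectrum.sample(rng, n)
    return pos, dirs, energies


@dataclass
class CalibrationRun:
    calibration: CalibrationResult
    dose: "TransportResult"
    water: VoxelGrid
    n_photons: int


def run_water_calibration(
    n_photons: int = 100_000,
    seed: int = 1,
    spacing_mm: float = 2.0,
    spectrum: Mv6Spectrum | None = None,
    rad: RadiologicalTables | None = None,
    opt: OpticalTables | None = None,
) -> CalibrationRun:
    """Simulate the MU calibration conditions and derive particles-per-MU.

    30x30x50 cm water sample, source-to-surface distance 100 cm, 10x10 cm
    field at the surface, beam along +z; D_d is read at the axis voxel
    nearest 1.5 cm depth and N = 1 cGy / D_d.
    """
    water = generate_water_phantom((30.0, 30.0, 50.0), (spacing_mm,) * 3)
    spec = spectrum or Mv6Spectrum()
    rng = np.random.default_rng(seed)
    states = sample_calibration_photons(n_photons, spec, rng)
    res = transport_xray(
        states, water,
        rad or default_radiological_tables(),
        opt or default_optical_tables(),
        rng_seed=seed,
        emission_fraction=0.0,
        bank_capacity=1,
    )
    cal = calibrate_mu(res.dose)
    return CalibrationRun(calibration=cal, dose=res, water=water, n_photons=n_photons)


def sample_plan_photons(
    plan: TreatmentPlan,
    n_total: int,
    spectrum: Mv6Spectrum,
    rng: np.random.Generator,
):
    """Sample beam-photon initial states for a whole plan, MU-proportionally.

    Returns a list (one entry per beam) of (positions, directions, energies).
    Photon counts are split across beams and control points proportionally
    to MU weight (largest-remainder rounding).
    """
    mu_beam = np.array(plan.beam_mu_totals())
    if mu_beam.sum() == 0:
        return [(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0)) for _ in plan.beams]
    n_beam = _proportional_counts(mu_beam, n_total)
    out = []
    iso = np.asarray(plan.isocenter, dtype=float)
    for cps, nb in zip(plan.beams, n_beam):
        w = np.array([cp.mu_weight for cp in cps])
        if w.sum() == 0 or nb == 0:
            out.append((np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0)))
            continue
        n_cp = _proportional_counts(w, nb)
        pos_l, dir_l = [], []
        for cp, m in zip(cps, n_cp):
            if m == 0:
                continue
            p, d = _sample_cp_directions(cp, m, rng, iso)
            pos_l.append(p)
            dir_l.append(d)
        pos = np.concatenate(pos_l) if pos_l else np.zeros((0, 3))
        dirs = np.concatenate(dir_l) if dir_l else np.zeros((0, 3))
        energies = spectrum.sample(rng, len(pos))
        out.append((pos, dirs, np.asarray(energies)))
    return out


def _proportional_counts(weights: np.ndarray, total: int) -> np.ndarray:
    frac = weights / weights.sum() * total
    base = np.floor(frac).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(frac - base))
    base[order[:rem]] += 1
    return base


def _sample_cp_directions(cp: BeamControlPoint, n: int, rng: np.random.Generator, iso):
    """Vectorized version of plan.sample_beam_photon for one control point."""
    cells = cp.open_cells
    source, axis = gantry_transform(cp.gantry_angle, iso, cp.source_axis_distance)
    v_hat = np.array([0.0, 0.0, 1.0])
    u_hat = np.cross(v_hat, axis)
    u_hat /= np.linalg.norm(u_hat)
    pick = cells[rng.integers(len(cells), size=n)]
    nu, nv = cp.aperture.shape
    sp = cp.aperture_spacing
    u = (pick[:, 0] - (nu - 1) / 2 + rng.random(n) - 0.5) * sp
    v = (pick[:, 1] - (nv - 1) / 2 + rng.random(n) - 0.5) * sp
    targets = iso[None, :] + u[:, None] * u_hat[None, :] + v[:, None] * v_hat[None, :]
    dirs = targets - source[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.tile(source, (n, 1)), dirs


@dataclass
class BeamResult:
    """Transport + optics output for one beam/arc."""

    transport: TransportResult
    optics: TraceResult | None
    n_source_photons: int
    mu_total: float


@dataclass
class SimulationResult:
    """Full treatment-simulation output."""

    grid: VoxelGrid
    mesh: SurfaceMesh
    plan: TreatmentPlan
    beams: list[BeamResult] = field(default_factory=list)
    seed: int = 0
    emission_fraction: float = 1.0

    @property
    def exits(self) -> ExitRecords:
        """Concatenated surface-exit records over all beams."""
        banks = [b.optics.exits for b in self.beams if b.optics is not None]
        return ExitRecords(
            element_id=np.concatenate([e.element_id for e in banks]),
            exit_position=np.concatenate([e.exit_position for e in banks]),
            exit_direction=np.concatenate([e.exit_direction for e in banks]),
            wavelength=np.concatenate([e.wavelength for e in banks]),
            birth_position=np.concatenate([e.birth_position for e in banks]),
            born_in_tumor=np.concatenate([e.born_in_tumor for e in banks]),
        )

    @property
    def total_dose_energy_mev(self) -> float:
        return sum(b.transport.deposited_energy_mev for b in self.beams)


def run_treatment_simulation(
    grid: VoxelGrid,
    plan: TreatmentPlan,
    n_photons: int,
    seed: int = 1,
    spectrum: Mv6Spectrum | None = None,
    rad: RadiologicalTables | None = None,
    opt: OpticalTables | None = None,
    emission_fraction: float = 1.0,
    trace_optics: bool = True,
    fresnel: bool = True,
    bank_capacity: int = 2_000_000,
    mesh: SurfaceMesh | None = None,
) -> SimulationResult:
    """Simulate one treatment session of ``plan`` on ``grid``.

    ``n_photons`` source photons are split across beams proportionally to
    their MU totals; per-beam dose/emission grids and (optionally) traced
    Cherenkov photon banks with surface-exit records are returned.
    ``emission_fraction`` thins the analog optical bank for tractability
    without affecting dose or the emission grid.
    """
    spec = spectrum or Mv6Spectrum()
    rad = rad or default_radiological_tables()
    opt = opt or default_optical_tables()
    mesh = mesh or extract_surface_mesh(grid)
    rng = np.random.default_rng(seed)
    beam_states = sample_plan_photons(plan, n_photons, spec, rng)

    result = SimulationResult(grid=grid, mesh=mesh, plan=plan, seed=seed,
                              emission_fraction=emission_fraction)
    for b_idx, (states, cps) in enumerate(zip(beam_states, plan.beams)):
        n_b = len(states[2])
        tr = transport_xray(
            states, grid, rad, opt,
            rng_seed=seed + 1000 * (b_idx + 1),
            emission_fraction=emission_fraction,
            bank_capacity=bank_capacity,
        )
        opt_res = None
        if trace_optics and tr.n_banked > 0:
            bank = tr.photon_bank
            opt_res = trace_photon_bank(
                bank["position"], bank["direction"], bank["wavelength"],
                grid, opt, mesh,
                rng_seed=seed + 1000 * (b_idx + 1) + 7,
                fresnel=fresnel,
                born_in_tumor=bank["birth_tissue"] == int(Tissue.TUMOR),
            )
        result.beams.append(
            BeamResult(
                transport=tr,
                optics=opt_res,
                n_source_photons=n_b,
                mu_total=float(sum(cp.mu_weight for cp in cps)),
            )
        )
    return result
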