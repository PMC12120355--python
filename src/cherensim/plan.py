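"""Treatment plans: IMRT beams / VMAT arcs as control-point sequences.

A control point is a snapshot of gantry angle, monitor-unit (MU) weight and
beam aperture.  The linear-accelerator head is reduced to a point source at
the source-axis distance with a parametric 6 MV bremsstrahlung-like energy
spectrum; the multileaf collimator is reduced to a binary aperture mask on a
regular grid in the isocenter plane.  Shipped defaults reproduce the
two-beam IMRT and two-arc VMAT laryngeal deliveries (gantry angles, control
point counts and MU totals) of the study this package models.

Gantry convention: the gantry angle is the angle between the beam direction
and the direction of gravity.  With patient axes x = left, y = anterior,
z = superior (supine patient), gravity is -y; at 0 deg the source sits
anterior and the beam points along -y, and angles increase toward the
patient's left, so at 90 deg the beam points along -x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_SAD_MM = 1000.0
DEFAULT_APERTURE_SPACING_MM = 2.5


@dataclass
class XRayPhoton:
    """A therapeutic X-ray photon (position mm, unit direction, energy MeV)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("direction must be unit length")
        if not 0 < self.energy <= 6.0:
            raise ValueError("energy must be in (0, 6] MeV")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class BeamControlPoint:
    """Gantry angle (deg), MU weight and binary aperture for one control point.

    The aperture mask lives on a regular ``aperture_spacing`` mm grid in the
    isocenter plane, centered on the isocenter; entry [i, j] covers the cell
    at in-plane coordinates (u_i, v_j) where u is the in-plane horizontal
    axis and v the patient superior axis.
    """

    gantry_angle: float
    mu_weight: float
    aperture: np.ndarray
    aperture_spacing: float = DEFAULT_APERTURE_SPACING_MM
    source_axis_distance: float = DEFAULT_SAD_MM

    def __post_init__(self) -> None:
        self.aperture = np.asarray(self.aperture, dtype=bool)
        if self.mu_weight < 0:
            raise ValueError("mu_weight must be nonnegative")
        if not 0 <= self.gantry_angle < 360:
            raise ValueError("gantry_angle must be in [0, 360)")
        if self.mu_weight > 0 and not self.aperture.any():
            raise ValueError("aperture must be nonempty when mu_weight > 0")

    @property
    def open_cells(self) -> np.ndarray:
        return np.argwhere(self.aperture)


@dataclass
class TreatmentPlan:
    """A delivery: list of beams (IMRT) or arcs (VMAT), each a CP sequence."""

    modality: str                                   # "IMRT" | "VMAT"
    beams: list[list[BeamControlPoint]]
    nominal_energy_mv: float = 6.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fractions: int = 20

    def __post_init__(self) -> None:
        if self.modality not in ("IMRT", "VMAT"):
            raise ValueError("modality must be IMRT or VMAT")
        for cps in self.beams:
            angles = [cp.gantry_angle for cp in cps]
            if self.modality == "IMRT" and len(set(angles)) > 1:
                raise ValueError("IMRT beams must have a single gantry angle")
            if self.modality == "VMAT" and len(angles) > 1:
                d = np.diff(angles)
                if not (np.all(d >= 0) or np.all(d <= 0)):
                    raise ValueError("VMAT arc gantry angles must be monotone")

    def beam_mu_totals(self) -> list[float]:
        return [float(sum(cp.mu_weight for cp in cps)) for cps in self.beams]

    @property
    def total_mu(self) -> float:
        return float(sum(self.beam_mu_totals()))


def square_aperture(side_mm: float, spacing: float = DEFAULT_APERTURE_SPACING_MM) -> np.ndarray:
    """Fully open square field of the given side length at the isocenter plane."""
    n = int(round(side_mm / spacing))
    return np.ones((n, n), dtype=bool)


def elliptical_aperture(
    semi_u_mm: float,
    semi_v_mm: float,
    frame_mm: float = 100.0,
    spacing: float = DEFAULT_APERTURE_SPACING_MM,
) -> np.ndarray:
    """Elliptical opening inside a square frame (a simple conformal field)."""
    n = int(round(frame_mm / spacing))
    u = (np.arange(n) - (n - 1) / 2) * spacing
    U, V = np.meshgrid(u, u, indexing="ij")
    return (U / semi_u_mm) ** 2 + (V / semi_v_mm) ** 2 <= 1.0


def _spread_mu(total: float, n_cp: int, weights=None) -> list[float]:
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_cp:
            raise ValueError("weight vector length != control point count")
        if not np.isclose(w.sum(), total, rtol=1e-9):
            raise ValueError("per-point MU weights do not sum to the beam MU total")
        return [float(x) for x in w]
    return [total / n_cp] * n_cp


def build_plan(config: dict) -> TreatmentPlan:
    """Build a :class:`TreatmentPlan` from a plan descriptor dictionary.

    ``config`` keys: ``modality``, ``isocenter`` (optional), ``fractions``
    (optional), ``beams``: list of per-beam blocks with keys ``gantry``
    (degrees; scalar for IMRT) or ``gantry_start``/``gantry_stop`` (VMAT),
    ``control_points``, ``mu_total``, optional ``mu_weights``, and optional
    ``aperture`` (2D 0/1 array or nested list; default 60 mm square field).
    """
    modality = config["modality"].upper()
    iso = tuple(config.get("isocenter", (0.0, 0.0, 0.0)))
    beams: list[list[BeamControlPoint]] = []
    for bc in config["beams"]:
        n_cp = int(bc["control_points"])
        mus = _spread_mu(float(bc["mu_total"]), n_cp, bc.get("mu_weights"))
        ap = bc.get("aperture")
        spacing = float(bc.get("aperture_spacing", DEFAULT_APERTURE_SPACING_MM))
        aperture = np.asarray(ap, dtype=bool) if ap is not None else square_aperture(60.0, spacing)
        sad = float(bc.get("source_axis_distance", DEFAULT_SAD_MM))
        if modality == "VMAT":
            angles = np.linspace(float(bc["gantry_start"]), float(bc["gantry_stop"]), n_cp)
        else:
            angles = np.full(n_cp, float(bc["gantry"]))
        beams.append(
            [
                BeamControlPoint(
                    gantry_angle=float(a) % 360.0,
                    mu_weight=mu,
                    aperture=aperture,
                    aperture_spacing=spacing,
                    source_axis_distance=sad,
                )
                for a, mu in zip(angles, mus)
            ]
        )
    return TreatmentPlan(
        modality=modality,
        beams=beams,
        nominal_energy_mv=float(config.get("nominal_energy_mv", 6.0)),
        isocenter=iso,
        fractions=int(config.get("fractions", 20)),
    )


def default_imrt_plan(aperture: np.ndarray | None = None, isocenter=(0.0, 0.0, 0.0)) -> TreatmentPlan:
    """Two fixed beams: left-lateral 90 deg / 157.5 MU / 8 CPs and
    right-anterior-oblique 278 deg / 155.1 MU / 10 CPs."""
    ap = aperture if aperture is not None else elliptical_aperture(30.0, 25.0, frame_mm=80.0)
    return build_plan(
        {
            "modality": "IMRT",
            "isocenter": list(isocenter),
            "beams": [
                {"gantry": 90.0, "control_points": 8, "mu_total": 157.5, "aperture": ap},
                {"gantry": 278.0, "control_points": 10, "mu_total": 155.1, "aperture": ap},
            ],
        }
    )


def default_vmat_plan(aperture: np.ndarray | None = None, isocenter=(0.0, 0.0, 0.0)) -> TreatmentPlan:
    """Two arcs: 100->260 deg CCW / 360.7 MU and 260->100 deg CW / 306.6 MU,
    114 control points each."""
    ap = aperture if aperture is not None else elliptical_aperture(30.0, 25.0, frame_mm=80.0)
    return build_plan(
        {
            "modality": "VMAT",
            "isocenter": list(isocenter),
            "beams": [
                {"gantry_start": 100.0, "gantry_stop": 260.0, "control_points": 114,
                 "mu_total": 360.7, "aperture": ap},
                {"gantry_start": 260.0, "gantry_stop": 100.0, "control_points": 114,
                 "mu_total": 306.6, "aperture": ap},
            ],
        }
    )


def gantry_transform(
    gantry_angle: float,
    isocenter,
    source_axis_distance: float = DEFAULT_SAD_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Source position and unit beam axis for a gantry angle.

    At 0 deg the source is anterior (+y from the isocenter) and the beam
    points along gravity (-y); angles increase toward the patient's left
    (beam along -x at 90 deg).  Returns ``(source_position, beam_axis)``.
    """
    if source_axis_distance <= 0:
        raise ValueError("source_axis_distance must be positive")
    gam = np.deg2rad(gantry_angle)
    axis = np.array([-np.sin(gam), -np.cos(gam), 0.0])
    source = np.asarray(isocenter, dtype=float) - source_axis_distance * axis
    return source, axis


class Mv6Spectrum:
    """Parametric 6 MV photon energy spectrum.

    The default is a histogram table computed from a bremsstrahlung-like
    gamma shape p(E) ~ E exp(-E / 0.9 MeV) truncated to (0.25, 6] MeV, binned
    at 0.25 MeV.  Its mean is ~1.8 MeV, a documented property of the chosen
    form.  A custom (edges, weights) histogram or a degenerate monoenergetic
    spectrum can be supplied instead.
    """

    def __init__(self, edges_mev: np.ndarray | None = None, weights: np.ndarray | None = None):
        if edges_mev is None:
            edges_mev = np.arange(0.25, 6.01, 0.25)
            centers = 0.5 * (edges_mev[:-1] + edges_mev[1:])
            weights = centers * np.exp(-centers / 0.9)
        self.edges = np.asarray(edges_mev, dtype=float)
        w = np.asarray(weights, dtype=float)
        if len(w) != len(self.edges) - 1:
            raise ValueError("need one weight per bin")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        self.pdf = w / w.sum()
        self.cdf = np.cumsum(self.pdf)

    @classmethod
    def monoenergetic(cls, energy_mev: float) -> "Mv6Spectrum":
        eps = 1e-9
        return cls(np.array([energy_mev - eps, energy_mev + eps]), np.array([1.0]))

    @property
    def mean_energy(self) -> float:
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(np.sum(centers * self.pdf))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        n = size if size is not None else 1
        b = np.searchsorted(self.cdf, rng.random(n))
        e = self.edges[b] + rng.random(n) * (self.edges[b + 1] - self.edges[b])
        e = np.minimum(e, 6.0)
        return e if size is not None else float(e[0])


def sample_beam_photon(
    cp: BeamControlPoint,
    spectrum: Mv6Spectrum,
    rng: np.random.Generator,
    isocenter=(0.0, 0.0, 0.0),
) -> XRayPhoton:
    """Draw one source photon aimed through the control point's aperture.

    The photon originates at the point source and passes through a uniformly
    sampled position inside a uniformly chosen open aperture cell in the
    isocenter plane.
    """
    cells = cp.open_cells
    if len(cells) == 0:
        raise ValueError("aperture is empty")
    source, axis = gantry_transform(cp.gantry_angle, isocenter, cp.source_axis_distance)
    # in-plane basis: u horizontal (in the gantry rotation plane), v superior
    v_hat = np.array([0.0, 0.0, 1.0])
    u_hat = np.cross(v_hat, axis)
    u_hat /= np.linalg.norm(u_hat)
    nu, nv = cp.aperture.shape
    i, j = cells[rng.integers(len(cells))]
    sp = cp.aperture_spacing
    u = (i - (nu - 1) / 2 + rng.random() - 0.5) * sp
    v = (j - (nv - 1) / 2 + rng.random() - 0.5) * sp
    target = np.asarray(isocenter, dtype=float) + u * u_hat + v * v_hat
    d = target - source
    d /= np.linalg.norm(d)
    return XRayPhoton(position=source, direction=d, energy=float(spectrum.sample(rng)))


def plan_to_yaml(plan: TreatmentPlan, path) -> None:
    """Serialize a plan (with full aperture masks) to YAML."""
    doc = {
        "modality": plan.modality,
        "nominal_energy_mv": plan.nominal_energy_mv,
        "isocenter": [float(v) for v in plan.isocenter],
        "fractions": plan.fractions,
        "beams": [
            {
                "gantry_angles": [float(cp.gantry_angle) for cp in cps],
                "mu_weights": [float(cp.mu_weight) for cp in cps],
                "aperture_spacing": float(cps[0].aperture_spacing),
                "source_axis_distance": float(cps[0].source_axis_distance),
                "aperture": cps[0].aperture.astype(int).tolist(),
            }
            for cps in plan.beams
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def plan_from_yaml(path) -> TreatmentPlan:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    beams = []
    for bc in doc["beams"]:
        ap = np.asarray(bc["aperture"], dtype=bool)
        beams.append(
            [
                BeamControlPoint(
                    gantry_angle=a,
                    mu_weight=mu,
                    aperture=ap,
                    aperture_spacing=bc["aperture_spacing"],
                    source_axis_distance=bc["source_axis_distance"],
                )
                for a, mu in zip(bc["gantry_angles"], bc["mu_weights"])
            ]
        )
    return TreatmentPlan(
        modality=doc["modality"],
        beams=beams,
        nominal_energy_mv=doc["nominal_energy_mv"],
        isocenter=tuple(doc["isocenter"]),
        fractions=doc["fractions"],
    )
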