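"""Spectrally resolved optical properties and radiological data tables.

Optical tables cover 500-1200 nm on a 10 nm grid, one row set per tissue:
absorption coefficient mu_a (1/mm), scattering coefficient mu_s (1/mm),
anisotropy factor g, refractive index n.  The default tables are qualitative
parameterizations of the published tissue-optics literature families
(hemoglobin-like absorption falling steeply from 500 nm, the ~975 nm water
band with a rise toward 1200 nm, a 930 nm lipid bump in adipose, power-law
reduced scattering); they are approximations and fully overridable, both
programmatically and via CSV.

Radiological tables cover 0.01-6 MeV: total X-ray attenuation split into
Compton (Klein-Nishina cross-section times electron density) and
photoelectric (Z_eff power law anchored to water) components, plus electron
collision stopping power (water reference values scaled by density and Z/A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cherensim.phantom import DEFAULT_DENSITIES, Tissue

WAVELENGTH_MIN_NM = 500.0
WAVELENGTH_MAX_NM = 1200.0
DEFAULT_WAVELENGTHS = np.arange(500.0, 1201.0, 10.0)

ELECTRON_REST_MEV = 0.511
#: classical electron radius, cm
_R_E_CM = 2.8179403262e-13
_N_AVOGADRO = 6.02214076e23

ENERGY_GRID_MEV = np.geomspace(0.01, 6.0, 96)

#: per-tissue composition: (Z_eff, Z/A ratio) — generic soft-tissue values
_COMPOSITION: dict[Tissue, tuple[float, float]] = {
    Tissue.AIR: (7.64, 0.499),
    Tissue.SKIN: (7.39, 0.549),
    Tissue.ADIPOSE: (6.33, 0.556),
    Tissue.MUSCLE: (7.42, 0.550),
    Tissue.BONE: (13.8, 0.521),
    Tissue.TUMOR: (7.42, 0.550),
    Tissue.WATER: (7.42, 0.5551),
}

# water collision stopping power, MeV cm^2/g, vs kinetic energy (ESTAR-style)
_WATER_STOPPING_E = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0])
_WATER_STOPPING_S = np.array([22.56, 11.84, 6.603, 4.115, 2.793, 2.034, 1.849, 1.795, 1.807, 1.825])


# ---------------------------------------------------------------------------
# optical tables


def _water_absorption(lam: np.ndarray) -> np.ndarray:
    """Water absorption shape over 500-1200 nm, 1/mm (975 nm band + IR tail)."""
    lam = np.asarray(lam, dtype=float)
    band = 0.05 * np.exp(-(((lam - 975.0) / 45.0) ** 2))
    tail = 0.11 * np.exp(-(((lam - 1450.0) / 160.0) ** 2))
    return band + tail + 3e-4


def _blood_absorption(lam: np.ndarray) -> np.ndarray:
    """Hemoglobin-like shape: steep fall from 500 nm plus a small 760 nm bump."""
    lam = np.asarray(lam, dtype=float)
    fall = np.exp(-(lam - 500.0) / 55.0)
    bump = 0.02 * np.exp(-(((lam - 760.0) / 30.0) ** 2))
    return fall + bump


def _mus_power_law(lam: np.ndarray, mus500: float, b: float) -> np.ndarray:
    return mus500 * (np.asarray(lam, dtype=float) / 500.0) ** (-b)


@dataclass
class OpticalTables:
    """Tabulated (mu_a, mu_s, g, n) per tissue on a shared wavelength grid."""

    wavelengths_nm: np.ndarray
    mu_a: dict[Tissue, np.ndarray]
    mu_s: dict[Tissue, np.ndarray]
    g: dict[Tissue, np.ndarray]
    n: dict[Tissue, np.ndarray]

    def __post_init__(self) -> None:
        for tab in (self.mu_a, self.mu_s):
            for arr in tab.values():
                if np.any(np.asarray(arr) < 0):
                    raise ValueError("mu_a and mu_s must be nonnegative")
        for arr in self.n.values():
            if np.any(np.asarray(arr) < 1):
                raise ValueError("refractive index must be >= 1")
        for arr in self.g.values():
            if np.any(np.abs(np.asarray(arr)) >= 1):
                raise ValueError("anisotropy factor must be in (-1, 1)")

    @property
    def tissues(self) -> list[Tissue]:
        return sorted(self.mu_a, key=int)

    def lookup(self, label: Tissue, lam_nm: float) -> tuple[float, float, float, float]:
        """Linear interpolation of (mu_a, mu_s, g, n) at wavelength ``lam_nm``."""
        if label not in self.mu_a:
            raise KeyError(f"unknown tissue label {label!r}")
        lam = float(lam_nm)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not lo <= lam <= hi:
            raise ValueError(f"wavelength {lam} nm outside [{lo}, {hi}] nm")
        w = self.wavelengths_nm
        return (
            float(np.interp(lam, w, self.mu_a[label])),
            float(np.interp(lam, w, self.mu_s[label])),
            float(np.interp(lam, w, self.g[label])),
            float(np.interp(lam, w, self.n[label])),
        )

    def band_mean_n(self, label: Tissue) -> float:
        """Band-averaged refractive index, used for Cherenkov kinematics."""
        return float(np.mean(self.n[label]))

    def as_arrays(self, n_tissues: int | None = None):
        """Dense (T, L) float64 arrays (mu_a, mu_s, g, n) indexed by label value."""
        T = n_tissues or (max(int(t) for t in self.mu_a) + 1)
        L = len(self.wavelengths_nm)
        out = [np.zeros((T, L)) for _ in range(4)]
        out[3][:] = 1.0
        for t in self.mu_a:
            out[0][int(t)] = self.mu_a[t]
            out[1][int(t)] = self.mu_s[t]
            out[2][int(t)] = self.g[t]
            out[3][int(t)] = self.n[t]
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tissues:
            for i, lam in enumerate(self.wavelengths_nm):
                rows.append(
                    (t.name.lower(), lam, self.mu_a[t][i], self.mu_s[t][i], self.g[t][i], self.n[t][i])
                )
        return pd.DataFrame(rows, columns=["tissue", "lambda_nm", "mu_a_per_mm", "mu_s_per_mm", "g", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OpticalTables":
        df = pd.read_csv(path)
        lam = np.sort(df["lambda_nm"].unique().astype(float))
        mu_a, mu_s, g, n = {}, {}, {}, {}
        for name, sub in df.groupby("tissue"):
            t = Tissue[name.upper()]
            sub = sub.sort_values("lambda_nm")
            mu_a[t] = sub["mu_a_per_mm"].to_numpy(float)
            mu_s[t] = sub["mu_s_per_mm"].to_numpy(float)
            g[t] = sub["g"].to_numpy(float)
            n[t] = sub["n"].to_numpy(float)
        return cls(wavelengths_nm=lam, mu_a=mu_a, mu_s=mu_s, g=g, n=n)


def default_optical_tables(wavelengths_nm: np.ndarray | None = None) -> OpticalTables:
    """Build the shipped default optical tables (qualitative approximations)."""
    lam = np.asarray(wavelengths_nm if wavelengths_nm is not None else DEFAULT_WAVELENGTHS, float)
    blood = _blood_absorption(lam)
    water = _water_absorption(lam)
    lipid = np.exp(-(((lam - 930.0) / 30.0) ** 2))

    # slight dispersion; tumor and adipose share the SAME anisotropy curve
    g_common = 0.90 + 0.02 * (lam - 500.0) / 700.0

    def disp(n0: float) -> np.ndarray:
        return n0 - 0.01 * (lam - 500.0) / 700.0

    mu_a = {
        Tissue.AIR: np.zeros_like(lam),
        Tissue.SKIN: 0.15 * np.exp(-(lam - 500.0) / 120.0) + 0.30 * water + 0.010,
        Tissue.ADIPOSE: 0.02 * np.exp(-(lam - 500.0) / 100.0) + 0.008 * lipid + 0.25 * water + 0.003,
        Tissue.MUSCLE: 0.12 * blood + 0.70 * water + 0.005,
        Tissue.BONE: 0.03 * np.exp(-(lam - 500.0) / 150.0) + 0.40 * water + 0.005,
        Tissue.TUMOR: 0.15 * blood + 0.80 * water + 0.004,
        Tissue.WATER: water.copy(),
    }
    mu_s = {
        Tissue.AIR: np.zeros_like(lam),
        Tissue.SKIN: _mus_power_law(lam, 25.0, 1.1),
        Tissue.ADIPOSE: _mus_power_law(lam, 12.0, 0.7),
        Tissue.MUSCLE: _mus_power_law(lam, 9.0, 0.9),
        Tissue.BONE: _mus_power_law(lam, 35.0, 0.6),
        Tissue.TUMOR: _mus_power_law(lam, 15.0, 1.0),
        Tissue.WATER: np.full_like(lam, 1e-3),
    }
    g = {
        Tissue.AIR: np.zeros_like(lam),
        Tissue.SKIN: 0.85 + 0.02 * (lam - 500.0) / 700.0,
        Tissue.ADIPOSE: g_common.copy(),
        Tissue.MUSCLE: 0.87 + 0.02 * (lam - 500.0) / 700.0,
        Tissue.BONE: np.full_like(lam, 0.92),
        Tissue.TUMOR: g_common.copy(),
        Tissue.WATER: np.zeros_like(lam),
    }
    n = {
        Tissue.AIR: np.ones_like(lam),
        Tissue.SKIN: disp(1.40),
        Tissue.ADIPOSE: disp(1.44),
        Tissue.MUSCLE: disp(1.37),
        Tissue.BONE: disp(1.55),
        Tissue.TUMOR: disp(1.39),
        Tissue.WATER: disp(1.33),
    }
    return OpticalTables(wavelengths_nm=lam, mu_a=mu_a, mu_s=mu_s, g=g, n=n)


def tissue_properties(label: Tissue, lam_nm: float, tables: OpticalTables | None = None):
    """(mu_a, mu_s, g, n) for ``label`` at ``lam_nm``; module-level convenience."""
    tab = tables if tables is not None else _default_optical_cache()
    return tab.lookup(label, lam_nm)


_OPTICAL_CACHE: OpticalTables | None = None


def _default_optical_cache() -> OpticalTables:
    global _OPTICAL_CACHE
    if _OPTICAL_CACHE is None:
        _OPTICAL_CACHE = default_optical_tables()
    return _OPTICAL_CACHE


# ---------------------------------------------------------------------------
# radiological tables


def klein_nishina_total_cross_section(energy_mev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross-section per electron, cm^2."""
    k = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    term1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    term2 = np.log(1 + 2 * k) / (2 * k)
    term3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * _R_E_CM**2 * (term1 + term2 + term3)


# photoelectric mass attenuation anchored so water at 10 keV ~ 4.9 cm^2/g
_PE_NORM = 4.9 / (7.42**4.5 / 0.01**3)


def _photoelectric_mass_atten(z_eff: float, energy_mev: np.ndarray) -> np.ndarray:
    return _PE_NORM * z_eff**4.5 / np.asarray(energy_mev, dtype=float) ** 3


@dataclass
class RadiologicalTables:
    """Per-tissue X-ray attenuation and electron stopping power tables.

    Attenuation coefficients are stored at each tissue's nominal density and
    rescaled by the local voxel density at transport time.  ``z_charge`` is
    the charge number of the Cherenkov-emitting particle (electrons: 1).
    """

    energies_mev: np.ndarray
    mu_compton: dict[Tissue, np.ndarray]      # 1/mm at nominal density
    mu_photoelectric: dict[Tissue, np.ndarray]  # 1/mm at nominal density
    stopping_power: dict[Tissue, np.ndarray]  # MeV/mm at nominal density
    nominal_density: dict[Tissue, float]      # g/cm^3
    z_charge: float = 1.0

    def mu_total(self, label: Tissue) -> np.ndarray:
        return self.mu_compton[label] + self.mu_photoelectric[label]

    def as_arrays(self, n_tissues: int | None = None):
        """(T, E) arrays (mu_compton, mu_photo, stopping, nominal_density)."""
        T = n_tissues or (max(int(t) for t in self.mu_compton) + 1)
        E = len(self.energies_mev)
        mc = np.zeros((T, E))
        mp = np.zeros((T, E))
        sp = np.zeros((T, E))
        rho = np.ones(T)
        for t in self.mu_compton:
            mc[int(t)] = self.mu_compton[t]
            mp[int(t)] = self.mu_photoelectric[t]
            sp[int(t)] = self.stopping_power[t]
            rho[int(t)] = self.nominal_density[t]
        return mc, mp, sp, rho

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.mu_compton, key=int):
            for i, e in enumerate(self.energies_mev):
                rows.append(
                    (t.name.lower(), e, self.mu_compton[t][i], self.mu_photoelectric[t][i],
                     self.stopping_power[t][i])
                )
        return pd.DataFrame(
            rows,
            columns=["tissue", "energy_mev", "mu_compton_per_mm", "mu_photoelectric_per_mm",
                     "stopping_mev_per_mm"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_radiological_tables(
    energies_mev: np.ndarray | None = None,
    z_charge: float = 1.0,
) -> RadiologicalTables:
    """Build default attenuation/stopping tables from closed-form physics."""
    E = np.asarray(energies_mev if energies_mev is not None else ENERGY_GRID_MEV, float)
    sigma_kn = klein_nishina_total_cross_section(E)
    mu_c, mu_pe, stop, rho0 = {}, {}, {}, {}
    water_stop_mass = np.interp(np.log(E), np.log(_WATER_STOPPING_E), _WATER_STOPPING_S)
    for t, (z_eff, z_a) in _COMPOSITION.items():
        rho = DEFAULT_DENSITIES[t]
        n_e_per_cm3 = rho * _N_AVOGADRO * z_a
        mu_c[t] = n_e_per_cm3 * sigma_kn / 10.0            # 1/mm
        mu_pe[t] = _photoelectric_mass_atten(z_eff, E) * rho / 10.0
        stop[t] = water_stop_mass * (z_a / 0.5551) * rho / 10.0  # MeV/mm
        rho0[t] = rho
    return RadiologicalTables(
        energies_mev=E,
        mu_compton=mu_c,
        mu_photoelectric=mu_pe,
        stopping_power=stop,
        nominal_density=rho0,
        z_charge=z_charge,
    )
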