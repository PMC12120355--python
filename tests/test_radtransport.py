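"""Cherenkov kinematics, Compton physics, dose scoring and X-ray/electron transport."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from cherensim.phantom import Tissue
from cherensim.plan import XRayPhoton
from cherensim.radtransport import (
    NO_THRESHOLD,
    beta_from_energy,
    cherenkov_threshold_energy,
    compton_scatter,
    compton_scattered_energy,
    expected_cherenkov_yield,
    frank_tamm_yield,
    klein_nishina_pdf,
    sample_cherenkov_photon,
    sample_cherenkov_wavelength,
    score_dose,
    transport_electron,
    transport_xray,
)

from conftest import homogeneous_grid, pure_photoelectric_tables


def _threshold_by_scanning(n, de=1e-6):
    """Independent oracle: scan kinetic energy until beta*n crosses 1."""
    e = 0.0
    while beta_from_energy(e) * n <= 1.0:
        e += de
        if e > 10:
            return np.inf
    return e


class TestCherenkovThreshold:
    def test_soft_tissue_threshold_rounds_to_point_two(self):
        e_thr = cherenkov_threshold_energy(1.4)
        assert np.isclose(e_thr, 0.219, atol=5e-4)
        assert round(e_thr, 1) == 0.2

    def test_water_threshold(self):
        assert np.isclose(cherenkov_threshold_energy(1.33), 0.264, atol=5e-4)

    @pytest.mark.parametrize("n", [1.33, 1.4, 1.55])
    def test_matches_energy_scan(self, n):
        assert np.isclose(cherenkov_threshold_energy(n), _threshold_by_scanning(n), atol=2e-6)

    def test_large_index_limit(self):
        assert cherenkov_threshold_energy(1e6) < 1e-6

    def test_no_threshold_below_unity_index(self):
        assert cherenkov_threshold_energy(1.0) == NO_THRESHOLD
        assert cherenkov_threshold_energy(0.9) == NO_THRESHOLD

    def test_nonpositive_index_rejected(self):
        with pytest.raises(ValueError):
            cherenkov_threshold_energy(0.0)


class TestFrankTamm:
    def test_reference_band_yield(self):
        # beta -> 1, n = 1.33, 400-700 nm: ~21.4 photons/mm
        y = frank_tamm_yield(1 - 1e-12, 1.33, 1, 400, 700)
        assert np.isclose(y, 21.4, rtol=5e-3)

    def test_matches_quadrature_over_beta_n_grid(self):
        """Closed form equals adaptive quadrature of the spectral density."""
        lam1, lam2 = 500.0, 1200.0
        for n in (1.3, 1.4, 1.5):
            for beta in np.linspace(1 / n + 0.01, 0.999, 7):
                const = 2 * np.pi / 137.036 * (1 - 1 / (beta**2 * n**2))
                num, _ = quad(lambda lam: const / lam**2 * 1e6, lam1, lam2,
                              epsrel=1e-12)
                closed = frank_tamm_yield(beta, n, 1, lam1, lam2)
                assert np.isclose(closed, num, rtol=1e-10)

    def test_zero_at_emission_condition(self):
        beta = 1 / 1.4
        assert frank_tamm_yield(beta, 1.4, 1, 500, 1200) == 0.0

    def test_charge_squared_scaling(self):
        y1 = frank_tamm_yield(0.99, 1.4, 1, 500, 1200)
        y2 = frank_tamm_yield(0.99, 1.4, 2, 500, 1200)
        assert np.isclose(y2, 4 * y1)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            frank_tamm_yield(0.99, 1.4, 1, 700, 700)


class TestCherenkovSampling:
    def test_inverse_cdf_endpoints_and_midpoint(self):
        assert sample_cherenkov_wavelength(0.0, 500, 1200) == 500
        assert np.isclose(sample_cherenkov_wavelength(1.0, 500, 1200), 1200)
        assert np.isclose(sample_cherenkov_wavelength(0.5, 500, 1200), 705.88, atol=0.01)

    def test_cone_angle(self):
        rng = np.random.default_rng(0)
        axis = np.array([0.0, 0.0, 1.0])
        for _ in range(100):
            d, lam = sample_cherenkov_photon(1 - 1e-12, 1.4, 500, 1200, axis, rng)
            assert np.isclose(np.dot(d, axis), 1 / 1.4, atol=1e-9)
            assert 500 <= lam <= 1200

    def test_subthreshold_rejected(self):
        with pytest.raises(ValueError):
            sample_cherenkov_photon(0.5, 1.4, 500, 1200, [0, 0, 1], np.random.default_rng(0))

    def test_wavelength_density_follows_inverse_square(self):
        """KS test of inverse-CDF samples against the 1/lambda^2 law."""
        from scipy.stats import kstest

        rng = np.random.default_rng(42)
        lam = sample_cherenkov_wavelength(rng.random(200_000), 500.0, 1200.0)

        def cdf(x):
            return (1 / 500 - 1 / np.asarray(x)) / (1 / 500 - 1 / 1200)

        assert kstest(lam, cdf).pvalue > 0.01


class TestCompton:
    def test_forward_scatter_preserves_energy(self):
        assert compton_scattered_energy(1.0, 0.0) == 1.0

    def test_backscatter_at_rest_energy(self):
        assert np.isclose(compton_scattered_energy(0.511, np.pi), 0.17033, atol=1e-5)

    def test_energy_shared_between_photon_and_electron(self):
        rng = np.random.default_rng(3)
        ph = XRayPhoton(np.zeros(3), np.array([0, 0, 1.0]), 2.0)
        for _ in range(50):
            sc, el = compton_scatter(ph, rng)
            assert np.isclose(sc.energy + el.kinetic_energy, 2.0)
            assert np.isclose(np.linalg.norm(sc.direction), 1.0)
            assert np.isclose(np.linalg.norm(el.direction), 1.0)

    def test_angle_distribution_matches_klein_nishina_quadrature(self):
        """Sampled scattering cosines vs numerically integrated Klein-Nishina."""
        rng = np.random.default_rng(11)
        ph = XRayPhoton(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        n = 100_000
        cos = np.empty(n)
        for i in range(n):
            sc, _ = compton_scatter(ph, rng)
            cos[i] = sc.direction[2]
        edges = np.linspace(-1, 1, 21)
        obs, _ = np.histogram(cos, bins=edges)
        expected = np.array(
            [quad(lambda c: klein_nishina_pdf(1.0, c), a, b)[0]
             for a, b in zip(edges[:-1], edges[1:])]
        )
        expected = expected / expected.sum() * n
        assert chisquare(obs, expected).pvalue > 0.01


class TestDoseScoring:
    def test_one_mev_in_default_voxel(self):
        grid = homogeneous_grid(Tissue.MUSCLE, (3, 3, 3), spacing=(1.0, 1.0, 1.3),
                                density=1.0)
        dep = np.zeros(grid.dims)
        dep[1, 1, 1] = 1.0
        dg = score_dose(dep, grid)
        assert np.isclose(dg.dose_gy[1, 1, 1], 1.232e-7, rtol=1e-3)

    def test_no_deposits_all_zero(self):
        grid = homogeneous_grid(Tissue.WATER, (3, 3, 3))
        assert np.all(score_dose(np.zeros(grid.dims), grid).dose_gy == 0)

    def test_density_doubling_halves_dose(self):
        dep = np.zeros((3, 3, 3))
        dep[1, 1, 1] = 1.0
        g1 = homogeneous_grid(Tissue.MUSCLE, (3, 3, 3), density=1.0)
        g2 = homogeneous_grid(Tissue.MUSCLE, (3, 3, 3), density=2.0)
        assert np.isclose(score_dose(dep, g1).dose_gy[1, 1, 1],
                          2 * score_dose(dep, g2).dose_gy[1, 1, 1])

    def test_energy_in_zero_density_voxel_rejected(self):
        grid = homogeneous_grid(Tissue.AIR, (3, 3, 3), density=0.0)
        dep = np.zeros(grid.dims)
        dep[1, 1, 1] = 0.5
        with pytest.raises(ValueError):
            score_dose(dep, grid)


class TestXRayTransport:
    def test_pure_photoelectric_slab_transmission(self, optical_tables):
        """Transmitted fraction through a non-scattering slab is exp(-mu L)."""
        mu, thickness = 0.1, 20.0  # exp(-2) ~ 0.135
        grid = homogeneous_grid(Tissue.WATER, (25, 25, int(thickness)), spacing=1.0)
        rad = pure_photoelectric_tables(mu)
        n = 100_000
        z0 = grid.extent_mm()[2, 0]
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, z0 - 5.0)])
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        energies = np.full(n, 2.0)
        res = transport_xray((pos, dirs, energies), grid, rad, optical_tables,
                             rng_seed=17)
        transmitted = np.mean(res.history_escapes_mev == energies)
        expected = np.exp(-mu * thickness)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(transmitted - expected) < 4 * sigma

    def test_vacuum_grid_photon_escapes_with_full_energy(self, optical_tables):
        grid = homogeneous_grid(Tissue.AIR, (10, 10, 10), density=0.0)
        rad = pure_photoelectric_tables(0.05)
        pos = np.array([[0.0, 0.0, -20.0]])
        dirs = np.array([[0.0, 0.0, 1.0]])
        res = transport_xray((pos, dirs, np.array([3.0])), grid, rad, optical_tables,
                             rng_seed=1)
        assert res.history_escapes_mev[0] == 3.0
        assert res.deposited_energy_mev == 0.0

    def test_per_history_energy_conservation(self, radiological_tables, optical_tables):
        grid = homogeneous_grid(Tissue.MUSCLE, (41, 41, 41), spacing=2.0)
        rng = np.random.default_rng(5)
        n = 2000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = np.zeros((n, 3))
        energies = rng.uniform(0.3, 6.0, n)
        res = transport_xray((pos, dirs, energies), grid, radiological_tables,
                             optical_tables, rng_seed=23)
        np.testing.assert_allclose(
            res.history_deposits_mev + res.history_escapes_mev, energies, rtol=1e-12
        )
        assert np.isclose(res.deposited_energy_mev + res.escaped_energy_mev,
                          energies.sum(), rtol=1e-10)

    def test_fixed_seed_is_reproducible(self, radiological_tables, optical_tables):
        grid = homogeneous_grid(Tissue.MUSCLE, (21, 21, 21), spacing=2.0)
        pos = np.zeros((100, 3))
        dirs = np.tile([0.0, 0.0, 1.0], (100, 1))
        e = np.full(100, 2.0)
        r1 = transport_xray((pos, dirs, e), grid, radiological_tables, optical_tables,
                            rng_seed=9)
        r2 = transport_xray((pos, dirs, e), grid, radiological_tables, optical_tables,
                            rng_seed=9)
        assert np.array_equal(r1.dose.energy_mev, r2.dose.energy_mev)
        assert np.array_equal(r1.photon_bank["wavelength"], r2.photon_bank["wavelength"])


class TestElectronTransport:
    def test_below_threshold_no_photons_full_deposit(self, optical_tables,
                                                     radiological_tables):
        grid = homogeneous_grid(Tissue.MUSCLE, (41, 41, 41))
        res = transport_electron(
            (np.zeros((50, 3)), np.tile([0, 0, 1.0], (50, 1)), np.full(50, 0.15)),
            grid, optical_tables, radiological_tables, rng_seed=2,
        )
        assert res.n_generated == 0
        np.testing.assert_allclose(res.history_deposits_mev, 0.15, rtol=1e-12)

    def test_mean_photon_count_matches_csda_step_sum(self, optical_tables,
                                                     radiological_tables):
        """MC Cherenkov yield of a 1 MeV electron vs the deterministic step-sum."""
        grid = homogeneous_grid(Tissue.MUSCLE, (81, 81, 81), density=1.05)
        n = 10_000
        res = transport_electron(
            (np.zeros((n, 3)), np.tile([0, 0, 1.0], (n, 1)), np.full(n, 1.0)),
            grid, optical_tables, radiological_tables, rng_seed=9,
        )
        expected = expected_cherenkov_yield(1.0, Tissue.MUSCLE, optical_tables,
                                            radiological_tables, density_g_cm3=1.05)
        mean = res.n_generated / n
        sigma = np.sqrt(expected / n)
        assert abs(mean - expected) < 3 * sigma

    def test_energy_conservation_exact(self, optical_tables, radiological_tables):
        grid = homogeneous_grid(Tissue.ADIPOSE, (21, 21, 21))
        rng = np.random.default_rng(8)
        n = 500
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        e = rng.uniform(0.05, 5.0, n)
        res = transport_electron((np.zeros((n, 3)), dirs, e), grid, optical_tables,
                                 radiological_tables, rng_seed=4)
        np.testing.assert_allclose(
            res.history_deposits_mev + res.history_escapes_mev, e, rtol=1e-12
        )

    def test_no_photon_born_below_local_emission_condition(self, optical_tables,
                                                           radiological_tables):
        """Every banked photon was born in a tissue whose band-mean index
        admits emission (beta n > 1 requires n > 1)."""
        grid = homogeneous_grid(Tissue.MUSCLE, (81, 81, 81))
        res = transport_electron(
            (np.zeros((2000, 3)), np.tile([0, 0, 1.0], (2000, 1)), np.full(2000, 2.0)),
            grid, optical_tables, radiological_tables, rng_seed=3,
        )
        tissues = res.photon_bank["birth_tissue"]
        assert len(tissues) > 0
        assert np.all(tissues != int(Tissue.AIR))
        for t in np.unique(tissues):
            assert optical_tables.band_mean_n(Tissue(t)) > 1.0

    def test_emission_grid_counts_match_bank_when_unthinned(self, optical_tables,
                                                            radiological_tables):
        grid = homogeneous_grid(Tissue.TUMOR, (81, 81, 81))
        res = transport_electron(
            (np.zeros((200, 3)), np.tile([0, 0, 1.0], (200, 1)), np.full(200, 1.5)),
            grid, optical_tables, radiological_tables, rng_seed=6,
        )
        assert res.emission.total == res.n_generated == res.n_banked
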