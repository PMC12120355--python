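"""MU calibration, surface maps, spectra, tumor spot, origin distributions."""

import numpy as np
import pytest

from cherensim.analysis import (
    CalibrationResult,
    SurfaceRegion,
    apply_fraction_cutoff,
    calibrate_mu,
    compute_spectrum,
    full_surface_region,
    identify_tumor_spot,
    make_reduced_area,
    origin_distribution,
    region_similarity,
    scale_to_physical,
    surface_intensity_map,
)
from cherensim.optics import ExitRecords
from cherensim.phantom import Tissue, extract_surface_mesh, generate_water_phantom
from cherensim.radtransport import DoseGrid, EmissionGrid, score_dose

from conftest import homogeneous_grid


def make_exits(element_ids, wavelengths=None, born_in_tumor=None, births=None):
    n = len(element_ids)
    return ExitRecords(
        element_id=np.asarray(element_ids, dtype=np.int64),
        exit_position=np.zeros((n, 3)),
        exit_direction=np.tile([0, 0, 1.0], (n, 1)),
        wavelength=np.asarray(wavelengths if wavelengths is not None
                              else np.full(n, 800.0), dtype=float),
        birth_position=np.asarray(births if births is not None else np.zeros((n, 3))),
        born_in_tumor=np.asarray(born_in_tumor if born_in_tumor is not None
                                 else np.zeros(n, dtype=bool)),
    )


@pytest.fixture(scope="module")
def single_voxel_mesh():
    grid = homogeneous_grid(Tissue.AIR, (3, 3, 3), spacing=(1.0, 1.0, 1.3))
    grid.tissue[1, 1, 1] = Tissue.MUSCLE
    grid.density[1, 1, 1] = 1.05
    return grid, extract_surface_mesh(grid)


@pytest.fixture(scope="module")
def slab_mesh():
    """7x1x7 muscle slab: the 49 top (y+) faces form a flat surface patch."""
    grid = homogeneous_grid(Tissue.AIR, (9, 3, 9), spacing=(1.0, 1.0, 1.0))
    grid.tissue[1:8, 1, 1:8] = Tissue.MUSCLE
    grid.density[1:8, 1, 1:8] = 1.05
    mesh = extract_surface_mesh(grid)
    top = np.flatnonzero((mesh.axis == 1) & (mesh.side == 1))
    # map (i, k) voxel coordinates to element ids
    idx = {(int(mesh.voxel_idx[e, 0]), int(mesh.voxel_idx[e, 2])): int(e) for e in top}
    return grid, mesh, idx


class TestCalibration:
    def test_particles_per_mu_arithmetic(self):
        cal = CalibrationResult.from_dose(2e-11)
        assert np.isclose(cal.particles_per_mu, 5e8, rtol=1e-12)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            CalibrationResult.from_dose(0.0)

    def test_linearity_in_deposits(self):
        water = generate_water_phantom((10, 10, 10), (5.0, 5.0, 5.0))
        dep = np.zeros(water.dims)
        dep[:, :, 2] = 0.5  # slab nearest 15 mm depth
        c1 = calibrate_mu(score_dose(dep, water))
        c2 = calibrate_mu(score_dose(2 * dep, water))
        assert np.isclose(c2.dose_per_particle_gy, 2 * c1.dose_per_particle_gy)
        assert np.isclose(c2.particles_per_mu, c1.particles_per_mu / 2)

    def test_self_consistency_one_mu_gives_one_cgy(self):
        cal = CalibrationResult.from_dose(3.7e-12)
        assert scale_to_physical(cal.dose_per_particle_gy, cal, 1.0) == pytest.approx(0.01)

    def test_scale_to_physical_product(self):
        cal = CalibrationResult.from_dose(2e-11)  # N = 5e8
        assert np.isclose(scale_to_physical(1e-11, cal, 157.5), 0.7875)

    def test_scale_zero_mu(self):
        cal = CalibrationResult.from_dose(1e-11)
        assert scale_to_physical(np.ones(5), cal, 0.0).sum() == 0.0

    def test_scale_linear_in_mu(self):
        cal = CalibrationResult.from_dose(1e-11)
        assert np.isclose(scale_to_physical(2.0, cal, 20.0),
                          2 * scale_to_physical(2.0, cal, 10.0))


class TestSurfaceMap:
    def test_count_over_area(self, single_voxel_mesh):
        grid, mesh = single_voxel_mesh
        e = int(np.flatnonzero(mesh.axis == 0)[0])  # an x face, area 1.3
        m = surface_intensity_map(make_exits([e, e, e]), mesh, threshold_fraction=0.0)
        assert np.isclose(m.values[e], 3 / 1.3, atol=1e-12)
        assert np.isclose(m.values[e], 2.308, atol=1e-3)

    def test_mass_balance_unfiltered(self, slab_mesh):
        _, mesh, idx = slab_mesh
        rng = np.random.default_rng(0)
        ids = rng.choice(list(idx.values()), size=500)
        m = surface_intensity_map(make_exits(ids), mesh, threshold_fraction=0.0)
        assert np.isclose(m.total_photons, 500.0, rtol=1e-12)

    def test_threshold_one_keeps_only_argmax(self, slab_mesh):
        _, mesh, idx = slab_mesh
        ids = [idx[(2, 2)]] * 5 + [idx[(4, 4)]] * 2
        m = surface_intensity_map(make_exits(ids), mesh, threshold_fraction=1.0)
        assert m.values[idx[(2, 2)]] > 0
        assert m.values[idx[(4, 4)]] == 0

    def test_default_band_thresholds(self, slab_mesh):
        _, mesh, idx = slab_mesh
        ids = list(idx.values())[:10]
        full = surface_intensity_map(make_exits(ids), mesh, band_nm=(500, 1200))
        narrow = surface_intensity_map(make_exits(ids, wavelengths=np.full(10, 715.0)),
                                       mesh, band_nm=(710, 720))
        assert full.threshold_fraction == 0.05
        assert narrow.threshold_fraction == 0.10

    def test_empty_band_gives_zero_map(self, slab_mesh):
        _, mesh, idx = slab_mesh
        m = surface_intensity_map(make_exits([idx[(1, 1)]], wavelengths=[800.0]),
                                  mesh, band_nm=(710, 720))
        assert np.all(m.values == 0)

    def test_median_filter_smooths_isolated_spike(self, slab_mesh):
        _, mesh, idx = slab_mesh
        m = surface_intensity_map(make_exits([idx[(4, 4)]] * 10), mesh,
                                  median_filter=True, threshold_fraction=0.0)
        assert m.median_filtered
        assert m.values[idx[(4, 4)]] == 0.0  # neighbors all zero -> median zero


class TestSpectrum:
    def test_single_wavelength_bank(self):
        s = compute_spectrum(np.full(100, 755.0), bin_width_nm=10.0)
        assert s.intensity.max() == 1.0
        assert (s.intensity > 0).sum() == 1

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrum(np.array([]))

    def test_peak_normalization(self):
        s = compute_spectrum(np.array([510.0, 510.0, 900.0]), bin_width_nm=10.0)
        assert s.intensity.max() == 1.0

    def test_emitted_spectrum_follows_inverse_square_law(self):
        """Sampled emission wavelengths give per-bin counts ~ integral of 1/lam^2."""
        from cherensim.radtransport import sample_cherenkov_wavelength

        rng = np.random.default_rng(33)
        lam = sample_cherenkov_wavelength(rng.random(1_000_000), 500.0, 1200.0)
        s = compute_spectrum(lam, bin_width_nm=50.0, normalization="sum")
        edges = s.bin_edges_nm
        expected = (1 / edges[:-1] - 1 / edges[1:]) / (1 / 500 - 1 / 1200)
        np.testing.assert_allclose(s.intensity, expected, rtol=0.02)


class TestTumorSpot:
    def test_all_exits_on_one_element(self, slab_mesh):
        _, mesh, idx = slab_mesh
        e = idx[(3, 3)]
        spot = identify_tumor_spot(make_exits([e] * 7, born_in_tumor=[True] * 7), mesh)
        assert list(spot.element_ids) == [e]

    def test_larger_cluster_wins(self, slab_mesh):
        _, mesh, idx = slab_mesh
        big = [idx[(1, 1)], idx[(1, 2)], idx[(2, 1)]]
        small = [idx[(6, 6)]]
        ids = big * 2 + small * 2
        spot = identify_tumor_spot(make_exits(ids, born_in_tumor=[True] * len(ids)), mesh)
        assert set(spot.element_ids) == set(big)

    def test_equal_clusters_tie_broken_by_min_element_id(self, slab_mesh):
        _, mesh, idx = slab_mesh
        a, b = idx[(1, 1)], idx[(6, 6)]
        ids = [a] * 3 + [b] * 3
        spot = identify_tumor_spot(make_exits(ids, born_in_tumor=[True] * 6), mesh)
        assert list(spot.element_ids) == [min(a, b)]

    def test_no_tumor_born_exits_rejected(self, slab_mesh):
        _, mesh, idx = slab_mesh
        with pytest.raises(ValueError, match="tumor"):
            identify_tumor_spot(make_exits([idx[(1, 1)]], born_in_tumor=[False]), mesh)


class TestOriginDistribution:
    def test_full_surface_total_equals_exit_count(self, slab_mesh):
        grid, mesh, idx = slab_mesh
        rng = np.random.default_rng(1)
        n = 300
        births = rng.uniform(-1, 1, size=(n, 3))
        ids = rng.choice(list(idx.values()), size=n)
        exits = make_exits(ids, births=births)
        dist = origin_distribution(exits, full_surface_region(mesh), grid)
        assert dist.total == n

    def test_single_element_region_counts_only_its_photons(self, slab_mesh):
        grid, mesh, idx = slab_mesh
        a, b = idx[(2, 2)], idx[(5, 5)]
        exits = make_exits([a, a, b],
                           births=[[1.0, 0, 0], [1.0, 0, 0], [-2.0, 0, 0]])
        region = SurfaceRegion(element_ids=np.array([a]), descriptor="one", mesh=mesh)
        dist = origin_distribution(exits, region, grid)
        assert dist.total == 2

    def test_nested_regions_monotone(self, slab_mesh):
        grid, mesh, idx = slab_mesh
        rng = np.random.default_rng(2)
        ids = rng.choice(list(idx.values()), size=200)
        exits = make_exits(ids, births=rng.uniform(-2, 2, size=(200, 3)))
        sub = SurfaceRegion(element_ids=np.array(list(idx.values())[:10]),
                            descriptor="sub", mesh=mesh)
        full = full_surface_region(mesh)
        da = origin_distribution(exits, sub, grid)
        db = origin_distribution(exits, full, grid)
        assert np.all(da.counts <= db.counts)


class TestReducedArea:
    def test_contains_narrow_spot(self, slab_mesh):
        _, mesh, idx = slab_mesh
        spot = SurfaceRegion(element_ids=np.array([idx[(3, 3)], idx[(4, 3)]]),
                             descriptor="tumor-spot", mesh=mesh)
        area = make_reduced_area(spot, mesh, 100.0)
        assert set(spot.element_ids) <= set(area.element_ids)

    def test_saturates_to_full_anterior_surface(self, slab_mesh):
        _, mesh, idx = slab_mesh
        spot = SurfaceRegion(element_ids=np.array([idx[(3, 3)]]),
                             descriptor="tumor-spot", mesh=mesh)
        wide = make_reduced_area(spot, mesh, 1000.0)
        wider = make_reduced_area(spot, mesh, 5000.0)
        assert set(wide.element_ids) == set(wider.element_ids)

    def test_narrower_width_gives_subset(self, slab_mesh):
        _, mesh, idx = slab_mesh
        spot = SurfaceRegion(element_ids=np.array([idx[(3, 3)]]),
                             descriptor="tumor-spot", mesh=mesh)
        a8 = make_reduced_area(spot, mesh, 4.0)
        a10 = make_reduced_area(spot, mesh, 6.0)
        assert set(a8.element_ids) <= set(a10.element_ids)

    def test_nonpositive_width_rejected(self, slab_mesh):
        _, mesh, idx = slab_mesh
        spot = SurfaceRegion(element_ids=np.array([idx[(3, 3)]]),
                             descriptor="tumor-spot", mesh=mesh)
        with pytest.raises(ValueError):
            make_reduced_area(spot, mesh, 0.0)


def _emission(counts):
    arr = np.asarray(counts, dtype=np.int64).reshape(-1, 1, 1)
    grid = homogeneous_grid(Tissue.MUSCLE, (len(counts), 1, 1))
    return EmissionGrid(counts=arr, grid=grid)


class TestRegionSimilarity:
    def test_identical_distributions(self):
        a = _emission([3, 1, 4])
        assert region_similarity(a, _emission([3, 1, 4])) == 1.0

    def test_disjoint_supports(self):
        assert region_similarity(_emission([1, 0, 0]), _emission([0, 0, 2])) == 0.0

    def test_half_overlap(self):
        a = _emission([5, 5, 0])
        b = _emission([5, 0, 5])
        assert region_similarity(a, b) == 0.5

    def test_symmetric(self):
        a = _emission([1, 2, 3])
        b = _emission([3, 2, 1])
        assert region_similarity(a, b) == region_similarity(b, a)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            region_similarity(_emission([0, 0, 0]), _emission([1, 0, 0]))


class TestFractionCutoff:
    def test_zero_fraction_identity(self):
        v = np.array([10.0, 5.0, 0.05])
        assert np.array_equal(apply_fraction_cutoff(v, 0.0), v)

    def test_one_percent_cutoff_drops_small_values(self):
        out = apply_fraction_cutoff(np.array([10.0, 5.0, 0.05]), 0.01)
        assert np.array_equal(out, [10.0, 5.0, 0.0])

    def test_fraction_one_keeps_only_max(self):
        out = apply_fraction_cutoff(np.array([2.0, 7.0, 7.0, 1.0]), 1.0)
        assert np.array_equal(out, [0.0, 7.0, 7.0, 0.0])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            apply_fraction_cutoff(np.array([1.0]), 1.5)
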