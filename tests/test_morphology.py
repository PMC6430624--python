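"""Morphology descriptors against counting, geometry and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from nestpore.image import ScalarField, VoxelImage
from nestpore.media import generate_analytic_geometry, generate_drained_state
from nestpore.morphology import (
    axis_connectivity,
    local_thickness,
    percolation_threshold,
    pore_occupancy,
    pore_size_distribution,
    porosity,
    rev_curve,
    segment_binary,
    structure_thickness,
)

from conftest import brute_force_local_thickness, random_two_phase


class TestSegmentBinary:
    def test_bimodal_mixture_recovers_fractions(self, rng):
        """Two well-separated Gaussians segment to the generating fractions."""
        frac = 0.3
        n = 32
        pore = rng.random((n, n, n)) < frac
        gray = np.where(pore, rng.normal(0.2, 0.05, (n, n, n)),
                        rng.normal(0.8, 0.05, (n, n, n)))
        img = segment_binary(gray, method="otsu")
        assert img.pore_mask().mean() == pytest.approx(frac, abs=0.02)
        assert 0.2 < img.provenance["threshold"] < 0.8

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment_binary(np.ones((4, 4, 4)))

    def test_binary_input_with_fixed_threshold_is_identity(self):
        """0/1 data at threshold 0.5: low values are pores, high solid."""
        data = np.zeros((4, 4, 4))
        data[:2] = 1.0
        img = segment_binary(data, method="fixed", threshold=0.5)
        assert np.all(img.labels[:2] == 1)  # bright voxels are solid
        assert np.all(img.labels[2:] == 0)


class TestPorosity:
    def test_all_pore_and_checkerboard(self):
        all_pore = VoxelImage(np.zeros((4, 4, 4), np.uint8), 1.0,
                              {0: "air", 1: "solid"})
        assert porosity(all_pore) == (1.0, 0.0)
        idx = np.indices((4, 4, 4)).sum(axis=0)
        board = VoxelImage((idx % 2).astype(np.uint8), 1.0,
                           {0: "air", 1: "solid"})
        phi, sd = porosity(board)
        assert phi == 0.5 and sd == 0.0

    def test_senegal_like_target(self, senegal_pack):
        phi, sd = porosity(senegal_pack)
        assert phi == pytest.approx(0.28, abs=0.01)
        assert sd > 0  # real media scatter slice to slice


class TestRevCurve:
    def test_largest_cube_normalises_to_one(self, senegal_pack):
        df = rev_curve(senegal_pack, [16, 32, 48, 64])
        assert df["normalized"].iloc[-1] == 1.0

    def test_homogeneous_medium_flat_beyond_grain_scale(self):
        img = random_two_phase((64, 64, 64), 0.4, seed=5)
        df = rev_curve(img, [16, 24, 32, 48, 64])
        assert np.all(np.abs(df["normalized"] - 1) < 0.05)

    def test_single_centered_sphere_matches_analytic_intersection(self):
        img = generate_analytic_geometry("spherical_cavity",
                                         shape=(64, 64, 64), radius=20)
        df = rev_curve(img, [16, 32, 64])
        # side 16 cube sits fully inside the radius-20 cavity
        assert df["porosity"].iloc[0] == 1.0
        # side 32: cube inscribed in the sphere up to the corners
        vol_sphere = 4 / 3 * np.pi * 20**3
        expect_mid = min(vol_sphere, 32**3)
        assert df["porosity"].iloc[1] == pytest.approx(
            (img.pore_mask()[16:48, 16:48, 16:48]).mean())

    def test_side_exceeding_image_rejected(self, senegal_pack):
        with pytest.raises(ValueError):
            rev_curve(senegal_pack, [128])


class TestLocalThickness:
    def test_spherical_cavity_maximum_is_radius(self):
        img = generate_analytic_geometry("spherical_cavity",
                                         shape=(48, 48, 48), radius=15)
        lt = local_thickness(img)
        assert lt.values.max() == pytest.approx(15, abs=1.0)

    def test_slab_interior_equals_half_width(self):
        img = generate_analytic_geometry("parallel_plates",
                                         shape=(24, 24, 24), aperture=10,
                                         gap_axis=0)
        lt = local_thickness(img)
        assert lt.values[12, 12, 12] == pytest.approx(5.0, abs=0.6)

    @pytest.mark.parametrize("seed,pore_frac", [(3, 0.45), (17, 0.6)])
    def test_equals_brute_force_oracle(self, seed, pore_frac):
        """Exact agreement with O(n²) exhaustive sphere fitting on 40³."""
        img = random_two_phase((40, 40, 40), pore_frac, seed=seed)
        lt = local_thickness(img).values
        mask = img.pore_mask()
        oracle = brute_force_local_thickness(mask)
        np.testing.assert_allclose(lt[mask], oracle[mask])

    def test_bounded_by_distance_transform_lower_bound(self, random_image):
        mask = random_image.pore_mask()
        dt = ndi.distance_transform_edt(mask)
        lt = local_thickness(random_image).values
        assert np.all(lt[mask] >= dt[mask] - 1e-12)


class TestPoreSizeDistribution:
    def test_monodisperse_cavity_is_point_mass(self):
        """Array of equal cavities: all inscribed radii agree."""
        labels = np.ones((36, 36, 36), np.uint8)
        for c in [(9, 9, 9), (9, 27, 27), (27, 9, 27), (27, 27, 9)]:
            zz, yy, xx = np.meshgrid(*(np.arange(36),) * 3, indexing="ij")
            labels[((zz - c[0]) ** 2 + (yy - c[1]) ** 2
                    + (xx - c[2]) ** 2) <= 36] = 0
        img = VoxelImage(labels, 1.0, {0: "air", 1: "solid"})
        psd = pore_size_distribution(img)
        assert psd.per_voxel.sd_um < 0.5
        assert psd.medial_axis.mean_um == pytest.approx(
            psd.per_voxel.mean_um, abs=1.0)

    def test_two_disjoint_tubes_split_mass_by_volume(self):
        """Disjoint tubes of radii r₁ < r₂: per-voxel PSD mass follows the
        volume of each tube, cleanly split at a radius between the two."""
        labels = np.ones((20, 40, 80), np.uint8)
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in labels.shape),
                                 indexing="ij")
        r1, r2 = 5, 10
        m1 = (yy - 12) ** 2 + (xx - 20) ** 2 <= r1**2
        m2 = (yy - 12) ** 2 + (xx - 60) ** 2 <= r2**2
        labels[m1] = 0
        labels[m2] = 0
        img = VoxelImage(labels, 1.0, {0: "air", 1: "solid"})
        psd = pore_size_distribution(img, bins=8).per_voxel
        v1, v2 = m1.sum(), m2.sum()
        below = psd.values_um <= 7.0
        assert below.mean() == pytest.approx(v1 / (v1 + v2), abs=0.05)

    def test_density_normalisation_and_cumulative(self, senegal_pack,
                                                  senegal_pack_thickness):
        psd = pore_size_distribution(senegal_pack,
                                     thickness=senegal_pack_thickness)
        for d in (psd.per_voxel, psd.medial_axis):
            widths = np.diff(d.bin_edges_um)
            assert (d.density * widths).sum() == pytest.approx(1.0)
            assert np.all(np.diff(d.cumulative) >= -1e-12)
            assert d.cumulative[-1] == pytest.approx(1.0)

    def test_senegal_like_bimodality(self):
        """Macropore population sits ≥3× above the micropore population.

        Uses pellets large enough (≈19 voxels) for the two pore scales to
        separate cleanly on the lattice.
        """
        from nestpore.media import MediumSpec, generate_pellet_pack

        # full-size pellets (0.52 mm) on a 112³ lattice at 15 μm
        spec = MediumSpec(seed=13, domain_shape=(112, 112, 112),
                          voxel_size=15.0)
        img = generate_pellet_pack(spec)
        lt = local_thickness(img, max_radii=80)
        psd = pore_size_distribution(img, bins=24, thickness=lt).per_voxel
        vals = psd.values_um
        micro_mode = np.median(vals[vals <= 40])
        macro_mode = np.median(vals[vals > 40])
        assert macro_mode / micro_mode >= 3.0


class TestAxisConnectivity:
    def test_through_tube_fully_connected(self):
        img = generate_analytic_geometry("tube", shape=(12, 24, 24),
                                         radius=6, axis=0)
        frac, mask = axis_connectivity(img, axis=0)
        assert frac == 1.0
        assert mask.sum() == img.pore_mask().sum()

    def test_blocked_tube_disconnected(self):
        img = generate_analytic_geometry("tube", shape=(12, 24, 24),
                                         radius=6, axis=0)
        labels = img.labels.copy()
        labels[6] = 1  # solid slab
        img2 = img.with_labels(labels)
        frac, mask = axis_connectivity(img2, axis=0)
        assert frac == 0.0 and mask.sum() == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_small_random_images(self,
                                                              connectivity):
        """Exhaustive BFS flood fill agrees on many tiny random lattices."""
        rng = np.random.default_rng(99)
        offsets = _neighbour_offsets(connectivity)
        for _ in range(40):
            mask = rng.random((4, 4, 4)) < rng.uniform(0.3, 0.8)
            frac, span = axis_connectivity(mask, axis=0,
                                           connectivity=connectivity)
            frac_o, span_o = _oracle_spanning(mask, offsets)
            assert frac == pytest.approx(frac_o)
            assert np.array_equal(span, span_o)


def _neighbour_offsets(connectivity):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offs.append((dz, dy, dx))
    return offs


def _oracle_spanning(mask, offsets):
    """Breadth-first flood fill from the z=0 face; check reach of z=-1."""
    shape = mask.shape
    visited = np.zeros(shape, bool)
    span = np.zeros(shape, bool)
    comp_of = {}
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = [start]
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(p[i] + off[i] for i in range(3))
                if all(0 <= q[i] < shape[i] for i in range(3)) and \
                        mask[q] and not visited[q]:
                    visited[q] = True
                    stack.append(q)
                    comp.append(q)
        comps.append(comp)
    total = mask.sum()
    n_span = 0
    for comp in comps:
        zs = {p[0] for p in comp}
        if 0 in zs and shape[0] - 1 in zs:
            n_span += len(comp)
            for p in comp:
                span[p] = True
    return (n_span / total if total else 0.0), span


class TestPercolationThreshold:
    def test_straight_tube_threshold_is_tube_radius(self):
        img = generate_analytic_geometry("tube", shape=(12, 32, 32),
                                         radius=8, axis=0)
        res = percolation_threshold(img, axis=0)
        assert res.percolating
        lt = local_thickness(img)
        assert res.threshold_um == lt.values.max()
        assert res.threshold_um == pytest.approx(8, abs=1.0)

    def test_two_parallel_tubes_take_the_larger_radius(self):
        labels = np.ones((12, 32, 64), np.uint8)
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in labels.shape),
                                 indexing="ij")
        labels[(yy - 16) ** 2 + (xx - 16) ** 2 <= 5**2] = 0
        labels[(yy - 16) ** 2 + (xx - 48) ** 2 <= 9**2] = 0
        img = VoxelImage(labels, 1.0, {0: "air", 1: "solid"})
        res = percolation_threshold(img, axis=0)
        assert res.threshold_um == pytest.approx(9, abs=1.0)

    def test_bisection_equals_linear_scan(self, senegal_pack,
                                          senegal_pack_thickness):
        """The bisection result is the exact discrete argmax."""
        res = percolation_threshold(senegal_pack, axis=0,
                                    thickness=senegal_pack_thickness)
        lt = senegal_pack_thickness.values
        mask = senegal_pack.pore_mask()
        best = None
        for r in res.candidate_radii_um:
            frac, _ = axis_connectivity(mask & (lt >= r), axis=0)
            if frac > 0:
                best = r
        assert res.threshold_um == best
        # one radius step above the threshold must not span
        above = res.candidate_radii_um[res.candidate_radii_um
                                       > res.threshold_um]
        if above.size:
            frac, _ = axis_connectivity(mask & (lt >= above[0]), axis=0)
            assert frac == 0.0

    def test_non_percolating_reported(self):
        labels = np.ones((8, 8, 8), np.uint8)
        labels[3:5, 3:5, 3:5] = 0  # isolated cavity
        img = VoxelImage(labels, 1.0, {0: "air", 1: "solid"})
        res = percolation_threshold(img, axis=0)
        assert not res.percolating


class TestPoreOccupancy:
    def test_all_water_when_entry_radius_huge(self, senegal_pack,
                                              senegal_pack_thickness):
        wet = generate_drained_state(senegal_pack, entry_radius_um=1e5,
                                     thickness=senegal_pack_thickness)
        occ = pore_occupancy(wet, senegal_pack_thickness)
        occupied = occ[occ.n_voxels > 0]
        assert np.allclose(occupied.water, 1.0)

    def test_fractions_sum_to_one(self, senegal_pack,
                                  senegal_pack_thickness):
        wet = generate_drained_state(senegal_pack, entry_radius_um=40.0,
                                     thickness=senegal_pack_thickness)
        occ = pore_occupancy(wet, senegal_pack_thickness)
        occupied = occ[occ.n_voxels > 0]
        total = occupied.water + occupied.connected_air \
            + occupied.disconnected_air
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_air_occupies_larger_pore_bins(self, senegal_pack,
                                           senegal_pack_thickness):
        """Drained air sits in larger pores than the remaining water."""
        wet = generate_drained_state(senegal_pack, entry_radius_um=40.0,
                                     thickness=senegal_pack_thickness)
        air = wet.phase_mask("air")
        water = wet.phase_mask("water")
        lt = senegal_pack_thickness.values
        if air.any() and water.any():
            assert lt[air].mean() >= lt[water].mean()

    def test_missing_phase_rejected(self, senegal_pack,
                                    senegal_pack_thickness):
        with pytest.raises(ValueError, match="water"):
            pore_occupancy(senegal_pack, senegal_pack_thickness)


class TestStructureThickness:
    def test_parallel_plates_gap_width(self):
        img = generate_analytic_geometry("parallel_plates",
                                         shape=(24, 24, 24), aperture=8,
                                         gap_axis=1)
        widths, hist = structure_thickness(img, 0, 0, target="channels")
        assert np.median(widths) == pytest.approx(8, abs=1.5)

    def test_wall_width(self):
        img = generate_analytic_geometry(
            "layered_slab", shape=(24, 12, 12),
            layers=[("air", 8), ("quartz", 8), ("air", 8)], axis=0)
        widths, _ = structure_thickness(img, 0, 0, target="walls")
        assert np.median(widths) == pytest.approx(8, abs=1.5)

    def test_erosion_eliminating_everything_raises(self):
        img = random_two_phase((16, 16, 16), 0.5, seed=2)
        with pytest.raises(ValueError, match="eliminated"):
            structure_thickness(img, 0, 50, target="walls")
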