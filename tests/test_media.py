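"""Synthetic-media generators: determinism, porosity control, geometry."""

import numpy as np
import pytest

from nestpore.image import VoxelImage
from nestpore.media import (
    CrackParams,
    MediumSpec,
    PackingError,
    generate_analytic_geometry,
    generate_cracked_matrix,
    generate_drained_state,
    generate_micropore_matrix,
    generate_pellet_pack,
    generate_sphere_pack,
)
from nestpore.morphology import axis_connectivity, local_thickness, porosity


class TestMediumSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            MediumSpec(target_porosity=1.2, seed=0)
        with pytest.raises(ValueError):
            MediumSpec(voxel_size=-1, seed=0)

    def test_yaml_round_trip_requires_seed(self):
        spec = MediumSpec(seed=5, crack_params=CrackParams(count=2))
        back = MediumSpec.from_yaml(spec.to_yaml())
        assert back == spec
        with pytest.raises(ValueError, match="seed"):
            MediumSpec.from_dict({"target_porosity": 0.3})


class TestSpherePack:
    SPEC = dict(domain_shape=(48, 48, 48), voxel_size=10.0,
                target_porosity=0.65, grain_radius_mean_um=60.0,
                grain_radius_sd_um=10.0)

    def test_determinism(self):
        a = generate_sphere_pack(MediumSpec(seed=8, **self.SPEC))
        b = generate_sphere_pack(MediumSpec(seed=8, **self.SPEC))
        assert np.array_equal(a.labels, b.labels)

    def test_porosity_within_one_percent(self):
        img = generate_sphere_pack(MediumSpec(seed=8, **self.SPEC))
        assert abs(img.pore_mask().mean() - 0.65) < 0.01

    def test_single_sphere_porosity_matches_voxel_count(self):
        """One interior grain: porosity is the voxelised-sphere complement.

        The voxel count of a centred radius-10 sphere (via the analytic
        cavity fixture, which shares the voxelisation) is ~4/3πr³, and a
        single-grain pack leaves exactly that complement unless the random
        centre is clipped by the boundary.
        """
        cavity = generate_analytic_geometry("spherical_cavity",
                                            shape=(32, 32, 32), radius=10)
        sphere_voxels = int(cavity.pore_mask().sum())
        assert sphere_voxels == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.05)
        spec = MediumSpec(seed=0, domain_shape=(32, 32, 32), voxel_size=10.0,
                          target_porosity=0.96, grain_radius_mean_um=100.0,
                          grain_radius_sd_um=1e-9)
        img = generate_sphere_pack(spec, max_attempts=10)
        solid = int((img.labels == 1).sum())
        assert 0 < solid <= sphere_voxels + 8  # clipping only removes voxels
        assert img.pore_mask().mean() == 1.0 - solid / 32**3

    def test_unreachable_target_raises_with_achieved_value(self):
        spec = MediumSpec(seed=1, domain_shape=(40, 40, 40), voxel_size=10.0,
                          target_porosity=0.3, overlap=0.0,
                          grain_radius_mean_um=50.0, grain_radius_sd_um=5.0)
        with pytest.raises(PackingError, match="achieved"):
            generate_sphere_pack(spec, max_attempts=3000)


class TestPelletPack:
    def test_determinism(self, senegal_like_spec, senegal_pack):
        again = generate_pellet_pack(senegal_like_spec)
        assert np.array_equal(again.labels, senegal_pack.labels)

    def test_total_porosity_within_one_percent(self, senegal_like_spec,
                                               senegal_pack):
        phi, _ = porosity(senegal_pack)
        assert abs(phi - senegal_like_spec.target_porosity) < 0.01

    def test_micropores_off_leaves_interpellet_voids_only(self,
                                                          senegal_like_spec):
        img = generate_pellet_pack(senegal_like_spec, carve_micropores=False)
        phi, _ = porosity(img)
        phi_macro = (0.28 - 0.183) / (1 - 0.183)
        assert abs(phi - phi_macro) < 0.01

    def test_axis_connectivity_above_ninety_percent(self, senegal_pack):
        frac, _ = axis_connectivity(senegal_pack, axis=0)
        assert frac > 0.90

    def test_infeasible_split_raises(self):
        with pytest.raises(ValueError, match="split"):
            generate_pellet_pack(
                MediumSpec(seed=0, target_porosity=0.1, micro_porosity=0.2)
            )


class TestGuineaLike:
    def test_cracked_low_porosity_matrix(self):
        """Guinea-like wall: 15% porosity dominated by large pores + cracks."""
        spec = MediumSpec(
            seed=21, domain_shape=(64, 64, 64), voxel_size=15.0,
            target_porosity=0.15, micro_porosity=0.0,
            pellet_radius_mean_mm=0.18, pellet_radius_sd_mm=0.09,
        )
        img = generate_pellet_pack(spec, carve_micropores=False)
        phi, _ = porosity(img)
        assert abs(phi - 0.15) < 0.01


class TestAnalyticGeometry:
    def test_tube_porosity_matches_area(self):
        img = generate_analytic_geometry("tube", shape=(8, 64, 64),
                                         radius=12, axis=0)
        phi = img.pore_mask().mean()
        assert phi == pytest.approx(np.pi * 12**2 / 64**2, rel=0.02)

    def test_layered_slab_fractions_exact(self):
        img = generate_analytic_geometry(
            "layered_slab", shape=(10, 4, 4),
            layers=[("quartz", 6), ("clay", 4)], axis=0)
        assert img.phase_fraction("quartz") == pytest.approx(0.6)
        assert img.phase_fraction("clay") == pytest.approx(0.4)

    def test_tetrahedral_cell_central_pore_radius(self):
        """Central pore of four tangent pellets admits a 0.2247R sphere."""
        R = 24
        img = generate_analytic_geometry("tetrahedral_cell",
                                         shape=(96, 96, 96), radius=R)
        lt = local_thickness(img)
        c = np.array(img.shape) // 2
        central = lt.values[c[0]-8:c[0]+8, c[1]-8:c[1]+8, c[2]-8:c[2]+8]
        expected = (np.sqrt(1.5) - 1) * R
        assert central.max() == pytest.approx(expected, abs=1.0)

    def test_feature_below_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            generate_analytic_geometry("tube", shape=(8, 16, 16),
                                       radius=1.5, axis=0)
        with pytest.raises(ValueError, match="unknown"):
            generate_analytic_geometry("moebius", shape=(8, 8, 8))


class TestCrackedMatrix:
    def test_single_plane_crack_porosity(self):
        """One planar crack of aperture a through an L³ box: φ ≈ a/L."""
        spec = MediumSpec(seed=0, domain_shape=(48, 48, 48), voxel_size=10.0)
        img = generate_cracked_matrix(
            spec, planes=[((24, 0, 0), (1, 0, 0), 40.0)])
        phi = img.pore_mask().mean()
        assert phi == pytest.approx(4 / 48, rel=0.3)

    def test_zero_cracks_gives_zero_porosity(self):
        spec = MediumSpec(seed=0, domain_shape=(16, 16, 16), voxel_size=10.0,
                          crack_params=CrackParams(count=0))
        img = generate_cracked_matrix(spec)
        assert img.pore_mask().sum() == 0
        assert img.provenance["crack_porosity"] == 0.0

    def test_crack_parallel_to_axis_does_not_span_it(self):
        spec = MediumSpec(seed=0, domain_shape=(32, 32, 32), voxel_size=10.0)
        img = generate_cracked_matrix(
            spec, planes=[((16, 0, 0), (1, 0, 0), 30.0)])
        frac, _ = axis_connectivity(img, axis=0)
        assert frac == 0.0  # crack plane is normal to z: no z-spanning path
        frac_y, _ = axis_connectivity(img, axis=1)
        assert frac_y == 1.0


class TestDrainedState:
    @pytest.fixture(scope="class")
    def two_tube(self):
        """Two parallel tubes, radii 4 and 9 voxels."""
        labels = np.ones((16, 32, 64), np.uint8)
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in labels.shape),
                                 indexing="ij")
        labels[(yy - 16) ** 2 + (xx - 16) ** 2 <= 4**2] = 0
        labels[(yy - 16) ** 2 + (xx - 46) ** 2 <= 9**2] = 0
        return VoxelImage(labels, voxel_size=1.0,
                          phase_table={0: "air", 1: "solid"})

    def test_entry_radius_above_max_pore_leaves_all_water(self, two_tube):
        out = generate_drained_state(two_tube, entry_radius_um=50.0)
        assert out.phase_mask("air").sum() == 0
        assert out.phase_mask("water").sum() == two_tube.pore_mask().sum()

    def test_entry_radius_zero_fills_all_pores_with_air(self, two_tube):
        out = generate_drained_state(two_tube, entry_radius_um=0.0)
        assert out.phase_mask("water").sum() == 0

    def test_tube_invaded_iff_entry_radius_below_tube_radius(self, two_tube):
        """Air spans a straight tube exactly when r_entry ≤ r_tube."""
        lt = local_thickness(two_tube)
        out = generate_drained_state(two_tube, entry_radius_um=6.0,
                                     thickness=lt)
        air = out.phase_mask("air")
        # large tube invaded, small tube not
        assert air[:, 16, 46].all()
        assert not air[:, 16, 16].any()

    def test_air_saturation_monotone_in_entry_radius(self, senegal_pack,
                                                     senegal_pack_thickness):
        pore = senegal_pack.pore_mask().sum()
        sats = []
        for r in (0.0, 20.0, 40.0, 80.0, 1e4):
            out = generate_drained_state(senegal_pack, entry_radius_um=r,
                                         thickness=senegal_pack_thickness)
            sats.append(out.phase_mask("air").sum() / pore)
        # at zero entry radius every inlet-connected pore is invaded
        assert sats[0] > 0.9 and sats[-1] == 0.0
        assert all(a >= b for a, b in zip(sats, sats[1:]))

    def test_sub_resolution_entry_radius_rejected(self, two_tube):
        with pytest.raises(ValueError, match="resolution"):
            generate_drained_state(two_tube, entry_radius_um=0.2)


def test_micropore_matrix_porosity_and_pore_scale():
    """Correlated-noise micropores hit the target porosity exactly and a
    medial-axis pore radius near the small-pore population mean."""
    spec = MediumSpec(seed=4, domain_shape=(64, 64, 64), voxel_size=15.0)
    img = generate_micropore_matrix(spec)
    assert img.pore_mask().mean() == pytest.approx(0.183, abs=0.002)
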