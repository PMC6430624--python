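import numpy as np
import pytest

from nestpore.image import VoxelImage
from nestpore.media import MediumSpec, generate_micropore_matrix, generate_pellet_pack
from nestpore.morphology import local_thickness


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_two_phase(shape, pore_fraction, seed):
    """Uncorrelated random two-phase image (1 = solid)."""
    r = np.random.default_rng(seed)
    labels = (r.random(shape) >= pore_fraction).astype(np.uint8)
    return VoxelImage(labels=labels, voxel_size=1.0,
                      phase_table={0: "air", 1: "solid"})


@pytest.fixture
def random_image():
    return random_two_phase((24, 24, 24), 0.5, seed=7)


# -- scaled Senegal-like media (session-scoped: generation is the cost) ----
#
# The physical parameters keep the published porosity structure (total 28%,
# 18.3% intra-pellet) but shrink the pellets so that both pore scales fit a
# 64³ lattice at 15 μm voxels.

@pytest.fixture(scope="session")
def senegal_like_spec():
    return MediumSpec(
        seed=11,
        domain_shape=(64, 64, 64),
        voxel_size=15.0,
        pellet_radius_mean_mm=0.18,
        pellet_radius_sd_mm=0.09,
    )


@pytest.fixture(scope="session")
def senegal_pack(senegal_like_spec):
    return generate_pellet_pack(senegal_like_spec)


@pytest.fixture(scope="session")
def senegal_pack_thickness(senegal_pack):
    return local_thickness(senegal_pack)


@pytest.fixture(scope="session")
def micropore_matrix(senegal_like_spec):
    return generate_micropore_matrix(senegal_like_spec)


def brute_force_local_thickness(mask):
    """O(n·ball) exhaustive sphere-fitting oracle, exact integer arithmetic."""
    from scipy import ndimage as ndi

    dt2 = np.round(ndi.distance_transform_edt(mask) ** 2).astype(np.int64)
    bf2 = np.zeros(mask.shape, dtype=np.int64)
    for y in np.argwhere(mask):
        r2 = int(dt2[tuple(y)])
        r = int(np.ceil(np.sqrt(r2)))
        lo = np.maximum(y - r, 0)
        hi = np.minimum(y + r + 1, mask.shape)
        zz, yy, xx = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
        )
        cov = (zz - y[0]) ** 2 + (yy - y[1]) ** 2 + (xx - y[2]) ** 2 < r2
        sub = bf2[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(sub, np.where(cov, r2, 0), out=sub)
    return np.sqrt(bf2.astype(float))
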