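"""Partition invariants for SLIC, grid, watershed and voxel partitions."""

import numpy as np
import pytest
from scipy import ndimage

from svflow import (
    Mask,
    Volume,
    grid_partition,
    region_table,
    slic_supervoxels,
    threshold_mask,
    voxel_partition,
    watershed_partition,
)


def assert_valid_partition(part, mask):
    """The shared contract: labels>0 iff mask, regions connected, ids dense."""
    lab = part.labels
    np.testing.assert_array_equal(lab > 0, mask.data)
    k = part.n_regions
    if k:
        present = np.unique(lab[lab > 0])
        np.testing.assert_array_equal(present, np.arange(1, k + 1))
    structure = ndimage.generate_binary_structure(lab.ndim, 1)
    for sl, lid in zip(ndimage.find_objects(lab), range(1, k + 1)):
        _, n = ndimage.label(lab[sl] == lid, structure=structure)
        assert n == 1, f"region {lid} is disconnected"


def test_slic_uniform_cube_region_count_and_sizes():
    shape = (30, 30, 30)
    vol = Volume(np.full(shape, 50.0), (1.0, 1.0, 1.0))
    mask = Mask(np.ones(shape, bool))
    part = slic_supervoxels(vol, mask, step=5)
    assert_valid_partition(part, mask)
    expected = (30 / 5) ** 3
    assert abs(part.n_regions - expected) <= 0.3 * expected
    sizes = np.bincount(part.labels.ravel())[1:]
    assert abs(np.mean(sizes) - 125) <= 0.3 * 125


def test_slic_empty_mask_gives_zero_regions():
    vol = Volume(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
    part = slic_supervoxels(vol, Mask(np.zeros((10, 10, 10), bool)), step=5)
    assert part.n_regions == 0


def test_slic_rejects_tiny_step():
    vol = Volume(np.zeros((10, 10, 10)), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        slic_supervoxels(vol, Mask(np.ones((10, 10, 10), bool)), step=1)


def test_slic_respects_boundaries_of_separated_nuclei(two_blob_volume):
    vol = two_blob_volume
    mask = threshold_mask(vol, threshold=30.0, smooth_sigma=0)
    part = slic_supervoxels(vol, mask, step=4)
    assert_valid_partition(part, mask)
    # ground-truth blob membership by proximity to the two known centers
    zz, yy, xx = np.indices(vol.shape, dtype=float)
    in_a = (yy + xx) < 40.0
    labels_a = set(np.unique(part.labels[mask.data & in_a]))
    labels_b = set(np.unique(part.labels[mask.data & ~in_a]))
    assert labels_a.isdisjoint(labels_b), "a super-voxel spans both nuclei"


def test_slic_is_deterministic(embryo_static):
    vol, _, _ = embryo_static
    mask = threshold_mask(vol)
    a = slic_supervoxels(vol, mask, step=5)
    b = slic_supervoxels(vol, mask, step=5)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_grid_partition_full_foreground_arithmetic():
    mask = Mask(np.ones((9, 9), bool))
    part = grid_partition(mask, step=3)
    assert part.n_regions == 9
    sizes = np.bincount(part.labels.ravel())[1:]
    assert (sizes == 9).all()


def test_grid_partition_empty_mask():
    assert grid_partition(Mask(np.zeros((9, 9), bool)), step=3).n_regions == 0


def test_grid_partition_splits_l_shape_per_connectivity():
    # L-shape crossing one box boundary: inside the 6x6 box at origin the
    # two arms meet; the stub continuing into the next box is separate.
    mask = np.zeros((6, 12), bool)
    mask[0:2, 0:8] = True  # horizontal arm crossing x=6 boundary
    mask[2:6, 0:2] = True  # vertical arm, same first box
    m = Mask(mask)
    part = grid_partition(m, step=6)
    assert_valid_partition(part, m)
    # box 0 contains the connected L (one region); box 1 the stub
    assert part.n_regions == 2


def test_watershed_blob_counts(two_blob_volume):
    vol = two_blob_volume
    mask = threshold_mask(vol, threshold=30.0, smooth_sigma=0)
    part = watershed_partition(vol, mask, seed_spacing=6.0)
    assert_valid_partition(part, mask)
    assert part.n_regions == 2
    single = Volume(vol.data[:, :20, :20], (2.0, 1.0, 1.0))
    smask = threshold_mask(single, threshold=30.0, smooth_sigma=0)
    spart = watershed_partition(single, smask, seed_spacing=6.0)
    assert spart.n_regions == 1
    empty = Mask(np.zeros(vol.shape, bool))
    assert watershed_partition(vol, empty, seed_spacing=6.0).n_regions == 0


def test_voxel_partition_one_region_per_voxel():
    rng = np.random.default_rng(5)
    mask = Mask(rng.random((6, 8, 8)) > 0.7)
    part = voxel_partition(mask)
    assert part.n_regions == mask.data.sum()
    assert_valid_partition(part, mask)


def test_region_table_cube_centroid_and_size():
    lab = np.zeros((6, 6, 6), np.int32)
    lab[0:2, 0:2, 0:2] = 1
    vol = Volume(np.ones((6, 6, 6)), (2.0, 1.0, 1.0))
    part = voxel_partition(Mask(lab > 0))
    part.labels = lab  # single region covering the cube
    table = region_table(part, vol)
    assert table.sizes[0] == 8
    np.testing.assert_allclose(table.centroids[0], [0.5 * 2.0, 0.5, 0.5])


def test_region_table_matches_brute_force(embryo_static):
    vol, _, _ = embryo_static
    mask = threshold_mask(vol)
    part = slic_supervoxels(vol, mask, step=5)
    table = region_table(part, vol)
    assert table.sizes.sum() == mask.data.sum()
    rng = np.random.default_rng(6)
    for lid in rng.choice(table.ids, size=5, replace=False):
        vox = np.argwhere(part.labels == lid)
        np.testing.assert_allclose(table.centroids_vox[lid - 1], vox.mean(axis=0))
        assert table.sizes[lid - 1] == len(vox)
        lo = vox.min(axis=0)
        hi = vox.max(axis=0)
        assert np.all(table.centroids_vox[lid - 1] >= lo)
        assert np.all(table.centroids_vox[lid - 1] <= hi)
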