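"""Pyramid construction, per-level solves and the full pipeline."""

import numpy as np
import pytest

from helpers import brute_force_integer_minimizer, shifted_blob_pair
from svflow import (
    FlowConfig,
    Mask,
    Volume,
    build_pyramid,
    estimate_flow,
    solve_level,
    threshold_mask,
)
from svflow.supervoxel import LabelPartition, slic_supervoxels


def test_pyramid_shapes_halve_per_level():
    vol = Volume(np.random.default_rng(0).random((64, 64, 64)),
                 (1.0, 1.0, 1.0))
    mask = Mask(np.ones((64, 64, 64), bool))
    labels = LabelPartition(np.ones((64, 64, 64), np.int32), "grid", 5)
    pyr = build_pyramid(vol, vol, mask, labels, FlowConfig(levels=3))
    assert [lvl.shape for lvl in pyr.levels] == [(64,) * 3, (32,) * 3, (16,) * 3]


def test_pyramid_constant_volume_stays_constant():
    vol = Volume(np.full((32, 32, 32), 7.0), (1.0, 1.0, 1.0))
    mask = Mask(np.ones((32, 32, 32), bool))
    labels = LabelPartition(np.ones((32, 32, 32), np.int32), "grid", 5)
    pyr = build_pyramid(vol, vol, mask, labels, FlowConfig(levels=3))
    for lvl in pyr.levels:
        np.testing.assert_allclose(lvl.source.data, 7.0)


def test_pyramid_skips_thin_axis_and_clamps_depth():
    vol = Volume(np.random.default_rng(1).random((3, 64, 64)), (8.0, 1.0, 1.0))
    mask = Mask(np.ones((3, 64, 64), bool))
    labels = LabelPartition(np.ones((3, 64, 64), np.int32), "grid", 5)
    pyr = build_pyramid(vol, vol, mask, labels, FlowConfig(levels=3))
    assert [lvl.shape for lvl in pyr.levels] == [
        (3, 64, 64), (3, 32, 32), (3, 16, 16)]
    tiny = Volume(np.random.default_rng(2).random((4, 4, 4)), (1.0, 1.0, 1.0))
    tmask = Mask(np.ones((4, 4, 4), bool))
    tlabels = LabelPartition(np.ones((4, 4, 4), np.int32), "grid", 2)
    with pytest.warns(UserWarning, match="clamped"):
        tpyr = build_pyramid(tiny, tiny, tmask, tlabels, FlowConfig(levels=3))
    assert len(tpyr) == 1


def test_pyramid_majority_vote_never_merges_separated_nuclei(two_blob_volume):
    vol = two_blob_volume
    mask = threshold_mask(vol, threshold=30.0, smooth_sigma=0)
    labels = slic_supervoxels(vol, mask, step=4)
    pyr = build_pyramid(vol, vol, mask, labels, FlowConfig(levels=3))
    zz, yy, xx = np.indices(vol.shape, dtype=float)
    in_a_fine = (yy + xx) < 40.0
    ids_a = set(np.unique(labels.labels[mask.data & in_a_fine])) - {0}
    ids_b = set(np.unique(labels.labels[mask.data & ~in_a_fine])) - {0}
    for lvl in pyr.levels[1:]:
        f = lvl.accum_factor
        zz, yy, xx = np.indices(lvl.shape, dtype=float)
        in_a = (yy * f[1] + xx * f[2]) < 40.0
        coarse_a = set(np.unique(lvl.labels[in_a])) - {0}
        coarse_b = set(np.unique(lvl.labels[~in_a])) - {0}
        assert coarse_a <= ids_a and coarse_b <= ids_b


def test_pyramid_mask_any_foreground_rule():
    mask = np.zeros((16, 16, 16), bool)
    mask[13, 5, 7] = True  # single voxel survives at every level
    vol = Volume(np.zeros((16, 16, 16)), (1.0, 1.0, 1.0))
    labels = LabelPartition(mask.astype(np.int32), "voxel", 1)
    pyr = build_pyramid(vol, vol, Mask(mask), labels, FlowConfig(levels=3))
    assert pyr.levels[1].labels[6, 2, 3] == 1
    assert pyr.levels[2].labels[3, 1, 1] == 1
    assert (pyr.levels[1].labels > 0).sum() == 1
    assert (pyr.levels[2].labels > 0).sum() == 1


def test_solve_level_recovers_integer_shift():
    ctx, shift = shifted_blob_pair(shift=(1.0, 2.0, -1.0))
    sol, info = solve_level(ctx, np.zeros(3), FlowConfig())
    oracle = brute_force_integer_minimizer(ctx, radius=3)
    np.testing.assert_allclose(oracle, shift)
    assert np.linalg.norm(sol - oracle) < 0.1
    assert info["energy_final"] <= info["energy_init"]


def test_solve_level_stationary_init_returns_init():
    ctx, shift = shifted_blob_pair(shift=(1.0, 0.0, 0.0))
    sol, info = solve_level(ctx, shift, FlowConfig())
    np.testing.assert_allclose(sol, shift, atol=1e-6)


def test_solve_level_descends_on_random_instances():
    from helpers import random_energy_instance

    for seed in (31, 32, 33):
        ctx, u0 = random_energy_instance(seed)
        sol, info = solve_level(ctx, u0, FlowConfig(max_iter=50))
        assert info["energy_final"] <= info["energy_init"] + 1e-12


def test_estimate_identical_volumes_gives_zero_flow(embryo_static):
    src, _, _ = embryo_static
    result = estimate_flow(src, src, cfg=FlowConfig())
    u = result.table[["u_z", "u_y", "u_x"]].to_numpy()
    assert np.abs(u).max() < 0.05
    assert not result.flow.vectors[:, ~result.flow.valid].any()


def test_estimate_shape_mismatch_and_empty_foreground():
    a = Volume(np.zeros((8, 10, 10)), (1.0, 1.0, 1.0))
    b = Volume(np.zeros((8, 10, 12)), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        estimate_flow(a, b)
    with pytest.warns(UserWarning, match="empty"):
        result = estimate_flow(a, a, cfg=FlowConfig(threshold=1.0))
    assert not result.flow.valid.any()
    assert len(result.table) == 0


def test_estimate_recovers_known_drift(embryo_drift_result, embryo_drift):
    from svflow import evaluate_flow, truth_to_ground_truth

    _, _, truth = embryo_drift
    report = evaluate_flow(embryo_drift_result.flow,
                           truth_to_ground_truth(truth))
    assert report.mean_ee < 0.25
    assert report.mean_normalized_ee < 0.1


def test_estimate_descends_across_levels(embryo_drift_result):
    logs = {entry["level"]: entry for entry in embryo_drift_result.level_log}
    for lvl in range(len(logs) - 1):
        # each finer level starts from the upsampled coarse solution and
        # must not end worse than it started
        assert logs[lvl]["energy_final"] <= logs[lvl]["energy_init"] + 1e-9


def test_estimate_is_deterministic(embryo_drift, embryo_drift_result):
    src, tgt, _ = embryo_drift
    again = estimate_flow(src, tgt, cfg=FlowConfig())
    assert again.table.equals(embryo_drift_result.table)
    np.testing.assert_array_equal(again.flow.vectors,
                                  embryo_drift_result.flow.vectors)
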