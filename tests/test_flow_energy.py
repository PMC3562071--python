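"""Huber penalty, interpolation, image gradients and the MRF energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from helpers import random_energy_instance, shifted_blob_pair
from svflow import Volume, build_graph, edge_weights, huber, presmooth
from svflow.flow_energy import (
    Penalty,
    build_energy_context,
    gradient_5pt,
    sample_trilinear,
)
from svflow.supervoxel import LabelPartition, region_table


@pytest.mark.parametrize(
    "r, delta, expected_val, expected_der",
    [
        (0.0, 1.0, 0.0, 0.0),
        (2.0, 2.0, 2.0, 2.0),             # boundary: delta^2/2, delta
        (6.0, 2.0, 2.0 * (6 - 1.0), 2.0),  # linear branch: 2.5*delta^2
        (-6.0, 2.0, 10.0, -2.0),
    ],
)
def test_huber_closed_form(r, delta, expected_val, expected_der):
    val, der = huber(np.array(r), delta)
    np.testing.assert_allclose(val, expected_val)
    np.testing.assert_allclose(der, expected_der)


def test_huber_continuous_at_transition():
    delta = 1.7
    eps = 1e-9
    below = huber(np.array(delta - eps), delta)
    above = huber(np.array(delta + eps), delta)
    np.testing.assert_allclose(below[0], above[0], atol=1e-7)
    np.testing.assert_allclose(below[1], above[1], atol=1e-7)


def test_huber_rejects_nonpositive_delta():
    with pytest.raises(ValueError):
        huber(np.zeros(3), 0.0)


@settings(max_examples=50, derandomize=True)
@given(st.floats(-50, 50), st.floats(0.1, 10))
def test_huber_properties(r, delta):
    val, der = huber(np.array(r), delta)
    assert val >= 0
    assert abs(der) <= delta + 1e-12  # derivative saturates at +-delta
    # convexity surrogate: derivative is nondecreasing
    val2, der2 = huber(np.array(r + 0.5), delta)
    assert der2 >= der - 1e-12


def test_presmooth_identity_and_mass():
    vol = Volume(np.random.default_rng(0).random((9, 9, 9)), (1.0, 1.0, 1.0))
    np.testing.assert_array_equal(presmooth(vol, 0.0).data, vol.data)
    impulse = np.zeros((15, 15, 15))
    impulse[7, 7, 7] = 1.0
    sm = presmooth(Volume(impulse, (1.0, 1.0, 1.0)), 1.2)
    np.testing.assert_allclose(sm.data.sum(), 1.0, rtol=1e-10)
    oracle = ndimage.gaussian_filter(impulse, 1.2, mode="reflect")
    np.testing.assert_allclose(sm.data, oracle)
    const = presmooth(Volume(np.full((8, 8), 3.0), (1.0, 1.0)), 2.0)
    np.testing.assert_allclose(const.data, 3.0)


def test_trilinear_exact_cases():
    rng = np.random.default_rng(1)
    data = rng.random((6, 7, 8)) * 10
    idx = np.array([[2, 3, 4], [1, 5, 2]]).T.astype(float)
    vals = sample_trilinear(data, idx)
    np.testing.assert_allclose(vals, [data[2, 3, 4], data[1, 5, 2]])
    # midpoint of two voxels
    line = np.zeros((1, 1, 2))
    line[0, 0, 0], line[0, 0, 1] = 10.0, 20.0
    mid = sample_trilinear(line, np.array([[0.0], [0.0], [0.5]]))
    np.testing.assert_allclose(mid, [15.0])


def test_trilinear_reproduces_linear_ramp():
    zz, yy, xx = np.indices((8, 9, 10), dtype=float)
    data = 2.0 * zz - 3.0 * yy + 0.5 * xx + 4.0
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, [7, 8, 9], size=(40, 3)).T
    expected = 2.0 * coords[0] - 3.0 * coords[1] + 0.5 * coords[2] + 4.0
    np.testing.assert_allclose(sample_trilinear(data, coords), expected,
                               rtol=1e-12)


def test_trilinear_clamps_to_edge():
    data = np.arange(5.0).reshape(1, 1, 5)
    vals = sample_trilinear(data, np.array([[0.0, 0.0], [0.0, 0.0],
                                            [-3.0, 7.0]]))
    np.testing.assert_allclose(vals, [0.0, 4.0])


def test_gradient_5pt_constant_ramp_cubic():
    const = np.full((7, 7, 7), 5.0)
    for g in gradient_5pt(const):
        np.testing.assert_allclose(g, 0.0)
    zz, yy, xx = np.indices((9, 9, 9), dtype=float)
    ramp = 1.5 * zz - 2.0 * yy + 0.25 * xx
    gz, gy, gx = gradient_5pt(ramp)
    interior = (slice(2, -2),) * 3
    np.testing.assert_allclose(gz[interior], 1.5, atol=1e-10)
    np.testing.assert_allclose(gy[interior], -2.0, atol=1e-10)
    np.testing.assert_allclose(gx[interior], 0.25, atol=1e-10)
    # five-point stencil is exact for cubics
    x = np.arange(11.0)
    cubic = (0.3 * x**3 - x**2 + 2 * x)[None, None, :] * np.ones((5, 5, 1))
    gx = gradient_5pt(cubic)[2]
    expected = 0.9 * x**2 - 2 * x + 2
    np.testing.assert_allclose(gx[2, 2, 2:-2], expected[2:-2], atol=1e-9)


def test_energy_zero_for_identical_volumes_zero_flow():
    rng = np.random.default_rng(3)
    data = rng.random((8, 10, 10)) * 100
    vol = Volume(data, (1.0, 1.0, 1.0))
    lab = np.zeros(vol.shape, np.int32)
    lab[2:6, 2:6, 2:6] = 1
    labels = LabelPartition(lab, "grid", 4)
    graph = build_graph(region_table(labels, vol), d_max=1e-6)
    graph = edge_weights(graph)
    ctx = build_energy_context(vol, vol, labels, graph,
                               Penalty("huber", 5.0), Penalty("huber", 1.0))
    e, g = ctx.energy_and_gradient(np.zeros(3))
    assert e == 0.0
    np.testing.assert_allclose(g, 0.0, atol=1e-12)


def test_integer_shift_is_global_minimum_over_grid():
    ctx, shift = shifted_blob_pair(shift=(1.0, 2.0, -1.0))
    e_shift, _ = ctx.energy_and_gradient(shift)
    assert e_shift < 1e-6  # exact copy at the shift
    for dz in range(-3, 4):
        for dy in range(-3, 4):
            for dx in range(-3, 4):
                e, _ = ctx.energy_and_gradient(np.array([dz, dy, dx], float))
                assert e >= e_shift - 1e-9


def test_analytic_gradient_matches_finite_differences():
    ctx, u0 = random_energy_instance(seed=42)
    e, grad = ctx.energy_and_gradient(u0)
    h = 1e-5
    for i in range(len(u0)):
        up, um = u0.copy(), u0.copy()
        up[i] += h
        um[i] -= h
        fd = (ctx.energy_and_gradient(up)[0] - ctx.energy_and_gradient(um)[0]) / (
            2 * h
        )
        denom = max(1e-8, abs(fd) + abs(grad[i]))
        assert abs(grad[i] - fd) / denom < 1e-4


def test_alpha_zero_decouples_regions():
    ctx, u0 = random_energy_instance(seed=7, alpha=0.0)
    e_total, _ = ctx.energy_and_gradient(u0)
    # evaluate each region's data term independently
    total = 0.0
    u = u0.reshape(ctx.n_regions, 3)
    for r in range(ctx.n_regions):
        sel = ctx.region_idx == r
        sub = ctx.coords[:, sel] + u[r][:, None]
        from svflow.flow_energy import _clamp

        vals = ndimage.map_coordinates(ctx.target, _clamp(sub, ctx.target.shape),
                                       order=1, mode="nearest")
        total += ctx.rho_d(ctx.is_vals[sel] - vals)[0].sum()
    np.testing.assert_allclose(e_total, total, rtol=1e-12)


def test_l2_penalty_is_plain_quadratic():
    ctx, u0 = random_energy_instance(seed=9, penalty="l2")
    val, der = ctx.rho_d(np.array([-3.0, 0.5, 10.0]))
    np.testing.assert_allclose(val, [4.5, 0.125, 50.0])
    np.testing.assert_allclose(der, [-3.0, 0.5, 10.0])
    e, g = ctx.energy_and_gradient(u0)
    assert np.isfinite(e) and np.isfinite(g).all()


def test_energy_invariant_under_region_relabeling():
    ctx, u0 = random_energy_instance(seed=21)
    k = ctx.n_regions
    perm = np.random.default_rng(0).permutation(k)
    inv = np.argsort(perm)
    ctx2_region_idx = inv[ctx.region_idx]
    import dataclasses

    ctx2 = dataclasses.replace(
        ctx,
        region_idx=ctx2_region_idx,
        edges=inv[ctx.edges] if len(ctx.edges) else ctx.edges,
    )
    u = u0.reshape(k, 3)
    e1, g1 = ctx.energy_and_gradient(u.ravel())
    e2, g2 = ctx2.energy_and_gradient(u[perm].ravel())
    np.testing.assert_allclose(e1, e2, rtol=1e-12)
    np.testing.assert_allclose(g1.reshape(k, 3), g2.reshape(k, 3)[inv],
                               rtol=1e-9, atol=1e-12)


def test_nan_params_raise_numeric_error():
    ctx, u0 = random_energy_instance(seed=3)
    u0[0] = np.nan
    with pytest.raises(FloatingPointError):
        ctx.energy_and_gradient(u0)
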