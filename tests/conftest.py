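"""Shared fixtures: small seeded synthetic volume pairs.

Expensive simulations and flow estimates are session-scoped so several
tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from svflow import (
    FlowConfig,
    Volume,
    division_config,
    embryo_small_config,
    estimate_flow,
    simulate_opposing_pair,
    simulate_pair,
    truth_to_ground_truth,
)

DRIFT = (1.0, 2.5, -1.5)  # z, y, x voxels


@pytest.fixture(scope="session")
def embryo_static():
    """Embryo-small pair with no motion (frames differ only by noise)."""
    cfg = embryo_small_config(seed=11, drift=(0.0, 0.0, 0.0))
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def embryo_drift():
    """Embryo-small pair rigidly translated by a known subvoxel vector."""
    cfg = embryo_small_config(seed=12, drift=DRIFT)
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def embryo_drift_result(embryo_drift):
    src, tgt, _ = embryo_drift
    return estimate_flow(src, tgt, cfg=FlowConfig())


@pytest.fixture(scope="session")
def division_pair():
    cfg = division_config(seed=13)
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def opposing_pair():
    """Two groups drifting oppositely, separated by > d_max."""
    cfg = embryo_small_config(seed=14, n_nuclei=60)
    return simulate_opposing_pair(
        cfg, drift_a=(0.0, 2.0, 1.5), drift_b=(0.0, -2.0, -1.5), gap_iso=32.0
    )


@pytest.fixture()
def two_blob_volume():
    """Two bright separated 3D Gaussian nuclei on a dark background."""
    shape = (16, 40, 40)
    zz, yy, xx = np.indices(shape, dtype=float)
    blob = lambda c, s: np.exp(
        -(((zz - c[0]) * 2) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        / (2 * s**2)
    )
    data = 100.0 * blob((8, 10, 10), 4.0) + 100.0 * blob((8, 30, 30), 4.0)
    return Volume(data, (2.0, 1.0, 1.0))
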