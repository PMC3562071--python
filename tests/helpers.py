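"""Small instance builders shared between unit and acceptance tests."""

from __future__ import annotations

import numpy as np

from svflow import Volume, build_graph, edge_weights
from svflow.flow_energy import Penalty, build_energy_context
from svflow.supervoxel import LabelPartition, region_table


def random_energy_instance(seed: int, alpha: float = 0.7,
                           penalty: str = "huber"):
    """A small seeded 2-3 region energy instance on random volumes."""
    rng = np.random.default_rng(seed)
    shape = (10, 12, 11)
    src = Volume(rng.random(shape) * 50 + 10, (2.0, 1.0, 1.0))
    tgt = Volume(rng.random(shape) * 50 + 10, (2.0, 1.0, 1.0))
    lab = np.zeros(shape, np.int32)
    lab[2:5, 2:6, 2:6] = 1
    lab[6:9, 5:9, 4:8] = 2
    if rng.random() > 0.3:
        lab[2:5, 7:10, 6:9] = 3
    labels = LabelPartition(lab, "grid", 3)
    graph = edge_weights(build_graph(region_table(labels, src), d_max=25.0))
    ctx = build_energy_context(
        src, tgt, labels, graph,
        Penalty(penalty, 5.0), Penalty(penalty, 1.0), alpha=alpha,
    )
    u0 = rng.uniform(-1.8, 1.8, ctx.n_params) + 0.13
    return ctx, u0


def shifted_blob_pair(shift=(1.0, 2.0, -1.0), shape=(16, 20, 20)):
    """Source blob and a target shifted by an integer vector, one region
    kept well inside the volume so boundary clamping never engages."""
    zz, yy, xx = np.indices(shape, dtype=float)
    c = np.array([shape[0] / 2, shape[1] / 2, shape[2] / 2])

    def blob(center):
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        return 100.0 * np.exp(-d2 / (2 * 2.0**2))

    src = Volume(blob(c), (1.0, 1.0, 1.0))
    tgt = Volume(blob(c + np.asarray(shift)), (1.0, 1.0, 1.0))
    lab = (src.data > 20.0).astype(np.int32)
    labels = LabelPartition(lab, "grid", 5)
    graph = edge_weights(build_graph(region_table(labels, src), d_max=25.0))
    ctx = build_energy_context(src, tgt, labels, graph,
                               Penalty("huber", 5.0), Penalty("huber", 1.0))
    return ctx, np.asarray(shift, float)


def brute_force_integer_minimizer(ctx, radius: int = 4) -> np.ndarray:
    """Exhaustive integer-grid search for a single-region instance."""
    assert ctx.n_regions == 1
    best, best_e = None, np.inf
    r = range(-radius, radius + 1)
    for dz in r:
        for dy in r:
            for dx in r:
                e, _ = ctx.energy_and_gradient(np.array([dz, dy, dx], float))
                if e < best_e:
                    best, best_e = np.array([dz, dy, dx], float), e
    return best
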