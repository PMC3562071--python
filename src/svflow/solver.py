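"""Coarse-to-fine estimation of the super-voxel flow.

The pipeline: pre-smooth and jointly normalize the volume pair, mask the
background, partition the foreground into super-voxels, build a Gaussian
pyramid of volumes/mask/labels, solve the region-translation energy with
L-BFGS at each level from coarse to fine (initializing each level from
the upsampled previous solution), and finally densify the per-region
translations into a per-voxel flow field.

The pyramid uses a fixed per-axis factor of 2, skipping axes that are
already 4 voxels or shorter (thin anisotropic Z stacks).  Masks are
downsampled with an any-foreground rule and labels by majority vote among
foreground children, so region identities are preserved across levels;
regions that vanish at a coarse level are re-initialized from the mean of
their graph neighbors when returning to the finer level.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .flow_energy import EnergyContext, Penalty, presmooth
from .foreground import threshold_mask
from .mrf_graph import face_adjacency_graph
from .supervoxel import (
    LabelPartition,
    RegionTable,
    grid_partition,
    region_table,
    slic_supervoxels,
    voxel_partition,
    watershed_partition,
)
from .volume_io import FlowField, Mask, Volume

__all__ = ["FlowConfig", "Pyramid", "build_pyramid", "solve_level",
           "estimate_flow", "FlowResult"]

log = logging.getLogger("svflow")


@dataclass
class FlowConfig:
    """All tunable parameters of the flow pipeline.

    Defaults follow the reference operating point: three pyramid levels,
    ``d_max = 25`` isotropic voxels (slightly above the typical
    nearest-neighbor distance of adjacent nuclei), SLIC super-voxels of
    nominal step 5 voxels, Huber penalties with ``delta_D = 5`` intensity
    units (on the [0, 255] normalized scale; intensities are well
    preserved between frames) and ``delta_S = 1`` voxel.
    """

    levels: int = 3
    d_max: float = 25.0
    step: float = 5.0
    alpha: float = 1.0
    lambda0: float = 1.0
    penalty: str = "huber"
    huber_data: float = 5.0
    huber_smooth: float = 1.0
    sigma: float = 1.0
    max_iter: int = 200
    gtol: float = 1e-5
    lbfgs_memory: int = 10
    partition: str = "slic"
    slic_compactness: float = 10.0
    threshold: float | str = "otsu"
    min_component: int = 27
    grad_mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.partition not in ("slic", "grid", "watershed", "voxel"):
            raise ValueError(f"unknown partition {self.partition!r}")
        if self.penalty not in ("huber", "l2"):
            raise ValueError(f"unknown penalty {self.penalty!r}")

    def penalties(self) -> tuple[Penalty, Penalty]:
        return (Penalty(self.penalty, self.huber_data),
                Penalty(self.penalty, self.huber_smooth))


@dataclass
class Level:
    """One pyramid level: volumes, labels and derived graph quantities."""

    source: Volume
    target: Volume
    labels: np.ndarray            # global region ids, 0 = background
    accum_factor: np.ndarray      # per-axis accumulated downsampling
    iso_factors: np.ndarray       # level voxel units -> finest isotropic units
    sizes: np.ndarray             # (K,) voxel counts at this level (0 = absent)
    present: np.ndarray           # (K,) bool
    edges: np.ndarray             # (E, 2) global region indices
    lambdas: np.ndarray           # (E,)
    smooth_scale: float = 1.0     # mean present region size at this level

    @property
    def shape(self) -> tuple[int, ...]:
        return self.source.shape


@dataclass
class Pyramid:
    """Finest-first list of levels sharing one global region id set."""

    levels: list[Level]
    n_regions: int

    def __len__(self) -> int:
        return len(self.levels)


def _downsample_volume(data: np.ndarray, ds: np.ndarray) -> np.ndarray:
    sigma = np.where(ds, 1.0, 0.0)
    if sigma.any():
        data = ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
    sl = tuple(slice(None, None, 2) if d else slice(None) for d in ds)
    return data[sl]


def _block_any(mask: np.ndarray, ds: np.ndarray) -> np.ndarray:
    """Coarse voxel is foreground if any child is."""
    out = mask
    for axis in range(mask.ndim):
        if not ds[axis]:
            continue
        n = out.shape[axis]
        if n % 2:
            pad = [(0, 0)] * out.ndim
            pad[axis] = (0, 1)
            out = np.pad(out, pad, mode="constant")
        a = np.moveaxis(out, axis, 0)
        a = a.reshape(-1, 2, *a.shape[1:])
        out = np.moveaxis(a.any(axis=1), 0, axis)
    return out


def _majority_labels(labels: np.ndarray, ds: np.ndarray,
                     coarse_shape: tuple[int, ...]) -> np.ndarray:
    """Majority vote among foreground children; 0 where no child is fg."""
    fg = np.nonzero(labels > 0)
    if len(fg[0]) == 0:
        return np.zeros(coarse_shape, dtype=np.int32)
    coarse_idx = tuple(
        (c // 2 if ds[a] else c) for a, c in enumerate(fg)
    )
    flat = np.ravel_multi_index(coarse_idx, coarse_shape)
    labs = labels[fg].astype(np.int64)
    pairs, counts = np.unique(np.stack([flat, labs]), axis=1, return_counts=True)
    # order by (voxel, count, label): last entry per voxel is the winner,
    # ties broken deterministically toward the larger label id
    order = np.lexsort((pairs[1], counts, pairs[0]))
    pairs, counts = pairs[:, order], counts[order]
    last = np.append(np.nonzero(np.diff(pairs[0]))[0], len(counts) - 1)
    out = np.zeros(coarse_shape, dtype=np.int32).ravel()
    out[pairs[0, last]] = pairs[1, last]
    return out.reshape(coarse_shape)


def _level_geometry(
    labels: np.ndarray,
    k_global: int,
    iso_factors: np.ndarray,
    d_max: float,
    lambda0: float,
    partition_method: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Sizes, presence, edges, weights and mean region size for one level.

    Centroids are expressed in finest-level isotropic units, so ``d_max``
    keeps one fixed meaning at every pyramid level.
    """
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k_global + 1)[1:].astype(np.int64)
    present = sizes > 0
    if not present.any():
        return sizes, present, np.zeros((0, 2), int), np.zeros(0), 1.0
    coords = np.indices(labels.shape).reshape(labels.ndim, -1)
    cent = np.full((k_global, labels.ndim), np.nan)
    for a in range(labels.ndim):
        s = np.bincount(flat, weights=coords[a], minlength=k_global + 1)[1:]
        cent[present, a] = s[present] / sizes[present]
    cent_iso = cent * iso_factors

    if partition_method == "voxel":
        part = LabelPartition(labels, "voxel", 1.0)
        table = RegionTable(np.arange(1, k_global + 1, dtype=np.int32), sizes,
                            cent_iso, cent, np.zeros(k_global))
        graph = face_adjacency_graph(part, table, d_max)
        edges, dists = graph.edges, graph.dists
    else:
        idx = np.flatnonzero(present)
        tree = cKDTree(cent_iso[idx])
        pairs = tree.query_pairs(r=d_max, output_type="ndarray")
        if len(pairs):
            edges = idx[pairs]
            dists = np.linalg.norm(cent_iso[edges[:, 0]] - cent_iso[edges[:, 1]],
                                   axis=1)
        else:
            edges, dists = np.zeros((0, 2), int), np.zeros(0)
    mean_size = float(sizes[present].mean())
    if len(edges):
        # weight uses sizes of present endpoints; mean over present regions
        size_min = np.minimum(sizes[edges[:, 0]], sizes[edges[:, 1]])
        lambdas = lambda0 * np.exp(-dists / d_max) * size_min / mean_size
    else:
        lambdas = np.zeros(0)
    return sizes, present, edges, lambdas, mean_size


def build_pyramid(
    source: Volume,
    target: Volume,
    mask: Mask,
    labels: LabelPartition,
    cfg: FlowConfig,
) -> Pyramid:
    """Build the finest-first Gaussian pyramid used by the solver.

    Volumes are Gaussian-antialiased then strided by 2 (per eligible
    axis); the mask follows the any-foreground rule and labels a majority
    vote among foreground children, so the same region id set is shared
    by all levels.
    """
    k_global = labels.n_regions
    base_iso = source.iso_scale
    accum = np.ones(source.ndim, dtype=np.int64)
    lab = labels.labels
    src, tgt, msk = source.data, target.data, mask.data
    levels: list[Level] = []
    for li in range(cfg.levels):
        if li > 0:
            ds = np.array([n > 4 for n in src.shape])
            if ds.any() and any(
                math.ceil(n / 2) < 4 for n, d in zip(src.shape, ds) if d
            ):
                ds = np.array([n > 4 and math.ceil(n / 2) >= 4 for n in src.shape])
            if not ds.any():
                warnings.warn(
                    f"pyramid clamped to {li} levels (volume too small)",
                    stacklevel=2,
                )
                break
            src = _downsample_volume(src, ds)
            tgt = _downsample_volume(tgt, ds)
            msk = _block_any(msk, ds)
            lab = _majority_labels(lab, ds, src.shape)
            accum = accum * np.where(ds, 2, 1)
        iso_factors = accum * base_iso
        scale_lvl = tuple(np.asarray(source.scale) * accum)
        sizes, present, edges, lambdas, mean_size = _level_geometry(
            lab, k_global, iso_factors, cfg.d_max, cfg.lambda0, cfg.partition
        )
        levels.append(Level(
            source=Volume(src, scale_lvl),
            target=Volume(tgt, scale_lvl),
            labels=lab,
            accum_factor=accum.copy(),
            iso_factors=iso_factors,
            sizes=sizes,
            present=present,
            edges=edges,
            lambdas=lambdas,
            smooth_scale=mean_size,
        ))
    return Pyramid(levels, k_global)


def solve_level(
    ctx: EnergyContext, init: np.ndarray, cfg: FlowConfig
) -> tuple[np.ndarray, dict]:
    """Minimize one level's energy with L-BFGS from ``init``.

    Returns translations with energy no larger than at ``init``; a failed
    line search degrades to the best iterate (never raises).
    """
    init = np.asarray(init, dtype=np.float64).ravel()
    n = len(init)
    e0, _ = ctx.energy_and_gradient(init)
    if n == 0:
        return init, {"energy_init": e0, "energy_final": e0, "n_iter": 0,
                      "status": "empty"}
    res = minimize(
        ctx.energy_and_gradient,
        init,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": cfg.max_iter,
            "maxcor": cfg.lbfgs_memory,
            "gtol": cfg.gtol * math.sqrt(n),
            "ftol": 1e-12,
        },
    )
    out = res.x
    e1 = float(res.fun)
    status = res.message if isinstance(res.message, str) else str(res.message)
    if not np.all(np.isfinite(out)) or e1 > e0:
        warnings.warn(f"L-BFGS did not descend ({status}); keeping init",
                      stacklevel=2)
        out, e1 = init, e0
    return out, {"energy_init": float(e0), "energy_final": e1,
                 "n_iter": int(res.nit), "status": status}


def _make_partition(vol: Volume, mask: Mask, cfg: FlowConfig) -> LabelPartition:
    if cfg.partition == "slic":
        return slic_supervoxels(vol, mask, step=cfg.step,
                                compactness=cfg.slic_compactness)
    if cfg.partition == "grid":
        return grid_partition(mask, step=int(cfg.step))
    if cfg.partition == "watershed":
        return watershed_partition(vol, mask, seed_spacing=cfg.step)
    return voxel_partition(mask)


@dataclass
class FlowResult:
    """Output of :func:`estimate_flow`."""

    flow: FlowField
    table: pd.DataFrame            # one row per region: id, size, centroid, u
    labels: LabelPartition
    mask: Mask
    regions: RegionTable
    config: FlowConfig
    level_log: list[dict] = field(default_factory=list)


def estimate_flow(
    source: Volume,
    target: Volume,
    mask: Mask | None = None,
    cfg: FlowConfig | None = None,
) -> FlowResult:
    """Full pipeline: mask, partition, coarse-to-fine solve, densify.

    The two volumes must have identical shape and scale.  Returns the
    per-voxel :class:`~svflow.volume_io.FlowField` (voxel units of the
    finest level; background invalid/zero) together with the per-region
    translation table.
    """
    cfg = cfg or FlowConfig()
    if source.shape != target.shape:
        raise ValueError(f"shape mismatch {source.shape} vs {target.shape}")

    # shared affine normalization to [0, 255] so penalty scales are stable
    lo = min(source.data.min(), target.data.min())
    hi = max(source.data.max(), target.data.max())
    span = hi - lo if hi > lo else 1.0

    def norm(v: Volume) -> Volume:
        return Volume((v.data - lo) / span * 255.0, v.scale, v.dtype_origin)

    src = presmooth(norm(source), cfg.sigma)
    tgt = presmooth(norm(target), cfg.sigma)

    if mask is None:
        mask = threshold_mask(src, threshold=cfg.threshold,
                              min_component=cfg.min_component, smooth_sigma=0.0)
    else:
        mask.validate_against(source)

    nd = source.ndim
    if not mask.data.any():
        empty_flow = FlowField(np.zeros((nd, *source.shape)),
                               np.zeros(source.shape, bool), scale=source.scale)
        empty_labels = LabelPartition(np.zeros(source.shape, np.int32),
                                      cfg.partition, cfg.step)
        return FlowResult(empty_flow, pd.DataFrame(), empty_labels, mask,
                          region_table(empty_labels, src), cfg)

    labels = _make_partition(src, mask, cfg)
    regions = region_table(labels, src)
    pyr = build_pyramid(src, tgt, mask, labels, cfg)
    k = pyr.n_regions
    rho_d, rho_s = cfg.penalties()

    u = np.zeros((k, nd))
    level_log: list[dict] = []
    prev_present: np.ndarray | None = None
    for li in range(len(pyr) - 1, -1, -1):
        lvl = pyr.levels[li]
        if prev_present is not None:
            ratio = prev_accum / lvl.accum_factor  # 2 on downsampled axes
            u = u * ratio
            newly = lvl.present & ~prev_present
            if newly.any():
                u[newly] = 0.0
                if len(lvl.edges):
                    u = _fill_from_neighbors(u, lvl.edges, newly, prev_present)
        ctx = EnergyContext(
            coords=np.stack([c.astype(float)
                             for c in np.nonzero(lvl.labels > 0)], axis=0),
            is_vals=lvl.source.data[lvl.labels > 0],
            region_idx=lvl.labels[lvl.labels > 0].astype(np.int64) - 1,
            n_regions=k,
            target=lvl.target.data,
            diffs=[np.diff(lvl.target.data, axis=a) for a in range(nd)],
            edges=lvl.edges,
            lambdas=lvl.lambdas,
            iso_factors=lvl.iso_factors,
            rho_d=rho_d,
            rho_s=rho_s,
            alpha=cfg.alpha,
            smooth_scale=lvl.smooth_scale,
            grad_mode=cfg.grad_mode,
        )
        sol, info = solve_level(ctx, u.ravel(), cfg)
        u = sol.reshape(k, nd)
        info.update(level=li, shape=lvl.shape,
                    n_regions=int(lvl.present.sum()), n_edges=len(lvl.edges))
        log.info("level %(level)d shape=%(shape)s regions=%(n_regions)d "
                 "edges=%(n_edges)d E %(energy_init).4g -> %(energy_final).4g "
                 "(%(n_iter)d it)", info)
        level_log.append(info)
        prev_present = lvl.present
        prev_accum = lvl.accum_factor

    vectors = np.zeros((nd, *source.shape))
    fg = labels.labels > 0
    for a in range(nd):
        vectors[a][fg] = u[labels.labels[fg] - 1, a]
    flow = FlowField(vectors, fg, scale=source.scale)
    table = pd.DataFrame({"id": regions.ids, "size": regions.sizes})
    axes = "zyx"[-nd:]
    for a, name in enumerate(axes):
        table[f"c_{name}"] = regions.centroids_vox[:, a]
    for a, name in enumerate(axes):
        table[f"u_{name}"] = u[:, a]
    return FlowResult(flow, table, labels, mask, regions, cfg, level_log)


def _fill_from_neighbors(u: np.ndarray, edges: np.ndarray, newly: np.ndarray,
                         informed: np.ndarray) -> np.ndarray:
    """Initialize regions absent at the coarser level from the mean
    translation of their graph neighbors that were present there."""
    u = u.copy()
    k = len(u)
    acc = np.zeros_like(u)
    cnt = np.zeros(k)
    for a, b in ((0, 1), (1, 0)):
        sel = newly[edges[:, a]] & informed[edges[:, b]]
        if sel.any():
            np.add.at(acc, edges[sel, a], u[edges[sel, b]])
            np.add.at(cnt, edges[sel, a], 1.0)
    has = cnt > 0
    u[has] = acc[has] / cnt[has, None]
    u[newly & ~has] = 0.0
    return u
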