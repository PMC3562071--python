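"""End-point-error evaluation of a flow field against per-nucleus truth.

Nuclei are textureless, so voxel-to-voxel correspondences cannot be
annotated; the ground truth instead records the center-of-mass
displacement of each nucleus.  The estimated displacement of a nucleus is
the mean flow over all voxels in its segmentation mask, and accuracy is
the end-point error

    EE = || u_hat(c) - w(c) ||_2

at each nucleus centroid ``c``, in isotropic units.  Reports include the
EE normalized by each nucleus' equivalent diameter (as a rule of thumb,
normalized EE below 0.5 is good for quantitative use, above 1.0 is not),
empirical percentiles, the cumulative error distribution and its area
under the curve (AUC) scaled so that a perfect flow scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import FlowField, read_label_volume

__all__ = [
    "GroundTruth",
    "EEReport",
    "nucleus_flow",
    "endpoint_error",
    "ee_report",
    "evaluate_flow",
    "load_ground_truth",
]

GOOD_NEE = 0.5   # normalized EE below this: good for quantitative use
BAD_NEE = 1.0    # above this: not good


@dataclass
class GroundTruth:
    """Per-nucleus segmentation masks, centroids and true displacements.

    ``label_volume`` assigns each voxel to a nucleus id (0 background).
    ``table`` has one row per evaluated nucleus: ``id`` (a label id in the
    volume; several rows may share one id, e.g. the two daughters of a
    division), centroid ``c_*`` (finest-level voxel coordinates), true
    displacement ``w_*`` (voxel units) and ``diameter`` — the equivalent
    diameter ``(6 V / pi)^(1/3)`` in 3D or ``2 (V / pi)^(1/2)`` in 2D of
    the mask volume ``V`` in isotropic units.
    """

    label_volume: np.ndarray
    table: pd.DataFrame
    scale: tuple[float, ...]

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if len(self.table):
            counts = np.bincount(self.label_volume.ravel())
            for lid in self.table["id"]:
                if lid >= len(counts) or counts[lid] == 0:
                    raise ValueError(f"nucleus id {lid} has an empty mask")

    @property
    def iso_scale(self) -> np.ndarray:
        s = np.asarray(self.scale, dtype=float)
        return s / s.min()

    @property
    def axes(self) -> str:
        return "zyx"[-self.label_volume.ndim:]


def equivalent_diameter(volume_iso: float | np.ndarray, ndim: int) -> np.ndarray:
    """Diameter of the sphere (circle) with the given isotropic volume."""
    v = np.asarray(volume_iso, dtype=float)
    if ndim == 3:
        return np.cbrt(6.0 * v / np.pi)
    return 2.0 * np.sqrt(v / np.pi)


def load_ground_truth(
    labels_path: str | Path,
    displacements_path: str | Path,
    scale: tuple[float, ...] | None = None,
) -> GroundTruth:
    """Read ground truth from a label TIFF plus a displacement TSV.

    The TSV has columns ``id`` and ``w_z, w_y, w_x`` (``w_y, w_x`` in 2D)
    in voxel units.  Diameters are derived from the mask volumes.
    """
    lab = read_label_volume(labels_path)
    nd = lab.ndim
    if scale is None:
        scale = (1.0,) * nd
    tsv = pd.read_csv(displacements_path, sep="\t")
    axes = "zyx"[-nd:]
    iso = np.asarray(scale, float) / min(scale)
    counts = np.bincount(lab.ravel())
    rows = []
    for _, r in tsv.iterrows():
        lid = int(r["id"])
        if lid <= 0 or lid >= len(counts) or counts[lid] == 0:
            raise ValueError(f"displacement row refers to missing label {lid}")
        vox = np.argwhere(lab == lid)
        cent = vox.mean(axis=0)
        vol_iso = counts[lid] * float(np.prod(iso))
        row = {"id": lid, "diameter": float(equivalent_diameter(vol_iso, nd))}
        row.update({f"c_{a}": cent[i] for i, a in enumerate(axes)})
        row.update({f"w_{a}": float(r[f"w_{a}"]) for a in axes})
        rows.append(row)
    return GroundTruth(lab, pd.DataFrame(rows), tuple(scale))


def nucleus_flow(flow: FlowField, gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Mean estimated displacement over each nucleus mask, voxel units.

    Background (invalid) voxels are excluded from the mean; a nucleus
    whose mask contains no valid flow voxel gets a zero estimate and is
    flagged in the returned boolean array.
    """
    nd = flow.ndim
    if gt.label_volume.shape != flow.shape:
        raise ValueError(
            f"ground-truth shape {gt.label_volume.shape} != flow {flow.shape}"
        )
    n_max = int(gt.label_volume.max(initial=0))
    flat = gt.label_volume.ravel()
    valid = flow.valid.ravel()
    sel = (flat > 0) & valid
    counts = np.bincount(flat[sel], minlength=n_max + 1)
    sums = np.stack([
        np.bincount(flat[sel], weights=flow.vectors[a].ravel()[sel],
                    minlength=n_max + 1)
        for a in range(nd)
    ], axis=1)
    ids = gt.table["id"].to_numpy()
    covered = counts[ids] > 0
    u_hat = np.zeros((len(ids), nd))
    u_hat[covered] = sums[ids[covered]] / counts[ids[covered], None]
    return u_hat, ~covered


def endpoint_error(u_hat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Euclidean end-point error per nucleus (rowwise)."""
    u_hat = np.atleast_2d(np.asarray(u_hat, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if u_hat.shape != w.shape:
        raise ValueError(f"shape mismatch {u_hat.shape} vs {w.shape}")
    return np.linalg.norm(u_hat - w, axis=1)


@dataclass
class EEReport:
    """Summary of an EE distribution.

    ``auc`` is the area under the cumulative distribution of normalized
    EE on ``[0, x_max]``, divided by ``x_max`` so that a perfect flow
    scores exactly 1 and errors at or beyond ``x_max`` score 0.
    """

    per_nucleus: pd.DataFrame
    percentiles: dict[int, float]
    auc: float
    x_max: float
    curve: pd.DataFrame

    @property
    def mean_ee(self) -> float:
        return float(self.per_nucleus["ee"].mean())

    @property
    def mean_normalized_ee(self) -> float:
        return float(self.per_nucleus["normalized_ee"].mean())


def _quality_band(nee: np.ndarray) -> np.ndarray:
    out = np.where(nee < GOOD_NEE, "good", "acceptable")
    return np.where(nee > BAD_NEE, "bad", out)


def ee_report(
    ees: np.ndarray,
    diameters: np.ndarray,
    x_max: float = 2.0,
    curve_samples: int = 201,
) -> EEReport:
    """Percentiles, cumulative curve and AUC of an EE sample.

    The AUC integrates the empirical cumulative distribution ``F`` of the
    diameter-normalized EE exactly (the ECDF is a step function, so the
    integral has the closed form ``mean(max(0, x_max - nee)) / x_max``);
    the sampled ``curve`` is provided for plotting only.
    """
    ees = np.asarray(ees, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    if len(ees) == 0:
        raise ValueError("cannot report on an empty EE sample")
    if np.any(diameters <= 0):
        raise ValueError("diameters must be positive")
    nee = ees / diameters
    percentiles = {p: float(np.percentile(ees, p)) for p in (90, 95, 99, 100)}
    auc = float(np.mean(np.clip(x_max - nee, 0.0, None)) / x_max)
    xs = np.linspace(0.0, x_max, curve_samples)
    fs = np.searchsorted(np.sort(nee), xs, side="right") / len(nee)
    per_nucleus = pd.DataFrame({
        "ee": ees,
        "normalized_ee": nee,
        "quality": _quality_band(nee),
    })
    return EEReport(per_nucleus, percentiles, auc, x_max,
                    pd.DataFrame({"x": xs, "F": fs}))


def evaluate_flow(flow: FlowField, gt: GroundTruth, x_max: float = 2.0) -> EEReport:
    """Score a flow field against ground truth (isotropic units).

    Converts both the per-nucleus mean flow and the true displacements
    from voxel units into isotropic units with the ground truth's scale
    before computing EE, so anisotropic sampling does not distort the
    metric.
    """
    axes = gt.axes
    u_hat, uncovered = nucleus_flow(flow, gt)
    w = gt.table[[f"w_{a}" for a in axes]].to_numpy(dtype=float)
    iso = gt.iso_scale
    ees = endpoint_error(u_hat * iso, w * iso)
    report = ee_report(ees, gt.table["diameter"].to_numpy(dtype=float), x_max)
    report.per_nucleus.insert(0, "id", gt.table["id"].to_numpy())
    report.per_nucleus["no_flow_coverage"] = uncovered
    return report
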