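"""Bootstrap consolidation and 2D spectral projections.

The bootstrap ensemble of a voxel holds up to ``n_bootstrap x 10`` discrete
components.  To display one distribution per voxel, components are grouped
across bootstraps by k-means with the L1 metric (k-medians) on the
max-normalized features (Diso(omega_ref), D_Delta^2(omega_ref), theta, phi,
R1, R2); each cluster is then collapsed into a single representative
component (weighted mean of each parameter, median of the member weights).
Representative components are deposited onto 64 x 64 meshes in the selected
two-parameter plane; ROI-characteristic distributions sum voxel meshes per
scan, normalize, and average across scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import VoxelDistribution, diso_ddeltasq_at, PARAM_NAMES
from .inversion import VoxelInversionResult

__all__ = [
    "ProjectionMesh",
    "PLANES",
    "cluster_components",
    "consolidate",
    "consolidate_result",
    "project_2d",
    "roi_characteristic_distribution",
]

log = logging.getLogger(__name__)

MESH_SIZE = 64
_COL = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Supported projection planes and their default axis (range, scale).
PLANES = {
    "diso-ddeltasq": (((0.05, 5.0), "log"), ((0.0, 1.0), "linear")),
    "diso-r1": (((0.05, 5.0), "log"), ((0.2, 2.0), "log")),
    "diso-r2": (((0.05, 5.0), "log"), ((1.0, 30.0), "log")),
    "ddeltasq-r1": (((0.0, 1.0), "linear"), ((0.2, 2.0), "log")),
    "ddeltasq-r2": (((0.0, 1.0), "linear"), ((1.0, 30.0), "log")),
}


@dataclass
class ProjectionMesh:
    """64 x 64 normalized weight mesh in a two-parameter plane."""

    plane: str
    grid: np.ndarray
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    x_scale: str = "log"
    y_scale: str = "linear"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (MESH_SIZE, MESH_SIZE):
            raise ValueError(f"mesh must be {MESH_SIZE}x{MESH_SIZE}")


def _pooled_features(result: VoxelInversionResult, omega_ref: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pool all bootstrap components; returns (features (n, 6), weights)."""
    feats, wts = [], []
    for sol in result.solutions:
        diso, dd2 = diso_ddeltasq_at(sol.params, omega_ref)
        diso, dd2 = diso[0], dd2[0]
        feats.append(np.column_stack([
            diso, dd2,
            sol.params[:, _COL["theta"]], sol.params[:, _COL["phi"]],
            sol.params[:, _COL["r1"]], sol.params[:, _COL["r2"]],
        ]))
        wts.append(sol.weights)
    return np.vstack(feats), np.concatenate(wts)


def cluster_components(result: VoxelInversionResult, omega_ref: float,
                       k: int, seed: int = 0) -> np.ndarray:
    """Group pooled bootstrap components with L1 k-means (k-medians).

    Features are divided by their maximum over the pooled components so each
    column peaks at 1; Lloyd iteration alternates L1 nearest-centroid
    assignment and coordinate-wise median updates.  Deterministic given seed.
    """
    feats, _ = _pooled_features(result, omega_ref)
    n_distinct = len(np.unique(feats, axis=0))
    if k > n_distinct:
        raise ValueError(
            f"k = {k} exceeds the {n_distinct} distinct components available")
    maxes = np.abs(feats).max(axis=0)
    maxes[maxes == 0] = 1.0
    X = feats / maxes

    rng = np.random.default_rng(seed)
    # deterministic greedy spread initialization (k-means++-like, L1)
    centroids = [X[int(rng.integers(len(X)))]]
    for _ in range(1, k):
        d = np.min(np.stack([np.abs(X - c).sum(axis=1) for c in centroids]), axis=0)
        centroids.append(X[int(np.argmax(d))])
    C = np.array(centroids)

    labels = np.zeros(len(X), dtype=int)
    for _ in range(100):
        dist = np.abs(X[:, None, :] - C[None, :, :]).sum(axis=2)
        new_labels = np.argmin(dist, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                C[j] = np.median(members, axis=0)
    return labels


def consolidate(result: VoxelInversionResult, labels: np.ndarray
                ) -> VoxelDistribution:
    """Collapse each cluster to one component.

    Per cluster: weight-weighted mean of every parameter, median of the
    member weights.  Empty clusters are skipped with a log entry.
    """
    params_all = np.vstack([sol.params for sol in result.solutions])
    weights_all = np.concatenate([sol.weights for sol in result.solutions])
    if len(labels) != len(weights_all):
        raise ValueError("labels must cover all pooled components")
    reps_p, reps_w = [], []
    for j in np.unique(labels):
        sel = labels == j
        w = weights_all[sel]
        if w.sum() <= 0:
            log.info("cluster %d has zero weight; skipped", j)
            continue
        reps_p.append(np.average(params_all[sel], axis=0, weights=w))
        reps_w.append(np.median(w))
    if not reps_p:
        raise ValueError("no non-empty clusters to consolidate")
    return VoxelDistribution(np.array(reps_p), np.array(reps_w))


def default_k(result: VoxelInversionResult) -> int:
    """Median number of positive-weight components per bootstrap solution."""
    counts = [int(np.sum(sol.weights > 0)) for sol in result.solutions]
    return max(int(np.median(counts)), 1)


def consolidate_result(result: VoxelInversionResult, omega_ref: float,
                       k: int | None = None, seed: int = 0) -> VoxelDistribution:
    """Cluster + consolidate in one call; k defaults to :func:`default_k`."""
    kk = default_k(result) if k is None else k
    labels = cluster_components(result, omega_ref, kk, seed=seed)
    return consolidate(result, labels)


def _axis_coords(values: np.ndarray, rng: tuple[float, float], scale: str
                 ) -> np.ndarray:
    lo, hi = rng
    if scale == "log":
        with np.errstate(divide="ignore"):
            t = (np.log(np.maximum(values, 1e-300)) - np.log(lo)) \
                / (np.log(hi) - np.log(lo))
    else:
        t = (values - lo) / (hi - lo)
    # edge clipping: out-of-range components land in the nearest edge cell
    return np.clip((t * MESH_SIZE).astype(int), 0, MESH_SIZE - 1)


def project_2d(v: VoxelDistribution, plane: str, omega_ref: float,
               x_range: tuple[float, float] | None = None,
               y_range: tuple[float, float] | None = None) -> ProjectionMesh:
    """Deposit component weights on a 64 x 64 mesh, normalized to sum 1."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; choose from {sorted(PLANES)}")
    (xr_def, xs), (yr_def, ys) = PLANES[plane]
    xr = x_range or xr_def
    yr = y_range or yr_def
    diso, dd2 = diso_ddeltasq_at(v.params, omega_ref)
    diso, dd2 = diso[0], dd2[0]
    axes = {"diso": diso, "ddeltasq": dd2,
            "r1": v.params[:, _COL["r1"]], "r2": v.params[:, _COL["r2"]]}
    xname, yname = plane.split("-")
    ix = _axis_coords(axes[xname], xr, xs)
    iy = _axis_coords(axes[yname], yr, ys)
    grid = np.zeros((MESH_SIZE, MESH_SIZE))
    np.add.at(grid, (ix, iy), v.weights)
    tot = grid.sum()
    if tot > 0:
        grid /= tot
    return ProjectionMesh(plane, grid, xr, yr, xs, ys)


def roi_characteristic_distribution(meshes_per_scan: list[list[ProjectionMesh]]
                                    ) -> ProjectionMesh:
    """Average of per-scan normalized ROI sums of voxel meshes.

    ``meshes_per_scan[s]`` holds the voxel meshes of one ROI in scan s.  Per
    scan the voxel meshes are summed and normalized; the normalized scan
    meshes are then averaged.
    """
    if not meshes_per_scan or any(not scan for scan in meshes_per_scan):
        raise ValueError("every scan must contribute at least one voxel mesh")
    first = meshes_per_scan[0][0]
    acc = np.zeros_like(first.grid)
    for scan in meshes_per_scan:
        ssum = np.sum([m.grid for m in scan], axis=0)
        tot = ssum.sum()
        if tot <= 0:
            raise ValueError("scan with zero total mesh weight")
        acc += ssum / tot
    acc /= len(meshes_per_scan)
    return ProjectionMesh(first.plane, acc, first.x_range, first.y_range,
                          first.x_scale, first.y_scale)
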