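"""Scalar parameter maps derived from voxel-wise distribution ensembles.

Per voxel the pipeline reports the distribution means E[Diso], E[D_Delta^2],
E[R1], E[R2] (diffusion metrics evaluated at the low end of the encoding
window; relaxation rates are frequency-free), their frequency-dependence
differences Delta_omega[x] across the window, the spectral-bin signal
fractions fbin1-3 (approximately white matter, gray matter, CSF), and
bin-resolved relaxation means.  Every statistic is computed per bootstrap
replicate and median-aggregated, which robustifies against replicates that
land in spurious minima of the ill-conditioned inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import VoxelDistribution, diso_ddeltasq_at, PARAM_NAMES
from .inversion import VoxelInversionResult

__all__ = [
    "BinDefinition",
    "MAP_NAMES",
    "voxel_statistics",
    "bin_fractions",
    "bin_resolved_relaxation",
    "compute_maps",
    "roi_reduce",
    "majority_vote_roi",
    "OMEGA_LOW",
    "OMEGA_HIGH",
]

log = logging.getLogger(__name__)
_COL = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Low and high ends of the encoding frequency window (rad/s).
OMEGA_LOW = 2.0 * np.pi * 6.6
OMEGA_HIGH = 2.0 * np.pi * 21.0

MAP_NAMES = (
    "e_diso", "e_ddeltasq", "e_r1", "e_r2",
    "delta_e_diso", "delta_e_ddeltasq",
    "fbin1", "fbin2", "fbin3",
    "e_r1_bin1", "e_r1_bin2", "e_r1_bin3",
    "e_r2_bin1", "e_r2_bin2", "e_r2_bin3",
)


@dataclass
class BinDefinition:
    """Spectral bins in the (Diso, D_Delta^2) plane.

    bin1 (WM-like): Diso <= ``diso_split`` and D_Delta^2 > ``ddeltasq_split``;
    bin2 (GM-like): Diso <= ``diso_split`` and D_Delta^2 <= ``ddeltasq_split``;
    bin3 (CSF-like): Diso > ``diso_split``.

    Boundary values are assigned to the lower-index bin (bin2 at the
    anisotropy boundary, bins 1/2 at the diffusivity boundary), and the
    CSF bin includes D_Delta^2 = 0 so that a perfectly isotropic
    fast-diffusing component counts as CSF.  Bin membership is evaluated at
    ``omega_eval`` (rad/s), the lowest protocol frequency by default.
    """

    diso_split: float = 2.5
    ddeltasq_split: float = 0.25
    omega_eval: float = OMEGA_LOW

    def assign(self, diso: np.ndarray, ddeltasq: np.ndarray) -> np.ndarray:
        """Bin index (1, 2, or 3) per component."""
        diso = np.asarray(diso, float)
        ddeltasq = np.asarray(ddeltasq, float)
        out = np.full(diso.shape, 3, dtype=int)
        low = diso <= self.diso_split
        out[low & (ddeltasq > self.ddeltasq_split)] = 1
        out[low & (ddeltasq <= self.ddeltasq_split)] = 2
        return out


def _dist_bins(v: VoxelDistribution, bins: BinDefinition) -> np.ndarray:
    diso, dd2 = diso_ddeltasq_at(v.params, bins.omega_eval)
    return bins.assign(diso[0], dd2[0])


def bin_fractions(v: VoxelDistribution, bins: BinDefinition | None = None
                  ) -> tuple[float, float, float]:
    """Normalized weight in each spectral bin; sums to 1."""
    bins = bins or BinDefinition()
    tot = v.total_weight
    if tot <= 0:
        return (np.nan, np.nan, np.nan)
    idx = _dist_bins(v, bins)
    return tuple(float(v.weights[idx == j].sum() / tot) for j in (1, 2, 3))


def bin_resolved_relaxation(v: VoxelDistribution, bins: BinDefinition | None = None
                            ) -> dict[str, float]:
    """Weighted mean R1 and R2 restricted to each bin; NaN for empty bins."""
    bins = bins or BinDefinition()
    if v.total_weight <= 0:
        return {f"e_{r}_bin{j}": np.nan for r in ("r1", "r2") for j in (1, 2, 3)}
    idx = _dist_bins(v, bins)
    out = {}
    for j in (1, 2, 3):
        sel = idx == j
        w = v.weights[sel]
        for r in ("r1", "r2"):
            key = f"e_{r}_bin{j}"
            if w.sum() > 0:
                out[key] = float(np.average(v.params[sel, _COL[r]], weights=w))
            else:
                out[key] = np.nan
    return out


def _solution_stats(sol: VoxelDistribution, omega_low: float, omega_high: float,
                    bins: BinDefinition) -> dict[str, float]:
    w = sol.weights
    tot = w.sum()
    if tot <= 0:
        return {k: np.nan for k in MAP_NAMES}
    diso, dd2 = diso_ddeltasq_at(sol.params, [omega_low, omega_high])
    out = {
        "e_diso": np.average(diso[0], weights=w),
        "e_ddeltasq": np.average(dd2[0], weights=w),
        "e_r1": np.average(sol.params[:, _COL["r1"]], weights=w),
        "e_r2": np.average(sol.params[:, _COL["r2"]], weights=w),
        "delta_e_diso": np.average(diso[1], weights=w) - np.average(diso[0], weights=w),
        "delta_e_ddeltasq": np.average(dd2[1], weights=w) - np.average(dd2[0], weights=w),
    }
    f1, f2, f3 = bin_fractions(sol, bins)
    out.update({"fbin1": f1, "fbin2": f2, "fbin3": f3})
    out.update(bin_resolved_relaxation(sol, bins))
    return out


def voxel_statistics(result: VoxelInversionResult | VoxelDistribution,
                     omega_low: float = OMEGA_LOW,
                     omega_high: float = OMEGA_HIGH,
                     bins: BinDefinition | None = None) -> dict[str, float]:
    """Median-over-bootstraps scalar statistics of one voxel.

    E[x] is the weight-weighted mean over components; Delta_omega[x] is the
    difference of E[x] between the window's high and low frequencies.  Each
    statistic is computed per bootstrap replicate, then the median is taken
    (NaN-aware for bin-resolved metrics, whose bins may be empty in some
    replicates).  Bin fractions are renormalized after the median so they
    sum to 1.  Returns NaN sentinels if no replicate carries weight.
    """
    bins = bins or BinDefinition(omega_eval=omega_low)
    if isinstance(result, VoxelDistribution):
        sols = [result]
    else:
        sols = result.solutions
    if not sols:
        return {k: np.nan for k in MAP_NAMES}
    rows = [_solution_stats(s, omega_low, omega_high, bins) for s in sols]
    out = {}
    with np.errstate(invalid="ignore"):
        for k in MAP_NAMES:
            vals = np.array([r[k] for r in rows])
            out[k] = float(np.nanmedian(vals)) if not np.all(np.isnan(vals)) else np.nan
    fsum = out["fbin1"] + out["fbin2"] + out["fbin3"]
    if np.isfinite(fsum) and fsum > 0:
        for k in ("fbin1", "fbin2", "fbin3"):
            out[k] /= fsum
    return out


def compute_maps(results: dict[int, VoxelInversionResult], shape: tuple,
                 omega_low: float = OMEGA_LOW, omega_high: float = OMEGA_HIGH,
                 bins: BinDefinition | None = None) -> dict[str, np.ndarray]:
    """Assemble 3D parameter maps from per-voxel inversion results.

    ``results`` maps flat voxel indices (C order over ``shape``) to
    inversion results; voxels without a result are NaN.
    """
    maps = {k: np.full(shape, np.nan).ravel() for k in MAP_NAMES}
    for vi, res in results.items():
        stats = voxel_statistics(res, omega_low, omega_high, bins)
        for k in MAP_NAMES:
            maps[k][vi] = stats[k]
    return {k: v.reshape(shape) for k, v in maps.items()}


def roi_reduce(map_volume: np.ndarray, roi_mask: np.ndarray,
               fbin3_volume: np.ndarray | None = None,
               csf_threshold: float = 0.2) -> float:
    """Mean of a map over an ROI, excluding CSF-contaminated voxels.

    Voxels with estimated CSF signal fraction fbin3 > ``csf_threshold`` are
    removed before averaging.  Returns NaN (with a log entry) if the ROI is
    empty after filtering.
    """
    roi = np.asarray(roi_mask).astype(bool)
    sel = roi.copy()
    if fbin3_volume is not None:
        sel &= ~(np.asarray(fbin3_volume) > csf_threshold)
    vals = np.asarray(map_volume)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.warning("ROI empty after CSF-fraction filtering")
        return np.nan
    return float(vals.mean())


def majority_vote_roi(masks: list[np.ndarray], min_agreement: float = 0.5
                      ) -> np.ndarray:
    """Template ROI by majority vote across subjects/repetitions.

    A voxel belongs to the template ROI when at least ``min_agreement`` of
    the input masks include it (>= 50% agreement by default).
    """
    if not masks:
        raise ValueError("need at least one mask")
    stack = np.stack([np.asarray(m).astype(bool) for m in masks])
    return stack.mean(axis=0) >= min_agreement
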