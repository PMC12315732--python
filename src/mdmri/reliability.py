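"""Test-retest reliability and repeatability statistics.

Reliability is quantified by the single-measurement absolute-agreement
intraclass correlation ICC(A,1): the fraction of total variance attributable
to true differences between subjects, estimated from a two-way ANOVA with
subjects as rows and sessions as columns.  Repeatability is the
within-subject coefficient of variation CVws = sigma_ws / |mean|.
Bland-Altman summaries quantify test-retest bias.  Voxel-wise analyses use
mask-aware Gaussian smoothing (contributions from outside the brain mask are
excluded by kernel renormalization) and an outlier-trimming rule for heavy
tailed CVws distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BlandAltmanSummary",
    "icc_a1",
    "classify_icc",
    "cv_ws",
    "bland_altman",
    "trim_cv_distribution",
    "gaussian_smooth_masked",
    "fwhm_to_sigma",
    "icc_fwhm_sweep",
]


def _validate_table(values: np.ndarray) -> np.ndarray:
    t = np.asarray(values, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be n_subjects x k_sessions with n, k >= 2")
    if not np.all(np.isfinite(t)):
        raise ValueError("table entries must be finite")
    return t


def icc_a1(values: np.ndarray, clamp: bool = False) -> float:
    """ICC(A,1): single-measurement, absolute-agreement intraclass correlation.

    Two-way ANOVA decomposition into subjects (rows), sessions (columns),
    and error, combined as

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

    The raw value is returned by default (it can be negative); with
    ``clamp=True`` negative estimates are reported as zero, the convention
    used when summarizing.  Returns NaN when the table has no variance at
    all (ICC undefined).
    """
    t = _validate_table(values)
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((t - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if sst == 0 or denom == 0:
        return np.nan
    icc = (msr - mse) / denom
    if clamp:
        icc = max(icc, 0.0)
    return float(icc)


def classify_icc(icc: float) -> str:
    """Reliability category: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def cv_ws(values: np.ndarray) -> float:
    """Within-subject coefficient of variation sqrt(MSws) / |grand mean|.

    MSws is the within-subject mean squares; the absolute value of the mean
    is used because some derived parameters can be negative.  Zero indicates
    perfect repeatability.
    """
    t = _validate_table(values)
    n, k = t.shape
    grand = t.mean()
    if grand == 0:
        raise ValueError("grand mean is zero; CVws normalization degenerate")
    ms_ws = np.sum((t - t.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
    return float(np.sqrt(ms_ws) / abs(grand))


@dataclass
class BlandAltmanSummary:
    mean_difference: float
    ci_low: float
    ci_high: float
    relative_mean_difference_pct: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")


def bland_altman(test: np.ndarray, retest: np.ndarray) -> BlandAltmanSummary:
    """Test-retest bias with 1.96-SD limits of agreement.

    Reports the mean difference, mean +- 1.96 * SD of the differences, and
    the mean difference as a percentage of the grand mean over all entries.
    """
    a = np.asarray(test, dtype=float).ravel()
    b = np.asarray(retest, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("test and retest vectors must have equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    grand = float(np.concatenate([a, b]).mean())
    rel = bias / grand * 100.0 if grand != 0 else np.nan
    return BlandAltmanSummary(bias, bias - 1.96 * sd, bias + 1.96 * sd, rel)


def trim_cv_distribution(values: np.ndarray, density_threshold: float = 1e-3,
                         max_iter: int = 100
                         ) -> tuple[np.ndarray, int]:
    """Iteratively trim sparse histogram bins from a CVws distribution.

    Applied only to distributions whose maximum exceeds 1.0 (100%): build a
    histogram with automatically selected bins (Freedman-Diaconis width,
    Sturges fallback for tiny samples), drop the values falling in occupied
    bins holding fewer than ``density_threshold`` of the current count, and
    repeat until every occupied bin is dense enough.  Returns the surviving
    values and the number removed.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or v.max() <= 1.0:
        return v, 0
    removed = 0
    for _ in range(max_iter):
        if v.size < 4:
            break
        edges = np.histogram_bin_edges(v, bins="auto")
        counts, _ = np.histogram(v, bins=edges)
        sparse = (counts > 0) & (counts < density_threshold * v.size)
        if not sparse.any():
            break
        keep = np.ones(v.size, dtype=bool)
        which = np.clip(np.digitize(v, edges) - 1, 0, len(counts) - 1)
        keep[sparse[which]] = False
        removed += int((~keep).sum())
        v = v[keep]
    return v, removed


def icc_fwhm_sweep(maps_by_scan: dict, mask: np.ndarray, fwhms_mm,
                   voxel_size_mm: float = 2.0) -> dict[float, float]:
    """Median voxel-wise ICC(A,1) as a function of smoothing FWHM.

    ``maps_by_scan`` maps (subject, session) to a 3D parameter volume.
    For each FWHM the maps are mask-smoothed, a subject x session table is
    formed per voxel, and the median in-mask ICC (clamped at zero) is
    reported.  Used to choose the smoothing level for voxel-wise analyses:
    moderate smoothing suppresses misalignment and noise variability (ICC
    rises), excessive smoothing erases spatially localized subject
    differences (ICC falls again).  FWHM 0 means no smoothing.
    """
    msk = np.asarray(mask).astype(bool)
    subjects = sorted({s for s, _ in maps_by_scan})
    sessions = sorted({r for _, r in maps_by_scan})
    flat = np.flatnonzero(msk.ravel())
    out = {}
    for fwhm in fwhms_mm:
        if fwhm > 0:
            sm = {k: gaussian_smooth_masked(np.nan_to_num(v), msk, fwhm,
                                            voxel_size_mm)
                  for k, v in maps_by_scan.items()}
        else:
            sm = {k: np.nan_to_num(v) for k, v in maps_by_scan.items()}
        tables = np.stack([[sm[(s, r)].ravel() for r in sessions]
                           for s in subjects])
        iccs = [icc_a1(tables[:, :, vi], clamp=True) for vi in flat]
        out[float(fwhm)] = float(np.nanmedian(iccs))
    return out


def fwhm_to_sigma(fwhm: float) -> float:
    """sigma = FWHM / (2 sqrt(2 ln 2))."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth_masked(volume: np.ndarray, mask: np.ndarray,
                           fwhm_mm: float, voxel_size_mm: float | tuple = 2.0
                           ) -> np.ndarray:
    """Gaussian smoothing that excludes out-of-mask signal contributions.

    smoothed = (K * (volume . mask)) / (K * mask) inside the mask, with K a
    Gaussian kernel of the requested FWHM (truncated at 4 sigma); voxels
    outside the mask are returned unchanged.  Constant fields inside any
    mask are preserved exactly.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask).astype(float)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes disagree")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (vol.ndim,))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vs
    filled = np.where(msk > 0, vol, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox, truncate=4.0)
    den = ndimage.gaussian_filter(msk, sigma=sigma_vox, truncate=4.0)
    out = vol.copy()
    inside = msk > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out[inside] = num[inside] / den[inside]
    return out
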