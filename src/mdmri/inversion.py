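"""Monte Carlo inversion of the voxel-wise D(omega)-R1-R2 distribution.

The inverse problem is severely ill-conditioned: a sparse set of
diffusion-relaxation weighted measurements constrains a nonparametric
distribution over nine component parameters.  The estimator combines

* random sampling of candidate components (log-uniform for scale
  parameters, uniform on the sphere for orientations),
* non-negative least squares (NNLS) to weight candidates against the data,
* quasi-genetic refinement: positive-weight survivors are carried and
  perturbed over generations, sharpening the candidate set around
  configurations the data supports, and
* bootstrap replication: measurements are resampled with replacement and
  the whole search repeated, yielding an ensemble of plausible solutions
  per voxel whose spread reflects fit uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .model import DRComponent, VoxelDistribution, design_matrix, PARAM_NAMES
from .protocol import Protocol

__all__ = [
    "InversionConfig",
    "VoxelInversionResult",
    "sample_component",
    "sample_components",
    "fit_weights",
    "invert_voxel",
    "invert_volume",
    "rician_floor_correct",
]


def rician_floor_correct(signals: np.ndarray, sigma) -> np.ndarray:
    """Magnitude (Rician) noise-floor correction of measured signals.

    For a Rician magnitude measurement m of true amplitude s,
    E[m^2] = s^2 + 2 sigma^2; the corrected amplitude estimate is
    sqrt(max(m^2 - 2 sigma^2, 0)).  Useful before least-squares fitting
    when magnitude data has not been denoised, where the noise floor
    otherwise masquerades as slowly attenuating signal at strong
    diffusion/relaxation weighting.
    """
    s = np.asarray(signals, dtype=float)
    return np.sqrt(np.maximum(s ** 2 - 2.0 * np.asarray(sigma, float) ** 2, 0.0))

_LOG_UNIFORM = ("d_par", "d_perp", "d0", "gamma_par", "gamma_perp", "r1", "r2")
_COL = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass
class InversionConfig:
    """Sampling ranges and algorithm controls for the Monte Carlo inversion.

    Ranges default to the published sampling box: diffusivities in
    (0.05, 5) um^2/ms, theta in (0, pi), phi in (0, 2 pi), R1 in (0.2, 2) 1/s,
    R2 in (1, 30) 1/s, and transition frequencies Gamma in (0.01, 1e4) rad/s.
    """

    d_par_range: tuple[float, float] = (0.05, 5.0)
    d_perp_range: tuple[float, float] = (0.05, 5.0)
    d0_range: tuple[float, float] = (0.05, 5.0)
    theta_range: tuple[float, float] = (0.0, np.pi)
    phi_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    r1_range: tuple[float, float] = (0.2, 2.0)
    r2_range: tuple[float, float] = (1.0, 30.0)
    gamma_range: tuple[float, float] = (0.01, 1.0e4)
    max_components: int = 10
    n_bootstrap: int = 300
    population_size: int = 200
    n_generations: int = 20
    mutation_scale: float = 0.2
    mutation_decay: float = 0.9        # anneal the mutation scale per generation
    n_polish: int = 25                 # fine-refinement passes on the pruned support
    polish_scale: float = 0.08
    polish_copies: int = 6
    weight_threshold: float = 1.0e-4   # drop weights below this fraction of total
    max_survivors: int = 30
    seed: int = 0

    def range_of(self, name: str) -> tuple[float, float]:
        if name in ("gamma_par", "gamma_perp"):
            return self.gamma_range
        return getattr(self, f"{name}_range")


@dataclass
class VoxelInversionResult:
    """Bootstrap ensemble of distribution solutions for one voxel."""

    solutions: list[VoxelDistribution]
    residuals: np.ndarray
    #: per-replicate incumbent residual after each generation,
    #: shape (n_bootstrap, n_generations + 1)
    generation_residuals: np.ndarray | None = None

    @property
    def n_bootstrap(self) -> int:
        return len(self.solutions)


def sample_components(cfg: InversionConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw n candidate components; returns a parameter array (n, 9).

    Scale parameters (diffusivities, transition frequencies, relaxation
    rates) are drawn log-uniformly; orientations uniformly on the sphere.
    """
    out = np.empty((n, len(PARAM_NAMES)))
    for name in PARAM_NAMES:
        lo, hi = cfg.range_of(name)
        j = _COL[name]
        if name in _LOG_UNIFORM:
            out[:, j] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        elif name == "theta":
            out[:, j] = np.arccos(rng.uniform(-1.0, 1.0, size=n))
        else:  # phi
            out[:, j] = rng.uniform(lo, hi, size=n)
    return out


def sample_component(cfg: InversionConfig, rng: np.random.Generator) -> DRComponent:
    return DRComponent(*sample_components(cfg, 1, rng)[0])


def _perturb(params: np.ndarray, cfg: InversionConfig,
             rng: np.random.Generator, scale: float | None = None) -> np.ndarray:
    """Multiplicative log-normal mutation of survivors, clipped to ranges."""
    sc = cfg.mutation_scale if scale is None else scale
    p = params.copy()
    for name in _LOG_UNIFORM:
        j = _COL[name]
        lo, hi = cfg.range_of(name)
        p[:, j] = np.clip(p[:, j] * np.exp(sc * rng.normal(size=len(p))), lo, hi)
    jt, jp = _COL["theta"], _COL["phi"]
    p[:, jt] = np.abs(p[:, jt] + sc * rng.normal(size=len(p)))
    p[:, jt] = np.where(p[:, jt] > np.pi, 2 * np.pi - p[:, jt], p[:, jt])
    p[:, jt] = np.clip(p[:, jt], 1e-9, np.pi)
    p[:, jp] = np.mod(p[:, jp] + sc * rng.normal(size=len(p)), 2 * np.pi)
    return p


def fit_weights(dictionary, signals: np.ndarray,
                protocol: Protocol) -> np.ndarray:
    """NNLS weights of dictionary components against measured signals.

    Minimizes ||A w - s||^2 subject to w >= 0, where column c of A is the
    unit-weight forward signal of component c under each measurement.
    """
    if isinstance(dictionary, np.ndarray):
        params = np.atleast_2d(dictionary)
    else:
        params = np.array([c.params() if isinstance(c, DRComponent) else np.asarray(c)
                           for c in dictionary])
    if params.size == 0:
        raise ValueError("dictionary must be non-empty")
    s = np.asarray(signals, dtype=float)
    if len(s) != len(protocol):
        raise ValueError(
            f"signal length {len(s)} does not match protocol length {len(protocol)}")
    if not np.all(np.isfinite(s)):
        raise ValueError("signals must be finite")
    A = design_matrix(params, protocol)
    w, _ = nnls(A, s)
    return w


def _nnls_prune(A: np.ndarray, s: np.ndarray, thresh: float
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """NNLS then drop negligible weights; returns (kept idx, weights, residual)."""
    w, _ = nnls(A, s)
    tot = w.sum()
    keep = np.flatnonzero(w > (thresh * tot if tot > 0 else 0))
    if keep.size == 0:
        keep = np.array([int(np.argmax(w))])
    res = float(np.linalg.norm(A[:, keep] @ w[keep] - s))
    return keep, w[keep], res


def invert_voxel(signals: np.ndarray, protocol: Protocol,
                 cfg: InversionConfig, voxel_index: int = 0,
                 noise_sigma: float | None = None
                 ) -> VoxelInversionResult:
    """Full Monte Carlo inversion of one voxel's signal vector.

    Each of ``cfg.n_bootstrap`` replicates resamples the measurements with
    replacement (at full length), then alternates candidate sampling, NNLS
    weighting, survivor retention, and survivor perturbation for
    ``cfg.n_generations`` generations, keeping the incumbent solution when no
    candidate set improves the residual.  The replicate finishes by pruning
    to at most ``cfg.max_components`` largest-weight components and
    refitting.  The random stream of each replicate derives from
    (seed, voxel_index, replicate) so results are scheduler-independent.

    If ``noise_sigma`` is given, signals are noise-floor corrected with
    :func:`rician_floor_correct` before fitting.
    """
    s = np.asarray(signals, dtype=float)
    if noise_sigma is not None:
        s = rician_floor_correct(s, noise_sigma)
    if len(s) != len(protocol):
        raise ValueError("signal length does not match protocol length")
    if not np.all(np.isfinite(s)):
        raise ValueError("signals contain non-finite values")
    if np.all(s == 0):
        raise ValueError("signals are identically zero; nothing to invert")

    solutions: list[VoxelDistribution] = []
    residuals = np.empty(cfg.n_bootstrap)
    gen_res = np.empty((cfg.n_bootstrap, cfg.n_generations + 1))
    for b in range(cfg.n_bootstrap):
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, voxel_index, b])
        idx = rng.integers(0, len(s), size=len(s))
        sb = s[idx]
        proto_b = protocol.subset(idx)

        best_params = None
        best_w = None
        best_res = np.inf
        survivors = np.empty((0, len(PARAM_NAMES)))
        for _gen in range(cfg.n_generations + 1):
            n_surv = len(survivors)
            parts = [survivors]
            if n_surv:
                # coarse-to-fine: two mutated copies, one at the annealed scale
                sc = cfg.mutation_scale * cfg.mutation_decay ** _gen
                parts.append(_perturb(survivors, cfg, rng, scale=sc))
                parts.append(_perturb(survivors, cfg, rng))
            n_fresh = max(cfg.population_size - 3 * n_surv, cfg.max_components)
            parts.append(sample_components(cfg, n_fresh, rng))
            pop = np.vstack(parts)
            A = design_matrix(pop, proto_b)
            keep, w, res = _nnls_prune(A, sb, cfg.weight_threshold)
            if res < best_res:
                best_params, best_w, best_res = pop[keep], w, res
            gen_res[b, _gen] = best_res
            # carry the incumbent's support (sorted by weight, capped)
            order = np.argsort(best_w)[::-1][:cfg.max_survivors]
            survivors = best_params[order]

        # prune to the largest-weight components and refit
        order = np.argsort(best_w)[::-1][:cfg.max_components]
        pruned = best_params[order]
        A = design_matrix(pruned, proto_b)
        keep, w, res = _nnls_prune(A, sb, cfg.weight_threshold)
        pruned, wts, best_res = pruned[keep], w, res
        # polish: fine annealed mutations of the pruned support only, which
        # collapses the diffuse candidate cloud onto the data-supported optimum
        for g in range(cfg.n_polish):
            sc = cfg.polish_scale * cfg.mutation_decay ** g
            cand = np.vstack([pruned] + [_perturb(pruned, cfg, rng, scale=sc)
                                         for _ in range(cfg.polish_copies)])
            A = design_matrix(cand, proto_b)
            keep, w, res = _nnls_prune(A, sb, cfg.weight_threshold)
            if res < best_res:
                order = np.argsort(w)[::-1][:cfg.max_components]
                pruned, wts, best_res = cand[keep][order], w[order], res
        A = design_matrix(pruned, proto_b)
        keep, w, res = _nnls_prune(A, sb, cfg.weight_threshold)
        if res <= best_res:
            solutions.append(VoxelDistribution(pruned[keep], w))
            residuals[b] = res
        else:
            solutions.append(VoxelDistribution(pruned, wts))
            residuals[b] = best_res
    return VoxelInversionResult(solutions, residuals, gen_res)


def invert_volume(signals: np.ndarray, protocol: Protocol, mask: np.ndarray,
                  cfg: InversionConfig) -> dict:
    """Invert every in-mask voxel of a 4D signal array.

    Returns a mapping from flat voxel index (C order over the 3D grid) to
    :class:`VoxelInversionResult`.  Per-voxel random streams derive from the
    flat index, so the result does not depend on iteration order.
    """
    sig = np.asarray(signals, dtype=float)
    msk = np.asarray(mask).astype(bool)
    if sig.shape[:-1] != msk.shape:
        raise ValueError("signal volume and mask shapes disagree")
    flat_idx = np.flatnonzero(msk.ravel())
    sig2 = sig.reshape(-1, sig.shape[-1])
    results: dict[int, VoxelInversionResult] = {}
    for vi in flat_idx:
        results[int(vi)] = invert_voxel(sig2[vi], protocol, cfg, voxel_index=int(vi))
    return results
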