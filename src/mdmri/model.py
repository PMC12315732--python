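"""Frequency-dependent multicomponent diffusion-relaxation signal model.

Each discrete component is an axisymmetric diffusion tensor whose axial and
radial diffusivities follow Lorentzian frequency profiles

    D_axis(omega) = D_axis(0) + (D0 - D_axis(0)) * omega^2 / (omega^2 + Gamma_axis^2),

rising (or falling) from the zero-frequency diffusivity toward the common
high-frequency isotropic diffusivity D0 with corner frequency Gamma, together
with longitudinal and transverse relaxation rates R1 and R2.  The voxel signal
is a weighted sum over components:

    S = sum_c f_c exp(-int b(omega):D_c(omega) domega)
              * (1 - exp(-TR * R1_c)) * exp(-TE * R2_c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import BTensorSpectrum, Measurement, Protocol

__all__ = [
    "DRComponent",
    "VoxelDistribution",
    "PARAM_NAMES",
    "lorentzian_axis",
    "component_tensor_at",
    "diso_ddeltasq_at",
    "attenuation",
    "signal",
    "design_matrix",
]

#: Column order of the component parameter array.
PARAM_NAMES = ("d_par", "d_perp", "theta", "phi", "d0",
               "gamma_par", "gamma_perp", "r1", "r2")
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)


@dataclass
class DRComponent:
    """One discrete diffusion-relaxation component.

    Diffusivities in um^2/ms, angles in rad, transition frequencies Gamma in
    rad/s, relaxation rates in 1/s, weight is a non-negative signal fraction.
    """

    d_par: float
    d_perp: float
    theta: float
    phi: float
    d0: float
    gamma_par: float
    gamma_perp: float
    r1: float
    r2: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.d_par, self.d_perp, self.d0) <= 0:
            raise ValueError("diffusivities must be positive")
        if min(self.r1, self.r2, self.gamma_par, self.gamma_perp) <= 0:
            raise ValueError("rates and transition frequencies must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    def params(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)


class VoxelDistribution:
    """Discrete distribution: parameter array (n, 9) plus weights (n)."""

    def __init__(self, params: np.ndarray, weights: np.ndarray):
        self.params = np.atleast_2d(np.asarray(params, dtype=float))
        self.weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if self.params.shape != (len(self.weights), N_PARAMS):
            raise ValueError("params must be (n, 9) matching weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @classmethod
    def from_components(cls, components: list[DRComponent]) -> "VoxelDistribution":
        return cls(np.array([c.params() for c in components]),
                   np.array([c.weight for c in components]))

    def components(self) -> list[DRComponent]:
        return [DRComponent(*p, weight=w) for p, w in zip(self.params, self.weights)]

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def lorentzian_axis(d_zero, d0, gamma, omega):
    """Lorentzian diffusivity profile along one tensor axis (um^2/ms).

    Equals ``d_zero`` at omega = 0 and tends to ``d0`` as omega -> inf, with
    half transition at omega = gamma.  Broadcasts over array inputs.
    """
    omega = np.asarray(omega, dtype=float)
    frac = omega ** 2 / (omega ** 2 + np.asarray(gamma, float) ** 2)
    return d_zero + (d0 - d_zero) * frac


def _axis_diffusivities(params: np.ndarray, omega) -> tuple[np.ndarray, np.ndarray]:
    """(D_par(omega), D_perp(omega)), each of shape (n_omega, n_components)."""
    p = np.atleast_2d(params)
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    dpar = lorentzian_axis(p[:, _IDX["d_par"]], p[:, _IDX["d0"]],
                           p[:, _IDX["gamma_par"]], om[:, None])
    dperp = lorentzian_axis(p[:, _IDX["d_perp"]], p[:, _IDX["d0"]],
                            p[:, _IDX["gamma_perp"]], om[:, None])
    return dpar, dperp


def diso_ddeltasq_at(params: np.ndarray, omega) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic diffusivity and squared normalized anisotropy at omega.

    Diso = (D_par + 2 D_perp)/3 and D_Delta = (D_par - D_perp)/(3 Diso);
    returns (Diso, D_Delta^2) broadcast over components x frequencies.
    """
    dpar, dperp = _axis_diffusivities(params, omega)
    diso = (dpar + 2.0 * dperp) / 3.0
    ddelta = (dpar - dperp) / (3.0 * diso)
    return diso, ddelta ** 2


def _orientation_vectors(params: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(params)
    th, ph = p[:, _IDX["theta"]], p[:, _IDX["phi"]]
    return np.stack([np.sin(th) * np.cos(ph),
                     np.sin(th) * np.sin(ph),
                     np.cos(th)], axis=-1)


def component_tensor_at(c: DRComponent, omega: float
                        ) -> tuple[np.ndarray, float, float]:
    """Lab-frame diffusion tensor at omega, with (Diso, D_Delta^2).

    The principal-frame tensor diag(D_perp, D_perp, D_par) evaluated at omega
    is rotated so its symmetry axis points along (theta, phi).
    """
    p = c.params()[None, :]
    dpar, dperp = _axis_diffusivities(p, float(omega))
    dpar, dperp = float(dpar[0, 0]), float(dperp[0, 0])
    u = _orientation_vectors(p)[0]
    tensor = dperp * np.eye(3) + (dpar - dperp) * np.outer(u, u)
    diso = (dpar + 2 * dperp) / 3.0
    ddelta = (dpar - dperp) / (3.0 * diso)
    return tensor, diso, ddelta ** 2


def attenuation(c: DRComponent, spectrum: BTensorSpectrum,
                min_points_per_transition: int = 4) -> float:
    """Diffusion attenuation exponent beta = int b(omega):D_c(omega) domega.

    Narrow-band spectra evaluate B : D(omega_cent) in closed form; full
    spectra integrate the Frobenius inner product on the spectrum's own grid
    (trapezoidal).  Warns if the grid undersamples a Lorentzian transition.
    """
    if spectrum.is_narrowband:
        tensor, _, _ = component_tensor_at(c, spectrum.omega_cent)
        return float(np.tensordot(spectrum.total_b_tensor, tensor))
    grid = spectrum.omega_grid
    if len(grid) > 1:
        # only grid steps that carry spectral power matter for resolution
        tr = np.abs(np.einsum("tii->t", spectrum.density))
        occupied = tr > 1e-12 * tr.max() if tr.max() > 0 else np.zeros_like(tr, bool)
        steps = np.diff(grid)[occupied[:-1] | occupied[1:]]
        gmin = min(c.gamma_par, c.gamma_perp)
        if steps.size and gmin < grid.max() \
                and steps.max() > gmin / min_points_per_transition:
            import warnings
            warnings.warn(
                "spectrum grid may undersample a Lorentzian transition "
                f"(Gamma = {gmin:.3g} rad/s, max grid step {steps.max():.3g})",
                stacklevel=2)
    p = c.params()[None, :]
    dpar, dperp = _axis_diffusivities(p, np.abs(grid))
    dpar, dperp = dpar[:, 0], dperp[:, 0]
    u = _orientation_vectors(p)[0]
    tensors = (dperp[:, None, None] * np.eye(3)[None]
               + (dpar - dperp)[:, None, None] * np.outer(u, u)[None])
    integrand = np.einsum("tij,tij->t", spectrum.density, tensors)
    return float(np.trapezoid(integrand, grid))


def _attenuation_matrix(params: np.ndarray, protocol: Protocol) -> np.ndarray:
    """beta[i, c] for narrow-band measurements, fully vectorized.

    For axisymmetric B and D,  B:D = b * Diso * (1 + 2 b_delta D_delta P2(cos psi))
    with psi the angle between the two symmetry axes.
    """
    p = np.atleast_2d(params)
    dpar, dperp = _axis_diffusivities(p, protocol.omega_cent)  # (M, P)
    diso = (dpar + 2 * dperp) / 3.0
    ddelta = (dpar - dperp) / (3.0 * diso)
    cospsi = protocol.directions @ _orientation_vectors(p).T   # (M, P)
    p2 = 0.5 * (3.0 * cospsi ** 2 - 1.0)
    return protocol.b[:, None] * diso * (
        1.0 + 2.0 * protocol.b_delta[:, None] * ddelta * p2)


def design_matrix(params: np.ndarray, protocol: Protocol) -> np.ndarray:
    """Unit-weight forward signals, shape (n_measurements, n_components).

    Column c is the signal of component c with weight 1 under every
    measurement, combining diffusion attenuation with T1 saturation and T2
    decay.  Measurements carrying a full spectrum are integrated by
    quadrature; narrow-band rows use the closed form.
    """
    p = np.atleast_2d(params)
    full = [i for i, m in enumerate(protocol.measurements) if m.spectrum is not None]
    beta = _attenuation_matrix(p, protocol)
    if full:
        comps = [DRComponent(*row) for row in p]
        for i in full:
            spec = protocol.measurements[i].spectrum
            beta[i] = [attenuation(c, spec) for c in comps]
    r1 = p[:, _IDX["r1"]][None, :]
    r2 = p[:, _IDX["r2"]][None, :]
    sat = 1.0 - np.exp(-protocol.tr_s[:, None] * r1)
    decay = np.exp(-protocol.te_ms[:, None] * 1e-3 * r2)
    return np.exp(-beta) * sat * decay


def signal(v: VoxelDistribution, m: Measurement | Protocol) -> float | np.ndarray:
    """Multicomponent signal under one measurement or a whole protocol."""
    proto = m if isinstance(m, Protocol) else Protocol([m])
    s = design_matrix(v.params, proto) @ v.weights
    return s if isinstance(m, Protocol) else float(s[0])
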