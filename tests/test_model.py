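"""Lorentzian diffusion spectra and the multicomponent signal equation."""

import numpy as np
import pytest

import mdmri
from mdmri.model import (
    DRComponent, VoxelDistribution, lorentzian_axis, component_tensor_at,
    attenuation, signal, design_matrix,
)
from mdmri.protocol import (
    BTensorSpectrum, Measurement, Protocol, _random_rotation,
    _axis_symmetric_btensor,
)


def _component(**kw):
    base = dict(d_par=2.0, d_perp=0.5, theta=0.0, phi=0.0, d0=1.0,
                gamma_par=1e6, gamma_perp=1e6, r1=0.5, r2=10.0)
    base.update(kw)
    return DRComponent(**base)


class TestLorentzianAxis:
    def test_limits_and_half_transition(self):
        assert lorentzian_axis(0.5, 3.0, 100.0, 0.0) == pytest.approx(0.5)
        assert lorentzian_axis(0.5, 3.0, 100.0, 100.0) == pytest.approx(1.75)
        assert lorentzian_axis(0.5, 3.0, 100.0, 1e9) == pytest.approx(3.0, abs=1e-6)

    def test_monotone_between_limits(self):
        om = np.linspace(0, 1e4, 200)
        rising = lorentzian_axis(0.5, 3.0, 500.0, om)
        falling = lorentzian_axis(3.0, 0.5, 500.0, om)
        assert np.all(np.diff(rising) >= 0)
        assert np.all(np.diff(falling) <= 0)
        assert np.all((rising >= 0.5) & (rising <= 3.0))


class TestComponentTensor:
    def test_aligned_component_is_diagonal(self):
        t, diso, dd2 = component_tensor_at(_component(theta=0.0), 0.0)
        assert np.allclose(t, np.diag([0.5, 0.5, 2.0]))
        assert diso == pytest.approx(1.0)
        assert dd2 == pytest.approx(0.25)

    def test_diso_rotation_invariant(self, rng):
        for _ in range(5):
            th = rng.uniform(0, np.pi)
            ph = rng.uniform(0, 2 * np.pi)
            t, diso, _ = component_tensor_at(_component(theta=th, phi=ph), 0.0)
            assert np.trace(t) / 3 == pytest.approx(1.0)
            assert diso == pytest.approx(1.0)

    def test_ddeltasq_in_unit_interval(self, rng):
        for _ in range(20):
            dpar, dperp = np.exp(rng.uniform(np.log(0.05), np.log(5), 2))
            _, _, dd2 = component_tensor_at(
                _component(d_par=dpar, d_perp=dperp), 0.0)
            assert 0.0 <= dd2 <= 1.0


class TestAttenuation:
    def test_isotropic_flat_component_gives_b_times_diso(self):
        c = _component(d_par=1.0, d_perp=1.0, d0=1.0)
        spec = BTensorSpectrum.narrowband(np.eye(3) / 3, 2 * np.pi * 10)
        assert attenuation(c, spec) == pytest.approx(1.0)

    def test_linear_encoding_along_fiber(self):
        c = _component(d_par=2.0, theta=0.0, d0=2.0, gamma_par=1e6)
        spec = BTensorSpectrum.narrowband(np.diag([0, 0, 1.0]), 2 * np.pi * 10)
        assert attenuation(c, spec) == pytest.approx(2.0)

    def test_narrowband_matches_fine_grid_quadrature(self):
        """Oracle: 10x-resolution quadrature of b(w):D(w) for a tight band."""
        c = _component(d_par=1.4, d_perp=0.3, theta=0.7, phi=1.2,
                       d0=2.2, gamma_par=300.0, gamma_perp=80.0)
        w0 = 2 * np.pi * 12.0
        B = _axis_symmetric_btensor(1.5, 1.0, np.array([0.3, 0.5, 0.81])
                                    / np.linalg.norm([0.3, 0.5, 0.81]))
        beta_coarse = attenuation(c, BTensorSpectrum.gaussian_band(B, w0, n=2001))
        beta_fine = attenuation(c, BTensorSpectrum.gaussian_band(B, w0, n=20001))
        narrow = attenuation(c, BTensorSpectrum.narrowband(B, w0))
        assert beta_coarse == pytest.approx(beta_fine, rel=1e-8)
        assert beta_fine == pytest.approx(narrow, rel=1e-6)

    def test_coarse_grid_warns(self):
        c = _component(gamma_par=50.0, gamma_perp=50.0)
        w = np.linspace(-500, 500, 21)  # 50 rad/s steps >> Gamma/4
        dens = np.tile(np.eye(3) / 3, (len(w), 1, 1)) * 1e-3
        spec = BTensorSpectrum(np.trapezoid(dens, w, axis=0), w, dens)
        with pytest.warns(UserWarning, match="undersample"):
            attenuation(c, spec)

    def test_rotation_equivariance(self, rng):
        """Rotating both the component axis and the b-tensor leaves beta fixed."""
        c = _component(d_par=1.8, d_perp=0.4, theta=0.9, phi=2.3)
        u = np.array([np.sin(0.9) * np.cos(2.3), np.sin(0.9) * np.sin(2.3),
                      np.cos(0.9)])
        n = np.array([0.2, -0.5, 0.84])
        n /= np.linalg.norm(n)
        B = _axis_symmetric_btensor(2.0, 1.0, n)
        w0 = 2 * np.pi * 10
        beta0 = attenuation(c, BTensorSpectrum.narrowband(B, w0))
        for _ in range(5):
            R = _random_rotation(rng)
            ur = R @ u
            cr = _component(d_par=1.8, d_perp=0.4,
                            theta=np.arccos(np.clip(ur[2], -1, 1)),
                            phi=np.mod(np.arctan2(ur[1], ur[0]), 2 * np.pi))
            beta_r = attenuation(cr, BTensorSpectrum.narrowband(R @ B @ R.T, w0))
            assert beta_r == pytest.approx(beta0, rel=1e-10)


class TestSignal:
    def test_scalar_example(self):
        """b=0, TR=7.6 s, R1=0.5/s, TE=40 ms, R2=10/s -> (1-e^-3.8) e^-0.4."""
        v = VoxelDistribution.from_components(
            [_component(d_par=1.0, d_perp=1.0, d0=1.0)])
        m = Measurement(0.0, 0.0, (0, 0, 1), 2 * np.pi * 6.6, 40.0, 7.6)
        expected = (1 - np.exp(-3.8)) * np.exp(-0.4)
        assert signal(v, m) == pytest.approx(expected, rel=1e-12)

    def test_weight_conservation_limit(self):
        """b=0, TR -> inf, TE -> 0 recovers the total weight."""
        comps = [_component(weight=0.7), _component(d_par=1.0, weight=0.3)]
        v = VoxelDistribution.from_components(comps)
        m = Measurement(0.0, 0.0, (0, 0, 1), 2 * np.pi * 6.6, 1e-9, 1e9)
        assert signal(v, m) == pytest.approx(1.0, rel=1e-9)

    def test_linearity_over_components(self, default_protocol):
        c1 = _component(weight=0.6)
        c2 = _component(d_par=0.8, d_perp=0.8, r2=20.0, weight=0.4)
        v12 = VoxelDistribution.from_components([c1, c2])
        s1 = signal(VoxelDistribution.from_components([c1]), default_protocol)
        s2 = signal(VoxelDistribution.from_components([c2]), default_protocol)
        s12 = signal(v12, default_protocol)
        assert np.allclose(s12, s1 + s2, rtol=1e-12)

    def test_signal_bounded_and_monotone(self):
        """0 < S <= total weight; S falls with b and TE, rises with TR."""
        v = VoxelDistribution.from_components(
            [_component(theta=0.4, phi=0.3, weight=1.0)])

        def meas(b=1.0, te=60.0, tr=3.5):
            return Measurement(b, 1.0, (0, 0, 1), 2 * np.pi * 10, te, tr)

        for b in (0.0, 0.5, 3.0):
            s = signal(v, meas(b=b))
            assert 0 < s <= 1.0
        sb = [signal(v, meas(b=b)) for b in (0.1, 0.5, 1.5, 3.0)]
        ste = [signal(v, meas(te=te)) for te in (40, 63, 83, 150)]
        str_ = [signal(v, meas(tr=tr)) for tr in (0.62, 1.75, 3.5, 7.6)]
        assert np.all(np.diff(sb) < 0)
        assert np.all(np.diff(ste) < 0)
        assert np.all(np.diff(str_) > 0)

    def test_design_matrix_columns_are_unit_weight_signals(self, default_protocol):
        c1, c2 = _component(), _component(d_par=0.7, d_perp=0.7, r1=1.2)
        A = design_matrix(np.array([c1.params(), c2.params()]), default_protocol)
        s1 = signal(VoxelDistribution.from_components([c1]), default_protocol)
        s2 = signal(VoxelDistribution.from_components([c2]), default_protocol)
        assert np.allclose(A[:, 0], s1)
        assert np.allclose(A[:, 1], s2)


class TestValidation:
    def test_component_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            _component(d_par=-1.0)
        with pytest.raises(ValueError):
            _component(r2=0.0)
        with pytest.raises(ValueError):
            DRComponent(1, 1, 0, 0, 1, 100, 100, 0.5, 10, weight=-0.1)

    def test_distribution_shape_check(self):
        with pytest.raises(ValueError):
            VoxelDistribution(np.ones((2, 9)), np.ones(3))
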