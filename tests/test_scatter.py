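"""Forward model: sphere transform, Ewald geometry, intensities, noise."""

import numpy as np
import pytest
from scipy.integrate import quad

import ankylo as ak
from ankylo.scatter import ewald_frequencies, sphere_ft


def quadrature_sphere_ft(radius, nu):
    """Independent radial-quadrature oracle: 4*pi int_0^R r^2 sinc(nu r) dr."""
    if nu == 0:
        return 4.0 * np.pi * radius**3 / 3.0
    val, _ = quad(lambda r: 4.0 * np.pi * r**2 * np.sin(nu * r) / (nu * r), 0, radius,
                  limit=200)
    return val


class TestSphereFT:
    def test_dc_limit_is_ball_volume(self):
        assert sphere_ft(1.0, 0.0) == pytest.approx(4.0 * np.pi / 3.0, rel=1e-14)

    def test_first_zero(self):
        # root of tan(x) = x, cross-checked against the quadrature oracle
        x0 = 4.493409457909064
        assert abs(sphere_ft(1.0, x0)) < 1e-12
        assert abs(quadrature_sphere_ft(1.0, x0)) < 1e-8

    def test_matches_radial_quadrature(self):
        nus = np.linspace(0.0, 4.0 * np.pi / 0.35, 50)
        ours = sphere_ft(0.31, nus)
        oracle = np.array([quadrature_sphere_ft(0.31, v) for v in nus])
        assert np.allclose(ours, oracle, rtol=1e-8, atol=1e-12)

    def test_small_argument_series_is_smooth(self):
        # values just below and above the series switch point agree
        nu = 1e-4 / 0.76
        below = sphere_ft(0.76, nu * 0.999)
        above = sphere_ft(0.76, nu * 1.001)
        # the closed form loses ~half its digits to cancellation here
        assert below == pytest.approx(above, rel=1e-6)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            sphere_ft(0.0, 1.0)
        with pytest.raises(ValueError):
            sphere_ft(-1.0, 1.0)


class TestEwaldGeometry:
    def test_forward_scattering_is_zero_frequency(self):
        assert np.allclose(ewald_frequencies(1.7, 0.0, 2.1), 0.0)

    def test_backscattering(self):
        nu = ewald_frequencies(1.0, np.pi, 0.0)
        assert np.allclose(nu, [0.0, 0.0, -4.0 * np.pi], atol=1e-12)

    def test_magnitude_identity(self, rng):
        theta = rng.uniform(0, np.pi, 200)
        phi = rng.uniform(0, 2 * np.pi, 200)
        nu = ewald_frequencies(0.35, theta, phi)
        expected = (4 * np.pi / 0.35) * np.sin(theta / 2)
        assert np.allclose(np.linalg.norm(nu, axis=-1), expected, rtol=1e-12)

    def test_sampling_lies_on_ewald_sphere(self):
        s = ak.EwaldSampling.from_grid(0.35, n_theta=16, n_phi=16)
        k = 2 * np.pi / 0.35
        radius = np.linalg.norm(s.frequencies + np.array([0.0, 0.0, k]), axis=1)
        assert np.allclose(radius, k, rtol=1e-10)

    def test_invalid_wavelength(self):
        with pytest.raises(ValueError):
            ewald_frequencies(0.0, 0.1, 0.1)

    def test_equiangular_layout(self):
        s = ak.EwaldSampling.from_grid(1.0, n_theta=8, n_phi=4, layout="equiangular")
        assert len(s) == 32
        with pytest.raises(ValueError):
            ak.EwaldSampling.from_grid(1.0, layout="banana")


class TestForwardIntensity:
    def test_single_atom_is_squared_form_factor(self):
        e = ak.ElementSpec("C", 0.76, 1, 2.0)
        mol = ak.Molecule([e], [ak.Atom(e, [0.4, -0.2, 1.1], 1.0)])
        s = ak.EwaldSampling.from_grid(1.2, n_theta=12, n_phi=12)
        I = ak.forward_intensity(mol, s, compute_total_power=False).intensities
        numag = np.linalg.norm(s.frequencies, axis=1)
        assert np.allclose(I, sphere_ft(0.76, numag) ** 2, rtol=1e-12)

    def test_two_atom_interference_closed_form(self):
        e = ak.ElementSpec("C", 0.76, 2, 2.0)
        d = 1.7
        mol = ak.Molecule(
            [e],
            [ak.Atom(e, [0, 0, d / 2], 1.0), ak.Atom(e, [0, 0, -d / 2], 1.0)],
        )
        s = ak.EwaldSampling.from_grid(1.2, n_theta=12, n_phi=12)
        I = ak.forward_intensity(mol, s, compute_total_power=False).intensities
        numag = np.linalg.norm(s.frequencies, axis=1)
        nz = s.frequencies[:, 2]
        expected = 4.0 * np.cos(nz * d / 2) ** 2 * sphere_ft(0.76, numag) ** 2
        assert np.allclose(I, expected, rtol=1e-10, atol=1e-12)

    def test_translation_invariance(self, threonine):
        s = ak.EwaldSampling.from_grid(1.5, n_theta=10, n_phi=10)
        a = ak.forward_intensity(threonine, s, compute_total_power=False).intensities
        b = ak.forward_intensity(
            threonine.translated([0.73, -1.1, 0.21]), s, compute_total_power=False
        ).intensities
        assert np.allclose(a, b, rtol=1e-10)

    def test_intensities_nonnegative(self, threonine):
        s = ak.EwaldSampling.from_grid(0.8, n_theta=16, n_phi=16)
        I = ak.forward_intensity(threonine, s, compute_total_power=False).intensities
        assert np.all(I >= 0)

    def test_empty_molecule_rejected(self):
        e = ak.ElementSpec("C", 0.76, 0, 2.0)
        mol = ak.Molecule([e], [])
        s = ak.EwaldSampling.from_grid(1.0, n_theta=4, n_phi=4)
        with pytest.raises(ValueError):
            ak.forward_intensity(mol, s)

    def test_matches_voxelized_fourier_oracle(self, threonine):
        """Brute-force oracle: voxelize the scattering potential on a fine
        grid and evaluate its discrete Fourier transform directly at the
        Ewald frequencies."""
        rng = np.random.default_rng(5)
        theta = rng.uniform(np.deg2rad(2), np.deg2rad(60), 80)
        phi = rng.uniform(0, 2 * np.pi, 80)
        s = ak.EwaldSampling(wavelength=1.0, theta=theta, phi=phi,
                             theta_min=np.deg2rad(2), theta_max=np.deg2rad(60))
        I = ak.forward_intensity(threonine, s, compute_total_power=False).intensities

        pos = threonine.positions()
        margin = 1.2
        lo = pos.min(axis=0) - margin
        extent = (pos.max(axis=0) - pos.min(axis=0)).max() + 2 * margin
        n = 200
        h = extent / n
        axes = [lo[d] + (np.arange(n) + 0.5) * h for d in range(3)]
        f = np.zeros((n, n, n))
        for atom in threonine.atoms:
            R = atom.element.radius
            sel = [np.abs(axes[d] - atom.position[d]) <= R + 2 * h for d in range(3)]
            idx = [np.where(sl)[0] for sl in sel]
            d2 = sum(
                ((axes[d][idx[d]] - atom.position[d]) ** 2).reshape(
                    [-1 if k == d else 1 for k in range(3)]
                )
                for d in range(3)
            )
            # partial-volume voxelization of the hard ball (linear edge ramp
            # approximates the voxel-coverage fraction)
            f[np.ix_(*idx)] += atom.amplitude * np.clip(
                (R - np.sqrt(d2)) / h + 0.5, 0.0, 1.0
            )
        # direct separable DTFT at each Ewald frequency (no interpolation),
        # deconvolved by the voxel box filter the partial-volume step applies
        F = np.empty(len(s), dtype=complex)
        for l in range(len(s)):
            ex = np.exp(-1j * s.frequencies[l, 0] * axes[0])
            ey = np.exp(-1j * s.frequencies[l, 1] * axes[1])
            ez = np.exp(-1j * s.frequencies[l, 2] * axes[2])
            F[l] = np.einsum("xyz,x,y,z->", f, ex, ey, ez, optimize=True)
        box = np.prod(np.sinc(s.frequencies * h / (2 * np.pi)), axis=1)
        I_oracle = np.abs(F * h**3 / box) ** 2
        # threshold set by the oracle's own edge-voxelization accuracy
        mask = I > 1e-3 * I.max()
        assert mask.sum() > 20
        rel = np.abs(I[mask] - I_oracle[mask]) / I[mask]
        assert np.max(rel) <= 0.01


class TestNoise:
    def _measurements(self, n_theta=100, n_phi=100):
        e = ak.ElementSpec("C", 0.76, 2, 2.0)
        mol = ak.Molecule(
            [e], [ak.Atom(e, [0, 0, 0.8], 2.0), ak.Atom(e, [0, 0, -0.8], 2.0)]
        )
        s = ak.EwaldSampling.from_grid(1.2, n_theta=n_theta, n_phi=n_phi)
        return ak.forward_intensity(mol, s)

    def test_zero_noise_is_identity(self):
        m = self._measurements(10, 10)
        noisy = ak.add_noise(m, 0.0, seed=42)
        assert np.array_equal(noisy.intensities, m.intensities)

    def test_seeded_reproducibility(self):
        m = self._measurements(10, 10)
        a = ak.add_noise(m, 1e-3, seed=9)
        b = ak.add_noise(m, 1e-3, seed=9)
        assert np.array_equal(a.intensities, b.intensities)
        c = ak.add_noise(m, 1e-3, seed=10)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_empirical_noise_power_fraction(self):
        # N = 1e-3 is the operating point of the performance study
        m = self._measurements(100, 100)
        noisy = ak.add_noise(m, 1e-3, seed=0)
        resid = noisy.intensities - m.intensities
        frac = np.var(resid) / m.total_signal_power
        assert frac == pytest.approx(1e-3, rel=0.2)

    def test_negative_intensities_not_clipped(self):
        m = self._measurements(40, 40)
        noisy = ak.add_noise(m, 0.3, seed=1)
        assert np.any(noisy.intensities < 0)

    def test_invalid_noise_level(self):
        m = self._measurements(4, 4)
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                ak.add_noise(m, bad, seed=0)


class TestGridAndSnap:
    def test_site_positions_roundtrip(self):
        g = ak.Grid3D.centered(4.0, 5)
        idx = np.arange(g.n_sites)
        pos = g.site_positions(idx)
        back = [g.nearest_site(p) for p in pos]
        assert list(idx) == back

    def test_snap_collision_raises(self):
        e = ak.ElementSpec("H", 0.31, 2, 1.0)
        mol = ak.Molecule(
            [e], [ak.Atom(e, [0.0, 0, 0], 1.0), ak.Atom(e, [0.05, 0, 0], 1.0)]
        )
        g = ak.Grid3D.centered(4.0, 5)
        with pytest.raises(ValueError):
            ak.snap_to_grid(mol, g)

    def test_demo_setup_snaps_cleanly(self):
        mol, grid, sampling = ak.demo_setup(n_theta=8, n_phi=8)
        assert len(mol) == 17
        sites = {grid.nearest_site(a.position) for a in mol.atoms}
        assert len(sites) == 17
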