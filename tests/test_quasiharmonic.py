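"""Mass-weighted PCA: covariance, modes, variance fractions, extremes."""

import numpy as np
import pytest

import flexscan as fs
from flexscan.quasiharmonic import diagonalize


def single_atom_conformer(mass=None):
    atom = fs.AtomRecord(serial=1, name="CA", element="C", residue_name="ALA",
                         residue_number=1, chain_id="A", xyz=np.zeros(3))
    if mass is not None:
        atom.mass = mass
    return fs.Conformer(label="single", atoms=[atom])


def _traj(coords, meta, interval=5.0):
    masses = np.array([a.mass for a in meta])
    return fs.Trajectory(coords=coords, frame_interval=interval,
                         masses=masses, atom_meta=list(meta))


def _modeset_from_matrix(c, masses=None):
    n = c.shape[0] // 3
    masses = np.ones(n) if masses is None else masses
    meta = [fs.AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A", np.zeros(3))
            for i in range(n)]
    return diagonalize(c, np.zeros((n, 3)), masses, meta)


class TestCovariance:
    def test_static_trajectory_gives_zero_matrix(self, helix24):
        coords = np.tile(helix24.coords, (10, 1, 1))
        cov, mean = fs.mass_weighted_covariance(_traj(coords, helix24.atoms))
        assert np.allclose(cov, 0.0)
        assert np.allclose(mean, helix24.coords)

    def test_single_atom_mass_weighting_closed_form(self):
        # 1 atom of mass 4 amu whose x alternates ±√0.5 about 0: var 0.5 Å²
        conf = single_atom_conformer(mass=4.0)
        coords = np.zeros((100, 1, 3))
        coords[::2, 0, 0] = np.sqrt(0.5)
        coords[1::2, 0, 0] = -np.sqrt(0.5)
        cov, _ = fs.mass_weighted_covariance(_traj(coords, conf.atoms, interval=5.0))
        assert cov[0, 0] == pytest.approx(4.0 * 0.5, rel=1e-9)

    def test_planted_diagonal_covariance_recovery(self, helix24):
        rng = np.random.default_rng(3)
        n = 24
        planted = np.linspace(0.5, 3.5, 3 * n)  # mass-weighted variances
        masses = helix24.masses
        sigma_cart = np.sqrt(planted) / np.repeat(np.sqrt(masses), 3)
        disp = rng.standard_normal((10_000, 3 * n)) * sigma_cart[None, :]
        coords = helix24.coords[None] + disp.reshape(-1, n, 3)
        cov, _ = fs.mass_weighted_covariance(_traj(coords, helix24.atoms))
        assert np.allclose(np.diag(cov), planted, rtol=0.05)

    def test_stride_matches_target_interval(self, helix24):
        coords = np.tile(helix24.coords, (100, 1, 1))
        coords += np.random.default_rng(0).standard_normal(coords.shape) * 0.1
        traj = _traj(coords, helix24.atoms, interval=1.0)  # 1 ps frames
        modes = fs.analyze_trajectory(traj, target_interval_ps=5.0)
        assert modes.stride_ps == pytest.approx(5.0)
        assert modes.n_frames_used == 20

    def test_too_few_frames_is_error(self, helix24):
        coords = np.tile(helix24.coords, (3, 1, 1))
        with pytest.raises(ValueError):
            fs.mass_weighted_covariance(_traj(coords, helix24.atoms, interval=5.0),
                                        target_interval_ps=100.0)


class TestDiagonalize:
    def test_known_diagonal_matrix(self):
        modes = _modeset_from_matrix(np.diag([4.0, 3.0, 2.0]))
        assert np.allclose(modes.eigenvalues, [4.0, 3.0, 2.0])
        overlap = np.abs(modes.eigenvectors)
        assert np.allclose(np.sort(overlap, axis=0)[-1], 1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((9, 9))
        c = a @ a.T
        modes = _modeset_from_matrix(c)
        rebuilt = modes.eigenvectors @ np.diag(modes.eigenvalues) @ modes.eigenvectors.T
        assert np.abs(rebuilt - c).max() < 1e-8

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((12, 12))
        c = a @ a.T
        modes = _modeset_from_matrix(c)
        assert modes.eigenvalues.sum() == pytest.approx(np.trace(c), abs=1e-6)

    def test_asymmetric_matrix_is_error(self):
        c = np.diag([1.0, 2.0, 3.0])
        c[0, 1] = 1e-4
        with pytest.raises(ValueError, match="asymmetric"):
            _modeset_from_matrix(c)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((6, 6))
        c = a @ a.T
        m1 = _modeset_from_matrix(c)
        m2 = _modeset_from_matrix(c.copy())
        assert np.allclose(m1.eigenvectors, m2.eigenvectors)
        for i in range(m1.n_modes):
            j = np.argmax(np.abs(m1.eigenvectors[:, i]))
            assert m1.eigenvectors[j, i] > 0

    def test_planted_mode_recovery(self, planted_mode_trajectory):
        traj, v = planted_mode_trajectory
        modes = fs.analyze_trajectory(traj)
        assert modes.eigenvalues[0] == pytest.approx(9.0, rel=0.1)
        assert modes.eigenvalues[1] == pytest.approx(1.0, rel=0.1)
        assert abs(modes.eigenvectors[:, 0] @ v[:, 0]) > 0.99


class TestVarianceFraction:
    def test_single_nonzero_eigenvalue(self):
        modes = _modeset_from_matrix(np.diag([5.0, 0.0, 0.0]))
        assert fs.variance_fraction(modes, 1) == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        modes = _modeset_from_matrix(np.diag([4.0, 3.0, 2.0, 1.0, 0, 0]))
        assert fs.variance_fraction(modes, 3) == pytest.approx(0.9)

    def test_non_decreasing_and_complete(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal((9, 9))
        modes = _modeset_from_matrix(a @ a.T)
        fracs = [fs.variance_fraction(modes, k) for k in range(1, 10)]
        assert np.all(np.diff(fracs) >= -1e-12)
        assert fracs[-1] == pytest.approx(1.0)

    def test_zero_spectrum_is_error(self):
        modes = _modeset_from_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            fs.variance_fraction(modes, 1)

    def test_planted_top3_fraction(self, helix24):
        # plant a spectrum whose top-3 fraction is 0.44 by construction
        n_modes = 12
        variances = np.array([20.0, 14.0, 10.0] + [56.0 / 9.0] * 9)
        assert variances[:3].sum() / variances.sum() == pytest.approx(0.44)
        v = fs.random_orthonormal_modes(24, n_modes, seed=21)
        spec = fs.ModeSpec(eigenvectors=v, variances=variances,
                           n_frames=10_000, seed=21)
        traj = fs.make_mode_trajectory(helix24, spec)
        modes = fs.analyze_trajectory(traj)
        assert fs.variance_fraction(modes, 3) == pytest.approx(0.44, abs=0.02)


class TestExtremeConformations:
    def test_zero_eigenvalue_returns_mean(self):
        modes = _modeset_from_matrix(np.diag([2.0, 0.0, 0.0]))
        plus, minus = fs.extreme_conformations(modes, 2)
        assert np.allclose(plus.coords, modes.mean_coords)
        assert np.allclose(minus.coords, modes.mean_coords)

    def test_unit_mass_amplitude_closed_form(self):
        # mass 1 amu, λ = 1 amu·Å², E = 2kT: displacement 2√λ/√m = 2.0 Å
        modes = _modeset_from_matrix(np.diag([1.0, 0.0, 0.0]))
        plus, minus = fs.extreme_conformations(modes, 0, energy_kT=2.0)
        d = np.linalg.norm(plus.coords - modes.mean_coords)
        assert d == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(plus.coords - modes.mean_coords,
                           -(minus.coords - modes.mean_coords), atol=1e-12)

    def test_displacement_scales_inverse_sqrt_mass(self):
        c = np.diag([1.0, 0.0, 0.0])
        d1 = np.linalg.norm(
            fs.extreme_conformations(_modeset_from_matrix(c, np.array([1.0])), 0)[0].coords
        )
        d2 = np.linalg.norm(
            fs.extreme_conformations(_modeset_from_matrix(c, np.array([2.0])), 0)[0].coords
        )
        assert d2 == pytest.approx(d1 / np.sqrt(2.0), rel=1e-9)

    def test_midpoint_is_mean(self, planted_mode_trajectory):
        traj, _ = planted_mode_trajectory
        modes = fs.analyze_trajectory(traj)
        plus, minus = fs.extreme_conformations(modes, 0)
        mid = (plus.coords + minus.coords) / 2
        assert np.allclose(mid, modes.mean_coords, atol=1e-9)

    def test_temperature_cancels(self, planted_mode_trajectory):
        traj, _ = planted_mode_trajectory
        modes = fs.analyze_trajectory(traj)
        a = fs.extreme_conformations(modes, 0, temperature=310.0)[0].coords
        b = fs.extreme_conformations(modes, 0, temperature=100.0)[0].coords
        assert np.allclose(a, b)

    def test_negative_energy_is_error(self, planted_mode_trajectory):
        traj, _ = planted_mode_trajectory
        modes = fs.analyze_trajectory(traj)
        with pytest.raises(ValueError):
            fs.extreme_conformations(modes, 0, energy_kT=-1.0)


class TestModeOverlap:
    def test_self_and_orthogonal(self):
        modes = _modeset_from_matrix(np.diag([4.0, 3.0, 2.0]))
        assert fs.mode_overlap(modes, 0, modes, 0) == pytest.approx(1.0)
        assert fs.mode_overlap(modes, 0, modes, 1) == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_is_error(self):
        a = _modeset_from_matrix(np.diag([1.0, 2.0, 3.0]))
        b = _modeset_from_matrix(np.diag([1.0] * 6))
        with pytest.raises(ValueError):
            fs.mode_overlap(a, 0, b, 0)

    def test_same_planted_mode_from_independent_trajectories(self, helix24):
        v = fs.random_orthonormal_modes(24, 1, seed=5)
        variances = np.array([9.0])
        m = []
        for seed in (5, 6):
            spec = fs.ModeSpec(eigenvectors=v, variances=variances,
                               n_frames=5000, seed=seed)
            m.append(fs.analyze_trajectory(fs.make_mode_trajectory(helix24, spec)))
        assert fs.mode_overlap(m[0], 0, m[1], 0) > 0.9


class TestLoopDisplacement:
    def _planted_modeset(self, helix24, direction_by_range):
        """ModeSet with one unit mode displacing given residue ranges."""
        n = 24
        v = np.zeros(3 * n)
        for (lo, hi), direction in direction_by_range.items():
            for rn in range(lo, hi + 1):
                v[3 * (rn - 1): 3 * rn] = direction
        v /= np.linalg.norm(v)
        lam = np.zeros(3 * n)
        lam[0] = 4.0
        evecs = np.eye(3 * n)
        evecs[:, 0] = v
        c = evecs @ np.diag(lam) @ evecs.T
        return diagonalize((c + c.T) / 2, helix24.coords, helix24.masses, helix24.atoms)

    def test_zero_mode_gives_zero_magnitudes(self, helix24):
        modes = self._planted_modeset(helix24, {(3, 6): np.array([1.0, 0, 0])})
        out = fs.loop_displacement_summary(modes, mode_index=5,
                                           residue_ranges={"A": (3, 6), "B": (10, 14)})
        assert np.allclose(out.magnitudes, 0.0)

    def test_opposed_ranges_have_negative_cosine(self, helix24):
        modes = self._planted_modeset(helix24, {
            (3, 6): np.array([1.0, 0, 0]),
            (12, 15): np.array([-1.0, 0, 0]),
        })
        out = fs.loop_displacement_summary(
            modes, 0, {"A": (3, 6), "B": (12, 15)})
        i, j = out.names.index("A"), out.names.index("B")
        assert out.direction_cosines[i, j] < 0

    def test_confined_mode_leaves_other_ranges_still(self, helix24):
        modes = self._planted_modeset(helix24, {(3, 6): np.array([0, 0, 1.0])})
        out = fs.loop_displacement_summary(
            modes, 0, {"active": (3, 6), "quiet": (12, 18)})
        mags = dict(zip(out.names, out.magnitudes))
        assert mags["quiet"] < 0.05 * mags["active"]

    def test_empty_range_is_omitted_with_warning(self, helix24):
        modes = self._planted_modeset(helix24, {(3, 6): np.array([1.0, 0, 0])})
        with pytest.warns(UserWarning, match="no mapped"):
            out = fs.loop_displacement_summary(
                modes, 0, {"A": (3, 6), "missing": (100, 110)})
        assert out.names == ["A"]
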