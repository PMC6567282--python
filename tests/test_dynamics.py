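import math

import numpy as np
import pytest

from cdlattice import dynamics, surrogate
from cdlattice.core import BODY_NP


B = 181.57
MASSES = (621.0, 175.0)


@pytest.fixture(scope="module")
def model():
    return dynamics.harmonic_lattice_model(1.0, 0.1, B, MASSES)


class TestHarmonicModel:
    def test_force_constants_match_finite_difference_hessian(self):
        """The Gauss-Newton Hessian of the spring energy equals a central
        finite-difference Hessian of the explicit energy function."""
        from cdlattice.dynamics import _supercell_hessians
        import itertools
        ha, hb, prim, index, nsc = _supercell_hessians(10.0, nsc=2)
        r0 = math.sqrt(3.0) * 10.0 / 4.0
        cells = list(index)
        nb = 2 * len(cells)
        pos0 = np.zeros((nb, 3))
        for c, i in index.items():
            o = np.array(c) @ prim
            pos0[2 * i] = o
            pos0[2 * i + 1] = o + 10.0 / 4.0
        from cdlattice.builders import _CAGE_NEIGHBOR_CELL
        from cdlattice.core import TETRA_DIRS_CAGE
        box = nsc * prim
        inv = np.linalg.inv(box)

        bonds = []
        for c, i in index.items():
            for s in range(4):
                nc = tuple((np.array(c) + _CAGE_NEIGHBOR_CELL[s]) % nsc)
                bonds.append((2 * i + 1, 2 * index[nc]))

        def min_image(dr):
            f = dr @ inv
            return (f - np.round(f)) @ box

        def energy(x, kr, kt):
            p = x.reshape(nb, 3)
            e = 0.0
            neigh = {}
            for (i, j) in bonds:
                dr = min_image(p[j] - p[i])
                r = np.linalg.norm(dr)
                e += 0.5 * kr * (r - r0) ** 2
                neigh.setdefault(i, []).append(dr / r)
                neigh.setdefault(j, []).append(-dr / r)
            cos0 = -1.0 / 3.0
            th0 = math.acos(cos0)
            import itertools as it
            for i, us in neigh.items():
                for ua, ub in it.combinations(us, 2):
                    c = np.clip(np.dot(ua, ub), -1, 1)
                    e += 0.5 * r0 * kt * (math.acos(c) - th0) ** 2
            return e

        rng = np.random.default_rng(0)
        h = 1e-5
        x0 = pos0.ravel()
        kr, kt = 0.7, 0.23
        H = kr * ha + r0 * 0.0
        H = kr * ha + kt * hb
        for _ in range(10):
            a = rng.integers(len(x0))
            b = rng.integers(len(x0))
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            fd = (energy(xpp, kr, kt) - energy(xpm, kr, kt)
                  - energy(xmp, kr, kt) + energy(xmm, kr, kt)) / (4 * h * h)
            assert fd == pytest.approx(H[a, b], rel=2e-3, abs=2e-4)

    def test_gamma_point_acoustic_zeros(self, model):
        w = model.frequencies(np.zeros((1, 3)))[0]
        assert np.allclose(w[:3], 0.0, atol=1e-7)
        assert np.all(w[3:] > 1e-3)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (1, 1, 1)])
    def test_two_lowest_branches_degenerate(self, model, direction):
        qs, qbar = dynamics.direction_qs(direction, 4, B)
        w = model.frequencies(qs)
        for i in range(1, 4):
            assert w[i, 0] == pytest.approx(w[i, 1], rel=1e-9)

    def test_six_branches(self, model):
        qs, _ = dynamics.direction_qs((1, 0, 0), 4, B)
        assert model.frequencies(qs).shape == (4, 6)

    def test_ktheta_zero_softens_transverse_branch(self):
        central = dynamics.harmonic_lattice_model(1.0, 0.0, B, MASSES)
        full = dynamics.harmonic_lattice_model(1.0, 0.1, B, MASSES)
        qs, _ = dynamics.direction_qs((1, 0, 0), 4, B)
        wc = central.frequencies(qs)[2]
        wf = full.frequencies(qs)[2]
        # transverse acoustic pair softens relative to the longitudinal
        assert wc[0] / wc[2] < wf[0] / wf[2]


class TestEstimator:
    def test_round_trip_eigenvalues_within_5pc(self, mode_surrogate):
        traj = mode_surrogate
        model = traj.meta["model"]
        for direction in ((1, 0, 0), (1, 1, 1)):
            qs, qbar = dynamics.direction_qs(direction, 4,
                                             traj.lattice_constant)
            est = dynamics.estimate_dynamical_matrix(traj, qs, T=0.09)
            for e, qb in zip(est, qbar):
                if qb < 1e-9:
                    continue
                true = np.sort(np.linalg.eigvalsh(
                    model.dynamical_matrices(e.q[None])[0]).real)
                meas = np.sqrt(np.clip(e.omega2, 0, None))
                assert meas == pytest.approx(np.sqrt(true), rel=0.05)

    def test_gamma_covariance_gives_acoustic_nulls(self, mode_surrogate):
        est = dynamics.estimate_dynamical_matrix(
            mode_surrogate, np.zeros((1, 3)), T=0.09)[0]
        assert np.sum(est.omega2 < 1e-10) >= 3

    def test_independent_oscillator_flat_dispersion(self):
        spec = surrogate.RotationSurrogateSpec(
            n=4, T=0.09, krot=(5.0, 5.0), ktrans=(0.04, 0.04),
            n_frames=6000, seed=21)
        traj = surrogate.sample_rigid_body_rotations(spec)
        traj.masses = np.ones(traj.n_bodies)
        qs, qbar = dynamics.direction_qs((1, 0, 0), 4,
                                         traj.lattice_constant)
        est = dynamics.estimate_dynamical_matrix(traj, qs, T=0.09)
        w2 = np.array([e.omega2 for e in est])
        # omega^2 = k/m for every branch and wavevector
        assert np.allclose(w2, 0.04, rtol=0.1)

    def test_too_few_frames_raises(self, mode_surrogate):
        import dataclasses
        short = dataclasses.replace(
            mode_surrogate, centers=mode_surrogate.centers[:4])
        with pytest.raises(ValueError, match="frames"):
            dynamics.estimate_dynamical_matrix(short, np.zeros((1, 3)),
                                               T=0.09)


class TestSpringFit:
    def test_thirteen_unique_points(self, mode_surrogate):
        disps = [dynamics.dispersion_from_trajectory(mode_surrogate, d,
                                                     T=0.09)
                 for d in ((1, 0, 0), (1, 1, 1))]
        pts = dynamics.dispersion_points(disps)
        assert len(pts) == 13

    def test_recovery_within_2pc(self, mode_surrogate):
        disps = [dynamics.dispersion_from_trajectory(mode_surrogate, d,
                                                     T=0.09)
                 for d in ((1, 0, 0), (1, 1, 1))]
        kr, kt, info = dynamics.fit_spring_constants(
            disps, mode_surrogate.lattice_constant, masses=MASSES)
        assert kr == pytest.approx(1.0, rel=0.02)
        assert kt == pytest.approx(0.1, rel=0.02)
        assert info["n_points"] == 13


class TestFreeEnergy:
    def test_identical_parameters_zero_delta(self):
        a = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES, grid=8)
        b = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES, grid=8)
        assert a.delta(b) == 0.0

    def test_frequency_scaling_log_rule(self):
        # scaling all omega by c (kr,ktheta by c^2) shifts F by 6 kT ln c
        c2 = 1.7
        a = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES, grid=8)
        b = dynamics.harmonic_free_energy(c2, 0.1 * c2, 0.09, B, MASSES,
                                          grid=8)
        expected = 6 * 0.09 * 0.5 * math.log(c2)
        assert b.delta(a) == pytest.approx(expected, rel=1e-9)

    def test_bz_grid_convergence(self):
        f16 = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES,
                                            grid=16)
        f32 = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES,
                                            grid=32)
        ref = dynamics.harmonic_free_energy(2.0, 0.2, 0.09, B, MASSES,
                                            grid=16)
        ref32 = dynamics.harmonic_free_energy(2.0, 0.2, 0.09, B, MASSES,
                                              grid=32)
        d16 = f16.delta(ref)
        d32 = f32.delta(ref32)
        assert d16 == pytest.approx(d32, rel=1e-3)

    def test_fitted_vs_true_constants_delta_within_5pc(self, mode_surrogate):
        disps = [dynamics.dispersion_from_trajectory(mode_surrogate, d,
                                                     T=0.09)
                 for d in ((1, 0, 0), (1, 1, 1))]
        kr, kt, _ = dynamics.fit_spring_constants(
            disps, mode_surrogate.lattice_constant, masses=MASSES)
        ref = dynamics.harmonic_free_energy(2.0, 0.2, 0.09,
                                            mode_surrogate.lattice_constant,
                                            MASSES)
        df_fit = dynamics.harmonic_free_energy(
            kr, kt, 0.09, mode_surrogate.lattice_constant, MASSES).delta(ref)
        df_true = dynamics.harmonic_free_energy(
            1.0, 0.1, 0.09, mode_surrogate.lattice_constant, MASSES) \
            .delta(ref)
        assert df_fit == pytest.approx(df_true, rel=0.05)

    def test_mixed_temperature_delta_rejected(self):
        a = dynamics.harmonic_free_energy(1.0, 0.1, 0.09, B, MASSES, grid=8)
        b = dynamics.harmonic_free_energy(1.0, 0.1, 0.18, B, MASSES, grid=8)
        with pytest.raises(ValueError):
            a.delta(b)
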