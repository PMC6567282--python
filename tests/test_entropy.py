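import math

import numpy as np
import pytest

from cdlattice import entropy, surrogate
from cdlattice.core import BODY_CAGE, BODY_NP


class TestTranslationalMsd:
    def test_plateau_matches_direct_variance(self, rotation_surrogate):
        m = entropy.msd_translational(rotation_surrogate)
        assert m.plateau == pytest.approx(m.direct, rel=0.02)

    def test_oscillator_closed_form(self, rotation_surrogate):
        # ktrans = 0.027 at T = 0.09: site-referenced <u2> = 3 kB T / k = 10
        m = entropy.msd_translational(rotation_surrogate)
        assert m.plateau == pytest.approx(3 * 0.09 / 0.027, rel=0.05)

    def test_curve_starts_small_and_saturates(self):
        # time-correlated (OU) trajectory: the lag curve must rise from
        # small values and saturate at twice the site-referenced variance
        spec = surrogate.RotationSurrogateSpec(
            n=2, T=0.09, krot=(5.0, 5.0), ktrans=(0.027, 0.027),
            n_frames=8000, seed=35, ou_tau=30.0)
        traj = surrogate.sample_rigid_body_rotations(spec)
        m = entropy.msd_translational(traj)
        assert m.curve[0] < 0.5 * m.curve[-1]
        assert m.plateau_window is not None
        assert m.plateau == pytest.approx(m.direct, rel=0.1)

    def test_temperature_doubling(self):
        u2 = {}
        for T in (0.09, 0.18):
            spec = surrogate.RotationSurrogateSpec(
                n=2, T=T, krot=(5.0, 5.0), ktrans=(0.027, 0.027),
                n_frames=6000, seed=31)
            traj = surrogate.sample_rigid_body_rotations(spec)
            u2[T] = entropy.msd_translational(traj).plateau
        deriv = entropy.temperature_linearity(u2)
        assert deriv == pytest.approx(1.0, abs=0.05)

    def test_drift_warns_no_plateau(self, caplog):
        n, f = 8, 400
        centers = np.cumsum(
            np.random.default_rng(0).standard_normal((f, n, 3)), axis=0)
        from cdlattice.core import BodyTrajectory
        traj = BodyTrajectory(
            centers=centers, box=np.eye(3) * 100,
            species=np.zeros(n, np.int8), cells=np.zeros((n, 3), int),
            masses=np.ones(n), ideal_centers=centers[0],
            lattice_constant=100.0)
        with caplog.at_level("WARNING", logger="cdlattice"):
            m = entropy.msd_translational(traj)
        assert m.plateau is None
        assert "plateau" in caplog.text


class TestRotationalMsd:
    def test_static_frame_zero(self):
        spec = surrogate.RotationSurrogateSpec(
            n=2, krot=(1e14, 1e14), n_frames=100, seed=32)
        traj = surrogate.sample_rigid_body_rotations(spec)
        m = entropy.msd_rotational(traj)
        assert m.curve.max() == pytest.approx(0.0, abs=1e-10)

    def test_pure_rotation_angle_exact(self):
        """A rigid rotation by alpha about z, probed by a vector in the xy
        plane, gives theta = alpha exactly."""
        from cdlattice.core import BodyTrajectory
        alpha = 0.3
        probes = np.array([[[1.0, 0.0, 0.0]]])
        rot = np.array([[[math.cos(alpha), -math.sin(alpha), 0.0],
                         [math.sin(alpha), math.cos(alpha), 0.0],
                         [0.0, 0.0, 1.0]]])
        ori = np.stack([probes, np.einsum("bij,bkj->bki", rot, probes)])
        traj = BodyTrajectory(
            centers=np.zeros((2, 1, 3)), box=np.eye(3) * 10,
            species=np.zeros(1, np.int8), cells=np.zeros((1, 3), int),
            masses=np.ones(1), ideal_centers=np.zeros((1, 3)),
            orientations=ori, lattice_constant=10.0)
        lags = entropy._lags(2)
        # single lag of 1: curve value is alpha^2
        m = entropy.msd_rotational(traj, window=(0, 10))
        assert m.curve[-1] == pytest.approx(alpha ** 2, rel=1e-9)

    def test_arc_constraint_trends_with_np_size(self):
        """Shared arc length: NP wobble falls and cage wobble grows as the
        NP diameter increases."""
        p = {}
        for d, seed in ((40.0, 33), (120.0, 34)):
            s = 5.0 * (d / 40.0) ** 0.25
            spec = surrogate.RotationSurrogateSpec(
                n=2, krot=None, arc_s=s, diameters=(d, 40.0),
                n_frames=5000, seed=seed)
            traj = surrogate.sample_rigid_body_rotations(spec)
            p[d] = (entropy.msd_rotational(traj, BODY_NP).plateau,
                    entropy.msd_rotational(traj, BODY_CAGE).plateau)
        assert p[120.0][0] < p[40.0][0]      # NP phi2 falls
        assert p[120.0][1] > p[40.0][1]      # cage phi2 grows

    def test_missing_orientations_raise(self, mode_surrogate):
        with pytest.raises(ValueError, match="orientation"):
            entropy.msd_rotational(mode_surrogate)


class TestDecomposition:
    def ref_rec(self):
        return dict(u2=10.0, phi2_np=0.0625, phi2_cage=0.0625, energy=5.0)

    def test_reference_row_is_zero(self):
        recs = {("a"): self.ref_rec(), ("b"): dict(
            u2=12.0, phi2_np=0.05, phi2_cage=0.08, energy=5.5)}
        rep = entropy.entropy_decomposition(recs, reference="a", T=0.09)
        row = rep.table[rep.table.system == "a"].iloc[0]
        assert row.dS_trans == 0.0 and row.dS_rot == 0.0 and row.dF == 0.0

    def test_ratio_e_gives_3kB(self):
        recs = {"ref": self.ref_rec(),
                "x": dict(u2=10.0 * math.e, phi2_np=0.0625,
                          phi2_cage=0.0625, energy=5.0)}
        rep = entropy.entropy_decomposition(recs, reference="ref", T=0.09)
        row = rep.table[rep.table.system == "x"].iloc[0]
        assert row.dS_trans == pytest.approx(3.0)

    def test_antisymmetric_under_swap(self):
        a = self.ref_rec()
        b = dict(u2=14.0, phi2_np=0.03, phi2_cage=0.09, energy=6.0)
        r1 = entropy.entropy_decomposition({"a": a, "b": b}, "a", T=0.09)
        r2 = entropy.entropy_decomposition({"a": a, "b": b}, "b", T=0.09)
        row1 = r1.table[r1.table.system == "b"].iloc[0]
        row2 = r2.table[r2.table.system == "a"].iloc[0]
        for col in ("dS_trans", "dS_rot", "dE", "dF"):
            assert row1[col] == pytest.approx(-row2[col])

    def test_per_species_u2_accepted(self):
        recs = {"ref": dict(u2_np=10.0, u2_cage=10.0, phi2_np=0.06,
                            phi2_cage=0.06),
                "x": dict(u2_np=20.0, u2_cage=10.0, phi2_np=0.06,
                          phi2_cage=0.06)}
        rep = entropy.entropy_decomposition(recs, "ref", T=0.09)
        row = rep.table[rep.table.system == "x"].iloc[0]
        assert row.dS_trans == pytest.approx(1.5 * math.log(2.0))

    def test_shifted_view_collapses_multiplicative_stiffness(self):
        """When stiffness only rescales amplitudes, re-referencing each ka
        to its smallest-NP system collapses the size dependence."""
        base = {40.0: (10.0, 0.0625, 0.0625), 80.0: (11.9, 0.044, 0.074)}
        recs = {}
        for ka, factor in ((0.5, 1.0), (2.0, 0.25)):
            for d, (u2, pn, pc) in base.items():
                recs[(d, ka)] = dict(u2=u2 * factor, phi2_np=pn * factor,
                                     phi2_cage=pc * factor)
        rep = entropy.entropy_decomposition(recs, (40.0, 0.5), T=0.09)
        sh = rep.shifted
        for d in base:
            rows = sh[[s == (d, k) for s, k in zip(sh.system, sh.ka)]]
            vals = rows.dF.to_numpy()
            assert np.allclose(vals, vals[0], atol=1e-12)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            entropy.entropy_decomposition({"a": self.ref_rec()}, "zz")

    def test_nonpositive_plateau_rejected(self):
        recs = {"ref": self.ref_rec(),
                "x": dict(u2=-1.0, phi2_np=0.05, phi2_cage=0.05)}
        with pytest.raises(ValueError):
            entropy.entropy_decomposition(recs, "ref")


class TestEnergyComponent:
    def test_identical_trajectories_zero(self, mode_surrogate):
        assert entropy.energy_component(mode_surrogate, mode_surrogate) == 0.0

    def test_equal_T_harmonic_surrogates_equipartition(self):
        """Same mode count and temperature: <V> = (T/2) * n_modes for both
        systems regardless of spring constants, so dE = 0."""
        de = []
        for kr, seed in ((1.0, 41), (3.0, 42)):
            spec = surrogate.HarmonicSurrogateSpec(
                n=2, kr=kr, ktheta=0.1 * kr, T=0.09, n_frames=8000,
                seed=seed)
            de.append(surrogate.sample_correlated_modes(spec))
        delta = entropy.energy_component(de[0], de[1])
        n_modes_per_cell = (6 * 8 - 3) / 8
        scale = 0.5 * 0.09 * n_modes_per_cell
        assert abs(delta) < 0.05 * scale

    def test_missing_energies_raise(self, rotation_surrogate):
        with pytest.raises(ValueError, match="energy"):
            entropy.energy_component(rotation_surrogate, rotation_surrogate)
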