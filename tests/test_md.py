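import numpy as np
import pytest

from cdlattice import md
from cdlattice.builders import LatticeSpec
from cdlattice.core import BODY_CAGE, COMPLEMENT, FENE_REST
from cdlattice.forcefield import ForceField

from conftest import single_site_system, strand_pair_system, toy_fene_crystal


def hybridized_count(system, pos, rhyb=1.5):
    top = system.topology
    sticky = np.nonzero((top.base >= 0) & (top.base <= 3))[0]
    base = top.base[sticky]
    strand = top.strand[sticky]
    comp = np.array([COMPLEMENT.get(int(b), -9) for b in base])
    p = pos[sticky]
    d = np.linalg.norm(p[:, None] - p[None], axis=-1)
    close = (d < rhyb) & (comp[:, None] == base[None]) \
        & (strand[:, None] != strand[None])
    return int(np.count_nonzero(np.triu(close, 1)))


class TestIntegrators:
    def test_nve_energy_drift_small(self):
        sys2 = strand_pair_system()
        cfg = md.ThermostatConfig(T=0.09, seed=1)
        traj = md.run_nve(sys2, cfg, 10_000, stride=100)
        n = sys2.topology.n_sites
        etot = traj.energies + 1.5 * n * traj.temperatures
        drift = abs(etot[-1] - etot[0]) / abs(etot[0])
        assert drift < 1e-4

    def test_nve_momentum_conserved(self):
        sys2 = strand_pair_system()
        cfg = md.ThermostatConfig(T=0.09, seed=2)
        traj, pos, vel, _ = md._run(sys2, cfg, 2_000, 2_000, "nve")
        p = vel.sum(axis=0)          # unit masses
        assert np.allclose(p, 0.0, atol=1e-10)

    def test_langevin_temperature_control(self):
        sys2 = strand_pair_system()
        cfg = md.ThermostatConfig(T=0.15, seed=3)
        traj = md.run_nvt(sys2, cfg, 30_000, stride=50)
        half = traj.temperatures[len(traj.temperatures) // 2:]
        se = half.std(ddof=1) / np.sqrt(len(half))
        # mean kinetic temperature within 3 standard errors (plus a floor
        # for the O(dt^2) splitting bias)
        assert abs(half.mean() - 0.15) < max(3 * se, 0.01)

    def test_tethered_particle_equipartition(self):
        # 64 non-interacting tethered particles for tight statistics:
        # site-referenced <u2> = 3 kB T / k within 5%
        from cdlattice.core import System, Topology
        n, k, T = 64, 0.5, 0.2
        grid = np.array([(i, j, l) for i in range(4) for j in range(4)
                         for l in range(4)], float) * 10.0
        top = Topology(
            pos=grid.copy(), diameter=np.ones(n), mass=np.ones(n),
            species=np.zeros(n, np.int8), body=np.arange(n, dtype=np.int32),
            strand=-np.ones(n, np.int32), base=-np.ones(n, np.int8),
            bonds=np.empty((0, 2), np.int32), bond_params=np.empty((0, 4)),
            bond_role=np.empty(0, np.int8), angles=np.empty((0, 3), np.int32),
            angle_k=np.empty(0))
        sysn = System(
            topology=top, box=np.eye(3) * 40.0,
            periodic=np.array([True] * 3),
            body_center_site=np.arange(n), body_species=np.zeros(n, np.int8),
            body_cell=np.zeros((n, 3), int), ideal_centers=grid,
            orientation_sites=[np.array([i]) for i in range(n)],
            ideal_neighbors=np.empty((0, 2), int), lattice_constant=40.0)
        cfg = md.ThermostatConfig(T=T, seed=4)
        traj = md.run_nvt(sysn, cfg, 60_000, stride=25,
                          tethers=(np.arange(n), grid, k))
        pos = traj.frames
        u2 = np.mean(np.sum((pos - pos.mean(axis=0)) ** 2, axis=-1))
        assert u2 == pytest.approx(3 * T / k, rel=0.05)

    def test_minimization_energy_nonincreasing(self):
        sys2 = strand_pair_system()
        rng = np.random.default_rng(5)
        sys2.topology.pos += 0.05 * rng.standard_normal(
            sys2.topology.pos.shape)
        ff = ForceField(sys2.topology, sys2.box, sys2.periodic)
        e0 = ff.compute(sys2.topology.pos)[0].total
        pos = md.minimize(sys2, n_steps=100)
        e1 = ff.compute(pos)[0].total
        assert e1 <= e0

    def test_restart_reproducible(self):
        sys2 = strand_pair_system()
        cfg = md.ThermostatConfig(T=0.09, seed=6)
        t1, pos1, vel1, _ = md._run(sys2, cfg, 1_000, 100, "nvt")
        t2, pos2, vel2, _ = md._run(sys2, cfg, 1_000, 100, "nvt")
        assert np.array_equal(pos1, pos2)
        assert np.array_equal(vel1, vel2)


class TestMelting:
    def test_two_strand_melting_brackets_working_temperature(self):
        """The calibrated base-pair well keeps an 8-mer duplex bound at the
        lattice temperature 0.09 and melts it by T = 0.30."""
        fractions = {}
        for T in (0.09, 0.30):
            sys2 = strand_pair_system()
            cfg = md.ThermostatConfig(T=T, seed=7)
            traj = md.run_nvt(sys2, cfg, 60_000, stride=400)
            tail = traj.frames[len(traj.frames) // 3:]
            fractions[T] = np.mean(
                [hybridized_count(sys2, p) >= 4 for p in tail])
        assert fractions[0.09] > 0.5
        assert fractions[0.30] < 0.5


class TestBarostat:
    def test_toy_crystal_relaxes_to_stress_free_constant(self):
        sys3 = toy_fene_crystal(n=4, a=1.05)
        cfg = md.ThermostatConfig(T=0.005, seed=8, barostat_kappa=5e-3)
        traj = md.run_npt_zero_pressure(sys3, cfg, 40_000, stride=400)
        a_fin = traj.boxes[-1][0, 0] / 4
        assert a_fin == pytest.approx(FENE_REST, rel=0.01)
        # time-averaged virial pressure compatible with zero
        late = traj.pressures[-40:]
        assert abs(late.mean()) < 3 * late.std(ddof=1)

    def test_triclinic_angles_preserved(self, small_lattice):
        box0 = small_lattice.box.copy()
        cfg = md.ThermostatConfig(T=0.09, seed=9)
        traj = md.run_npt_zero_pressure(small_lattice, cfg, 300, stride=100)
        box1 = traj.boxes[-1]
        for i in range(3):
            for j in range(3):
                cos0 = box0[i] @ box0[j] / np.linalg.norm(box0[i]) \
                    / np.linalg.norm(box0[j])
                cos1 = box1[i] @ box1[j] / np.linalg.norm(box1[i]) \
                    / np.linalg.norm(box1[j])
                assert cos1 == pytest.approx(cos0, abs=1e-12)


class TestLatticePreparation:
    def test_single_cell_stays_fully_bonded(self, small_lattice):
        spec = LatticeSpec(nx=1, ny=1, nz=1, d=40.0, ka=1.0)
        from cdlattice.builders import build_bulk_lattice
        cell = build_bulk_lattice(spec)
        cfg = md.ThermostatConfig(T=0.09, seed=10)
        targets = cell.topology.pos[cell.body_center_site]
        traj = md.run_nvt(cell, cfg, 4_000, stride=400,
                          tethers=(cell.body_center_site, targets, 20.0))
        assert not traj.aborted
        links = md.count_hybridized_pairs(cell, traj.frames[-1])
        assert (links.kind == "lattice").sum() == 4
        # 4 of 20 NP strands used: 16 free
        np_strands = set(links.strand_i) | set(links.strand_j)
        used = [s for s in np_strands
                if cell.topology.body[
                    np.nonzero(cell.topology.strand == s)[0][0]] == 0]
        assert len(used) == 4

    def test_two_step_preparation_yields_fully_bonded_lattice(self):
        spec = LatticeSpec(nx=2, ny=2, nz=2, d=40.0, ka=1.0)
        cfg = md.ThermostatConfig(T=0.09, seed=12)
        system, traj = md.prepare_bonded_lattice(
            spec, cfg, step1_steps=2_000, step2_steps=2_000, stride=500)
        links = md.count_hybridized_pairs(system, system.topology.pos)
        lat = links[links.kind == "lattice"]
        # every cage keeps all four links after replication + P=0 relaxation
        from collections import Counter
        per_cage = Counter()
        for _, row in lat.iterrows():
            cage = row.body_i if system.body_species[row.body_i] \
                == BODY_CAGE else row.body_j
            per_cage[cage] += 1
        n_cages = int(np.sum(system.body_species == BODY_CAGE))
        assert len(per_cage) == n_cages
        assert all(v == 4 for v in per_cage.values())

    def test_ideal_bulk_has_no_reorientation_bonds(self, small_lattice):
        links = md.count_hybridized_pairs(small_lattice)
        assert (links.kind == "reorientation").sum() == 0
        assert (links.kind == "lattice").sum() == 4 * 8


class TestCoarseGraining:
    def test_body_centers_and_probes(self, small_lattice):
        cfg = md.ThermostatConfig(T=0.09, seed=11)
        traj = md.run_nvt(small_lattice, cfg, 200, stride=100)
        bt = md.coarse_grain(small_lattice, traj)
        assert bt.centers.shape == (2, small_lattice.n_bodies, 3)
        assert bt.orientations.shape[2:] == (4, 3)
        norms = np.linalg.norm(bt.orientations, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        # bodies stay near their ideal sites over a short run
        disp = np.linalg.norm(bt.centers[-1] - small_lattice.ideal_centers,
                              axis=-1)
        assert disp.max() < small_lattice.lattice_constant / 4
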