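import numpy as np
import pytest

from cdlattice import builders, md, surrogate
from cdlattice.core import System, Topology


@pytest.fixture(scope="session")
def cage_template():
    return builders.build_cage(1.0)


@pytest.fixture(scope="session")
def np_template():
    return builders.build_np(40.0, 1.0)


@pytest.fixture(scope="session")
def small_lattice(cage_template, np_template):
    return builders.build_bulk_lattice(
        builders.LatticeSpec(nx=2, ny=2, nz=2, d=40.0, ka=1.0),
        cage=cage_template, nano=np_template)


@pytest.fixture(scope="session")
def mode_surrogate():
    """Correlated-mode surrogate at known spring constants (shared by the
    dynamical-matrix and free-energy tests)."""
    spec = surrogate.HarmonicSurrogateSpec(
        n=4, kr=1.0, ktheta=0.1, T=0.09, masses=(621.0, 175.0),
        n_frames=10_000, seed=42)
    return surrogate.sample_correlated_modes(spec)


@pytest.fixture(scope="session")
def rotation_surrogate():
    spec = surrogate.RotationSurrogateSpec(
        n=2, T=0.09, krot=(5.0, 2.0), ktrans=(0.027, 0.027),
        n_frames=10_000, seed=7)
    return surrogate.sample_rigid_body_rotations(spec)


def single_site_system(box_edge=20.0):
    top = Topology(
        pos=np.zeros((1, 3)), diameter=np.ones(1), mass=np.ones(1),
        species=np.zeros(1, np.int8), body=np.zeros(1, np.int32),
        strand=-np.ones(1, np.int32), base=-np.ones(1, np.int8),
        bonds=np.empty((0, 2), np.int32), bond_params=np.empty((0, 4)),
        bond_role=np.empty(0, np.int8), angles=np.empty((0, 3), np.int32),
        angle_k=np.empty(0))
    return System(
        topology=top, box=np.eye(3) * box_edge,
        periodic=np.array([True] * 3), body_center_site=np.array([0]),
        body_species=np.array([0]), body_cell=np.zeros((1, 3), int),
        ideal_centers=np.zeros((1, 3)), orientation_sites=[np.array([0])],
        ideal_neighbors=np.empty((0, 2), int), lattice_constant=box_edge)


def strand_pair_system(sep=2.97):
    """Two complementary free 15-mers, sticky ends zipped antiparallel."""
    from cdlattice.builders import build_free_strand
    from cdlattice.core import merge_topologies, CAGE_STICKY, NP_STICKY, \
        BB_SPACING
    s1 = build_free_strand(CAGE_STICKY, (0, 0, 0), (0, 0, 1))
    s2 = build_free_strand(NP_STICKY, (0, sep, 21 * BB_SPACING), (0, 0, -1))
    top = merge_topologies([s1, s2])
    return System(
        topology=top, box=np.eye(3) * 25.0, periodic=np.array([True] * 3),
        body_center_site=np.array([0, 30]), body_species=np.array([0, 1]),
        body_cell=np.zeros((2, 3), int), ideal_centers=np.zeros((2, 3)),
        orientation_sites=[np.array([0]), np.array([30])],
        ideal_neighbors=np.empty((0, 2), int), lattice_constant=25.0)


def toy_fene_crystal(n=4, a=1.05):
    """Simple-cubic crystal of small beads held by standard FENE bonds; a
    minimal stress-free reference for barostat tests."""
    import itertools
    cells = list(itertools.product(range(n), repeat=3))
    idx = {c: i for i, c in enumerate(cells)}
    pts = np.array(cells, float) * a
    bonds = []
    for c, i in idx.items():
        for ax in range(3):
            nc = list(c)
            nc[ax] = (nc[ax] + 1) % n
            bonds.append((i, idx[tuple(nc)]))
    N = len(pts)
    top = Topology(
        pos=pts, diameter=np.ones(N) * 0.8, mass=np.ones(N),
        species=np.zeros(N, np.int8), body=np.arange(N, dtype=np.int32),
        strand=-np.ones(N, np.int32), base=-np.ones(N, np.int8),
        bonds=np.array(bonds, np.int32),
        bond_params=np.tile([30.0, 1.5, 1.0, 0.0], (len(bonds), 1)),
        bond_role=np.full(len(bonds), 5, np.int8),
        angles=np.empty((0, 3), np.int32), angle_k=np.empty(0))
    return System(
        topology=top, box=np.eye(3) * n * a, periodic=np.array([True] * 3),
        body_center_site=np.arange(N), body_species=np.zeros(N, np.int8),
        body_cell=np.zeros((N, 3), int), ideal_centers=pts,
        orientation_sites=[np.array([i]) for i in range(N)],
        ideal_neighbors=np.empty((0, 2), int), lattice_constant=n * a)
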