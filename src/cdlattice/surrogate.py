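"""Synthetic trajectories with the statistical structure the analysis assumes.

Three generators:

* correlated lattice vibrations: normal modes of the nearest-neighbour
  spring model are sampled as independent Gaussians with equipartition
  variance kB T / omega^2 and back-transformed to real-space body
  displacements (frames i.i.d. by default, optionally OU-correlated);
* independent rigid-body rotations (and optionally translations): each body
  wobbles about a reference orientation with <phi^2> = 3 kB T / krot, or
  with the geometric arc-length constraint <phi^2> = (2 s / d)^2 shared
  between species;
* a perturbed ideal lattice (one frame of i.i.d. Gaussian displacements)
  for structure-factor and bond-counting fixtures.

Every generator takes an explicit seed; a study fans per-stage seeds out of
one root ``numpy.random.SeedSequence``.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (BODY_CAGE, BODY_NP, BodyTrajectory, TETRA_DIRS_CAGE,
                   TETRA_DIRS_NP, logger)
from .builders import cd_lattice_constant, ideal_body_lattice
from .dynamics import commensurate_qs, harmonic_lattice_model

__all__ = [
    "HarmonicSurrogateSpec", "RotationSurrogateSpec",
    "sample_correlated_modes", "sample_rigid_body_rotations",
    "perturbed_ideal_lattice",
]


@dataclass
class HarmonicSurrogateSpec:
    """Correlated-mode surrogate of an n^3 CD lattice."""

    n: int = 4
    kr: float = 1.0
    ktheta: float = 0.1
    T: float = 0.09
    masses: tuple = (621.0, 175.0)      # site-sum body masses (NP, cage), d=40
    b: float | None = None
    n_frames: int = 10_000
    seed: int = 0
    ou_tau: float | None = None         # frame-correlation time; None = i.i.d.
    frame_dt: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kr, self.ktheta) <= 0 or self.T <= 0:
            raise ValueError("kr, ktheta and T must be positive")


@dataclass
class RotationSurrogateSpec:
    """Independent-oscillator rotational (and optional translational)
    surrogate.  Either per-species rotational stiffnesses ``krot`` or the
    shared-arc mode (``arc_s`` with body diameters) must be given."""

    n: int = 2
    T: float = 0.09
    krot: tuple | None = (5.0, 5.0)     # (NP, cage); None with arc mode
    arc_s: float | None = None          # shared arc length
    diameters: tuple = (40.0, 40.0)     # (d_NP, d_cage) for arc mode
    ktrans: tuple | None = None         # optional center springs (NP, cage)
    b: float | None = None
    n_frames: int = 5_000
    seed: int = 0
    ou_tau: float | None = None
    frame_dt: float = 1.0

    def phi2(self) -> np.ndarray:
        """Target <phi^2> per species (NP, cage)."""
        if self.arc_s is not None:
            return (2.0 * self.arc_s / np.asarray(self.diameters)) ** 2
        if self.krot is None:
            raise ValueError("specify krot or arc_s")
        return 3.0 * self.T / np.asarray(self.krot, dtype=float)


def _frame_noise(rng, n_modes: int, n_frames: int, ou_tau, dt) -> np.ndarray:
    """(n_modes, n_frames) unit-variance noise, i.i.d. or OU in time."""
    if ou_tau is None:
        return rng.standard_normal((n_modes, n_frames))
    rho = math.exp(-dt / ou_tau)
    z = np.empty((n_modes, n_frames))
    z[:, 0] = rng.standard_normal(n_modes)
    amp = math.sqrt(1.0 - rho * rho)
    for t in range(1, n_frames):
        z[:, t] = rho * z[:, t - 1] + amp * rng.standard_normal(n_modes)
    return z


def sample_correlated_modes(spec: HarmonicSurrogateSpec) -> BodyTrajectory:
    """Draw Gaussian lattice vibrations of the spring model.

    Normal-mode amplitudes carry variance kB T / omega^2; acoustic zero modes
    at Gamma (uniform translations) are excluded, so the center of mass is
    pinned.  The per-frame displacement covariance equals kB T D^-1(q) by
    construction.
    """
    b = spec.b if spec.b is not None else cd_lattice_constant(40.0)
    model = harmonic_lattice_model(spec.kr, spec.ktheta, b, spec.masses,
                                   nsc=max(4, spec.n))
    centers, species, cells, box = ideal_body_lattice(spec.n, b)
    nb = len(centers)
    nc = spec.n ** 3
    prim = b / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
    origins = cells[0::2] @ prim           # one origin per cell (NP rows)

    # enumerate commensurate q as integer triples to pair q with -q
    ms = list(itertools.product(range(spec.n), repeat=3))
    conj = {m: tuple((-np.array(m)) % spec.n) for m in ms}
    g = 2.0 * math.pi * np.linalg.inv(prim).T
    sqrt_m = np.sqrt(np.asarray(spec.masses))

    cols = []        # real-space real basis columns, scaled by sqrt(T)/omega
    handled = set()
    for m in ms:
        if m in handled:
            continue
        mc = conj[m]
        q = (np.array(m) / spec.n) @ g
        dmat = model.dynamical_matrices(q[None])[0]
        if mc == m:
            # D(q) is real at self-conjugate q; diagonalize as real so that
            # degenerate pairs come out as real standing waves
            dmat = dmat.real
        w2, evec = np.linalg.eigh(dmat)
        if np.any(w2 < -1e-8):
            raise ValueError("negative eigenvalue in surrogate model")
        phase = np.exp(1j * (origins @ q))             # (nc,)
        for lam in range(6):
            if w2[lam] <= 1e-12 * max(1.0, w2.max()):
                continue                                # acoustic null at Gamma
            amp = math.sqrt(spec.T / w2[lam])
            # mode field on (cell, body-of-cell, xyz), mass-unweighted
            e = evec[:, lam].reshape(2, 3) / sqrt_m[:, None]
            fld = phase[:, None, None] * e[None, :, :] / math.sqrt(nc)
            if mc == m:
                cols.append(amp * fld.real.ravel())
            else:
                cols.append(amp * math.sqrt(2.0) * fld.real.ravel())
                cols.append(amp * math.sqrt(2.0) * fld.imag.ravel())
        handled.add(m)
        handled.add(mc)

    basis = np.stack(cols, axis=1)                     # (3*nb, n_modes)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    z = _frame_noise(rng, basis.shape[1], spec.n_frames, spec.ou_tau,
                     spec.frame_dt)
    disp = (basis @ z).T.reshape(spec.n_frames, nc, 2, 3)

    # scatter cell-ordered displacements back to body order (NP, cage pairs)
    u = np.empty((spec.n_frames, nb, 3))
    u[:, 0::2, :] = disp[:, :, 0, :]
    u[:, 1::2, :] = disp[:, :, 1, :]
    masses = np.where(species == BODY_NP, spec.masses[0], spec.masses[1])

    # harmonic potential energy per frame: mode coordinate Q = sqrt(T)/omega z,
    # so V = sum 1/2 omega^2 Q^2 = (T/2) sum z^2 (equipartition diagnostic)
    energies = 0.5 * spec.T * (z * z).sum(axis=0)
    return BodyTrajectory(
        centers=centers[None] + u, box=box, species=species, cells=cells,
        masses=masses, ideal_centers=centers,
        times=np.arange(spec.n_frames) * spec.frame_dt,
        energies=energies, lattice_constant=b,
        meta=dict(kind="correlated_modes", spec=spec, model=model))


def sample_rigid_body_rotations(spec: RotationSurrogateSpec) -> BodyTrajectory:
    """Small random rigid rotations of each body's vertex frame (plus
    optional independent center translations).

    Rotation vectors are i.i.d. Gaussian with total variance <phi^2> per
    species, so the recovered stiffness is krot = 3 kB T / <phi^2>.
    """
    b = spec.b if spec.b is not None else cd_lattice_constant(40.0)
    centers, species, cells, box = ideal_body_lattice(spec.n, b)
    nb = len(centers)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    phi2 = spec.phi2()
    sig = np.sqrt(phi2 / 3.0)[species]                 # per-axis std
    z = _frame_noise(rng, nb * 3, spec.n_frames, spec.ou_tau, spec.frame_dt)
    rotvec = z.T.reshape(spec.n_frames, nb, 3) * sig[None, :, None]

    probes = np.where(species[:, None, None] == BODY_NP,
                      TETRA_DIRS_NP[None], TETRA_DIRS_CAGE[None])
    mats = Rotation.from_rotvec(rotvec.reshape(-1, 3)).as_matrix()
    mats = mats.reshape(spec.n_frames, nb, 3, 3)
    orient = np.einsum("fbij,bkj->fbki", mats, probes)

    ctr = np.repeat(centers[None], spec.n_frames, axis=0)
    if spec.ktrans is not None:
        st = np.sqrt(spec.T / np.asarray(spec.ktrans, dtype=float))[species]
        zt = _frame_noise(rng, nb * 3, spec.n_frames, spec.ou_tau,
                          spec.frame_dt)
        ctr = ctr + zt.T.reshape(spec.n_frames, nb, 3) * st[None, :, None]

    return BodyTrajectory(
        centers=ctr, box=box, species=species, cells=cells,
        masses=np.ones(nb), ideal_centers=centers,
        times=np.arange(spec.n_frames) * spec.frame_dt,
        orientations=orient, lattice_constant=b,
        meta=dict(kind="rigid_rotations", spec=spec, phi2=phi2))


def perturbed_ideal_lattice(n: int, amplitude: float, seed: int = 0,
                            b: float | None = None,
                            n_frames: int = 1) -> BodyTrajectory:
    """Ideal CD body centers plus i.i.d. Gaussian displacements of the given
    per-component standard deviation."""
    b = b if b is not None else cd_lattice_constant(40.0)
    centers, species, cells, box = ideal_body_lattice(n, b)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    disp = amplitude * rng.standard_normal((n_frames, len(centers), 3)) \
        if amplitude > 0 else np.zeros((n_frames, len(centers), 3))
    return BodyTrajectory(
        centers=centers[None] + disp, box=box, species=species, cells=cells,
        masses=np.ones(len(centers)), ideal_centers=centers,
        lattice_constant=b,
        meta=dict(kind="perturbed_ideal", amplitude=amplitude, seed=seed))
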