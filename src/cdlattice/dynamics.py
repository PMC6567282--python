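"""Lattice dynamics from trajectory fluctuations.

The vibrational spectrum of the superlattice is coarse-grained to the body
centers (NP and cage, masses = total body masses).  The dynamical matrix at
wavevector q is estimated from equal-time displacement covariances,

    D^{-1}(q) = <w(q) w(q)^dagger> / (kB T),   w = sqrt(m) u,

whose eigenvalues are the squared branch frequencies omega^2(q).  A minimal
harmonic model -- radial springs kr on the four nearest-neighbour links and
angular springs ktheta on the bond-angle triplets (energy
1/2 kr sum dr^2 + 1/2 r0 ktheta sum dtheta^2) -- supplies the analytic
dispersion used to fit (kr, ktheta) and to integrate the classical harmonic
free energy over the Brillouin zone.  Only free-energy differences are
meaningful (the additive ideal/quantum constant cancels).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import BODY_CAGE, BODY_NP, BodyTrajectory, TETRA_DIRS_CAGE, logger

__all__ = [
    "HarmonicLatticeModel", "DynamicalMatrixEstimate", "DispersionData",
    "FreeEnergyResult", "harmonic_lattice_model", "estimate_dynamical_matrix",
    "dispersion_from_trajectory", "dispersion_points", "fit_spring_constants",
    "harmonic_free_energy", "commensurate_qs", "direction_qs",
]


# ---------------------------------------------------------------------------
# Harmonic lattice model (the independent analytic oracle)
# ---------------------------------------------------------------------------
@dataclass
class HarmonicLatticeModel:
    """Force-constant representation of the nearest-neighbour spring model on
    the ideal CD lattice.  D(q) = (kr A(q) + ktheta B(q)) mass-weighted."""

    kr: float
    ktheta: float
    b: float
    masses: tuple                 # (m_NP, m_cage)
    r_vectors: np.ndarray         # (NR, 3) cell-offset vectors
    blocks_a: np.ndarray          # (NR, 6, 6) kr=1 force constants
    blocks_b: np.ndarray          # (NR, 6, 6) ktheta=1 (incl. r0 prefactor)

    def dynamical_matrices(self, qs: np.ndarray) -> np.ndarray:
        """Stack of 6x6 dynamical matrices for wavevectors ``qs`` (N, 3)."""
        qs = np.atleast_2d(qs)
        phase = np.exp(1j * (qs @ self.r_vectors.T))        # (N, NR)
        phi = (self.kr * np.einsum("nr,rij->nij", phase, self.blocks_a)
               + self.ktheta * np.einsum("nr,rij->nij", phase, self.blocks_b))
        m = np.sqrt(np.repeat(self.masses, 3))
        return phi / np.outer(m, m)[None]

    def frequencies(self, qs: np.ndarray) -> np.ndarray:
        """Branch frequencies omega (N, 6), ascending; tiny negative
        round-off eigenvalues are clipped to zero."""
        w2 = np.linalg.eigvalsh(self.dynamical_matrices(qs))
        if np.any(w2 < -1e-8 * max(1.0, np.abs(w2).max())):
            raise ValueError("harmonic model is unstable (negative omega^2)")
        return np.sqrt(np.clip(w2, 0.0, None))


def _supercell_hessians(b: float, nsc: int = 4) -> tuple[np.ndarray, ...]:
    """Unit-coefficient Hessians of the spring model on an nsc^3 supercell,
    computed from the internal-coordinate Jacobians (exact at equilibrium:
    H = sum_coords k J J^T)."""
    prim = b / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
    cells = list(itertools.product(range(nsc), repeat=3))
    index = {c: i for i, c in enumerate(cells)}
    nb = 2 * len(cells)
    pos = np.zeros((nb, 3))
    for c, i in index.items():
        o = np.array(c) @ prim
        pos[2 * i] = o                      # NP
        pos[2 * i + 1] = o + b / 4.0        # cage
    r0 = math.sqrt(3.0) * b / 4.0

    # bonds: each cage to its 4 NP neighbours (cell offsets as in builders)
    from .builders import _CAGE_NEIGHBOR_CELL
    bonds = []
    for c, i in index.items():
        for s in range(4):
            nc = tuple((np.array(c) + _CAGE_NEIGHBOR_CELL[s]) % nsc)
            bonds.append((2 * i + 1, 2 * index[nc], TETRA_DIRS_CAGE[s]))

    neigh: dict[int, list] = {}
    for (i, j, u) in bonds:
        neigh.setdefault(i, []).append((j, u))
        neigh.setdefault(j, []).append((i, -u))

    ha = np.zeros((3 * nb, 3 * nb))
    hb = np.zeros((3 * nb, 3 * nb))
    for (i, j, u) in bonds:
        block = np.outer(u, u)
        ha[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        ha[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
        ha[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        ha[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block

    # angles at every body between each pair of its bond directions
    sin0 = math.sqrt(8.0) / 3.0          # tetrahedral angle, cos = -1/3
    cos0 = -1.0 / 3.0
    for i, nbrs in neigh.items():
        for (j, uj), (k, uk) in itertools.combinations(nbrs, 2):
            dj = (cos0 * uj - uk) / (r0 * sin0)
            dk = (cos0 * uk - uj) / (r0 * sin0)
            di = -(dj + dk)
            for (a, ga) in ((i, di), (j, dj), (k, dk)):
                for (bb, gb) in ((i, di), (j, dj), (k, dk)):
                    hb[3 * a:3 * a + 3, 3 * bb:3 * bb + 3] += r0 * np.outer(ga, gb)
    return ha, hb, prim, index, nsc


def harmonic_lattice_model(kr: float, ktheta: float, b: float,
                           masses=(1.0, 1.0), nsc: int = 4) -> HarmonicLatticeModel:
    """Build the analytic model by folding the supercell Hessian into
    force-constant blocks Phi(R) between cell 0 and cell R."""
    ha, hb, prim, index, nsc = _supercell_hessians(b, nsc)
    rvecs, blocks_a, blocks_b = [], [], []
    i0 = index[(0, 0, 0)]
    for c, i in index.items():
        # minimum-image cell offset (couplings reach at most one cell)
        off = np.array([((x + nsc // 2) % nsc) - nsc // 2 for x in c])
        rvecs.append(off @ prim)
        ba = np.zeros((6, 6))
        bb = np.zeros((6, 6))
        for mu in range(2):
            for nu in range(2):
                ba[3 * mu:3 * mu + 3, 3 * nu:3 * nu + 3] = \
                    ha[3 * (2 * i0 + mu):3 * (2 * i0 + mu) + 3,
                       3 * (2 * i + nu):3 * (2 * i + nu) + 3]
                bb[3 * mu:3 * mu + 3, 3 * nu:3 * nu + 3] = \
                    hb[3 * (2 * i0 + mu):3 * (2 * i0 + mu) + 3,
                       3 * (2 * i + nu):3 * (2 * i + nu) + 3]
        blocks_a.append(ba)
        blocks_b.append(bb)
    return HarmonicLatticeModel(
        kr=kr, ktheta=ktheta, b=b, masses=tuple(masses),
        r_vectors=np.array(rvecs), blocks_a=np.array(blocks_a),
        blocks_b=np.array(blocks_b))


# ---------------------------------------------------------------------------
# Wavevector grids
# ---------------------------------------------------------------------------
def reciprocal_primitive(b: float) -> np.ndarray:
    prim = b / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
    return 2.0 * math.pi * np.linalg.inv(prim).T


def commensurate_qs(n: int, b: float, drop_gamma: bool = False) -> np.ndarray:
    """All wavevectors commensurate with an n^3 supercell."""
    g = reciprocal_primitive(b)
    ms = np.array(list(itertools.product(range(n), repeat=3)), dtype=float)
    qs = (ms / n) @ g
    if drop_gamma:
        qs = qs[np.linalg.norm(qs, axis=1) > 1e-12]
    return qs


def direction_qs(direction, n: int, b: float) -> tuple[np.ndarray, np.ndarray]:
    """The n distinct supercell-commensurate wavevectors along a symmetry
    direction; returns (q vectors, reduced magnitudes qbar = |q| b / 2pi)."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    if np.allclose(np.abs(direction), [1, 0, 0]):
        qs = np.array([[2.0 * j / n, 0.0, 0.0] for j in range(n)])
    elif np.allclose(np.abs(direction), 1.0 / math.sqrt(3.0)):
        qs = np.array([[j / n] * 3 for j in range(n)])
    else:
        raise ValueError("supported directions: (100) and (111)")
    qs = qs * 2.0 * math.pi / b
    return qs, np.linalg.norm(qs, axis=1) * b / (2.0 * math.pi)


# ---------------------------------------------------------------------------
# Estimation from trajectories
# ---------------------------------------------------------------------------
@dataclass
class DynamicalMatrixEstimate:
    q: np.ndarray
    matrix: np.ndarray            # 6x6 complex (mass-weighted)
    omega2: np.ndarray            # ascending eigenvalues
    n_frames: int
    condition: float = 0.0


@dataclass
class DispersionData:
    direction: tuple
    qbar: np.ndarray
    omega: np.ndarray             # (nq, 6) branch frequencies
    kr: float | None = None
    ktheta: float | None = None
    fit_residual: float | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for i, qb in enumerate(self.qbar):
            for br in range(self.omega.shape[1]):
                rows.append(dict(direction=str(self.direction), qbar=qb,
                                 branch=br, omega=self.omega[i, br]))
        return pd.DataFrame(rows)


def _cell_order(traj: BodyTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (NP, cage) bodies per cell, and the cell origin vectors."""
    key = {}
    for i in range(traj.n_bodies):
        key[(tuple(traj.cells[i]), int(traj.species[i]))] = i
    cells = sorted({tuple(c) for c in traj.cells})
    idx = np.array([[key[(c, BODY_NP)], key[(c, BODY_CAGE)]] for c in cells])
    n = round(len(cells) ** (1 / 3))
    prim = traj.lattice_constant / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1],
                                                   [1, 1, 0]])
    origins = np.array(cells, dtype=float) @ prim
    return idx, origins


def estimate_dynamical_matrix(traj: BodyTrajectory, qs: np.ndarray,
                              T: float) -> list[DynamicalMatrixEstimate]:
    """Fluctuation estimate of D(q) from body-center displacements.

    Displacements are taken from per-body mean positions, mass-weighted,
    Fourier-transformed over cells, and the 6x6 equal-time covariance is
    (pseudo-)inverted; near-null acoustic directions at q = 0 map to zero
    eigenvalues.
    """
    if traj.n_frames < 8:
        raise ValueError(
            f"{traj.n_frames} frames cannot constrain a 6x6 covariance; "
            "use >= 500 frames (1e4 recommended)")
    idx, origins = _cell_order(traj)
    nc = len(origins)
    u = traj.centers - traj.centers.mean(axis=0, keepdims=True)
    w = u * np.sqrt(traj.masses)[None, :, None]
    # (F, nc, 2, 3)
    w_cell = w[:, idx, :]
    out = []
    qs = np.atleast_2d(qs)
    phases = np.exp(-1j * (qs @ origins.T))          # (nq, nc)
    for qi, q in enumerate(qs):
        wq = np.einsum("c,fcms->fms", phases[qi], w_cell) / math.sqrt(nc)
        v = wq.reshape(traj.n_frames, 6)
        c = (v[:, :, None] * v[:, None, :].conj()).mean(axis=0)
        evals, evecs = np.linalg.eigh(c)
        scale = evals.max()
        if scale <= 0:
            raise ValueError("degenerate covariance; more frames needed")
        inv = np.where(evals > 1e-8 * scale, 1.0 / np.maximum(evals, 1e-300), 0.0)
        d = (evecs * inv[None, :]) @ evecs.conj().T * T
        w2 = np.sort(np.linalg.eigvalsh(d))
        out.append(DynamicalMatrixEstimate(
            q=q, matrix=d, omega2=w2, n_frames=traj.n_frames,
            condition=float(evals.max() / max(evals.min(), 1e-300))))
    return out


def dispersion_from_trajectory(traj: BodyTrajectory, direction, T: float,
                               n: int | None = None) -> DispersionData:
    n = n or round((traj.n_bodies // 2) ** (1 / 3))
    qs, qbar = direction_qs(direction, n, traj.lattice_constant)
    est = estimate_dynamical_matrix(traj, qs, T)
    omega = np.sqrt(np.clip([e.omega2 for e in est], 0.0, None))
    return DispersionData(direction=tuple(direction), qbar=qbar, omega=omega)


# ---------------------------------------------------------------------------
# Spring-constant fit
# ---------------------------------------------------------------------------
def dispersion_points(disps: list[DispersionData]) -> pd.DataFrame:
    """Unique fit points: per direction and qbar, the degenerate transverse
    pair is averaged into one point and the third branch is a second point;
    the origin (all branches acoustic-zero) is shared across directions and
    kept once."""
    rows = []
    origin_done = False
    for disp in disps:
        for i, qb in enumerate(disp.qbar):
            low = np.sort(disp.omega[i])[:3]
            if qb < 1e-12:
                if not origin_done:
                    rows.append(dict(direction="shared", qbar=0.0,
                                     branch="acoustic", omega=0.0))
                    origin_done = True
                continue
            rows.append(dict(direction=str(disp.direction), qbar=qb,
                             branch="TA", omega=float(low[:2].mean())))
            rows.append(dict(direction=str(disp.direction), qbar=qb,
                             branch="LA", omega=float(low[2])))
    return pd.DataFrame(rows)


def fit_spring_constants(disps: list[DispersionData], b: float,
                         masses=(1.0, 1.0), x0=(1.0, 0.1),
                         nsc: int = 4) -> tuple[float, float, dict]:
    """Nonlinear least squares of measured branch frequencies against the
    analytic spring-model dispersion; returns (kr, ktheta, info)."""
    qlist, targets = [], []
    origin_done = False
    for disp in disps:
        n = len(disp.qbar)
        qs, qbar = direction_qs(disp.direction, n, b)
        for i in range(n):
            low = np.sort(disp.omega[i])[:3]
            if qbar[i] < 1e-12:
                if origin_done:
                    continue
                origin_done = True
                qlist.append(qs[i])
                targets.append(("origin", 0.0))
                continue
            qlist.append(qs[i])
            targets.append(("both", (float(low[:2].mean()), float(low[2]))))
    qarr = np.array(qlist)

    base = harmonic_lattice_model(1.0, 1.0, b, masses, nsc=nsc)

    def model_freqs(kr, kt):
        m = HarmonicLatticeModel(kr, kt, b, tuple(masses), base.r_vectors,
                                 base.blocks_a, base.blocks_b)
        return m.frequencies(qarr)

    def residuals(x):
        kr, kt = np.maximum(x, 0.0)
        freqs = model_freqs(kr, kt)
        res = []
        for row, (kind, tgt) in zip(freqs, targets):
            low = np.sort(row)[:3]
            if kind == "origin":
                res.append(low[0])
            else:
                res.append(low[:2].mean() - tgt[0])
                res.append(low[2] - tgt[1])
        return np.array(res)

    sol = least_squares(residuals, x0=np.asarray(x0, dtype=float),
                        bounds=([0.0, 0.0], [np.inf, np.inf]))
    kr, kt = sol.x
    n_points = sum(1 if k == "origin" else 2 for k, _ in targets)
    info = dict(residual=float(np.sqrt(np.mean(sol.fun ** 2))),
                n_points=n_points, success=bool(sol.success))
    if not sol.success:  # pragma: no cover
        logger.warning("spring-constant fit did not converge: %s", sol.message)
    return float(kr), float(kt), info


# ---------------------------------------------------------------------------
# Harmonic free energy
# ---------------------------------------------------------------------------
@dataclass
class FreeEnergyResult:
    """Classical harmonic free energy per primitive cell, up to an additive
    constant common to all systems at the same temperature: F* = kB T * <sum_l
    ln omega_l(q)>_BZ.  Differences of ``free_energy`` between systems equal
    Delta F."""

    free_energy: float
    kr: float
    ktheta: float
    T: float
    grid: int
    masses: tuple

    def delta(self, reference: "FreeEnergyResult") -> float:
        if abs(self.T - reference.T) > 1e-12:
            raise ValueError("free-energy differences require equal T")
        return self.free_energy - reference.free_energy


def harmonic_free_energy(kr: float, ktheta: float, T: float, b: float,
                         masses=(1.0, 1.0), grid: int = 16,
                         nsc: int = 4) -> FreeEnergyResult:
    """Brillouin-zone integral of the classical mode free energy on a
    shifted uniform grid (the measure-zero acoustic Gamma point is avoided
    by the half-step offset)."""
    model = harmonic_lattice_model(kr, ktheta, b, masses, nsc=nsc)
    g = reciprocal_primitive(b)
    fr = (np.array(list(itertools.product(range(grid), repeat=3))) + 0.5) / grid
    qs = fr @ g
    w2 = np.linalg.eigvalsh(model.dynamical_matrices(qs))
    if np.any(w2 <= 0):
        bad = np.count_nonzero(w2 <= 0)
        raise ValueError(f"unstable model: {bad} non-positive omega^2 in BZ")
    f = T * 0.5 * np.log(w2).sum(axis=1).mean()
    return FreeEnergyResult(free_energy=float(f), kr=kr, ktheta=ktheta, T=T,
                            grid=grid, masses=tuple(masses))
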