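"""Potential energy and forces for the coarse-grained model.

Interactions (reduced Lennard-Jones units, sigma = eps = 1 unless noted):

* FENE bonds shifted by Delta (rest length Delta + 0.96...), including the
  short-range WCA core in (r - Delta);
* angle terms V = ka (1 + cos theta) orienting grafted linkers outward and
  stiffening the DNA backbone;
* expanded WCA repulsion between non-bonded sites, core shifted by
  Delta_ij = (d_i + d_j)/2 - 2^(1/6) so repulsion starts at surface contact,
  truncated and shifted to zero at Delta_ij + 2^(1/6);
* an attractive cut-shifted Lennard-Jones well between complementary
  nucleobases (A-T, C-G) of distinct strands -- the only attraction in the
  model, giving specific, thermally reversible hybridization.  Its depth
  ``EPS_BP`` is calibrated so the two-strand 8-mer melting midpoint lies
  between the lattice working temperature 0.09 and 0.30.

Non-bonded exclusions: site pairs within three bonds of each other, plus the
explicit frame-core exclusions listed by the topology.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import COMPLEMENT, Topology, WCA_SHIFT, logger

__all__ = ["EPS_BP", "BASE_CUTOFF", "ForceField", "FeneOverstretchError"]

#: depth of the complementary base-pair well (calibrated so the two-strand
#: 8-mer melting midpoint lies between T = 0.09 and 0.30; see methods note)
EPS_BP = 0.8
#: cutoff of the base-pair attraction
BASE_CUTOFF = 2.5
#: energy shift so the base-pair well is zero at its cutoff
_BASE_SHIFT = 4.0 * (BASE_CUTOFF ** -12 - BASE_CUTOFF ** -6)


class FeneOverstretchError(RuntimeError):
    def __init__(self, bond_index: int, i: int, j: int, r: float):
        super().__init__(
            f"FENE bond {bond_index} ({i}-{j}) overstretched: r = {r:.4f}")
        self.bond_index = bond_index


# ---------------------------------------------------------------------------
# Exclusion table (pairs within 3 bonds)
# ---------------------------------------------------------------------------
def _bond_graph_exclusions(n: int, bonds: np.ndarray,
                           extra: np.ndarray, depth: int = 3) -> tuple:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    excl: list[set] = [set() for _ in range(n)]
    for s in range(n):
        seen = {s: 0}
        frontier = [s]
        for d in range(1, depth + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = d
                        nxt.append(v)
            frontier = nxt
        for v in seen:
            if v != s:
                excl[s].add(v)
    for i, j in extra:
        excl[int(i)].add(int(j))
        excl[int(j)].add(int(i))
    ptr = np.zeros(n + 1, dtype=np.int64)
    idx = []
    for s in range(n):
        row = sorted(excl[s])
        ptr[s + 1] = ptr[s] + len(row)
        idx.extend(row)
    return ptr, np.array(idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def _min_image(dx, dy, dz, box, inv, px, py, pz):
    sx = dx * inv[0, 0] + dy * inv[1, 0] + dz * inv[2, 0]
    sy = dx * inv[0, 1] + dy * inv[1, 1] + dz * inv[2, 1]
    sz = dx * inv[0, 2] + dy * inv[1, 2] + dz * inv[2, 2]
    if px:
        sx -= round(sx)
    if py:
        sy -= round(sy)
    if pz:
        sz -= round(sz)
    rx = sx * box[0, 0] + sy * box[1, 0] + sz * box[2, 0]
    ry = sx * box[0, 1] + sy * box[1, 1] + sz * box[2, 1]
    rz = sx * box[0, 2] + sy * box[1, 2] + sz * box[2, 2]
    return rx, ry, rz


@njit(cache=True, fastmath=True)
def _is_excluded(i, j, excl_ptr, excl_idx):
    lo = excl_ptr[i]
    hi = excl_ptr[i + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = excl_idx[mid]
        if v == j:
            return True
        elif v < j:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, inv, px, py, pz, diam, base, strand, comp,
                excl_ptr, excl_idx, skin, out_i, out_j, out_delta, out_attr):
    """Verlet pair list with per-pair shifted cutoffs; returns pair count
    (or -1 if the buffers are too small)."""
    n = pos.shape[0]
    count = 0
    cap = out_i.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            rx, ry, rz = _min_image(dx, dy, dz, box, inv, px, py, pz)
            r2 = rx * rx + ry * ry + rz * rz
            attr = False
            if (base[i] >= 0 and base[j] >= 0 and strand[i] != strand[j]
                    and strand[i] >= 0 and strand[j] >= 0
                    and comp[base[i]] == base[j]):
                attr = True
                cut = 2.5
            else:
                cut = (diam[i] + diam[j]) * 0.5 - 1.122462048309373 \
                    + 1.122462048309373
                cut = (diam[i] + diam[j]) * 0.5
            rc = cut + skin
            if r2 < rc * rc:
                if _is_excluded(i, j, excl_ptr, excl_idx):
                    continue
                if count >= cap:
                    return -1
                out_i[count] = i
                out_j[count] = j
                out_delta[count] = (diam[i] + diam[j]) * 0.5 \
                    - 1.122462048309373
                out_attr[count] = attr
                count += 1
    return count


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, inv, px, py, pz, pair_i, pair_j, pair_delta,
                pair_attr, n_pairs, eps_bp, forces):
    """Expanded-WCA repulsion + complementary-base attraction; returns
    (repulsive energy, attractive energy, virial)."""
    e_rep = 0.0
    e_att = 0.0
    virial = 0.0
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        rx, ry, rz = _min_image(dx, dy, dz, box, inv, px, py, pz)
        r2 = rx * rx + ry * ry + rz * rz
        r = math.sqrt(r2)
        if pair_attr[p]:
            if r < 2.5:
                sr2 = 1.0 / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e_att += 4.0 * eps_bp * (sr12 - sr6) - eps_bp * _BASE_SHIFT_C
                fmag = eps_bp * (48.0 * sr12 - 24.0 * sr6) / r2
            else:
                continue
        else:
            rr = r - pair_delta[p]
            if rr >= 1.122462048309373:
                continue
            if rr < 1e-9:
                rr = 1e-9
            si = 1.0 / rr
            s6 = si * si * si * si * si * si
            s12 = s6 * s6
            e_rep += 4.0 * (s12 - s6) + 1.0
            fmag = (48.0 * s12 - 24.0 * s6) * si / r
        fx = fmag * rx
        fy = fmag * ry
        fz = fmag * rz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        virial += fmag * r2
    return e_rep, e_att, virial


_BASE_SHIFT_C = _BASE_SHIFT


@njit(cache=True, fastmath=True)
def fene_forces(pos, box, inv, px, py, pz, bonds, params, forces):
    """FENE + core bond terms; returns (energy, virial, bad_bond_index)."""
    e = 0.0
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        kb = params[b, 0]
        r0 = params[b, 1]
        eps = params[b, 2]
        delta = params[b, 3]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        rx, ry, rz = _min_image(dx, dy, dz, box, inv, px, py, pz)
        r = math.sqrt(rx * rx + ry * ry + rz * rz)
        rr = r - delta
        x = rr / r0
        if x >= 1.0 or rr <= 0.0:
            return e, virial, b
        e += -0.5 * kb * r0 * r0 * math.log(1.0 - x * x)
        fmag = -kb * rr / (1.0 - x * x) / r
        if rr < 1.122462048309373:
            si = 1.0 / rr
            s6 = si ** 6
            s12 = s6 * s6
            e += 4.0 * eps * (s12 - s6) + eps
            fmag += eps * (48.0 * s12 - 24.0 * s6) * si / r
        fx = fmag * rx
        fy = fmag * ry
        fz = fmag * rz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        virial += fmag * (rx * rx + ry * ry + rz * rz)
    return e, virial, -1


@njit(cache=True, fastmath=True)
def angle_forces(pos, box, inv, px, py, pz, angles, ks, forces):
    """V = ka (1 + cos theta), theta at the middle site; returns
    (energy, virial)."""
    e = 0.0
    virial = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ka = ks[a]
        ux, uy, uz = _min_image(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                                pos[i, 2] - pos[j, 2], box, inv, px, py, pz)
        vx, vy, vz = _min_image(pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1],
                                pos[k, 2] - pos[j, 2], box, inv, px, py, pz)
        ru2 = ux * ux + uy * uy + uz * uz
        rv2 = vx * vx + vy * vy + vz * vz
        ru = math.sqrt(ru2)
        rv = math.sqrt(rv2)
        dot = ux * vx + uy * vy + uz * vz
        c = dot / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        e += ka * (1.0 + c)
        # dV/d(cos) = ka; grad of cos wrt end sites
        inv_rurv = 1.0 / (ru * rv)
        gix = (vx * inv_rurv - c * ux / ru2)
        giy = (vy * inv_rurv - c * uy / ru2)
        giz = (vz * inv_rurv - c * uz / ru2)
        gkx = (ux * inv_rurv - c * vx / rv2)
        gky = (uy * inv_rurv - c * vy / rv2)
        gkz = (uz * inv_rurv - c * vz / rv2)
        fix = -ka * gix
        fiy = -ka * giy
        fiz = -ka * giz
        fkx = -ka * gkx
        fky = -ka * gky
        fkz = -ka * gkz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial += fix * ux + fiy * uy + fiz * uz
        virial += fkx * vx + fky * vy + fkz * vz
    return e, virial


@njit(cache=True, fastmath=True)
def tether_forces(pos, idx, targets, k, forces):
    e = 0.0
    for t in range(idx.shape[0]):
        i = idx[t]
        dx = pos[i, 0] - targets[t, 0]
        dy = pos[i, 1] - targets[t, 1]
        dz = pos[i, 2] - targets[t, 2]
        e += 0.5 * k * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= k * dx
        forces[i, 1] -= k * dy
        forces[i, 2] -= k * dz
    return e


@njit(cache=True, fastmath=True)
def max_displacement2(pos, ref):
    best = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best


# ---------------------------------------------------------------------------
# ForceField facade
# ---------------------------------------------------------------------------
@dataclass
class EnergyReport:
    fene: float
    angle: float
    wca: float
    base_pair: float
    tether: float = 0.0

    @property
    def total(self) -> float:
        return self.fene + self.angle + self.wca + self.base_pair + self.tether


class ForceField:
    """Evaluates energies/forces for a topology in a periodic box, with a
    displacement-triggered Verlet neighbour list (skin 0.3 sigma)."""

    def __init__(self, topology: Topology, box: np.ndarray,
                 periodic, skin: float = 0.3, eps_bp: float = EPS_BP):
        self.top = topology
        self.box = np.asarray(box, dtype=float)
        self.inv = np.linalg.inv(self.box)
        self.periodic = np.asarray(periodic, dtype=bool)
        self.skin = skin
        self.eps_bp = eps_bp
        n = topology.n_sites
        self.excl_ptr, self.excl_idx = _bond_graph_exclusions(
            n, topology.bonds, topology.extra_exclusions)
        self.comp = np.full(8, -1, dtype=np.int8)
        for a, b in COMPLEMENT.items():
            self.comp[a] = b
        self._cap = max(64, 80 * n)
        self._alloc()
        self.n_pairs = 0
        self._ref_pos: np.ndarray | None = None
        self.tether_idx = np.empty(0, dtype=np.int64)
        self.tether_targets = np.empty((0, 3))
        self.tether_k = 0.0

    def _alloc(self) -> None:
        self.pair_i = np.empty(self._cap, dtype=np.int64)
        self.pair_j = np.empty(self._cap, dtype=np.int64)
        self.pair_delta = np.empty(self._cap)
        self.pair_attr = np.zeros(self._cap, dtype=np.bool_)

    def set_box(self, box: np.ndarray, isotropic_scale: float | None = None) -> None:
        """Update the cell.  For a small isotropic rescale (barostat step)
        the pair list stays valid within the skin, so the displacement
        reference is scaled along instead of forcing a rebuild."""
        self.box = np.asarray(box, dtype=float)
        self.inv = np.linalg.inv(self.box)
        if isotropic_scale is not None and self._ref_pos is not None:
            self._ref_pos *= isotropic_scale
        else:
            self._ref_pos = None

    def set_tethers(self, idx, targets, k) -> None:
        self.tether_idx = np.asarray(idx, dtype=np.int64)
        self.tether_targets = np.asarray(targets, dtype=float)
        self.tether_k = float(k)

    def clear_tethers(self) -> None:
        self.tether_idx = np.empty(0, dtype=np.int64)
        self.tether_k = 0.0

    def _maybe_rebuild(self, pos: np.ndarray) -> None:
        if self._ref_pos is not None:
            if max_displacement2(pos, self._ref_pos) < (self.skin / 2) ** 2:
                return
        while True:
            n = build_pairs(pos, self.box, self.inv, *self.periodic,
                            self.top.diameter, self.top.base, self.top.strand,
                            self.comp, self.excl_ptr, self.excl_idx,
                            self.skin, self.pair_i, self.pair_j,
                            self.pair_delta, self.pair_attr)
            if n >= 0:
                break
            self._cap *= 2
            self._alloc()
        self.n_pairs = n
        self._ref_pos = pos.copy()

    def compute(self, pos: np.ndarray,
                forces: np.ndarray | None = None) -> tuple:
        """Returns (EnergyReport, forces, virial).  Raises
        FeneOverstretchError when a bond leaves its FENE domain."""
        self._maybe_rebuild(pos)
        if forces is None:
            forces = np.zeros_like(pos)
        else:
            forces[:] = 0.0
        px, py, pz = self.periodic
        e_rep, e_att, v_pair = pair_forces(
            pos, self.box, self.inv, px, py, pz, self.pair_i, self.pair_j,
            self.pair_delta, self.pair_attr, self.n_pairs, self.eps_bp,
            forces)
        e_fene, v_fene, bad = fene_forces(
            pos, self.box, self.inv, px, py, pz, self.top.bonds,
            self.top.bond_params, forces)
        if bad >= 0:
            i, j = self.top.bonds[bad]
            r = np.linalg.norm(pos[j] - pos[i])
            raise FeneOverstretchError(bad, int(i), int(j), float(r))
        e_ang, v_ang = angle_forces(
            pos, self.box, self.inv, px, py, pz, self.top.angles,
            self.top.angle_k, forces)
        e_teth = 0.0
        if len(self.tether_idx):
            e_teth = tether_forces(pos, self.tether_idx, self.tether_targets,
                                   self.tether_k, forces)
        report = EnergyReport(fene=e_fene, angle=e_ang, wca=e_rep,
                              base_pair=e_att, tether=e_teth)
        virial = v_pair + v_fene + v_ang
        return report, forces, virial

    def potential_energy(self, pos: np.ndarray) -> EnergyReport:
        report, _, _ = self.compute(pos)
        return report
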