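"""Reduced-scale molecular dynamics for the coarse-grained model.

Velocity-Verlet integration with a Langevin (BAOAB) or Nose-Hoover
thermostat, and a weak-coupling isotropic barostat for zero-pressure runs
(triclinic cell angles are preserved; only the scale breathes).  Production
defaults follow the study protocol: timestep 0.003, T = 0.09 (below the DNA
melting temperature), thermostat/barostat damping 1.0 / 3.0, P = 0.

Desk-scale contract: lattices up to 2x2x2 cells and slabs of a few tens of
bodies are the intended problem sizes here; paper-scale runs are accepted
but impractical on one CPU.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (BODY_CAGE, BODY_NP, BodyTrajectory, COMPLEMENT, System,
                   Topology, logger, minimum_image)
from .builders import LatticeSpec, build_bulk_lattice
from .forcefield import ForceField, FeneOverstretchError

__all__ = [
    "ThermostatConfig", "SiteTrajectory", "run_nvt", "run_npt_zero_pressure",
    "run_nve", "prepare_bonded_lattice", "count_hybridized_pairs",
    "coarse_grain", "PreparationError",
]


class PreparationError(RuntimeError):
    pass


@dataclass
class ThermostatConfig:
    T: float = 0.09
    P: float = 0.0
    damping_t: float = 1.0
    damping_p: float = 3.0
    timestep: float = 0.003
    seed: int = 0
    thermostat: str = "langevin"          # or "nose_hoover"
    barostat_kappa: float = 2e-3          # weak-coupling compressibility/tau
    max_scale_step: float = 2e-4          # cap on per-step box strain


@dataclass
class SiteTrajectory:
    frames: np.ndarray                    # (F, N, 3) unwrapped
    boxes: np.ndarray                     # (F, 3, 3)
    energies: np.ndarray                  # (F,) potential energy
    temperatures: np.ndarray              # (F,) kinetic temperature
    pressures: np.ndarray                 # (F,) virial pressure
    times: np.ndarray
    aborted: bool = False


def _init_velocities(n, masses, T, rng):
    v = rng.standard_normal((n, 3)) * np.sqrt(T / masses)[:, None]
    v -= np.average(v, axis=0, weights=masses)[None]
    return v


def _kinetic_T(v, masses):
    ke = 0.5 * np.sum(masses[:, None] * v * v)
    return 2.0 * ke / (3.0 * len(v))


def _run(system: System, config: ThermostatConfig, n_steps: int,
         stride: int, ensemble: str, tethers=None,
         start_pos: np.ndarray | None = None,
         start_vel: np.ndarray | None = None,
         ff: ForceField | None = None) -> tuple[SiteTrajectory, np.ndarray,
                                                np.ndarray, ForceField]:
    top = system.topology
    n = top.n_sites
    dt = config.timestep
    masses = top.mass
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ff = ff or ForceField(top, system.box, system.periodic)
    if tethers is not None:
        ff.set_tethers(*tethers)
    pos = np.array(start_pos if start_pos is not None else top.pos,
                   dtype=float)
    vel = np.array(start_vel if start_vel is not None
                   else _init_velocities(n, masses, config.T, rng))
    inv_m = 1.0 / masses[:, None]

    gamma = 1.0 / config.damping_t
    c1 = math.exp(-gamma * dt)
    c2 = np.sqrt(config.T * (1.0 - c1 * c1) / masses)[:, None]

    # Nose-Hoover single-chain variables
    q_nh = 3.0 * n * config.T * config.damping_t ** 2
    xi = 0.0

    report, forces, virial = ff.compute(pos)
    frames, boxes, es, ts, ps, times = [], [], [], [], [], []
    aborted = False
    n_rec = 0
    for step in range(n_steps):
        if ensemble != "nve" and config.thermostat == "nose_hoover":
            ke = 0.5 * np.sum(masses[:, None] * vel * vel)
            xi += dt / (2 * q_nh) * (2 * ke - 3 * n * config.T)
            vel *= math.exp(-xi * dt / 2)
        vel += 0.5 * dt * forces * inv_m
        if ensemble != "nve" and config.thermostat == "langevin":
            pos += 0.5 * dt * vel
            vel = c1 * vel + c2 * rng.standard_normal((n, 3))
            pos += 0.5 * dt * vel
        else:
            pos += dt * vel
        try:
            report, forces, virial = ff.compute(pos)
        except FeneOverstretchError:
            aborted = True
            logger.warning("aborting run at step %d: bond overstretch", step)
            break
        vel += 0.5 * dt * forces * inv_m
        if ensemble != "nve" and config.thermostat == "nose_hoover":
            ke = 0.5 * np.sum(masses[:, None] * vel * vel)
            xi += dt / (2 * q_nh) * (2 * ke - 3 * n * config.T)
            vel *= math.exp(-xi * dt / 2)

        vol = abs(np.linalg.det(ff.box))
        kin_t = _kinetic_T(vel, masses)
        pressure = (3.0 * n * kin_t + virial) / (3.0 * vol)
        if ensemble == "npt":
            strain = config.barostat_kappa * dt / config.damping_p \
                * (pressure - config.P)
            strain = min(max(strain, -config.max_scale_step),
                         config.max_scale_step)
            mu = 1.0 + strain
            ff.set_box(ff.box * mu, isotropic_scale=mu)
            pos *= mu

        if (step + 1) % stride == 0 or step == n_steps - 1:
            if not np.all(np.isfinite(pos)):
                aborted = True
                logger.warning("non-finite coordinates at step %d; aborting "
                               "with last recorded frame", step)
                break
            frames.append(pos.copy())
            boxes.append(ff.box.copy())
            es.append(report.total)
            ts.append(kin_t)
            ps.append(pressure)
            times.append((step + 1) * dt)
            n_rec += 1
    traj = SiteTrajectory(
        frames=np.array(frames), boxes=np.array(boxes),
        energies=np.array(es), temperatures=np.array(ts),
        pressures=np.array(ps), times=np.array(times), aborted=aborted)
    return traj, pos, vel, ff


def run_nvt(system: System, config: ThermostatConfig, n_steps: int,
            stride: int = 100, tethers=None, **kw) -> SiteTrajectory:
    return _run(system, config, n_steps, stride, "nvt", tethers, **kw)[0]


def run_nve(system: System, config: ThermostatConfig, n_steps: int,
            stride: int = 100, **kw) -> SiteTrajectory:
    return _run(system, config, n_steps, stride, "nve", **kw)[0]


def run_npt_zero_pressure(system: System, config: ThermostatConfig,
                          n_steps: int, stride: int = 100,
                          **kw) -> SiteTrajectory:
    return _run(system, config, n_steps, stride, "npt", **kw)[0]


def minimize(system: System, n_steps: int = 200,
             step_size: float = 1e-4) -> np.ndarray:
    """Steepest-descent quench (the T = 0 limit); energy non-increasing."""
    ff = ForceField(system.topology, system.box, system.periodic)
    pos = system.topology.pos.copy()
    e_prev = None
    for _ in range(n_steps):
        report, forces, _ = ff.compute(pos)
        if e_prev is not None and report.total > e_prev:
            step_size *= 0.5
        e_prev = report.total
        fmax = np.abs(forces).max()
        if fmax < 1e-10:
            break
        pos = pos + step_size * forces / max(1.0, fmax)
    return pos


# ---------------------------------------------------------------------------
# Hybridization bookkeeping
# ---------------------------------------------------------------------------
def count_hybridized_pairs(system: System, pos: np.ndarray | None = None,
                           nmin: int = 4, rhyb: float = 1.5) -> pd.DataFrame:
    """Cage-NP links from sticky-end contacts.

    A strand pair is hybridized when at least ``nmin`` of its eight
    complementary base pairs sit within ``rhyb``; the body-level table marks
    links between ideal lattice neighbours as ``lattice`` and all others as
    ``reorientation`` (surface bodies bonding to interior partners).
    Diagnostic only -- the dynamics never uses this criterion.
    """
    top = system.topology
    pos = top.pos if pos is None else pos
    sticky = np.nonzero((top.base >= 0) & (top.base <= 3))[0]
    if not len(sticky):
        return pd.DataFrame(columns=["body_i", "body_j", "n_bp", "kind"])
    p = pos[sticky]
    base = top.base[sticky]
    strand = top.strand[sticky]
    body = top.body[sticky]

    # pair distances with minimum image (desk-scale system sizes)
    dr = p[:, None, :] - p[None, :, :]
    dr = minimum_image(dr.reshape(-1, 3), system.box,
                       system.periodic).reshape(len(p), len(p), 3)
    dist = np.linalg.norm(dr, axis=-1)
    comp = np.array([COMPLEMENT.get(int(b), -9) for b in base])
    close = (dist < rhyb) & (comp[:, None] == base[None, :]) \
        & (strand[:, None] != strand[None, :])
    ii, jj = np.nonzero(np.triu(close, 1))

    counts: dict = {}
    for a, b in zip(ii, jj):
        key = (int(strand[a]), int(strand[b])) if strand[a] < strand[b] \
            else (int(strand[b]), int(strand[a]))
        counts[key] = counts.get(key, 0) + 1
    strand_body = {}
    for a in range(len(sticky)):
        strand_body[int(strand[a])] = int(body[a])

    ideal = {tuple(sorted(map(int, pair))) for pair in system.ideal_neighbors}
    rows = []
    for (s1, s2), nbp in sorted(counts.items()):
        if nbp < nmin:
            continue
        b1, b2 = strand_body[s1], strand_body[s2]
        if b1 == b2:
            continue
        kind = "lattice" if tuple(sorted((b1, b2))) in ideal \
            else "reorientation"
        rows.append(dict(body_i=min(b1, b2), body_j=max(b1, b2),
                         strand_i=s1, strand_j=s2, n_bp=nbp, kind=kind))
    return pd.DataFrame(
        rows, columns=["body_i", "body_j", "strand_i", "strand_j", "n_bp",
                       "kind"])


# ---------------------------------------------------------------------------
# Two-step lattice preparation
# ---------------------------------------------------------------------------
def prepare_bonded_lattice(spec: LatticeSpec, config: ThermostatConfig,
                           step1_steps: int = 4000, step2_steps: int = 4000,
                           tether_k: float = 20.0, retries: int = 2,
                           stride: int = 500) -> tuple[System, SiteTrajectory]:
    """Two-step protocol for a defect-free, fully bonded CD lattice.

    Step 1: a single primitive cell with NP and cage centers tethered to
    their ideal sites runs NVT at T until all four cage linkers are
    hybridized.  Step 2: the bonded cell is replicated (unwrapped) to the
    requested size, tethers are removed, and the lattice relaxes at P = 0.
    """
    cell_spec = replace(spec, nx=1, ny=1, nz=1)
    full_n = spec.nx
    last_err = None
    for attempt in range(retries + 1):
        cfg = replace(config, seed=config.seed + 1000 * attempt)
        cell = build_bulk_lattice(cell_spec)
        targets = cell.topology.pos[cell.body_center_site]
        traj, pos, vel, _ = _run(
            cell, cfg, step1_steps, stride, "nvt",
            tethers=(cell.body_center_site, targets, tether_k))
        links = count_hybridized_pairs(cell, pos)
        n_links = len(links[links.kind == "lattice"])
        if traj.aborted or n_links < 4:
            last_err = f"attempt {attempt}: {n_links}/4 links hybridized"
            logger.warning("lattice preparation %s", last_err)
            continue

        full = build_bulk_lattice(spec)
        n_cell_sites = cell.topology.n_sites
        prim = spec_primitives(cell.lattice_constant)
        import itertools as _it
        for ci, cvec in enumerate(_it.product(range(full_n), repeat=3)):
            shift = np.asarray(cvec, dtype=float) @ prim
            full.topology.pos[ci * n_cell_sites:(ci + 1) * n_cell_sites] = \
                pos + shift
        traj2 = run_npt_zero_pressure(full, config, step2_steps,
                                      stride=stride)
        if traj2.aborted:
            last_err = f"attempt {attempt}: replication run aborted"
            continue
        full.topology.pos[:] = traj2.frames[-1]
        full.box = traj2.boxes[-1]
        links = count_hybridized_pairs(full, traj2.frames[-1])
        per_cage = links[links.kind == "lattice"].shape[0]
        full.meta["lattice_links"] = int(per_cage)
        return full, traj2
    raise PreparationError(f"bonded-lattice preparation failed: {last_err}")


def spec_primitives(b: float) -> np.ndarray:
    return b / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])


# ---------------------------------------------------------------------------
# Coarse-graining to body trajectories
# ---------------------------------------------------------------------------
def coarse_grain(system: System, traj: SiteTrajectory) -> BodyTrajectory:
    """Body-center (center-of-mass) trajectory with orientation probes."""
    top = system.topology
    nb = system.n_bodies
    m = top.mass
    mtot = np.bincount(top.body, weights=m, minlength=nb)
    coms = np.empty((len(traj.frames), nb, 3))
    for f, pos in enumerate(traj.frames):
        for ax in range(3):
            coms[f, :, ax] = np.bincount(top.body, weights=m * pos[:, ax],
                                         minlength=nb) / mtot
    k = min(len(p) for p in system.orientation_sites)
    orient = np.empty((len(traj.frames), nb, k, 3))
    for i, sites in enumerate(system.orientation_sites):
        v = traj.frames[:, sites[:k], :] - coms[:, i, None, :]
        orient[:, i] = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return BodyTrajectory(
        centers=coms, box=traj.boxes[-1], species=system.body_species,
        cells=system.body_cell, masses=mtot,
        ideal_centers=system.ideal_centers, times=traj.times,
        orientations=orient, energies=traj.energies,
        lattice_constant=system.lattice_constant,
        meta=dict(kind="md", aborted=traj.aborted))
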