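"""Trajectory and topology I/O.

Dialects:

* extended XYZ with ``name x y z [body species]`` columns (the package's
  native text dialect for both site- and body-level trajectories);
* LAMMPS dump (``id type xu yu zu``, orthogonal or triclinic with tilt
  factors), written natively and read through MDAnalysis;
* LAMMPS data files (atoms/bonds/angles, triclinic tilt factors) for
  interoperability with external MD engines;
* a YAML system manifest carrying the body/species maps needed to
  reconstruct body-level analyses from bare coordinate files.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .core import (BodyTrajectory, SPECIES_NAMES, System, Topology, logger)

__all__ = [
    "write_xyz", "read_xyz", "write_lammps_dump", "read_lammps_dump",
    "write_lammps_data", "write_manifest", "read_manifest",
    "read_trajectory", "body_trajectory_frames",
]


class TrajectoryFormatError(ValueError):
    pass


def _box_to_lammps(box: np.ndarray) -> tuple:
    """Reduce row-vector cell to LAMMPS lx/ly/lz + tilt (requires the usual
    lower-triangular orientation; our builders emit general rows, so rotate
    first via QR when needed)."""
    a, b, c = box
    if abs(a[1]) > 1e-10 or abs(a[2]) > 1e-10 or abs(b[2]) > 1e-10:
        raise TrajectoryFormatError(
            "cell rows must be lower-triangular for LAMMPS output; "
            "use lammps_canonical_box() first")
    return a[0], b[1], c[2], b[0], c[0], c[1]


def lammps_canonical_box(box: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation Q and lower-triangular cell L with L = box @ Q.T."""
    # QR of the transpose gives an upper-triangular factor; transpose back
    q, r = np.linalg.qr(box.T)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    L = (r * signs[:, None]).T
    Q = (q * signs[None, :]).T
    return Q, L


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------
def write_xyz(path, frames: np.ndarray, names, box: np.ndarray,
              bodies=None, species=None) -> None:
    """Extended XYZ; the comment line carries the 9 cell components."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for f, pos in enumerate(frames):
            fh.write(f"{len(pos)}\n")
            cell = " ".join(f"{x:.10g}" for x in np.asarray(box).ravel())
            fh.write(f'frame={f} cell="{cell}"\n')
            for i, r in enumerate(pos):
                extra = ""
                if bodies is not None:
                    extra += f" {int(bodies[i])}"
                if species is not None:
                    extra += f" {int(species[i])}"
                fh.write(f"{names[i]} {r[0]:.10g} {r[1]:.10g} {r[2]:.10g}"
                         f"{extra}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray, list, np.ndarray | None]:
    """Returns (frames, box, names, extra integer columns or None)."""
    frames, names, extras = [], [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            break
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: bad atom count at frame {nframe}")
        header = lines[i + 1] if i + 1 < len(lines) else ""
        if 'cell="' in header:
            cell = header.split('cell="')[1].split('"')[0]
            box = np.array([float(x) for x in cell.split()]).reshape(3, 3)
        rows = lines[i + 2:i + 2 + n]
        if len(rows) < n:
            raise TrajectoryFormatError(
                f"{path}: truncated frame {nframe} "
                f"({len(rows)} of {n} atoms)")
        pos = np.empty((n, 3))
        fr_names = []
        fr_extra = []
        for j, row in enumerate(rows):
            parts = row.split()
            fr_names.append(parts[0])
            pos[j] = [float(x) for x in parts[1:4]]
            fr_extra.append([int(x) for x in parts[4:]])
        frames.append(pos)
        names = fr_names
        extras = fr_extra
        i += 2 + n
        nframe += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no complete frames")
    extra_arr = np.array(extras, dtype=int) if extras and extras[0] else None
    return np.array(frames), box, names, extra_arr


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------
def write_lammps_dump(path, frames, types, box: np.ndarray,
                      timesteps=None) -> None:
    """Dump with unwrapped coordinates; triclinic boxes get tilt factors."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    lx, ly, lz, xy, xz, yz = _box_to_lammps(box)
    triclinic = any(abs(t) > 1e-12 for t in (xy, xz, yz))
    with open(path, "w") as fh:
        for f, pos in enumerate(frames):
            step = timesteps[f] if timesteps is not None else f
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(pos))
            if triclinic:
                xlo = min(0.0, xy, xz, xy + xz)
                xhi = lx + max(0.0, xy, xz, xy + xz)
                ylo = min(0.0, yz)
                yhi = ly + max(0.0, yz)
                fh.write("ITEM: BOX BOUNDS xy xz yz pp pp pp\n")
                fh.write(f"{xlo:.10g} {xhi:.10g} {xy:.10g}\n")
                fh.write(f"{ylo:.10g} {yhi:.10g} {xz:.10g}\n")
                fh.write(f"0 {lz:.10g} {yz:.10g}\n")
            else:
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                fh.write(f"0 {lx:.10g}\n0 {ly:.10g}\n0 {lz:.10g}\n")
            fh.write("ITEM: ATOMS id type xu yu zu\n")
            for i, r in enumerate(pos):
                fh.write(f"{i + 1} {int(types[i])} "
                         f"{r[0]:.10g} {r[1]:.10g} {r[2]:.10g}\n")


def read_lammps_dump(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a dump via MDAnalysis; returns (frames, box, types).

    The box is reconstructed from the last frame's dimensions (lengths and
    angles) as a lower-triangular row-vector cell.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.mdamath import triclinic_vectors

    u = mda.Universe(str(path), format="LAMMPSDUMP",
                     lammps_coordinate_convention="unwrapped")
    frames = []
    box = None
    for ts in u.trajectory:
        frames.append(u.atoms.positions.astype(float).copy())
        box = triclinic_vectors(ts.dimensions).astype(float)
    types = np.array([int(t) for t in u.atoms.types])
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    return np.array(frames), box, types


# ---------------------------------------------------------------------------
# LAMMPS data
# ---------------------------------------------------------------------------
def write_lammps_data(path, system: System) -> None:
    """Minimal molecular data file (atoms with molecule tags, bonds, angles).

    Bond/angle coefficient lines are left to the driver script; types index
    the distinct parameter rows in order of first appearance.
    """
    top = system.topology
    Q, L = lammps_canonical_box(system.box)
    pos = top.pos @ Q.T
    lx, ly, lz, xy, xz, yz = _box_to_lammps(L)

    bond_types: list[tuple] = []
    bond_type_of = []
    for row in top.bond_params:
        key = tuple(np.round(row, 9))
        if key not in bond_types:
            bond_types.append(key)
        bond_type_of.append(bond_types.index(key) + 1)
    angle_types: list[float] = []
    angle_type_of = []
    for k in top.angle_k:
        key = round(float(k), 9)
        if key not in angle_types:
            angle_types.append(key)
        angle_type_of.append(angle_types.index(key) + 1)

    with open(path, "w") as fh:
        fh.write("# cdlattice coarse-grained CD superlattice\n\n")
        fh.write(f"{top.n_sites} atoms\n{len(top.bonds)} bonds\n"
                 f"{len(top.angles)} angles\n\n")
        fh.write(f"{int(top.species.max()) + 1} atom types\n"
                 f"{len(bond_types)} bond types\n"
                 f"{len(angle_types)} angle types\n\n")
        fh.write(f"0 {lx:.10g} xlo xhi\n0 {ly:.10g} ylo yhi\n"
                 f"0 {lz:.10g} zlo zhi\n")
        fh.write(f"{xy:.10g} {xz:.10g} {yz:.10g} xy xz yz\n\n")
        fh.write("Masses\n\n")
        for t in range(int(top.species.max()) + 1):
            sel = top.species == t
            m = float(top.mass[sel][0]) if np.any(sel) else 1.0
            fh.write(f"{t + 1} {m:.10g}\n")
        fh.write("\nAtoms # molecular\n\n")
        for i in range(top.n_sites):
            fh.write(f"{i + 1} {int(top.body[i]) + 1} "
                     f"{int(top.species[i]) + 1} "
                     f"{pos[i, 0]:.10g} {pos[i, 1]:.10g} {pos[i, 2]:.10g}\n")
        fh.write("\nBonds\n\n")
        for bi, (i, j) in enumerate(top.bonds):
            fh.write(f"{bi + 1} {bond_type_of[bi]} {i + 1} {j + 1}\n")
        if len(top.angles):
            fh.write("\nAngles\n\n")
            for ai, (i, j, k) in enumerate(top.angles):
                fh.write(f"{ai + 1} {angle_type_of[ai]} "
                         f"{i + 1} {j + 1} {k + 1}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------
def write_manifest(path, system: System) -> None:
    top = system.topology
    doc = dict(
        kind="cdlattice-system",
        lattice_constant=float(system.lattice_constant),
        box=[[float(x) for x in row] for row in system.box],
        periodic=[bool(p) for p in system.periodic],
        species_names={int(k): v for k, v in SPECIES_NAMES.items()},
        site_species=[int(s) for s in top.species],
        site_body=[int(b) for b in top.body],
        body_species=[int(s) for s in system.body_species],
        body_center_site=[int(s) for s in system.body_center_site],
        body_cell=[[int(x) for x in c] for c in system.body_cell],
        orientation_sites=[[int(x) for x in p]
                           for p in system.orientation_sites],
        meta={k: v for k, v in system.meta.items()
              if isinstance(v, (int, float, str, bool, tuple, list))},
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("kind") != "cdlattice-system":
        raise TrajectoryFormatError(f"{path}: not a cdlattice manifest")
    return doc


def read_trajectory(path, dialect: str | None = None,
                    manifest=None) -> dict:
    """Read XYZ or LAMMPS-dump coordinates.

    Returns a dict with ``frames`` (F, N, 3), ``box``, and per-atom
    ``types``/``names``; when ``manifest`` (path or dict) is given, body and
    species maps are attached so body-level analyses can be reconstructed.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xyz" if path.suffix.lower() in (".xyz", ".exyz") \
            else "lammps_dump"
    if dialect == "xyz":
        frames, box, names, extra = read_xyz(path)
        out = dict(frames=frames, box=box, names=names, extra=extra)
    elif dialect == "lammps_dump":
        frames, box, types = read_lammps_dump(path)
        out = dict(frames=frames, box=box, types=types)
    else:
        raise TrajectoryFormatError(f"unknown dialect {dialect}")
    if manifest is not None:
        doc = manifest if isinstance(manifest, dict) else read_manifest(manifest)
        n = frames.shape[1]
        if len(doc["site_body"]) != n:
            raise TrajectoryFormatError(
                f"manifest describes {len(doc['site_body'])} sites but "
                f"trajectory frame 0 has {n}")
        out["manifest"] = doc
    return out


def body_trajectory_frames(traj: BodyTrajectory) -> tuple:
    """Helper: (frames, names, box) for writing body-level trajectories."""
    names = ["NP" if s == 0 else "CAGE" for s in traj.species]
    return traj.centers, names, traj.box
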