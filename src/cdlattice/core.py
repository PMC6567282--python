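"""Core containers and model constants.

The model is a coarse-grained, Lennard-Jones-reduced-unit representation of a
DNA-linked nanoparticle (NP) cubic-diamond (CD) superlattice: rigid tetrahedral
DNA-origami cages with four sticky single-stranded DNA linkers, and
dodecahedral NPs uniformly grafted with twenty complementary linkers.  Lengths
are in sigma (~0.65 nm), temperature in eps/kB, masses in reduced units (every
force site has mass 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("cdlattice")
if not logger.handlers:  # library default: quiet INFO-level stream handler
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)

# ---------------------------------------------------------------------------
# Species / base codes
# ---------------------------------------------------------------------------
CAGE_EDGE = 0        # 9.9-sigma beads of the rigid cage frame (edges + truncated vertices)
CAGE_CENTER = 1      # 40-sigma sphere representing the NP caged at the tetrahedron core
CAGE_ANCHOR = 2      # first nucleotide backbone bead at each truncated vertex
NP_VERTEX = 3        # 1-sigma dodecahedron vertex sites
NP_CENTER = 4        # central NP site (excluded volume = inscribed sphere)
DNA_BB = 5           # DNA backbone bead
DNA_BASE = 6         # DNA nucleobase bead
CAGE_VERTEX = 7      # small truncated-vertex beads tying the corner together

SPECIES_NAMES = {
    CAGE_EDGE: "cage_edge",
    CAGE_CENTER: "cage_center",
    CAGE_ANCHOR: "cage_vertex_dna_anchor",
    NP_VERTEX: "np_vertex",
    NP_CENTER: "np_center",
    DNA_BB: "dna_backbone",
    DNA_BASE: "dna_base",
    CAGE_VERTEX: "cage_vertex",
}

# nucleobase codes; SPACER is inert (the seven spacer nucleotides have no
# complement in the system, so their bases never attract)
BASE_A, BASE_C, BASE_G, BASE_T, BASE_SPACER = 0, 1, 2, 3, 4
BASE_FROM_CHAR = {"A": BASE_A, "C": BASE_C, "G": BASE_G, "T": BASE_T, "N": BASE_SPACER}
COMPLEMENT = {BASE_A: BASE_T, BASE_T: BASE_A, BASE_C: BASE_G, BASE_G: BASE_C}

# body species for the two-body CD basis
BODY_NP = 0
BODY_CAGE = 1

# ---------------------------------------------------------------------------
# Interaction constants (reduced units)
# ---------------------------------------------------------------------------
WCA_SHIFT = 2.0 ** (1.0 / 6.0)      # position of the WCA cutoff in (r - Delta)
FENE_REST = 0.9608971989592554      # minimum of the standard FENE potential (Delta=0)

#: particle diameters for excluded volume (NP center is set per NP size)
DIAM_CAGE_EDGE = 9.9
DIAM_CAGE_CENTER = 40.0
DIAM_DNA = 1.0

#: regular dodecahedron geometry: edge / circumscribed diameter = 1/(sqrt(3)*phi)
GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
DODECA_EDGE_OVER_D = 1.0 / (np.sqrt(3.0) * GOLDEN)
#: inscribed / circumscribed radius ratio of the dodecahedron
#: (r_in = a*sqrt(250+110*sqrt(5))/20, R = a*sqrt(3)*(1+sqrt(5))/4 for edge a)
DODECA_INSCRIBED_OVER_CIRCUM = float(
    (np.sqrt(250.0 + 110.0 * np.sqrt(5.0)) / 20.0)
    / (np.sqrt(3.0) * (1.0 + np.sqrt(5.0)) / 4.0))

# FENE bond parameter rows (kb, R0, eps, delta), one per bonded role.
BOND_EDGE_1 = (240.0, 1.5, 8.0, 6.36)      # edge beads, first neighbour
BOND_EDGE_2 = (240.0, 1.5, 8.0, 13.67)     # edge beads, second neighbour (linearity)
BOND_ANCHOR_CENTER = (240.0, 1.5, 8.0, 36.52)  # vertex DNA anchor to cage center
BOND_VERTEX_EDGE = (30.0, 1.5, 1.0, 15.08)  # truncated-vertex bead to edge bead
BOND_CORNER = (30.0, 1.5, 1.0, 9.15)       # corner-region links (vertex-vertex,
                                           # anchor-vertex, edge-to-edge at corners)
BOND_DNA = (30.0, 1.5, 1.0, 0.0)           # all intra-DNA + grafting bonds

BOND_ROLE_NAMES = [
    "edge_first_neighbor", "edge_second_neighbor", "anchor_center",
    "vertex_edge", "corner", "dna", "np_center_vertex", "np_vertex_vertex",
    "tether",
]

#: default sticky-end sequences (5'->3' read outward from the body); the NP
#: sequence is the reverse complement of the cage sequence so that only
#: cage-NP hybridization is possible, and neither 8-mer is self-complementary.
CAGE_STICKY = "GCGCAGTC"
NP_STICKY = "GACTGCGC"
N_SPACER = 7
N_STICKY = 8
N_NT = N_SPACER + N_STICKY           # nucleotides per strand
BB_SPACING = FENE_REST               # backbone-backbone rest distance

#: tetrahedral bonding directions of the two CD sublattices (unit vectors).
#: NPs use the positive set, cages the negated set, so that every cage strand
#: points at a nearest-neighbour NP in the ideal lattice.
TETRA_DIRS_NP = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float) / np.sqrt(3.0)
TETRA_DIRS_CAGE = -TETRA_DIRS_NP


def seed_sequence(seed: int) -> np.random.SeedSequence:
    """Root seed sequence; every stochastic routine spawns children from one
    of these so that a single integer reproduces a whole study."""
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------
@dataclass
class Topology:
    """Typed force sites plus bond/angle lists for one or more bodies.

    All arrays are aligned on the site axis.  ``strand`` is -1 for non-DNA
    sites; ``base`` is -1 for non-base sites.  ``extra_exclusions`` lists
    site pairs whose non-bonded interaction is switched off in addition to
    the automatic bond-graph exclusions (pairs within three bonds).
    """

    pos: np.ndarray                  # (N, 3) float
    diameter: np.ndarray             # (N,)
    mass: np.ndarray                 # (N,)
    species: np.ndarray              # (N,) int8
    body: np.ndarray                 # (N,) int32
    strand: np.ndarray               # (N,) int32, -1 for non-DNA
    base: np.ndarray                 # (N,) int8, -1 for non-base sites
    bonds: np.ndarray                # (NB, 2) int32
    bond_params: np.ndarray          # (NB, 4) float: kb, R0, eps, delta
    bond_role: np.ndarray            # (NB,) int8
    angles: np.ndarray               # (NA, 3) int32, angle at middle index
    angle_k: np.ndarray              # (NA,)
    extra_exclusions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int32))

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def copy(self) -> "Topology":
        return Topology(*[np.array(getattr(self, f)) for f in (
            "pos", "diameter", "mass", "species", "body", "strand", "base",
            "bonds", "bond_params", "bond_role", "angles", "angle_k",
            "extra_exclusions")])

    def translated(self, shift: np.ndarray) -> "Topology":
        out = self.copy()
        out.pos = out.pos + np.asarray(shift, dtype=float)
        return out


def merge_topologies(parts: Sequence[Topology]) -> Topology:
    """Concatenate topologies, offsetting site, body and strand indices."""
    site_off = 0
    body_off = 0
    strand_off = 0
    acc: dict[str, list[np.ndarray]] = {f: [] for f in (
        "pos", "diameter", "mass", "species", "body", "strand", "base",
        "bonds", "bond_params", "bond_role", "angles", "angle_k",
        "extra_exclusions")}
    for t in parts:
        acc["pos"].append(t.pos)
        acc["diameter"].append(t.diameter)
        acc["mass"].append(t.mass)
        acc["species"].append(t.species)
        acc["body"].append(t.body + body_off)
        strand = t.strand.copy()
        strand[strand >= 0] += strand_off
        acc["strand"].append(strand)
        acc["base"].append(t.base)
        acc["bonds"].append(t.bonds + site_off)
        acc["bond_params"].append(t.bond_params)
        acc["bond_role"].append(t.bond_role)
        acc["angles"].append(t.angles + site_off)
        acc["angle_k"].append(t.angle_k)
        acc["extra_exclusions"].append(t.extra_exclusions + site_off)
        site_off += t.n_sites
        body_off += int(t.body.max()) + 1 if len(t.body) else 0
        if np.any(t.strand >= 0):
            strand_off += int(t.strand.max()) + 1
    return Topology(
        pos=np.concatenate(acc["pos"]),
        diameter=np.concatenate(acc["diameter"]),
        mass=np.concatenate(acc["mass"]),
        species=np.concatenate(acc["species"]),
        body=np.concatenate(acc["body"]).astype(np.int32),
        strand=np.concatenate(acc["strand"]).astype(np.int32),
        base=np.concatenate(acc["base"]),
        bonds=np.concatenate(acc["bonds"]).astype(np.int32),
        bond_params=np.concatenate(acc["bond_params"]),
        bond_role=np.concatenate(acc["bond_role"]),
        angles=np.concatenate(acc["angles"]).astype(np.int32),
        angle_k=np.concatenate(acc["angle_k"]),
        extra_exclusions=np.concatenate(acc["extra_exclusions"]).astype(np.int32),
    )


# ---------------------------------------------------------------------------
# System and trajectories
# ---------------------------------------------------------------------------
@dataclass
class System:
    """A topology in a (possibly triclinic) periodic box, with body maps.

    ``box`` holds the three cell vectors as rows; fractional wrapping is
    half-open [0, 1).  ``ideal_neighbors`` lists cage-NP body pairs that are
    nearest neighbours of the ideal CD lattice (used to tell lattice bonds
    from surface-reorientation bonds).
    """

    topology: Topology
    box: np.ndarray                       # (3, 3) row vectors
    periodic: np.ndarray                  # (3,) bool
    body_center_site: np.ndarray          # (B,) site index of each body center
    body_species: np.ndarray              # (B,) BODY_NP / BODY_CAGE
    body_cell: np.ndarray                 # (B, 3) int lattice-cell index (-1 for slabs' z? kept real)
    ideal_centers: np.ndarray             # (B, 3) ideal body-center positions
    orientation_sites: list               # per body: array of probe site indices
    ideal_neighbors: np.ndarray           # (K, 2) body index pairs (cage, np)
    lattice_constant: float = 0.0         # conventional CD lattice constant b
    meta: dict = field(default_factory=dict)

    @property
    def n_bodies(self) -> int:
        return len(self.body_center_site)


@dataclass
class BodyTrajectory:
    """Time-ordered body-center coordinates (and optional orientation probes)
    in a periodic box.  This is the common currency of every analysis stage:
    MD runs are coarse-grained to it and the harmonic surrogate emits it
    directly.

    ``orientations`` has shape (F, B, K, 3): K unit probe vectors per body
    (cage linker directions / NP tetrad vertices).  ``energies`` is the total
    potential energy per frame when available.
    """

    centers: np.ndarray                   # (F, B, 3)
    box: np.ndarray                       # (3, 3)
    species: np.ndarray                   # (B,)
    cells: np.ndarray                     # (B, 3) int
    masses: np.ndarray                    # (B,)
    ideal_centers: np.ndarray             # (B, 3)
    times: np.ndarray | None = None       # (F,)
    orientations: np.ndarray | None = None
    energies: np.ndarray | None = None
    lattice_constant: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.centers)

    @property
    def n_bodies(self) -> int:
        return self.centers.shape[1]


def wrap_fractional(pos: np.ndarray, box: np.ndarray,
                    periodic: np.ndarray | None = None) -> np.ndarray:
    """Wrap Cartesian coordinates into the half-open [0,1) fractional cell."""
    inv = np.linalg.inv(box)
    frac = pos @ inv
    if periodic is None:
        frac = frac - np.floor(frac)
    else:
        for ax in range(3):
            if periodic[ax]:
                frac[..., ax] -= np.floor(frac[..., ax])
    return frac @ box


def minimum_image(dr: np.ndarray, box: np.ndarray,
                  periodic: np.ndarray | None = None) -> np.ndarray:
    """Minimum-image displacement vectors for a triclinic box."""
    inv = np.linalg.inv(box)
    frac = dr @ inv
    if periodic is None:
        frac = frac - np.round(frac)
    else:
        for ax in range(3):
            if periodic[ax]:
                frac[..., ax] -= np.round(frac[..., ax])
    return frac @ box
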