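"""Construction of coarse-grained topologies and initial coordinates.

Builds the four-valent DNA-origami tetrahedral cage, the dodecahedral
DNA-grafted nanoparticle (NP), fully bonded bulk cubic-diamond (CD) lattices,
and crystal slabs exposing (100)/(110)/(111) facets.

Geometry conventions
--------------------
* The cage frame is a regular tetrahedron with truncated corners.  Each edge
  carries seven 9.9-sigma beads at the first-neighbour FENE rest spacing; the
  outermost beads of the three edges meeting at a corner are tied together,
  three truncated-vertex beads sit on the truncation plane, and a single
  anchor bead (the first nucleotide of the vertex linker) sits on the
  corner axis, tethered to the 40-sigma central sphere.  The exact placement
  of the corner beads is fixed by requiring every bond of the corner region
  to sit at its FENE rest length; this has a unique (chiral) solution.
* NPs are regular dodecahedra (20 vertex sites + 1 center).  The first four
  vertices are the cube-diagonal tetrad that faces the four cage neighbours
  in the ideal CD lattice.
* In lattices, every cage-NP nearest-neighbour link is built pre-hybridized:
  the two facing strands run antiparallel on laterally offset lines with
  their eight sticky bases in contact, so a short thermal run only has to
  keep (not find) the bonds.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import (
    BASE_FROM_CHAR, BASE_SPACER, BB_SPACING, BODY_CAGE, BODY_NP,
    BOND_ANCHOR_CENTER, BOND_CORNER, BOND_DNA, BOND_EDGE_1, BOND_EDGE_2,
    BOND_VERTEX_EDGE, CAGE_ANCHOR, CAGE_CENTER, CAGE_EDGE, CAGE_STICKY,
    CAGE_VERTEX,
    DIAM_CAGE_CENTER, DIAM_CAGE_EDGE, DIAM_DNA, DNA_BASE, DNA_BB,
    DODECA_INSCRIBED_OVER_CIRCUM, FENE_REST, GOLDEN, N_NT, N_SPACER, N_STICKY,
    NP_CENTER, NP_STICKY, NP_VERTEX, TETRA_DIRS_CAGE, TETRA_DIRS_NP,
    Topology, System, logger, merge_topologies,
)

__all__ = [
    "StrandSpec", "LatticeSpec", "SlabSpec", "ConfigurationError",
    "GeometryError", "build_cage", "build_np", "build_bulk_lattice",
    "build_slab", "ideal_body_lattice", "cd_lattice_constant",
    "pair_rest_distance",
]

# bond-role codes (index into BOND_ROLE_NAMES)
ROLE_EDGE1, ROLE_EDGE2, ROLE_ANCHOR_CENTER = 0, 1, 2
ROLE_VERTEX_EDGE, ROLE_CORNER, ROLE_DNA = 3, 4, 5
ROLE_NP_CV, ROLE_NP_VV, ROLE_TETHER = 6, 7, 8


class ConfigurationError(ValueError):
    """Raised for inconsistent model specifications (bad strand, bond role)."""


class GeometryError(ValueError):
    """Raised when requested geometry cannot host the DNA links."""


def _rest(row) -> float:
    return row[3] + FENE_REST


# ---------------------------------------------------------------------------
# Strand / lattice specs
# ---------------------------------------------------------------------------
@dataclass
class StrandSpec:
    """A 15-nucleotide linker: seven inert spacers plus an eight-base sticky
    end, read outward from the grafting point."""

    n_spacer: int = N_SPACER
    n_sticky: int = N_STICKY
    sticky_sequence: str = CAGE_STICKY

    def __post_init__(self) -> None:
        if self.n_spacer + self.n_sticky != N_NT:
            raise ConfigurationError(
                f"strand must have {N_NT} nucleotides, got "
                f"{self.n_spacer}+{self.n_sticky}")
        if len(self.sticky_sequence) != self.n_sticky:
            raise ConfigurationError("sticky sequence length mismatch")
        bad = set(self.sticky_sequence) - set("ACGT")
        if bad:
            raise ConfigurationError(f"unknown bases {bad}")

    @property
    def base_codes(self) -> np.ndarray:
        codes = [BASE_SPACER] * self.n_spacer + [
            BASE_FROM_CHAR[c] for c in self.sticky_sequence]
        return np.array(codes, dtype=np.int8)


@dataclass
class LatticeSpec:
    """Replication counts and lattice constant of a bulk CD lattice.

    The primitive cell holds one NP (at the origin) and one cage (at
    b/4*(1,1,1)); the box is triclinic with equal side lengths and 60-degree
    angles (the FCC primitive cell of the NP sublattice).
    """

    nx: int = 4
    ny: int = 4
    nz: int = 4
    b: float | None = None        # conventional lattice constant; None = from rest geometry
    d: float = 40.0               # NP circumscribed diameter
    ka: float = 1.0               # DNA / linker angular stiffness


@dataclass
class SlabSpec:
    facet: tuple[int, int, int] = (1, 1, 1)
    n_layers: int = 8
    surface_cells: tuple[int, int] = (4, 4)
    termination: str = "min_broken"      # or "cage_both_sides"
    d: float = 40.0
    ka: float = 1.0
    b: float | None = None
    vacuum: float = 80.0


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------
@dataclass
class BodyTemplate:
    topology: Topology
    center_site: int
    probe_sites: np.ndarray            # orientation probes (anchors / tetrad vertices)
    strand_dirs: np.ndarray            # (S, 3) outward grafting directions
    strand_bb: np.ndarray              # (S, N_NT) backbone site indices
    strand_base: np.ndarray            # (S, N_NT) base site indices
    strand_graft: np.ndarray           # (S,) site the strand is anchored to
    body_species: int = BODY_CAGE
    meta: dict = field(default_factory=dict)


class _TopoBuilder:
    """Incremental topology assembly."""

    def __init__(self) -> None:
        self.pos: list = []
        self.diameter: list = []
        self.species: list = []
        self.strand: list = []
        self.base: list = []
        self.bonds: list = []
        self.bond_params: list = []
        self.bond_role: list = []
        self.angles: list = []
        self.angle_k: list = []
        self.exclusions: list = []

    def add_site(self, pos, diameter, species, strand=-1, base=-1) -> int:
        self.pos.append(np.asarray(pos, dtype=float))
        self.diameter.append(diameter)
        self.species.append(species)
        self.strand.append(strand)
        self.base.append(base)
        return len(self.pos) - 1

    def add_bond(self, i, j, row, role) -> None:
        self.bonds.append((i, j))
        self.bond_params.append(row)
        self.bond_role.append(role)

    def add_angle(self, i, j, k, ka) -> None:
        self.angles.append((i, j, k))
        self.angle_k.append(ka)

    def build(self) -> Topology:
        n = len(self.pos)
        return Topology(
            pos=np.array(self.pos, dtype=float).reshape(n, 3),
            diameter=np.array(self.diameter, dtype=float),
            mass=np.ones(n),
            species=np.array(self.species, dtype=np.int8),
            body=np.zeros(n, dtype=np.int32),
            strand=np.array(self.strand, dtype=np.int32),
            base=np.array(self.base, dtype=np.int8),
            bonds=(np.array(self.bonds, dtype=np.int32).reshape(-1, 2)
                   if self.bonds else np.empty((0, 2), dtype=np.int32)),
            bond_params=(np.array(self.bond_params, dtype=float).reshape(-1, 4)
                         if self.bond_params else np.empty((0, 4))),
            bond_role=np.array(self.bond_role, dtype=np.int8),
            angles=(np.array(self.angles, dtype=np.int32).reshape(-1, 3)
                    if self.angles else np.empty((0, 3), dtype=np.int32)),
            angle_k=np.array(self.angle_k, dtype=float),
            extra_exclusions=(np.array(self.exclusions, dtype=np.int32).reshape(-1, 2)
                              if self.exclusions else np.empty((0, 2), dtype=np.int32)),
        )


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to u."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def _add_strand(tb: _TopoBuilder, graft_site: int, origin: np.ndarray,
                direction: np.ndarray, spec: StrandSpec, ka: float,
                strand_id: int, angle_anchor: int | None,
                first_is_anchor: bool) -> tuple[list[int], list[int]]:
    """Append one 15-nt linker extending from ``origin`` along ``direction``.

    ``first_is_anchor``: the cage linker's first backbone bead is the frame
    anchor (already a site, graft_site); NP linkers add all 15 backbones and
    graft to a dodecahedron vertex.  Returns (backbone sites, base sites).
    """
    u = direction / np.linalg.norm(direction)
    p = _perpendicular(u)
    codes = spec.base_codes
    bbs: list[int] = []
    bases: list[int] = []
    for j in range(N_NT):
        if j == 0 and first_is_anchor:
            bb = graft_site
            tb.strand[bb] = strand_id
        else:
            bb = tb.add_site(origin + (j * BB_SPACING) * u, DIAM_DNA, DNA_BB,
                             strand=strand_id)
        base = tb.add_site(tb.pos[bb] + BB_SPACING * p, DIAM_DNA, DNA_BASE,
                           strand=strand_id, base=int(codes[j]))
        tb.add_bond(bb, base, BOND_DNA, ROLE_DNA)
        if bbs:
            tb.add_bond(bbs[-1], bb, BOND_DNA, ROLE_DNA)
        elif not first_is_anchor:
            tb.add_bond(graft_site, bb, BOND_DNA, ROLE_DNA)
        bbs.append(bb)
        bases.append(base)
    # orientation: angle at the grafted nucleotide between the body center and
    # the next nucleotide, V = ka (1 + cos theta), minimised when the strand
    # points radially outward; plus the same term along the backbone, which
    # makes ka the persistence knob of the whole linker.
    if angle_anchor is not None:
        tb.add_angle(angle_anchor, bbs[0], bbs[1], ka)
    for j in range(N_NT - 2):
        tb.add_angle(bbs[j], bbs[j + 1], bbs[j + 2], ka)
    return bbs, bases


def build_free_strand(sequence: str = CAGE_STICKY, origin=(0.0, 0.0, 0.0),
                      direction=(0.0, 0.0, 1.0), ka: float = 1.0) -> Topology:
    """A single ungrafted 15-nt linker (melting / hybridization studies)."""
    spec = StrandSpec(sticky_sequence=sequence)
    tb = _TopoBuilder()
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    first = tb.add_site(origin, DIAM_DNA, DNA_BB, strand=0)
    _add_strand(tb, first, origin, direction, spec, ka, strand_id=0,
                angle_anchor=None, first_is_anchor=True)
    return tb.build()


# ---------------------------------------------------------------------------
# Cage
# ---------------------------------------------------------------------------
def _cage_corner_geometry() -> dict:
    """Solve the truncated-corner placement so all corner bonds are at rest.

    Unknown is the azimuthal rotation psi of the truncated-vertex triangle
    relative to the edge tangents; the radial placement follows from the
    anchor-center and corner-bond rest lengths.
    """
    r_e1 = _rest(BOND_EDGE_1)
    r_corner = _rest(BOND_CORNER)
    r_ve = _rest(BOND_VERTEX_EDGE)
    r_ac = _rest(BOND_ANCHOR_CENTER)
    u0 = r_corner                      # corner bead offset = edge-edge rest length
    L = 6 * r_e1 + 2 * u0              # ideal (untruncated) edge length
    rc = r_corner / math.sqrt(3.0)     # vertex-triangle circumradius
    h = r_ac + math.sqrt(r_corner ** 2 - rc ** 2)   # triangle plane radius
    return dict(r_e1=r_e1, r_corner=r_corner, r_ve=r_ve, r_ac=r_ac,
                u0=u0, L=L, rc=rc, h=h)


def build_cage(ka: float = 1.0, strand: StrandSpec | None = None) -> BodyTemplate:
    """Tetrahedral DNA-origami cage: 42 edge beads, 12 truncated-vertex beads,
    4 linker anchors, 1 central 40-sigma sphere, 4 grafted linkers."""
    if not (0.5 <= ka <= 2.0):
        logger.warning("ka=%.3g outside the studied stiffness range [0.5, 2.0]", ka)
    strand = strand or StrandSpec(sticky_sequence=CAGE_STICKY)
    g = _cage_corner_geometry()
    dirs = TETRA_DIRS_CAGE
    corners = g["L"] * math.sqrt(3.0 / 8.0) * dirs   # corner circumradius = L*sqrt(3/8)

    tb = _TopoBuilder()
    center = tb.add_site((0.0, 0.0, 0.0), DIAM_CAGE_CENTER, CAGE_CENTER)

    # edge bead chains (6 edges x 7 beads) + first/second-neighbour bonds
    edge_sites: dict[tuple[int, int], list[int]] = {}
    for a, bb in itertools.combinations(range(4), 2):
        e = corners[bb] - corners[a]
        e /= np.linalg.norm(e)
        chain = []
        for j in range(7):
            u = g["u0"] + j * g["r_e1"]
            chain.append(tb.add_site(corners[a] + u * e, DIAM_CAGE_EDGE, CAGE_EDGE))
        for j in range(6):
            tb.add_bond(chain[j], chain[j + 1], BOND_EDGE_1, ROLE_EDGE1)
        for j in range(5):
            tb.add_bond(chain[j], chain[j + 2], BOND_EDGE_2, ROLE_EDGE2)
        edge_sites[(a, bb)] = chain

    def outer_bead(corner, other):
        chain = edge_sites[(min(corner, other), max(corner, other))]
        return chain[0] if corner < other else chain[-1]

    anchors: list[int] = []
    strand_bb: list[list[int]] = []
    strand_base: list[list[int]] = []
    for c in range(4):
        v = dirs[c]
        others = [o for o in range(4) if o != c]
        # corner ties between outermost edge beads
        for o1, o2 in itertools.combinations(others, 2):
            tb.add_bond(outer_bead(c, o1), outer_bead(c, o2),
                        BOND_CORNER, ROLE_CORNER)
        anchor = tb.add_site(g["r_ac"] * v, DIAM_DNA, CAGE_ANCHOR)
        tb.add_bond(anchor, center, BOND_ANCHOR_CENTER, ROLE_ANCHOR_CENTER)
        anchors.append(anchor)

        # truncated-vertex beads: solve the triangle azimuth so the
        # vertex-edge bond is at rest
        vert_sites = []
        for o in others:
            e = corners[o] - corners[c]
            e /= np.linalg.norm(e)
            t = e - np.dot(e, v) * v
            t /= np.linalg.norm(t)
            s = np.cross(v, t)
            ob_pos = corners[c] + g["u0"] * e

            def mismatch(psi, t=t, s=s, ob=ob_pos):
                w = math.cos(psi) * t + math.sin(psi) * s
                pos = g["h"] * v + g["rc"] * w
                return np.linalg.norm(pos - ob) - g["r_ve"]

            psi = brentq(mismatch, 1e-6, 2.0 * math.pi / 3.0 - 1e-6, xtol=1e-12)
            w = math.cos(psi) * t + math.sin(psi) * s
            # the truncated-vertex beads are small (linker-scale) sites: the
            # corner must leave the central channel open for the DNA strand
            vb = tb.add_site(g["h"] * v + g["rc"] * w, DIAM_DNA, CAGE_VERTEX)
            tb.add_bond(vb, ob_pos_idx := outer_bead(c, o), BOND_VERTEX_EDGE,
                        ROLE_VERTEX_EDGE)
            tb.add_bond(vb, anchor, BOND_CORNER, ROLE_CORNER)
            vert_sites.append(vb)
        for v1, v2 in itertools.combinations(vert_sites, 2):
            tb.add_bond(v1, v2, BOND_CORNER, ROLE_CORNER)

        bbs, bases = _add_strand(tb, anchor, g["r_ac"] * v, v, strand, ka,
                                 strand_id=c, angle_anchor=center,
                                 first_is_anchor=True)
        strand_bb.append(bbs)
        strand_base.append(bases)

    # the 40-sigma core overlaps the rigid frame it belongs to; frame-core
    # pairs are excluded like bonded pairs (the frame is fully bonded anyway)
    topo = tb.build()
    frame = np.nonzero(topo.species == CAGE_EDGE)[0]
    topo.extra_exclusions = np.array(
        [(center, int(i)) for i in frame], dtype=np.int32)

    return BodyTemplate(
        topology=topo, center_site=center,
        probe_sites=np.array(anchors, dtype=np.int32),
        strand_dirs=dirs.copy(),
        strand_bb=np.array(strand_bb, dtype=np.int32),
        strand_base=np.array(strand_base, dtype=np.int32),
        strand_graft=np.array(anchors, dtype=np.int32),
        body_species=BODY_CAGE,
        meta=dict(ka=ka, corner_radius=float(np.linalg.norm(corners[0])),
                  anchor_radius=g["r_ac"], edge_length=g["L"]),
    )


# ---------------------------------------------------------------------------
# Nanoparticle
# ---------------------------------------------------------------------------
def _dodecahedron_vertices() -> np.ndarray:
    """Unit-circumradius regular dodecahedron; the first four vertices are the
    cube-diagonal tetrad used for lattice bonding."""
    phi = GOLDEN
    cube = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1),
            (-1, -1, -1), (-1, 1, 1), (1, -1, 1), (1, 1, -1)]
    rest = []
    for a, bb in ((0.0, 1 / phi),):
        for s1 in (1, -1):
            for s2 in (1, -1):
                rest += [(a, s1 * bb, s2 * phi), (s1 * bb, s2 * phi, a),
                         (s2 * phi, a, s1 * bb)]
    verts = np.array(cube + rest, dtype=float)
    return verts / np.sqrt(3.0)


def build_np(d: float = 40.0, ka: float = 1.0,
             strand: StrandSpec | None = None) -> BodyTemplate:
    """Dodecahedral NP: 20 vertex sites + 1 center (21 force sites) and 20
    grafted linkers (300 nucleotides)."""
    if not (40.0 <= d <= 120.0):
        logger.warning("NP diameter d=%.3g outside the studied range [40, 120]; "
                       "building anyway", d)
    strand = strand or StrandSpec(sticky_sequence=NP_STICKY)
    verts = _dodecahedron_vertices() * (d / 2.0)
    edge = d * (1.0 / (np.sqrt(3.0) * GOLDEN))
    ell = d / 2.8                                # Table-value vertex spacing
    tb = _TopoBuilder()
    center = tb.add_site((0, 0, 0), d * DODECA_INSCRIBED_OVER_CIRCUM, NP_CENTER)
    vsites = [tb.add_site(v, DIAM_DNA, NP_VERTEX) for v in verts]
    row_cv = (30.0, 1.5, 1.0, d / 2.0 - FENE_REST)
    row_vv = (30.0, 1.5, 1.0, ell - FENE_REST)
    for v in vsites:
        tb.add_bond(center, v, row_cv, ROLE_NP_CV)
    dists = np.linalg.norm(verts[:, None] - verts[None], axis=-1)
    for i in range(20):
        for j in range(i + 1, 20):
            if dists[i, j] < edge * 1.2:
                tb.add_bond(vsites[i], vsites[j], row_vv, ROLE_NP_VV)

    strand_bb, strand_base = [], []
    for s, v in enumerate(verts):
        u = v / np.linalg.norm(v)
        bbs, bases = _add_strand(tb, vsites[s], v + BB_SPACING * u, u, strand,
                                 ka, strand_id=s, angle_anchor=center,
                                 first_is_anchor=False)
        strand_bb.append(bbs)
        strand_base.append(bases)

    return BodyTemplate(
        topology=tb.build(), center_site=center,
        probe_sites=np.array(vsites[:4], dtype=np.int32),
        strand_dirs=verts / np.linalg.norm(verts, axis=1, keepdims=True),
        strand_bb=np.array(strand_bb, dtype=np.int32),
        strand_base=np.array(strand_base, dtype=np.int32),
        strand_graft=np.array(vsites, dtype=np.int32),
        body_species=BODY_NP,
        meta=dict(d=d, ka=ka, edge=edge, ell=ell),
    )


# ---------------------------------------------------------------------------
# Lattice geometry helpers
# ---------------------------------------------------------------------------
def link_rest_distance(d: float) -> float:
    """Ideal cage-center to NP-center separation of one hybridized link."""
    r_ac = _rest(BOND_ANCHOR_CENTER)
    return r_ac + d / 2.0 + (2 * N_NT - N_STICKY) * BB_SPACING


def pair_rest_distance(d: float) -> float:  # pragma: no cover - alias
    return link_rest_distance(d)


def cd_lattice_constant(d: float) -> float:
    """Conventional CD lattice constant with nearest-neighbour links at rest."""
    return 4.0 * link_rest_distance(d) / math.sqrt(3.0)


#: lateral half-offset of the two zipped strands from the link axis, chosen so
#: facing bases sit near the hybridization-well minimum (separation ~1.05)
_ZIP_HALF_SEP = (2 * BB_SPACING + 1.05) / 2.0


def _zip_positions(topo: Topology, tmpl: BodyTemplate, offset: int,
                   strand_idx: int, center: np.ndarray, u: np.ndarray,
                   p: np.ndarray, start_radius: float, lateral_sign: float,
                   base_sign: float) -> None:
    """Reposition one linker into zipped geometry: an axial run at
    ``start_radius`` from ``center`` along ``u``, ramping laterally over the
    spacer region to ``lateral_sign * _ZIP_HALF_SEP`` off the axis."""
    bbs = tmpl.strand_bb[strand_idx] + offset
    bases = tmpl.strand_base[strand_idx] + offset
    for j in range(N_NT):
        ramp = min(j, N_SPACER - 1) / (N_SPACER - 1)
        axial = start_radius + j * BB_SPACING
        lat = lateral_sign * _ZIP_HALF_SEP * ramp
        topo.pos[bbs[j]] = center + axial * u + lat * p
        topo.pos[bases[j]] = topo.pos[bbs[j]] + base_sign * BB_SPACING * p


def _zip_link(topo: Topology, cage_t: BodyTemplate, np_t: BodyTemplate,
              cage_off: int, np_off: int, strand_idx: int,
              cage_center: np.ndarray, u: np.ndarray, d: float) -> None:
    """Pre-hybridize cage strand s with the facing NP strand s along axis u
    (unit vector from the cage center toward the NP ideal position)."""
    p = _perpendicular(u)
    r_ac = _rest(BOND_ANCHOR_CENTER)
    D = link_rest_distance(d)
    np_center_image = cage_center + D * u
    _zip_positions(topo, cage_t, cage_off, strand_idx, cage_center, u, p,
                   r_ac, lateral_sign=-1.0, base_sign=+1.0)
    # the NP may be stored as a periodic image; positions are laid out in the
    # image frame and shifted by the (lattice-vector) difference afterwards
    np_real = topo.pos[np_t.center_site + np_off]
    shift = np_real - np_center_image
    _zip_positions(topo, np_t, np_off, strand_idx, np_center_image, -u, p,
                   d / 2.0 + BB_SPACING, lateral_sign=+1.0, base_sign=-1.0)
    sel = np.concatenate([np_t.strand_bb[strand_idx], np_t.strand_base[strand_idx]])
    topo.pos[sel + np_off] += shift


def ideal_body_lattice(n: int, b: float) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray]:
    """Body-center lattice only (no force sites): returns (centers, species,
    cells, box) for an n^3 CD lattice, NP first then cage in each cell."""
    prim = b / 2.0 * np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
    cells = np.array(list(itertools.product(range(n), repeat=3)), dtype=int)
    origins = cells @ prim
    centers = np.empty((len(cells) * 2, 3))
    species = np.empty(len(cells) * 2, dtype=np.int8)
    cc = np.empty((len(cells) * 2, 3), dtype=int)
    centers[0::2] = origins
    centers[1::2] = origins + b / 4.0
    species[0::2] = BODY_NP
    species[1::2] = BODY_CAGE
    cc[0::2] = cells
    cc[1::2] = cells
    return centers, species, cc, n * prim


# cage strand s points along TETRA_DIRS_CAGE[s]; its NP neighbour sits in the
# cell shifted by these primitive-translation offsets
_CAGE_NEIGHBOR_CELL = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def build_bulk_lattice(spec: LatticeSpec,
                       cage: BodyTemplate | None = None,
                       nano: BodyTemplate | None = None) -> System:
    """Fully bonded n^3 bulk CD lattice with every nearest-neighbour link
    pre-hybridized.  All cages share one orientation; NPs the opposite."""
    if not (spec.nx == spec.ny == spec.nz and spec.nx >= 1):
        raise ConfigurationError("bulk lattice must be cubic in cells, n>=1")
    n = spec.nx
    d, ka = spec.d, spec.ka
    b = spec.b if spec.b is not None else cd_lattice_constant(d)
    cage = cage or build_cage(ka)
    nano = nano or build_np(d, ka)
    D = math.sqrt(3.0) * b / 4.0
    min_D = cage.meta["corner_radius"] + d / 2.0
    if D < min_D:
        raise GeometryError(
            f"lattice constant b={b:.3g} leaves no room for the DNA links "
            f"(center separation {D:.3g} < {min_D:.3g})")

    centers, species, cells, box = ideal_body_lattice(n, b)
    parts, offsets, off = [], [], 0
    for i in range(len(centers)):
        tmpl = nano if species[i] == BODY_NP else cage
        parts.append(tmpl.topology.translated(centers[i]))
        offsets.append(off)
        off += tmpl.topology.n_sites
    topo = merge_topologies(parts)

    n_cells = n ** 3
    cell_index = {tuple(c): i for i, c in enumerate(
        itertools.product(range(n), repeat=3))}
    links = []
    for ci, cell in enumerate(itertools.product(range(n), repeat=3)):
        cage_body = 2 * ci + 1
        for s in range(4):
            ncell = tuple((np.array(cell) + _CAGE_NEIGHBOR_CELL[s]) % n)
            np_body = 2 * cell_index[ncell]
            u = TETRA_DIRS_CAGE[s]
            _zip_link(topo, cage, nano, offsets[cage_body], offsets[np_body],
                      s, centers[cage_body], u, d)
            links.append((cage_body, np_body))

    probe, bcs = [], []
    for i in range(len(centers)):
        tmpl = nano if species[i] == BODY_NP else cage
        probe.append(tmpl.probe_sites + offsets[i])
        bcs.append(tmpl.center_site + offsets[i])

    return System(
        topology=topo, box=box, periodic=np.array([True] * 3),
        body_center_site=np.array(bcs, dtype=np.int32),
        body_species=species, body_cell=cells,
        ideal_centers=centers, orientation_sites=probe,
        ideal_neighbors=np.array(links, dtype=np.int32),
        lattice_constant=b,
        meta=dict(n=n, d=d, ka=ka, n_cells=n_cells),
    )


# ---------------------------------------------------------------------------
# Slabs
# ---------------------------------------------------------------------------
#: in-plane lattice translations (units of b) and outward normals per facet
_FACETS = {
    (1, 0, 0): dict(A1=(0.0, 0.5, 0.5), A2=(0.0, 0.5, -0.5)),
    (1, 1, 0): dict(A1=(0.0, 0.0, 1.0), A2=(0.5, -0.5, 0.0)),
    (1, 1, 1): dict(A1=(0.5, -0.5, 0.0), A2=(0.5, 0.0, -0.5)),
}

_CONV_BASIS_NP = np.array([(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)])
_CONV_BASIS_CAGE = _CONV_BASIS_NP + 0.25


def _slab_sites(facet, s1, s2, n_layers_span):
    """Enumerate CD body sites of an in-plane-periodic column, keyed by
    wrapped in-plane fractions and the out-of-plane coordinate zeta (units of
    b).  Returns sorted layer zetas and per-site records."""
    f = _FACETS[tuple(facet)]
    A1, A2 = np.array(f["A1"]), np.array(f["A2"])
    nrm = np.array(facet, dtype=float)
    nrm /= np.linalg.norm(nrm)
    M = np.linalg.inv(np.stack([A1 * s1, A2 * s2, nrm]).T)
    m = n_layers_span + 4
    seen = {}
    for cell in itertools.product(range(-m, m + 1), repeat=3):
        for basis, sp in ((_CONV_BASIS_NP, BODY_NP), (_CONV_BASIS_CAGE, BODY_CAGE)):
            for bpos in basis:
                r = np.array(cell, dtype=float) + bpos
                c = M @ r
                zeta = c[2]
                if not (-0.05 <= zeta <= n_layers_span):
                    continue
                f1, f2 = c[0] % 1.0, c[1] % 1.0
                key = (round(f1 % 1.0, 6) % 1.0, round(f2 % 1.0, 6) % 1.0,
                       round(zeta, 6))
                if key not in seen:
                    pos = (f1 * s1) * A1 + (f2 * s2) * A2 + zeta * nrm
                    seen[key] = (pos, sp, zeta)
    zetas = sorted({round(z, 6) for (_, _, z) in seen.values()})
    return seen, zetas, A1, A2, nrm


def _severed_count(bodies, zlo, zhi, nrm, b):
    """Nearest-neighbour link ends falling outside the zeta window."""
    cnt = 0
    for pos, sp in bodies:
        dirs = TETRA_DIRS_NP if sp == BODY_NP else TETRA_DIRS_CAGE
        for u in dirs:
            z = (pos + (math.sqrt(3.0) / 4.0) * u) @ nrm
            if z < zlo - 1e-9 or z > zhi + 1e-9:
                cnt += 1
    return cnt


def build_slab(spec: SlabSpec, cage: BodyTemplate | None = None,
               nano: BodyTemplate | None = None) -> System:
    """Crystal slab with the requested facet exposed: periodic in plane,
    non-periodic along z, strands of severed links left dangling."""
    facet = tuple(spec.facet)
    if facet not in _FACETS:
        raise ConfigurationError(f"unsupported facet {facet}; "
                                 "use (100), (110) or (111)")
    d, ka = spec.d, spec.ka
    b = spec.b if spec.b is not None else cd_lattice_constant(d)
    cage = cage or build_cage(ka)
    nano = nano or build_np(d, ka)
    s1, s2 = spec.surface_cells

    # work in units of b until the final scaling
    span = max(spec.n_layers, 4)
    seen, zetas, A1, A2, nrm = _slab_sites(facet, s1, s2, span)

    # choose the window of n_layers consecutive layers per the termination
    best = None
    for start in range(0, len(zetas) - spec.n_layers + 1):
        window = zetas[start:start + spec.n_layers]
        zlo, zhi = window[0], window[-1]
        bodies = [(pos, sp) for (pos, sp, z) in seen.values()
                  if zlo - 1e-6 <= z <= zhi + 1e-6]
        if spec.termination == "cage_both_sides":
            lo_sp = {sp for (pos, sp, z) in seen.values() if abs(z - zlo) < 1e-6}
            hi_sp = {sp for (pos, sp, z) in seen.values() if abs(z - zhi) < 1e-6}
            if lo_sp != {BODY_CAGE} or hi_sp != {BODY_CAGE}:
                continue
        cuts = _severed_count(bodies, zlo, zhi, nrm, b)
        if best is None or cuts < best[0]:
            best = (cuts, window, bodies)
    if best is None:
        raise GeometryError(
            f"no {spec.termination} window of {spec.n_layers} layers for {facet}; "
            "for (100) cage-terminated slabs use an odd layer count")
    _, window, bodies = best

    # rotate so the facet normal is +z and A1 lies in the xy plane
    xhat = A1 / np.linalg.norm(A1)
    zhat = nrm
    yhat = np.cross(zhat, xhat)
    Q = np.stack([xhat, yhat, zhat])

    centers = np.array([pos for pos, sp in bodies]) * b
    species = np.array([sp for pos, sp in bodies], dtype=np.int8)

    parts, offsets, off = [], [], 0
    for i in range(len(centers)):
        tmpl = nano if species[i] == BODY_NP else cage
        parts.append(tmpl.topology.translated(centers[i]))
        offsets.append(off)
        off += tmpl.topology.n_sites
    topo = merge_topologies(parts)

    # in-plane periodic neighbour lookup for link zipping
    Ain = np.stack([A1 * s1 * b, A2 * s2 * b, nrm])
    Minv = np.linalg.inv(Ain.T)

    def wrap_key(r):
        c = Minv @ r
        return (round(c[0] % 1.0, 5) % 1.0, round(c[1] % 1.0, 5) % 1.0,
                round(c[2] / b, 5))

    lookup = {wrap_key(centers[i]): i for i in range(len(centers))}
    D = math.sqrt(3.0) * b / 4.0
    links = []
    for i in range(len(centers)):
        if species[i] != BODY_CAGE:
            continue
        for s in range(4):
            u = TETRA_DIRS_CAGE[s]
            target = centers[i] + D * u
            j = lookup.get(wrap_key(target))
            if j is None:
                continue
            _zip_link(topo, cage, nano, offsets[i], offsets[j], s,
                      centers[i], u, d)
            links.append((i, j))

    # final rigid rotation into the slab frame + vacuum along z
    topo.pos = topo.pos @ Q.T
    centers_r = centers @ Q.T
    zmin = topo.pos[:, 2].min()
    topo.pos[:, 2] -= zmin - spec.vacuum
    centers_r[:, 2] -= zmin - spec.vacuum
    thickness = topo.pos[:, 2].max() + spec.vacuum
    box = np.stack([Q @ (A1 * s1 * b), Q @ (A2 * s2 * b),
                    np.array([0.0, 0.0, thickness])])

    probe, bcs = [], []
    for i in range(len(centers)):
        tmpl = nano if species[i] == BODY_NP else cage
        probe.append(tmpl.probe_sites + offsets[i])
        bcs.append(tmpl.center_site + offsets[i])

    n_np = int(np.sum(species == BODY_NP))
    return System(
        topology=topo, box=box, periodic=np.array([True, True, False]),
        body_center_site=np.array(bcs, dtype=np.int32),
        body_species=species,
        body_cell=np.zeros((len(centers), 3), dtype=int),
        ideal_centers=centers_r, orientation_sites=probe,
        ideal_neighbors=np.array(links, dtype=np.int32).reshape(-1, 2),
        lattice_constant=b,
        meta=dict(facet=facet, n_layers=spec.n_layers, d=d, ka=ka,
                  n_np=n_np, termination=spec.termination,
                  area=float(np.linalg.norm(np.cross(box[0], box[1])))),
    )
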