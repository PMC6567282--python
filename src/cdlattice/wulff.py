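"""Facet surface energies and equilibrium crystallite shapes.

Two routes to the surface energy of a CD facet:

* a broken-bond count: severed nearest-neighbour links per unit area of the
  cut plane, at the termination with the fewest cuts (each link costs one
  DNA hybridization energy, so per-area link counts are relative surface
  energies);
* a slab estimator gamma = (<E_slab> - <E_bulk,matched>) / (2A) from
  simulated (or synthetic) slab and bulk energies.

The equilibrium crystallite shape follows from the Wulff rule
lambda = gamma_hkl / l_hkl = const: the shape is the intersection of
half-spaces at distances proportional to the facet energies, expanded over
the full cubic point group.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .core import BODY_CAGE, BODY_NP, TETRA_DIRS_CAGE, TETRA_DIRS_NP, logger

__all__ = [
    "FacetEnergy", "WulffShape", "broken_bond_density",
    "surface_energy_from_slab", "wulff_construct", "shape_threshold_scan",
    "cubic_family",
]

_LOW_INDEX = {(1, 0, 0), (1, 1, 0), (1, 1, 1)}


@dataclass
class FacetEnergy:
    hkl: tuple[int, int, int]
    gamma: float
    gamma_rel: float          # gamma / gamma_111
    source: str               # "broken_bond" or "slab_md"
    ka: float | None = None
    uncertainty: float = 0.0


@dataclass
class WulffShape:
    gammas: dict                       # family -> gamma
    vertices: np.ndarray               # polyhedron vertices
    area_fractions: dict               # family -> fraction of surface area
    label: str = "other"
    facet_normals: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Broken-bond counting
# ---------------------------------------------------------------------------
def broken_bond_density(hkl, termination: str = "min",
                        cells: int = 8) -> tuple[float, float]:
    """Severed nearest-neighbour links per unit area for a cut normal to hkl.

    Enumerates the bodies of an in-plane-periodic CD column (``cells`` x
    ``cells`` in-plane primitive cells, unit lattice constant, several layer
    periods deep), scans every distinct cut plane between layers, and counts
    links whose two ends straddle the cut.  Returns ``(per_area,
    per_surface_body)``; "min" selects the parallel plane with fewest cuts
    (for (111) that is 1 per surface body, the alternative is 3; for (100)
    every plane severs 2).
    """
    from .builders import _slab_sites  # shared facet geometry

    hkl = tuple(sorted((int(abs(h)) for h in hkl), reverse=True))
    if hkl not in _LOW_INDEX:
        raise ValueError(f"{hkl} is not a low-index CD facet; "
                         "supported: (100), (110), (111)")
    seen, zetas, A1, A2, nrm = _slab_sites(hkl, cells, cells, 3)
    area = float(np.linalg.norm(np.cross(A1, A2))) * cells * cells
    bodies = [(pos, sp, z) for (pos, sp, z) in seen.values()]
    nn = math.sqrt(3.0) / 4.0

    # cuts between consecutive layers, restricted to the middle of the column
    mids = [(zetas[i] + zetas[i + 1]) / 2.0 for i in range(len(zetas) - 1)]
    mids = [c for c in mids if 1.0 <= c <= 2.0]
    results = []
    for c in mids:
        cut = 0
        surface = 0
        below = max(z for z in zetas if z < c)
        for pos, sp, z in bodies:
            if z >= c:
                continue
            dirs = TETRA_DIRS_NP if sp == BODY_NP else TETRA_DIRS_CAGE
            cut += int(np.sum((pos + nn * dirs) @ nrm > c))
            if abs(z - below) < 1e-5:
                surface += 1
        results.append((cut, surface))
    counts = np.array([r[0] for r in results])
    idx = int(np.argmin(counts) if termination == "min" else np.argmax(counts))
    count, n_surface = results[idx]
    return count / area, count / n_surface


# ---------------------------------------------------------------------------
# Slab estimator (Eq.-4 style)
# ---------------------------------------------------------------------------
def surface_energy_from_slab(slab_energies, bulk_energies, area: float,
                             slab_bodies: int, bulk_bodies: int,
                             hkl=(1, 1, 1), ka: float | None = None,
                             n_blocks: int = 5) -> FacetEnergy:
    """gamma = (<E_slab> - <E_bulk, matched>) / (2 A).

    The bulk reference is rescaled per body to the slab composition (slab
    faces need not contain an integer number of NP-cage pairs).  Uncertainty
    is estimated by block averaging over the two energy series.
    """
    es = np.asarray(slab_energies, dtype=float)
    eb = np.asarray(bulk_energies, dtype=float) * (slab_bodies / bulk_bodies)
    if slab_bodies <= 0 or bulk_bodies <= 0:
        raise ValueError("body counts must be positive for composition matching")
    gamma = (es.mean() - eb.mean()) / (2.0 * area)

    def block_err(x):
        nb = min(n_blocks, len(x))
        blocks = np.array_split(x, nb)
        means = np.array([b.mean() for b in blocks])
        return means.std(ddof=1) / math.sqrt(nb) if nb > 1 else 0.0

    err = math.hypot(block_err(es), block_err(eb)) / (2.0 * area)
    return FacetEnergy(hkl=tuple(hkl), gamma=float(gamma), gamma_rel=math.nan,
                       source="slab_md", ka=ka, uncertainty=float(err))


# ---------------------------------------------------------------------------
# Wulff construction
# ---------------------------------------------------------------------------
def cubic_family(hkl) -> np.ndarray:
    """Unit normals of all cubic-point-group images of the hkl plane."""
    h = np.array(hkl, dtype=float)
    seen = set()
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1.0, -1.0), repeat=3):
            v = h[list(perm)] * signs
            v = v / np.linalg.norm(v)
            key = tuple(np.round(v, 9))
            if key not in seen:
                seen.add(key)
                out.append(v)
    return np.array(out)


def wulff_construct(gammas: dict, area_tol: float = 1e-6) -> WulffShape:
    """Equilibrium shape from per-family surface energies.

    ``gammas`` maps a representative Miller triple, e.g. (1,0,0), to its
    surface energy; each family is expanded over the 48 cubic symmetry
    operations and the shape is the intersection of half-spaces
    n.x <= gamma.  Returns per-family area fractions of the polyhedron.
    """
    if not gammas:
        raise ValueError("at least one facet family is required")
    fams, normals, offsets = [], [], []
    for hkl, g in gammas.items():
        if g <= 0:
            raise ValueError(f"gamma for {hkl} must be positive")
        fam = cubic_family(hkl)
        fams.append((tuple(hkl), len(fam)))
        normals.append(fam)
        offsets.append(np.full(len(fam), float(g)))
    normals = np.vstack(normals)
    offsets = np.concatenate(offsets)
    # bounded iff the normals positively span R^3; {100}/{110}/{111} families do
    halfspaces = np.hstack([normals, -offsets[:, None]])
    try:
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    except Exception as exc:  # pragma: no cover - scipy raises QhullError
        raise ValueError(f"unbounded or degenerate Wulff intersection: {exc}")
    verts = hs.intersections
    hull = ConvexHull(verts)

    # attribute each hull facet to the input plane it lies on
    fam_area: dict = {f: 0.0 for f, _ in fams}
    plane_families = []
    for (f, cnt) in fams:
        plane_families += [f] * cnt
    for simplex, eq in zip(hull.simplices, hull.equations):
        nrm = eq[:3]
        dist = -eq[3]
        match = np.argmax(normals @ nrm)
        if (np.dot(normals[match], nrm) > 1.0 - 1e-8
                and abs(offsets[match] - dist) < 1e-6 * max(1.0, dist)):
            tri = verts[simplex]
            a = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
            fam_area[plane_families[match]] += a
    total = sum(fam_area.values())
    fracs = {f: (a / total if total else 0.0) for f, a in fam_area.items()}
    fracs = {f: (0.0 if a < area_tol else a) for f, a in fracs.items()}

    label = _classify(fracs)
    return WulffShape(gammas=dict(gammas), vertices=verts,
                      area_fractions=fracs, label=label,
                      facet_normals=normals)


def _classify(fracs: dict) -> str:
    f100 = fracs.get((1, 0, 0), 0.0)
    f110 = fracs.get((1, 1, 0), 0.0)
    f111 = fracs.get((1, 1, 1), 0.0)
    if f100 > 0 and f111 == 0 and f110 == 0:
        return "cube"
    if f111 > 0 and f100 == 0 and f110 == 0:
        return "octahedron"
    if f111 > 0 and f100 == 0 and f110 > 0:
        return "edge-truncated octahedron"
    if f111 > 0 and f100 > 0:
        return "truncated octahedron" if f111 >= f100 else "truncated cube"
    return "other"


def shape_threshold_scan(gamma110_rel: float = 1.22,
                         lo: float = 0.3, hi: float = 2.2,
                         tol: float = 1e-4) -> dict:
    """Bisection thresholds of the crystallite-shape diagram in
    gamma100/gamma111 at fixed gamma110/gamma111.

    Returns the largest ratio still giving a pure cube (no {111} area) and
    the smallest ratio at which the {100} area vanishes (octahedron, up to
    slight {110} edge truncation when gamma110_rel < sqrt(3/2)).
    """

    def fracs(g100):
        # near-tangent facets carry O(dg^2) area; the generic reporting cutoff
        # would bias the bisection, so vanishing is detected at round-off level
        shape = wulff_construct({(1, 0, 0): g100, (1, 1, 0): gamma110_rel,
                                 (1, 1, 1): 1.0}, area_tol=1e-12)
        return shape.area_fractions

    def f111_appears(g100):
        return fracs(g100)[(1, 1, 1)] > 0.0

    def f100_vanishes(g100):
        return fracs(g100)[(1, 0, 0)] == 0.0

    if not f111_appears(hi) or f111_appears(lo):
        raise ValueError("scan range does not bracket the cube threshold")
    a, b = lo, hi
    while b - a > tol:
        m = 0.5 * (a + b)
        if f111_appears(m):
            b = m
        else:
            a = m
    cube_only = 0.5 * (a + b)

    a, b = lo, hi
    if f100_vanishes(lo) or not f100_vanishes(hi):
        raise ValueError("scan range does not bracket the octahedron threshold")
    while b - a > tol:
        m = 0.5 * (a + b)
        if f100_vanishes(m):
            b = m
        else:
            a = m
    octahedron_only = 0.5 * (a + b)

    edge_shape = wulff_construct({(1, 0, 0): max(hi, 2.0),
                                  (1, 1, 0): gamma110_rel, (1, 1, 1): 1.0})
    return dict(cube_only=cube_only, octahedron_only=octahedron_only,
                octahedron_edge_truncated=edge_shape.area_fractions[(1, 1, 0)] > 0,
                gamma110_rel=gamma110_rel)
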