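import itertools
import math

import numpy as np
import pytest

from cdlattice import builders
from cdlattice.core import (BODY_CAGE, BODY_NP, CAGE_ANCHOR, CAGE_CENTER,
                            DNA_BASE, DNA_BB, FENE_REST, GOLDEN, NP_CENTER,
                            NP_VERTEX, minimum_image)


def fene_windows_ok(top, box=None):
    dr = top.pos[top.bonds[:, 0]] - top.pos[top.bonds[:, 1]]
    if box is not None:
        dr = minimum_image(dr, box)
    r = np.linalg.norm(dr, axis=1)
    delta = top.bond_params[:, 3]
    r0 = top.bond_params[:, 1]
    return np.all((r > delta) & (r < delta + r0))


class TestCage:
    def test_composition(self, cage_template):
        top = cage_template.topology
        assert np.sum(top.species == CAGE_CENTER) == 1
        # 6 edges x 7 beads
        from cdlattice.core import CAGE_EDGE
        assert np.sum(top.species == CAGE_EDGE) == 42
        assert np.sum(top.species == CAGE_ANCHOR) == 4
        # 4 strands x 15 nucleotides, anchor doubling as the first backbone
        assert np.sum(top.base >= 0) == 4 * 15
        assert top.n_sites == 175

    def test_bond_lengths_inside_fene_window(self, cage_template):
        assert fene_windows_ok(cage_template.topology)

    def test_first_neighbor_edge_rest_length(self, cage_template):
        # rest separation 7.32 sigma < bead diameter 9.9: exclusion zones of
        # bonded edge beads overlap by design, with no non-bonded pair term
        top = cage_template.topology
        first = top.bond_role == builders.ROLE_EDGE1
        r = np.linalg.norm(top.pos[top.bonds[first, 0]]
                           - top.pos[top.bonds[first, 1]], axis=1)
        assert r == pytest.approx(6.36 + FENE_REST, abs=1e-9)
        assert np.all(r < 9.9)

    def test_table_rows(self, cage_template):
        top = cage_template.topology
        rows = {tuple(p) for p in np.round(top.bond_params, 4).tolist()}
        assert (240.0, 1.5, 8.0, 6.36) in rows      # edge first neighbour
        assert (240.0, 1.5, 8.0, 13.67) in rows     # edge second neighbour
        assert (240.0, 1.5, 8.0, 36.52) in rows     # anchor to center

    def test_strands_point_outward(self, cage_template):
        top = cage_template.topology
        for s in range(4):
            bbs = cage_template.strand_bb[s]
            v1 = top.pos[bbs[0]]
            v2 = top.pos[bbs[1]] - v1
            cos = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_stiffness_range_warning(self, caplog):
        with caplog.at_level("WARNING", logger="cdlattice"):
            builders.build_cage(3.0)
        assert "stiffness" in caplog.text


class TestNanoparticle:
    def test_force_site_count(self, np_template):
        top = np_template.topology
        assert np.sum((top.species == NP_VERTEX)
                      | (top.species == NP_CENTER)) == 21
        assert np.sum(top.strand >= 0) // 30 == 20          # 20 strands
        assert np.sum(top.base >= 0) == 300                 # nucleotides

    @pytest.mark.parametrize("d", [40.0, 80.0, 120.0])
    def test_vertex_spacing_matches_dodecahedron_oracle(self, d):
        tmpl = builders.build_np(d)
        verts = tmpl.topology.pos[tmpl.topology.species == NP_VERTEX]
        dist = np.linalg.norm(verts[:, None] - verts[None], axis=-1)
        nn = np.sort(dist[dist > 0])[:60]  # 30 edges, twice
        exact = d / (math.sqrt(3.0) * GOLDEN)
        assert np.allclose(nn, exact, atol=1e-6)

    def test_bond_deltas(self):
        d = 40.0
        tmpl = builders.build_np(d)
        top = tmpl.topology
        cv = top.bond_params[top.bond_role == builders.ROLE_NP_CV, 3]
        vv = top.bond_params[top.bond_role == builders.ROLE_NP_VV, 3]
        assert cv == pytest.approx(d / 2 - FENE_REST)
        assert vv == pytest.approx(d / 2.8 - FENE_REST)

    def test_center_excluded_volume_is_inscribed_sphere(self, np_template):
        top = np_template.topology
        d_center = top.diameter[top.species == NP_CENTER][0]
        assert d_center == pytest.approx(40.0 * 1.113516 / 1.401259, rel=1e-4)

    def test_size_range_warning(self, caplog):
        with caplog.at_level("WARNING", logger="cdlattice"):
            builders.build_np(150.0)
        assert "range" in caplog.text


class TestBulkLattice:
    def test_counts_4x4x4(self, cage_template, np_template):
        sys4 = builders.build_bulk_lattice(
            builders.LatticeSpec(nx=4, ny=4, nz=4),
            cage=cage_template, nano=np_template)
        assert np.sum(sys4.body_species == BODY_NP) == 64
        assert np.sum(sys4.body_species == BODY_CAGE) == 64

    def test_single_cell_box_angles(self, cage_template, np_template):
        sys1 = builders.build_bulk_lattice(
            builders.LatticeSpec(nx=1, ny=1, nz=1),
            cage=cage_template, nano=np_template)
        assert sys1.n_bodies == 2
        for i, j in itertools.combinations(range(3), 2):
            cos = (sys1.box[i] @ sys1.box[j]
                   / np.linalg.norm(sys1.box[i])
                   / np.linalg.norm(sys1.box[j]))
            assert cos == pytest.approx(0.5, abs=1e-12)

    def test_every_cage_has_four_np_neighbors(self, small_lattice):
        sys2 = small_lattice
        b = sys2.lattice_constant
        for i in np.nonzero(sys2.body_species == BODY_CAGE)[0]:
            dr = minimum_image(sys2.ideal_centers
                               - sys2.ideal_centers[i], sys2.box)
            dist = np.linalg.norm(dr, axis=1)
            nn = np.abs(dist - math.sqrt(3) * b / 4) < 1e-6
            assert np.sum(nn) == 4
            assert set(sys2.body_species[nn]) == {BODY_NP}

    def test_sublattices_are_fcc(self):
        # 12-neighbour shell at b/sqrt(2) for each species (4^3 cells so
        # periodic images do not fold the shell onto itself)
        from cdlattice.builders import ideal_body_lattice
        b = 180.0
        cen_all, species, _, box = ideal_body_lattice(4, b)
        for sp in (BODY_NP, BODY_CAGE):
            cen = cen_all[species == sp]
            dr = minimum_image((cen[:, None] - cen[None]).reshape(-1, 3),
                               box).reshape(len(cen), len(cen), 3)
            dist = np.linalg.norm(dr, axis=-1)
            for i in range(len(cen)):
                shell = np.abs(dist[i] - b / math.sqrt(2)) < 1e-6
                assert np.sum(shell) == 12

    def test_bonds_inside_window_after_zipping(self, small_lattice):
        assert fene_windows_ok(small_lattice.topology, small_lattice.box)

    def test_rebuild_is_bit_identical(self, cage_template, np_template):
        a = builders.build_bulk_lattice(
            builders.LatticeSpec(nx=1, ny=1, nz=1),
            cage=cage_template, nano=np_template)
        b = builders.build_bulk_lattice(
            builders.LatticeSpec(nx=1, ny=1, nz=1),
            cage=cage_template, nano=np_template)
        assert np.array_equal(a.topology.pos, b.topology.pos)
        assert np.array_equal(a.box, b.box)

    def test_too_small_box_is_rejected(self, cage_template, np_template):
        with pytest.raises(builders.GeometryError):
            builders.build_bulk_lattice(
                builders.LatticeSpec(nx=1, ny=1, nz=1, b=80.0),
                cage=cage_template, nano=np_template)


class TestSlabs:
    def test_111_counts(self, cage_template, np_template):
        slab = builders.build_slab(
            builders.SlabSpec(facet=(1, 1, 1), n_layers=8,
                              surface_cells=(4, 4)),
            cage=cage_template, nano=np_template)
        assert slab.n_bodies >= 128
        z = slab.ideal_centers[:, 2]
        top_layer = np.abs(z - z.max()) < 1e-6
        assert np.sum(top_layer) == 16
        # one face all NP, the other all cage
        faces = {tuple(sorted(set(slab.body_species[np.abs(z - zz) < 1e-6])))
                 for zz in (z.min(), z.max())}
        assert faces == {(BODY_NP,), (BODY_CAGE,)}

    def test_111_min_termination_one_dangling_bond_per_surface_body(
            self, cage_template, np_template):
        slab = builders.build_slab(
            builders.SlabSpec(facet=(1, 1, 1), n_layers=8,
                              surface_cells=(2, 2)),
            cage=cage_template, nano=np_template)
        links = {tuple(sorted(p)) for p in map(tuple, slab.ideal_neighbors)}
        n_links = len(slab.ideal_neighbors)
        # cages own all links; only the bottom cage face loses one each
        n_cages = int(np.sum(slab.body_species == BODY_CAGE))
        z = slab.ideal_centers[:, 2]
        bottom = np.sum((slab.body_species == BODY_CAGE)
                        & (np.abs(z - z.min()) < 1e-6))
        assert n_links == 4 * n_cages - bottom

    def test_100_breaks_two_of_four(self, cage_template, np_template):
        slab = builders.build_slab(
            builders.SlabSpec(facet=(1, 0, 0), n_layers=5,
                              surface_cells=(2, 2),
                              termination="cage_both_sides"),
            cage=cage_template, nano=np_template)
        z = slab.ideal_centers[:, 2]
        for zz in (z.min(), z.max()):
            surf = np.nonzero(np.abs(z - zz) < 1e-6)[0]
            assert set(slab.body_species[surf]) == {BODY_CAGE}
            for i in surf:
                n = np.sum((slab.ideal_neighbors == i).any(axis=1))
                assert n == 2          # two of four bonds broken

    def test_unsupported_facet(self):
        with pytest.raises(builders.ConfigurationError):
            builders.build_slab(builders.SlabSpec(facet=(2, 1, 1)))


class TestStrandSpec:
    def test_wrong_length_rejected(self):
        with pytest.raises(builders.ConfigurationError):
            builders.StrandSpec(n_spacer=6, n_sticky=8)

    def test_bad_base_rejected(self):
        with pytest.raises(builders.ConfigurationError):
            builders.StrandSpec(sticky_sequence="GCGCAGXX")

    def test_default_sequences_complementary_not_self(self):
        from cdlattice.core import CAGE_STICKY, NP_STICKY, COMPLEMENT, \
            BASE_FROM_CHAR
        cage = [BASE_FROM_CHAR[c] for c in CAGE_STICKY]
        nano = [BASE_FROM_CHAR[c] for c in NP_STICKY]
        # antiparallel complement of the cage sticky end is the NP sticky end
        assert [COMPLEMENT[b] for b in cage[::-1]] == nano
        # neither is its own antiparallel complement
        assert [COMPLEMENT[b] for b in cage[::-1]] != cage
        assert [COMPLEMENT[b] for b in nano[::-1]] != nano
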