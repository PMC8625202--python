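"""Model construction: beads, elastic networks, linkers, Gō terms, H-bonds."""

import numpy as np
import pytest

import shearfold as sf
from shearfold.model import (ModelError, ONE_TO_THREE, RESIDUE_MASS,
                             rebuild_amide_hydrogens)
from shearfold.synthetic import make_toy_sheet, make_vwf_like_construct

# -- PDB reduction ----------------------------------------------------------

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.600   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.200   0.600   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.400   1.800   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.000  -1.000   1.100  1.00  0.00           C
ATOM      6  N   GLY A   2       3.500   0.600   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.500   0.000   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.700   0.600   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       5.900   1.800   0.000  1.00  0.00           O
ATOM     10  N   LEU A   3       7.000   0.600   0.000  1.00  0.00           N
ATOM     11  CA  LEU A   3       8.000   0.000   0.000  1.00  0.00           C
ATOM     12  C   LEU A   3       9.200   0.600   0.000  1.00  0.00           C
ATOM     13  O   LEU A   3       9.400   1.800   0.000  1.00  0.00           O
ATOM     14  CB  LEU A   3       8.000  -1.000   1.100  1.00  0.00           C
ATOM     15  CG  LEU A   3       8.400  -2.300   1.700  1.00  0.00           C
END
"""


class TestLoadCaStructure:
    def test_three_residue_reduction(self):
        beads = sf.load_ca_structure(THREE_RES_PDB, "A")
        # Ala and Leu give backbone + sidechain; Gly only backbone
        assert len(beads) == 5
        roles = [b.bead_role for b in beads]
        assert roles == ["backbone", "sidechain", "backbone",
                         "backbone", "sidechain"]
        np.testing.assert_allclose(beads[0].position, [1.0, 0.0, 0.0])
        # Leu sidechain bead sits at the centroid of CB and CG
        np.testing.assert_allclose(beads[4].position, [8.2, -1.65, 1.4])

    def test_missing_chain_lists_available(self):
        with pytest.raises(ModelError, match="available chains.*A"):
            sf.load_ca_structure(THREE_RES_PDB, "B")

    def test_hairpin_ca_positions_match_text_parse(self, hairpin_pdb):
        beads = sf.load_ca_structure(hairpin_pdb, "A")
        # independent plain-text parse of the Cα records
        expected = {}
        for line in hairpin_pdb.splitlines():
            if line.startswith("ATOM") and line[12:16].strip() == "CA":
                res = int(line[22:26])
                expected[res] = [float(line[30 + 8 * i:38 + 8 * i])
                                 for i in range(3)]
        backbone = [b for b in beads if b.bead_role == "backbone"]
        assert len(backbone) == len(expected)
        for b in backbone:
            np.testing.assert_allclose(b.position,
                                       expected[b.residue_global_index],
                                       atol=1e-3)


class TestElasticNetwork:
    def test_collinear_beads(self):
        beads = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                         bead_role="backbone", position=[4.0 * i, 0, 0])
                 for i in range(3)]
        en = sf.build_elastic_network(beads, cutoff=6.0)
        pairs = {(s.i, s.j) for s in en.springs}
        assert pairs == {(0, 1), (1, 2)}
        assert all(abs(s.r0 - 4.0) < 1e-12 for s in en.springs)
        assert all(s.k == 5.0 for s in en.springs)

    def test_beads_beyond_cutoff(self):
        beads = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                         bead_role="backbone", position=[7.0 * i, 0, 0])
                 for i in range(2)]
        assert sf.build_elastic_network(beads, cutoff=6.0).springs == []

    def test_matches_brute_force_and_permutation(self, rng):
        pos = rng.uniform(0, 20, size=(50, 3))
        beads = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                         bead_role="backbone", position=p)
                 for i, p in enumerate(pos)]
        en = sf.build_elastic_network(beads, cutoff=6.0)
        brute = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(pos[i] - pos[j]) < 6.0:
                    brute.add((i, j))
        assert {(s.i, s.j) for s in en.springs} == brute
        # permuting bead order yields the same unordered spring set
        perm = rng.permutation(50)
        beads_p = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                           bead_role="backbone", position=pos[perm[i]])
                   for i in range(50)]
        en_p = sf.build_elastic_network(beads_p, cutoff=6.0)
        mapped = {tuple(sorted((perm[s.i], perm[s.j]))) for s in en_p.springs}
        assert mapped == brute

    def test_degenerate_geometry(self):
        beads = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                         bead_role="backbone", position=[1.0, 2.0, 3.0])
                 for i in range(4)]
        with pytest.raises(ModelError, match="coincident"):
            sf.build_elastic_network(beads)


class TestLinkerChain:
    @pytest.mark.parametrize("length,nb,na,nt", [(5, 4, 3, 2), (2, 1, 0, 0)])
    def test_term_counts(self, length, nb, na, nt):
        seq = "GSAGT"[:length]
        beads, bonds, angles, torsions, _ = sf.build_linker_chain(seq)
        assert (len(beads), len(bonds), len(angles), len(torsions)) == \
            (length, nb, na, nt)

    def test_default_parameters_attached(self):
        _, bonds, angles, torsions, _ = sf.build_linker_chain("GSAGT")
        assert all(b.r0 == 3.8 and b.k == 149.0 for b in bonds)
        assert all(a.theta0_deg == 110.0 and a.k_theta == 1.5e-3
                   for a in angles)
        assert all(t.phi0_deg == 180.0 and t.multiplicity == 2
                   and t.k_phi == 1.0 for t in torsions)

    def test_unknown_residue_letter(self):
        with pytest.raises(ModelError, match="unknown residue"):
            sf.build_linker_chain("GSX")

    def test_hp_classes_assigned(self):
        beads, *_ = sf.build_linker_chain("GAVD")
        assert [b.hp_class for b in beads] == ["P", "H", "H", "P"]


class TestClassifyHP:
    @pytest.mark.parametrize("res,cls", [("Leu", "H"), ("Asp", "P"),
                                         ("V", "H"), ("g", "P")])
    def test_known_classes(self, res, cls):
        assert sf.classify_hp(res) == cls

    def test_full_sweep_total_and_exclusive(self):
        classes = {three: sf.classify_hp(three) for three in ONE_TO_THREE.values()}
        assert len(classes) == 20
        assert set(classes.values()) <= {"H", "P"}
        hydrophobic = {k for k, v in classes.items() if v == "H"}
        assert hydrophobic == {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "CYS"}

    def test_unknown_code(self):
        with pytest.raises(ModelError):
            sf.classify_hp("XYZ")


class TestGoModel:
    def test_native_pairs_nonempty_and_ordered(self, hairpin_pdb):
        beads = sf.load_ca_structure(hairpin_pdb, "A")
        go = sf.build_go_model(beads)
        assert go.native_pairs
        assert all(p.i < p.j for p in go.native_pairs)
        res = {b.id: b.residue_local_index for b in beads}
        assert all(abs(res[p.i] - res[p.j]) >= 3 for p in go.native_pairs)

    def test_terms_depend_on_reference_structure_only(self, hairpin_pdb):
        beads = sf.load_ca_structure(hairpin_pdb, "A")
        ref_pairs = {(p.i, p.j) for p in sf.build_go_model(beads).native_pairs}
        # stretching a *copy* afterwards must not change the recorded terms
        stretched = sf.load_ca_structure(hairpin_pdb, "A")
        go = sf.build_go_model(stretched)
        for k, b in enumerate(stretched):
            b.position = np.array([3.8 * k, 0.0, 0.0])
        assert {(p.i, p.j) for p in go.native_pairs} == ref_pairs

    def test_pairs_match_brute_force(self, hairpin_pdb):
        beads = sf.load_ca_structure(hairpin_pdb, "A")
        go = sf.build_go_model(beads, native_cutoff=6.5,
                               min_residue_separation=3)
        brute = set()
        for a in range(len(beads)):
            for b in range(a + 1, len(beads)):
                ba, bb = beads[a], beads[b]
                if abs(ba.residue_local_index - bb.residue_local_index) < 3:
                    continue
                if np.linalg.norm(ba.position - bb.position) < 6.5:
                    brute.add(tuple(sorted((ba.id, bb.id))))
        assert {(p.i, p.j) for p in go.native_pairs} == brute

    def test_too_few_residues(self):
        beads = [sf.Bead(id=i, residue_local_index=i + 1, residue_name="GLY",
                         bead_role="backbone", position=[3.8 * i, 0, 0])
                 for i in range(3)]
        with pytest.raises(ModelError, match="at least 4"):
            sf.build_go_model(beads)


class TestNativeHBonds:
    def _sheet(self, d):
        """Two 4-residue strands with O(i)···HN(j) across at distance d."""
        n = 8
        res = list(range(1, n + 1))
        o = np.zeros((n, 3))
        h = np.zeros((n, 3))
        for i in range(4):           # strand 1: residues 1-4
            o[i] = [3.5 * i, 0.0, 1.0]
            h[i] = [3.5 * i, 0.0, -1.0]
        for i in range(4, 8):        # strand 2: residues 5-8
            o[i] = [3.5 * (i - 4), 0.0, 1.0 + d + 2.0]
            h[i] = [3.5 * (i - 4), 0.0, 1.0 + d]
        return res, o, h

    def test_all_pairs_at_2A_included(self):
        res, o, h = self._sheet(2.0)
        hb = sf.derive_native_hbonds(res, o, h, cutoff=3.0,
                                     strand_ranges={"s1": (1, 4), "s2": (5, 8)})
        # O of strand-1 residue i to HN of strand-2 residue i+4, 4 columns
        assert len(hb.contacts) == 4
        assert all(abs(c.d_ref - 2.0) < 1e-12 for c in hb.contacts)
        assert all(c.strand_pair_label == "s1s2" for c in hb.contacts)

    def test_pair_beyond_cutoff_excluded(self):
        res, o, h = self._sheet(3.5)
        hb = sf.derive_native_hbonds(res, o, h, cutoff=3.0)
        assert len(hb.contacts) == 0

    def test_count_matches_brute_force(self, rng):
        n = 20
        res = list(range(1, n + 1))
        o = rng.uniform(0, 15, (n, 3))
        h = rng.uniform(0, 15, (n, 3))
        hb = sf.derive_native_hbonds(res, o, h, cutoff=3.0)
        brute = sum(1 for a in range(n) for d in range(n)
                    if abs(res[a] - res[d]) >= 2
                    and np.linalg.norm(o[a] - h[d]) <= 3.0)
        assert len(hb.contacts) == brute

    def test_amide_h_reconstruction_geometry(self):
        npos = np.array([0.0, 0.0, 0.0])
        ca = np.array([1.45, 0.0, 0.0])
        cprev = np.array([-0.8, 1.2, 0.0])
        hpos = rebuild_amide_hydrogens(npos, ca, cprev, nh_length=1.0)
        assert abs(np.linalg.norm(hpos - npos) - 1.0) < 1e-12
        assert abs(hpos[2]) < 1e-12  # stays in the peptide plane


class TestAssembleConstruct:
    def test_default_linker_lengths(self):
        model = make_vwf_like_construct()
        assert len(model.segment_indices("L12")) == 37
        assert len(model.segment_indices("L23")) == 15

    def test_toy_construct_segments_and_terminal_bonds(self):
        from shearfold.synthetic import make_three_blob_construct
        model = make_three_blob_construct(n_per_blob=10,
                                          linker_sequences=("GSAGT", "GSA"))
        assert sorted(set(model.segment_labels)) == ["A1", "A2", "A3",
                                                     "L12", "L23"]
        assert len(model.terminal_bonds) == 2
        # bead count conservation: 3 blobs + both linkers
        assert model.n_beads == 3 * 10 + 5 + 3
        # terminal bonds join A2 termini to L12/L23 ends
        for bi in model.terminal_bonds:
            bond = model.bonds[bi]
            segs = {model.segment_labels[bond.i], model.segment_labels[bond.j]}
            assert segs in ({"L12", "A2"}, {"A2", "L23"})

    def test_no_cross_segment_native_terms(self):
        model = make_vwf_like_construct()
        for p in model.native_pairs:
            assert model.segment_labels[p.i] == model.segment_labels[p.j]
        for s in model.springs:
            assert model.segment_labels[s.i] == model.segment_labels[s.j]


class TestResidueNumbering:
    def test_local_to_global_map(self):
        numbering = sf.ResidueNumbering(global_start=1495, length=177)
        assert sf.map_residue_number(numbering, 1) == 1495
        # the scissile-bond tyrosine: local 111 -> global 1605
        assert sf.map_residue_number(numbering, 111) == 1605
        # the recognition-site aspartate: local 120 -> global 1614
        assert sf.map_residue_number(numbering, 120) == 1614

    @pytest.mark.parametrize("bad", [0, 178, -3])
    def test_out_of_range(self, bad):
        numbering = sf.ResidueNumbering(global_start=1495, length=177)
        with pytest.raises(ModelError):
            sf.map_residue_number(numbering, bad)


class TestSerialization:
    def test_json_roundtrip(self, toy_sheet):
        text = toy_sheet.model.to_json()
        model2 = sf.ConstructModel.from_json(text)
        assert model2.n_beads == toy_sheet.model.n_beads
        np.testing.assert_allclose(model2.positions(),
                                   toy_sheet.model.positions())
        assert model2.to_json() == text

    def test_pdb_export_parses_back(self, toy_sheet):
        pdb = toy_sheet.model.to_pdb()
        assert pdb.count("ATOM") == toy_sheet.model.n_beads

    def test_invalid_bead_rejected(self):
        with pytest.raises(ModelError):
            sf.Bead(id=0, residue_local_index=0, residue_name="GLY",
                    bead_role="backbone", position=[0, 0, 0])
        with pytest.raises(ModelError):
            sf.Bead(id=0, residue_local_index=1, residue_name="GLY",
                    bead_role="backbone", position=[0, 0, 0], hp_class="H")
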