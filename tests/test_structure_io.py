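"""Structure parsing, atom-name normalization, bond perception, NMR-STAR."""

import numpy as np
import pytest

from nucshift import fixtures
from nucshift.naming import normalize_atom_names
from nucshift.structure import (
    atom_id,
    perceive_bonds,
    perceive_bonds_distance,
    read_shift_table,
    read_structure,
)
from nucshift.templates import template_atom_names


class TestReadStructure:
    def test_toy_dinucleotide_parses(self):
        st = fixtures.make_toy_nucleic("GC", form="single")
        assert st.n_models == 1
        assert len(st.models[0].residues()) == 2
        assert all(st.entity_class[(c, r)] == "nucleic"
                   for c, r, _ in st.models[0].residues())

    def test_model_selection_picks_exactly_one(self):
        st10 = fixtures.make_toy_nucleic("GC", n_models=10, jitter=0.05, seed=1)
        text = st10.source_text
        sel = read_structure(text, [1])
        assert sel.n_models == 1
        allm = read_structure(text, "all")
        assert allm.n_models == 10
        np.testing.assert_allclose(sel.models[0].coords_array(),
                                   allm.models[0].coords_array())

    def test_out_of_range_model_rejected(self):
        st = fixtures.make_toy_nucleic("GC")
        with pytest.raises(ValueError, match="out of range"):
            read_structure(st.source_text, [3])

    def test_missing_hydrogens_is_hard_error(self):
        st = fixtures.make_toy_nucleic("GC")
        stripped = "\n".join(
            l for l in st.source_text.splitlines()
            if not (l.startswith("ATOM") and l[76:78].strip() == "H")
        )
        with pytest.raises(ValueError, match="no hydrogens"):
            read_structure(stripped)

    def test_dialects_normalize_to_identical_structures(self):
        """The same molecule written with H2''/H5'' vs H2'2/H5'2 names parses
        to field-identical structures."""
        st = fixtures.make_toy_nucleic("GC")
        v3 = st.source_text
        v2 = (v3.replace("H2''", "H2'2").replace("H5''", "H5'2")
              .replace(" OP1", " O1P").replace(" OP2", " O2P"))
        a, b = read_structure(v3), read_structure(v2)
        assert [x.atom_id for x in a.models[0].atoms] == \
               [x.atom_id for x in b.models[0].atoms]

    def test_phosphate_formal_charge_assigned(self, seven_mer):
        charged = [a for a in seven_mer.models[0].atoms if a.formal_charge]
        # 6 internal phosphodiester groups, one -1 each
        assert len(charged) == 6
        assert all(a.formal_charge == -1 and a.name in ("OP1", "OP2") for a in charged)


class TestNaming:
    @pytest.mark.parametrize("raw,res,want", [
        ("H5*", "DG", "H5'"),
        ("H2'1", "DA", "H2'"),
        ("H2'2", "DA", "H2''"),
        ("1H5'", "DG", "H5'"),
        ("2H5'", "DG", "H5''"),
        ("O1P", "DC", "OP1"),
        ("1H2", "DG", "H21"),
        ("2H4", "DC", "H42"),
        ("H5M1", "DT", "H71"),
        ("C5M", "DT", "C7"),
        ("H3T", "DT", "HO3'"),
        ("H8", "DA", "H8"),
    ])
    def test_dialect_mapping(self, raw, res, want):
        assert normalize_atom_names(raw, res) == want

    def test_idempotent_on_mapped_names(self):
        corpus = ["H5*", "H2'1", "1H5'", "O1P", "H5M1", "2H2", "H1'", "HO3'",
                  "H2''", "N9", "C1'", "H3T", "HN"]
        for raw in corpus:
            for res in ("DA", "DC", "DG", "DT"):
                once = normalize_atom_names(raw, res)
                assert normalize_atom_names(once, res) == once

    def test_full_census_of_seven_mer_matches_templates(self, seven_mer):
        """Every atom name in the fixture maps into the CCD template set
        (terminal HO5' is the deliberate chain-cap exception)."""
        unmatched = []
        for a in seven_mer.models[0].atoms:
            known = template_atom_names(a.resname)
            if a.name not in known and a.name != "HO5'":
                unmatched.append(a.atom_id)
        assert unmatched == []


class TestBondPerception:
    def test_dinucleotide_has_one_bridge(self):
        st = fixtures.make_toy_nucleic("GC")
        g = perceive_bonds(st.models[0])
        bridges = [(u, v) for u, v in g.edges
                   if {u.rsplit("/", 1)[1], v.rsplit("/", 1)[1]} == {"O3'", "P"}]
        assert len(bridges) == 1

    def test_water_bonds(self):
        text = (
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H\n"
            "ATOM      3  H2  HOH A   1      -0.240   0.930   0.000  1.00  0.00           H\n"
            "END\n")
        st = read_structure(text)
        g = perceive_bonds(st.models[0])
        heavy = [e for e in g.edges if "H" not in
                 (g.nodes[e[0]]["element"], g.nodes[e[1]]["element"])]
        assert len(heavy) == 0 and g.number_of_edges() == 2

    def test_template_and_distance_paths_agree(self):
        """On an unmodified toy structure the CCD-template bonds equal the
        covalent-radius distance perception."""
        st = fixtures.make_toy_nucleic("GC")
        gt = perceive_bonds(st.models[0])
        gd = perceive_bonds_distance(st.models[0])
        assert {frozenset(e) for e in gt.edges} == {frozenset(e) for e in gd.edges}

    def test_bond_graph_is_simple_and_symmetric(self, seven_mer_pipeline):
        g, _, _ = seven_mer_pipeline
        assert all(u != v for u, v in g.edges)


class TestShiftTable:
    def _star(self, rows):
        entries = {}
        for k, v in rows.items():
            entries[k] = v
        return fixtures.shift_table_to_star(entries)

    def test_filter_by_nucleus(self, gc_synthetic):
        _, _, table, _, star = gc_synthetic
        t_h = read_shift_table(star, nucleus="1H")
        assert len(t_h) == len(table)
        t_p = read_shift_table(star, nucleus="31P")
        assert len(t_p) == 0

    def test_v2_dialect_name_matched_after_normalization(self):
        star = self._star({("A", 1, "DG", "H5*"): 4.2})
        t = read_shift_table(star)
        assert ("A", 1, "DG", "H5'") in t.entries

    def test_star_roundtrip_matches_structure(self, gc_synthetic):
        st, _, table, _, star = gc_synthetic
        t = read_shift_table(star)
        matched, unmatched = t.match_structure(st)
        assert matched == len(table) and unmatched == 0

    def test_unmatched_entries_kept_and_flagged(self, gc_synthetic):
        st, _, _, _, _ = gc_synthetic
        star = self._star({("A", 1, "DG", "H8"): 7.9, ("Z", 99, "DG", "H8"): 8.0})
        t = read_shift_table(star)
        matched, unmatched = t.match_structure(st)
        assert matched == 1 and unmatched == 1
        assert t.unmatched == [("Z", 99, "DG", "H8")]

    def test_duplicate_keys_rejected(self):
        star = self._star({("A", 1, "DG", "H8"): 7.9})
        dup_line = [l for l in star.splitlines() if l.strip().startswith("1 A")][0]
        bad = star.replace(dup_line, dup_line + "\n" + dup_line.replace("7.9000", "8.1000"))
        with pytest.raises(ValueError, match="duplicate"):
            read_shift_table(bad)

    def test_no_loop_is_error(self):
        with pytest.raises(ValueError, match="no chemical-shift loop"):
            read_shift_table("data_empty\n")


def test_topology_identity_asserted_across_models():
    st = fixtures.make_toy_nucleic("GC", n_models=3, jitter=0.01, seed=2)
    text = st.source_text
    # corrupt one atom name in model 2 only
    lines = text.splitlines()
    in_m2 = False
    for i, l in enumerate(lines):
        if l.startswith("MODEL") and " 2" in l:
            in_m2 = True
        if in_m2 and l.startswith("ATOM") and " N9 " in l:
            lines[i] = l.replace(" N9 ", " N8 ")
            break
    with pytest.raises(ValueError, match="inconsistent topology"):
        read_structure("\n".join(lines))
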