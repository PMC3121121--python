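"""Contact typing, directly broken contacts and feature-vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from dbac.burial import atom_burial_levels, build_contact_graph
from dbac.features import (AC_COLUMNS, DBAC_COLUMNS, classify_contact,
                           directly_broken_contacts, feature_vector,
                           interfacial_contacts, typed_contacts)
from dbac.structure import (ACCEPTOR, DONOR, NEGATIVE, POSITIVE, Structure,
                            assign_chem_classes)

from conftest import make_atom


class TestClassifyContact:
    @pytest.mark.parametrize("a,b,expected", [
        (("LYS", "NZ"), ("ASP", "OD1"), "I"),
        (("SER", "OG"), ("GLY", "O"), "II"),
        (("LEU", "CD1"), ("VAL", "CG1"), "III"),
        (("HIS", "NE2"), ("GLU", "OE2"), "I"),   # I takes precedence over II
        (("LYS", "NZ"), ("SER", "OG"), "II"),    # positive x acceptor -> II
    ])
    def test_examples(self, a, b, expected):
        ca = assign_chem_classes(*a)
        cb = assign_chem_classes(*b)
        assert classify_contact(ca, cb) == expected
        assert classify_contact(cb, ca) == expected  # orientation-free

    CLASSES = st_.frozensets(
        st_.sampled_from([POSITIVE, NEGATIVE, DONOR, ACCEPTOR]), max_size=4)

    @settings(max_examples=200, derandomize=True)
    @given(CLASSES, CLASSES)
    def test_precedence_is_total_and_exclusive(self, ca, cb):
        t = classify_contact(ca, cb)
        assert t in ("I", "II", "III")
        is_pair_i = (POSITIVE in ca and NEGATIVE in cb) or \
                    (POSITIVE in cb and NEGATIVE in ca)
        is_pair_ii = (DONOR in ca and ACCEPTOR in cb) or \
                     (DONOR in cb and ACCEPTOR in ca)
        assert (t == "I") == is_pair_i
        if t == "II":
            assert is_pair_ii and not is_pair_i
        if t == "III":
            assert not is_pair_i and not is_pair_ii


def _two_chain_structure():
    """SER (chain A) facing a GLY backbone fragment (chain B) plus a water."""
    atoms = [
        make_atom(1, "N", "SER", ("A", 1, ""), "N", (0, 0, 0)),
        make_atom(2, "CA", "SER", ("A", 1, ""), "C", (1.5, 0, 0)),
        make_atom(3, "CB", "SER", ("A", 1, ""), "C", (2.2, 1.2, 0)),
        make_atom(4, "OG", "SER", ("A", 1, ""), "O", (3.0, 2.2, 0)),
        make_atom(5, "CA", "GLY", ("B", 9, ""), "C", (5.5, 2.8, 0.4)),
        make_atom(6, "O", "GLY", ("B", 9, ""), "O", (6.0, 0.5, 1.2)),
        make_atom(7, "O", "HOH", ("B", 50, ""), "O", (1.0, 3.0, 1.0),
                  is_water=True),
    ]
    return Structure(atoms=atoms, side_a=frozenset("A"),
                     side_b=frozenset("B"))


class TestInterfacialAndDirectlyBroken:
    def _graph(self):
        st = _two_chain_structure()
        return st, build_contact_graph(st, np.ones(len(st), dtype=bool))

    def test_cross_side_edges_only(self):
        st, g = self._graph()
        inter = interfacial_contacts(g)
        for i, j in inter:
            sides = {st.side_of(st.atoms[i]), st.side_of(st.atoms[j])}
            assert sides == {"A", "B"}

    def test_water_contacts_excluded(self):
        st, g = self._graph()
        water = next(i for i, a in enumerate(st.atoms) if a.is_water)
        assert all(water not in e for e in interfacial_contacts(g))

    def test_missing_partition_is_an_error(self):
        st = _two_chain_structure()
        st2 = Structure(atoms=st.atoms, side_a=frozenset("AB"))
        g = build_contact_graph(st2, np.ones(len(st2), dtype=bool))
        with pytest.raises(ValueError, match="partition"):
            interfacial_contacts(g)

    def test_side_chain_beyond_cbeta_is_directly_broken(self):
        st, g = self._graph()
        inter = interfacial_contacts(g)
        broken = directly_broken_contacts(st, ("A", 1, ""), inter)
        names = {st.atoms[mine].name for mine, _ in broken}
        assert names == {"OG"}  # OG--CA and OG--O survive, CB--* do not
        partners = {st.atoms[p].name for _, p in broken}
        assert "CA" in partners  # partner may be any atom, backbone included

    def test_residue_without_removable_atoms_has_none(self):
        st, g = self._graph()
        inter = interfacial_contacts(g)
        assert directly_broken_contacts(st, ("B", 9, ""), inter) == []

    def test_unknown_residue_raises(self):
        st, g = self._graph()
        with pytest.raises(KeyError):
            directly_broken_contacts(st, ("A", 99, ""), [])


class TestFeatureVector:
    def test_no_interfacial_contacts_gives_zero_counts(self):
        atoms = [make_atom(i + 1, n, "SER", ("A", 1, ""), e, c) for i, (n, e, c)
                 in enumerate([("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                               ("CB", "C", (2.2, 1.2, 0)),
                               ("OG", "O", (3.0, 2.2, 0))])]
        atoms += [make_atom(9, "CA", "GLY", ("B", 2, ""), "C", (40, 40, 40)),
                  make_atom(10, "O", "GLY", ("B", 2, ""), "O", (43, 40, 40))]
        st = Structure(atoms=atoms, side_a=frozenset("A"),
                       side_b=frozenset("B"))
        g = build_contact_graph(st, np.ones(len(st), dtype=bool))
        fv = feature_vector(st, atom_burial_levels(g), ("A", 1, ""))
        assert fv.drop("RBL").sum() == 0

    def test_mode_column_counts(self, toy_mixed_pipeline):
        pruned, _, assignment, expected = toy_mixed_pipeline
        rid = next(iter(expected))
        assert list(feature_vector(pruned, assignment, rid, "DBAC").index) \
            == DBAC_COLUMNS
        assert list(feature_vector(pruned, assignment, rid, "AC").index) \
            == AC_COLUMNS
        with pytest.raises(ValueError):
            feature_vector(pruned, assignment, rid, "XYZ")

    def test_planted_counts_recovered(self, toy_mixed_pipeline):
        pruned, _, assignment, expected = toy_mixed_pipeline
        for rid, want in expected.items():
            fv = feature_vector(pruned, assignment, rid, mode="AC")
            got = {k: int(fv[k]) for k in want}
            assert got == want

    def test_counting_conservation_in_ac_mode(self, toy_mixed_pipeline):
        pruned, graph, assignment, expected = toy_mixed_pipeline
        inter = interfacial_contacts(graph)
        for rid in expected:
            fv = feature_vector(pruned, assignment, rid, mode="AC")
            total = int(fv.drop("RBL").sum())
            assert total == len(directly_broken_contacts(pruned, rid, inter))

    def test_partition_swap_leaves_features_unchanged(self, toy_mixed_pipeline):
        pruned, _, assignment, expected = toy_mixed_pipeline
        swapped = Structure(atoms=pruned.atoms, side_a=pruned.side_b,
                            side_b=pruned.side_a)
        g2 = build_contact_graph(swapped, assignment.graph.exposed)
        asn2 = atom_burial_levels(g2)
        for rid in expected:
            a = feature_vector(pruned, assignment, rid, mode="AC")
            b = feature_vector(swapped, asn2, rid, mode="AC")
            assert a.equals(b)

    def test_deep_band_coherence(self, toy_mixed_pipeline):
        pruned, _, assignment, expected = toy_mixed_pipeline
        for rid in expected:
            deep = [tc for tc in typed_contacts(pruned, assignment, rid)
                    if tc.burial_level >= 2]
            fv = feature_vector(pruned, assignment, rid, mode="AC")
            assert fv["C_I_ge2"] + fv["C_II_2"] + fv["C_II_ge3"] + \
                fv["C_III_2"] + fv["C_III_ge3"] == len(deep)
            ge3 = [tc for tc in deep if tc.burial_level >= 3
                   and tc.contact_type != "I"]
            assert fv["C_II_ge3"] + fv["C_III_ge3"] == len(ge3)
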