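"""Parsing, canonical fragment identity, and subgraph embedding."""

import itertools

import pytest

from molassembly.molgraph import (Fragment, MolecularGraph,
                                  MoleculeFormatError, canonical_key,
                                  parse_molecule, subgraph_embeddings)
from conftest import brute_force_isomorphic, random_small_graphs


class TestParseMolecule:
    @pytest.mark.parametrize("smiles, atoms, bonds", [
        ("CO", 2, 1),                     # methanol
        ("CCC", 3, 2),                    # propane
        ("Nc1ncnc2[nH]cnc12", 10, 11),    # adenine, kekulized
        ("Cc1c[nH]c(=O)[nH]c1=O", 9, 9),  # thymine
    ])
    def test_atom_and_bond_counts(self, smiles, atoms, bonds):
        m = parse_molecule(smiles)
        assert (m.atom_count, m.bond_count) == (atoms, bonds)

    def test_propane_is_two_single_cc_bonds(self):
        m = parse_molecule("CCC")
        assert all(o == 1 for _, _, o in m.bonds)
        assert all(a == "C" for a in m.atoms)

    def test_kekulized_no_fractional_orders(self):
        m = parse_molecule("c1ccccc1")
        assert sorted(o for _, _, o in m.bonds) == [1, 1, 1, 2, 2, 2]

    def test_inchi_and_molblock_agree_with_smiles(self):
        smi = parse_molecule("CC(=O)O")
        inchi = parse_molecule(
            "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)", fmt="inchi")
        assert canonical_key(smi.as_fragment()) == \
            canonical_key(inchi.as_fragment())
        from rdkit import Chem
        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CC(=O)O"))
        mb = parse_molecule(block, fmt="molblock")
        assert canonical_key(mb.as_fragment()) == \
            canonical_key(smi.as_fragment())

    def test_parse_failure_names_input(self):
        with pytest.raises(MoleculeFormatError, match="could not parse"):
            parse_molecule("not_a_smiles((")

    def test_salt_rejected_with_instruction(self):
        with pytest.raises(MoleculeFormatError, match="strip components"):
            parse_molecule("[Na+].[Cl-]")

    def test_unknown_format(self):
        with pytest.raises(MoleculeFormatError):
            parse_molecule("CO", fmt="pdb")

    def test_stereo_and_charge_discarded(self):
        flat = parse_molecule("C(O)C(N)C")
        chiral = parse_molecule("C(O)[C@@H](N)C")
        assert canonical_key(flat.as_fragment()) == \
            canonical_key(chiral.as_fragment())

    def test_round_trip_preserves_isomorphism_class(self, molecule_panel):
        assert len(molecule_panel) >= 20
        for m in molecule_panel:
            again = parse_molecule(m.to_smiles())
            assert canonical_key(again.as_fragment()) == \
                canonical_key(m.as_fragment())


class TestCanonicalKey:
    def test_isomorphic_fragments_share_key(self):
        f1 = Fragment(("C", "C"), ((0, 1, 1),))
        f2 = Fragment(("C", "C"), ((1, 0, 1),))
        assert f1.canonical_key == f2.canonical_key

    def test_bond_order_distinguishes(self):
        single = Fragment(("C", "C"), ((0, 1, 1),))
        double = Fragment(("C", "C"), ((0, 1, 2),))
        assert single.canonical_key != double.canonical_key

    def test_ccn_vs_cnc_distinct(self):
        ccn = Fragment(("C", "C", "N"), ((0, 1, 1), (1, 2, 1)))
        cnc = Fragment(("C", "N", "C"), ((0, 1, 1), (1, 2, 1)))
        assert not brute_force_isomorphic(ccn, cnc)
        assert ccn.canonical_key != cnc.canonical_key

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            Fragment(("C",), ())

    def test_agrees_with_brute_force_oracle_pairwise(self):
        graphs = random_small_graphs(16, max_bonds=6)
        frags = [g.as_fragment() for g in graphs]
        # also add label permutations of a few, which must match their source
        for g in graphs[:4]:
            n = len(g.atoms)
            perm = list(reversed(range(n)))
            atoms = tuple(g.atoms[perm[i]] for i in range(n))
            inv = {perm[i]: i for i in range(n)}
            bonds = tuple((inv[i], inv[j], o) for i, j, o in g.bonds)
            frags.append(Fragment(atoms, bonds))
        for f1, f2 in itertools.combinations(frags, 2):
            same_key = f1.canonical_key == f2.canonical_key
            assert same_key == brute_force_isomorphic(f1, f2), \
                (f1, f2)


class TestSubgraphEmbeddings:
    def test_cc_into_propane(self):
        cc = Fragment(("C", "C"), ((0, 1, 1),))
        assert len(subgraph_embeddings(cc, parse_molecule("CCC"))) == 2

    def test_co_double_into_propane_absent(self):
        co = Fragment(("C", "O"), ((0, 1, 2),))
        assert subgraph_embeddings(co, parse_molecule("CCC")) == []

    def test_two_bond_path_into_butane_matches_enumeration(self):
        path2 = Fragment(("C", "C", "C"), ((0, 1, 1), (1, 2, 1)))
        butane = parse_molecule("CCCC")
        found = subgraph_embeddings(path2, butane)
        # brute force: all adjacent bond pairs
        expected = 0
        for b1, b2 in itertools.combinations(range(butane.bond_count), 2):
            e1, e2 = butane.bonds[b1], butane.bonds[b2]
            if set(e1[:2]) & set(e2[:2]):
                expected += 1
        assert len(found) == expected == 2

    def test_embeddings_are_label_preserving_and_injective(self):
        frag = Fragment(("C", "N"), ((0, 1, 1),))
        target = parse_molecule("CNC(C)N")
        for amap in subgraph_embeddings(frag, target):
            assert len(set(amap.values())) == len(amap)
            for fa, ta in amap.items():
                assert frag.atoms[fa] == target.atoms[ta]
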