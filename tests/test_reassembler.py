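"""Assembly-pool molecule generation and plausibility filters."""

import pytest

from molassembly.config import ConfigError, GenerationConstraints
from molassembly.molgraph import parse_molecule, subgraph_embeddings
from molassembly.reassembler import (UnsatisfiableConstraintsError,
                                     arbitrary_fragment_pool, build_pool,
                                     degrees_of_unsaturation,
                                     plausibility_filter, random_baseline,
                                     reassemble)

OPIATE_BOND_TYPES = [("C", "C", 1), ("C", "C", 2), ("C", "O", 1),
                     ("C", "O", 2), ("C", "N", 1), ("C", "N", 2)]


def permissive(**kw) -> GenerationConstraints:
    base = dict(mw_range=(100.0, 500.0), dou_range=(0.0, 99.0),
                require_embeddable_3d=False, n_molecules=5, seed=1,
                attempt_factor=500)
    base.update(kw)
    return GenerationConstraints(**base)


@pytest.fixture(scope="module")
def opiate_pool(natural_opiates):
    parents = list(natural_opiates.values())
    pool, records = build_pool(parents, 30, seed=1)
    return parents, pool, records


class TestBuildPool:
    def test_pool_blocks_annotated_with_real_sites(self, opiate_pool):
        parents, pool, records = opiate_pool
        assert pool.size > 0
        assert records
        for rec in records[:40]:
            # every site corresponds to a real boundary bond in some parent
            found = False
            for parent in parents:
                for amap in subgraph_embeddings(rec.fragment, parent,
                                                max_embeddings=4):
                    found = True
            assert found

    def test_two_copies_of_same_molecule_allowed(self, nucleobases):
        a = nucleobases["adenine"]
        pool, records = build_pool([a, a], 300, seed=1)
        assert pool.size > 0          # internal duplication blocks
        assert all(r.sites for r in records)

    def test_share_nothing_parents_give_empty_composite_pool(self):
        pool, records = build_pool(
            [parse_molecule("CCC"), parse_molecule("COC")], 100, seed=1)
        assert pool.size == 0         # only basic bonds remain
        assert records == []

    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="two parents"):
            build_pool([parse_molecule("CCC")], 10, seed=1)


class TestReassemble:
    def test_generates_requested_count_with_provenance(self, opiate_pool):
        _, pool, records = opiate_pool
        gen = reassemble(pool, records, permissive(
            mw_range=(281.0, 368.0), dou_range=(9.0, 12.0), n_molecules=8))
        assert len(gen.molecules) == 8
        assert all(gen.provenance)
        block_keys = set(pool.blocks)
        for prov in gen.provenance:
            assert set(prov) <= block_keys

    def test_provenance_fragments_embed_in_product(self, opiate_pool):
        _, pool, records = opiate_pool
        gen = reassemble(pool, records, permissive(n_molecules=4))
        for mol, prov in zip(gen.molecules, gen.provenance):
            for key in prov:
                frag = pool.blocks[key]
                assert subgraph_embeddings(frag, mol, max_embeddings=1)

    def test_all_outputs_pass_filters(self, opiate_pool):
        _, pool, records = opiate_pool
        constraints = permissive(mw_range=(281.0, 368.0),
                                 dou_range=(9.0, 12.0), n_molecules=10)
        gen = reassemble(pool, records, constraints)
        for mol in gen.molecules:
            ok, reason = plausibility_filter(mol, constraints)
            assert ok, reason

    def test_zero_molecules_no_work(self, opiate_pool):
        _, pool, records = opiate_pool
        gen = reassemble(pool, records, permissive(n_molecules=0))
        assert gen.molecules == []

    def test_no_open_sites_unsatisfiable(self, opiate_pool):
        _, pool, records = opiate_pool
        with pytest.raises(UnsatisfiableConstraintsError, match="site"):
            reassemble(pool, [], permissive())

    def test_seed_reproducibility(self, opiate_pool):
        _, pool, records = opiate_pool
        g1 = reassemble(pool, records, permissive(seed=42))
        g2 = reassemble(pool, records, permissive(seed=42))
        assert sorted(g1.smiles()) == sorted(g2.smiles())

    def test_unique_flag_deduplicates(self, opiate_pool):
        _, pool, records = opiate_pool
        gen = reassemble(pool, records, permissive(n_molecules=10))
        uniq = gen.unique()
        assert len(set(uniq.smiles())) == len(uniq.molecules)


class TestRandomBaseline:
    def test_generates_in_window(self):
        c = GenerationConstraints(mw_range=(281.0, 368.0),
                                  dou_range=(9.0, 12.0),
                                  require_embeddable_3d=False,
                                  n_molecules=5, seed=2)
        gen = random_baseline(OPIATE_BOND_TYPES, c)
        assert len(gen.molecules) == 5
        for mol in gen.molecules:
            rd = mol.to_rdkit()
            assert 9 <= degrees_of_unsaturation(rd) <= 12

    def test_single_molecule_with_permissive_constraints(self):
        gen = random_baseline([("C", "C", 1)], permissive(
            mw_range=(50.0, 200.0), n_molecules=1))
        assert len(gen.molecules) == 1

    def test_unreachable_unsaturation_exhausts_attempt_budget(self):
        # a DoU window far beyond what random growth produces within the
        # MW cap: the generator must give up with rejection statistics
        c = GenerationConstraints(mw_range=(281.0, 368.0),
                                  dou_range=(20.0, 99.0),
                                  require_embeddable_3d=False,
                                  n_molecules=3, seed=1, attempt_factor=40)
        with pytest.raises(UnsatisfiableConstraintsError) as exc:
            random_baseline([("C", "C", 1)], c)
        assert exc.value.rejected

    def test_seed_reproducibility(self):
        c = permissive(mw_range=(150.0, 400.0), seed=5)
        g1 = random_baseline(OPIATE_BOND_TYPES, c)
        g2 = random_baseline(OPIATE_BOND_TYPES, c)
        assert g1.smiles() == g2.smiles()


class TestPlausibilityFilter:
    def test_morphine_passes_mw_and_dou(self, natural_opiates):
        morphine = natural_opiates["morphine"]
        rd = morphine.to_rdkit()
        from rdkit.Chem import Descriptors
        assert Descriptors.MolWt(rd) == pytest.approx(285.34, abs=0.01)
        assert degrees_of_unsaturation(rd) == 9
        ok, reason = plausibility_filter(
            morphine, GenerationConstraints(require_embeddable_3d=False))
        assert ok, reason

    def test_small_fragment_fails_mw(self):
        ok, reason = plausibility_filter(
            parse_molecule("c1ccccc1C(=O)O"),
            GenerationConstraints(require_embeddable_3d=False))
        assert not ok and reason == "mw"

    def test_forbidden_motif_fails_smarts(self):
        constraints = GenerationConstraints(
            mw_range=(0.0, 1000.0), dou_range=(0.0, 99.0),
            require_embeddable_3d=False)
        peroxide = parse_molecule("CCOOCC")
        ok, reason = plausibility_filter(peroxide, constraints)
        assert not ok and reason == "smarts"

    def test_embed3d_probe_accepts_normal_molecule(self, natural_opiates):
        ok, reason = plausibility_filter(
            natural_opiates["codeine"],
            GenerationConstraints(mw_range=(0.0, 1000.0),
                                  dou_range=(0.0, 99.0),
                                  require_embeddable_3d=True))
        assert ok, reason

    def test_malformed_smarts_is_config_error(self):
        with pytest.raises(ConfigError, match="SMARTS"):
            GenerationConstraints(forbidden_smarts=["[[["])


class TestArbitraryFragmentPool:
    def test_samples_fragments_with_sites(self, natural_opiates):
        records = arbitrary_fragment_pool(
            list(natural_opiates.values()), 20, (2, 6), seed=1)
        assert records
        for rec in records:
            assert 2 <= rec.fragment.bond_count <= 6
            assert rec.sites
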