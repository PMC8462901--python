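"""Assembly steps, pathways, exact and Monte-Carlo index searches."""

import math

import pytest

from molassembly.assembly_core import (AssemblyPool, AssemblyStep,
                                       InvalidStepError, TooManyBondsError,
                                       apply_step, exact_ma, key_step_view,
                                       ma_bounds, mc_ma, multiset_view,
                                       pathway_index)
from molassembly.fixtures import make_toy_graphs
from molassembly.molgraph import Fragment, canonical_key, parse_molecule
from conftest import brute_force_ma, random_small_graphs

CC = Fragment(("C", "C"), ((0, 1, 1),))
CCC = Fragment(("C", "C", "C"), ((0, 1, 1), (1, 2, 1)))


class TestApplySteps:
    def test_join_two_cc_overlapping_one_carbon(self):
        step = AssemblyStep(left=CC, right=CC,
                            atom_identification={0: 1},
                            product=CCC)
        pool = apply_step(AssemblyPool(), step)
        assert CCC.canonical_key in pool.entries

    def test_join_ccc_and_cc_gives_butane_skeleton(self):
        butane = parse_molecule("CCCC").as_fragment()
        step = AssemblyStep(left=CCC, right=CC,
                            atom_identification={0: 2},
                            product=butane)
        pool = AssemblyPool()
        pool.add(CCC)
        pool = apply_step(pool, step)
        assert butane.canonical_key in pool.entries

    def test_label_mismatch_rejected(self):
        cn = Fragment(("C", "N"), ((0, 1, 1),))
        with pytest.raises(InvalidStepError, match="differ"):
            AssemblyStep(left=CC, right=cn, atom_identification={1: 0},
                         product=CCC)

    def test_disconnected_product_rejected(self):
        butane = parse_molecule("CCCC").as_fragment()
        with pytest.raises(InvalidStepError, match="product"):
            AssemblyStep(left=CC, right=CC, atom_identification={},
                         product=butane)

    def test_coinciding_bonds_rejected(self):
        with pytest.raises(InvalidStepError, match="coincide"):
            AssemblyStep(left=CC, right=CC,
                         atom_identification={0: 0, 1: 1}, product=CC)

    def test_missing_operand_rejected(self):
        butane = parse_molecule("CCCC").as_fragment()
        step = AssemblyStep(left=CCC, right=CC, atom_identification={0: 2},
                            product=butane)
        with pytest.raises(InvalidStepError, match="not available"):
            apply_step(AssemblyPool(), step)  # CCC never built

    def test_shortest_adenine_pathway_replays_to_adenine(self, nucleobases):
        adenine = nucleobases["adenine"]
        index, pathway = exact_ma(adenine)
        assert index == pathway_index(pathway) == 7
        pool = pathway.replay()
        assert canonical_key(adenine.as_fragment()) in pool.entries


class TestExactMA:
    def test_single_bond_molecule_is_basic(self):
        assert exact_ma(parse_molecule("CO"))[0] == 0

    def test_propane(self):
        assert exact_ma(parse_molecule("CCC"))[0] == 1

    def test_thymine(self, nucleobases):
        assert exact_ma(nucleobases["thymine"])[0] == 6

    def test_guard_refuses_large_molecules(self, natural_opiates):
        with pytest.raises(TooManyBondsError, match="mc_ma"):
            exact_ma(natural_opiates["morphine"])

    @pytest.mark.parametrize("family,size", [
        ("path", 5), ("ring", 6), ("star", 4), ("hetero", 5),
    ])
    def test_matches_brute_force_oracle_on_toys(self, family, size):
        (g,) = make_toy_graphs(family, [size])
        assert exact_ma(g)[0] == brute_force_ma(g)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        for g in random_small_graphs(12, max_bonds=6):
            assert exact_ma(g)[0] == brute_force_ma(g), g


class TestMonteCarloMA:
    def test_adenine_converges_to_seven(self, nucleobases):
        best, pathway, trace = mc_ma(nucleobases["adenine"], 3000, seed=1)
        assert best == pathway.index == 7

    def test_one_iteration_within_naive_bound(self, nucleobases):
        m = nucleobases["guanine"]
        best, pathway, _ = mc_ma(m, 1, seed=7)
        assert best <= m.bond_count - 1
        pathway.replay()

    def test_octane_equals_exact(self):
        octane = parse_molecule("CCCCCCCC")  # 7 C-C bonds
        exact, _ = exact_ma(octane)
        best, _, _ = mc_ma(octane, 2000, seed=3)
        assert best == exact == 4

    def test_deterministic_for_fixed_seed(self, nucleobases):
        m = nucleobases["thymine"]
        r1 = mc_ma(m, 300, seed=11)
        r2 = mc_ma(m, 300, seed=11)
        assert r1[0] == r2[0]
        assert r1[1].to_json_lines() == r2[1].to_json_lines()
        assert r1[2] == r2[2]

    def test_best_so_far_monotone_and_bounded(self, nucleobases):
        m = nucleobases["cytosine"]
        best, pathway, trace = mc_ma(m, 800, seed=5)
        values = [v for _, v in trace]
        assert values == sorted(values, reverse=True)
        lo, hi = ma_bounds(m)
        assert lo <= best <= hi

    def test_bond_additivity_along_pathway(self, nucleobases):
        _, pathway, _ = mc_ma(nucleobases["uracil"], 300, seed=2)
        for s in pathway.steps:
            assert s.product.bond_count == \
                s.left.bond_count + s.right.bond_count


class TestBounds:
    @pytest.mark.parametrize("bonds,expected", [
        (1, (0, 0)), (8, (3, 7)), (11, (4, 10)),
    ])
    def test_closed_form(self, bonds, expected):
        g = make_toy_graphs("path", [bonds])[0]
        assert ma_bounds(g) == expected

    def test_adenine_ma_within_bounds(self, nucleobases):
        lo, hi = ma_bounds(nucleobases["adenine"])
        assert lo <= 7 <= hi


class TestViews:
    def test_adenine_key_blocks_and_multiset(self, nucleobases):
        _, pathway = exact_ma(nucleobases["adenine"])
        view = key_step_view(pathway)
        assert all(view.use_counts[b.canonical_key] >= 2
                   for b in view.key_blocks)
        ms = multiset_view(view)
        # any optimal pathway saves bond_count-1 steps per extra block use:
        # naive(10) - MA(7) = 3
        savings = sum(mult * (b.bond_count - 1)
                      for b, mult in zip(view.key_blocks,
                                         (ms.entries[b.canonical_key]
                                          for b in view.key_blocks)))
        assert savings == 3
        # the shortest adenine pathway has two key blocks of 2 and 3 bonds,
        # each appearing once after cancellation
        assert sorted(b.bond_count for b in view.key_blocks) == [2, 3]
        assert sorted(ms.entries.values()) == [1, 1]

    def test_bond_by_bond_pathway_has_no_key_blocks(self):
        m = parse_molecule("CCOC")  # no repeated composite needed
        _, pathway = exact_ma(m)
        if pathway.index == m.bond_count - 1:
            view = key_step_view(pathway)
            assert view.key_blocks == []
            assert multiset_view(view).entries == {}

    def test_round_trip_multiset_and_use_counts(self, nucleobases):
        _, pathway = exact_ma(nucleobases["thymine"])
        view = key_step_view(pathway)
        ms = multiset_view(view)
        assert ms.to_use_counts() == view.use_counts

    def test_dependency_edges_point_to_consumers(self, nucleobases):
        _, pathway = exact_ma(nucleobases["adenine"])
        view = key_step_view(pathway)
        keys = {b.canonical_key for b in view.key_blocks}
        targets = set(view.target_keys)
        for a, b in view.edges:
            assert a in keys
            assert b in keys | targets


class TestSerialization:
    def test_pathway_json_lines(self, nucleobases):
        _, pathway = exact_ma(nucleobases["uracil"])
        import json
        lines = pathway.to_json_lines().splitlines()
        assert len(lines) == pathway.index
        rec = json.loads(lines[-1])
        assert set(rec) == {"left_key", "right_key", "identification",
                            "product_key"}
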