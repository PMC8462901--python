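"""Joint shortest assembly pathways for molecule sets: assembly trees.

A group of molecules is assembled in one pool, so a block built for one
target is free for every other.  The index of the shortest joint pathway
(the assembly tree MA) is therefore at most the sum of the individual MAs,
and strictly smaller whenever targets share composite structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx

from ._space import FragmentSpace
from .assembly_core import (AssemblyPathway, Recipe, TooManyBondsError,
                            _operand_use_counts, exact_ma, key_step_view,
                            mc_search, recipe_to_pathway, DEFAULT_MAX_BONDS)
from .molgraph import Fragment, MolecularGraph

__all__ = ["AssemblyTree", "AssemblySpace", "joint_ma", "naive_step_counts",
           "assembly_space", "export_tree", "tree_from_json"]


@dataclass
class AssemblyTree:
    """Best joint pathway for a molecule set, as a DAG of key blocks."""

    targets: list[MolecularGraph]
    tree_ma: int
    pathway: AssemblyPathway
    key_blocks: list[Fragment]
    edges: list[tuple[str, str]]        # dependency edges between node keys
    pathways_sampled: int
    trace: list[tuple[int, int]] = field(default_factory=list)

    def node_labels(self) -> dict[str, str]:
        labels = {}
        for i, t in enumerate(self.targets):
            labels[t.as_fragment().canonical_key] = t.name or f"target{i}"
        for b in self.key_blocks:
            labels.setdefault(b.canonical_key, b.to_smiles())
        return labels


@dataclass
class AssemblySpace:
    """Key building blocks across all sampled pathways of a molecule set.

    Only shared structure belongs to the space: blocks reused within one
    pathway or embedding in at least two targets.  ``size_trace`` records
    the cumulative size per MC iteration (the saturation diagnostic).
    """

    blocks: dict[str, Fragment]
    size_trace: list[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.blocks)


def joint_ma(targets: list[MolecularGraph], iterations: int, seed: int,
             **params) -> AssemblyTree:
    """Monte-Carlo search for the shortest joint assembly pathway.

    Duplicate targets are collapsed first (a type is constructed once;
    instances are free).  For a single target this reduces to
    :func:`molassembly.assembly_core.mc_ma`.
    """
    if not targets:
        raise ValueError("need at least one target")
    space = FragmentSpace(targets)
    best, recipe, trace, _, _ = mc_search(space, space.target_keys,
                                          iterations, seed, **params)
    pathway = recipe_to_pathway(space, recipe, space.targets, rng_seed=seed)
    view = key_step_view(pathway)
    lo = max(math.ceil(math.log2(t.bond_count)) for t in space.targets)
    hi = sum(t.bond_count for t in space.targets) - len(space.targets)
    assert lo <= best <= hi
    return AssemblyTree(targets=space.targets, tree_ma=best, pathway=pathway,
                        key_blocks=view.key_blocks, edges=view.edges,
                        pathways_sampled=iterations, trace=trace)


def naive_step_counts(targets: list[MolecularGraph],
                      iterations: int = 20000, seed: int = 0,
                      max_bonds: int = DEFAULT_MAX_BONDS,
                      ) -> tuple[int, int]:
    """Reference step counts for a molecule set.

    Returns ``(bond_by_bond, separate_ma_sum)``: the steps needed adding one
    bond at a time to each distinct molecule, and the sum of the individual
    assembly indices (exact search when the molecule is small enough,
    converged MC otherwise).
    """
    space = FragmentSpace(targets)
    uniq = space.targets
    bond_by_bond = sum(t.bond_count for t in uniq) - len(uniq)
    total = 0
    for t in uniq:
        if t.bond_count <= max_bonds:
            ma, _ = exact_ma(t, max_bonds=max_bonds)
        else:
            from .assembly_core import mc_ma
            ma, _, _ = mc_ma(t, iterations, seed)
        total += ma
    return bond_by_bond, total


def assembly_space(targets: list[MolecularGraph], iterations: int, seed: int,
                   keep_suboptimal: bool = True, **params) -> AssemblySpace:
    """Union of key blocks over all sampled pathways.

    With ``keep_suboptimal`` every completed sampled pathway contributes its
    key blocks (the paper's algorithm also outputs longer pathways);
    otherwise only blocks of the best pathway are kept.
    """
    space = FragmentSpace(targets)
    best, recipe, _, block_counts, size_trace = mc_search(
        space, space.target_keys, iterations, seed,
        collect_blocks=keep_suboptimal, **params)
    if not keep_suboptimal:
        counts = _operand_use_counts(space, recipe, space.target_keys)
        block_counts = {k: 1 for k, u in counts.items()
                        if u >= 2 or space.containment(k) >= 2}
        size_trace = [(iterations - 1, len(block_counts))]
    blocks = {k: space.fragment(k) for k in block_counts}
    return AssemblySpace(blocks=blocks, size_trace=size_trace)


# ---------------------------------------------------------------------------
# export


def _tree_graph(t: AssemblyTree) -> nx.DiGraph:
    g = nx.DiGraph()
    labels = t.node_labels()
    target_keys = {x.as_fragment().canonical_key for x in t.targets}
    key_keys = {b.canonical_key for b in t.key_blocks}
    # basic bonds used by the pathway appear as leaf nodes
    basics = {}
    for s in t.pathway.steps:
        for op in (s.left, s.right):
            if op.is_basic():
                basics[op.canonical_key] = str(op.as_bond_type())
    for k in sorted(target_keys | key_keys) + sorted(basics):
        kind = ("target" if k in target_keys else
                "key_block" if k in key_keys else "basic")
        g.add_node(k, label=labels.get(k, basics.get(k, k)), kind=kind)
    for a, b in t.edges:
        g.add_edge(a, b)
    return g


def export_tree(t: AssemblyTree, format: str = "DOT") -> str:
    """Serialize a tree as DOT, GraphML, or JSON (round-trippable)."""
    fmt = format.upper()
    g = _tree_graph(t)
    if fmt == "DOT":
        lines = ["digraph assembly_tree {"]
        ids = {k: f"n{i}" for i, k in enumerate(sorted(g.nodes))}
        for k in sorted(g.nodes):
            d = g.nodes[k]
            shape = {"target": "doubleoctagon", "key_block": "box",
                     "basic": "plaintext"}[d["kind"]]
            label = d["label"].replace('"', r'\"')
            lines.append(f'  {ids[k]} [label="{label}", shape={shape}];')
        for a, b in sorted(g.edges):
            lines.append(f"  {ids[a]} -> {ids[b]};")
        lines.append("}")
        return "\n".join(lines)
    if fmt == "GRAPHML":
        return "\n".join(nx.generate_graphml(g))
    if fmt == "JSON":
        return json.dumps({
            "tree_ma": t.tree_ma,
            "pathways_sampled": t.pathways_sampled,
            "targets": [{"name": x.name, "smiles": x.to_smiles()}
                        for x in t.targets],
            "nodes": [{"key": k, **g.nodes[k]} for k in sorted(g.nodes)],
            "edges": sorted(g.edges),
        }, indent=2)
    raise ValueError(f"unknown export format {format!r}")


def tree_from_json(text: str) -> dict:
    """Parse a JSON tree export (used for round-trip checks)."""
    return json.loads(text)
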