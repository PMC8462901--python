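"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's canonical-key machinery:
isomorphism is decided by permutation search, and minimal assembly indices
for tiny graphs are found by an independent recursive search over edge
bipartitions with permutation-based duplicate detection.
"""

from __future__ import annotations

import itertools
import random

import pytest

from molassembly import fixtures as fx
from molassembly.molgraph import Fragment, MolecularGraph, parse_molecule


# ---------------------------------------------------------------------------
# brute-force graph isomorphism (permutation search)


def brute_force_isomorphic(g1, g2) -> bool:
    a1, e1 = tuple(g1.atoms), g1.bonds
    a2, e2 = tuple(g2.atoms), g2.bonds
    if len(a1) != len(a2) or len(e1) != len(e2):
        return False
    if sorted(a1) != sorted(a2):
        return False
    bonds2 = {(min(i, j), max(i, j), o) for i, j, o in e2}
    for perm in itertools.permutations(range(len(a2))):
        if any(a1[k] != a2[perm[k]] for k in range(len(a1))):
            continue
        if all((min(perm[i], perm[j]), max(perm[i], perm[j]), o) in bonds2
               for i, j, o in e1):
            return True
    return False


# ---------------------------------------------------------------------------
# independent tiny-graph assembly-index oracle


def _bf_connected(edges):
    if not edges:
        return False
    verts = {v for e in edges for v in e[:2]}
    seen = {next(iter(verts))}
    grow = True
    while grow:
        grow = False
        for i, j, _ in edges:
            if i in seen and j not in seen:
                seen.add(j)
                grow = True
            elif j in seen and i not in seen:
                seen.add(i)
                grow = True
    return seen == verts


def _bf_iso_edges(e1, e2) -> bool:
    """Label-aware isomorphism of edge lists whose vertices are
    (id, element) tuples."""
    def norm(edges):
        verts = sorted({v for e in edges for v in e[:2]})
        idx = {v: k for k, v in enumerate(verts)}
        labels = [v[1] for v in verts]
        return [(idx[i], idx[j], o) for i, j, o in edges], labels

    n1, l1 = norm(e1)
    n2, l2 = norm(e2)
    if len(l1) != len(l2) or len(n1) != len(n2):
        return False
    if sorted(l1) != sorted(l2):
        return False
    b2 = {(min(i, j), max(i, j), o) for i, j, o in n2}
    for perm in itertools.permutations(range(len(l2))):
        if any(l1[k] != l2[perm[k]] for k in range(len(l1))):
            continue
        if all((min(perm[i], perm[j]), max(perm[i], perm[j]), o) in b2
               for i, j, o in n1):
            return True
    return False


def brute_force_ma(graph: MolecularGraph) -> int:
    """Minimal assembly index by exhaustive search (labels via elements
    folded into edge tuples; only suitable for a handful of bonds)."""
    # encode element labels into the edge tuples so edge-level isomorphism
    # is label-aware: vertices renamed to (id, element)
    def tag(edges, atoms):
        return [((i, atoms[i]), (j, atoms[j]), o) for i, j, o in edges]

    target = tag(graph.bonds, graph.atoms)

    best = [len(target) - 1]

    def search(pending, built, steps):
        if steps >= best[0]:
            return
        if not pending:
            best[0] = steps
            return
        pending = sorted(pending, key=lambda es: -len(es))
        f, rest = pending[0], pending[1:]
        m = len(f)
        for r in range(0, 1 << (m - 1)):
            mask = r | (1 << (m - 1))  # last edge always in part1
            part1 = [f[k] for k in range(m) if mask >> k & 1]
            part2 = [f[k] for k in range(m) if not mask >> k & 1]
            if not part2:
                continue
            if not (_bf_connected(part1) and _bf_connected(part2)):
                continue
            new_pending = list(rest)
            new_built = list(built) + [f]
            for part in (part1, part2):
                if len(part) <= 1:
                    continue
                if any(_bf_iso_edges(part, g) for g in new_built):
                    continue
                if any(_bf_iso_edges(part, g) for g in new_pending):
                    continue
                new_pending.append(part)
            search(new_pending, new_built, steps + 1)

    if len(target) <= 1:
        return 0
    search([target], [], 0)
    return best[0]


# ---------------------------------------------------------------------------
# independent tiny-string assembly oracle


def brute_force_string_steps(s: str) -> int:
    """Minimal concatenation steps to build ``s`` from single characters
    with free reuse of every built substring (exhaustive, tiny inputs)."""
    best = [len(s) - 1]

    def search(pending, built, steps):
        if steps >= best[0]:
            return
        if not pending:
            best[0] = steps
            return
        pending = sorted(pending, key=len, reverse=True)
        f, rest = pending[0], pending[1:]
        for cut in range(1, len(f)):
            a, b = f[:cut], f[cut:]
            new_pending = list(rest)
            new_built = set(built) | {f}
            for part in (a, b):
                if len(part) > 1 and part not in new_built \
                        and part not in new_pending:
                    new_pending.append(part)
            search(new_pending, new_built, steps + 1)

    if len(s) <= 1:
        return 0
    search([s], set(), 0)
    return best[0]


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def nucleobases() -> dict[str, MolecularGraph]:
    return {m.name: m for m in fx.load_set("nucleobases")}


@pytest.fixture(scope="session")
def natural_opiates() -> dict[str, MolecularGraph]:
    return {m.name: m for m in fx.load_set("natural_opiates")}


@pytest.fixture(scope="session")
def opiate_family() -> dict[str, MolecularGraph]:
    return {m.name: m for m in fx.load_set("opiate_family")}


def random_small_graphs(n: int, max_bonds: int = 8, seed: int = 20240901
                        ) -> list[MolecularGraph]:
    """Deterministic random connected labelled graphs for oracle testing."""
    rng = random.Random(seed)
    elements = ["C", "C", "C", "N", "O"]
    out = []
    while len(out) < n:
        nb = rng.randint(2, max_bonds)
        atoms = [rng.choice(elements)]
        bonds = []
        order_used = {}
        for _ in range(nb):
            if bonds and rng.random() < 0.2:
                # try a ring closure
                i, j = rng.randrange(len(atoms)), rng.randrange(len(atoms))
                if i != j and (min(i, j), max(i, j)) not in order_used:
                    order_used[(min(i, j), max(i, j))] = 1
                    bonds.append((min(i, j), max(i, j), rng.choice([1, 1, 2])))
                    continue
            host = rng.randrange(len(atoms))
            atoms.append(rng.choice(elements))
            j = len(atoms) - 1
            order_used[(host, j)] = 1
            bonds.append((host, j, rng.choice([1, 1, 1, 2])))
        if len(bonds) < 2:
            continue
        try:
            out.append(MolecularGraph(tuple(atoms), tuple(bonds),
                                      name=f"rand{len(out)}"))
        except Exception:
            continue
    return out


@pytest.fixture(scope="session")
def molecule_panel() -> list[MolecularGraph]:
    """>= 20 diverse real molecules for round-trip checks."""
    mols = (fx.load_set("nucleobases") + fx.load_set("biomolecules")
            + fx.load_set("plasticizers") + fx.load_set("opiate_family"))
    uniq = {}
    for m in mols:
        uniq.setdefault(m.to_smiles(), m)
    return list(uniq.values())
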