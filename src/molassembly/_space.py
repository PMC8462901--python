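"""Fragment-class registry and assembly-step enumeration.

The search engine never manipulates concrete fragments directly: it works on
isomorphism classes identified by canonical keys.  For each class the
registry stores one representative graph, the bond count, and — computed
lazily — the list of ways the representative can be produced by a single
assembly step.  Reversing a step that superimposes atoms of two building
blocks corresponds exactly to a bipartition of the product's bond set into
two connected halves, so the enumeration walks all edge bipartitions.

Restricting the search to fragments that arise as subgraphs of a target is
sound: a building block that does not embed in any target can never be part
of one (bond multisets only grow along a pathway).
"""

from __future__ import annotations

from .molgraph import Fragment, MolecularGraph, embeds_in
from ._canon import canonical_string

GraphT = tuple[tuple[str, ...], tuple[tuple[int, int, int], ...]]


def _connected_mask(edges, mask: int) -> bool:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = 0
    k = 0
    m = mask
    while m:
        if m & 1:
            i, j, _ = edges[k]
            for x in (i, j):
                if x not in parent:
                    parent[x] = x
                    comps += 1
            a, b = find(i), find(j)
            if a != b:
                parent[a] = b
                comps -= 1
        m >>= 1
        k += 1
    return comps == 1


def _subgraph(atoms, edges, mask: int) -> GraphT:
    sel = [edges[k] for k in range(len(edges)) if mask >> k & 1]
    verts = sorted({i for i, j, _ in sel} | {j for _, j, _ in sel})
    idx = {v: k for k, v in enumerate(verts)}
    return (tuple(atoms[v] for v in verts),
            tuple((idx[i], idx[j], o) for i, j, o in sel))


# full bipartition enumeration is O(2^bonds); beyond this many bonds the
# Monte-Carlo search samples bipartitions instead
SPLIT_ENUM_MAX = 12


def graph_invariant(atoms, edges) -> tuple:
    """Cheap isomorphism-invariant fingerprint of a labelled graph."""
    deg: dict[int, list] = {}
    for i, j, o in edges:
        deg.setdefault(i, []).append(o)
        deg.setdefault(j, []).append(o)
    profile = sorted((atoms[v], tuple(sorted(os))) for v, os in deg.items())
    bond_profile = sorted((min(atoms[i], atoms[j]), max(atoms[i], atoms[j]), o)
                          for i, j, o in edges)
    return (len(atoms), tuple(bond_profile), tuple(profile))


class FragmentSpace:
    """Registry of fragment isomorphism classes over a set of target graphs."""

    def __init__(self, targets: list[MolecularGraph]):
        self.targets: list[MolecularGraph] = []
        seen = set()
        for t in targets:
            k = canonical_string(t.atoms, t.bonds)
            if k not in seen:
                seen.add(k)
                self.targets.append(t)
        self._rep: dict[str, GraphT] = {}
        self.bonds: dict[str, int] = {}
        self._splits: dict[str, list[tuple[str, str, int]]] = {}
        self._ncontain: dict[str, int] = {}
        self._inv_index: dict[tuple, set[str]] = {}
        self.target_keys = [self.register(t.atoms, t.bonds) for t in self.targets]

    def register(self, atoms, edges) -> str:
        key = canonical_string(atoms, tuple(edges))
        if key not in self._rep:
            # store the *canonical* representative so reps are run-independent
            from ._canon import canonical_form
            a, e = canonical_form(tuple(atoms), tuple(edges))
            self._rep[key] = (a, e)
            self.bonds[key] = len(e)
            self._inv_index.setdefault(graph_invariant(a, e), set()).add(key)
        return key

    def match_known(self, graph: GraphT, known: set[str]) -> str | None:
        """Canonical key of ``graph`` if it is (possibly) one of ``known``.

        The cheap invariant prefilter avoids canonicalizing graphs that
        cannot match any registered class.
        """
        inv = graph_invariant(*graph)
        bucket = self._inv_index.get(inv)
        if not bucket or not (bucket & known):
            return None
        key = canonical_string(*graph)
        return key if key in known else None

    def representative(self, key: str) -> GraphT:
        return self._rep[key]

    def fragment(self, key: str) -> Fragment:
        a, e = self._rep[key]
        return Fragment(a, e)

    def splits(self, key: str) -> list[tuple[str, str, int]]:
        """All distinct ways to produce this class by one assembly step.

        Returns ``(key_a, key_b, witness_mask)`` triples, one per unordered
        pair of child classes; the witness mask selects the bonds of the
        representative that belong to the first child.
        """
        if key in self._splits:
            return self._splits[key]
        atoms, edges = self._rep[key]
        m = len(edges)
        if m > SPLIT_ENUM_MAX:
            raise ValueError(
                f"refusing to enumerate all bipartitions of a {m}-bond "
                f"fragment (> {SPLIT_ENUM_MAX}); use sample_bipartitions")
        full = (1 << m) - 1
        seen: set[tuple[str, str]] = set()
        out: list[tuple[str, str, int]] = []
        # masks containing edge 0 enumerate each unordered bipartition once
        for mask in range(1, full, 2):
            comp = full ^ mask
            if not (_connected_mask(edges, mask) and _connected_mask(edges, comp)):
                continue
            k1 = self.register(*_subgraph(atoms, edges, mask))
            k2 = self.register(*_subgraph(atoms, edges, comp))
            pair = (k1, k2) if k1 <= k2 else (k2, k1)
            if pair not in seen:
                seen.add(pair)
                if pair == (k1, k2):
                    out.append((k1, k2, mask))
                else:
                    out.append((k2, k1, comp))
        out.sort()
        self._splits[key] = out
        return out

    def subgraph_pair(self, key: str, mask: int) -> tuple[GraphT, GraphT]:
        atoms, edges = self._rep[key]
        full = (1 << len(edges)) - 1
        return (_subgraph(atoms, edges, mask),
                _subgraph(atoms, edges, full ^ mask))

    def sample_bipartitions(self, key: str, rng, k: int,
                            tries_per_sample: int = 6) -> list[int]:
        """Up to ``k`` random connected bipartition masks of a fragment.

        A random connected edge subset is grown to a random size and kept if
        its complement is connected.  At least one valid mask is always
        returned (peeling a single non-bridge or leaf edge always works).
        """
        atoms, edges = self._rep[key]
        m = len(edges)
        full = (1 << m) - 1
        atom_edges: dict[int, list[int]] = {}
        for idx, (i, j, _) in enumerate(edges):
            atom_edges.setdefault(i, []).append(idx)
            atom_edges.setdefault(j, []).append(idx)
        masks: set[int] = set()
        for _ in range(k * tries_per_sample):
            if len(masks) >= k:
                break
            target = rng.randint(1, m - 1)
            seed = rng.randrange(m)
            chosen = {seed}
            frontier = set()
            for v in edges[seed][:2]:
                frontier.update(atom_edges[v])
            frontier -= chosen
            while len(chosen) < target and frontier:
                e = rng.choice(sorted(frontier))
                chosen.add(e)
                for v in edges[e][:2]:
                    frontier.update(atom_edges[v])
                frontier -= chosen
            if len(chosen) == m:
                continue
            mask = 0
            for e in chosen:
                mask |= 1 << e
            if _connected_mask(edges, full ^ mask):
                masks.add(mask)
        if not masks:
            order = list(range(m))
            rng.shuffle(order)
            for e in order:
                mask = 1 << e
                if _connected_mask(edges, full ^ mask):
                    masks.add(mask)
                    break
        assert masks, "connected graph must admit a bipartition"
        return sorted(masks)

    def containment(self, key: str) -> int:
        """Number of targets this class embeds into (sharing potential)."""
        if key not in self._ncontain:
            frag = self.fragment(key)
            self._ncontain[key] = sum(
                1 for t in self.targets if embeds_in(frag, t))
        return self._ncontain[key]
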