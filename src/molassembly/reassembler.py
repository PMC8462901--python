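"""Generate novel molecules by reconnecting assembly-pool fragments.

The Reassembler runs the assembly process in reverse: the pool blocks of a
parent set are annotated with the bonds through which they were connected
inside their parents (attachment records), and new molecules are grown by
joining blocks only through those recorded patterns.  A bond-by-bond random
generator over the parents' bond types provides the null baseline.

Every generated molecule passes the plausibility filters: molecular weight
window, degrees-of-unsaturation window, forbidden-SMARTS motifs, and
(optionally) a 3D-embeddability probe with a fixed conformer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .assembly_tree import AssemblySpace, assembly_space
from .config import GenerationConstraints
from .molgraph import (Fragment, MolecularGraph, subgraph_embeddings)

__all__ = ["AttachmentRecord", "GeneratedSet", "build_pool", "reassemble",
           "random_baseline", "plausibility_filter", "degrees_of_unsaturation",
           "UnsatisfiableConstraintsError", "arbitrary_fragment_pool"]

_VALENCE = {"C": 4, "N": 3, "O": 2, "P": 5, "S": 2, "F": 1, "Cl": 1,
            "Br": 1, "I": 1}


class UnsatisfiableConstraintsError(RuntimeError):
    def __init__(self, msg: str, rejected: dict):
        super().__init__(f"{msg}; rejection counts: {rejected}")
        self.rejected = rejected


@dataclass
class AttachmentRecord:
    """How a pool fragment was connected inside its parent compound(s).

    Each site is ``(atom index in fragment, bond order, partner element)``:
    in some parent, that fragment atom carried an additional bond of that
    order to an atom of that element.
    """

    fragment: Fragment
    sites: list[tuple[int, int, str]]

    @property
    def key(self) -> str:
        return self.fragment.canonical_key


@dataclass
class GeneratedSet:
    molecules: list[MolecularGraph]
    provenance: list[list[str]]          # pool-fragment keys per molecule
    rejected_counts: dict = field(default_factory=dict)

    def smiles(self) -> list[str]:
        return [m.to_smiles() for m in self.molecules]

    def unique(self) -> "GeneratedSet":
        """Canonical-SMILES de-duplicated copy."""
        seen = set()
        mols, prov = [], []
        for m, p in zip(self.molecules, self.provenance):
            s = m.to_smiles()
            if s not in seen:
                seen.add(s)
                mols.append(m)
                prov.append(p)
        return GeneratedSet(mols, prov, dict(self.rejected_counts))


def degrees_of_unsaturation(mol: Chem.Mol) -> float:
    """(2 C + 2 + N - H) / 2 on the implicit-hydrogen formula."""
    c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    n = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")
    h = sum(a.GetTotalNumHs(includeNeighbors=True) for a in mol.GetAtoms())
    return (2 * c + 2 + n - h) / 2


def plausibility_filter(m: MolecularGraph | Chem.Mol,
                        constraints: GenerationConstraints,
                        ) -> tuple[bool, str]:
    """Apply the filter cascade; the reason names the first failing filter."""
    if isinstance(m, MolecularGraph):
        try:
            mol = m.to_rdkit()
        except Exception:
            return False, "valence"
    else:
        mol = m
    mw = Descriptors.MolWt(mol)
    lo, hi = constraints.mw_range
    if not (lo <= mw <= hi):
        return False, "mw"
    dou = degrees_of_unsaturation(mol)
    lo, hi = constraints.dou_range
    if not (lo <= dou <= hi):
        return False, "dou"
    for patt, query in constraints.compiled_smarts:
        if mol.HasSubstructMatch(query):
            return False, "smarts"
    if constraints.require_embeddable_3d:
        probe = Chem.AddHs(Chem.Mol(mol))
        if AllChem.EmbedMolecule(probe, randomSeed=0xF00D) != 0:
            return False, "embed3d"
        try:
            if AllChem.MMFFOptimizeMolecule(probe, maxIters=200) not in (0, 1):
                return False, "embed3d"
        except Exception:
            return False, "embed3d"
    return True, "ok"


# ---------------------------------------------------------------------------
# pool construction


def build_pool(parents: list[MolecularGraph], iterations: int, seed: int,
               max_embeddings: int = 8, **params,
               ) -> tuple[AssemblySpace, list[AttachmentRecord]]:
    """Assembly pool of a parent set, annotated with attachment sites.

    Pool blocks come from the joint assembly space of the parents; each block
    records every distinct way it was connected inside a parent (boundary
    bonds of its subgraph embeddings, up to ``max_embeddings`` per parent).
    """
    if len(parents) < 2:
        raise ValueError("attachment context requires at least two parents "
                         "(duplicates are allowed)")
    space = assembly_space(parents, iterations, seed, **params)
    uniq_parents = {p.as_fragment().canonical_key: p for p in parents}
    records = []
    for key, frag in sorted(space.blocks.items()):
        sites: set[tuple[int, int, str]] = set()
        for parent in uniq_parents.values():
            pbonds = {}
            for bi, (i, j, o) in enumerate(parent.bonds):
                pbonds.setdefault(i, []).append((j, o, bi))
                pbonds.setdefault(j, []).append((i, o, bi))
            embeddings = subgraph_embeddings(frag, parent,
                                             max_embeddings=max_embeddings)
            for amap in embeddings:
                image_atoms = set(amap.values())
                used_bonds = set()
                inv = {v: k for k, v in amap.items()}
                for fi, fj, fo in frag.bonds:
                    u, v = amap[fi], amap[fj]
                    for w, o, bi in pbonds[u]:
                        if w == v and o == fo and bi not in used_bonds:
                            used_bonds.add(bi)
                            break
                for fa, pa in amap.items():
                    for w, o, bi in pbonds[pa]:
                        if bi in used_bonds:
                            continue
                        sites.add((fa, o, parent.atoms[w]))
        if sites:
            records.append(AttachmentRecord(fragment=frag,
                                            sites=sorted(sites)))
    return space, records


def arbitrary_fragment_pool(parents: list[MolecularGraph], n_fragments: int,
                            size_range: tuple[int, int], seed: int,
                            ) -> list[AttachmentRecord]:
    """Experimental baseline pool: random connected edge-subgraphs of the
    parents (no assembly-space structure), with their boundary sites."""
    rng = random.Random(seed)
    records: dict[str, AttachmentRecord] = {}
    lo, hi = size_range
    guard = 0
    while len(records) < n_fragments and guard < 100 * n_fragments:
        guard += 1
        parent = parents[rng.randrange(len(parents))]
        target_size = rng.randint(lo, min(hi, parent.bond_count))
        start = rng.randrange(parent.bond_count)
        chosen = {start}
        frontier = set(range(parent.bond_count)) - chosen
        adj_atoms = set(parent.bonds[start][:2])
        while len(chosen) < target_size:
            grow = [bi for bi in frontier
                    if parent.bonds[bi][0] in adj_atoms
                    or parent.bonds[bi][1] in adj_atoms]
            if not grow:
                break
            bi = grow[rng.randrange(len(grow))]
            chosen.add(bi)
            frontier.discard(bi)
            adj_atoms.update(parent.bonds[bi][:2])
        sel = [parent.bonds[bi] for bi in sorted(chosen)]
        verts = sorted({i for i, j, _ in sel} | {j for _, j, _ in sel})
        idx = {v: k for k, v in enumerate(verts)}
        frag = Fragment(tuple(parent.atoms[v] for v in verts),
                        tuple((idx[i], idx[j], o) for i, j, o in sel))
        sites = set()
        inside = set(chosen)
        for v in verts:
            for bi, (i, j, o) in enumerate(parent.bonds):
                if bi in inside:
                    continue
                if i == v:
                    sites.add((idx[v], o, parent.atoms[j]))
                elif j == v:
                    sites.add((idx[v], o, parent.atoms[i]))
        if sites and frag.canonical_key not in records:
            records[frag.canonical_key] = AttachmentRecord(frag, sorted(sites))
    return list(records.values())


# ---------------------------------------------------------------------------
# generation


def _fragment_to_rwmol(frag: Fragment) -> Chem.RWMol:
    rw = Chem.RWMol()
    for a in frag.atoms:
        rw.AddAtom(Chem.Atom(a))
    for i, j, o in frag.bonds:
        rw.AddBond(i, j, Chem.BondType.values[o])
    return rw


def _mol_to_graph(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple((b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   int(b.GetBondTypeAsDouble())) for b in mol.GetBonds())
    return MolecularGraph(atoms, bonds, name=name)


def _approx_mw(atoms: list, order_sum: dict) -> float:
    """Implicit-hydrogen molecular weight from elements and bond orders."""
    from rdkit.Chem import GetPeriodicTable
    pt = GetPeriodicTable()
    heavy = sum(pt.GetAtomicWeight(a) for a in atoms)
    h = sum(max(0, _VALENCE.get(a, 4) - order_sum.get(i, 0))
            for i, a in enumerate(atoms))
    return heavy + 1.008 * h


def reassemble(pool: AssemblySpace, records: list[AttachmentRecord],
               constraints: GenerationConstraints) -> GeneratedSet:
    """Generate molecules by joining pool fragments at recorded sites.

    A join creates a new bond between two fragment atoms whose records match
    crosswise: each side's site must name the other's bond order and element.
    Rejected candidates are replaced until ``n_molecules`` pass all filters
    or the attempt budget runs out.
    """
    if constraints.n_molecules == 0:
        return GeneratedSet([], [], {})
    usable = [r for r in records if r.sites]
    rejected: dict[str, int] = {}
    if not usable:
        raise UnsatisfiableConstraintsError(
            "no pool fragment has an open attachment site", rejected)
    # cross-compatibility index: a site (a, o, e) on an atom of element x
    # joins a site (b, o, x) on an atom of element e
    index: dict[tuple[int, str, str], list[tuple[AttachmentRecord, int]]] = {}
    for r in usable:
        for (b, o, e) in r.sites:
            index.setdefault((o, r.fragment.atoms[b], e), []).append((r, b))
    rng = random.Random(constraints.seed)
    accepted: list[MolecularGraph] = []
    provenance: list[list[str]] = []
    budget = constraints.attempt_factor * constraints.n_molecules
    mw_lo, mw_hi = constraints.mw_range
    attempts = 0
    while len(accepted) < constraints.n_molecules and attempts < budget:
        attempts += 1
        rec = usable[rng.randrange(len(usable))]
        atoms = list(rec.fragment.atoms)
        bonds = list(rec.fragment.bonds)
        order_sum: dict[int, int] = {}
        for i, j, o in bonds:
            order_sum[i] = order_sum.get(i, 0) + o
            order_sum[j] = order_sum.get(j, 0) + o
        open_sites = [(a, o, e) for a, o, e in rec.sites]
        used = [rec.key]
        failed = False
        while True:
            mw = _approx_mw(atoms, order_sum)
            if mw > mw_hi:
                failed = True
                break
            if mw >= mw_lo:
                break
            if not open_sites:
                failed = True
                break
            a, o, e = open_sites[rng.randrange(len(open_sites))]
            partners = index.get((o, e, atoms[a]), ())
            if not partners:
                open_sites.remove((a, o, e))
                continue
            r2, b = partners[rng.randrange(len(partners))]
            offset = len(atoms)
            atoms.extend(r2.fragment.atoms)
            for i, j, oo in r2.fragment.bonds:
                bonds.append((i + offset, j + offset, oo))
                order_sum[i + offset] = order_sum.get(i + offset, 0) + oo
                order_sum[j + offset] = order_sum.get(j + offset, 0) + oo
            bonds.append((a, b + offset, o))
            order_sum[a] = order_sum.get(a, 0) + o
            order_sum[b + offset] = order_sum.get(b + offset, 0) + o
            open_sites.remove((a, o, e))
            taken = False
            for bb, oo, ee in r2.sites:
                if not taken and bb == b and oo == o and ee == atoms[a]:
                    taken = True  # the site consumed by this join
                    continue
                open_sites.append((bb + offset, oo, ee))
            used.append(r2.key)
        if failed:
            rejected["growth"] = rejected.get("growth", 0) + 1
            continue
        try:
            g = MolecularGraph(tuple(atoms), tuple(bonds),
                               name=f"gen{len(accepted)}")
            candidate = g.to_rdkit()
        except Exception:
            rejected["valence"] = rejected.get("valence", 0) + 1
            continue
        ok, reason = plausibility_filter(candidate, constraints)
        if not ok:
            rejected[reason] = rejected.get(reason, 0) + 1
            continue
        accepted.append(g)
        provenance.append(used)
    if len(accepted) < constraints.n_molecules:
        raise UnsatisfiableConstraintsError(
            f"only {len(accepted)}/{constraints.n_molecules} molecules "
            f"accepted after {attempts} attempts", rejected)
    return GeneratedSet(accepted, provenance, rejected)


def random_baseline(bond_types: list[tuple[str, str, int]],
                    constraints: GenerationConstraints,
                    ring_closure_prob: float = 0.25) -> GeneratedSet:
    """Null model: grow molecules bond by bond from bare bond types.

    ``bond_types`` entries are (element, element, order).  New atoms are
    attached at random valence-compatible positions; occasional ring
    closures provide the unsaturation that the degrees-of-unsaturation
    window demands.  The same filters apply as for the Reassembler.
    """
    if not bond_types:
        raise ValueError("bond_types must be nonempty")
    if constraints.n_molecules == 0:
        return GeneratedSet([], [], {})
    rng = random.Random(constraints.seed)
    from rdkit.Chem import GetPeriodicTable
    pt = GetPeriodicTable()
    w = {e: pt.GetAtomicWeight(e)
         for bt in bond_types for e in bt[:2]}

    rejected: dict[str, int] = {}
    accepted: list[MolecularGraph] = []
    budget = constraints.attempt_factor * constraints.n_molecules
    attempts = 0
    mw_lo, mw_hi = constraints.mw_range
    while len(accepted) < constraints.n_molecules and attempts < budget:
        attempts += 1
        e1, e2, o = bond_types[rng.randrange(len(bond_types))]
        atoms = [e1, e2]
        free = [_VALENCE[e1] - o, _VALENCE[e2] - o]
        bonds = [(0, 1, o)]
        bonded = {(0, 1)}
        failed = False
        stall = 0
        while True:
            mw = (sum(w[a] for a in atoms) + 1.008 * sum(free))
            if mw > mw_hi or stall > 50:
                failed = True
                break
            if mw >= mw_lo:
                break
            ea, eb, o = bond_types[rng.randrange(len(bond_types))]
            stall += 1
            if rng.random() < ring_closure_prob:
                cand = [(i, j) for i in range(len(atoms))
                        for j in range(i + 1, len(atoms))
                        if (i, j) not in bonded
                        and {atoms[i], atoms[j]} == {ea, eb}
                        and free[i] >= o and free[j] >= o]
                if cand:
                    i, j = cand[rng.randrange(len(cand))]
                    bonds.append((i, j, o))
                    bonded.add((i, j))
                    free[i] -= o
                    free[j] -= o
                    stall = 0
                    continue
            hosts = [i for i in range(len(atoms))
                     if atoms[i] in (ea, eb) and free[i] >= o]
            if not hosts:
                continue
            i = hosts[rng.randrange(len(hosts))]
            new_elem = eb if atoms[i] == ea else ea
            atoms.append(new_elem)
            free.append(_VALENCE[new_elem] - o)
            j = len(atoms) - 1
            bonds.append((i, j, o))
            bonded.add((i, j))
            free[i] -= o
            stall = 0
        if failed:
            rejected["growth"] = rejected.get("growth", 0) + 1
            continue
        try:
            g = MolecularGraph(tuple(atoms), tuple(bonds),
                               name=f"rand{len(accepted)}")
            mol = g.to_rdkit()
        except Exception:
            rejected["valence"] = rejected.get("valence", 0) + 1
            continue
        ok, reason = plausibility_filter(mol, constraints)
        if not ok:
            rejected[reason] = rejected.get(reason, 0) + 1
            continue
        accepted.append(g)
    if len(accepted) < constraints.n_molecules:
        raise UnsatisfiableConstraintsError(
            f"only {len(accepted)}/{constraints.n_molecules} molecules "
            f"accepted after {attempts} attempts", rejected)
    return GeneratedSet(accepted, [[] for _ in accepted], rejected)
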