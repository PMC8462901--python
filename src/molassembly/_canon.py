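"""Canonical labeling of small vertex- and edge-labelled graphs.

Fragments in an assembly pool are connected labelled graphs that need not be
valence-valid molecules, so plain canonical SMILES cannot serve as their
identity key.  The canonical form here reorders atoms by RDKit's canonical
ranking computed on a hydrogen-free, implicit-H-suppressed molecule object
(ring perception only, no valence sanitization) and serializes the relabelled
graph.  Two graphs are isomorphic under (element, bond order) labels iff
their canonical strings are equal; symmetric graphs (stars, rings) are
handled in polynomial time.

Graphs are plain tuples: ``atoms`` is a tuple of element symbols indexed by
atom id, ``bonds`` a tuple of ``(i, j, order)`` with integer order.
"""

from __future__ import annotations

from rdkit import Chem

Graph = tuple[tuple[str, ...], tuple[tuple[int, int, int], ...]]

_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}


def _fragment_mol(atoms: tuple[str, ...],
                  bonds: tuple[tuple[int, int, int], ...]) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in atoms:
        at = Chem.Atom(a)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for i, j, o in bonds:
        rw.AddBond(int(i), int(j), _BOND_TYPE[o])
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def canonical_form(atoms: tuple[str, ...],
                   bonds: tuple[tuple[int, int, int], ...]) -> Graph:
    """Return the canonical isomorph of a labelled graph."""
    mol = _fragment_mol(atoms, bonds)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True,
                                         includeChirality=False))
    pos = {v: r for v, r in enumerate(ranks)}
    out_atoms = [""] * len(atoms)
    for v, a in enumerate(atoms):
        out_atoms[pos[v]] = a
    es = tuple(sorted(
        (min(pos[i], pos[j]), max(pos[i], pos[j]), o) for i, j, o in bonds))
    return tuple(out_atoms), es


def canonical_string(atoms: tuple[str, ...],
                     bonds: tuple[tuple[int, int, int], ...]) -> str:
    """Serialize the canonical form as a string key.

    Equal strings <=> label-isomorphic graphs.
    """
    a, es = canonical_form(atoms, bonds)
    return "|".join(a) + "||" + ";".join(f"{i},{j},{o}" for i, j, o in es)
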