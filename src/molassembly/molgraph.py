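"""Hydrogen-suppressed labelled molecular graphs and assembly fragments.

Molecules are modelled as connected graphs over heavy atoms: nodes carry an
element symbol, edges carry an integer bond order (1, 2 or 3).  Aromatic
systems are kekulized deterministically, stereochemistry, charges and
isotopes are discarded — assembly theory is a statement about labelled
graphs, not about 3D chemistry.

A :class:`Fragment` is any connected subgraph of such a molecule.  Fragments
need not satisfy valence rules: they are building blocks in an assembly
pool, not molecules.  Their identity is the canonical key of the labelled
graph, so two fragments compare equal exactly when they are isomorphic under
element and bond-order labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from rdkit import Chem
from rdkit import RDLogger

from ._canon import canonical_string

RDLogger.DisableLog("rdApp.*")

BOND_ORDER_SYMBOL = {1: "-", 2: "=", 3: "#"}

InputFormat = Literal["smiles", "inchi", "molblock"]


class MoleculeFormatError(ValueError):
    """Raised when molecular input cannot be parsed or violates invariants."""


@dataclass(frozen=True)
class BondType:
    """An unordered pair of element symbols with an integer bond order.

    Bond types are the basic building blocks of molecular assembly: they are
    present in every assembly pool with unlimited multiplicity.
    """

    elements: frozenset | tuple
    order: int

    def __post_init__(self):
        pair = tuple(sorted(self.elements if not isinstance(self.elements, str)
                            else (self.elements,)))
        if len(pair) == 1:
            pair = (pair[0], pair[0])
        object.__setattr__(self, "elements", pair)
        if self.order not in (1, 2, 3):
            raise ValueError(f"bond order must be 1, 2 or 3, got {self.order}")

    def __str__(self) -> str:
        a, b = self.elements
        return f"{a}{BOND_ORDER_SYMBOL[self.order]}{b}"


@dataclass(frozen=True)
class MolecularGraph:
    """A connected, hydrogen-suppressed, kekulized molecular graph.

    ``atoms[i]`` is the element symbol of atom ``i``; ``bonds`` holds
    ``(i, j, order)`` triples with ``i < j``.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        norm = tuple(sorted((min(i, j), max(i, j), int(o)) for i, j, o in self.bonds))
        object.__setattr__(self, "bonds", norm)
        n = len(self.atoms)
        seen = set()
        for i, j, o in norm:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise MoleculeFormatError(f"bad bond ({i},{j})")
            if o not in (1, 2, 3):
                raise MoleculeFormatError(f"bond order {o} is not kekulized")
            if (i, j) in seen:
                raise MoleculeFormatError(f"duplicate bond ({i},{j})")
            seen.add((i, j))
        if any(a in ("H", "D", "T") for a in self.atoms):
            raise MoleculeFormatError("hydrogens must be suppressed")
        if n and not _connected(n, norm):
            raise MoleculeFormatError(
                "disconnected input (e.g. a salt); strip components first")

    @property
    def bond_count(self) -> int:
        return len(self.bonds)

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    def bond_types(self) -> set[BondType]:
        """The set of basic building blocks occurring in this molecule."""
        return {BondType((self.atoms[i], self.atoms[j]), o)
                for i, j, o in self.bonds}

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit molecule (implicit hydrogens, sanitized).

        Charges are not part of the graph model; atoms whose bond-order sum
        exceeds the neutral valence (e.g. quaternary/pyridinium nitrogen)
        get the matching formal charge back so the molecule sanitizes.
        """
        rw = Chem.RWMol()
        for a in self.atoms:
            rw.AddAtom(Chem.Atom(a))
        for i, j, o in self.bonds:
            rw.AddBond(i, j, Chem.BondType.values[o])
        order_sum = [0] * len(self.atoms)
        for i, j, o in self.bonds:
            order_sum[i] += o
            order_sum[j] += o
        neutral = {"N": 3, "O": 2}
        for atom in rw.GetAtoms():
            cap = neutral.get(atom.GetSymbol())
            if cap is not None:
                excess = order_sum[atom.GetIdx()] - cap
                if excess > 0:
                    atom.SetFormalCharge(excess)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())

    def as_fragment(self) -> "Fragment":
        return Fragment(self.atoms, self.bonds)


@dataclass(frozen=True)
class Fragment:
    """A connected labelled subgraph; the unit stored in assembly pools."""

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        norm = tuple(sorted((min(i, j), max(i, j), int(o)) for i, j, o in self.bonds))
        object.__setattr__(self, "bonds", norm)
        if not norm:
            raise ValueError("empty fragment")
        if not _connected(len(self.atoms), norm):
            raise ValueError("fragment must be connected")

    @property
    def bond_count(self) -> int:
        return len(self.bonds)

    @property
    def canonical_key(self) -> str:
        return canonical_key(self)

    def is_basic(self) -> bool:
        return self.bond_count == 1

    def as_bond_type(self) -> BondType:
        if not self.is_basic():
            raise ValueError("only single-bond fragments are basic blocks")
        i, j, o = self.bonds[0]
        return BondType((self.atoms[i], self.atoms[j]), o)

    def to_smiles(self) -> str:
        """SMILES of the bare fragment (atoms written without implicit H)."""
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a)
            at.SetNoImplicit(True)
            rw.AddAtom(at)
        for i, j, o in self.bonds:
            rw.AddBond(i, j, Chem.BondType.values[o])
        mol = rw.GetMol()
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        return Chem.MolToSmiles(mol)


def _connected(n: int, bonds: Iterable[tuple[int, int, int]]) -> bool:
    bonds = list(bonds)
    touched = {i for b in bonds for i in b[:2]} | set(range(n))
    if len(touched) <= 1:
        return True
    adj: dict[int, list[int]] = {v: [] for v in touched}
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    stack = [next(iter(touched))]
    seen = set(stack)
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen == touched


def canonical_key(fragment: Fragment | MolecularGraph) -> str:
    """Canonical identity string: equal iff label-isomorphic."""
    if not fragment.bonds:
        raise ValueError("empty fragment has no canonical key")
    return canonical_string(fragment.atoms, fragment.bonds)


def _from_rdkit(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MoleculeFormatError(
            f"disconnected input with {len(frags)} components (e.g. a salt); "
            "strip components and parse each separately")
    # canonical kekulization: renumber atoms by canonical rank and rebuild
    # with sorted bond insertion, so the alternating-bond assignment depends
    # only on the isomorphism class of the aromatic graph, not on the input
    # atom or bond order
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = [0] * len(ranks)
    for old, r in enumerate(ranks):
        order[r] = old
    mol = Chem.RenumberAtoms(mol, order)
    rw = Chem.RWMol()
    for a in mol.GetAtoms():
        na = Chem.Atom(a.GetSymbol())
        na.SetFormalCharge(a.GetFormalCharge())
        na.SetNumExplicitHs(a.GetTotalNumHs())
        na.SetNoImplicit(True)  # pin H counts: tautomer must not drift
        na.SetIsAromatic(a.GetIsAromatic())
        rw.AddAtom(na)
    pairs = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                   for b in mol.GetBonds())
    for i, j in pairs:
        rw.AddBond(i, j, mol.GetBondBetweenAtoms(i, j).GetBondType())
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        o = b.GetBondTypeAsDouble()
        if o != int(o):
            raise MoleculeFormatError(f"non-integer bond order {o} after kekulization")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(o)))
    return MolecularGraph(atoms, tuple(bonds), name=name)


def parse_molecule(text: str, fmt: InputFormat = "smiles",
                   name: str = "") -> MolecularGraph:
    """Parse a molecule into a kekulized, hydrogen-suppressed labelled graph.

    Stereochemistry, charges and isotopes are discarded.  Disconnected
    structures (salts, mixtures) are rejected.
    """
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt == "inchi":
        mol = Chem.MolFromInchi(text)
    elif fmt == "molblock":
        mol = Chem.MolFromMolBlock(text)
    else:
        raise MoleculeFormatError(f"unknown format {fmt!r}")
    if mol is None:
        raise MoleculeFormatError(f"could not parse {fmt} input: {text[:80]!r}")
    return _from_rdkit(mol, name=name)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read a SMILES file: one molecule per line, optional tab-separated name."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            out.append(parse_molecule(smi, "smiles", name=name))
    return out


def read_sdf_file(path) -> list[MolecularGraph]:
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise MoleculeFormatError(f"could not parse SDF record {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
        out.append(_from_rdkit(mol, name=name))
    return out


def subgraph_embeddings(fragment: Fragment,
                        target: MolecularGraph | Fragment,
                        max_embeddings: int | None = None,
                        ) -> list[dict[int, int]]:
    """All label-preserving embeddings of ``fragment`` into ``target``.

    An embedding maps fragment atoms injectively onto target atoms and
    fragment bonds onto distinct target bonds with matching order.  Two
    embeddings covering the same set of target bonds (differing only by a
    fragment automorphism) are reported once.
    """
    fa, fe = fragment.atoms, fragment.bonds
    ta, te = target.atoms, target.bonds
    if len(fe) > len(te):
        return []

    # order fragment bonds so each new bond touches an already-mapped atom
    ordered = [fe[0]]
    placed = {fe[0][0], fe[0][1]}
    rest = list(fe[1:])
    while rest:
        for k, e in enumerate(rest):
            if e[0] in placed or e[1] in placed:
                ordered.append(rest.pop(k))
                placed.update(e[:2])
                break

    tadj: dict[int, list[tuple[int, int, int]]] = {}
    for k, (i, j, o) in enumerate(te):
        tadj.setdefault(i, []).append((j, o, k))
        tadj.setdefault(j, []).append((i, o, k))

    results: list[dict[int, int]] = []
    seen_images: set[frozenset[int]] = set()

    def dfs(idx: int, amap: dict[int, int], used: frozenset[int]) -> bool:
        if idx == len(ordered):
            if used not in seen_images:
                seen_images.add(used)
                results.append(dict(amap))
            return max_embeddings is not None and len(results) >= max_embeddings
        i, j, o = ordered[idx]
        if i in amap and j in amap:
            for v, oo, ek in tadj.get(amap[i], ()):
                if v == amap[j] and oo == o and ek not in used:
                    if dfs(idx + 1, amap, used | {ek}):
                        return True
            return False
        if j in amap:
            i, j = j, i
        mapped = set(amap.values())
        for v, oo, ek in tadj.get(amap[i], ()):
            if (oo == o and ek not in used and v not in mapped
                    and ta[v] == fa[j]):
                amap[j] = v
                if dfs(idx + 1, amap, used | {ek}):
                    return True
                del amap[j]
        return False

    i0, j0, o0 = ordered[0]
    stop = False
    for k, (i, j, o) in enumerate(te):
        if stop:
            break
        if o != o0:
            continue
        for (u, v) in ((i, j), (j, i)):
            if ta[u] == fa[i0] and ta[v] == fa[j0]:
                if dfs(1, {i0: u, j0: v}, frozenset([k])):
                    stop = True
                    break
    return results


def embeds_in(fragment: Fragment, target: MolecularGraph | Fragment) -> bool:
    """True when at least one embedding exists."""
    return bool(subgraph_embeddings(fragment, target, max_embeddings=1))
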