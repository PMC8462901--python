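"""Built-in molecule and sequence fixtures.

Standard published structures (as SMILES) of the compound sets used in the
assembly-tree case studies, pinned here so everything runs offline:
nucleobases, a dozen vital biomolecules, common plasticizers, the opiate
family, and the six natural opiates used for assembly-pool generation.
Stereochemistry in the SMILES is informative only — assembly computations
work on the stereo-stripped labelled graph.

Also provides deterministic toy graphs (paths, rings, stars, duplicated-motif
composites) whose assembly indices are small enough for the exact search, for
use as oracle fixtures.
"""

from __future__ import annotations

from .molgraph import MolecularGraph, parse_molecule

__all__ = ["NUCLEOBASES", "BIOMOLECULES", "PLASTICIZERS", "OPIATE_FAMILY",
           "NATURAL_OPIATES", "ALTERNATED_NUCLEOBASE_SETS", "FIG_Y",
           "catalog", "load_set", "make_toy_graphs"]

NUCLEOBASES = {
    "adenine": "Nc1ncnc2[nH]cnc12",
    "guanine": "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "thymine": "Cc1c[nH]c(=O)[nH]c1=O",
    "uracil": "O=c1cc[nH]c(=O)[nH]1",
    "cytosine": "Nc1cc[nH]c(=O)n1",
}

# the dozen vital biomolecules of the prebiotic-chemistry tree; the
# "symbolic RNA" entry is pinned as a single RNA nucleotide unit (AMP) and
# is approximate by construction
BIOMOLECULES = {
    **NUCLEOBASES,
    "pyruvate": "CC(=O)C(=O)O",
    "citrate": "OC(=O)CC(O)(C(=O)O)CC(=O)O",
    "d-ribose": "OC[C@H]1O[C@H](O)[C@H](O)[C@@H]1O",
    "NAD+": ("NC(=O)c1ccc[n+](c1)[C@@H]1O[C@H](COP(=O)([O-])OP(=O)(O)OC"
             "[C@H]2O[C@H](n3cnc4c(N)ncnc43)[C@H](O)[C@@H]2O)"
             "[C@@H](O)[C@H]1O"),
    "ADP": ("Nc1ncnc2n(cnc12)[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)O)"
            "[C@@H](O)[C@H]1O"),
    "ATP": ("Nc1ncnc2n(cnc12)[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)OP(=O)(O)O)"
            "[C@@H](O)[C@H]1O"),
    "symbolic-RNA": "Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)O)C(O)C1O",
}

# ten commonly used plasticizers (the named ones plus standard co-occurring
# phthalate/adipate/trimellitate esters)
PLASTICIZERS = {
    "BBP": "CCCCOC(=O)c1ccccc1C(=O)OCc1ccccc1",
    "DEHP": "CCCCC(CC)COC(=O)c1ccccc1C(=O)OCC(CC)CCCC",
    "DEHA": "CCCCC(CC)COC(=O)CCCCC(=O)OCC(CC)CCCC",
    "tricresyl-phosphate": "Cc1ccccc1OP(=O)(Oc1ccccc1C)Oc1ccccc1C",
    "DMP": "COC(=O)c1ccccc1C(=O)OC",
    "DEP": "CCOC(=O)c1ccccc1C(=O)OCC",
    "DBP": "CCCCOC(=O)c1ccccc1C(=O)OCCCC",
    "DIBP": "CC(C)COC(=O)c1ccccc1C(=O)OCC(C)C",
    "DOTP": "CCCCC(CC)COC(=O)c1ccc(cc1)C(=O)OCC(CC)CCCC",
    "TOTM": ("CCCCC(CC)COC(=O)c1ccc(C(=O)OCC(CC)CCCC)c(c1)"
             "C(=O)OCC(CC)CCCC"),
}

# the ten opiate-family compounds (nine opiates plus salvinorin A)
OPIATE_FAMILY = {
    "morphine": "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5",
    "codeine": "COc1ccc2C[C@H]3N(C)CC[C@]45[C@@H](Oc1c24)[C@@H](O)C=C[C@H]35",
    "thebaine": "COc1ccc2C[C@H]3N(C)CC[C@]45C(Oc1c24)C(OC)=CC=C35",
    "papaverine": "COc1ccc(Cc2nccc3cc(OC)c(OC)cc23)cc1OC",
    "fentanyl": "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "remifentanil": "CCC(=O)N(c1ccccc1)C1(C(=O)OC)CCN(CCC(=O)OC)CC1",
    "methadone": "CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1",
    "pethidine": "CCOC(=O)C1(c2ccccc2)CCN(C)CC1",
    "diamorphine": ("CN1CC[C@]23c4c5ccc(OC(C)=O)c4O[C@H]2[C@@H](OC(C)=O)"
                    "C=C[C@H]3[C@H]1C5"),
    "salvinorin-A": ("CC(=O)OC1C(=O)C2C3(C)CC(c4ccoc4)OC(=O)C3CCC2(C)"
                     "C(C(=O)OC)C1"),
}

# the six natural opiates used to build the generative assembly pool
NATURAL_OPIATES = {
    "codeine": OPIATE_FAMILY["codeine"],
    "morphine": OPIATE_FAMILY["morphine"],
    "noscapine": "CN1CCc2cc3OCOc3c(OC)c2C1C1OC(=O)c2c(OC)c(OC)ccc21",
    "oripavine": "Oc1ccc2C[C@H]3N(C)CC[C@]45C(Oc1c24)C(OC)=CC=C35",
    "papaverine": OPIATE_FAMILY["papaverine"],
    "thebaine": OPIATE_FAMILY["thebaine"],
}

# synthetic "alternated" nucleobase sets: structural analogs with relocated
# substituents, built to be less related than the natural set (the natural
# bases' relatedness is the point of comparison)
ALTERNATED_NUCLEOBASE_SETS = {
    "alternated-1": {
        "2-aminopurine": "Nc1ncc2[nH]cnc2n1",
        "5-methylcytosine": "Cc1c[nH]c(=O)nc1N",
        "barbituric-acid": "O=C1CC(=O)NC(=O)N1",
        "pyrazine-2-carboxamide": "NC(=O)c1cnccn1",
        "4-aminopyridine": "Nc1ccncc1",
    },
    "alternated-2": {
        "isoguanine": "Nc1nc(=O)c2[nH]cnc2[nH]1",
        "6-methyluracil": "Cc1cc(=O)[nH]c(=O)[nH]1",
        "melamine": "Nc1nc(N)nc(N)n1",
        "cyanuric-acid": "O=c1[nH]c(=O)[nH]c(=O)[nH]1",
        "imidazole-4-carboxamide": "NC(=O)c1c[nH]cn1",
    },
}

# the worked compressed gene-sequence string (segments separated by "_",
# digits are back-references to earlier segments)
FIG_Y = "CG_TTG_A1_GAC1G_3CTC4_1T5CAG42342543"

_CATALOGS = {
    "nucleobases": NUCLEOBASES,
    "biomolecules": BIOMOLECULES,
    "plasticizers": PLASTICIZERS,
    "opiate_family": OPIATE_FAMILY,
    "natural_opiates": NATURAL_OPIATES,
}


def catalog() -> dict[str, list[str]]:
    """Names of all fixture catalogs and their members."""
    out = {name: sorted(table) for name, table in _CATALOGS.items()}
    out["alternated_nucleobase_sets"] = sorted(ALTERNATED_NUCLEOBASE_SETS)
    out["sequences"] = ["fig_Y"]
    return out


def load_set(name: str) -> list[MolecularGraph]:
    """Parse a fixture catalog into molecular graphs."""
    if name in _CATALOGS:
        table = _CATALOGS[name]
    elif name in ALTERNATED_NUCLEOBASE_SETS:
        table = ALTERNATED_NUCLEOBASE_SETS[name]
    else:
        raise KeyError(f"unknown fixture set {name!r}")
    return [parse_molecule(smi, "smiles", name=nm)
            for nm, smi in sorted(table.items())]


def make_toy_graphs(family: str, sizes: list[int]) -> list[MolecularGraph]:
    """Deterministic labelled toy graphs with oracle-computable MA.

    Families: ``path`` (chain of B single C-C bonds), ``ring`` (cycle of B
    single C-C bonds), ``star`` (B bonds from one center), ``motif`` (two
    copies of a (B//2)-bond path joined at one shared atom, guaranteeing a
    duplicated block), ``hetero`` (alternating C/N path with alternating
    single/double bonds).
    """
    out = []
    for b in sizes:
        if b < 1:
            raise ValueError("size must be >= 1 bond")
        if family == "path":
            atoms = tuple("C" for _ in range(b + 1))
            bonds = tuple((i, i + 1, 1) for i in range(b))
        elif family == "ring":
            if b < 3:
                raise ValueError("rings need >= 3 bonds")
            atoms = tuple("C" for _ in range(b))
            bonds = tuple((i, (i + 1) % b, 1) for i in range(b))
        elif family == "star":
            atoms = tuple("C" for _ in range(b + 1))
            bonds = tuple((0, i + 1, 1) for i in range(b))
        elif family == "motif":
            half = max(1, b // 2)
            atoms = tuple("C" for _ in range(2 * half + 1))
            bonds = tuple((i, i + 1, 1) for i in range(2 * half))
        elif family == "hetero":
            atoms = tuple("C" if i % 2 == 0 else "N" for i in range(b + 1))
            bonds = tuple((i, i + 1, 1 + (i % 2)) for i in range(b))
        else:
            raise ValueError(f"unknown toy family {family!r}")
        out.append(MolecularGraph(atoms, bonds, name=f"{family}-{b}"))
    return out
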