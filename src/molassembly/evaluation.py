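"""Score generated molecule sets against their parents.

Three standard cheminformatics metrics: nearest-parent Tanimoto similarity
on Morgan (circular, radius 2, 2048-bit) fingerprints, the quantitative
estimate of drug-likeness (QED), and Crippen atom-contribution logP.
``compare_sets`` assembles the per-molecule records into a report with
set-level summaries and one-sided rank tests for the generated-vs-baseline
direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, DataStructs, QED
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .molgraph import MolecularGraph

__all__ = ["tanimoto_to_parents", "qed_score", "logp_score", "compare_sets",
           "EvaluationReport"]

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _mol(m: MolecularGraph | Chem.Mol) -> Chem.Mol:
    if isinstance(m, MolecularGraph):
        return m.to_rdkit()
    return m


def _fp(mol: Chem.Mol):
    return _FPGEN.GetFingerprint(mol)


def tanimoto_to_parents(m: MolecularGraph | Chem.Mol,
                        parents: list[MolecularGraph],
                        aggregate: str = "max") -> float:
    """Tanimoto similarity of a molecule to a parent set.

    By default the nearest parent (max) is reported; ``aggregate="mean"``
    averages over all parents instead.
    """
    if not parents:
        raise ValueError("parents must be nonempty")
    fp = _fp(_mol(m))
    sims = [DataStructs.TanimotoSimilarity(fp, _fp(_mol(p))) for p in parents]
    return max(sims) if aggregate == "max" else sum(sims) / len(sims)


def qed_score(m: MolecularGraph | Chem.Mol) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    return float(QED.qed(_mol(m)))


def logp_score(m: MolecularGraph | Chem.Mol) -> float:
    """Crippen atom-contribution logP estimate."""
    return float(Crippen.MolLogP(_mol(m)))


@dataclass
class EvaluationReport:
    records: pd.DataFrame       # columns: set, name, tanimoto, qed, logp
    summary: pd.DataFrame       # per set x metric: mean/median/quartiles
    direction_tests: dict       # metric -> {u, p_value, direction}

    def to_json(self) -> str:
        return json.dumps({
            "summary": json.loads(self.summary.to_json(orient="index")),
            "direction_tests": self.direction_tests,
        }, indent=2)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def compare_sets(generated: list[MolecularGraph],
                 baseline: list[MolecularGraph],
                 parents: list[MolecularGraph],
                 aggregate: str = "max") -> EvaluationReport:
    """Per-molecule metrics plus generated-vs-baseline direction tests.

    The rank test (one-sided Mann-Whitney U) asks whether the generated set
    scores higher than the baseline on each metric; ``direction`` reports
    "generated" when the generated mean exceeds the baseline mean.
    """
    for name, group in (("generated", generated), ("baseline", baseline),
                        ("parents", parents)):
        if not group:
            raise ValueError(f"{name} set is empty")
    rows = []
    for label, group in (("generated", generated), ("baseline", baseline),
                         ("parents", parents)):
        for i, m in enumerate(group):
            mol = _mol(m)
            rows.append({
                "set": label,
                "name": getattr(m, "name", "") or f"{label}{i}",
                "tanimoto": tanimoto_to_parents(mol, parents, aggregate),
                "qed": qed_score(mol),
                "logp": logp_score(mol),
            })
    records = pd.DataFrame(rows)
    summary = (records.groupby("set")[["tanimoto", "qed", "logp"]]
               .describe(percentiles=[0.25, 0.5, 0.75]))
    direction = {}
    gen = records[records["set"] == "generated"]
    base = records[records["set"] == "baseline"]
    for metric in ("tanimoto", "qed", "logp"):
        u, p = stats.mannwhitneyu(gen[metric], base[metric],
                                  alternative="greater")
        direction[metric] = {
            "u": float(u),
            "p_value": float(p),
            "direction": ("generated" if gen[metric].mean() > base[metric].mean()
                          else "baseline"),
        }
    return EvaluationReport(records=records, summary=summary,
                            direction_tests=direction)
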