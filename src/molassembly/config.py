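"""Run configuration: iteration budgets, generation constraints, SMARTS alerts.

A plain YAML file can override any default, e.g.::

    iterations: 50000
    seed: 7
    constraints:
      mw_range: [281, 368]
      dou_range: [9, 12]
      n_molecules: 1000
      require_embeddable_3d: true
    forbidden_smarts:
      - "[#8]-[#8]"
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml
from rdkit import Chem

# Small standard structural-alert list (reactive / implausible motifs).
# User-replaceable: the published alert list for the generation filters is
# not reproduced anywhere in machine-readable form, so this is a documented
# default, not a pinned reference.
DEFAULT_FORBIDDEN_SMARTS = [
    "[#8]-[#8]",          # peroxide
    "[#16]-[#16]",        # disulfide (no sulfur in the default pools anyway)
    "[#7]-[#7]-[#7]",     # triazane / azide chain
    "C=C=C",              # allene
    "[#6]=[#6]=[#8]",     # ketene
    "[#7]=[#7]",          # azo
    "[C;!R]=[C;!R]-[OH]", # acyclic enol
    "[#8]=[#6]-[#8]-[#8]",# acyl peroxide-ish
]


class ConfigError(ValueError):
    pass


@dataclass
class GenerationConstraints:
    """Filter window for generated molecules."""

    mw_range: tuple[float, float] = (281.0, 368.0)
    dou_range: tuple[float, float] = (9.0, 12.0)
    forbidden_smarts: list[str] = field(
        default_factory=lambda: list(DEFAULT_FORBIDDEN_SMARTS))
    require_embeddable_3d: bool = True
    n_molecules: int = 1000
    seed: int = 0
    attempt_factor: int = 1000  # attempts budget = attempt_factor * n

    def __post_init__(self):
        for lo, hi in (self.mw_range, self.dou_range):
            if lo > hi:
                raise ConfigError(f"range [{lo}, {hi}] has min > max")
        self.compiled_smarts = []
        for patt in self.forbidden_smarts:
            q = Chem.MolFromSmarts(patt)
            if q is None:
                raise ConfigError(f"malformed SMARTS pattern: {patt!r}")
            self.compiled_smarts.append((patt, q))


@dataclass
class RunConfig:
    iterations: int = 20000
    seed: int = 0
    dup_bias: float = 8.0
    share_weight: float = 1.0
    constraints: GenerationConstraints = field(
        default_factory=GenerationConstraints)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ckw = raw.pop("constraints", {})
        smarts = raw.pop("forbidden_smarts", None)
        if smarts is not None:
            ckw["forbidden_smarts"] = smarts
        known = {k: v for k, v in raw.items()
                 if k in ("iterations", "seed", "dup_bias", "share_weight")}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "mw_range" in ckw:
            ckw["mw_range"] = tuple(ckw["mw_range"])
        if "dou_range" in ckw:
            ckw["dou_range"] = tuple(ckw["dou_range"])
        return cls(constraints=GenerationConstraints(**ckw), **known)
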