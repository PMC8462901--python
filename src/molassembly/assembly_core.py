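"""Assembly pools, steps, pathways, and shortest-pathway search.

An assembly step takes two building blocks from the pool, superimposes some
of their atoms (never bonds), and adds the connected product back to the
pool, where every produced type has unlimited instances.  The assembly index
of a pathway is its number of steps; the molecular assembly number (MA) of a
molecule is the index of its shortest pathway.

Because every type is built at most once and reused freely, a pathway is
equivalent to a set of fragment isomorphism classes, each with one producing
step whose operands are basic bonds or smaller classes.  The searches here
therefore run top-down: a target class is split into two connected halves
(the reverse of an assembly step), halves that match an already-scheduled
class are free, and the pathway length is the number of distinct classes
built.

Two searches are provided:

* :func:`exact_ma` — iterative-deepening depth-first search with memoization
  and a doubling lower bound; exact, for molecules up to ``max_bonds`` bonds.
* :func:`mc_ma` — seeded Monte-Carlo sampling of split recipes with a bias
  toward duplicate-creating and target-shared halves, plus iterated local
  perturbation of the best recipe found; asymptotically finds the shortest
  pathway and in practice converges quickly.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field

from ._space import FragmentSpace, _subgraph
from .molgraph import Fragment, MolecularGraph, canonical_key

__all__ = [
    "AssemblyPool", "AssemblyStep", "AssemblyPathway", "KeyStepView",
    "MultisetView", "apply_step", "pathway_index", "exact_ma", "mc_ma",
    "ma_bounds", "key_step_view", "multiset_view",
]


class InvalidStepError(ValueError):
    """Raised when an assembly step violates the join rules."""


# ---------------------------------------------------------------------------
# pool / step / pathway data model


@dataclass
class AssemblyPool:
    """Multiset of available building blocks, keyed by canonical key.

    Basic blocks (single typed bonds) are implicitly present with infinite
    multiplicity; every produced composite type is likewise reusable without
    limit, so the pool only records *which* types exist.
    """

    entries: dict[str, Fragment] = field(default_factory=dict)

    def contains(self, f: Fragment) -> bool:
        return f.is_basic() or f.canonical_key in self.entries

    def add(self, f: Fragment) -> None:
        self.entries[f.canonical_key] = f


@dataclass(frozen=True)
class AssemblyStep:
    """One join: superimpose atoms of ``right`` onto atoms of ``left``.

    ``atom_identification`` maps right-fragment atom ids to left-fragment
    atom ids; identified atoms must carry equal element labels.  Bonds are
    never superimposed, so the product bond multiset is the disjoint union
    of the operands' bonds.
    """

    left: Fragment
    right: Fragment
    atom_identification: dict
    product: Fragment

    def __post_init__(self):
        _validate_step(self)


def _validate_step(step: AssemblyStep) -> None:
    ident = step.atom_identification
    for r, l in ident.items():
        if step.right.atoms[r] != step.left.atoms[l]:
            raise InvalidStepError(
                f"identified atoms differ: {step.right.atoms[r]} vs "
                f"{step.left.atoms[l]}")
    if len(set(ident.values())) != len(ident):
        raise InvalidStepError("atom identification must be injective")
    product = _join(step.left, step.right, ident)
    if canonical_key(product) != step.product.canonical_key:
        raise InvalidStepError("declared product does not match the join")


def _join(left: Fragment, right: Fragment, ident: dict) -> Fragment:
    nl = len(left.atoms)
    relabel = {}
    nxt = nl
    for r in range(len(right.atoms)):
        if r in ident:
            relabel[r] = ident[r]
        else:
            relabel[r] = nxt
            nxt += 1
    atoms = list(left.atoms) + [right.atoms[r] for r in range(len(right.atoms))
                                if r not in ident]
    bonds = list(left.bonds)
    seen = {(i, j) for i, j, _ in bonds}
    for i, j, o in right.bonds:
        a, b = relabel[i], relabel[j]
        a, b = min(a, b), max(a, b)
        if (a, b) in seen:
            raise InvalidStepError(
                "bonds may not coincide: only atoms can be superimposed")
        seen.add((a, b))
        bonds.append((a, b, o))
    try:
        return Fragment(tuple(atoms), tuple(bonds))
    except ValueError as exc:
        raise InvalidStepError(f"invalid product: {exc}") from exc


def apply_step(pool: AssemblyPool, step: AssemblyStep) -> AssemblyPool:
    """Execute a step: check operand availability, add the product."""
    for operand in (step.left, step.right):
        if not pool.contains(operand):
            raise InvalidStepError(
                f"operand {operand.to_smiles()} not available in pool")
    product = _join(step.left, step.right, step.atom_identification)
    new = AssemblyPool(dict(pool.entries))
    new.add(product)
    return new


@dataclass
class AssemblyPathway:
    """An ordered sequence of assembly steps ending with the target(s)."""

    steps: list[AssemblyStep]
    targets: list[MolecularGraph]
    rng_seed: int | None = None

    @property
    def index(self) -> int:
        return len(self.steps)

    def replay(self) -> AssemblyPool:
        """Run every step through :func:`apply_step` from an empty pool."""
        pool = AssemblyPool()
        for step in self.steps:
            pool = apply_step(pool, step)
        return pool

    def to_json_lines(self) -> str:
        recs = []
        for s in self.steps:
            recs.append(json.dumps({
                "left_key": s.left.canonical_key,
                "right_key": s.right.canonical_key,
                "identification": {str(k): v
                                   for k, v in s.atom_identification.items()},
                "product_key": s.product.canonical_key,
            }))
        return "\n".join(recs)


def pathway_index(p: AssemblyPathway) -> int:
    """The assembly index of a pathway: its number of steps."""
    return p.index


def ma_bounds(m: MolecularGraph | Fragment) -> tuple[int, int]:
    """(lower, upper) bounds on MA for a molecule with B bonds.

    Fragment size at most doubles per step, so MA >= ceil(log2 B); building
    bond by bond gives MA <= B - 1.
    """
    b = m.bond_count
    if b < 1:
        raise ValueError("molecule must have at least one bond")
    return math.ceil(math.log2(b)), b - 1


# ---------------------------------------------------------------------------
# recipes: class-level pathway descriptions produced by the searches

Recipe = dict  # key -> (key_a, key_b, witness_mask)


def _recipe_order(space: FragmentSpace, recipe: Recipe) -> list[str]:
    return sorted(recipe, key=lambda k: (space.bonds[k], k))


def recipe_to_pathway(space: FragmentSpace, recipe: Recipe,
                      targets: list[MolecularGraph],
                      rng_seed: int | None = None) -> AssemblyPathway:
    """Materialize a class-level recipe into concrete assembly steps."""
    steps = []
    for key in _recipe_order(space, recipe):
        k1, k2, mask = recipe[key]
        atoms, edges = space.representative(key)
        full = (1 << len(edges)) - 1
        ga = _subgraph(atoms, edges, mask)
        gb = _subgraph(atoms, edges, full ^ mask)
        # recover the product-coordinate atom sets to build the identification
        sel_a = [edges[k] for k in range(len(edges)) if mask >> k & 1]
        sel_b = [edges[k] for k in range(len(edges)) if (full ^ mask) >> k & 1]
        va = sorted({i for i, j, _ in sel_a} | {j for _, j, _ in sel_a})
        vb = sorted({i for i, j, _ in sel_b} | {j for _, j, _ in sel_b})
        pos_a = {v: k for k, v in enumerate(va)}
        pos_b = {v: k for k, v in enumerate(vb)}
        ident = {pos_b[v]: pos_a[v] for v in vb if v in pos_a}
        left, right = Fragment(*ga), Fragment(*gb)
        if left.canonical_key != k1 and left.canonical_key != k2:
            raise AssertionError("witness mask inconsistent with recipe")
        steps.append(AssemblyStep(left=left, right=right,
                                  atom_identification=ident,
                                  product=Fragment(atoms, edges)))
    return AssemblyPathway(steps=steps, targets=list(targets),
                           rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# exact search

DEFAULT_MAX_BONDS = 12


class TooManyBondsError(ValueError):
    pass


def _lb(space: FragmentSpace, pending: frozenset, built_max: int) -> int:
    if not pending:
        return 0
    bmax = max(space.bonds[k] for k in pending)
    base = max(built_max, 1)
    chain = math.ceil(math.log2(bmax / base)) if bmax > base else 1
    return max(len(pending), chain)


_MEMO_CAP = 1_500_000


def _exact_search(space: FragmentSpace, target_keys: list[str]
                  ) -> tuple[int, Recipe]:
    pending0 = frozenset(k for k in set(target_keys) if space.bonds[k] > 1)
    if not pending0:
        return 0, {}
    lb = max(max(math.ceil(math.log2(space.bonds[k])) for k in target_keys),
             len(pending0))
    ub = sum(space.bonds[k] for k in set(target_keys)) - len(set(target_keys))

    def dfs(pending, built, budget, built_max, memo):
        if not pending:
            return {}
        if _lb(space, pending, built_max) > budget:
            return None
        state = (pending, built)
        if memo.get(state, -1) >= budget:
            return None
        f = max(pending, key=lambda k: (space.bonds[k], k))
        rest = pending - {f}
        nbuilt = built | {f}
        nmax = max(built_max, space.bonds[f])
        splits = space.splits(f)

        def preference(tr):
            k1, k2, _ = tr
            s = 0
            for k in (k1, k2):
                if space.bonds[k] > 1 and (k in nbuilt or k in rest):
                    s -= 2
            if k1 == k2:
                s -= 1
            return s

        for k1, k2, mask in sorted(splits, key=preference):
            np = set(rest)
            for k in (k1, k2):
                if space.bonds[k] > 1 and k not in nbuilt:
                    np.add(k)
            sub = dfs(frozenset(np), nbuilt, budget - 1, nmax, memo)
            if sub is not None:
                sub[f] = (k1, k2, mask)
                return sub
        if len(memo) < _MEMO_CAP:
            memo[state] = budget
        return None

    for budget in range(lb, ub + 1):
        memo: dict = {}
        recipe = dfs(pending0, frozenset(), budget, 1, memo)
        if recipe is not None:
            return budget, recipe
    raise AssertionError("bond-by-bond pathway always exists")  # pragma: no cover


def exact_ma(m: MolecularGraph, max_bonds: int = DEFAULT_MAX_BONDS
             ) -> tuple[int, AssemblyPathway]:
    """Exact molecular assembly number with a witnessing shortest pathway.

    The search space grows exponentially with bond count, so molecules above
    ``max_bonds`` are refused; use :func:`mc_ma` for those.
    """
    if m.bond_count > max_bonds:
        raise TooManyBondsError(
            f"{m.bond_count} bonds exceeds max_bonds={max_bonds}; "
            "use mc_ma for larger molecules")
    space = FragmentSpace([m])
    index, recipe = _exact_search(space, space.target_keys)
    return index, recipe_to_pathway(space, recipe, [m])


# ---------------------------------------------------------------------------
# Monte-Carlo search

_SAMPLED_CANDIDATES = 12


def _choose_split(space: FragmentSpace, f: str, rng, known: set,
                  dup_bias: float, share_weight: float,
                  double_bonus: bool = True):
    """Pick one producing step for class ``f``.

    Small fragments use the full enumerated split list with duplicate and
    target-sharing biases; large fragments weigh a random sample of
    bipartitions, with duplicates detected through the invariant prefilter
    (sharing bias is not estimated there — duplication dominates once blocks
    of the pathway exist).
    """
    from ._space import SPLIT_ENUM_MAX
    if space.bonds[f] <= SPLIT_ENUM_MAX:
        splits = space.splits(f)
        weights = []
        for k1, k2, _ in splits:
            w = 1.0
            if double_bonus and k1 == k2 and space.bonds[k1] > 1:
                w *= dup_bias * space.bonds[k1]  # doubling step
            for k in (k1, k2):
                b = space.bonds[k]
                if b > 1:
                    if k in known:
                        w *= dup_bias * b
                    elif share_weight:
                        w *= 1.0 + share_weight * (b - 1) * (
                            space.containment(k) - 1)
            weights.append(w)
        (choice,) = rng.choices(splits, weights=weights, k=1)
        return choice
    from ._space import graph_invariant
    masks = space.sample_bipartitions(f, rng, _SAMPLED_CANDIDATES)
    weights = []
    for mask in masks:
        g1, g2 = space.subgraph_pair(f, mask)
        w = 1.0
        if (double_bonus and len(g1[1]) > 1
                and graph_invariant(*g1) == graph_invariant(*g2)):
            from ._canon import canonical_string
            if canonical_string(*g1) == canonical_string(*g2):
                w *= dup_bias * len(g1[1])  # doubling step
        for g in (g1, g2):
            b = len(g[1])
            if b > 1 and space.match_known(g, known) is not None:
                w *= dup_bias * b
        weights.append(w)
    (mask,) = rng.choices(masks, weights=weights, k=1)
    g1, g2 = space.subgraph_pair(f, mask)
    k1 = space.register(*g1)
    k2 = space.register(*g2)
    if k1 <= k2:
        return (k1, k2, mask)
    _, edges = space.representative(f)
    full = (1 << len(edges)) - 1
    return (k2, k1, full ^ mask)


def mc_search(space: FragmentSpace, target_keys: list[str], iterations: int,
              seed: int, dup_bias: float = 8.0, share_weight: float = 1.0,
              exploit: float = 0.7, perturb: float = 0.3,
              double_bonus_prob: float = 0.5,
              collect_blocks: bool = False,
              ) -> tuple[int, Recipe, list[tuple[int, int]],
                         dict[str, int], list[tuple[int, int]]]:
    """Sample split recipes; keep the shortest.

    Proposal distribution: halves that duplicate an already-scheduled class
    are upweighted by ``dup_bias`` (times their bond count — the larger the
    reused block, the more steps saved), and unseen halves by how many
    targets they embed in (``share_weight``).  Once a best recipe exists,
    a fraction ``exploit`` of iterations restart from it with a fraction
    ``perturb`` of its decisions re-randomized.

    Returns ``(best_index, best_recipe, trace, block_counts, size_trace)``
    where ``trace`` records (iteration, best index) at every improvement and,
    when ``collect_blocks`` is set, ``block_counts`` accumulates every key
    block seen in any completed sampled pathway and ``size_trace`` its
    cumulative size per iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = random.Random(seed)
    tkeys = []
    for k in target_keys:  # preserve order, drop duplicates
        if k not in tkeys:
            tkeys.append(k)
    pending0 = [k for k in tkeys if space.bonds[k] > 1]
    naive = sum(space.bonds[k] for k in tkeys) - len(tkeys)
    best = naive + 1
    best_recipe: Recipe | None = None
    trace: list[tuple[int, int]] = []
    block_counts: dict[str, int] = {}
    size_trace: list[tuple[int, int]] = []

    for it in range(iterations):
        frozen: dict = {}
        if best_recipe is not None and rng.random() < exploit:
            ks = list(best_recipe)
            rng.shuffle(ks)
            keep = int(len(ks) * (1.0 - perturb))
            frozen = {k: best_recipe[k] for k in ks[:keep]}
        pending = list(pending0)
        built: set[str] = set()
        recipe: Recipe = {}
        steps = 0
        abandoned = False
        # alternate between a doubling-greedy and a sharing-led proposal
        # regime; each finds optima the other can miss
        double_bonus = rng.random() < double_bonus_prob
        while pending:
            pending.sort(key=lambda k: (-space.bonds[k], k))
            f = pending.pop(0)
            built.add(f)
            steps += 1
            if (not collect_blocks and best_recipe is not None
                    and steps + len(pending) >= best):
                abandoned = True
                break
            if f in frozen:
                choice = frozen[f]
            else:
                choice = _choose_split(space, f, rng, built.union(pending),
                                       dup_bias, share_weight, double_bonus)
            recipe[f] = choice
            for k in choice[:2]:
                if space.bonds[k] > 1 and k not in built and k not in pending:
                    pending.append(k)
        if abandoned:
            continue
        if collect_blocks:
            counts = _operand_use_counts(space, recipe, tkeys)
            for k, u in counts.items():
                if u >= 2 or space.containment(k) >= 2:
                    block_counts[k] = block_counts.get(k, 0) + 1
            size_trace.append((it, len(block_counts)))
        if steps < best:
            best = steps
            best_recipe = recipe
            trace.append((it, best))
        elif steps == best and rng.random() < 0.3:
            best_recipe = recipe  # plateau walk: drift across equal optima
    assert best_recipe is not None
    return best, best_recipe, trace, block_counts, size_trace


def _operand_use_counts(space: FragmentSpace, recipe: Recipe,
                        target_keys: list[str]) -> dict[str, int]:
    """How many times each composite class is consumed as an operand."""
    counts: dict[str, int] = {k: 0 for k in recipe}
    for k1, k2, _ in recipe.values():
        for k in (k1, k2):
            if space.bonds[k] > 1:
                counts[k] = counts.get(k, 0) + 1
    return counts


def mc_ma(m: MolecularGraph, iterations: int, seed: int,
          **params) -> tuple[int, AssemblyPathway, list[tuple[int, int]]]:
    """Monte-Carlo assembly-index search for a single molecule.

    Returns the best (lowest) index found, its pathway, and a trace of
    (iteration, best index) improvements.  Deterministic for a fixed seed;
    the best-so-far index is non-increasing in the iteration budget.
    """
    space = FragmentSpace([m])
    best, recipe, trace, _, _ = mc_search(space, space.target_keys,
                                          iterations, seed, **params)
    return best, recipe_to_pathway(space, recipe, [m], rng_seed=seed), trace


# ---------------------------------------------------------------------------
# key-step and multiset views


@dataclass
class KeyStepView:
    """The hierarchical skeleton of a pathway.

    Key blocks are the building blocks used as an operand more than once;
    a dependency edge (a, b) states that a must be made before b because a
    is consumed (directly or through single-use intermediates) to make b.
    """

    key_blocks: list[Fragment]
    edges: list[tuple[str, str]]
    use_counts: dict[str, int]
    target_keys: list[str]


@dataclass
class MultisetView:
    """Key blocks with the multiplicities left after cancelling the stacked
    key-step equations: block consumed u times and produced once leaves
    multiplicity u - 1."""

    entries: dict[str, int]

    def to_use_counts(self) -> dict[str, int]:
        return {k: v + 1 for k, v in self.entries.items()}


def _pathway_class_data(p: AssemblyPathway):
    """Recover per-class children and use counts from concrete steps."""
    children: dict[str, tuple[str, str]] = {}
    frags: dict[str, Fragment] = {}
    for s in p.steps:
        pk = s.product.canonical_key
        children[pk] = (s.left.canonical_key, s.right.canonical_key)
        frags[pk] = s.product
        for op in (s.left, s.right):
            frags.setdefault(op.canonical_key, op)
    counts: dict[str, int] = {}
    for lk, rk in children.values():
        for k in (lk, rk):
            if frags[k].bond_count > 1:
                counts[k] = counts.get(k, 0) + 1
    return children, frags, counts


def key_step_view(p: AssemblyPathway) -> KeyStepView:
    children, frags, counts = _pathway_class_data(p)
    target_keys = [canonical_key(t.as_fragment()) for t in p.targets]
    key_keys = {k for k, u in counts.items() if u >= 2}
    nodes = key_keys | set(target_keys)

    def leaves(k: str) -> list[str]:
        if frags[k].bond_count == 1:
            return []
        if k in nodes:
            return [k]
        if k not in children:
            return []
        lk, rk = children[k]
        return leaves(lk) + leaves(rk)

    edges = set()
    for k in nodes:
        if k not in children:
            continue
        lk, rk = children[k]
        for dep in leaves(lk) + leaves(rk):
            edges.add((dep, k))
    ordered = sorted(key_keys, key=lambda k: (frags[k].bond_count, k))
    return KeyStepView(
        key_blocks=[frags[k] for k in ordered],
        edges=sorted(edges),
        use_counts={k: counts[k] for k in key_keys},
        target_keys=target_keys,
    )


def multiset_view(k: KeyStepView) -> MultisetView:
    """Cancel blocks appearing on both sides of the stacked equations."""
    return MultisetView(entries={key: u - 1 for key, u in k.use_counts.items()})
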