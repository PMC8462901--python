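# Methods

## Graph model and canonical identity

Molecules are connected, hydrogen-suppressed labelled graphs: element
symbols on atoms, integer bond orders (1/2/3) on bonds. Stereochemistry,
charges and isotopes are discarded at parse time — assembly theory is a
statement about labelled graphs. Charged centres keep only their element
label; when a graph is rebuilt into an RDKit molecule (for SMILES output,
QED, fingerprints), formal charges are restored where the bond-order sum
exceeds the neutral valence (pyridinium-type N, etc.).

Fragments — connected subgraphs, not required to satisfy valence — are
identified by a canonical key: atoms are reordered by RDKit's canonical
ranking computed on a non-sanitized fragment molecule (ring perception only,
hydrogen-free), and the relabelled graph is serialized. Equal keys ⇔
label-isomorphic graphs. A hand-rolled individualization–refinement
canonicalizer was evaluated first but is factorial on highly symmetric
graphs (a 9-edge star already costs a minute); the ranking-based form is
polynomial and is cross-checked in the tests against a brute-force
permutation isomorphism oracle.

### Canonical kekulization

Aromatic systems are kekulized deterministically as a function of the
molecule's isomorphism class: atoms are renumbered by canonical rank, the
molecule is rebuilt with bonds inserted in sorted order and with hydrogen
counts pinned, and only then kekulized. Two pitfalls motivated this: RDKit's
kekulization depends on internal atom *and bond* storage order, so the same
molecule read from two SMILES spellings can otherwise receive non-isomorphic
alternating-bond assignments; and the default sanitizer's hydrogen
adjustment can silently relocate a pyrrole-type hydrogen (changing the
tautomer). With the canonical procedure, parse → write → parse preserves the
isomorphism class for every fixture compound.

Kekulization is a genuine degree of freedom, not a formality: adenine admits
two valid kekulé structures (note that RDKit's resonance enumerator reports
only one). Single-molecule assembly indices were kekulé-invariant in every
case we tested (adenine is 7 under both forms), but the *joint* index of the
five nucleobases is 15 under the package's canonical choice and 14 under
the alternative adenine kekulé — the shared adenine/guanine block differs.
Reported joint indices therefore refer to the package's canonical graphs.

## Assembly searches

A pathway never benefits from constructing the same fragment type twice
(every produced type is infinitely reusable), so a pathway is equivalent to
a *recipe*: a set of fragment isomorphism classes, each with one producing
step whose operands are basic bonds or smaller classes in the set. The
searches run top-down. Reversing an atom-superimposition join is exactly a
bipartition of a fragment's bond set into two connected halves, so the step
space of a class is its set of connected edge bipartitions. Restricting the
search to fragments that embed in a target is sound because bond multisets
only grow along a pathway.

**Exact search** (`exact_ma`, molecules ≤ 12 bonds by default): iterative
deepening on the pathway length, processing the largest pending class first,
with memoization of failed (pending, built) states and a doubling lower
bound — fragment size at most doubles per step, so a class of b bonds needs
at least ⌈log₂(b / largest built size)⌉ further steps, and each pending
class needs at least one. Bipartitions of a class are enumerated once
(2^(B−1) masks, deduplicated by canonical child pairs) and cached. The
12-bond guard keeps the enumeration and the search tractable; all five
nucleobases (8–12 bonds) solve in seconds.

**Monte-Carlo search** (`mc_ma`, `joint_ma`): each iteration samples one
recipe top-down. For classes up to 12 bonds the choice is a weighted draw
over the enumerated splits; larger classes draw from a random sample of
connected bipartitions (grown edge sets with connected complements). Weights
implement two heuristics with tunable strengths:

* duplication (`dup_bias`, default 8): a half that matches an
  already-scheduled class — detected cheaply through an invariant prefilter
  before any canonicalization — is upweighted by `dup_bias × bonds`, since
  reusing a b-bond block saves b − 1 steps; a split into two isomorphic new
  halves gets the same bonus in a fraction (`double_bonus_prob`, default
  0.5) of iterations;
* sharing (`share_weight`, default 1): an unseen half embeddable in k
  targets is upweighted by 1 + share_weight·(b−1)(k−1), steering joint
  searches toward blocks that can serve several molecules.

Once a best recipe exists, 70% of iterations (`exploit`) restart from it
with 30% of its decisions re-randomized (`perturb`), and recipes that tie
the best occasionally replace it (plateau walking), so the search drifts
across equal-length optima instead of fixating on one basin. Sampling is
abandoned early when the running step count cannot beat the best. A single
`random.Random(seed)` stream drives everything: fixed seed ⇒ bit-identical
output, and the best-so-far index is non-increasing in the budget. Every
split has positive probability, so the sampler finds the shortest pathway
given enough iterations; the heuristics only change how fast.

Budgets used in the shipped tests and acceptance script: 15 000 iterations
and five seeds for joint nucleobase searches (convergence plateaus well
before that: adenine alone converges within ~100 iterations, the
five-base set within a few thousand), and a few hundred iterations for the
large-molecule (opiate) diagnostics, where only qualitative properties —
monotone improvement, bound compliance, assembly-space saturation — are
asserted.

### A note on the five-nucleobase joint index

The published joint index for A, G, T, U, C is 16. The converged search
finds 15 (and 14 under the alternative adenine kekulé; that 14-step recipe
was verified step by step against an independent bipartition re-derivation).
Since the same code reproduces every other anchor exactly — single-molecule
indices 7/6/5/7/8 summing to 33, the pair index 12, the bond-by-bond count
43 — we attribute the difference to search convergence, not to a model
difference, and report the search's actual best.

## Key-step and multiset views

Key building blocks are the composite classes consumed as operands at least
twice. Stacking every step's equation (product = left + right) and
cancelling classes that appear on both sides leaves each key block with
multiplicity (uses − 1) — the multiset view; basic bonds are omitted as
trivial. Dependency edges run from a key block to the key blocks and targets
whose production consumes it, directly or through single-use intermediates.
The two views interconvert without ambiguity (multiplicity = uses − 1).

## Sequence assembly

Sequences assemble from single characters by concatenation; the compressed
form is an ordered list of segments over literals and references to strictly
earlier segments, the final segment expanding to the whole sequence.
Reconstructing a k-token segment costs k − 1 steps. References are single
digits for up to nine segments; beyond that the codec switches to a
bracketed dialect declared in a header line, keeping the digit notation
byte-compatible for small cases. Entropy is computed over *all* characters
of a string, separators included for rendered compressed strings — the
convention under which the worked 36-character example gives 3.251 bits.

`compress` is a randomized-greedy factorization: repeatedly pick a repeated
token window (maximum-savings, or any positive-savings window weighted by
savings², at even odds) and replace its non-overlapping occurrences in the
final segment by a reference; restart several times with seeded tie-breaks
and keep the fewest-steps encoding. Optimality is not claimed — on the
worked 60-base example the search reaches the printed 25 steps given a few
hundred restarts — and the step count never exceeds the naive length − 1.

## Reassembler

`build_pool` runs the joint search over the parent compounds, collects the
assembly space (blocks reused within a pathway or embeddable in ≥ 2
parents), and annotates each block with its attachment sites: the boundary
bonds of its subgraph embeddings in the parents (capped at 8 embeddings per
parent), recorded as (fragment atom, bond order, partner element).
`reassemble` grows molecules by joining fragments only at crosswise-matching
recorded sites — each side must name the other's bond order and element —
until the molecular weight enters the target window, then applies the filter
cascade: MW window, degrees of unsaturation (2C + 2 + N − H)/2 on the
implicit-hydrogen formula, forbidden-SMARTS motifs, and optionally a 3D
embedding probe (one ETKDG attempt with a fixed conformer seed followed by
MMFF cleanup; failure rejects). Rejected candidates are replaced; after
1000 × n attempts the constraints are declared unsatisfiable, with
per-filter rejection counts. The default alert list is a small standard set
of reactive/implausible motifs (peroxide, azo, allene, ketene, ...) and is
deliberately user-replaceable; no shipped result depends on its contents.

The random baseline grows molecules bond by bond from bare bond types with
occasional ring closures under element valence caps, then applies the same
filters. The arbitrary-fragment baseline (random connected subgraphs of the
parents, with boundary sites) is included as an experimental variant.

## Evaluation

Nearest-parent Tanimoto on Morgan fingerprints (radius 2, 2048 bits; `--mean`
aggregation available), QED, and Crippen logP, with set-level summaries and
one-sided Mann-Whitney U direction tests for generated vs baseline. logP
assertions in the tests carry ±0.5 tolerance since atom-contribution
parameterizations differ between implementations.

## What the fixtures do and do not show

Fixture structures are pinned standard SMILES of the named compounds; the
"symbolic RNA" entry is a single AMP-like nucleotide unit and approximate by
construction, and the "alternated" nucleobase sets are synthetic analog sets
(substituents relocated) built to be less mutually related than the natural
bases — tests assert only the qualitative direction (higher joint index than
the natural set). Toy graphs (paths, rings, stars, heteroatom chains) have
oracle-verifiable indices but none of the ring-fusion complexity of real
molecules; passing the toy equivalence suite shows search correctness on
small graphs, not convergence guarantees at drug scale, where only
qualitative properties are asserted.

## Known limitations

* Exact search is single-molecule and ≤ 12 bonds; joint indices are upper
  bounds from a stochastic search (tight on everything we can verify).
* Joint indices depend on the kekulization convention (see above); all
  reported values refer to the package's canonical kekulization.
* The compression search is heuristic; reported step counts are upper
  bounds on the sequence's assembly index.
* Generated molecules are filtered for plausibility, not synthesizability
  or activity.
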