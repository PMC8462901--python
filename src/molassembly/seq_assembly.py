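"""Assembly calculus on character sequences.

Sequences are assembled from single characters by concatenation, the string
analogue of molecular assembly: every built segment becomes reusable, so a
sequence with internal repeats needs fewer concatenations than the naive
one-character-at-a-time construction.

The compressed notation follows the segment/back-reference convention: a
compressed sequence is an ordered list of segments separated by ``_``; each
segment is a string of literal characters and references to strictly earlier
segments, and the final segment expands to the original sequence.  With at
most nine segments a reference is a single digit (e.g. ``A1``); beyond that
the codec switches to a bracketed dialect (``A(12)``), declared in a header
line of the serialized form.

Reconstructing a segment with k tokens takes k - 1 concatenation steps, so
the step count of a compressed sequence is the sum of (token count - 1)
over all segments, final segment included.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["Sequence", "CompressedSequence", "compress", "decompress",
           "step_count", "shannon_entropy", "parse_compressed",
           "read_fasta", "write_fasta"]

RESERVED = set("0123456789_()")

Token = str | int  # literal character, or 1-based reference to a segment


@dataclass(frozen=True)
class Sequence:
    text: str
    name: str = ""

    def __post_init__(self):
        if not self.text:
            raise ValueError("sequence must be nonempty")
        bad = set(self.text) & RESERVED
        if bad:
            raise ValueError(
                f"alphabet collides with reserved symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.text)


@dataclass
class CompressedSequence:
    """Ordered segments of literal/back-reference tokens."""

    segments: list[list[Token]]

    def __post_init__(self):
        for idx, seg in enumerate(self.segments):
            if not seg:
                raise ValueError(f"segment {idx + 1} is empty")
            for tok in seg:
                if isinstance(tok, int) and not (1 <= tok <= idx):
                    raise ValueError(
                        f"segment {idx + 1} references segment {tok}: "
                        "references must point strictly earlier")

    @property
    def dialect(self) -> str:
        return "digit" if len(self.segments) <= 9 else "bracket"

    @property
    def rendered(self) -> str:
        """The flat compressed string with ``_`` separators (no header)."""
        def tok(t: Token) -> str:
            if isinstance(t, int):
                return str(t) if self.dialect == "digit" else f"({t})"
            return t
        return "_".join("".join(tok(t) for t in seg) for seg in self.segments)

    def serialize(self) -> str:
        return f"#dialect={self.dialect}\n{self.rendered}"


def parse_compressed(text: str) -> CompressedSequence:
    """Parse a rendered compressed string (optional ``#dialect=`` header)."""
    dialect = "digit"
    lines = text.strip().splitlines()
    if lines and lines[0].startswith("#dialect="):
        dialect = lines[0].split("=", 1)[1].strip()
        lines = lines[1:]
    body = "".join(lines)
    if dialect not in ("digit", "bracket"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segments: list[list[Token]] = []
    for part in body.split("_"):
        seg: list[Token] = []
        i = 0
        while i < len(part):
            ch = part[i]
            if dialect == "bracket" and ch == "(":
                j = part.index(")", i)
                seg.append(int(part[i + 1:j]))
                i = j + 1
            elif ch.isdigit():
                if dialect == "bracket":
                    raise ValueError("bare digit in bracket dialect")
                seg.append(int(ch))
                i += 1
            else:
                seg.append(ch)
                i += 1
        segments.append(seg)
    return CompressedSequence(segments)


def decompress(c: CompressedSequence) -> Sequence:
    """Expand the final segment into the original sequence."""
    cache: list[str] = []
    for idx, seg in enumerate(c.segments):
        out = []
        for tok in seg:
            if isinstance(tok, int):
                if tok > idx:
                    raise ValueError("malformed input: forward reference")
                out.append(cache[tok - 1])
            else:
                out.append(tok)
        cache.append("".join(out))
    return Sequence(cache[-1])


def step_count(c: CompressedSequence) -> int:
    """Pairwise concatenations needed, given free reuse of earlier segments."""
    return sum(len(seg) - 1 for seg in c.segments)


def shannon_entropy(text: str) -> float:
    """Shannon entropy in bits per symbol over *all* characters of the string
    (separators included, for rendered compressed strings)."""
    if not text:
        raise ValueError("entropy of an empty string is undefined")
    n = len(text)
    counts = Counter(text)
    h = -sum((v / n) * math.log2(v / n) for v in counts.values())
    return h if h > 0 else 0.0  # avoid IEEE -0.0 for single-symbol strings


# ---------------------------------------------------------------------------
# compression search


def _nonoverlapping_count(tokens: list[Token], w: tuple[Token, ...]) -> list[int]:
    """Greedy left-to-right starting positions of non-overlapping matches."""
    L = len(w)
    hits = []
    i = 0
    while i + L <= len(tokens):
        if tuple(tokens[i:i + L]) == w:
            hits.append(i)
            i += L
        else:
            i += 1
    return hits


def _best_repeats(tokens: list[Token], max_len: int = 30
                  ) -> dict[tuple[Token, ...], int]:
    """Savings of every repeated token window: (count-1) * (len-1)."""
    out: dict[tuple[Token, ...], int] = {}
    n = len(tokens)
    for L in range(2, min(max_len, n // 2) + 1):
        windows = Counter(tuple(tokens[i:i + L]) for i in range(n - L + 1))
        for w, c in windows.items():
            if c < 2:
                continue
            hits = _nonoverlapping_count(tokens, w)
            if len(hits) >= 2:
                out[w] = (len(hits) - 1) * (L - 1)
    return out


def _greedy_compress(text: str, rng: random.Random) -> CompressedSequence:
    main: list[Token] = list(text)
    segments: list[list[Token]] = []
    def tok_key(w):
        return tuple((0, t, "") if isinstance(t, int) else (1, 0, t)
                     for t in w)

    while True:
        repeats = _best_repeats(main)
        if not repeats:
            break
        best = max(repeats.values())
        if best <= 0:
            break
        if rng.random() < 0.5:
            # greedy: one of the maximum-savings windows
            candidates = sorted((w for w, s in repeats.items() if s == best),
                                key=tok_key)
            w = candidates[rng.randrange(len(candidates))]
        else:
            # randomized-greedy: any positive window, weighted by savings^2
            candidates = sorted((w for w, s in repeats.items() if s > 0),
                                key=tok_key)
            weights = [repeats[w] ** 2 for w in candidates]
            (w,) = rng.choices(candidates, weights=weights, k=1)
        segments.append(list(w))
        ref = len(segments)
        hits = _nonoverlapping_count(main, w)
        new_main: list[Token] = []
        pos = 0
        for h in hits:
            new_main.extend(main[pos:h])
            new_main.append(ref)
            pos = h + len(w)
        new_main.extend(main[pos:])
        main = new_main
    return CompressedSequence(segments + [main])


def compress(s: Sequence | str, iterations: int = 20, seed: int = 0
             ) -> CompressedSequence:
    """Search for a short segment/back-reference encoding.

    Greedy repeated-window factorization with seeded tie-breaking, restarted
    ``iterations`` times; the encoding with the fewest reconstruction steps
    wins (ties broken toward the first found).  Optimality is not claimed —
    the goal is a short assembly pathway, not competitive data compression.
    """
    if isinstance(s, str):
        s = Sequence(s)
    rng = random.Random(seed)
    best: CompressedSequence | None = None
    best_steps = len(s.text)  # > n - 1, so the first attempt always wins
    for _ in range(max(1, iterations)):
        cand = _greedy_compress(s.text, rng)
        steps = step_count(cand)
        if steps < best_steps:
            best, best_steps = cand, steps
    assert best is not None and best_steps <= len(s.text) - 1
    return best


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[Sequence]:
    from Bio import SeqIO
    return [Sequence(str(rec.seq), name=rec.id)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[Sequence], path) -> None:
    from Bio.Seq import Seq as BioSeq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    recs = [SeqRecord(BioSeq(s.text), id=s.name or f"seq{i}", description="")
            for i, s in enumerate(seqs)]
    SeqIO.write(recs, str(path), "fasta")
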