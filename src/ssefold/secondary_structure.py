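"""Base pairs and dot-bracket secondary structures.

Indices are 1-based along the chain.  Pseudoknots are expressed through
additional bracket alphabets ``()``, ``[]``, ``{}``, ``<>``; each layer is
matched independently by a stack.  Two cleaning operations are provided:

* :func:`resolve_pair_conflicts` reduces a list of geometric pair
  candidates (which may share residues) to one partner per residue using a
  ranked criterion list: sequence interval > 4, standard pair (AU/GC/GU),
  neighbour support, then geometry score / span / position as deterministic
  tie-breakers.
* :func:`remove_crossing_pairs` drops a minimum set of pairs so the rest is
  crossing-free (maximum-cardinality nested subset, exact DP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .chem import is_standard_pair
from .errors import DotBracketError, InputError, SsefoldError

OPEN_BRACKETS = "([{<"
CLOSE_BRACKETS = ")]}>"
N_LAYERS = len(OPEN_BRACKETS)
VALID_BASES = frozenset("ACGU")


@dataclass(frozen=True, order=True)
class BasePair:
    """One base pair between 1-based residue indices i < j."""

    i: int
    j: int
    standard: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.i < self.j:
            raise InputError(f"base pair requires i < j, got ({self.i}, {self.j})")

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)


def make_pair(i: int, j: int, sequence: str) -> BasePair:
    """Construct a pair with the standard flag derived from the sequence."""
    if i > j:
        i, j = j, i
    return BasePair(i, j, is_standard_pair(sequence[i - 1], sequence[j - 1]))


@dataclass
class SecondaryStructure:
    """A sequence over {A,C,G,U} plus a set of base pairs."""

    sequence: str
    pairs: frozenset[BasePair]

    def __init__(self, sequence: str, pairs: Iterable[BasePair | tuple[int, int]]):
        bad = set(sequence) - VALID_BASES
        if bad:
            raise InputError(f"sequence contains non-RNA characters: {sorted(bad)}")
        norm = []
        for p in pairs:
            i, j = (p.i, p.j) if isinstance(p, BasePair) else (p[0], p[1])
            if not (1 <= i <= len(sequence) and 1 <= j <= len(sequence)):
                raise InputError(f"pair ({i}, {j}) outside sequence of length {len(sequence)}")
            if not isinstance(p, BasePair):
                p = make_pair(i, j, sequence)
            norm.append(p)
        self.sequence = sequence
        self.pairs = frozenset(norm)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pair_tuples(self) -> set[tuple[int, int]]:
        return {p.as_tuple() for p in self.pairs}

    def partner_map(self) -> dict[int, int]:
        """index -> paired index; raises if a residue pairs twice."""
        out: dict[int, int] = {}
        for p in self.pairs:
            for a, b in ((p.i, p.j), (p.j, p.i)):
                if a in out:
                    raise SsefoldError(f"residue {a} participates in more than one pair")
                out[a] = b
        return out

    def is_nested(self) -> bool:
        return not any(
            _crossing(p.as_tuple(), q.as_tuple())
            for p in self.pairs for q in self.pairs if p < q
        )


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def parse_dotbracket(text: str, sequence: str) -> SecondaryStructure:
    """Parse dot-bracket ``text`` against ``sequence``.

    Each bracket alphabet is matched independently, so crossing (pseudoknot)
    pairs are representable with extra layers.
    """
    if len(text) != len(sequence):
        raise InputError(
            f"structure length {len(text)} != sequence length {len(sequence)}"
        )
    stacks: list[list[int]] = [[] for _ in range(N_LAYERS)]
    pairs: list[BasePair] = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in OPEN_BRACKETS:
            stacks[OPEN_BRACKETS.index(ch)].append(pos)
        elif ch in CLOSE_BRACKETS:
            stack = stacks[CLOSE_BRACKETS.index(ch)]
            if not stack:
                raise DotBracketError(
                    f"unmatched {ch!r} at position {pos}", position=pos
                )
            pairs.append(make_pair(stack.pop(), pos, sequence))
        else:
            raise DotBracketError(
                f"invalid character {ch!r} at position {pos}", position=pos
            )
    for layer, stack in enumerate(stacks):
        if stack:
            raise DotBracketError(
                f"unmatched {OPEN_BRACKETS[layer]!r} at position {stack[-1]}",
                position=stack[-1],
            )
    return SecondaryStructure(sequence, pairs)


def to_dotbracket(ss: SecondaryStructure) -> str:
    """Serialize pairs to dot-bracket text.

    Nested pairs use ``()``; crossing pairs are pushed to further layers
    greedily in order of ascending i.
    """
    layers: list[list[tuple[int, int]]] = [[] for _ in range(N_LAYERS)]
    out = ["."] * len(ss)
    for pair in sorted(ss.pairs):
        pt = pair.as_tuple()
        for depth, layer in enumerate(layers):
            if not any(_crossing(pt, q) for q in layer):
                layer.append(pt)
                out[pt[0] - 1] = OPEN_BRACKETS[depth]
                out[pt[1] - 1] = CLOSE_BRACKETS[depth]
                break
        else:
            raise SsefoldError(
                f"more than {N_LAYERS} mutually crossing layers; pair {pt} "
                "cannot be serialized"
            )
    return "".join(out)


def _criterion_key(
    cand: tuple[BasePair, float], all_pairs: set[tuple[int, int]]
) -> tuple:
    """Ranked comparison key, higher sorts first.

    Order: interval |j-i| > 4; standard pair; neighbour support (a candidate
    (i-1, j+1) or (i+1, j-1) exists); then geometry score, smaller span and
    smaller i as deterministic tie-breakers.
    """
    pair, score = cand
    i, j = pair.i, pair.j
    neighbour = (i - 1, j + 1) in all_pairs or (i + 1, j - 1) in all_pairs
    return (j - i > 4, pair.standard, neighbour, score, -(j - i), -i, -j)


def resolve_pair_conflicts(
    candidates: Sequence[tuple[BasePair, float]], sequence: str
) -> SecondaryStructure:
    """Keep at most one partner per residue among geometric candidates.

    Candidates are ranked by the criterion key and accepted greedily; a
    candidate is dropped when either of its residues is already claimed by a
    better-ranked pair.  This equals a brute-force search for the
    conflict-free subset whose ranked key sequence is lexicographically
    greatest (the greedy choice is exchange-optimal because keys are static).
    """
    all_pairs = {c[0].as_tuple() for c in candidates}
    taken: set[int] = set()
    kept: list[BasePair] = []
    for pair, _score in sorted(
        candidates, key=lambda c: _criterion_key(c, all_pairs), reverse=True
    ):
        if pair.i in taken or pair.j in taken:
            continue
        taken.update(pair.as_tuple())
        kept.append(pair)
    return SecondaryStructure(sequence, kept)


def remove_crossing_pairs(
    ss: SecondaryStructure,
) -> tuple[SecondaryStructure, frozenset[BasePair]]:
    """Return a maximum-cardinality crossing-free substructure.

    Exact interval dynamic programming; on ties the pair opening at the
    smaller index is preferred, which makes the traceback deterministic.
    """
    partner = ss.partner_map()
    n = len(ss)

    @lru_cache(maxsize=None)
    def best(lo: int, hi: int) -> tuple[int, frozenset[tuple[int, int]]]:
        if lo > hi:
            return 0, frozenset()
        j = partner.get(lo)
        take = None
        if j is not None and lo < j <= hi:
            n_in, s_in = best(lo + 1, j - 1)
            n_out, s_out = best(j + 1, hi)
            take = (1 + n_in + n_out, s_in | s_out | {(lo, j)})
        n_skip, s_skip = best(lo + 1, hi)
        if take is not None and take[0] >= n_skip:
            # ties prefer keeping the pair that opens at the smaller index
            return take
        return n_skip, s_skip

    _count, kept_tuples = best(1, n)
    best.cache_clear()
    kept = frozenset(p for p in ss.pairs if p.as_tuple() in kept_tuples)
    removed = ss.pairs - kept
    return SecondaryStructure(ss.sequence, kept), removed


def read_record(text: str) -> SecondaryStructure:
    """Parse the two-line plain-text record (sequence line, structure line)."""
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) != 2:
        raise InputError("expected exactly two non-empty lines (sequence, structure)")
    return parse_dotbracket(lines[1], lines[0])


def write_record(ss: SecondaryStructure) -> str:
    return f"{ss.sequence}\n{to_dotbracket(ss)}\n"
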