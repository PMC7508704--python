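"""Decomposition of a secondary structure into smallest secondary elements.

An SSE is a stem, or a loop (hairpin, bulge, internal, junction, open loop)
*together with two base pairs of each stem connected to it* — the annexed
"flanking pairs" provide the superposition anchors used when templates are
joined during assembly.

Two library schemes exist.  ``lib2`` decomposes the structure as given;
``lib1`` first opens every single-base-pair stem (a helix of one pair),
iterated to a fixed point, which merges the surrounding loops into one
larger loop and makes templates more tolerant to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DecompositionError, SsefoldError
from .model import ResidueRecord, RnaChain
from .secondary_structure import BasePair, SecondaryStructure, make_pair

SSE_TYPES = ("stem", "hairpin_loop", "bulge_loop", "internal_loop", "junction", "open_loop")
SCHEMES = ("lib1", "lib2")

#: separator between discontinuous strand segments in record serializations
SEGMENT_SEPARATOR = "&"


@dataclass
class Stem:
    """A maximal run of stacked pairs (i, j), (i+1, j-1), ..."""

    pairs: list[tuple[int, int]]  # ascending i

    @property
    def outer(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.pairs[-1]

    def __len__(self) -> int:
        return len(self.pairs)

    def terminal_pairs(self, side: str) -> list[tuple[int, int]]:
        """Up to two pairs nearest the given side ('inner' or 'outer')."""
        k = min(2, len(self.pairs))
        return self.pairs[-k:] if side == "inner" else self.pairs[:k]


@dataclass(eq=False)
class SseRecord:
    """One template record: an SSE with its 2D pattern and (optionally) 3D."""

    sse_type: str
    segments: list[tuple[int, int]]          # 1-based inclusive ranges, sorted
    flanking_pairs: list[BasePair]           # annexed pairs from adjacent stems
    pairs: list[BasePair]                    # all pairs internal to the record
    sequence: str                            # segment bases joined by '&'
    dot_bracket: str                         # matching pattern, same separators
    length: int                              # total member residue count
    n_incident_stems: int = 0                # >0 for loops; junction bucket key
    family: str = ""
    source_id: str = ""
    source_chain: str = ""
    residues: Optional[dict[int, ResidueRecord]] = field(default=None, repr=False)

    @property
    def member_indices(self) -> list[int]:
        out: list[int] = []
        for a, b in self.segments:
            out.extend(range(a, b + 1))
        return out

    @property
    def has_coordinates(self) -> bool:
        return self.residues is not None

    def identity_key(self) -> tuple[str, str, str]:
        """Key under which exact duplicates are folded (type + 2D + sequence)."""
        return (self.sse_type, self.sequence, self.dot_bracket)

    def topology_key(self) -> tuple[str, str]:
        """Sequence-agnostic search key: type + dot-bracket pattern."""
        return (self.sse_type, self.dot_bracket)


def find_stems(ss: SecondaryStructure) -> list[Stem]:
    """Maximal stems of a crossing-free structure, sorted by outer i."""
    if not ss.is_nested():
        raise SsefoldError("stem finding requires a crossing-free structure")
    pairs = sorted(p.as_tuple() for p in ss.pairs)
    stems: list[Stem] = []
    for i, j in pairs:
        if stems and stems[-1].inner == (i - 1, j + 1):
            stems[-1].pairs.append((i, j))
        else:
            stems.append(Stem([(i, j)]))
    return stems


def open_single_pairs(ss: SecondaryStructure) -> SecondaryStructure:
    """Remove every stem of exactly one pair, iterated to a fixed point.

    Opening one pair can leave a neighbouring stem isolated as a new
    single-pair stem, so the rule is applied until none remain.
    """
    current = ss
    while True:
        singles = [s for s in find_stems(current) if len(s) == 1]
        if not singles:
            return current
        doomed = {s.pairs[0] for s in singles}
        current = SecondaryStructure(
            current.sequence,
            [p for p in current.pairs if p.as_tuple() not in doomed],
        )


@dataclass
class _Node:
    stem: Optional[Stem]            # None at the exterior
    children: list["_Node"] = field(default_factory=list)


def _build_tree(stems: list[Stem]) -> _Node:
    root = _Node(None)
    stack = [root]

    def encloses(node: _Node, stem: Stem) -> bool:
        if node.stem is None:
            return True
        i, j = node.stem.inner
        return i < stem.outer[0] and stem.outer[1] < j

    for stem in stems:  # sorted by outer i
        while not encloses(stack[-1], stem):
            stack.pop()
        node = _Node(stem)
        stack[-1].children.append(node)
        stack.append(node)
    return root


def _merge_runs(indices: set[int]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for idx in sorted(indices):
        if runs and idx == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], idx)
        else:
            runs.append((idx, idx))
    return runs


def _make_record(
    sse_type: str,
    members: set[int],
    internal_pairs: list[tuple[int, int]],
    flanking: list[tuple[int, int]],
    ss: SecondaryStructure,
    n_incident: int = 0,
) -> SseRecord:
    segments = _merge_runs(members)
    open_at = {i for i, _ in internal_pairs}
    close_at = {j for _, j in internal_pairs}
    seq_parts, db_parts = [], []
    for a, b in segments:
        seq_parts.append(ss.sequence[a - 1:b])
        db_parts.append(
            "".join(
                "(" if k in open_at else ")" if k in close_at else "."
                for k in range(a, b + 1)
            )
        )
    return SseRecord(
        sse_type=sse_type,
        segments=segments,
        flanking_pairs=[make_pair(i, j, ss.sequence) for i, j in sorted(flanking)],
        pairs=[make_pair(i, j, ss.sequence) for i, j in sorted(internal_pairs)],
        sequence=SEGMENT_SEPARATOR.join(seq_parts),
        dot_bracket=SEGMENT_SEPARATOR.join(db_parts),
        length=len(members),
        n_incident_stems=n_incident,
    )


def decompose(ss: SecondaryStructure, scheme: str = "lib1") -> list[SseRecord]:
    """Split a crossing-free structure into SSE records (2D only).

    Every residue of the chain is covered by at least one record; residues
    shared between a stem and a loop are exactly the annexed flanking-pair
    residues.  Raises :class:`DecompositionError` when no pairs remain (such
    a chain is library-ineligible).
    """
    if scheme not in SCHEMES:
        raise SsefoldError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "lib1":
        ss = open_single_pairs(ss)
    if not ss.pairs:
        raise DecompositionError("structure has no base pairs; cannot form SSEs")
    stems = find_stems(ss)
    root = _build_tree(stems)
    n = len(ss)
    records: list[SseRecord] = []

    # exterior (open) loop: 5'/3' tails and gaps between root-level stems
    exterior: set[int] = set()
    cursor = 1
    for child in root.children:
        exterior.update(range(cursor, child.stem.outer[0]))
        cursor = child.stem.outer[1] + 1
    exterior.update(range(cursor, n + 1))
    if exterior or len(root.children) >= 2:
        flanks = [p for c in root.children for p in c.stem.terminal_pairs("outer")]
        members = set(exterior)
        for i, j in flanks:
            members.update((i, j))
        records.append(
            _make_record("open_loop", members, flanks, flanks, ss,
                         n_incident=len(root.children))
        )

    def visit(node: _Node) -> None:
        stem = node.stem
        records.append(
            _make_record("stem", {k for p in stem.pairs for k in p}, stem.pairs, [], ss)
        )
        ii, ij = stem.inner
        kids = node.children
        flanks = stem.terminal_pairs("inner") + [
            p for c in kids for p in c.stem.terminal_pairs("outer")
        ]
        members = {k for p in flanks for k in p}
        gaps: list[int] = []  # unpaired residue counts of each loop segment
        cursor = ii + 1
        for child in kids:
            co, cj = child.stem.outer
            gaps.append(co - cursor)
            members.update(range(cursor, co))
            cursor = cj + 1
        gaps.append(ij - cursor)
        members.update(range(cursor, ij))
        if not kids:
            sse_type = "hairpin_loop"
        elif len(kids) == 1:
            sse_type = "internal_loop" if all(g > 0 for g in gaps) else "bulge_loop"
        else:
            sse_type = "junction"
        records.append(
            _make_record(sse_type, members, flanks, flanks, ss,
                         n_incident=len(kids) + 1)
        )
        for child in kids:
            visit(child)

    for child in root.children:
        visit(child)
    return records


def attach_coordinates(chain: RnaChain, records: list[SseRecord]) -> list[SseRecord]:
    """Copy each record's member residues (with coordinates) from the chain."""
    for rec in records:
        rec.residues = {}
        for idx in rec.member_indices:
            rec.residues[idx] = chain.residue(idx).copy()
        rec.source_id = chain.source_id
        rec.source_chain = chain.chain_id
    return records
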