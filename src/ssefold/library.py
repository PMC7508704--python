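"""The SSE template library: build, deduplicate, search, persist, update.

Records are grouped by a *topology key* — SSE type plus the sequence-
agnostic dot-bracket pattern (segment lengths and flanking-pair arrangement)
— and searched by exact topology with candidates ranked by full-sequence
identity.  Two levels of deduplication exist:

* exact duplicates (same type, sequence, pattern *and* coordinates) are
  folded away at insertion time;
* :func:`filter_unique` additionally keeps one representative per
  (sequence, pattern) regardless of coordinates, mirroring the "filter"
  counts of the library statistics.

On disk a library is a directory: ``meta.txt`` (scheme + provenance),
``index.txt`` (line-oriented key-value blocks) and one PDB fragment file
per record.  The layout is inspectable, diff-able and append-friendly.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

from . import pair_annotation, structure_io
from .config import AnnotationParams
from .errors import LibraryError
from .model import AtomRecord, ResidueRecord, RnaChain
from .secondary_structure import BasePair
from .sse import SCHEMES, SseRecord, attach_coordinates, decompose

logger = logging.getLogger(__name__)

_JUNCTION_BUCKETS = {3: "3wj", 4: "4wj", 5: "5wj"}
_LOOP_BUCKETS = ("hairpin", "bulge", "internal", "3wj", "4wj", "5wj", "nwj", "open")


@dataclass
class TemplateLibrary:
    scheme: str
    records: list[SseRecord] = field(default_factory=list)
    #: source_id -> insertion batch number (0 = initial build)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise LibraryError(f"unknown scheme {self.scheme!r}")
        self._index: dict[tuple[str, str], list[SseRecord]] = defaultdict(list)
        for rec in self.records:
            self._index[rec.topology_key()].append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def insert(self, record: SseRecord) -> bool:
        """Insert unless an exact duplicate exists; returns True if stored.

        When coordinates, sequence and pattern all coincide, the copy with
        the lexicographically smaller (source_id, chain) is retained, which
        makes the stored set independent of insertion order.
        """
        if not record.has_coordinates:
            raise LibraryError("library records must carry coordinates")
        bucket = self._index[record.topology_key()]
        for pos, existing in enumerate(bucket):
            if existing.identity_key() != record.identity_key():
                continue
            if _coords_equal(existing, record):
                if (record.source_id, record.source_chain) < (
                    existing.source_id, existing.source_chain
                ):
                    bucket[pos] = record
                    self.records[self.records.index(existing)] = record
                return False
        bucket.append(record)
        self.records.append(record)
        return True

    def candidates(self, topology_key: tuple[str, str]) -> list[SseRecord]:
        return list(self._index.get(topology_key, ()))


def _coords_equal(a: SseRecord, b: SseRecord) -> bool:
    if set(a.residues) != set(b.residues):
        return False
    for idx, ra in a.residues.items():
        rb = b.residues[idx]
        if [x.name for x in ra.atoms] != [x.name for x in rb.atoms]:
            return False
        if not np.array_equal(ra.coords(), rb.coords()):
            return False
    return True


def _insert_chain(
    library: TemplateLibrary, chain: RnaChain, annotation: AnnotationParams | None
) -> int:
    if chain.secondary_structure is None:
        pair_annotation.derive_secondary_structure(chain, annotation)
    if not pair_annotation.is_library_eligible(chain):
        logger.info("chain %s/%s has no base pairs; skipped",
                    chain.source_id, chain.chain_id)
        return 0
    records = decompose(chain.secondary_structure, library.scheme)
    attach_coordinates(chain, records)
    return sum(library.insert(rec) for rec in records)


def build_library(
    chains: Iterable[RnaChain], scheme: str = "lib1",
    annotation: AnnotationParams | None = None,
) -> TemplateLibrary:
    """Decompose sanitized chains and collect their SSE templates.

    Insertion order is deterministic (sorted by source id, then chain id);
    per-chain failures are logged and skipped, never fatal.
    """
    library = TemplateLibrary(scheme)
    for chain in sorted(chains, key=lambda c: (c.source_id, c.chain_id)):
        library.provenance.setdefault(chain.source_id, 0)
        try:
            _insert_chain(library, chain, annotation)
        except Exception:
            logger.exception("chain %s/%s failed; skipped",
                             chain.source_id, chain.chain_id)
    return library


def update_library(
    library: TemplateLibrary, new_chains: Iterable[RnaChain],
    annotation: AnnotationParams | None = None,
) -> TemplateLibrary:
    """Incremental insertion; equals rebuilding from the chain union.

    Chains whose source_id is already in the provenance are skipped, so the
    operation is idempotent.
    """
    out = TemplateLibrary(library.scheme, list(library.records), dict(library.provenance))
    batch = max(out.provenance.values(), default=-1) + 1
    fresh = [c for c in new_chains if c.source_id not in out.provenance]
    for chain in sorted(fresh, key=lambda c: (c.source_id, c.chain_id)):
        out.provenance.setdefault(chain.source_id, batch)
        try:
            _insert_chain(out, chain, annotation)
        except Exception:
            logger.exception("chain %s/%s failed; skipped",
                             chain.source_id, chain.chain_id)
    return out


def filter_unique(library: TemplateLibrary) -> TemplateLibrary:
    """One representative per (type, sequence, pattern).

    The record from the lexicographically smallest (source_id, chain)
    wins, making the result deterministic.
    """
    best: dict[tuple[str, str, str], SseRecord] = {}
    for rec in library.records:
        key = rec.identity_key()
        cur = best.get(key)
        if cur is None or (rec.source_id, rec.source_chain) < (cur.source_id, cur.source_chain):
            best[key] = rec
    kept = [r for r in library.records if best[r.identity_key()] is r]
    return TemplateLibrary(library.scheme, kept, dict(library.provenance))


def sequence_identity(a: str, b: str) -> float:
    """Fraction of matching characters between equal-length sequences."""
    if len(a) != len(b):
        raise LibraryError("identity requires equal-length sequences")
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def search(
    library: TemplateLibrary, query: SseRecord,
    exclude_source: frozenset[str] | set[str] = frozenset(),
    max_hits: Optional[int] = None,
) -> list[SseRecord]:
    """Templates matching the query's exact topology, best first.

    Ranking: full-sequence identity over all segments and flanking pairs
    (descending), then source id / chain ascending for determinism.
    Records from excluded sources (the self-exclusion protocol) are never
    returned.  An empty result is allowed.
    """
    hits = [
        rec for rec in library.candidates(query.topology_key())
        if rec.source_id not in exclude_source
    ]
    hits.sort(key=lambda r: (-sequence_identity(query.sequence, r.sequence),
                             r.source_id, r.source_chain))
    return hits[:max_hits] if max_hits is not None else hits


def _bucket(record: SseRecord) -> Optional[str]:
    if record.sse_type == "hairpin_loop":
        return "hairpin"
    if record.sse_type == "bulge_loop":
        return "bulge"
    if record.sse_type == "internal_loop":
        return "internal"
    if record.sse_type == "junction":
        return _JUNCTION_BUCKETS.get(record.n_incident_stems, "nwj")
    if record.sse_type == "open_loop":
        return "open"
    return None  # stems are counted separately


def library_stats(library: TemplateLibrary) -> dict[str, dict[str, int]]:
    """Loop counts per bucket, raw ("all") and deduplicated ("filter").

    Junctions are bucketed by incident helix count (3wj/4wj/5wj, and nwj
    for six or more); "all" sums the loop buckets; stems are reported
    under their own key and excluded from "all".
    """
    out = {b: {"all": 0, "filter": 0} for b in _LOOP_BUCKETS}
    out["stem"] = {"all": 0, "filter": 0}
    out["all"] = {"all": 0, "filter": 0}
    for kind, lib in (("all", library), ("filter", filter_unique(library))):
        for rec in lib.records:
            bucket = _bucket(rec)
            if bucket is None:
                out["stem"][kind] += 1
            else:
                out[bucket][kind] += 1
                out["all"][kind] += 1
    return out


def format_stats(stats: dict[str, dict[str, int]]) -> str:
    """Tab-separated table of the bucket counts."""
    lines = ["bucket\tall\tfilter"]
    for bucket in (*_LOOP_BUCKETS, "stem", "all"):
        row = stats[bucket]
        lines.append(f"{bucket}\t{row['all']}\t{row['filter']}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# persistence

def save_library(library: TemplateLibrary, path: str | Path) -> None:
    root = Path(path)
    (root / "frags").mkdir(parents=True, exist_ok=True)
    meta = [f"scheme\t{library.scheme}", f"records\t{len(library.records)}"]
    for source, batch in sorted(library.provenance.items()):
        meta.append(f"source\t{source}\t{batch}")
    (root / "meta.txt").write_text("\n".join(meta) + "\n")
    blocks = []
    for num, rec in enumerate(library.records, start=1):
        frag = f"frags/{num:06d}.pdb"
        chain = RnaChain(rec.source_id, rec.source_chain or "A",
                         [rec.residues[k] for k in sorted(rec.residues)])
        _write_fragment(root / frag, chain)
        blocks.append(_format_record(num, rec, frag))
    (root / "index.txt").write_text("\n".join(blocks))


def _format_record(num: int, rec: SseRecord, frag: str) -> str:
    pairs = ",".join(f"{p.i}:{p.j}" for p in rec.pairs)
    flanks = ",".join(f"{p.i}:{p.j}" for p in rec.flanking_pairs)
    segments = ",".join(f"{a}-{b}" for a, b in rec.segments)
    return (
        f"record\t{num:06d}\n"
        f"type\t{rec.sse_type}\n"
        f"source\t{rec.source_id}\n"
        f"chain\t{rec.source_chain}\n"
        f"segments\t{segments}\n"
        f"pairs\t{pairs}\n"
        f"flanking\t{flanks}\n"
        f"sequence\t{rec.sequence}\n"
        f"dot_bracket\t{rec.dot_bracket}\n"
        f"length\t{rec.length}\n"
        f"incident\t{rec.n_incident_stems}\n"
        f"family\t{rec.family}\n"
        f"fragment\t{frag}\n"
    )


def _write_fragment(path: Path, chain: RnaChain) -> None:
    """PDB fragment keeping the original (non-contiguous) residue indices."""
    structure_io.write_pdb(path, [chain])


def _read_fragment(path: Path) -> dict[int, ResidueRecord]:
    st = gemmi.read_structure(str(path))
    out: dict[int, ResidueRecord] = {}
    for res in st[0][0]:
        atoms = [
            AtomRecord(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
            for a in res
        ]
        idx = res.seqid.num
        out[idx] = ResidueRecord(res.name, res.name, atoms, idx)
    return out


def load_library(path: str | Path) -> TemplateLibrary:
    root = Path(path)
    if not (root / "meta.txt").exists():
        raise LibraryError(f"{root} is not a template library (no meta.txt)")
    scheme = None
    provenance: dict[str, int] = {}
    for line in (root / "meta.txt").read_text().splitlines():
        parts = line.split("\t")
        if parts[0] == "scheme":
            scheme = parts[1]
        elif parts[0] == "source":
            provenance[parts[1]] = int(parts[2])
    records = []
    for block in (root / "index.txt").read_text().split("\nrecord\t"):
        if not block.strip():
            continue
        records.append(_parse_record(block, root))
    return TemplateLibrary(scheme, records, provenance)


def _parse_record(block: str, root: Path) -> SseRecord:
    fields: dict[str, str] = {}
    for line in block.strip().splitlines():
        key, _, value = line.partition("\t")
        if key == "record" or not key:
            continue
        fields.setdefault(key, value)
    segments = [
        (int(a), int(b))
        for a, b in (s.split("-") for s in fields["segments"].split(",") if s)
    ]
    sequence = fields["sequence"]
    flat = sequence.replace("&", "")
    full = ["A"] * (max(b for _, b in segments))
    for (a, b), seg in zip(segments, _split_segments(flat, segments)):
        full[a - 1:b] = list(seg)
    full_seq = "".join(full)

    def parse_pairs(raw: str) -> list[BasePair]:
        out = []
        for item in raw.split(","):
            if not item:
                continue
            i, j = item.split(":")
            from .secondary_structure import make_pair
            out.append(make_pair(int(i), int(j), full_seq))
        return out

    residues = _read_fragment(root / fields["fragment"])
    return SseRecord(
        sse_type=fields["type"],
        segments=segments,
        flanking_pairs=parse_pairs(fields["flanking"]),
        pairs=parse_pairs(fields["pairs"]),
        sequence=sequence,
        dot_bracket=fields["dot_bracket"],
        length=int(fields["length"]),
        n_incident_stems=int(fields["incident"]),
        family=fields.get("family", ""),
        source_id=fields["source"],
        source_chain=fields["chain"],
        residues=residues,
    )


def _split_segments(flat: str, segments: list[tuple[int, int]]) -> list[str]:
    out, pos = [], 0
    for a, b in segments:
        n = b - a + 1
        out.append(flat[pos:pos + n])
        pos += n
    return out
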