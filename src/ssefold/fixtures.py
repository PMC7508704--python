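"""Synthetic full-heavy-atom RNA fixtures with known secondary structure.

The generator's goal is *unambiguous annotation*, not conformational
realism: every base pair written into a fixture must be recovered by the
geometric annotator, and no spurious pair may appear.  The layout is
therefore deliberately open:

* each stem is an ideal A-form-like duplex on its own grid slot, axis
  vertical, built from the idealized residue templates (G-U pairs get an
  in-plane wobble shear);
* hairpin loops coil around their closing stem's axis just above it, bases
  pointing radially outward;
* all other unpaired segments (bulge/internal/junction strands, exterior
  tails) are laid out as straight, evenly spaced runs in a separate strand
  region, one row per segment.

Spacings are chosen so that for every non-paired residue pair at least one
detection criterion (C1'-C1' window, plane angle, inter-base rise, or polar
edge contact) fails by a comfortable margin.  What this sacrifices — loop
closure and backbone continuity *between* elements — is documented in the
methods note; within stems the backbone is covalently continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import (
    COMPLEMENT,
    MATE_TRANSFORM,
    WOBBLE_SHIFT,
    residue_template,
)
from .config import HelixParams
from .errors import FixtureError
from .model import AtomRecord, ResidueRecord, RnaChain
from .secondary_structure import SecondaryStructure, parse_dotbracket
from .sse import Stem, _build_tree, find_stems

GRID_SPACING = 40.0       # Å between stem axes
COIL_RADIUS = 12.0        # Å, hairpin coil around its stem
COIL_PITCH = 11.0         # Å rise per coil turn
COIL_CLEARANCE = 8.0      # Å above the stem top
LOOP_SPACING = 5.9        # Å between consecutive loop residues
PARK_X = -30.0            # strand region starts here and extends to -x
PARK_PITCH = 12.0         # Å between strand rows


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain."""

    sequence: str
    structure: str
    seed: int = 0
    amplitude: float = 0.0  # Gaussian coordinate noise, Å

    def __post_init__(self):
        if self.amplitude < 0:
            raise FixtureError("noise amplitude must be >= 0")


def _residue_from_template(
    base: str,
    index: int,
    rotation: np.ndarray,
    translation: np.ndarray,
    helix: HelixParams,
    pre_shift: np.ndarray | None = None,
) -> ResidueRecord:
    template = residue_template(base, helix)
    atoms = []
    for name, xyz in template.items():
        pos = xyz + pre_shift if pre_shift is not None else xyz
        atoms.append(AtomRecord(name, name[0], rotation @ pos + translation))
    return ResidueRecord(base, base, atoms, index)


def _rz(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _frame(point: np.ndarray, tangent: np.ndarray, outward: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation+translation placing a residue with its C1' on ``point``,
    base normal along ``tangent`` and base edge extending along ``outward``."""
    zf = tangent / np.linalg.norm(tangent)
    yf = -(outward - np.dot(outward, zf) * zf)
    yf /= np.linalg.norm(yf)
    xf = np.cross(yf, zf)
    rot = np.column_stack([xf, yf, zf])
    c1 = residue_template("A")["C1'"]  # C1' is base-independent
    return rot, point - rot @ c1


def _check_complementary(sequence: str, pairs) -> None:
    for i, j in pairs:
        bi, bj = sequence[i - 1], sequence[j - 1]
        if bj not in COMPLEMENT.get(bi, ()):
            raise FixtureError(
                f"pair ({i},{j}) {bi}-{bj} is not AU/GC/GU; ideal helix "
                "geometry requires complementary strands"
            )


def _place_pair(
    residues: dict[int, ResidueRecord],
    i: int, j: int, base_i: str, base_j: str,
    step: int, slot_x: float, helix: HelixParams,
) -> None:
    """Place one pair at helical step ``step`` on the given slot."""
    tau = math.radians(helix.twist_deg)
    shift = np.array([slot_x, 0.0, step * helix.rise])
    rot1 = _rz(step * tau)
    wobble = {base_i, base_j} == {"G", "U"}
    pre1 = -WOBBLE_SHIFT if (wobble and base_i == "U") else None
    pre2 = -WOBBLE_SHIFT if (wobble and base_j == "U") else None
    residues[i] = _residue_from_template(base_i, i, rot1, shift, helix, pre1)
    residues[j] = _residue_from_template(base_j, j, rot1 @ MATE_TRANSFORM, shift, helix, pre2)


def build_ideal_helix(
    seq5: str, seq3: str, helix: HelixParams | None = None, source_id: str = "HELIX"
) -> RnaChain:
    """Free-standing ideal duplex; ``seq5`` pairs with ``seq3`` (both 5'->3').

    The chain lists the first strand followed by the second strand in
    *reversed* order, so paired residues sit at a constant index offset of
    n; this keeps every constructed pair non-adjacent and hence visible to
    the annotator.  The object is a detection fixture, not a folded chain.
    """
    helix = helix or HelixParams()
    if len(seq5) != len(seq3):
        raise FixtureError("duplex strands must have equal length")
    n = len(seq5)
    rev3 = seq3[::-1]
    _check_complementary(seq5 + rev3, [(k, n + k) for k in range(1, n + 1)])
    residues: dict[int, ResidueRecord] = {}
    for k in range(1, n + 1):
        _place_pair(residues, k, n + k, seq5[k - 1], rev3[k - 1], k - 1, 0.0, helix)
    return RnaChain(source_id, "A", [residues[k] for k in sorted(residues)])


def _coil_hairpin(
    residues: dict[int, ResidueRecord],
    run: tuple[int, int], sequence: str, stem: Stem, slot_x: float,
    helix: HelixParams,
) -> None:
    """Place a hairpin loop on a helical coil above its closing stem."""
    s, e = run
    n = e - s + 1
    top = len(stem) - 1
    tau = math.radians(helix.twist_deg)
    c1 = residue_template("A")["C1'"]
    anchor = _rz(top * tau) @ c1
    az0 = math.atan2(anchor[1], anchor[0]) + 0.5
    per_rad = math.hypot(COIL_RADIUS, COIL_PITCH / (2 * math.pi))
    sweep = (n + 1) * LOOP_SPACING / per_rad
    z0 = top * helix.rise + COIL_CLEARANCE
    for k in range(1, n + 1):
        theta = az0 + sweep * k / (n + 1)
        point = np.array([
            slot_x + COIL_RADIUS * math.cos(theta),
            COIL_RADIUS * math.sin(theta),
            z0 + (theta - az0) / (2 * math.pi) * COIL_PITCH,
        ])
        tangent = np.array([
            -COIL_RADIUS * math.sin(theta),
            COIL_RADIUS * math.cos(theta),
            COIL_PITCH / (2 * math.pi),
        ])
        outward = np.array([math.cos(theta), math.sin(theta), 0.0])
        rot, trans = _frame(point, tangent, outward)
        idx = s + k - 1
        residues[idx] = _residue_from_template(sequence[idx - 1], idx, rot, trans, helix)


def _park_run(
    residues: dict[int, ResidueRecord],
    run: tuple[int, int], sequence: str, row: int, helix: HelixParams,
) -> None:
    """Place an unpaired segment as a straight row in the strand region."""
    s, e = run
    x = PARK_X - PARK_PITCH * row
    tangent = np.array([0.0, 1.0, 0.0])
    outward = np.array([-1.0, 0.0, 0.0])
    for k, idx in enumerate(range(s, e + 1)):
        point = np.array([x, k * LOOP_SPACING, 0.0])
        rot, trans = _frame(point, tangent, outward)
        residues[idx] = _residue_from_template(sequence[idx - 1], idx, rot, trans, helix)


def build_toy_rna(
    spec: FixtureSpec, helix: HelixParams | None = None, source_id: str = "TOY"
) -> tuple[RnaChain, SecondaryStructure]:
    """Build a full heavy-atom chain realizing ``spec`` exactly.

    Returns the chain together with the ground-truth secondary structure.
    The structure must be crossing-free and all paired bases complementary.
    """
    helix = helix or HelixParams()
    ss = parse_dotbracket(spec.structure, spec.sequence)
    if not ss.is_nested():
        raise FixtureError("fixture structures must be crossing-free")
    _check_complementary(spec.sequence, ss.pair_tuples)
    stems = find_stems(ss)
    partner = ss.partner_map()
    residues: dict[int, ResidueRecord] = {}

    # stems on grid slots, depth-first order
    slot_of: dict[int, float] = {}
    counter = 0

    def assign(node):
        nonlocal counter
        for child in node.children:
            slot_of[id(child.stem)] = counter * GRID_SPACING
            counter += 1
            assign(child)

    root = _build_tree(stems)
    assign(root)
    stem_at_inner = {s.inner: s for s in stems}
    for stem in stems:
        slot = slot_of[id(stem)]
        for t, (i, j) in enumerate(stem.pairs):
            _place_pair(residues, i, j, spec.sequence[i - 1], spec.sequence[j - 1],
                        t, slot, helix)

    # unpaired runs: hairpins coil above their stem, the rest is parked
    row = 0
    idx = 1
    n = len(ss)
    while idx <= n:
        if idx in partner:
            idx += 1
            continue
        end = idx
        while end + 1 <= n and (end + 1) not in partner:
            end += 1
        closing = stem_at_inner.get((idx - 1, end + 1)) if idx > 1 else None
        if closing is not None and partner.get(idx - 1) == end + 1:
            _coil_hairpin(residues, (idx, end), spec.sequence, closing,
                          slot_of[id(closing)], helix)
        else:
            _park_run(residues, (idx, end), spec.sequence, row, helix)
            row += 1
        idx = end + 1

    chain = RnaChain(source_id, "A", [residues[k] for k in sorted(residues)])
    if spec.amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        for res in chain.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, spec.amplitude, 3)
    return chain, ss


def corrupt_fixture(chain: RnaChain, action: str, **kwargs) -> RnaChain:
    """Introduce one engineered defect; everything else is untouched.

    Actions: ``truncate_residue(index, n_atoms=8)`` keeps only the first
    ``n_atoms`` atoms of one residue; ``duplicate_chain(chain_id='B')``
    returns an identical copy under another chain id; ``displace_strand
    (start, end, offset=(20,0,0))`` rigidly translates an index range.
    """
    out = chain.copy()
    if action == "truncate_residue":
        index = kwargs["index"]
        n_atoms = kwargs.get("n_atoms", 8)
        res = out.residue(index)
        res.atoms = res.atoms[:n_atoms]
    elif action == "duplicate_chain":
        out.chain_id = kwargs.get("chain_id", "B")
    elif action == "displace_strand":
        start, end = kwargs["start"], kwargs["end"]
        offset = np.asarray(kwargs.get("offset", (20.0, 0.0, 0.0)), dtype=float)
        for res in out.residues:
            if start <= res.index <= end:
                for atom in res.atoms:
                    atom.position = atom.position + offset
    else:
        raise FixtureError(f"unknown corruption action {action!r}")
    return out


def random_fixture_spec(rng: np.random.Generator, length: int, seed: int = 0,
                        amplitude: float = 0.0) -> FixtureSpec:
    """Random nested structure of the given length plus a compatible sequence.

    Hairpin loops have at least 3 nt; stems are 1-6 pairs (single-pair stems
    included so both library schemes are exercised); junctions and tails
    appear for longer chains.
    """
    structure = _random_interior(rng, length, exterior=True)
    sequence = _sequence_for(rng, structure)
    return FixtureSpec(sequence, structure, seed=seed, amplitude=amplitude)


_PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


def _sequence_for(rng: np.random.Generator, structure: str) -> str:
    ss_pairs = parse_dotbracket(structure, "A" * len(structure)).pair_tuples
    seq = [None] * len(structure)
    for i, j in sorted(ss_pairs):
        bi, bj = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
        seq[i - 1], seq[j - 1] = bi, bj
    for k in range(len(seq)):
        if seq[k] is None:
            seq[k] = "ACGU"[rng.integers(4)]
    return "".join(seq)


def _random_helix_unit(rng: np.random.Generator, n: int) -> str:
    """One helix (possibly branching inside) occupying exactly n residues."""
    k_max = (n - 3) // 2
    k = int(rng.integers(1, min(6, k_max) + 1))
    return "(" * k + _random_interior(rng, n - 2 * k, exterior=False) + ")" * k


def _random_interior(rng: np.random.Generator, n: int, exterior: bool) -> str:
    """Loop content of n residues: dots and zero or more child helices."""
    min_helix = 5  # 1 pair + 3-nt hairpin
    if n < min_helix or rng.random() < (0.15 if n >= 12 else 0.4):
        return "." * n
    # decide children count by available room
    max_children = min(3, n // min_helix)
    n_children = int(rng.integers(1, max_children + 1))
    if not exterior and n_children == 1 and rng.random() < 0.5 and n >= min_helix:
        # pure interior helix continuation (makes bulges/internal loops)
        left = int(rng.integers(0, min(4, n - min_helix) + 1))
        right = int(rng.integers(0, min(4, n - min_helix - left) + 1))
        return "." * left + _random_helix_unit(rng, n - left - right) + "." * right
    sizes = []
    remaining = n
    for c in range(n_children):
        hi = remaining - min_helix * (n_children - c - 1)
        size = int(rng.integers(min_helix, hi + 1)) if c < n_children - 1 else 0
        sizes.append(size)
        remaining -= size
    sizes[-1] = remaining
    parts = []
    for size in sizes:
        gap = int(rng.integers(0, min(3, max(0, size - min_helix)) + 1))
        if size - gap >= min_helix:
            parts.append("." * gap + _random_helix_unit(rng, size - gap))
        else:
            parts.append("." * size)
    return "".join(parts)
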