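"""Idealized nucleotide geometry and residue chemistry tables.

The four ribonucleotides are described in a *pair reference frame*: the mean
base plane is z = 0, the pseudo-dyad of a Watson-Crick pair is the x axis,
and the paired mate of a residue is obtained by rotating 180 deg about x
(``MATE_TRANSFORM``).  Base-ring coordinates are standard planar ring
geometry; the shared ribose is an idealized C3'-endo-like sugar.  The
backbone atoms C5', O5', P, OP1, OP2 are derived at import time by a small
deterministic distance-geometry relaxation so that, when residues are
stacked with the default helical twist and rise, the inter-residue
O3'(k)-P(k+1) distance closes to a bonded 1.6 A.

These templates serve three purposes: the synthetic-fixture generator, the
completion of partially observed residues ("grafting"), and base swaps when
a template sequence is mutated onto a target sequence.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .config import HelixParams

BASES = ("A", "C", "G", "U")
PURINES = frozenset({"A", "G"})
STANDARD_PAIRS = frozenset({frozenset("AU"), frozenset("GC"), frozenset("GU")})

#: Watson-Crick / wobble complement sets used by the fixture generator.
COMPLEMENT = {"A": {"U"}, "U": {"A", "G"}, "G": {"C", "U"}, "C": {"G"}}

#: glycosidic nitrogen by base class
GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: ring atoms, in cyclic order (used for centroid, plane fit and handedness)
BASE_RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: polar heavy atoms on the pairing edges, probed for hydrogen-bond contacts
POLAR_EDGE_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}

# planar base coordinates (x, y) in the pair reference frame, z = 0
_BASE_XY = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053),
    },
}

# shared ribose, fixed part.  O3' points along +z (the 3' direction of a
# strand ascending the helix axis).
_SUGAR_FIXED = {
    "C1'": (-2.55, 5.10, 0.00),
    "O4'": (-3.65, 5.60, -0.85),
    "C4'": (-4.75, 5.25, 0.00),
    "C3'": (-4.40, 5.55, 1.45),
    "O3'": (-5.10, 4.85, 2.45),
    "C2'": (-3.05, 5.05, 1.35),
    "O2'": (-2.20, 6.05, 1.80),
}

#: rotate 180 deg about x: maps a residue frame onto its pair mate's frame
MATE_TRANSFORM = np.diag([1.0, -1.0, -1.0])

#: in-plane shear (applied to the U of a G-U pair) producing wobble geometry
WOBBLE_SHIFT = np.array([0.0, 1.2, 0.0])


def is_standard_pair(base_i: str, base_j: str) -> bool:
    """True iff the two bases form AU, GC or GU in either order."""
    return frozenset((base_i, base_j)) in STANDARD_PAIRS


def _relax_backbone(helix: HelixParams) -> dict[str, np.ndarray]:
    """Solve for C5', O5', P closing the backbone onto the previous residue.

    Targets: C4'-C5' 1.51, C5'-O5' 1.42, O5'-P 1.59 and P-O3'(prev) 1.60,
    where O3'(prev) is the fixed O3' mapped back one helical step.  A plain
    iterative projection onto the distance constraints converges in a few
    hundred sweeps and is fully deterministic.
    """
    tau = math.radians(helix.twist_deg)
    rz = np.array([
        [math.cos(tau), math.sin(tau), 0.0],
        [-math.sin(tau), math.cos(tau), 0.0],
        [0.0, 0.0, 1.0],
    ])  # Rz(-tau)
    c4 = np.array(_SUGAR_FIXED["C4'"])
    o3_prev = rz @ np.array(_SUGAR_FIXED["O3'"]) - np.array([0.0, 0.0, helix.rise])

    # initial guess: points along C4' -> O3'(prev) with out-of-line offsets
    axis = o3_prev - c4
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    pts = {
        "C5'": c4 + 0.25 * axis + 0.9 * perp,
        "O5'": c4 + 0.50 * axis + 1.2 * perp,
        "P": c4 + 0.75 * axis + 0.8 * perp,
    }
    bonds = [
        ("C4'", "C5'", 1.51), ("C5'", "O5'", 1.42),
        ("O5'", "P", 1.59), ("P", "O3'prev", 1.60),
    ]
    anchors = {"C4'": c4, "O3'prev": o3_prev}

    def pos(name):
        return anchors[name] if name in anchors else pts[name]

    for _ in range(400):
        for a, b, d0 in bonds:
            pa, pb = pos(a), pos(b)
            delta = pb - pa
            dist = np.linalg.norm(delta)
            corr = (dist - d0) / dist * delta
            if a in anchors:
                pts[b] = pb - corr
            elif b in anchors:
                pts[a] = pa + corr
            else:
                pts[a] = pa + 0.5 * corr
                pts[b] = pb - 0.5 * corr

    p = pts["P"]
    u1 = (pts["O5'"] - p) / np.linalg.norm(pts["O5'"] - p)
    u2 = (o3_prev - p) / np.linalg.norm(o3_prev - p)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    side = np.cross(u1, u2)
    side /= np.linalg.norm(side)
    op1 = p + 1.48 * (bisector + 1.1 * side) / np.linalg.norm(bisector + 1.1 * side)
    op2 = p + 1.48 * (bisector - 1.1 * side) / np.linalg.norm(bisector - 1.1 * side)
    return {
        "C5'": pts["C5'"], "O5'": pts["O5'"], "P": p, "OP1": op1, "OP2": op2,
    }


@lru_cache(maxsize=None)
def _sugar_template(twist_deg: float, rise: float) -> dict[str, np.ndarray]:
    derived = _relax_backbone(HelixParams(twist_deg=twist_deg, rise=rise))
    sugar = {k: np.array(v) for k, v in _SUGAR_FIXED.items()}
    sugar.update(derived)
    return sugar


def residue_template(base: str, helix: HelixParams | None = None) -> dict[str, np.ndarray]:
    """Full heavy-atom template of one ribonucleotide in the pair frame.

    Returns a fresh ``{atom name: xyz}`` mapping (safe to mutate).
    """
    if base not in BASES:
        raise KeyError(f"not a standard base: {base!r}")
    helix = helix or HelixParams()
    out = {k: v.copy() for k, v in _sugar_template(helix.twist_deg, helix.rise).items()}
    for name, (x, y) in _BASE_XY[base].items():
        out[name] = np.array([x, y, 0.0])
    return out


#: names of the heavy atoms a complete residue of each base must carry
EXPECTED_HEAVY_ATOMS = {
    base: frozenset(_SUGAR_FIXED) | {"C5'", "O5'", "P", "OP1", "OP2"} | frozenset(_BASE_XY[base])
    for base in BASES
}

#: sugar/backbone atom names shared by all four bases (used for base swaps)
BACKBONE_ATOMS = frozenset(_SUGAR_FIXED) | {"C5'", "O5'", "P", "OP1", "OP2"}

# Curated parent-base lookup for modified nucleotides, keyed by the deposited
# three-letter (or one/two-letter) chemical component id.  Derived once from
# the public chemical component dictionary's parent annotations; unknown
# components map to None at the call site.
MODIFIED_PARENT = {
    # standard codes map to themselves
    "A": "A", "C": "C", "G": "G", "U": "U",
    # common adenosine modifications
    "1MA": "A", "2MA": "A", "MA6": "A", "6MA": "A", "6MZ": "A", "A2M": "A",
    "AET": "A", "MIA": "A", "T6A": "A", "RIA": "A", "AP7": "A", "A23": "A",
    "A44": "A", "PPU": "A", "A3P": "A", "12A": "A", "2MZ": "A", "31M": "A",
    # cytidine
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "CBV": "C", "CCC": "C",
    "C43": "C", "5IC": "C", "1SC": "C", "RSP": "C", "S4C": "C", "C31": "C",
    # guanosine
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "YG": "G",
    "YYG": "G", "G7M": "G", "O2G": "G", "QUO": "G", "23G": "G", "G46": "G",
    "GDP": "G", "GTP": "G", "5GP": "G", "I": "G", "IG": "G", "XUG": "G",
    # uridine
    "PSU": "U", "5MU": "U", "H2U": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "5BU": "U", "DHU": "U", "U8U": "U", "3MU": "U", "70U": "U", "UD5": "U",
    "SSU": "U", "S4U": "U", "MNU": "U", "2MU": "U", "U34": "U", "U36": "U",
    "RUS": "U", "FHU": "U", "5FU": "U",
}
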