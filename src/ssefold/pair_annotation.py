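"""Geometric base-pair annotation from 3D coordinates.

Each base gets a :class:`BaseFrame` (ring centroid, best-fit plane normal,
glycosidic nitrogen).  A candidate pair (i, j), i+1 < j, is emitted when

* the ring-centroid distance is within a prefilter radius,
* the C1'-C1' distance is within the pairing window,
* the base planes are nearly parallel or anti-parallel,
* the "rise" between the bases (centroid displacement projected on the
  mean normal) is small, and
* at least one polar heavy atom of one pairing edge contacts the other
  edge within hydrogen-bonding distance.

Non-standard base combinations are retained on purpose; downstream
conflict resolution decides among residues claimed by several partners.
Thresholds live in :class:`ssefold.config.AnnotationParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .chem import BASE_RING_ATOMS, GLYCOSIDIC_ATOM, POLAR_EDGE_ATOMS
from .config import AnnotationParams
from .errors import AnnotationError, InputError
from .geometry import fit_plane_normal
from .model import ResidueRecord, RnaChain
from .secondary_structure import (
    BasePair,
    SecondaryStructure,
    make_pair,
    remove_crossing_pairs,
    resolve_pair_conflicts,
)


@dataclass(frozen=True)
class BaseFrame:
    """Base-plane frame of one residue."""

    origin: np.ndarray          # ring-atom centroid, Å
    normal: np.ndarray          # unit base-plane normal
    glycosidic_atom: np.ndarray  # N9 (purine) or N1 (pyrimidine) position


def base_frame(residue: ResidueRecord) -> BaseFrame:
    """Compute the base frame; raises if ring atoms are missing."""
    base = residue.parent_base
    if base is None:
        raise AnnotationError(f"residue {residue.index} has no parent base")
    ring = BASE_RING_ATOMS[base]
    try:
        pts = residue.coords(ring)
        glyco = residue.coords([GLYCOSIDIC_ATOM[base]])[0]
    except KeyError as exc:
        raise AnnotationError(str(exc)) from exc
    return BaseFrame(pts.mean(axis=0), fit_plane_normal(pts), glyco)


def _pair_geometry(
    ri: ResidueRecord, fi: BaseFrame, rj: ResidueRecord, fj: BaseFrame,
    params: AnnotationParams,
) -> float | None:
    """Geometry score if (i, j) satisfies all pairing criteria, else None."""
    delta = fj.origin - fi.origin
    dist = float(np.linalg.norm(delta))
    if dist > params.origin_cutoff:
        return None
    ci, cj = ri.atom("C1'"), rj.atom("C1'")
    if ci is None or cj is None:
        return None
    c1c1 = float(np.linalg.norm(cj.position - ci.position))
    if c1c1 > params.c1_cutoff:
        return None
    cosang = float(np.clip(np.dot(fi.normal, fj.normal), -1.0, 1.0))
    angle = math.degrees(math.acos(abs(cosang)))  # folded to [0, 90]
    if angle > params.plane_angle_deg:
        return None
    nj = fj.normal if cosang >= 0 else -fj.normal
    mean_normal = fi.normal + nj
    mean_normal /= np.linalg.norm(mean_normal)
    vertical = abs(float(np.dot(delta, mean_normal)))
    if vertical > params.vertical_cutoff:
        return None
    pi = ri.coords(POLAR_EDGE_ATOMS[ri.parent_base])
    pj = rj.coords(POLAR_EDGE_ATOMS[rj.parent_base])
    hmin = float(np.sqrt(((pi[:, None, :] - pj[None, :, :]) ** 2).sum(-1).min()))
    if hmin > params.hbond_cutoff:
        return None
    # equal-weight sum of normalized criterion margins; used only to break
    # ties during conflict resolution
    return (
        (1.0 - c1c1 / params.c1_cutoff)
        + (1.0 - angle / params.plane_angle_deg)
        + (1.0 - vertical / params.vertical_cutoff)
        + (1.0 - hmin / params.hbond_cutoff)
    )


def detect_base_pairs(
    chain: RnaChain, params: AnnotationParams | None = None
) -> list[tuple[BasePair, float]]:
    """All geometric pair candidates with their geometry scores.

    Residues missing ring atoms are skipped (sanitized chains have none).
    """
    params = params or AnnotationParams()
    frames: dict[int, BaseFrame] = {}
    for res in chain.residues:
        try:
            frames[res.index] = base_frame(res)
        except AnnotationError:
            continue
    indices = sorted(frames)
    if len(indices) < 2:
        return []
    origins = np.array([frames[i].origin for i in indices])
    tree = cKDTree(origins)
    sequence = chain.sequence
    out: list[tuple[BasePair, float]] = []
    for a, b in sorted(tree.query_pairs(params.origin_cutoff)):
        i, j = indices[a], indices[b]
        if i + 1 >= j:  # no self or adjacent-residue pairs
            continue
        score = _pair_geometry(
            chain.residue(i), frames[i], chain.residue(j), frames[j], params
        )
        if score is not None:
            out.append((make_pair(i, j, sequence), score))
    return out


def derive_secondary_structure(
    chain: RnaChain, params: AnnotationParams | None = None
) -> SecondaryStructure:
    """Detect pairs, resolve conflicts, drop crossings; attach to the chain.

    The crossing (pseudoknot) pairs removed in the last step are stored on
    ``chain.removed_crossing_pairs``.
    """
    candidates = detect_base_pairs(chain, params)
    resolved = resolve_pair_conflicts(candidates, chain.sequence)
    nested, removed = remove_crossing_pairs(resolved)
    chain.removed_crossing_pairs = removed
    chain.secondary_structure = nested
    return nested


def is_library_eligible(chain: RnaChain) -> bool:
    """Chains whose derived structure has no pairs cannot contribute SSEs."""
    ss = chain.secondary_structure
    return ss is not None and len(ss.pairs) > 0


def read_pair_file(path: str | Path, sequence: str) -> list[tuple[BasePair, float]]:
    """Import an externally produced base-pair list.

    Format: one pair per line, two whitespace-separated 1-based indices;
    ``#`` comments and blank lines are ignored.  Scores default to 0 so the
    ranked conflict criteria alone decide among conflicting imports.
    """
    out: list[tuple[BasePair, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected two indices, got {body!r}")
        i, j = int(parts[0]), int(parts[1])
        if not (1 <= i <= len(sequence) and 1 <= j <= len(sequence)):
            raise InputError(f"{path}:{lineno}: index out of range")
        out.append((make_pair(i, j, sequence), 0.0))
    return out
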