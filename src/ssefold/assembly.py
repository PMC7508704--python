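"""Assembly of a target RNA from SSE templates, and its refinement.

The target's secondary structure is decomposed into SSE records; for each
record the best library template (exact topology, highest sequence
identity) is chosen, the template sequence is mutated onto the target
sequence by idealized base grafting, and the fragments are chained
together by superposing the two shared flanking base pairs of every
stem-loop interface (anchor atoms P, C4', C1' and the glycosidic N of the
four shared residues).

The assembled model can then be

* relaxed by gradient descent on a soft-sphere clash energy with harmonic
  restraints that hold backbone connectivity and the flanking-pair
  interfaces (:func:`minimize_clashes`),
* refined by simulated-annealing Monte Carlo rigid-body moves of helical
  arms and loop segments (:func:`samc_optimize`), and
* summarized by k-medoids clustering of the sampled ensemble on the
  pairwise-RMSD matrix with one representative per cluster, ranked by
  energy (:func:`cluster_and_rank`).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chem import BACKBONE_ATOMS, GLYCOSIDIC_ATOM, PURINES, residue_template
from .config import EnergyParams, SamcParams
from .errors import AssemblyError, ComparisonError, MinimizationError
from .geometry import RigidTransform, rotation_about_axis, superpose
from .library import TemplateLibrary, search
from .model import AtomRecord, ResidueRecord, RnaChain
from .secondary_structure import SecondaryStructure
from .sse import SseRecord, decompose

logger = logging.getLogger(__name__)

ANCHOR_ATOMS = ("P", "C4'", "C1'")  # + glycosidic N per base


def _anchor_names(base: str) -> tuple[str, ...]:
    return ANCHOR_ATOMS + (GLYCOSIDIC_ATOM.get(base, "N1"),)


@dataclass(eq=False)
class AssemblyResult:
    """A full-coordinate model plus its provenance and score."""

    chain: RnaChain
    records: list[SseRecord] = field(repr=False, default_factory=list)
    template_provenance: dict[int, tuple[str, str]] = field(default_factory=dict)
    energy: float = 0.0
    rmsd_to_reference: Optional[float] = None

    def copy(self) -> "AssemblyResult":
        return AssemblyResult(
            self.chain.copy(), self.records, dict(self.template_provenance),
            self.energy, self.rmsd_to_reference,
        )

    def coordinates(self) -> np.ndarray:
        return np.concatenate([r.coords() for r in self.chain.residues])


def _graft_base(target_base: str, template_res: ResidueRecord) -> ResidueRecord:
    """Residue with the template's backbone and the target's base.

    If the bases agree the residue is copied verbatim; otherwise an
    idealized residue of the target base is superposed onto the template's
    sugar and contributes the base atoms.
    """
    if template_res.parent_base == target_base or template_res.original_name == target_base:
        out = template_res.copy()
        out.original_name = target_base
        out.parent_base = target_base
        return out
    shared = sorted(BACKBONE_ATOMS & template_res.atom_names())
    ideal = residue_template(target_base)
    transform, _ = superpose(
        np.array([ideal[n] for n in shared]), template_res.coords(shared)
    )
    atoms = [
        AtomRecord(a.name, a.element, a.position.copy())
        for a in template_res.atoms if a.name in BACKBONE_ATOMS
    ]
    for name in sorted(set(ideal) - BACKBONE_ATOMS):
        pos = transform.apply(ideal[name][None, :])[0]
        atoms.append(AtomRecord(name, name[0], pos))
    return ResidueRecord(target_base, target_base, atoms, template_res.index)


def _instantiate(
    template: SseRecord, target: SseRecord, sequence: str
) -> dict[int, ResidueRecord]:
    """Template residues re-keyed to target indices, bases grafted."""
    t_members = template.member_indices
    q_members = target.member_indices
    if len(t_members) != len(q_members):
        raise AssemblyError(
            f"template/target size mismatch for {target.dot_bracket!r}"
        )
    out: dict[int, ResidueRecord] = {}
    for t_idx, q_idx in zip(t_members, q_members):
        res = _graft_base(sequence[q_idx - 1], template.residues[t_idx])
        res.index = q_idx
        out[q_idx] = res
    return out


def assemble(
    sequence: str,
    ss: SecondaryStructure,
    library: TemplateLibrary,
    exclude_source: frozenset[str] | set[str] = frozenset(),
    scheme: Optional[str] = None,
    seed: int = 0,
) -> AssemblyResult:
    """Build a model for ``sequence``/``ss`` from library templates.

    Fragments are joined outward-in along the stem tree; an SSE without any
    matching template aborts with an error naming its pattern.  The
    procedure is deterministic.
    """
    del seed  # the assembly stage itself is deterministic; kept for symmetry
    scheme = scheme or library.scheme
    records = decompose(ss, scheme)
    chosen: list[SseRecord] = []
    for rec in records:
        hits = search(library, rec, exclude_source=exclude_source, max_hits=1)
        if not hits:
            raise AssemblyError(
                f"no template for {rec.sse_type} with pattern {rec.dot_bracket!r}"
            )
        chosen.append(hits[0])

    members = [set(rec.member_indices) for rec in records]
    placed: dict[int, ResidueRecord] = {}
    done = [False] * len(records)
    order = [0]
    done[0] = True
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for other in range(len(records)):
            if not done[other] and len(members[cur] & members[other]) >= 2:
                done[other] = True
                order.append(other)
                queue.append(other)
    if not all(done):
        raise AssemblyError("SSE graph is disconnected; cannot chain fragments")

    provenance: dict[int, tuple[str, str]] = {}
    for pos in order:
        rec, tmpl = records[pos], chosen[pos]
        frag = _instantiate(tmpl, rec, sequence)
        shared = sorted(set(frag) & set(placed))
        if shared:
            names = {idx: _anchor_names(sequence[idx - 1]) for idx in shared}
            moving = np.concatenate([frag[i].coords(names[i]) for i in shared])
            fixed = np.concatenate([placed[i].coords(names[i]) for i in shared])
            transform, _ = superpose(moving, fixed)
            for res in frag.values():
                for atom in res.atoms:
                    atom.position = transform.apply(atom.position[None, :])[0]
        for idx, res in frag.items():
            placed.setdefault(idx, res)
        provenance[pos] = (tmpl.source_id, tmpl.source_chain)

    n = len(sequence)
    missing = [i for i in range(1, n + 1) if i not in placed]
    if missing:
        raise AssemblyError(f"assembly left residues without coordinates: {missing}")
    chain = RnaChain("MODEL", "A", [placed[i] for i in range(1, n + 1)])
    chain.secondary_structure = ss
    result = AssemblyResult(chain, records, provenance)
    model = EnergyModel(result)
    result.energy = model.energy(model.coords0)
    return result


def result_from_chain(
    chain: RnaChain, ss: SecondaryStructure, scheme: str = "lib1"
) -> AssemblyResult:
    """Wrap an existing chain as an :class:`AssemblyResult`.

    Used when a model comes from disk: the SSE records (needed for
    moveable elements and interface restraints) are re-derived from the
    given secondary structure and the chain's own coordinates.
    """
    from .sse import attach_coordinates

    records = decompose(ss, scheme)
    attach_coordinates(chain, records)
    chain.secondary_structure = ss
    result = AssemblyResult(chain, records, {})
    model = EnergyModel(result)
    result.energy = model.energy(model.coords0)
    return result


# ---------------------------------------------------------------------------
# energy model

class EnergyModel:
    """Soft-sphere clash energy plus harmonic connectivity restraints.

    Terms (all constants in :class:`EnergyParams`):

    * non-bonded repulsion ``k_clash * (d0 - d)^2`` for heavy-atom pairs
      closer than the contact distance ``d0`` (atoms of the same or of
      sequence-adjacent residues excluded);
    * harmonic O3'(i)-P(i+1) links toward the bonded length; links longer
      than the chain-break cutoff at setup time are held at their current
      length instead of being pulled closed;
    * harmonic pair-distance restraints among the anchor atoms of every
      flanking base pair, holding the stem-loop interfaces as assembled.
    """

    def __init__(self, result: AssemblyResult, params: EnergyParams | None = None):
        self.params = params or EnergyParams()
        chain = result.chain
        coords, residue_of, index_of = [], [], {}
        for res in chain.residues:
            for atom in res.atoms:
                index_of[(res.index, atom.name)] = len(coords)
                coords.append(atom.position)
                residue_of.append(res.index)
        self.coords0 = np.array(coords)
        self.residue_of = np.array(residue_of)
        self.index_of = index_of

        pairs, targets = [], []
        for res in chain.residues[:-1]:
            nxt = chain.residues[res.index]  # 0-based list; res.index is 1-based
            a = index_of.get((res.index, "O3'"))
            b = index_of.get((nxt.index, "P"))
            if a is None or b is None:
                continue
            current = float(np.linalg.norm(self.coords0[b] - self.coords0[a]))
            target = self.params.bond_length_o3p if current <= self.params.chain_break_cutoff else current
            pairs.append((a, b))
            targets.append(target)
        for rec in result.records:
            for bp in rec.flanking_pairs:
                names_i = _anchor_names(chain.residue(bp.i).parent_base or "A")
                names_j = _anchor_names(chain.residue(bp.j).parent_base or "A")
                for ni in names_i:
                    for nj in names_j:
                        a, b = index_of.get((bp.i, ni)), index_of.get((bp.j, nj))
                        if a is None or b is None:
                            continue
                        pairs.append((a, b))
                        targets.append(float(np.linalg.norm(self.coords0[b] - self.coords0[a])))
        self.restraint_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.restraint_targets = np.array(targets)

    def _clash_pairs(self, coords: np.ndarray) -> np.ndarray:
        tree = cKDTree(coords)
        raw = tree.query_pairs(self.params.contact_distance, output_type="ndarray")
        if len(raw) == 0:
            return raw.reshape(0, 2)
        keep = np.abs(self.residue_of[raw[:, 0]] - self.residue_of[raw[:, 1]]) > 1
        return raw[keep]

    def energy(self, coords: np.ndarray) -> float:
        e, _ = self.energy_and_gradient(coords, need_gradient=False)
        return e

    def clash_count(self, coords: np.ndarray) -> int:
        return len(self._clash_pairs(coords))

    def energy_and_gradient(
        self, coords: np.ndarray, need_gradient: bool = True
    ) -> tuple[float, Optional[np.ndarray]]:
        p = self.params
        energy = 0.0
        grad = np.zeros_like(coords) if need_gradient else None
        clashes = self._clash_pairs(coords)
        if len(clashes):
            delta = coords[clashes[:, 1]] - coords[clashes[:, 0]]
            dist = np.linalg.norm(delta, axis=1)
            dist = np.maximum(dist, 1e-8)
            gap = p.contact_distance - dist
            energy += p.k_clash * float(np.sum(gap ** 2))
            if need_gradient:
                f = (2.0 * p.k_clash * gap / dist)[:, None] * delta
                np.add.at(grad, clashes[:, 0], f)
                np.add.at(grad, clashes[:, 1], -f)
        if len(self.restraint_pairs):
            delta = coords[self.restraint_pairs[:, 1]] - coords[self.restraint_pairs[:, 0]]
            dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-8)
            diff = dist - self.restraint_targets
            energy += p.k_restraint * float(np.sum(diff ** 2))
            if need_gradient:
                f = (2.0 * p.k_restraint * diff / dist)[:, None] * delta
                np.add.at(grad, self.restraint_pairs[:, 0], -f)
                np.add.at(grad, self.restraint_pairs[:, 1], f)
        if not math.isfinite(energy):
            raise MinimizationError("non-finite energy")
        return energy, grad


Scorer = Callable[[np.ndarray], float]


def _set_coords(result: AssemblyResult, coords: np.ndarray) -> None:
    pos = 0
    for res in result.chain.residues:
        for atom in res.atoms:
            atom.position = coords[pos].copy()
            pos += 1


def minimize_clashes(
    result: AssemblyResult, params: EnergyParams | None = None
) -> AssemblyResult:
    """Gradient-based energy minimization (L-BFGS with analytic gradient).

    The line search only accepts descent steps, so the final energy never
    exceeds the initial one; termination is by gradient norm or iteration
    cap.  Raises :class:`MinimizationError` on non-finite energies.
    """
    from scipy.optimize import minimize as scipy_minimize

    params = params or EnergyParams()
    model = EnergyModel(result, params)
    x0 = model.coords0.ravel().copy()
    e0 = model.energy(model.coords0)

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        energy, grad = model.energy_and_gradient(x.reshape(-1, 3))
        return energy, grad.ravel()

    opt = scipy_minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": params.max_iter, "gtol": params.grad_tol},
    )
    coords = opt.x.reshape(-1, 3)
    energy = model.energy(coords)
    if energy > e0:  # defensive: keep the descent contract
        coords, energy = model.coords0.copy(), e0
    out = result.copy()
    _set_coords(out, coords)
    out.energy = energy
    return out


# ---------------------------------------------------------------------------
# moveable elements and SAMC

@dataclass(frozen=True)
class MoveableElement:
    """A rigid group (helical arm with its distal subtree, or a loop
    segment) with the pivot about which it may rotate."""

    residues: frozenset[int]
    pivot: np.ndarray
    axis: np.ndarray

    def __hash__(self):  # pragma: no cover - identity hash is fine
        return hash((self.residues, tuple(self.pivot)))


def moveable_elements(result: AssemblyResult) -> list[MoveableElement]:
    chain = result.chain
    elements: list[MoveableElement] = []

    def centroid(indices) -> np.ndarray:
        return np.mean([chain.residue(i).coords().mean(axis=0) for i in indices], axis=0)

    for rec in result.records:
        if rec.sse_type == "stem":
            outer_i, outer_j = rec.pairs[0].i, rec.pairs[0].j
            inner = rec.pairs[-1]
            arm = frozenset(range(outer_i, outer_j + 1))
            pivot = centroid([outer_i, outer_j])
            tip = centroid([inner.i, inner.j])
            axis = tip - pivot
            if np.linalg.norm(axis) < 1e-6:
                axis = np.array([0.0, 0.0, 1.0])
            elements.append(MoveableElement(arm, pivot, axis / np.linalg.norm(axis)))
        else:
            flank_members = {k for bp in rec.flanking_pairs for k in (bp.i, bp.j)}
            for a, b in rec.segments:
                seg = [k for k in range(a, b + 1) if k not in flank_members]
                if not seg:
                    continue
                pivot_res = seg[0] - 1 if seg[0] > 1 else seg[-1] + 1
                pivot = (
                    centroid([pivot_res])
                    if 1 <= pivot_res <= len(chain)
                    else centroid(seg)
                )
                axis = centroid([seg[-1]]) - centroid([seg[0]]) if len(seg) > 1 else np.array([0.0, 0.0, 1.0])
                if np.linalg.norm(axis) < 1e-6:
                    axis = np.array([0.0, 0.0, 1.0])
                elements.append(
                    MoveableElement(frozenset(seg), pivot, axis / np.linalg.norm(axis))
                )
    return elements


def _element_rows(model: EnergyModel, element: MoveableElement) -> np.ndarray:
    return np.flatnonzero(np.isin(model.residue_of, list(element.residues)))


def samc_optimize(
    result: AssemblyResult,
    n_steps: int = 5000,
    schedule: SamcParams | None = None,
    sample_every: int = 100,
    seed: int = 0,
    scorer: Optional[Scorer] = None,
    energy_params: EnergyParams | None = None,
) -> list[AssemblyResult]:
    """Simulated-annealing Monte Carlo over rigid-body moves.

    A randomly chosen moveable element is translated, rotated about a point
    or rotated about an axis; moves are accepted by the Metropolis rule at
    the current temperature, which cools geometrically.  Snapshots are
    taken every ``sample_every`` accepted moves; the best-energy structure
    is always part of the returned ensemble.  Fixed seed implies a
    reproducible trajectory.
    """
    schedule = schedule or SamcParams()
    model = EnergyModel(result, energy_params)
    score: Scorer = scorer if scorer is not None else model.energy
    elements = moveable_elements(result)
    if not elements:
        logger.warning("no moveable elements; returning the input structure")
        out = result.copy()
        return [out]
    rows = [_element_rows(model, el) for el in elements]
    rng = np.random.default_rng(seed)
    coords = model.coords0.copy()
    energy = float(score(coords))
    best_coords, best_energy = coords.copy(), energy
    temperature = schedule.t_start
    accepted = 0
    snapshots: list[tuple[np.ndarray, float]] = []
    max_rot = math.radians(schedule.max_rotation_deg)
    for step_no in range(1, n_steps + 1):
        k = int(rng.integers(len(elements)))
        element, idx = elements[k], rows[k]
        move = int(rng.integers(3))
        trial = coords.copy()
        if move == 0:  # translation
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            trial[idx] += rng.uniform(0, schedule.max_translation) * direction
        else:
            if move == 1:  # rotation about a random axis through the pivot
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
            else:  # rotation about the element's own axis
                axis = element.axis
            angle = rng.uniform(-max_rot, max_rot)
            rot = rotation_about_axis(axis, angle)
            trial[idx] = (trial[idx] - element.pivot) @ rot.T + element.pivot
        e_trial = float(score(trial))
        delta = e_trial - energy
        if delta <= 0 or rng.random() < math.exp(-delta / max(temperature, 1e-12)):
            coords, energy = trial, e_trial
            accepted += 1
            if energy < best_energy:
                best_coords, best_energy = coords.copy(), energy
            if accepted % sample_every == 0:
                snapshots.append((coords.copy(), energy))
        if step_no % schedule.cool_every == 0:
            temperature = max(schedule.t_end, temperature * schedule.cooling)
    if not snapshots or snapshots[-1][1] > best_energy:
        snapshots.append((best_coords, best_energy))
    ensemble = []
    for coords_k, energy_k in snapshots:
        out = result.copy()
        _set_coords(out, coords_k)
        out.energy = energy_k
        ensemble.append(out)
    return ensemble


# ---------------------------------------------------------------------------
# comparison and clustering

def rmsd_to_reference(
    result: AssemblyResult | RnaChain,
    reference: RnaChain,
    atom_names: Optional[Sequence[str]] = None,
) -> float:
    """RMSD after optimal superposition over shared heavy atoms."""
    chain = result.chain if isinstance(result, AssemblyResult) else result
    if len(chain) != len(reference):
        raise ComparisonError(
            f"residue count mismatch: {len(chain)} vs {len(reference)}"
        )
    a, b = [], []
    for res, ref in zip(chain.residues, reference.residues):
        names = [x.name for x in res.atoms if ref.atom(x.name) is not None]
        if atom_names is not None:
            names = [n for n in names if n in atom_names]
        a.extend(res.coords(names))
        b.extend(ref.coords(names))
    if len(a) < 3:
        raise ComparisonError("fewer than 3 shared atoms in the selection")
    _, value = superpose(np.array(a), np.array(b))
    return value


def pairwise_rmsd_matrix(ensemble: Sequence[AssemblyResult]) -> np.ndarray:
    n = len(ensemble)
    coords = [r.coordinates() for r in ensemble]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, value = superpose(coords[i], coords[j])
            out[i, j] = out[j, i] = value
    return out


def _assign(dist: np.ndarray, medoids: tuple[int, ...]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def _exact_medoids(dist: np.ndarray, k: int) -> tuple[int, ...]:
    n = len(dist)
    best, best_cost = None, math.inf
    for combo in itertools.combinations(range(n), k):
        cost = _assign(dist, combo)
        if cost < best_cost - 1e-12:
            best, best_cost = combo, cost
    return best


def _pam_medoids(dist: np.ndarray, k: int) -> tuple[int, ...]:
    n = len(dist)
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:  # greedy farthest-point seeding
        gains = dist[:, medoids].min(axis=1)
        gains[medoids] = -1
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    improved = True
    while improved:
        improved = False
        cost = _assign(dist, tuple(medoids))
        for pos in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = sorted(medoids[:pos] + [cand] + medoids[pos + 1:])
                if _assign(dist, tuple(trial)) < cost - 1e-12:
                    medoids, cost, improved = trial, _assign(dist, tuple(trial)), True
    return tuple(medoids)


def cluster_and_rank(
    ensemble: Sequence[AssemblyResult], n_clusters: int
) -> list[AssemblyResult]:
    """Top-N representatives: k-medoids on the pairwise RMSD matrix.

    Small problems are solved exactly (all medoid subsets enumerated);
    larger ones by PAM iteration from a deterministic greedy seed.  The
    cluster medoids are returned ranked by energy, ascending.
    """
    n = len(ensemble)
    if n == 0:
        return []
    if n_clusters > n:
        logger.warning("ensemble of %d smaller than N=%d; reducing", n, n_clusters)
        n_clusters = n
    dist = pairwise_rmsd_matrix(ensemble)
    if math.comb(n, n_clusters) <= 20000:
        medoids = _exact_medoids(dist, n_clusters)
    else:
        medoids = _pam_medoids(dist, n_clusters)
    reps = [ensemble[m] for m in medoids]
    reps.sort(key=lambda r: r.energy)
    return reps
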