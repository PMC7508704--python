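"""Superposition, template assembly, relaxation, SAMC and clustering."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ssefold.assembly import (
    EnergyModel,
    assemble,
    cluster_and_rank,
    minimize_clashes,
    moveable_elements,
    pairwise_rmsd_matrix,
    result_from_chain,
    rmsd_to_reference,
    samc_optimize,
)
from ssefold.errors import AssemblyError, ComparisonError, GeometryError
from ssefold.fixtures import FixtureSpec, build_toy_rna
from ssefold.geometry import rotation_about_axis, superpose
from ssefold.library import build_library
from ssefold.pair_annotation import derive_secondary_structure
from ssefold.secondary_structure import parse_dotbracket


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        transform, rmsd = superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        rot = rotation_about_axis(np.array([1.0, -0.4, 2.0]), 0.77)
        shift = np.array([4.0, 5.0, -6.0])
        transform, rmsd = superpose(pts, pts @ rot.T + shift)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation, rot, atol=1e-9)
        assert np.isclose(np.linalg.det(transform.rotation), 1.0)

    def test_perturbed_point_matches_grid_search(self):
        """Kabsch minimum equals an independent brute-force search over
        rotations (scipy rotations on a fine grid + refinement)."""
        moving = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        fixed = moving.copy()
        fixed[3] += np.array([0.4, -0.2, 0.3])
        _, rmsd = superpose(moving, fixed)

        mc, fc = moving - moving.mean(0), fixed - fixed.mean(0)
        best = np.inf
        base = Rotation.identity()
        scale = 0.4
        for _ in range(8):  # coarse-to-fine random search around the best
            rot_rng = np.random.default_rng(7)
            for _ in range(3000):
                r = base * Rotation.from_rotvec(rot_rng.normal(0, scale, 3))
                val = np.sqrt(np.mean(np.sum((mc @ r.as_matrix().T - fc) ** 2, -1)))
                if val < best:
                    best, base = val, r
            scale /= 3
        assert abs(rmsd - best) < 1e-3

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _self_setup(seq, db, source="SRC1", scheme="lib2"):
    chain, _ = build_toy_rna(FixtureSpec(seq, db), source_id=source)
    derive_secondary_structure(chain)
    lib = build_library([chain], scheme)
    return chain, lib


class TestAssemble:
    def test_self_inclusion_reconstruction(self):
        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        assert rmsd_to_reference(result, chain) <= 0.1

    def test_junction_self_reconstruction(self):
        seq = "GGGG" + "AA" + "GGGG" + "AAAA" + "CCCC" + "A" + \
            "GGGG" + "AAAA" + "CCCC" + "AA" + "CCCC"
        db = "((((" + ".." + "((((" + "...." + "))))" + "." + \
            "((((" + "...." + "))))" + ".." + "))))"
        chain, lib = _self_setup(seq, db)
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        assert rmsd_to_reference(result, chain) <= 0.1

    def test_missing_template_is_an_error_naming_the_pattern(self):
        chain, lib = _self_setup("GGGGAAAACCCC", "((((....))))")
        other = parse_dotbracket("(((......)))", "GGGAAAAAACCC")
        with pytest.raises(AssemblyError) as err:
            assemble("GGGAAAAAACCC", other, lib)
        assert "((" in str(err.value)

    def test_deterministic(self):
        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        a = assemble(chain.sequence, chain.secondary_structure, lib, seed=5)
        b = assemble(chain.sequence, chain.secondary_structure, lib, seed=5)
        assert np.array_equal(a.coordinates(), b.coordinates())

    def test_self_exclusion_uses_other_source(self):
        donor, _ = _self_setup("GGGGACCACCCC", "((((....))))", source="DONOR")
        target, _ = _self_setup("GGGGAAAACCCC", "((((....))))", source="TARGT")
        lib = build_library([donor, target], "lib2")
        result = assemble(
            target.sequence, target.secondary_structure, lib,
            exclude_source={"TARGT"},
        )
        assert result.template_provenance
        assert all(src == "DONOR" for src, _ in result.template_provenance.values())

    def test_chimeric_grafting_keeps_full_atom_sets(self):
        from ssefold.chem import EXPECTED_HEAVY_ATOMS

        donor, _ = _self_setup("GGGGACCACCCC", "((((....))))", source="DONOR")
        lib = build_library([donor], "lib2")
        target_ss = parse_dotbracket("((((....))))", "GGGGAAAACCCC")
        result = assemble("GGGGAAAACCCC", target_ss, lib)
        assert result.chain.sequence == "GGGGAAAACCCC"
        for res in result.chain.residues:
            assert res.atom_names() == set(EXPECTED_HEAVY_ATOMS[res.parent_base])


def _clashed_two_arm():
    seq = "GGGG" + "AAAA" + "CCCC" + "AA" + "GGGG" + "AAAA" + "CCCC"
    db = "((((" + "...." + "))))" + ".." + "((((" + "...." + "))))"
    chain, lib = _self_setup(seq, db)
    result = assemble(chain.sequence, chain.secondary_structure, lib)
    for res in result.chain.residues:
        if 15 <= res.index <= 26:
            for atom in res.atoms:
                atom.position = atom.position + np.array([-36.0, 1.0, 1.0])
    model = EnergyModel(result)
    result.energy = model.energy(model.coords0)
    return result


class TestMinimizeClashes:
    def test_clash_free_input_left_nearly_unchanged(self):
        chain, lib = _self_setup("GGGGAAAACCCC", "((((....))))")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        relaxed = minimize_clashes(result)
        disp = np.abs(relaxed.coordinates() - result.coordinates()).max()
        assert disp < 0.05
        assert relaxed.energy <= result.energy

    def test_engineered_clash_resolved(self):
        result = _clashed_two_arm()
        relaxed = minimize_clashes(result)
        model = EnergyModel(relaxed)
        assert relaxed.energy < result.energy
        assert model.clash_count(relaxed.coordinates()) == 0

    def test_energy_never_increases(self):
        result = _clashed_two_arm()
        assert minimize_clashes(result).energy <= result.energy


class TestSamcOptimize:
    def test_zero_scorer_accepts_every_move(self):
        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        ensemble = samc_optimize(result, n_steps=200, sample_every=10, seed=1,
                                 scorer=lambda coords: 0.0)
        # acceptance rate 1 -> exactly n_steps/sample_every snapshots
        assert len(ensemble) == 20

    def test_degenerate_schedule_identical_structures(self):
        from ssefold.config import SamcParams

        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        frozen = SamcParams(t_start=1.0, t_end=1.0, max_translation=0.0,
                            max_rotation_deg=0.0)
        ensemble = samc_optimize(result, n_steps=100, schedule=frozen,
                                 sample_every=10, seed=2)
        for member in ensemble:
            assert np.allclose(member.coordinates(), result.coordinates())

    def test_downhill_direction_found(self):
        result = _clashed_two_arm()
        ensemble = samc_optimize(result, n_steps=800, sample_every=50, seed=3)
        assert min(r.energy for r in ensemble) < result.energy

    def test_same_seed_identical_ensembles(self):
        result = _clashed_two_arm()
        a = samc_optimize(result, n_steps=300, sample_every=25, seed=9)
        b = samc_optimize(result, n_steps=300, sample_every=25, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.coordinates(), y.coordinates())

    def test_single_rigid_sse_returns_input(self):
        chain, lib = _self_setup("GGGGGGAACCCCCC", "((((((..))))))")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        # restrict records to the stem only: no moveable loop segments
        result.records = [r for r in result.records if r.sse_type == "stem"]
        # the stem arm is the single element; drop it to force the warning path
        result.records = []
        ensemble = samc_optimize(result, n_steps=50, seed=0)
        assert len(ensemble) == 1
        assert np.allclose(ensemble[0].coordinates(), result.coordinates())


class TestMoveableElements:
    def test_arms_and_segments(self):
        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        elements = moveable_elements(result)
        arm = next(e for e in elements if len(e.residues) == 12)
        assert arm.residues == frozenset(range(3, 15))  # stem + hairpin
        assert any(e.residues == frozenset({1, 2}) for e in elements)  # 5' tail

    def test_moves_preserve_internal_geometry(self):
        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        before = result.coordinates()
        ensemble = samc_optimize(result, n_steps=50, sample_every=5, seed=4,
                                 scorer=lambda coords: 0.0)
        after = ensemble[-1].coordinates()
        stem_rows = []
        pos = 0
        for res in result.chain.residues:
            for _ in res.atoms:
                # stem residues move only as part of the rigid arm; the
                # hairpin segment is a separate element
                if res.index in (3, 4, 5, 6, 11, 12, 13, 14):
                    stem_rows.append(pos)
                pos += 1
        a, b = before[stem_rows], after[stem_rows]
        da = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=-1)
        db = np.linalg.norm(b[:, None, :] - b[None, :, :], axis=-1)
        assert np.allclose(da, db, atol=1e-9)


class TestClusterAndRank:
    def _ensemble_from(self, shifts, energies, jitter=None):
        chain, lib = _self_setup("GGGGAAAACCCC", "((((....))))")
        base = assemble(chain.sequence, chain.secondary_structure, lib)
        out = []
        for k, (shift, energy) in enumerate(zip(shifts, energies)):
            member = base.copy()
            for res in member.chain.residues:
                if res.index >= 9:  # deform one strand only: distinct shapes
                    for atom in res.atoms:
                        atom.position = atom.position + np.asarray(shift, dtype=float)
            member.energy = energy
            out.append(member)
        return out

    def test_planted_clusters_recovered(self, rng):
        centers = [(0, 0, 0), (18, 0, 0), (0, 18, 0)]
        shifts, energies = [], []
        for c_idx, center in enumerate(centers):
            for k in range(4):
                shifts.append(np.asarray(center) + rng.normal(0, 0.05, 3))
                energies.append(10.0 * c_idx + k)
        ensemble = self._ensemble_from(shifts, energies)
        reps = cluster_and_rank(ensemble, 3)
        dist = pairwise_rmsd_matrix(ensemble)
        rep_rows = [ensemble.index(r) for r in reps]
        # exactly one representative per planted group of four
        assert sorted(r // 4 for r in rep_rows) == [0, 1, 2]
        # ranked by energy ascending
        assert [r.energy for r in reps] == sorted(r.energy for r in reps)

    def test_single_cluster_is_global_medoid(self):
        shifts = [(0, 0, 0), (4, 0, 0), (8, 0, 0), (8.5, 0, 0)]
        ensemble = self._ensemble_from(shifts, [1, 2, 3, 4])
        dist = pairwise_rmsd_matrix(ensemble)
        expected = int(np.argmin(dist.sum(axis=1)))
        reps = cluster_and_rank(ensemble, 1)
        assert ensemble.index(reps[0]) == expected

    def test_n_equals_ensemble_size(self):
        shifts = [(0, 0, 0), (5, 0, 0), (10, 0, 0)]
        ensemble = self._ensemble_from(shifts, [3, 1, 2])
        reps = cluster_and_rank(ensemble, 3)
        assert {ensemble.index(r) for r in reps} == {0, 1, 2}

    def test_matches_brute_force_partitions(self, rng):
        """k-medoids objective equals exhaustive best-of-all-partitions."""
        for trial in range(5):
            shifts = [rng.uniform(0, 12, 3) for _ in range(6)]
            ensemble = self._ensemble_from(shifts, list(range(6)))
            dist = pairwise_rmsd_matrix(ensemble)
            k = 2 + trial % 2
            reps = cluster_and_rank(ensemble, k)
            medoids = sorted(ensemble.index(r) for r in reps)
            got_cost = dist[:, medoids].min(axis=1).sum()
            best_cost = min(
                sum(
                    min(dist[list(group)][:, m].sum() for m in group)
                    for group in partition
                )
                for partition in _partitions(range(6), k)
            )
            assert abs(got_cost - best_cost) < 1e-9

    def test_oversized_n_reduced(self):
        shifts = [(0, 0, 0), (5, 0, 0)]
        ensemble = self._ensemble_from(shifts, [1, 2])
        assert len(cluster_and_rank(ensemble, 5)) == 2


def _partitions(items, k):
    items = list(items)
    if not items:
        if k == 0:
            yield []
        return
    first, rest = items[0], items[1:]
    for partition in _partitions(rest, k):
        for idx in range(len(partition)):
            yield partition[:idx] + [partition[idx] + [first]] + partition[idx + 1:]
    for partition in _partitions(rest, k - 1):
        yield partition + [[first]]


class TestRmsdToReference:
    def test_self_zero(self, hairpin_chain):
        assert rmsd_to_reference(hairpin_chain, hairpin_chain) < 1e-12

    def test_rigid_copy_zero(self, hairpin_chain):
        moved = hairpin_chain.copy()
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 0.4)
        for res in moved.residues:
            for atom in res.atoms:
                atom.position = rot @ atom.position + np.array([3.0, 1.0, 2.0])
        assert rmsd_to_reference(moved, hairpin_chain) < 1e-9

    def test_selection_and_mismatch(self, hairpin_chain):
        moved = hairpin_chain.copy()
        value_all = rmsd_to_reference(moved, hairpin_chain)
        value_p = rmsd_to_reference(moved, hairpin_chain, atom_names=["P", "C1'", "C4'"])
        assert value_all < 1e-9 and value_p < 1e-9
        short = hairpin_chain.copy()
        short.residues = short.residues[:-1]
        with pytest.raises(ComparisonError):
            rmsd_to_reference(short, hairpin_chain)

    def test_agrees_with_independent_implementation(self, rng, hairpin_chain):
        """Cross-check against scipy's Wahba solver on perturbed copies."""
        noisy = hairpin_chain.copy()
        for res in noisy.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0, 0.5, 3)
        got = rmsd_to_reference(noisy, hairpin_chain)
        a = np.concatenate([r.coords() for r in noisy.residues])
        b = np.concatenate([r.coords() for r in hairpin_chain.residues])
        a_c, b_c = a - a.mean(0), b - b.mean(0)
        rot, _ = Rotation.align_vectors(b_c, a_c)
        expected = np.sqrt(np.mean(np.sum((a_c @ rot.as_matrix().T - b_c) ** 2, -1)))
        assert abs(got - expected) < 1e-9


class TestResultFromChain:
    def test_round_trip_through_disk_model(self, tmp_path):
        from ssefold.structure_io import read_structure, write_pdb

        chain, lib = _self_setup("AAGGGGAAAACCCCAA", "..((((....))))..")
        result = assemble(chain.sequence, chain.secondary_structure, lib)
        path = tmp_path / "model.pdb"
        write_pdb(path, [result.chain])
        back = read_structure(path)[0]
        wrapped = result_from_chain(back, chain.secondary_structure, "lib2")
        assert len(wrapped.records) == len(result.records)
        assert moveable_elements(wrapped)
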