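"""Stem finding, single-pair opening, and SSE decomposition."""

import pytest

from helpers_oracles import enumerate_nested, naive_classify
from ssefold.errors import DecompositionError
from ssefold.fixtures import FixtureSpec, build_toy_rna
from ssefold.secondary_structure import SecondaryStructure, parse_dotbracket
from ssefold.sse import (
    attach_coordinates,
    decompose,
    find_stems,
    open_single_pairs,
)


def _ss(text):
    return parse_dotbracket(text, "A" * len(text))


class TestFindStems:
    def test_single_stem(self):
        stems = find_stems(_ss("((((....))))"))
        assert len(stems) == 1 and len(stems[0]) == 4

    def test_two_stems(self):
        stems = find_stems(_ss("((..((...))..))"))
        assert [len(s) for s in stems] == [2, 2]

    def test_no_stems(self):
        assert find_stems(_ss("....")) == []

    def test_every_pair_in_exactly_one_stem(self):
        ss = _ss("..((((...((((....))))...((((....))))...))))..")
        stems = find_stems(ss)
        covered = [p for s in stems for p in s.pairs]
        assert sorted(covered) == sorted(ss.pair_tuples)


class TestOpenSinglePairs:
    def test_isolated_pairs_removed_merging_loops(self):
        # two isolated single pairs (10,40) and (35,39) plus a real stem;
        # opening both produces one large loop
        pairs = [(10, 40), (35, 39), (15, 25), (16, 24), (17, 23)]
        ss = SecondaryStructure("A" * 45, pairs)
        opened = open_single_pairs(ss)
        assert opened.pair_tuples == {(15, 25), (16, 24), (17, 23)}

    def test_multi_pair_stem_unchanged(self):
        ss = _ss("((((....))))")
        assert open_single_pairs(ss).pair_tuples == ss.pair_tuples

    def test_iterated_to_fixed_point(self):
        # (1,11) and (3,9) are nested single-pair stems; removing one
        # strands the other, so iteration empties the structure
        ss = _ss("(.(.....).)")
        assert open_single_pairs(ss).pair_tuples == set()


class TestDecompose:
    def test_hairpin_two_records(self):
        records = decompose(_ss("((((....))))"), "lib2")
        kinds = [r.sse_type for r in records]
        assert kinds == ["stem", "hairpin_loop"]
        hairpin = records[1]
        assert {p.as_tuple() for p in hairpin.flanking_pairs} == {(3, 10), (4, 9)}
        assert hairpin.dot_bracket == "((....))"
        assert hairpin.length == 8

    def test_three_way_junction_and_open_loop(self):
        ss = _ss("..((((...((((....))))...((((....))))...))))..")
        records = decompose(ss, "lib2")
        kinds = [r.sse_type for r in records]
        assert kinds.count("junction") == 1
        assert kinds.count("open_loop") == 1
        junction = next(r for r in records if r.sse_type == "junction")
        assert junction.n_incident_stems == 3
        open_loop = next(r for r in records if r.sse_type == "open_loop")
        covered = set(open_loop.member_indices)
        assert {1, 2, len(ss) - 1, len(ss)} <= covered  # both tails

    def test_zero_length_bulge_side(self):
        # helix-helix with a gap on exactly one strand
        ss = SecondaryStructure("A" * 14, [(1, 14), (2, 13), (3, 10), (4, 9)])
        records = decompose(ss, "lib2")
        kinds = [r.sse_type for r in records]
        assert kinds.count("bulge_loop") == 1
        bulge = next(r for r in records if r.sse_type == "bulge_loop")
        # the empty strand side shows as directly abutting brackets
        assert "((((" in bulge.dot_bracket.replace("&", "")

    def test_no_pairs_is_an_error(self):
        with pytest.raises(DecompositionError):
            decompose(_ss("......"), "lib2")
        with pytest.raises(DecompositionError):
            # a lone single pair opens away under lib1
            decompose(_ss("..(....).."), "lib1")

    def test_lib1_opens_before_identifying(self):
        ss = _ss("((((..(.....)..))))")
        lib2_kinds = sorted(r.sse_type for r in decompose(ss, "lib2"))
        lib1_kinds = sorted(r.sse_type for r in decompose(ss, "lib1"))
        assert lib2_kinds == ["hairpin_loop", "internal_loop", "stem", "stem"]
        assert lib1_kinds == ["hairpin_loop", "stem"]

    def test_lib_schemes_agree_without_single_pair_stems(self):
        for text in ["((((....))))", "((..((...))..))",
                     "..((((...((...))...((...))...))))"]:
            ss = _ss(text)
            r1 = [(r.sse_type, r.segments, r.dot_bracket) for r in decompose(ss, "lib1")]
            r2 = [(r.sse_type, r.segments, r.dot_bracket) for r in decompose(ss, "lib2")]
            assert r1 == r2

    def test_every_residue_covered_and_pairs_partitioned(self):
        for text in ["((((....))))", "..((((...((((....))))...((((....))))...)))).."]:
            ss = _ss(text)
            records = decompose(ss, "lib2")
            covered = set()
            for r in records:
                covered.update(r.member_indices)
            assert covered == set(range(1, len(ss) + 1))
            stem_pairs = [p.as_tuple() for r in records if r.sse_type == "stem"
                          for p in r.pairs]
            assert sorted(stem_pairs) == sorted(ss.pair_tuples)

    def test_classification_matches_naive_walker_small(self):
        """Spot-check against the independent stem-tree walker (the
        exhaustive sweep lives in the acceptance tests)."""
        for length in (6, 8, 10):
            for text in enumerate_nested(length):
                if "(" not in text:
                    continue
                assert _loop_summary(text) == sorted(naive_classify(text))


def _loop_summary(text):
    """(closing pair, type, incident stems) per loop record, sorted."""
    ss = _ss(text)
    out = []
    n = len(text)
    for rec in decompose(ss, "lib2"):
        if rec.sse_type == "stem":
            continue
        if rec.sse_type == "open_loop":
            out.append(((0, n + 1), rec.sse_type, rec.n_incident_stems))
        else:
            # the loop's closing stem contributes the min-i flank pair; its
            # stem-mate one step further in, when annexed too, is the true
            # inner closing pair
            flanks = {(p.i, p.j) for p in rec.flanking_pairs}
            a, b = min(flanks)
            closing = (a + 1, b - 1) if (a + 1, b - 1) in flanks else (a, b)
            out.append((closing, rec.sse_type, rec.n_incident_stems))
    return sorted(out)


class TestAttachCoordinates:
    def test_hairpin_record_has_eight_residues(self, hairpin_chain):
        records = decompose(hairpin_chain.secondary_structure, "lib2")
        attach_coordinates(hairpin_chain, records)
        hairpin = next(r for r in records if r.sse_type == "hairpin_loop")
        assert len(hairpin.residues) == 8

    def test_stem_record_has_2k_residues(self, hairpin_chain):
        records = decompose(hairpin_chain.secondary_structure, "lib2")
        attach_coordinates(hairpin_chain, records)
        stem = next(r for r in records if r.sse_type == "stem")
        assert len(stem.residues) == 2 * len(stem.pairs) == 8

    def test_coordinates_are_copies(self, hairpin_chain):
        records = decompose(hairpin_chain.secondary_structure, "lib2")
        attach_coordinates(hairpin_chain, records)
        rec = records[0]
        idx = rec.member_indices[0]
        rec.residues[idx].atoms[0].position += 99.0
        assert hairpin_chain.residue(idx).atoms[0].position[0] < 1e6
        assert not (
            rec.residues[idx].atoms[0].position
            == hairpin_chain.residue(idx).atoms[0].position
        ).all()

    def test_records_cover_chain(self):
        spec = FixtureSpec("AAGGGGAAAACCCCAA", "..((((....)))).." )
        chain, ss = build_toy_rna(spec)
        records = attach_coordinates(chain, decompose(ss, "lib2"))
        covered = set()
        for rec in records:
            covered.update(rec.residues)
        assert covered == set(range(1, len(chain) + 1))
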