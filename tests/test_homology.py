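"""Homology table: duplication records, PSV extraction, projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paracn.homology import (
    Duplication,
    HomologyTable,
    apply_psvs,
    build_table,
    extract_psvs,
    merge_multicopy,
    parse_cigar,
    read_paf,
    reverse_complement,
)
from paracn.intervals import GenomicInterval


def iv(start, end, contig="chr1", strand="+"):
    return GenomicInterval(contig, start, end, strand)


def make_dup(len1=600, start1=0, start2=5000, cigar=None, strand="+"):
    cigar = cigar or ((len1, "="),)
    from paracn.homology import _consumed

    len2 = _consumed(cigar, 2)
    return Duplication(
        iv(start1, start1 + len1), iv(start2, start2 + len2, strand=strand), cigar
    )


class TestDuplication:
    def test_cigar_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="CIGAR consumes"):
            Duplication(iv(0, 600), iv(5000, 5601), ((600, "="),))

    def test_similarity_counts_matching_columns(self):
        dup = make_dup(cigar=((10, "="), (2, "X"), (8, "="), (1, "D"), (580, "=")))
        assert dup.similarity == pytest.approx(598 / 601)

    def test_flip_is_involution(self):
        dup = make_dup(cigar=((10, "="), (1, "I"), (589, "=")))
        back = dup.flipped().flipped()
        assert back.region1 == dup.region1
        assert back.cigar == dup.cigar


class TestProjection:
    def test_all_match_offset_shift(self):
        dup = make_dup()
        assert dup.project(10) == 5010

    def test_deletion_cigar_walk(self):
        # 10=1D10=: one bp of region2 absent from region1
        dup = make_dup(len1=20, cigar=((10, "="), (1, "D"), (10, "=")))
        assert dup.project(15) == 5000 + 16
        assert dup.project(9) == 5009

    def test_insertion_maps_to_gap(self):
        dup = make_dup(len1=21, cigar=((10, "="), (1, "I"), (10, "=")))
        assert dup.project(10) is None
        assert dup.project_nearest(10) == 5009  # left-preferring

    def test_outside_region_raises(self):
        dup = make_dup()
        with pytest.raises(ValueError, match="outside"):
            dup.project(601)

    def test_minus_strand_reverses(self):
        dup = make_dup(len1=10, cigar=((10, "="),), strand="-")
        # first base of region1 pairs with last base of region2
        assert dup.project(0) == 5009
        assert dup.project(9) == 5000

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_projection_involution_on_match_columns(self, data):
        """Projecting then back-projecting any aligned position returns it."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        ops = []
        len1 = len2 = 0
        for _ in range(rng.integers(1, 8)):
            op = rng.choice(list("=XID"), p=[0.6, 0.2, 0.1, 0.1])
            n = int(rng.integers(1, 20))
            ops.append((n, op))
            len1 += n if op in "=XI" else 0
            len2 += n if op in "=XD" else 0
        if len1 == 0 or len2 == 0:
            return
        strand = data.draw(st.sampled_from(["+", "-"]))
        dup = Duplication(iv(100, 100 + len1), iv(9000, 9000 + len2, strand=strand), tuple(ops))
        for pos in range(100, 100 + len1):
            p2 = dup.project(pos)
            if p2 is not None:
                assert dup.project(p2, from_region=2) == pos


class TestExtractPsvs:
    def test_identical_copies_no_psvs(self):
        seq = "ACGT" * 150
        genome = {"chr1": "N" * 0 + seq + "X" * 4400 + seq}
        dup = Duplication(iv(0, 600), iv(5000, 5600), ((600, "="),))
        assert extract_psvs(dup, genome) == []

    def test_substitutions_and_deletion(self):
        # copies differing by 2 substitutions and one 1 bp deletion -> 3 PSVs
        s1 = "AAAAACAAAAGAAAAACAAAA"  # 21 bp; C@5, G@10, C@16
        # s2: sub 5 C->G, base 10 absent, sub s1[16] C->T
        s2 = "AAAAAGAAAAAAAAATAAAA"   # 20 bp
        genome = {"c": s1 + s2}
        cigar = parse_cigar("5=1X4=1I5=1X4=")
        dup = Duplication(iv(0, 21, "c"), iv(21, 41, "c"), cigar)
        psvs = extract_psvs(dup, genome)
        assert len(psvs) == 3
        assert [p.position.start for p in psvs] == [5, 9, 16]
        assert psvs[0].alleles == ["C", "G"]
        assert psvs[1].alleles == ["AG", "A"]  # left-anchored indel
        assert psvs[2].alleles == ["C", "T"]
        # round trip: applying alleles to seq1 reconstructs seq2
        assert apply_psvs(s1, dup, psvs) == s2

    def test_column_to_coordinate_projection(self):
        # substitution at alignment column 10, region1 start 1000
        s1 = "A" * 10 + "C" + "A" * 9
        s2 = "A" * 10 + "G" + "A" * 9
        genome = {"c": "T" * 1000 + s1 + "T" * 3980 + s2}
        dup = Duplication(
            iv(1000, 1020, "c"), iv(5000, 5020, "c"), parse_cigar("10=1X9=")
        )
        psvs = extract_psvs(dup, genome)
        assert len(psvs) == 1
        assert psvs[0].position.start == 1010
        assert psvs[0].copies[1].start == 5010

    def test_minus_strand_alleles(self):
        s1 = "AAAAACAAAA"
        s2 = reverse_complement("AAAAAGAAAA")
        genome = {"c": s1 + s2}
        dup = Duplication(
            iv(0, 10, "c"), iv(10, 20, "c", "-"), parse_cigar("5=1X4=")
        )
        psvs = extract_psvs(dup, genome)
        assert psvs[0].alleles == ["C", "G"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_roundtrip_random_alignments(self, seed):
        """PSV alleles applied to seq1 reconstruct seq2 for random =/X/I/D
        alignments (indels kept off the first column so anchoring works)."""
        rng = np.random.default_rng(seed)
        ops = [(int(rng.integers(2, 10)), "=")]
        for _ in range(rng.integers(1, 6)):
            ops.append((int(rng.integers(1, 4)), str(rng.choice(list("XID")))))
            ops.append((int(rng.integers(2, 10)), "="))
        from paracn.homology import _consumed

        len1, len2 = _consumed(ops, 1), _consumed(ops, 2)
        bases = "ACGT"
        s1 = []
        s2 = []
        for n, op in ops:
            for _ in range(n):
                if op == "=":
                    b = bases[rng.integers(4)]
                    s1.append(b)
                    s2.append(b)
                elif op == "X":
                    b = rng.integers(4)
                    s1.append(bases[b])
                    s2.append(bases[(b + 1 + rng.integers(3)) % 4])
                elif op == "I":
                    s1.append(bases[rng.integers(4)])
                else:
                    s2.append(bases[rng.integers(4)])
        s1, s2 = "".join(s1), "".join(s2)
        genome = {"c": s1 + s2}
        dup = Duplication(iv(0, len1, "c"), iv(len1, len1 + len2, "c"), tuple(ops))
        psvs = extract_psvs(dup, genome)
        assert apply_psvs(s1, dup, psvs) == s2
        starts = [p.position.start for p in psvs]
        assert starts == sorted(starts)


class TestBuildTable:
    def test_empty_input(self):
        assert len(build_table([])) == 0

    def test_threshold_pass(self):
        dup = make_dup(len1=600)
        table = build_table([dup], min_length=500, min_similarity=0.97)
        assert len(table) == 1
        assert table.duplications[0].similarity == 1.0

    @pytest.mark.parametrize(
        "len1,cigar,expect",
        [
            (499, None, 0),                               # too short
            (600, ((580, "="), (20, "X")), 0),            # similarity 0.967
            (600, ((585, "="), (15, "X")), 1),            # similarity 0.975
        ],
    )
    def test_threshold_filters(self, len1, cigar, expect):
        dup = make_dup(len1=len1, cigar=cigar or ((len1, "="),))
        assert len(build_table([dup], 500, 0.97)) == expect

    def test_tangled_flagging(self):
        """A segment in 11 pairwise records: all flagged, excluded from
        copy-number queries but retained in the table."""
        dups = [
            make_dup(len1=600, start1=0, start2=10000 + 2000 * i)
            for i in range(11)
        ]
        table = build_table(dups, 500, 0.9)
        assert all(d.tangled for d in table.duplications)
        assert table.overlapping(iv(0, 600)) == []
        assert len(table.overlapping(iv(0, 600), include_tangled=True)) == 11
        # 10 records sharing a segment stay usable
        table10 = build_table(dups[:10], 500, 0.9)
        assert not any(d.tangled for d in table10.duplications)

    def test_malformed_paf_record_rejected(self, caplog):
        good = "\t".join(
            ["chr1", "99999", "0", "600", "+", "chr1", "99999", "5000",
             "5600", "600", "600", "60", "cg:Z:600="]
        )
        bad = good.replace("cg:Z:600=", "cg:Z:999=")  # length mismatch
        dups = read_paf([good, bad])
        assert len(dups) == 1

    def test_serialization_roundtrip(self, tmp_path):
        dups = [
            make_dup(len1=600, cigar=((300, "="), (1, "X"), (299, "="))),
            make_dup(len1=900, start1=20000, start2=50000),
        ]
        table = build_table(dups, 500, 0.9, genome_id="toy")
        for name in ["t.bed", "t.bed.gz"]:
            path = str(tmp_path / name)
            table.save(path)
            loaded = HomologyTable.load(path)
            assert loaded.genome_id == "toy"
            assert len(loaded) == 2
            assert {d.to_row() for d in loaded.duplications} == {
                d.to_row() for d in table.duplications
            }


class TestMergeMulticopy:
    def test_single_pair(self):
        groups = merge_multicopy([make_dup()])
        assert len(groups) == 1
        assert len(groups[0]) == 2

    def test_transitive_closure_on_shared_copy(self):
        # A<->B and B<->C overlap on B -> one group {A, B, C}
        ab = make_dup(len1=600, start1=0, start2=10000)
        bc = make_dup(len1=600, start1=10100, start2=30000)
        groups = merge_multicopy([ab, bc])
        assert len(groups) == 1
        assert len(groups[0]) == 3

    def test_disjoint_pairs_stay_separate(self):
        ab = make_dup(start1=0, start2=10000)
        cd = make_dup(start1=50000, start2=90000)
        assert len(merge_multicopy([ab, cd])) == 2

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_group_count_matches_graph_components(self, seed):
        """Group count equals connected components of the brute-force
        interval-overlap graph."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        dups = []
        for _ in range(rng.integers(1, 15)):
            a = int(rng.integers(0, 50)) * 1000
            b = int(rng.integers(0, 50)) * 1000
            while abs(a - b) < 600:
                b = int(rng.integers(0, 50)) * 1000
            dups.append(make_dup(len1=600, start1=a, start2=b))
        groups = merge_multicopy(dups)
        g = nx.Graph()
        for i, d in enumerate(dups):
            g.add_edge((i, 1), (i, 2))
        for i, d in enumerate(dups):
            for j, e in enumerate(dups):
                for si, ri in ((1, d.region1), (2, d.region2)):
                    for sj, rj in ((1, e.region1), (2, e.region2)):
                        if (i, si) != (j, sj) and ri.overlaps(rj):
                            g.add_edge((i, si), (j, sj))
        assert len(groups) == nx.number_connected_components(g)
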