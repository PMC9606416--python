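"""Interval model, algebra, and BED/GTF/FASTA IO."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from safeharbor.intervals import (
    BedParseError,
    ContigNotIndexedError,
    GenomicInterval,
    IntervalSet,
    TssIndex,
    anti_join,
    extract_sequences,
    intersect,
    merge,
    read_bed,
    read_tss_index,
    tss_distance,
    write_bed,
)

from conftest import (
    brute_force_merge,
    coords,
    cover_mask,
    mask_to_intervals,
    random_interval_set,
)


iv_strategy = st.builds(
    lambda c, s, w: GenomicInterval(c, s, s + w),
    st.sampled_from(["c1", "c2"]),
    st.integers(0, 50_000),
    st.integers(1, 5_000),
)
ivset_strategy = st.lists(iv_strategy, max_size=20).map(IntervalSet)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 600, 100)
        with pytest.raises(ValueError):
            GenomicInterval("c", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("c", -1, 5)

    def test_length_and_overlap(self):
        a = GenomicInterval("c", 100, 600)
        assert a.length == 500
        assert a.overlaps(GenomicInterval("c", 599, 700))
        assert not a.overlaps(GenomicInterval("c", 600, 700))  # half-open
        assert not a.overlaps(GenomicInterval("d", 100, 600))


class TestIntervalSetSemantics:
    def test_sorted_and_deduplicated(self):
        s = IntervalSet(
            [
                GenomicInterval("c2", 5, 10),
                GenomicInterval("c1", 50, 60),
                GenomicInterval("c1", 5, 10),
                GenomicInterval("c1", 5, 10),
            ]
        )
        assert coords(s) == [("c1", 5, 10), ("c1", 50, 60), ("c2", 5, 10)]


class TestBedIO:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t600\tpeakA\t50\n")
        (iv,) = read_bed(p)
        assert (iv.contig, iv.start, iv.end, iv.name, iv.score) == (
            "chr1", 100, 600, "peakA", 50.0,
        )

    def test_empty_file_and_skipped_lines(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0
        p.write_text("track name=x\n# comment\n\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    @pytest.mark.parametrize(
        "line", ["chr1\t600\t100", "chr1\tx\t100", "chr1\t100"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_round_trip_identity_on_random_sets(self, tmp_path, rng):
        s = random_interval_set(rng, 100)
        p = tmp_path / "rt.bed"
        write_bed(s, p)
        assert read_bed(p) == s

    def test_round_trip_preserves_name_score_strand(self, tmp_path):
        s = IntervalSet([GenomicInterval("c", 1, 9, "-", "x", 3.5)])
        p = tmp_path / "rt.bed"
        write_bed(s, p)
        (iv,) = read_bed(p)
        assert (iv.name, iv.score, iv.strand) == ("x", 3.5, "-")


GTF_LINE = '{c}\tsrc\tgene\t{s}\t{e}\t.\t{strand}\t.\tgene_id "{g}";\n'


class TestTssIndex:
    def test_strand_rule_and_coordinate_conversion(self, tmp_path):
        p = tmp_path / "ann.gtf"
        p.write_text(
            GTF_LINE.format(c="c1", s=1001, e=2000, strand="+", g="gA")
            + GTF_LINE.format(c="c1", s=3001, e=4000, strand="-", g="gB")
        )
        idx = read_tss_index(p)
        assert sorted(idx.positions("c1").tolist()) == [1000, 3999]
        body = idx.gene_bodies[0]
        assert (body.start, body.end) == (1000, 2000)

    def test_contigs_independent(self, tmp_path):
        p = tmp_path / "ann.gtf"
        p.write_text(
            GTF_LINE.format(c="c1", s=1, e=100, strand="+", g="gA")
            + GTF_LINE.format(c="c2", s=50_001, e=50_100, strand="+", g="gB")
        )
        idx = read_tss_index(p)
        assert tss_distance(GenomicInterval("c1", 5_000, 5_100), idx) == 5_000
        assert tss_distance(GenomicInterval("c2", 5_000, 5_100), idx) == 44_900

    def test_missing_strand_skipped_and_counted(self, tmp_path):
        p = tmp_path / "ann.gtf"
        p.write_text(
            GTF_LINE.format(c="c1", s=1, e=100, strand="+", g="gA")
            + GTF_LINE.format(c="c1", s=500, e=600, strand=".", g="gB")
        )
        idx = read_tss_index(p)
        assert len(idx) == 1
        assert idx.skipped == 1


class TestMerge:
    def test_strict_gap_boundary(self):
        near = IntervalSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 249, 300)])
        far = IntervalSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 250, 300)])
        assert coords(merge(near, 150)) == [("c", 0, 300)]  # gap 149 < 150
        assert coords(merge(far, 150)) == coords(far)  # gap 150, not merged

    def test_zero_gap_is_overlap_merge(self):
        s = IntervalSet(
            [
                GenomicInterval("c", 0, 100),
                GenomicInterval("c", 50, 150),
                GenomicInterval("c", 150, 200),  # book-ended: stays apart
            ]
        )
        assert coords(merge(s, 0)) == [("c", 0, 150), ("c", 150, 200)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge(IntervalSet(), -1)

    @given(ivset_strategy, st.integers(0, 500))
    def test_idempotent(self, s, gap):
        once = merge(s, gap)
        assert merge(once, gap) == once

    def test_matches_brute_force_fixpoint(self, rng):
        for _ in range(25):
            s = random_interval_set(rng, int(rng.integers(1, 15)), max_width=2_000)
            gap = int(rng.integers(0, 1_000))
            assert coords(merge(s, gap)) == brute_force_merge(s, gap)


class TestIntersect:
    def test_basic_and_disjoint(self):
        a = IntervalSet([GenomicInterval("c", 0, 100)])
        b = IntervalSet([GenomicInterval("c", 50, 150)])
        assert coords(intersect(a, b)) == [("c", 50, 100)]
        assert len(intersect(a, IntervalSet([GenomicInterval("c", 500, 600)]))) == 0

    @given(ivset_strategy, ivset_strategy)
    def test_commutative(self, a, b):
        assert intersect(a, b) == intersect(b, a)

    def test_equals_bitmask_and_oracle(self, rng):
        L = 100_000
        for _ in range(25):
            a = random_interval_set(rng, int(rng.integers(1, 20)), length=L)
            b = random_interval_set(rng, int(rng.integers(1, 20)), length=L)
            expected = mask_to_intervals(
                cover_mask(a, "c", L) & cover_mask(b, "c", L), "c"
            )
            assert coords(intersect(a, b)) == expected


class TestAntiJoin:
    def test_whole_interval_semantics(self):
        a = IntervalSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)])
        b = IntervalSet([GenomicInterval("c", 90, 110)])
        assert coords(anti_join(a, b)) == [("c", 200, 300)]

    def test_empty_b_is_identity(self):
        a = IntervalSet([GenomicInterval("c", 0, 100)])
        assert anti_join(a, IntervalSet()) == a

    @given(ivset_strategy, ivset_strategy)
    def test_result_is_subset_of_a(self, a, b):
        kept = set(coords(anti_join(a, b)))
        assert kept <= set(coords(a))

    def test_matches_per_base_overlap_oracle(self, rng):
        L = 100_000
        for _ in range(25):
            a = random_interval_set(rng, int(rng.integers(1, 20)), length=L)
            b = random_interval_set(rng, int(rng.integers(1, 20)), length=L)
            bmask = cover_mask(b, "c", L)
            expected = [
                (iv.contig, iv.start, iv.end)
                for iv in a
                if not bmask[iv.start : iv.end].any()
            ]
            assert coords(anti_join(a, b)) == expected


class TestTssDistance:
    def test_left_gap_and_inside(self):
        idx = TssIndex([("c", 4_000, "+", "g")], IntervalSet())
        assert tss_distance(GenomicInterval("c", 10_000, 11_000), idx) == 6_000
        idx2 = TssIndex([("c", 10_500, "+", "g")], IntervalSet())
        assert tss_distance(GenomicInterval("c", 10_000, 11_000), idx2) == 0

    def test_unknown_contig_signaled(self):
        idx = TssIndex([("c", 0, "+", "g")], IntervalSet())
        with pytest.raises(ContigNotIndexedError):
            tss_distance(GenomicInterval("other", 0, 10), idx)

    def test_matches_exhaustive_scan(self, rng):
        positions = sorted(int(p) for p in rng.integers(0, 100_000, size=40))
        idx = TssIndex(
            [("c", p, "+", f"g{i}") for i, p in enumerate(positions)], IntervalSet()
        )
        for _ in range(50):
            s = int(rng.integers(0, 99_000))
            iv = GenomicInterval("c", s, s + int(rng.integers(1, 1_000)))
            exhaustive = min(
                0 if iv.start <= p < iv.end else (iv.start - p if p < iv.start else p - iv.end)
                for p in positions
            )
            assert tss_distance(iv, idx) == exhaustive


class TestExtractSequences:
    @pytest.fixture
    def genome(self, tmp_path):
        p = tmp_path / "genome.fa"
        p.write_text(">c\nAACGTA\n>d\nTTTTACGTACGTTTTT\n")
        return p

    def test_forward_and_reverse_complement(self, genome):
        fwd = extract_sequences(IntervalSet([GenomicInterval("c", 2, 5)]), genome)
        assert str(fwd[0].seq) == "CGT"
        assert fwd[0].id == "c:2-5"
        rev = extract_sequences(IntervalSet([GenomicInterval("c", 2, 5, "-")]), genome)
        assert str(rev[0].seq) == "ACG"

    def test_lengths_match_intervals(self, genome, rng):
        ivs = IntervalSet(
            GenomicInterval("d", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 8, 100), rng.integers(1, 8, 100))
        )
        for iv, rec in zip(ivs, extract_sequences(ivs, genome)):
            assert len(rec.seq) == iv.length

    def test_out_of_range_interval_raises(self, genome):
        with pytest.raises(IndexError, match="c:2-50"):
            extract_sequences(IntervalSet([GenomicInterval("c", 2, 50)]), genome)
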