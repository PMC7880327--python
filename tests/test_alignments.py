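"""SAM filtering, CIGAR block arithmetic, junctions, and coverage."""

import numpy as np
import pysam
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from ripsplice.alignments import (
    AlignmentTable,
    FilterStats,
    SplicedAlignment,
    coverage,
    extract_junctions,
    read_alignments,
)
from ripsplice.annotation import SpliceJunction

HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def _sam(tmp_path, lines, name="t.sam"):
    p = tmp_path / name
    p.write_text(HEADER + "".join(l + "\n" for l in lines))
    return p


def _rec(qname, flag, pos1, cigar, mapq=50, tags="NH:i:1"):
    return f"{qname}\t{flag}\tchr1\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\t{tags}"


class TestReadAlignments:
    def test_simple_match_block(self, tmp_path):
        path = _sam(tmp_path, [_rec("r1", 0, 100, "50M")])
        (aln,) = read_alignments(path)
        assert aln.blocks == ((99, 149),)
        assert aln.strand == "+"

    def test_gapped_cigar_blocks_match_standard_parser(self, tmp_path):
        path = _sam(tmp_path, [_rec("r1", 16, 1, "20M100N30M")])
        (aln,) = read_alignments(path)
        assert aln.blocks == ((0, 20), (120, 150))
        assert aln.strand == "-"
        with pysam.AlignmentFile(str(path)) as fh:
            rec = next(iter(fh))
        assert list(aln.blocks) == rec.get_blocks()

    def test_deletion_extends_block_insertion_softclip_do_not(self, tmp_path):
        # 10M2D10M spans 22 ref bases in one block; 5S/3I consume query only
        path = _sam(tmp_path, [_rec("r1", 0, 11, "5S10M2D10M3I5M")])
        (aln,) = read_alignments(path)
        assert aln.blocks == ((10, 37),)

    def test_filters_and_counters(self, tmp_path):
        path = _sam(tmp_path, [
            _rec("ok", 0, 100, "50M"),
            _rec("secondary", 256, 100, "50M"),
            _rec("unmapped", 4, 0, "*"),
            _rec("lowmapq", 0, 100, "50M", mapq=3, tags="XX:i:0"),
            _rec("rescued", 0, 100, "50M", mapq=3, tags="NH:i:1"),
        ])
        stats = FilterStats()
        kept = list(read_alignments(path, stats=stats))
        assert {a.blocks for a in kept} == {((99, 149),)}
        assert len(kept) == 2                      # ok + NH-rescued
        assert stats.secondary == 1
        assert stats.unmapped == 1
        assert stats.low_mapq == 1
        assert stats.kept == 2

    def test_malformed_cigar_skipped_with_counter(self, tmp_path):
        path = _sam(tmp_path, [
            _rec("ok", 0, 100, "50M"),
            _rec("clip_only", 0, 100, "5S"),  # no reference-consuming block
        ])
        stats = FilterStats()
        kept = list(read_alignments(path, stats=stats))
        assert len(kept) == 1
        assert stats.malformed == 1

    def test_table_matches_stream(self, tiny_dataset):
        path = tiny_dataset / "rnaseq_A_rep1.sam"
        streamed = list(read_alignments(path))
        table = AlignmentTable.from_sam(path)
        assert len(table) == len(streamed)
        for i in (0, len(streamed) // 2, len(streamed) - 1):
            assert table.read_blocks(i) == list(streamed[i].blocks)
            assert table.strand_of(i) == streamed[i].strand


class TestJunctions:
    def test_identical_gapped_reads_accumulate(self, tmp_path):
        path = _sam(tmp_path, [_rec(f"r{i}", 0, 1, "20M100N30M")
                               for i in range(10)])
        jc = extract_junctions(AlignmentTable.from_sam(path))
        assert jc[SpliceJunction("chr1", "+", 20, 120)] == 10
        assert len(jc) == 1

    def test_ungapped_library_has_no_junctions(self, tmp_path):
        path = _sam(tmp_path, [_rec(f"r{i}", 0, i + 1, "50M") for i in range(5)])
        assert len(extract_junctions(AlignmentTable.from_sam(path))) == 0

    def test_multi_gap_read_counts_each_junction(self, tmp_path):
        path = _sam(tmp_path, [_rec("r", 0, 1, "10M10N10M10N10M")])
        jc = extract_junctions(AlignmentTable.from_sam(path))
        assert jc[SpliceJunction("chr1", "+", 10, 20)] == 1
        assert jc[SpliceJunction("chr1", "+", 30, 40)] == 1

    def test_strand_separates_junctions(self, tmp_path):
        path = _sam(tmp_path, [_rec("f", 0, 1, "10M10N10M"),
                               _rec("r", 16, 1, "10M10N10M")])
        jc = extract_junctions(AlignmentTable.from_sam(path))
        assert jc[SpliceJunction("chr1", "+", 10, 20)] == 1
        assert jc[SpliceJunction("chr1", "-", 10, 20)] == 1

    def test_simulator_library_matches_independent_recount(self, tiny_dataset):
        """Junction counts equal a from-scratch pysam CIGAR walk."""
        path = tiny_dataset / "rnaseq_B_rep2.sam"
        expected: dict = {}
        with pysam.AlignmentFile(str(path)) as fh:
            for rec in fh:
                pos = rec.reference_start
                strand = "-" if rec.is_reverse else "+"
                for op, ln in rec.cigartuples:
                    if op in (0, 2, 7, 8):
                        pos += ln
                    elif op == 3:
                        key = (strand, pos, pos + ln)
                        expected[key] = expected.get(key, 0) + 1
                        pos += ln
        jc = extract_junctions(AlignmentTable.from_sam(path))
        got = {(j.strand, j.donor_end, j.acceptor_start): c for j, c in jc}
        assert got == expected

    def test_no_phantom_junctions(self, tiny_result, tiny_dataset):
        """Observed junctions are exactly those of the simulated isoforms."""
        from ripsplice.reads import CONDITIONS
        from ripsplice.genome import generate_genome
        design = generate_genome(tiny_result.config)
        allowed = set()
        for g in design.genes:
            for iso in (g.model, g.alt):
                if iso is None:
                    continue
                for (_, e1), (s2, _) in zip(iso.exons, iso.exons[1:]):
                    allowed.add((g.strand, e1, s2))
        for cond in CONDITIONS:
            jc = extract_junctions(AlignmentTable.from_sam(
                tiny_dataset / f"rnaseq_{cond}_rep1.sam"))
            observed = {(j.strand, j.donor_end, j.acceptor_start) for j, _ in jc}
            assert observed <= allowed


def _brute_coverage(alns, start, end, strand=None):
    depth = np.zeros(end - start, dtype=int)
    for a in alns:
        if strand is not None and a.strand != strand:
            continue
        for s, e in a.blocks:
            for p in range(max(s, start), min(e, end)):
                depth[p - start] += 1
    return depth


class TestCoverage:
    def test_single_read(self):
        a = SplicedAlignment("c", "+", ((100, 150),))
        d = coverage([a], "c", 90, 160)
        assert d[10:60].tolist() == [1] * 50
        assert d.sum() == 50

    def test_one_base_overlap(self):
        alns = [SplicedAlignment("c", "+", ((100, 150),)),
                SplicedAlignment("c", "+", ((149, 200),))]
        d = coverage(alns, "c", 100, 200)
        assert d[49] == 2
        assert (d == 2).sum() == 1

    def test_bounds_error(self):
        with pytest.raises(ValueError):
            coverage([], "c", 50, 40)

    def test_random_fixture_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        alns = []
        for _ in range(50):
            s = int(rng.integers(0, 900))
            if rng.random() < 0.4:
                gap = int(rng.integers(1, 50))
                l1, l2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
                blocks = ((s, s + l1), (s + l1 + gap, s + l1 + gap + l2))
            else:
                blocks = ((s, s + int(rng.integers(10, 80))),)
            strand = "+" if rng.random() < 0.5 else "-"
            alns.append(SplicedAlignment("c", strand, blocks))
        for strand in (None, "+", "-"):
            got = coverage(alns, "c", 0, 1100, strand=strand)
            assert np.array_equal(got, _brute_coverage(alns, 0, 1100, strand))
            table = AlignmentTable.from_alignments(alns)
            got_t = coverage(table, "c", 0, 1100, strand=strand)
            assert np.array_equal(got_t, _brute_coverage(alns, 0, 1100, strand))

    @settings(max_examples=30, deadline=None)
    @seed(2024)
    @given(st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1,
        max_size=40))
    def test_depth_conserves_covered_bases(self, reads):
        alns = [SplicedAlignment("c", "+", ((s, s + l),)) for s, l in reads]
        d = coverage(alns, "c", 0, 600)
        assert d.sum() == sum(l for _, l in reads)
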