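"""Data model, FASTA/SAM/BED/GFF3 I/O, exact alignment, annotation."""

import numpy as np
import pytest

from srna_dekit.align import align_reads_exact, reverse_complement
from srna_dekit.annotate import annotate_reads
from srna_dekit.core import (
    ConfigurationError,
    ReadLibrary,
    SampleHierarchy,
    build_expression_matrix,
    filter_matrix,
)
from srna_dekit.io import (
    FastaParseError,
    load_alignments,
    read_fasta_counts,
    write_fasta_counts,
)

from conftest import random_library, random_sequence

SEQ21 = "ACGTACGTACGTACGTACGTA"
SEQ22 = "ACGTACGTACGTACGTACGTAC"


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestReadFastaCounts:
    def test_plain_collapses_identical_reads(self, tmp_path):
        p = tmp_path / "r.fa"
        write_fasta(p, [("a", SEQ21), ("b", SEQ21), ("c", SEQ21)])
        lib = read_fasta_counts(p, "plain")
        assert lib.counts == {SEQ21: 3}
        assert lib.redundant_total == 3 and lib.nonredundant_total == 1

    def test_count_suffix_header(self, tmp_path):
        p = tmp_path / "r.fa"
        write_fasta(p, [("seq1-534", SEQ22), ("seq2_12", SEQ21)])
        lib = read_fasta_counts(p, "count_suffix")
        assert lib.counts == {SEQ22: 534, SEQ21: 12}

    def test_count_suffix_without_count_raises(self, tmp_path):
        p = tmp_path / "r.fa"
        write_fasta(p, [("nocount", SEQ21)])
        with pytest.raises(FastaParseError, match="nocount"):
            read_fasta_counts(p, "count_suffix")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text("")
        lib = read_fasta_counts(p, "plain")
        assert lib.redundant_total == 0 and len(lib) == 0

    def test_u_normalized_to_t(self, tmp_path):
        p = tmp_path / "r.fa"
        write_fasta(p, [("a", SEQ21.replace("T", "U"))])
        lib = read_fasta_counts(p, "plain")
        assert lib.counts == {SEQ21: 1}

    def test_length_window_dropped_with_tally(self, tmp_path):
        p = tmp_path / "r.fa"
        write_fasta(p, [("short-7", "ACGT"), ("long-2", "A" * 50), ("ok-3", SEQ21)])
        lib = read_fasta_counts(p, "count_suffix")
        assert lib.counts == {SEQ21: 3}
        assert lib.dropped_by_length == 9

    def test_roundtrip_count_suffix(self, tmp_path, rng):
        """Writing a library as count_suffix FASTA and re-reading reproduces it."""
        for i in range(5):
            lib = random_library(rng, f"rep{i}")
            p = tmp_path / f"lib{i}.fa"
            write_fasta_counts(lib, p)
            back = read_fasta_counts(p, "count_suffix", replicate_id=lib.replicate_id)
            assert back.counts == lib.counts
            assert back.redundant_total == lib.redundant_total


class TestExpressionMatrix:
    def test_union_with_zero_fill(self):
        h = SampleHierarchy([("x", ["A"]), ("y", ["B"])])
        s1, s2 = SEQ21, SEQ22
        m = build_expression_matrix(
            [ReadLibrary("A", {s1: 2}), ReadLibrary("B", {s2: 3})], h
        )
        assert m.values.loc[s1].tolist() == [2, 0]
        assert m.values.loc[s2].tolist() == [0, 3]

    def test_shared_sequence_row(self):
        h = SampleHierarchy([("x", ["A", "B"])])
        m = build_expression_matrix(
            [ReadLibrary("A", {SEQ21: 2}), ReadLibrary("B", {SEQ21: 5, SEQ22: 1})], h
        )
        assert m.values.loc[SEQ21].tolist() == [2, 5]

    def test_column_sums_equal_redundant_totals(self, rng, hierarchy_2x2):
        libs = [random_library(rng, rid) for rid in hierarchy_2x2.replicate_ids]
        m = build_expression_matrix(libs, hierarchy_2x2)
        for lib in libs:
            assert m.column_sums()[lib.replicate_id] == lib.redundant_total

    def test_replicate_mismatch_raises(self, hierarchy_2x2):
        with pytest.raises(ConfigurationError, match="missing"):
            build_expression_matrix([ReadLibrary("c1", {SEQ21: 1})], hierarchy_2x2)

    def test_duplicate_replicate_ids_rejected(self):
        with pytest.raises(ConfigurationError, match="not unique"):
            SampleHierarchy([("x", ["A"]), ("y", ["A"])])


class TestFilterMatrix:
    def test_dropping_all_replicates_removes_treatment(self, paired_matrix):
        out = filter_matrix(paired_matrix, drop_replicates={"t1", "t2"})
        assert out.hierarchy.treatment_ids == ["ctrl"]
        assert out.replicate_ids == ["c1", "c2"]

    def test_size_range_keeps_only_matching_lengths(self, paired_matrix):
        out = filter_matrix(paired_matrix, size_range=(21, 21))
        assert all(len(s) == 21 for s in out.sequences)
        assert len(out.sequences) == 4  # all fixture sequences are 21-mers

    def test_identity(self, paired_matrix):
        out = filter_matrix(paired_matrix)
        assert out.values.equals(paired_matrix.values)

    def test_empty_size_range_raises(self, paired_matrix):
        with pytest.raises(ConfigurationError):
            filter_matrix(paired_matrix, size_range=(25, 20))


def brute_force_hits(read, genome):
    """Independent both-strand substring scan."""
    hits = []
    rc = reverse_complement(read)
    for chrom, seq in genome.items():
        for i in range(len(seq) - len(read) + 1):
            if seq[i : i + len(read)] == read:
                hits.append((chrom, i, "+"))
            if seq[i : i + len(read)] == rc:
                hits.append((chrom, i, "-"))
    return hits


class TestAlignReadsExact:
    def test_planted_forward_hit(self, rng):
        g = random_sequence(rng, 500)
        read = g[100:121]
        aln = align_reads_exact(ReadLibrary("r", {read: 1}), {"chr1": g})
        assert ("chr1", 100, "+") in aln.hits[read]

    def test_planted_reverse_hit(self, rng):
        g = random_sequence(rng, 300)
        read = reverse_complement(g[50:71])
        aln = align_reads_exact(ReadLibrary("r", {read: 1}), {"chr1": g})
        assert aln.hits[read] == brute_force_hits(read, {"chr1": g})
        assert ("chr1", 50, "-") in aln.hits[read]

    def test_absent_read_has_no_hits(self, rng):
        g = "A" * 200
        read = "C" * 21
        aln = align_reads_exact(ReadLibrary("r", {read: 3}), {"chr1": g})
        assert aln.hits[read] == []

    def test_oracle_equivalence_on_random_genomes(self, rng):
        """Agrees with the brute-force both-strand scan, all occurrences."""
        for _ in range(5):
            genome = {
                "c1": random_sequence(rng, int(rng.integers(200, 800))),
                "c2": random_sequence(rng, int(rng.integers(200, 800))),
            }
            reads = {}
            for _ in range(10):  # half planted, half random
                L = int(rng.integers(16, 26))
                if rng.random() < 0.5:
                    chrom = "c1" if rng.random() < 0.5 else "c2"
                    i = int(rng.integers(0, len(genome[chrom]) - L))
                    seq = genome[chrom][i : i + L]
                    if rng.random() < 0.5:
                        seq = reverse_complement(seq)
                else:
                    seq = random_sequence(rng, L)
                reads[seq] = 1
            aln = align_reads_exact(ReadLibrary("r", reads), genome)
            for read in reads:
                assert sorted(aln.hits[read]) == sorted(brute_force_hits(read, genome))


SAM_TEMPLATE = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chr1\tLN:1000
fwd\t0\tchr1\t101\t255\t{L}M\t*\t0\t0\t{fwd}\t*
rev\t16\tchr1\t201\t255\t{L}M\t*\t0\t0\t{rev}\t*
gapped\t0\tchr1\t301\t255\t10M1I10M\t*\t0\t0\t{gap}\t*
"""


class TestLoadAlignments:
    def test_sam_coordinates_and_gap_filter(self, tmp_path, rng):
        read = random_sequence(rng, 21)
        rev_read = random_sequence(rng, 21)
        gap_read = random_sequence(rng, 21)
        sam = tmp_path / "a.sam"
        # reverse-strand SAM stores the reverse complement of the read
        sam.write_text(SAM_TEMPLATE.format(
            L=21, fwd=read, rev=reverse_complement(rev_read), gap=gap_read))
        lib = ReadLibrary("r", {read: 1, rev_read: 2, gap_read: 3})
        aln = load_alignments(sam, lib)
        assert aln.hits[read] == [("chr1", 100, "+")]   # SAM POS 101 -> 0-based 100
        assert aln.hits[rev_read] == [("chr1", 200, "-")]
        assert aln.hits[gap_read] == []                  # ungapped-only rule
        assert aln.genome_lengths == {"chr1": 1000}

    def test_bed_start_used_as_is(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(f"chr2\t100\t121\t{SEQ21}\t0\t+\n")
        aln = load_alignments(bed, ReadLibrary("r", {SEQ21: 1}))
        assert aln.hits[SEQ21] == [("chr2", 100, "+")]

    def test_unknown_sequence_skipped(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(f"chr2\t100\t121\t{SEQ21}\t0\t+\n")
        aln = load_alignments(bed, ReadLibrary("r", {SEQ22: 1}))
        assert aln.hits[SEQ22] == []


GFF = """##gff-version 3
chr1\tsrc\tmiRNA\t91\t130\t.\t+\t.\tID=mir1
chr1\tsrc\ttRNA\t500\t540\t.\t-\t.\tID=trna1
"""


class TestAnnotateReads:
    @pytest.fixture
    def gff_path(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(GFF)
        return p

    def test_full_containment_assigns_class(self, gff_path):
        # hit [100, 121) inside miRNA feature at 0-based [90, 130)
        aln_hits = {SEQ21: [("chr1", 100, "+")]}
        from srna_dekit.core import AlignmentSet

        cls = annotate_reads(AlignmentSet(aln_hits), gff_path, {"miRNA", "tRNA"})
        assert cls.classes[SEQ21] == {"miRNA"}

    def test_boundary_overlap_is_unannotated(self, gff_path):
        # hit [110, 131) sticks 1 nt beyond the feature end
        from srna_dekit.core import AlignmentSet

        cls = annotate_reads(AlignmentSet({SEQ21: [("chr1", 110, "+")]}),
                             gff_path, {"miRNA"})
        assert cls.classes[SEQ21] == {"unannotated"}

    def test_zero_hit_read_unannotated(self, gff_path):
        from srna_dekit.core import AlignmentSet

        cls = annotate_reads(AlignmentSet({SEQ21: []}), gff_path, {"miRNA"})
        assert cls.classes[SEQ21] == {"unannotated"}

    def test_strand_aware_switch(self, gff_path):
        from srna_dekit.core import AlignmentSet

        aln = AlignmentSet({SEQ21: [("chr1", 100, "-")]})
        strand_agnostic = annotate_reads(aln, gff_path, {"miRNA"})
        strand_aware = annotate_reads(aln, gff_path, {"miRNA"}, strand_aware=True)
        assert strand_agnostic.classes[SEQ21] == {"miRNA"}
        assert strand_aware.classes[SEQ21] == {"unannotated"}
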