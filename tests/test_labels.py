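"""Percent-identity labels from alignments: CIGAR walking, additivity, and a
cross-check of alignment-based labels against simulator truth labels."""

import subprocess

import numpy as np
import pytest

from readscrub.io import write_fasta, write_fastq
from readscrub.labels import (AlignmentRecord, label_dataset,
                              read_sam_alignments, segment_identity)
from readscrub.pipeline import build_segments
from readscrub.simulate import (SimConfig, simulate_genome, simulate_reads,
                                truth_labels)

SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr\tLN:1000\n"


def _sam(tmp_path, records):
    path = tmp_path / "aln.sam"
    path.write_text(SAM_HEADER + "".join(records))
    return path


def _line(qname, flag, cigar, seq, pos=1, tags=""):
    return (f"{qname}\t{flag}\tchr\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
            f"{'I' * len(seq)}{tags}\n")


class TestSegmentIdentity:
    def test_matches_and_mismatches(self, tmp_path):
        # 18 matches then 2 mismatches over a 20-base read
        sam = _sam(tmp_path, [_line("r", 0, "18=2X", "A" * 20)])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 20)) == pytest.approx(0.9)
        assert segment_identity(aln, (0, 18)) == 1.0
        assert segment_identity(aln, (18, 20)) == 0.0

    def test_insertions_do_not_match(self, tmp_path):
        # 10=2I8=: 20 read bases, the 2 inserted ones cannot match
        sam = _sam(tmp_path, [_line("r", 0, "10=2I8=", "A" * 20)])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 20)) == pytest.approx(18 / 20)

    def test_deletion_consumes_no_read_bases(self, tmp_path):
        sam = _sam(tmp_path, [_line("r", 0, "10=5D10=", "A" * 20)])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 20)) == 1.0

    def test_fully_clipped_range_is_zero(self, tmp_path):
        sam = _sam(tmp_path, [_line("r", 0, "10S10=", "A" * 20)])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 10)) == 0.0

    def test_reverse_strand_mask_in_read_orientation(self, tmp_path):
        # stored (reverse-complemented) sequence starts with 5 mismatches ->
        # in original read orientation the LAST 5 bases are the mismatches
        sam = _sam(tmp_path, [_line("r", 16, "5X15=", "A" * 20)])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 15)) == 1.0
        assert segment_identity(aln, (15, 20)) == 0.0

    def test_unmapped_read_is_zero(self, tmp_path):
        sam = _sam(tmp_path, [_line("r", 4, "*", "A" * 20)])
        assert segment_identity(read_sam_alignments(sam)["r"], (0, 20)) == 0.0

    def test_empty_range_rejected(self, tmp_path):
        sam = _sam(tmp_path, [_line("r", 0, "20=", "A" * 20)])
        with pytest.raises(ValueError, match="empty"):
            segment_identity(read_sam_alignments(sam)["r"], (5, 5))

    def test_ambiguous_m_without_md_counts_as_match_with_warning(
            self, tmp_path, caplog):
        sam = _sam(tmp_path, [_line("r", 0, "20M", "A" * 20)])
        with caplog.at_level("WARNING"):
            aln = read_sam_alignments(sam)["r"]
        assert "MD" in caplog.text
        assert segment_identity(aln, (0, 20)) == 1.0

    def test_m_with_md_resolves_mismatches(self, tmp_path):
        sam = _sam(tmp_path, [_line("r", 0, "20M", "A" * 20, tags="\tMD:Z:18C1")])
        aln = read_sam_alignments(sam)["r"]
        assert segment_identity(aln, (0, 20)) == pytest.approx(19 / 20)


def test_additivity_whole_read_equals_weighted_segment_mean(rng):
    """Match counts are additive, so whole-read identity is the
    length-weighted mean of segment identities, exactly."""
    for _ in range(20):
        n = int(rng.integers(10, 500))
        mask = rng.random(n) < 0.8
        aln = AlignmentRecord("r", mask)
        cuts = np.unique(rng.integers(1, n, size=4)) if n > 1 else []
        bounds = [0, *cuts, n]
        total = 0.0
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                total += segment_identity(aln, (a, b)) * (b - a)
        assert total / n == pytest.approx(mask.mean(), abs=1e-12)


@pytest.fixture(scope="module")
def aligned_sim(sim_small, segments_small, tmp_path_factory):
    _, genomes, reads, _ = sim_small
    segments, _ = segments_small
    d = tmp_path_factory.mktemp("aln")
    write_fasta(genomes, d / "g.fasta")
    write_fastq(reads, d / "r.fastq")
    sam = subprocess.run(
        ["minimap2", "-a", "--eqx", "-x", "map-ont",
         str(d / "g.fasta"), str(d / "r.fastq")],
        capture_output=True, text=True, check=True).stdout
    (d / "aln.sam").write_text(sam)
    return read_sam_alignments(d / "aln.sam"), segments


class TestLabelDataset:
    def test_one_label_per_segment(self, aligned_sim):
        alignments, segments = aligned_sim
        labels = label_dataset(alignments, segments)
        assert len(labels) == len(segments)
        assert all(0.0 <= lab.identity <= 1.0 for lab in labels)

    def test_cross_oracle_alignment_vs_truth(self, sim_small, segments_small,
                                             aligned_sim):
        """Alignment-derived labels agree with the simulator's error-mask
        labels to within 0.05 mean absolute difference on >= 100 reads."""
        _, _, reads, truths = sim_small
        assert len(reads) >= 100
        alignments, segments = aligned_sim
        by_alignment = label_dataset(alignments, segments)
        by_truth = truth_labels(truths, segments)
        diff = np.abs(np.array([a.identity for a in by_alignment])
                      - np.array([t.identity for t in by_truth]))
        assert diff.mean() < 0.05

    def test_error_free_reads_label_one(self, tmp_path):
        cfg = SimConfig(genome_lengths=(8_000,), coverage=5, error_rate=0.0,
                        junk_rate=0.0, chimera_rate=0.0, rng_seed=3)
        genomes = simulate_genome(cfg)
        reads, truths = simulate_reads(genomes, cfg)
        segments = build_segments(reads)
        write_fasta(genomes, tmp_path / "g.fasta")
        write_fastq(reads, tmp_path / "r.fastq")
        sam = subprocess.run(
            ["minimap2", "-a", "--eqx", "-x", "map-ont",
             str(tmp_path / "g.fasta"), str(tmp_path / "r.fastq")],
            capture_output=True, text=True, check=True).stdout
        (tmp_path / "aln.sam").write_text(sam)
        labels = label_dataset(read_sam_alignments(tmp_path / "aln.sam"),
                               segments)
        identities = np.array([lab.identity for lab in labels])
        assert (identities == 1.0).mean() > 0.99
        assert all(lab.identity == 1.0
                   for lab in truth_labels(truths, segments))
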