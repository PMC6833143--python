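"""Overlap detection: chaining correctness, symmetry, serialization, PAF path."""

import itertools
import subprocess

import pytest

from readscrub.io import Read, write_fastq
from readscrub.minimizers import MinimizerConfig, extract_minimizers
from readscrub.overlap import (OverlapConfig, _chain, build_index,
                               find_overlaps, paf_to_overlaps, parse_overlaps,
                               serialize_overlaps)
from readscrub.simulate import SimConfig, simulate_genome, simulate_reads
from .conftest import random_seq

REVCOMP = str.maketrans("ACGT", "TGCA")


def _read(rid, seq):
    return Read(rid, seq, "I" * len(seq))


class TestBuildIndex:
    def test_empty(self):
        assert build_index([]) == {}

    def test_single_read_entries_match_sketch(self, rng):
        read = _read("a", random_seq(rng, 300))
        index = build_index([read])
        sketch = extract_minimizers(read.seq)
        assert sorted(h for h in index) == sorted({m.hash for m in sketch})
        occurrences = [occ for hits in index.values() for occ in hits]
        assert len(occurrences) == len(sketch)

    def test_identical_reads_hit_both(self, rng):
        seq = random_seq(rng, 300)
        index = build_index([_read("a", seq), _read("b", seq)])
        for hits in index.values():
            assert {r for r, _, _ in hits} == {"a", "b"}

    def test_duplicate_ids_rejected(self, rng):
        seq = random_seq(rng, 100)
        with pytest.raises(ValueError, match="duplicate"):
            build_index([_read("a", seq), _read("a", seq)])


class TestFindOverlaps:
    def test_identical_reads_full_match_both_directions(self, rng):
        seq = random_seq(rng, 400)
        reads = [_read("a", seq), _read("b", seq)]
        piles = find_overlaps(reads)
        sketch = extract_minimizers(seq)
        for ref, query in [("a", "b"), ("b", "a")]:
            (ov,) = piles[ref]
            assert ov.query_id == query and ov.strand == "+"
            assert len(ov.matches) == len(sketch)
            assert [m.ref_index for m in ov.matches] == list(range(len(sketch)))

    def test_reverse_complement_reported_opposite_strand(self, rng):
        seq = random_seq(rng, 400)
        rc = seq.translate(REVCOMP)[::-1]
        piles = find_overlaps([_read("a", seq), _read("b", rc)])
        (ov,) = piles["a"]
        assert ov.strand == "-"
        assert len(ov.matches) == len(extract_minimizers(seq))
        qstarts = [m.query_start for m in ov.matches]
        assert qstarts == sorted(qstarts, reverse=True)

    def test_unrelated_reads_no_overlap(self, rng):
        piles = find_overlaps([_read("a", random_seq(rng, 300)),
                               _read("b", random_seq(rng, 300))])
        assert piles["a"] == [] and piles["b"] == []

    def test_symmetric_detection(self, sim_small, piles_small):
        pairs = {(ov.ref_id, ov.query_id)
                 for pile in piles_small.values() for ov in pile}
        for a, b in pairs:
            assert (b, a) in pairs

    def test_every_read_overlaps_at_covered_depth(self):
        """Error-free 30x reads from one genome all overlap something."""
        cfg = SimConfig(genome_lengths=(4_000,), coverage=30,
                        read_length_median=800, error_rate=0.0, junk_rate=0.0,
                        chimera_rate=0.0, rng_seed=5)
        reads, _ = simulate_reads(simulate_genome(cfg), cfg)
        piles = find_overlaps(reads)
        assert all(len(piles[r.id]) >= 1 for r in reads)


class TestChaining:
    @staticmethod
    def brute_force_best(pairs, strand, max_gap):
        """Longest valid co-linear subsequence by explicit enumeration."""
        sign = 1 if strand == "+" else -1
        order = sorted(pairs, key=lambda p: (p[0], sign * p[2]))
        best = 0
        for size in range(len(order), 0, -1):
            for combo in itertools.combinations(order, size):
                ok = all(
                    p[0] < q[0] and sign * (q[2] - p[2]) > 0
                    and q[1] - p[1] <= max_gap and abs(q[2] - p[2]) <= max_gap
                    for p, q in zip(combo, combo[1:]))
                if ok:
                    return size
            if best:
                break
        return 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_chain_is_optimal_on_small_instances(self, rng, strand):
        for _ in range(30):
            n = int(rng.integers(1, 11))
            pairs = [(int(rng.integers(0, 15)), 0, int(rng.integers(0, 300)))
                     for _ in range(n)]
            pairs = [(r, r * 30, q) for r, _, q in pairs]  # base pos ~ index
            chain = _chain(pairs, strand, max_gap=200)
            assert len(chain) == self.brute_force_best(pairs, strand, 200)


class TestSerialization:
    def test_empty_set_header_only(self, tmp_path):
        path = tmp_path / "ov.tsv"
        serialize_overlaps({}, path)
        assert path.read_text().count("\n") == 1
        assert parse_overlaps(path) == {}

    def test_round_trip(self, piles_small, tmp_path):
        path = tmp_path / "ov.tsv"
        serialize_overlaps(piles_small, path)
        parsed = parse_overlaps(path)
        nonempty = {k: sorted(v, key=lambda o: o.query_id)
                    for k, v in piles_small.items() if v}
        assert parsed == nonempty

    def test_hand_written_two_match_file(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text(
            "ref_id\tquery_id\tstrand\tk\tref_start\tref_end\t"
            "query_start\tquery_end\tmatches\n"
            "a\tb\t+\t15\t10\t115\t5\t110\t3:5,7:95\n")
        parsed = parse_overlaps(path)
        (ov,) = parsed["a"]
        assert [(m.ref_index, m.query_start) for m in ov.matches] == [(3, 5), (7, 95)]
        assert ov.ref_span == (10, 115) and ov.k == 15

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text(
            "ref_id\tquery_id\tstrand\tk\tref_start\tref_end\t"
            "query_start\tquery_end\tmatches\n"
            "a\tb\t+\t15\t0\t1\t0\t1\tnot-pairs\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_overlaps(path)


class TestPafInput:
    def test_minimap2_paf_recovers_matches(self, sim_small, tmp_path):
        """An external overlapper's PAF yields piles for most reads."""
        _, _, reads, _ = sim_small
        fastq = tmp_path / "reads.fastq"
        write_fastq(reads, fastq)
        paf = subprocess.run(
            ["minimap2", "-x", "ava-ont", str(fastq), str(fastq)],
            capture_output=True, text=True, check=True).stdout
        paf_path = tmp_path / "ava.paf"
        paf_path.write_text(paf)
        piles = paf_to_overlaps(paf_path, reads)
        with_pile = sum(bool(p) for p in piles.values())
        # a production overlapper is conservative on short noisy reads, but
        # a substantial fraction of the reads must still gain a pile
        assert with_pile >= 0.4 * len(reads)
        assert sum(len(p) for p in piles.values()) >= 100
        cfg = OverlapConfig()
        for pile in piles.values():
            for ov in pile:
                assert len(ov.matches) >= cfg.min_shared
                ridx = [m.ref_index for m in ov.matches]
                assert ridx == sorted(ridx)

    def test_short_paf_line_rejected(self, sim_small, tmp_path):
        _, _, reads, _ = sim_small
        bad = tmp_path / "bad.paf"
        bad.write_text("a\t100\t0\t50\n")
        with pytest.raises(ValueError, match="12 columns"):
            paf_to_overlaps(bad, reads)
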