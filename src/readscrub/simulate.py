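"""Synthetic long-read generator with ground truth.

Emulates the error structure of noisy long reads (nanopore-like): a baseline
per-base error rate with indels dominating, clustered low-quality "junk"
segments with strongly elevated error, occasional chimeric reads joining two
independent loci, and quality scores that track — noisily — the local error
rate.  Every read carries a per-base error mask and its source intervals, so
segment identity labels can be computed without any reference alignment.

Defaults: one 50 kb genome at 30x, log-normal read lengths with median 2 kb
(mean about 2.6 kb), 15% baseline error of which 60% are indels, 30% of
reads containing one 100-1000 bp junk segment at 30-50% error, 5% chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import Read
from .labels import SegmentLabel
from .pileup import PileupSegment

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    genome_lengths: tuple[int, ...] = (50_000,)
    coverage: float = 30.0
    read_length_median: int = 2_000
    read_length_sigma: float = 0.72   # log-normal sigma; mean ~= 2.6 kb
    min_read_length: int = 200
    error_rate: float = 0.15          # baseline per-base error probability
    indel_fraction: float = 0.6       # fraction of errors that are indels
    junk_rate: float = 0.3            # fraction of reads with a junk segment
    junk_error_range: tuple[float, float] = (0.3, 0.5)
    junk_length_range: tuple[int, int] = (100, 1_000)
    chimera_rate: float = 0.05
    quality_sd: float = 3.0           # sd of per-base Phred around its mean
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.indel_fraction, self.junk_rate,
                     self.chimera_rate, *self.junk_error_range):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if any(l <= 0 for l in self.genome_lengths):
            raise ValueError("genome lengths must be positive")


@dataclass(frozen=True)
class TruthInterval:
    """One source interval of a read: read span <- genome span."""

    read_start: int
    read_end: int
    genome_id: str
    strand: str
    genome_start: int
    genome_end: int
    kind: str  # "primary" or "chimera"


@dataclass
class ReadTruth:
    read_id: str
    intervals: list[TruthInterval]
    junk_ranges: list[tuple[int, int]]   # read-coordinate junk spans
    error_mask: np.ndarray               # bool, True where the read base is an error
    n_template_bases: int = 0
    n_error_events: int = 0


def simulate_genome(cfg: SimConfig = SimConfig()) -> dict[str, str]:
    """Uniform random ACGT genomes of the configured lengths."""
    rng = np.random.default_rng([cfg.rng_seed, 0])
    return {
        f"genome{i}": "".join(rng.choice(_BASES, size=length))
        for i, length in enumerate(cfg.genome_lengths)
    }


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _phred_chars(local_error: np.ndarray, rng: np.random.Generator,
                 sd: float) -> str:
    """Quality characters whose expected Phred tracks the local error rate."""
    mean_q = -10.0 * np.log10(np.maximum(local_error, 1e-4))
    q = np.clip(np.round(rng.normal(mean_q, sd)), 0, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def _emit(template: str, planned_error: np.ndarray, rng: np.random.Generator,
          cfg: SimConfig) -> tuple[str, np.ndarray, np.ndarray, np.ndarray, int]:
    """Apply the error process to a template.

    Returns (read seq, error mask, per-base local error rate, read position
    of each template base (-1 where deleted), number of error events).
    An insertion places one random base before the template base; a deletion
    drops the template base.
    """
    out: list[str] = []
    mask: list[bool] = []
    local: list[float] = []
    t_to_read = np.full(len(template), -1, dtype=np.int64)
    is_err = rng.random(len(template)) < planned_error
    kind = rng.random((len(template), 2))  # [indel?, ins-vs-del / sub base]
    n_events = 0
    for t, base in enumerate(template):
        e = planned_error[t]
        if is_err[t]:
            n_events += 1
            if kind[t, 0] < cfg.indel_fraction:
                if kind[t, 1] < 0.5:  # insertion, then the real base
                    out.append(_BASES[rng.integers(4)])
                    mask.append(True)
                    local.append(e)
                    t_to_read[t] = len(out)
                    out.append(base)
                    mask.append(False)
                    local.append(e)
                # else: deletion -> template base dropped
            else:  # substitution
                choices = [b for b in "ACGT" if b != base]
                t_to_read[t] = len(out)
                out.append(choices[int(kind[t, 1] * 3)])
                mask.append(True)
                local.append(e)
        else:
            t_to_read[t] = len(out)
            out.append(base)
            mask.append(False)
            local.append(e)
    return ("".join(out), np.array(mask, dtype=bool),
            np.array(local, dtype=float), t_to_read, n_events)


def simulate_reads(genomes: Mapping[str, str], cfg: SimConfig = SimConfig()
                   ) -> tuple[list[Read], dict[str, ReadTruth]]:
    """Sample reads at the configured coverage with full ground truth."""
    rng = np.random.default_rng([cfg.rng_seed, 1])
    names = list(genomes)
    reads: list[Read] = []
    truths: dict[str, ReadTruth] = {}
    counter = 0

    for gi, name in enumerate(names):
        genome = genomes[name]
        target = cfg.coverage * len(genome)
        emitted = 0
        while emitted < target:
            length = int(rng.lognormal(np.log(cfg.read_length_median),
                                       cfg.read_length_sigma))
            length = int(np.clip(length, cfg.min_read_length, len(genome)))

            # Source parts: one locus, or two independent loci for a chimera.
            parts: list[tuple[str, str, int, int, str]] = []
            if rng.random() < cfg.chimera_rate:
                half = max(length // 2, cfg.min_read_length // 2)
                while True:
                    other_name = names[rng.integers(len(names))]
                    start1 = rng.integers(0, len(genome) - half + 1)
                    other_genome = genomes[other_name]
                    start2 = rng.integers(0, max(len(other_genome) - half, 0) + 1)
                    if other_name != name or abs(int(start2) - int(start1)) > half:
                        break
                parts.append((name, "primary", int(start1), int(start1) + half,
                              "+" if rng.random() < 0.5 else "-"))
                end2 = min(int(start2) + half, len(other_genome))
                parts.append((other_name, "chimera", int(start2), end2,
                              "+" if rng.random() < 0.5 else "-"))
            else:
                start = int(rng.integers(0, len(genome) - length + 1))
                parts.append((name, "primary", start, start + length,
                              "+" if rng.random() < 0.5 else "-"))

            template = ""
            boundaries = [0]
            for gname, _kind, gstart, gend, strand in parts:
                chunk = genomes[gname][gstart:gend]
                template += chunk if strand == "+" else _revcomp(chunk)
                boundaries.append(len(template))

            planned = np.full(len(template), cfg.error_rate, dtype=float)
            junk_t: tuple[int, int] | None = None
            if rng.random() < cfg.junk_rate and len(template) > 0:
                jlen = int(rng.integers(cfg.junk_length_range[0],
                                        cfg.junk_length_range[1] + 1))
                jlen = min(jlen, len(template))
                j0 = int(rng.integers(0, len(template) - jlen + 1))
                junk_t = (j0, j0 + jlen)
                planned[j0 : j0 + jlen] = rng.uniform(*cfg.junk_error_range)

            seq, mask, local, t_to_read, n_events = _emit(template, planned, rng, cfg)
            if len(seq) == 0:
                continue
            read_id = f"read{counter:05d}"
            counter += 1
            qual = _phred_chars(local, rng, cfg.quality_sd)
            reads.append(Read(read_id, seq, qual))

            def read_pos(t: int) -> int:
                """First read position at or after template position t."""
                while t < len(t_to_read) and t_to_read[t] < 0:
                    t += 1
                return int(t_to_read[t]) if t < len(t_to_read) else len(seq)

            intervals = []
            for p, (gname, kind, gstart, gend, strand) in enumerate(parts):
                r0, r1 = read_pos(boundaries[p]), read_pos(boundaries[p + 1])
                intervals.append(TruthInterval(r0, r1, gname, strand,
                                               gstart, gend, kind))
            if intervals:
                head = intervals[0]
                intervals[0] = TruthInterval(0, head.read_end, head.genome_id,
                                             head.strand, head.genome_start,
                                             head.genome_end, head.kind)
                last = intervals[-1]
                intervals[-1] = TruthInterval(last.read_start, len(seq),
                                              last.genome_id, last.strand,
                                              last.genome_start, last.genome_end,
                                              last.kind)
            junk_ranges = []
            if junk_t is not None:
                junk_ranges.append((read_pos(junk_t[0]), read_pos(junk_t[1])))
            truths[read_id] = ReadTruth(
                read_id=read_id, intervals=intervals, junk_ranges=junk_ranges,
                error_mask=mask, n_template_bases=len(template),
                n_error_events=n_events)
            emitted += len(seq)
        _ = gi
    return reads, truths


def truth_labels(truths: Mapping[str, ReadTruth],
                 segments: Sequence[PileupSegment]) -> list[SegmentLabel]:
    """Reference-free identity labels from the simulator's error masks."""
    labels = []
    for seg in segments:
        if seg.ref_id not in truths:
            raise ValueError(f"unknown read id {seg.ref_id!r} in segments")
        mask = truths[seg.ref_id].error_mask
        b0, b1 = seg.base_range
        identity = 1.0 - float(mask[b0:b1].mean()) if b1 > b0 else 0.0
        labels.append(SegmentLabel(seg.ref_id, seg.segment_index,
                                   seg.base_range, identity))
    return labels


def read_identity(truth: ReadTruth) -> float:
    """Whole-read identity: fraction of non-error read bases."""
    return 1.0 - float(truth.error_mask.mean())


# ---------------------------------------------------------------------------
# Truth TSV: read_id, intervals, junk ranges, run-length-encoded error mask.
# ---------------------------------------------------------------------------

def _rle(mask: np.ndarray) -> str:
    if len(mask) == 0:
        return ""
    runs = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            runs.append(f"{int(mask[start])}x{i - start}")
            start = i
    return ",".join(runs)


def _unrle(text: str) -> np.ndarray:
    if not text:
        return np.zeros(0, dtype=bool)
    parts = []
    for token in text.split(","):
        value, count = token.split("x")
        parts.append(np.full(int(count), bool(int(value))))
    return np.concatenate(parts)


def write_truth_tsv(truths: Mapping[str, ReadTruth], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tintervals\tjunk\terror_mask_rle\n")
        for read_id in sorted(truths):
            t = truths[read_id]
            ivals = ";".join(
                f"{iv.read_start}-{iv.read_end}:{iv.genome_id}:{iv.strand}:"
                f"{iv.genome_start}-{iv.genome_end}:{iv.kind}"
                for iv in t.intervals)
            junk = ";".join(f"{a}-{b}" for a, b in t.junk_ranges)
            handle.write(f"{read_id}\t{ivals}\t{junk}\t{_rle(t.error_mask)}\n")


def read_truth_tsv(path: str | Path) -> dict[str, ReadTruth]:
    truths: dict[str, ReadTruth] = {}
    with open(path) as handle:
        handle.readline()
        for line in handle:
            read_id, ivals, junk, rle = line.rstrip("\n").split("\t")
            intervals = []
            for token in ivals.split(";") if ivals else []:
                rspan, gname, strand, gspan, kind = token.split(":")
                r0, r1 = map(int, rspan.split("-"))
                g0, g1 = map(int, gspan.split("-"))
                intervals.append(TruthInterval(r0, r1, gname, strand, g0, g1, kind))
            junk_ranges = [tuple(map(int, t.split("-")))
                           for t in junk.split(";") if t]
            mask = _unrle(rle)
            truths[read_id] = ReadTruth(read_id, intervals, junk_ranges, mask)
    return truths
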