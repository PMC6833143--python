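"""Remove below-threshold read segments, split reads at the removals, drop
short fragments, and write scrubbed FASTQ.

A segment whose predicted identity falls below the threshold (default 0.8)
is removed in full; the maximal runs of kept segments become fragments,
named ``<read_id>:<n>`` left to right.  Fragments shorter than ``min_length``
(default 500 bases) are discarded — the length filter applies per fragment,
after splitting.  A read whose segments are all kept passes through intact
under its original identifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import Read, read_fastq, write_fastq

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScrubConfig:
    threshold: float = 0.8   # identity cutoff: segments below this are removed
    min_length: int = 500    # minimum fragment length in bases

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")


@dataclass
class ScrubStats:
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    bases_removed: int = 0
    fragments_dropped_short: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)
            handle.write("\n")


@dataclass(frozen=True)
class SegmentPrediction:
    base_range: tuple[int, int]
    prediction: float


def kept_intervals(read: Read, predictions: Sequence[SegmentPrediction],
                   cfg: ScrubConfig = ScrubConfig()) -> list[tuple[int, int]]:
    """Half-open base intervals of the read that survive scrubbing.

    ``predictions`` must carry base ranges that partition [0, len(read)).
    Maximal runs of kept (prediction >= threshold) segments are merged, then
    runs shorter than ``min_length`` are discarded.
    """
    ordered = sorted(predictions, key=lambda p: p.base_range[0])
    pos = 0
    for p in ordered:
        if p.base_range[0] != pos or p.base_range[1] <= p.base_range[0]:
            raise ValueError(
                f"read {read.id!r}: segment ranges do not partition the read "
                f"(gap or overlap at base {pos})")
        pos = p.base_range[1]
    if pos != len(read):
        raise ValueError(
            f"read {read.id!r}: segment ranges do not partition the read "
            f"(they end at {pos}, read length is {len(read)})")

    runs: list[tuple[int, int]] = []
    for p in ordered:
        if p.prediction >= cfg.threshold:
            if runs and runs[-1][1] == p.base_range[0]:
                runs[-1] = (runs[-1][0], p.base_range[1])
            else:
                runs.append(p.base_range)
    return [r for r in runs if r[1] - r[0] >= cfg.min_length]


def scrub_read(read: Read, predictions: Sequence[SegmentPrediction],
               cfg: ScrubConfig = ScrubConfig()) -> list[Read]:
    """Split one read at below-threshold segments; returns kept fragments."""
    runs = kept_intervals(read, predictions, cfg)
    if len(runs) == 1 and runs[0] == (0, len(read)):
        return [read]
    return [
        Read(id=f"{read.id}:{n}", seq=read.seq[start:end],
             qual=read.qual[start:end])
        for n, (start, end) in enumerate(runs)
    ]


def _kept_bases(read: Read, predictions: Sequence[SegmentPrediction],
                cfg: ScrubConfig) -> int:
    return sum(len(frag) for frag in scrub_read(read, predictions, cfg))


def scrub_reads(reads: Iterable[Read],
                predictions: Mapping[str, Sequence[SegmentPrediction]],
                cfg: ScrubConfig = ScrubConfig()
                ) -> tuple[list[Read], ScrubStats]:
    """Scrub every read; reads without predictions pass through unmodified."""
    stats = ScrubStats()
    out: list[Read] = []
    for read in reads:
        stats.reads_in += 1
        stats.bases_in += len(read)
        if read.id not in predictions:
            logger.warning("read %s has no predictions; passing through", read.id)
            out.append(read)
            stats.bases_out += len(read)
            continue
        preds = predictions[read.id]
        kept_runs = scrub_read(read, preds, cfg)
        no_filter = scrub_read(read, preds, ScrubConfig(cfg.threshold, 0))
        stats.fragments_dropped_short += len(no_filter) - len(kept_runs)
        out.extend(kept_runs)
        stats.bases_out += sum(len(f) for f in kept_runs)
    stats.reads_out = len(out)
    stats.bases_removed = stats.bases_in - stats.bases_out
    return out, stats


# ---------------------------------------------------------------------------
# Predictions TSV and file-to-file scrubbing.
# ---------------------------------------------------------------------------

def write_predictions_tsv(rows, path: str | Path) -> None:
    """rows: iterable of (ref_id, segment_index, base_start, base_end, prediction)."""
    with open(path, "w") as handle:
        handle.write("ref_id\tsegment_index\tbase_start\tbase_end\tprediction\n")
        for ref_id, idx, b0, b1, pred in rows:
            handle.write(f"{ref_id}\t{idx}\t{b0}\t{b1}\t{pred:.6f}\n")


def read_predictions_tsv(path: str | Path) -> dict[str, list[SegmentPrediction]]:
    table: dict[str, list[SegmentPrediction]] = {}
    with open(path) as handle:
        handle.readline()
        for line in handle:
            ref_id, _idx, b0, b1, pred = line.rstrip("\n").split("\t")
            table.setdefault(ref_id, []).append(
                SegmentPrediction((int(b0), int(b1)), float(pred)))
    return table


def scrub_fastq(fastq_in: str | Path, predictions_tsv: str | Path,
                cfg: ScrubConfig, fastq_out: str | Path) -> ScrubStats:
    reads = read_fastq(fastq_in)
    table = read_predictions_tsv(predictions_tsv)
    out, stats = scrub_reads(reads, table, cfg)
    write_fastq(out, fastq_out)
    return stats
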