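"""Convenience drivers tying the stages together in memory.

The file-to-file equivalents live behind the command-line interface; these
helpers serve library users, the test suite, and the acceptance script.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import Read
from .labels import SegmentLabel
from .minimizers import MinimizerConfig
from .model import ScrubModel, TrainConfig, predict, train
from .overlap import Overlap, OverlapConfig, find_overlaps
from .pileup import PileupConfig, PileupSegment, encode_pileup, segment_pileup
from .scrub import ScrubConfig, SegmentPrediction, scrub_reads
from .simulate import ReadTruth, truth_labels


def build_segments(reads: Sequence[Read],
                   piles: Mapping[str, list[Overlap]] | None = None,
                   minimizer_cfg: MinimizerConfig = MinimizerConfig(),
                   overlap_cfg: OverlapConfig = OverlapConfig(),
                   pileup_cfg: PileupConfig = PileupConfig(),
                   ) -> list[PileupSegment]:
    """Overlap (unless piles are supplied), encode, and segment every read."""
    if piles is None:
        piles = find_overlaps(list(reads), minimizer_cfg, overlap_cfg)
    by_id = {r.id: r for r in reads}
    segments: list[PileupSegment] = []
    for read in reads:
        img = encode_pileup(read, piles.get(read.id, []), by_id,
                            pileup_cfg, minimizer_cfg)
        segments.extend(segment_pileup(img, pileup_cfg))
    return segments


def train_on_truth(reads: Sequence[Read], truths: Mapping[str, ReadTruth],
                   train_cfg: TrainConfig = TrainConfig(),
                   minimizer_cfg: MinimizerConfig = MinimizerConfig(),
                   overlap_cfg: OverlapConfig = OverlapConfig(),
                   pileup_cfg: PileupConfig = PileupConfig(),
                   ) -> tuple[ScrubModel, list[float], list[PileupSegment],
                              list[SegmentLabel]]:
    """Build segments, label them from simulator truth, and train."""
    segments = build_segments(reads, None, minimizer_cfg, overlap_cfg, pileup_cfg)
    labels = truth_labels(truths, segments)
    model, history = train(segments, labels, train_cfg, minimizer_cfg, pileup_cfg)
    return model, history, segments, labels


def predictions_by_read(segments: Sequence[PileupSegment],
                        values: np.ndarray) -> dict[str, list[SegmentPrediction]]:
    """Group per-segment predicted identities by read for scrubbing."""
    table: dict[str, list[SegmentPrediction]] = {}
    for seg, value in zip(segments, values, strict=True):
        table.setdefault(seg.ref_id, []).append(
            SegmentPrediction(seg.base_range, float(value)))
    return table


def scrub_with_model(reads: Sequence[Read], model: ScrubModel,
                     segments: Sequence[PileupSegment],
                     scrub_cfg: ScrubConfig = ScrubConfig()):
    """Predict on prebuilt segments and scrub; returns (reads out, stats)."""
    values = predict(model, segments)
    return scrub_reads(reads, predictions_by_read(segments, values), scrub_cfg)
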