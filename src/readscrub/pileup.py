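"""RGB pileup image encoding of read-to-read overlaps.

One image per reference read: each column is one minimizer of the reference
read, row 0 is the reference itself and the remaining rows are (up to
``depth - 1``) matching reads from its overlap pile.  Per pixel:

* red — 255 if that row's read shares the column's minimizer, 70 if it is
  inside the matched span but lacks the minimizer, 0 outside the match;
* green — twice the average Phred+33 quality character value over the base
  interval the pixel covers, clamped to [66, 254];
* blue — base distance to the next minimizer, clamped at 255 (disagreement
  between rows in this channel is the indel signal).

Images are cut into fixed-width segments (default 48 columns) whose base
ranges partition the reference read; the final partial segment is
right-padded with black columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import Read
from .minimizers import MinimizerConfig, extract_minimizers
from .overlap import Overlap

RED_MATCH = 255
RED_NO_MATCH = 70
GREEN_MIN = 66
GREEN_MAX = 254


@dataclass(frozen=True)
class PileupConfig:
    depth: int = 24          # rows per image, including the reference read
    segment_length: int = 48  # columns (minimizers) per segment
    rng_seed: int = 0         # seed for sampling matching reads from large piles

    def __post_init__(self) -> None:
        if self.depth < 1 or self.segment_length < 1:
            raise ValueError("depth and segment_length must be >= 1")


@dataclass
class PileupImage:
    grid: np.ndarray              # depth x C x 3, uint8
    ref_id: str
    row_reads: list[str]          # row 0 = reference read
    column_coords: list[tuple[int, int]]  # half-open base intervals per column

    @property
    def n_columns(self) -> int:
        return self.grid.shape[1]


@dataclass
class PileupSegment:
    grid: np.ndarray              # depth x segment_length x 3, uint8
    ref_id: str
    segment_index: int
    column_range: tuple[int, int]  # half-open, in image columns
    base_range: tuple[int, int]    # half-open, in reference read bases


def _mean_quality(qual: str, lo: int, hi: int) -> float:
    """Mean ASCII value of the quality characters in [lo, hi)."""
    lo = max(0, min(lo, len(qual) - 1))
    hi = max(lo + 1, min(hi, len(qual)))
    window = qual[lo:hi]
    return sum(map(ord, window)) / len(window)


def _green(mean_ascii: float) -> int:
    return int(np.clip(round(2 * mean_ascii), GREEN_MIN, GREEN_MAX))


def encode_pileup(ref_read: Read, pile: list[Overlap], reads: Mapping[str, Read],
                  cfg: PileupConfig = PileupConfig(),
                  minimizer_cfg: MinimizerConfig = MinimizerConfig()) -> PileupImage:
    """Encode one reference read's overlap pile into an RGB image.

    Matching reads are ordered by descending shared-minimizer count; when the
    pile exceeds ``depth - 1`` reads, that many are sampled uniformly without
    replacement using ``cfg.rng_seed``.  For a matching read, base positions
    at columns where it lacks the minimizer are inferred by linear
    interpolation between the flanking matched minimizers.
    """
    for ov in pile:
        if ov.ref_id != ref_read.id:
            raise ValueError(f"overlap ref_id {ov.ref_id!r} != read id {ref_read.id!r}")

    sketch = extract_minimizers(ref_read.seq, minimizer_cfg)
    starts = [m.start for m in sketch]
    n_cols = len(starts)
    length = len(ref_read)
    k = minimizer_cfg.k

    # Column i spans [boundary[i], boundary[i+1]); column 0 reaches back to
    # base 0 and the final column runs to the read end, so that segment base
    # ranges partition the whole read.
    boundaries = [0] + starts[1:] + [length]
    coords = [(boundaries[i], boundaries[i + 1]) for i in range(n_cols)]

    grid = np.zeros((cfg.depth, n_cols, 3), dtype=np.uint8)
    if n_cols == 0:
        return PileupImage(grid, ref_read.id, [ref_read.id], coords)

    # Row 0: the reference read contains every one of its own minimizers.
    for c in range(n_cols):
        lo, hi = coords[c]
        nxt = starts[c + 1] if c + 1 < n_cols else length
        grid[0, c] = (
            RED_MATCH,
            _green(_mean_quality(ref_read.qual, lo, hi)),
            min(nxt - starts[c], 255),
        )

    ranked = sorted(pile, key=lambda o: (-len(o.matches), o.query_id, o.strand))
    if len(ranked) > cfg.depth - 1:
        rng = np.random.default_rng(cfg.rng_seed)
        keep = sorted(rng.choice(len(ranked), size=cfg.depth - 1, replace=False))
        ranked = [ranked[i] for i in keep]

    row_reads = [ref_read.id] + [ov.query_id for ov in ranked]
    for row, ov in enumerate(ranked, start=1):
        query = reads[ov.query_id]
        cs = np.array([m.ref_index for m in ov.matches])
        qs = np.array([m.query_start for m in ov.matches], dtype=float)
        matched = set(int(c) for c in cs)
        c_first, c_last = int(cs[0]), int(cs[-1])
        # Query coordinate at each column boundary of the matched span; one
        # extra anchor past the last match closes the final interval.
        sign = 1.0 if ov.strand == "+" else -1.0
        anchor_c = np.append(cs, c_last + 1)
        anchor_q = np.append(qs, qs[-1] + sign * k)
        cols = np.arange(c_first, c_last + 2)
        qcoord = np.interp(cols, anchor_c, anchor_q)
        for c in range(c_first, c_last + 1):
            q0, q1 = qcoord[c - c_first], qcoord[c - c_first + 1]
            lo, hi = int(np.floor(min(q0, q1))), int(np.ceil(max(q0, q1)))
            grid[row, c] = (
                RED_MATCH if c in matched else RED_NO_MATCH,
                _green(_mean_quality(query.qual, lo, hi)),
                min(int(round(abs(q1 - q0))), 255),
            )
    return PileupImage(grid, ref_read.id, row_reads, coords)


def segment_pileup(img: PileupImage, cfg: PileupConfig = PileupConfig()
                   ) -> list[PileupSegment]:
    """Cut an image into consecutive ``segment_length``-column segments.

    The final partial segment is right-padded with black columns; its base
    range runs to the read end, so base ranges partition [0, read length).
    """
    n_cols = img.n_columns
    if n_cols == 0:
        return []
    seg_len = cfg.segment_length
    boundaries = [c[0] for c in img.column_coords] + [img.column_coords[-1][1]]
    segments = []
    for index, c0 in enumerate(range(0, n_cols, seg_len)):
        c1 = min(c0 + seg_len, n_cols)
        grid = np.zeros((img.grid.shape[0], seg_len, 3), dtype=np.uint8)
        grid[:, : c1 - c0] = img.grid[:, c0:c1]
        segments.append(PileupSegment(
            grid=grid, ref_id=img.ref_id, segment_index=index,
            column_range=(c0, c1), base_range=(boundaries[c0], boundaries[c1]),
        ))
    return segments


# ---------------------------------------------------------------------------
# Persistence: one HDF5 tensor container + sidecar TSV, or per-segment PNGs.
# ---------------------------------------------------------------------------

def save_segments_h5(segments: list[PileupSegment], path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("grids", data=np.stack([s.grid for s in segments])
                         if segments else np.zeros((0, 0, 0, 3), dtype=np.uint8))
        f.create_dataset("ref_id", data=[s.ref_id for s in segments])
        f.create_dataset("segment_index", data=[s.segment_index for s in segments])
        f.create_dataset("base_start", data=[s.base_range[0] for s in segments])
        f.create_dataset("base_end", data=[s.base_range[1] for s in segments])
        f.create_dataset("col_start", data=[s.column_range[0] for s in segments])
        f.create_dataset("col_end", data=[s.column_range[1] for s in segments])


def load_segments_h5(path: str | Path) -> list[PileupSegment]:
    import h5py

    with h5py.File(path, "r") as f:
        if f["grids"].shape[0] == 0:
            return []
        return [
            PileupSegment(
                grid=np.asarray(f["grids"][i]),
                ref_id=f["ref_id"][i].decode(),
                segment_index=int(f["segment_index"][i]),
                column_range=(int(f["col_start"][i]), int(f["col_end"][i])),
                base_range=(int(f["base_start"][i]), int(f["base_end"][i])),
            )
            for i in range(f["grids"].shape[0])
        ]


def write_segment_index_tsv(segments: list[PileupSegment], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("ref_id\tsegment_index\tbase_start\tbase_end\n")
        for s in segments:
            handle.write(f"{s.ref_id}\t{s.segment_index}\t"
                         f"{s.base_range[0]}\t{s.base_range[1]}\n")


def save_segment_png(segment: PileupSegment, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(segment.grid, mode="RGB").save(str(path), format="PNG")
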