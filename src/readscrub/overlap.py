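"""All-vs-all read overlap detection from shared co-linear minimizers.

Each read serves as a "reference read" once; every other read sharing at
least ``min_shared`` co-linear minimizer occurrences with it becomes a
"matching read" in its pile.  Chaining is a longest increasing subsequence
over shared occurrences (by query position, per relative strand) with a cap
on the base distance between consecutive chained matches — deliberately
simpler than a production overlapper's scored chaining, because downstream
only the matched minimizer positions are consumed.

A standard PAF file from an external overlapper can be substituted for the
native all-vs-all pass: matched minimizer positions are then recovered by
intersecting the two reads' sketches within the PAF interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import Read
from .minimizers import Minimizer, MinimizerConfig, extract_minimizers


@dataclass(frozen=True)
class OverlapConfig:
    min_shared: int = 4          # minimum co-linear shared minimizers per pair
    max_gap: int = 500           # max base distance between chained matches
    max_occurrences: int = 200   # minimizers seen in more reads are skipped

    def __post_init__(self) -> None:
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")


@dataclass(frozen=True)
class MinimizerMatch:
    """One shared minimizer: index into the reference sketch + query position."""

    ref_index: int
    query_start: int
    strand: str


@dataclass
class Overlap:
    ref_id: str
    query_id: str
    strand: str
    matches: list[MinimizerMatch] = field(default_factory=list)
    ref_span: tuple[int, int] = (0, 0)      # half-open base interval, ref read
    query_span: tuple[int, int] = (0, 0)    # half-open base interval, query read
    k: int = 15

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Overlap):
            return NotImplemented
        return (
            self.ref_id == other.ref_id
            and self.query_id == other.query_id
            and self.strand == other.strand
            and self.matches == other.matches
            and self.ref_span == other.ref_span
            and self.query_span == other.query_span
            and self.k == other.k
        )


def sketch_reads(reads: Iterable[Read], cfg: MinimizerConfig) -> dict[str, list[Minimizer]]:
    sketches: dict[str, list[Minimizer]] = {}
    for read in reads:
        if read.id in sketches:
            raise ValueError(f"duplicate read identifier {read.id!r}")
        sketches[read.id] = extract_minimizers(read.seq, cfg)
    return sketches


def build_index(reads: Iterable[Read], cfg: MinimizerConfig = MinimizerConfig()
                ) -> dict[int, list[tuple[str, int, str]]]:
    """Map each minimizer hash to every (read_id, start, strand) occurrence."""
    index: dict[int, list[tuple[str, int, str]]] = {}
    for read_id, sketch in sketch_reads(reads, cfg).items():
        for occ in sketch:
            index.setdefault(occ.hash, []).append((read_id, occ.start, occ.strand))
    return index


def _chain(pairs: list[tuple[int, int, int]], strand: str, max_gap: int
           ) -> list[tuple[int, int]]:
    """Longest gap-limited co-linear chain.

    ``pairs`` holds (ref_index, ref_base_start, query_base_start).  Returns
    (ref_index, query_start) of the best chain: ref_index strictly
    increasing, query_start strictly increasing on "+" / decreasing on "-",
    consecutive base gaps on both reads bounded by ``max_gap``.
    """
    sign = 1 if strand == "+" else -1
    pairs = sorted(pairs, key=lambda p: (p[0], sign * p[2]))
    n = len(pairs)
    if n and all(
        p[0] < q[0] and sign * (q[2] - p[2]) > 0
        and q[1] - p[1] <= max_gap and abs(q[2] - p[2]) <= max_gap
        for p, q in zip(pairs, pairs[1:])
    ):
        return [(p[0], p[2]) for p in pairs]  # already one valid chain
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        rj, bj, qj = pairs[j]
        for i in range(j):
            ri, bi, qi = pairs[i]
            if ri >= rj or sign * (qj - qi) <= 0:
                continue
            if bj - bi > max_gap or abs(qj - qi) > max_gap:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best[j], -j), default=-1)
    if end < 0:
        return []
    chain = []
    while end >= 0:
        chain.append((pairs[end][0], pairs[end][2]))
        end = prev[end]
    chain.reverse()
    return chain


def find_overlaps(reads: list[Read],
                  minimizer_cfg: MinimizerConfig = MinimizerConfig(),
                  overlap_cfg: OverlapConfig = OverlapConfig(),
                  ) -> dict[str, list[Overlap]]:
    """All-vs-all overlap detection; returns per reference read its pile."""
    sketches = sketch_reads(reads, minimizer_cfg)
    index: dict[int, list[tuple[str, int, str]]] = {}
    for read_id, sketch in sketches.items():
        for occ in sketch:
            index.setdefault(occ.hash, []).append((read_id, occ.start, occ.strand))

    k = minimizer_cfg.k
    piles: dict[str, list[Overlap]] = {}
    for read in reads:
        sketch = sketches[read.id]
        # (query_id, relative strand) -> list of (ref_index, ref_start, query_start)
        candidates: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for ref_index, occ in enumerate(sketch):
            hits = index.get(occ.hash, ())
            if len(hits) > overlap_cfg.max_occurrences:
                continue
            for query_id, qstart, qstrand in hits:
                if query_id == read.id:
                    continue
                rel = "+" if qstrand == occ.strand else "-"
                candidates.setdefault((query_id, rel), []).append(
                    (ref_index, occ.start, qstart)
                )
        pile: list[Overlap] = []
        for (query_id, rel), pairs in sorted(candidates.items()):
            chain = _chain(pairs, rel, overlap_cfg.max_gap)
            if len(chain) < overlap_cfg.min_shared:
                continue
            matches = [MinimizerMatch(ri, qs, rel) for ri, qs in chain]
            ref_starts = [sketch[m.ref_index].start for m in matches]
            qstarts = [m.query_start for m in matches]
            pile.append(Overlap(
                ref_id=read.id, query_id=query_id, strand=rel, matches=matches,
                ref_span=(min(ref_starts), max(ref_starts) + k),
                query_span=(min(qstarts), max(qstarts) + k),
                k=k,
            ))
        piles[read.id] = pile
    return piles


# ---------------------------------------------------------------------------
# Native match file: TSV with one row per overlap.
# ---------------------------------------------------------------------------

_HEADER = ("ref_id\tquery_id\tstrand\tk\tref_start\tref_end\t"
           "query_start\tquery_end\tmatches\n")


def serialize_overlaps(piles: Mapping[str, list[Overlap]], path: str | Path) -> None:
    """Write overlaps as TSV, deterministically ordered by (ref_id, query_id)."""
    with open(path, "w") as handle:
        handle.write(_HEADER)
        for ref_id in sorted(piles):
            for ov in sorted(piles[ref_id], key=lambda o: o.query_id):
                pairs = ",".join(f"{m.ref_index}:{m.query_start}" for m in ov.matches)
                handle.write(
                    f"{ov.ref_id}\t{ov.query_id}\t{ov.strand}\t{ov.k}\t"
                    f"{ov.ref_span[0]}\t{ov.ref_span[1]}\t"
                    f"{ov.query_span[0]}\t{ov.query_span[1]}\t{pairs}\n"
                )


def parse_overlaps(path: str | Path) -> dict[str, list[Overlap]]:
    piles: dict[str, list[Overlap]] = {}
    with open(path) as handle:
        header = handle.readline()
        if header != _HEADER:
            raise ValueError(f"line 1: unexpected header {header!r}")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            try:
                ref_id, query_id, strand, k, rs, re_, qs, qe, pairs = fields
                matches = [
                    MinimizerMatch(int(a), int(b), strand)
                    for a, b in (p.split(":") for p in pairs.split(","))
                ]
                ov = Overlap(
                    ref_id=ref_id, query_id=query_id, strand=strand,
                    matches=matches, ref_span=(int(rs), int(re_)),
                    query_span=(int(qs), int(qe)), k=int(k),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"line {lineno}: malformed row: {exc}") from exc
            piles.setdefault(ref_id, []).append(ov)
    return piles


# ---------------------------------------------------------------------------
# PAF input path.
# ---------------------------------------------------------------------------

def paf_to_overlaps(path: str | Path, reads: list[Read],
                    minimizer_cfg: MinimizerConfig = MinimizerConfig(),
                    overlap_cfg: OverlapConfig = OverlapConfig(),
                    symmetrize: bool = True) -> dict[str, list[Overlap]]:
    """Recover matched minimizer positions from standard PAF records.

    For each PAF record the two reads' sketches are intersected within the
    reported intervals and chained.  All-vs-all overlappers usually emit each
    pair once; ``symmetrize`` additionally processes the mirrored pair so
    every read's pile is complete.
    """
    sketches = sketch_reads(reads, minimizer_cfg)
    by_id = {r.id: r for r in reads}
    k = minimizer_cfg.k

    intervals: list[tuple[str, str, str, tuple[int, int], tuple[int, int]]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: PAF needs >= 12 columns, got {len(f)}")
            qname, _, qstart, qend, strand, tname = f[0], f[1], f[2], f[3], f[4], f[5]
            tstart, tend = f[7], f[8]
            if qname not in by_id or tname not in by_id:
                continue
            rec = (tname, qname, strand, (int(tstart), int(tend)), (int(qstart), int(qend)))
            intervals.append(rec)
            if symmetrize and qname != tname:
                intervals.append((qname, tname, strand,
                                  (int(qstart), int(qend)), (int(tstart), int(tend))))

    piles: dict[str, list[Overlap]] = {r.id: [] for r in reads}
    seen: set[tuple[str, str, str]] = set()
    for ref_id, query_id, strand, (rs, re_), (qs, qe) in intervals:
        if ref_id == query_id or (ref_id, query_id, strand) in seen:
            continue
        seen.add((ref_id, query_id, strand))
        ref_sketch = sketches[ref_id]
        query_hits: dict[int, list[tuple[int, str]]] = {}
        for occ in sketches[query_id]:
            if qs <= occ.start < qe:
                query_hits.setdefault(occ.hash, []).append((occ.start, occ.strand))
        pairs: list[tuple[int, int, int]] = []
        for ref_index, occ in enumerate(ref_sketch):
            if not (rs <= occ.start < re_):
                continue
            for qstart, qstrand in query_hits.get(occ.hash, ()):
                if ("+" if qstrand == occ.strand else "-") == strand:
                    pairs.append((ref_index, occ.start, qstart))
        chain = _chain(pairs, strand, overlap_cfg.max_gap)
        if len(chain) < overlap_cfg.min_shared:
            continue
        matches = [MinimizerMatch(ri, q, strand) for ri, q in chain]
        ref_starts = [ref_sketch[m.ref_index].start for m in matches]
        qstarts = [m.query_start for m in matches]
        piles[ref_id].append(Overlap(
            ref_id=ref_id, query_id=query_id, strand=strand, matches=matches,
            ref_span=(min(ref_starts), max(ref_starts) + k),
            query_span=(min(qstarts), max(qstarts) + k), k=k,
        ))
    for pile in piles.values():
        pile.sort(key=lambda o: o.query_id)
    return piles
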