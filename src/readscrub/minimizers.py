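"""(w,k)-minimizer extraction from nucleotide sequences.

A minimizer is the minimum-order k-mer among each window of *w* consecutive
k-mers.  Two sequences sharing an identical substring of length ``w + k - 1``
are guaranteed to share a minimizer inside it, which is what makes minimizer
sketches an effective compressed representation for read-to-read overlap
detection.

The order key is an invertible 64-bit mixing hash of the 2-bit-encoded
canonical k-mer (lexicographic minimum of the forward k-mer and its reverse
complement), so sketches are strand-agnostic and poly-A stretches are not
systematically favoured the way plain alphabetical order would favour them.
Ties within a window select every tied occurrence, which preserves the
window-sharing guarantee exactly.  k-mers containing any non-ACGT base are
ineligible and windows are formed over the remaining valid k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_MASK64 = (1 << 64) - 1


@dataclass(frozen=True)
class MinimizerConfig:
    """Sketch parameters: window size ``w`` (in k-mers) and k-mer length ``k``."""

    w: int = 5
    k: int = 15

    def __post_init__(self) -> None:
        if self.w < 1 or self.k < 1:
            raise ValueError(f"w and k must be >= 1, got w={self.w}, k={self.k}")


@dataclass(frozen=True, order=True)
class Minimizer:
    """One selected k-mer occurrence.

    ``start`` is the 0-based base position in the read, ``strand`` is the
    orientation of the canonical k-mer at that position, and ``hash`` is the
    integer order key under which it was minimal.
    """

    start: int
    strand: str  # "+" if the forward k-mer is canonical, else "-"
    hash: int


def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: an invertible avalanche over uint64."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized canonical k-mer codes.

    Returns (starts, canonical codes, forward-is-canonical flags) for every
    k-mer start whose window of k bases is N-free.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return np.empty(0, dtype=np.int64), empty, np.empty(0, dtype=bool)
    bad = (codes >= 4).astype(np.int64)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0  # length n

    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | (c64[j : j + n] & np.uint64(3))
        # complement of base at position k-1-j, placed at significance j..
        rev = (rev << np.uint64(2)) | ((np.uint64(3) - c64[k - 1 - j : k - 1 - j + n]) & np.uint64(3))
    starts = np.nonzero(valid)[0]
    fwd, rev = fwd[starts], rev[starts]
    forward_canonical = fwd <= rev
    canon = np.where(forward_canonical, fwd, rev)
    return starts, canon, forward_canonical


def extract_minimizers(seq: str, cfg: MinimizerConfig = MinimizerConfig()) -> list[Minimizer]:
    """Extract all (w,k)-minimizer occurrences of ``seq``, sorted by start.

    For every window of ``w`` consecutive valid k-mers, every occurrence
    achieving the window minimum of the order key is selected; occurrences
    are deduplicated across windows.  A sequence shorter than ``k`` (or with
    fewer than ``w`` valid k-mers) yields an empty list.
    """
    starts, canon, fwd_canon = _encode_kmers(seq, cfg.k)
    m = len(starts) - cfg.w + 1
    if m <= 0:
        return []
    hashes = _mix64(canon)
    win = np.lib.stride_tricks.sliding_window_view(hashes, cfg.w)
    mins = win.min(axis=1)
    rows, offs = np.nonzero(win == mins[:, None])
    sel = np.unique(rows + offs)
    return [
        Minimizer(int(starts[i]), "+" if fwd_canon[i] else "-", int(hashes[i]))
        for i in sel
    ]


# ---------------------------------------------------------------------------
# Brute-force oracle: explicit window enumeration with independent scalar
# arithmetic, kept free of any sliding-window optimisation so it can serve
# as a test oracle for extract_minimizers.
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SCALAR_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _scalar_mix64(x: int) -> int:
    z = (x + 0x9E3779B97F4A7C15) & _MASK64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _MASK64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return z


def _scalar_kmer(kmer: str) -> tuple[int, str]:
    """(order key, canonical strand) for one k-mer string."""
    rc = "".join(_COMP[b] for b in reversed(kmer))
    fwd_code = 0
    for b in kmer:
        fwd_code = fwd_code * 4 + _SCALAR_CODE[b]
    rc_code = 0
    for b in rc:
        rc_code = rc_code * 4 + _SCALAR_CODE[b]
    if fwd_code <= rc_code:
        return _scalar_mix64(fwd_code), "+"
    return _scalar_mix64(rc_code), "-"


def brute_force_minimizers(seq: str, cfg: MinimizerConfig = MinimizerConfig()) -> list[Minimizer]:
    """Reference implementation by explicit enumeration of every window."""
    seq = seq.upper()
    occurrences = []  # valid k-mer occurrences in order
    for start in range(len(seq) - cfg.k + 1):
        kmer = seq[start : start + cfg.k]
        if any(b not in _SCALAR_CODE for b in kmer):
            continue
        key, strand = _scalar_kmer(kmer)
        occurrences.append(Minimizer(start, strand, key))
    selected: dict[int, Minimizer] = {}
    for i in range(len(occurrences) - cfg.w + 1):
        window = occurrences[i : i + cfg.w]
        best = min(occ.hash for occ in window)
        for occ in window:
            if occ.hash == best:
                selected[occ.start] = occ
    return [selected[s] for s in sorted(selected)]


def write_minimizer_tsv(per_read: dict[str, list[Minimizer]], path) -> None:
    """Dump occurrences as TSV: read_id, start, strand, hash."""
    with open(path, "w") as handle:
        handle.write("read_id\tstart\tstrand\thash\n")
        for read_id in per_read:
            for occ in per_read[read_id]:
                handle.write(f"{read_id}\t{occ.start}\t{occ.strand}\t{occ.hash}\n")
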