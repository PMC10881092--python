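"""(w,k)-minimizer sketches and the shared-minimizer similarity.

A (w,k)-minimizer of a sequence is the k-mer with the smallest hash value in a
window of w consecutive k-mers.  The sketch of a read is the *set* of its
minimizer hashes; the similarity of two reads is the number of shared hashes
divided by the smaller sketch size, a cheap, error-tolerant proxy for the
shared-k-mer fraction.  The algorithm only ever needs to decide *dissimilarity*
(two reads from distinct genes share almost no k-mers), which this sketch
answers reliably even at long-read error rates.

The k-mer hash is a fixed, seed-free 64-bit finalizer (splitmix64) applied to
the 2-bit packed k-mer, so sketches are bit-reproducible across runs and
platforms.  With ``canonical=True`` every k-mer is replaced by the smaller of
its own packing and that of its reverse complement before hashing, which makes
sketches strand-symmetric (needed for cDNA reads, which arrive in both
orientations).  k-mers containing N are invalid and never become minimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import Read

_UINT64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)

# A,C,G,T(acgt) -> 0..3; anything else (incl. N) -> 4 = invalid
_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters: k-mer size, window of consecutive k-mers, strand mode.

    Defaults (k=11, w=5) are tuned to the long-read error regime: with ~7%
    per-base error on *each* of two reads, an 11-mer survives intact in both
    with probability ~0.2, keeping same-gene similarity comfortably above the
    alpha=0.03 dissimilarity threshold, while random cross-gene 11-mer sharing
    stays two orders of magnitude below it.  k matches the spliced aligner's
    own k-mer size; the dense window (w=5 keeps ~1/3 of k-mers) limits the
    extra variance that minimizer selection adds on noisy reads.
    """

    k: int = 11
    w: int = 5
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k > 31:
            raise ValueError("k must be <= 31 to fit the 2-bit packing in 64 bits")
        if self.w < 1:
            raise ValueError("w must be >= 1")

    @property
    def min_sketchable_length(self) -> int:
        """Shortest read with at least one full window: k + w - 1."""
        return self.k + self.w - 1


@dataclass(frozen=True)
class MinimizerSketch:
    """The set of minimizer hash values of one read (set semantics: duplicates collapse)."""

    read_index: int
    hashes: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.hashes)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # Bijective 64-bit finalizer: distinct k-mer codes get distinct hashes.
    z = x.astype(np.uint64, copy=True)
    z += np.uint64(0x9E3779B97F4A7C15)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _kmer_hash_track(sequence: str, k: int, canonical: bool) -> np.ndarray:
    """Per-position k-mer hashes; invalid (N-containing) positions hold UINT64_MAX."""
    vals = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if vals.size < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(vals, k)
    powers = np.int64(4) ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    if canonical:
        rc = (3 - win)[:, ::-1] @ powers
        codes = np.minimum(codes, rc)
    valid = (win != 4).all(axis=1)
    hashes = _splitmix64(codes.astype(np.uint64))
    hashes[~valid] = _UINT64_MAX
    return hashes


def sketch_sequence(
    sequence: str, params: SketchParams, read_index: int = 0
) -> MinimizerSketch:
    """Sketch a bare sequence (see :func:`sketch_read`)."""
    track = _kmer_hash_track(sequence, params.k, params.canonical)
    if track.size < params.w:
        return MinimizerSketch(read_index, frozenset())
    mins = np.unique(sliding_window_view(track, params.w).min(axis=1))
    if mins.size and mins[-1] == _UINT64_MAX:
        # windows with no valid k-mer contribute nothing
        mins = mins[:-1]
    return MinimizerSketch(read_index, frozenset(int(h) for h in mins))


def sketch_read(read: Read, params: SketchParams) -> MinimizerSketch:
    """Minimizer sketch of a read; empty for reads shorter than k+w-1."""
    return sketch_sequence(read.sequence, params, read.index)


def similarity(a: MinimizerSketch, b: MinimizerSketch) -> float:
    """Shared-hash count over the smaller sketch size; 0 when either sketch is empty."""
    if not a.hashes or not b.hashes:
        return 0.0
    return len(a.hashes & b.hashes) / min(a.size, b.size)


def build_inverted_index(
    sketches: Iterable[MinimizerSketch],
) -> dict[int, set[int]]:
    """Map every hash to the set of read indices whose sketch contains it.

    Reads sharing zero hashes have similarity 0 by definition, so candidate
    lookup through this index followed by :func:`similarity` is equivalent to
    exhaustive all-pairs comparison.
    """
    index: dict[int, set[int]] = {}
    for sk in sketches:
        for h in sk.hashes:
            index.setdefault(h, set()).add(sk.read_index)
    return index


def shared_hash_counts(
    sketch: MinimizerSketch, index: Mapping[int, Iterable[int]]
) -> dict[int, int]:
    """Number of hashes shared with each indexed read (absent reads share 0)."""
    counts: dict[int, int] = {}
    for h in sketch.hashes:
        for idx in index.get(h, ()):
            counts[idx] = counts.get(idx, 0) + 1
    return counts
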