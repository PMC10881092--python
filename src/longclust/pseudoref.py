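"""Pseudo-reference extraction: a maximal set of mutually dissimilar reads.

Each selected read acts as the proxy of one expressed gene.  The underlying
optimisation — maximise |P| subject to pairwise similarity < alpha over P — is
solved greedily: process reads longest-first, admit the first read
unconditionally, then admit each read longer than the length threshold L iff
its sketch similarity to every current member stays below alpha.  Transcripts
of one gene share most of their exonic sequence, so a second read from an
already-represented gene is rejected, while reads from distinct genes share
almost no minimizers and are admitted.

L is the Nxx length of the reads in play (N60 in the first iteration of the
pipeline, N80 in the second, N90 afterwards): restricting candidates to the
long half of the length distribution keeps selection cheap while the longest
reads carry the most complete exon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Read
from .sketch import MinimizerSketch, SketchParams, similarity, sketch_read


def nxx_length(lengths, fraction: float) -> int:
    """Nxx length: sort descending and return the length at which the running
    base total first reaches ``fraction`` of all bases (N50 at 0.5, etc.)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("nxx_length of an empty length list")
    if (arr <= 0).any():
        raise ValueError("read lengths must be positive")
    arr = np.sort(arr)[::-1]
    csum = np.cumsum(arr)
    target = fraction * float(csum[-1])
    pos = int(np.searchsorted(csum, target, side="left"))
    return int(arr[pos])


@dataclass
class PseudoReference:
    """Ordered gene proxies selected in one iteration.

    ``members`` are in admission order (descending length, ties by ascending
    read index); ``cluster_offset`` is the first cluster id given to this
    iteration's members by the pipeline.
    """

    members: list[Read] = field(default_factory=list)
    sketches: list[MinimizerSketch] = field(default_factory=list)
    cluster_offset: int = 0

    @property
    def member_indices(self) -> list[int]:
        return [r.index for r in self.members]

    def __len__(self) -> int:
        return len(self.members)


def select_pseudo_reference(
    reads: list[Read],
    L: int,
    alpha: float,
    params: SketchParams,
    use_index: bool = True,
) -> PseudoReference:
    """Greedy longest-first selection of mutually dissimilar reads.

    The first length-ordered read with a non-empty sketch is admitted
    unconditionally; every later read must be longer than ``L`` and have
    similarity < ``alpha`` to *all* current members.  Reads too short to sketch
    (< k+w-1) are never admitted: an empty sketch would satisfy the constraint
    vacuously, not meaningfully.

    ``use_index=False`` compares each candidate against every member directly;
    ``use_index=True`` prunes via an inverted hash index.  Both paths return
    the identical set.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not reads:
        raise ValueError("cannot select a pseudo-reference from zero reads")

    order = sorted(reads, key=lambda r: (-r.length, r.index))
    members: list[Read] = []
    sketches: list[MinimizerSketch] = []
    # inverted index over *member* hashes, mapping to member position
    index: dict[int, list[int]] = {}
    sizes: list[int] = []

    for read in order:
        if members and read.length <= L:
            continue
        sk = sketch_read(read, params)
        if not sk.hashes:
            continue
        if members:
            if use_index:
                counts: dict[int, int] = {}
                for h in sk.hashes:
                    for pos in index.get(h, ()):
                        counts[pos] = counts.get(pos, 0) + 1
                admit = all(
                    shared / min(sk.size, sizes[pos]) < alpha
                    for pos, shared in counts.items()
                )
            else:
                admit = all(similarity(sk, msk) < alpha for msk in sketches)
            if not admit:
                continue
        pos = len(members)
        members.append(read)
        sketches.append(sk)
        sizes.append(sk.size)
        if use_index:
            for h in sk.hashes:
                index.setdefault(h, []).append(pos)

    return PseudoReference(members=members, sketches=sketches)
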