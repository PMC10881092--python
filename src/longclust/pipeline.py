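"""The iterative clustering driver.

Each iteration: compute the length threshold L from the Nxx schedule
(N60, N80, N90, N90, ...), extract a pseudo-reference from the reads still in
play, seed one cluster per member, spliced-align the remaining reads against
the members, and assign every read with a proper primary alignment to its
target member's cluster.  Reads that fail to align, or whose primary alignment
is not proper, become the input of the next iteration; whatever is left after
the final iteration is reported as unclustered (-1).

The core algorithm is deterministic: identical input and configuration (and
aligner version) give byte-identical cluster tables.  Clusters are never
merged across iterations; a gene whose reads all failed in iteration 1 simply
seeds a fresh cluster later, which keeps the partition intact as long as the
gene's reads travel together.
"""

from __future__ import annotations

import contextlib
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from .aligner import (
    collect_query_alignments,
    is_proper,
    run_spliced_aligner,
    summarize_alignment,
)
from .io_formats import Read, write_fasta
from .pseudoref import PseudoReference, nxx_length, select_pseudo_reference
from .sketch import SketchParams

logger = logging.getLogger(__name__)

#: align_fn(queries_fasta, reference_fasta, out_sam, config) -> path to SAM
AlignFn = Callable[[str, str, str, "PipelineConfig"], str]


@dataclass
class PipelineConfig:
    """Tunable knobs of the clustering pipeline.

    ``L_fractions`` is the per-iteration Nxx schedule; the last value is
    reused beyond its end (N60, N80, then N90 for every later iteration).
    ``alpha`` is the maximum sketch similarity tolerated between two
    pseudo-reference members, i.e. between two putative genes.
    """

    iterations: int = 3
    alpha: float = 0.03
    L_fractions: tuple[float, ...] = (0.6, 0.8, 0.9)
    sketch: SketchParams = field(default_factory=SketchParams)
    threads: int = 1
    aligner_path: str = "minimap2"
    seed: int = 0  # used by synthetic data / testing only; clustering is deterministic

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not self.L_fractions:
            raise ValueError("L_fractions must be non-empty")

    def fraction_for(self, iteration: int) -> float:
        """Nxx fraction for a 0-based iteration number."""
        return self.L_fractions[min(iteration, len(self.L_fractions) - 1)]


@dataclass
class IterationStats:
    iteration: int
    n_input: int
    L: int
    n_members: int
    n_assigned: int
    n_leftover: int


@dataclass
class ClusterAssignment:
    """Final read-to-cluster mapping.

    ``mapping`` sends every input read index to a dense cluster id >= 0 or to
    the unclustered sentinel -1.  ``provenance`` records, per cluster, the
    iteration (0-based) and the pseudo-reference member read that seeded it.
    """

    mapping: dict[int, int] = field(default_factory=dict)
    provenance: dict[int, tuple[int, int]] = field(default_factory=dict)
    stats: list[IterationStats] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.provenance)

    @property
    def n_unclustered(self) -> int:
        return sum(1 for c in self.mapping.values() if c == -1)


@contextlib.contextmanager
def _workdir(path: str | os.PathLike | None) -> Iterator[str]:
    if path is not None:
        os.makedirs(path, exist_ok=True)
        yield os.fspath(path)
    else:
        with tempfile.TemporaryDirectory(prefix="longclust_") as td:
            yield td


def _default_align(queries: str, reference: str, out_sam: str, config: PipelineConfig) -> str:
    return run_spliced_aligner(
        queries, reference, out_sam,
        threads=config.threads, aligner_path=config.aligner_path,
    )


def run_iteration(
    reads: list[Read],
    config: PipelineConfig,
    iteration: int,
    cluster_offset: int = 0,
    align_fn: AlignFn | None = None,
    workdir: str | os.PathLike | None = None,
) -> tuple[dict[int, int], list[Read], PseudoReference, IterationStats]:
    """One clustering round over ``reads``.

    Returns (partial assignment, leftover reads, pseudo-reference, stats).
    Members occupy cluster ids ``cluster_offset .. cluster_offset+|P|-1`` in
    admission order.
    """
    if not reads:
        raise ValueError("run_iteration on zero reads")
    align_fn = align_fn or _default_align
    L = nxx_length((r.length for r in reads), config.fraction_for(iteration))
    pref = select_pseudo_reference(reads, L, config.alpha, config.sketch)
    pref.cluster_offset = cluster_offset

    assignment: dict[int, int] = {}
    cluster_of_member: dict[int, int] = {}
    for pos, member in enumerate(pref.members):
        cid = cluster_offset + pos
        assignment[member.index] = cid
        cluster_of_member[member.index] = cid

    member_set = set(cluster_of_member)
    queries = [r for r in reads if r.index not in member_set]
    leftover: list[Read] = []

    if queries and pref.members:
        with _workdir(workdir) as wd:
            ref_path = os.path.join(wd, f"pseudoref_it{iteration}.fa")
            qry_path = os.path.join(wd, f"queries_it{iteration}.fa")
            sam_path = os.path.join(wd, f"aln_it{iteration}.sam")
            # reference/query names are the stable read indices
            write_fasta(
                (Read(m.index, str(m.index), m.sequence) for m in pref.members),
                ref_path,
            )
            write_fasta((Read(r.index, str(r.index), r.sequence) for r in queries), qry_path)
            sam_path = align_fn(qry_path, ref_path, sam_path, config)
            by_query = collect_query_alignments(sam_path)
        for r in queries:
            qa = by_query.get(str(r.index))
            if qa is None or qa.primary is None:
                leftover.append(r)
                continue
            summary = summarize_alignment(qa.primary, has_secondary=qa.has_secondary)
            if is_proper(summary) and summary.target_member in cluster_of_member:
                assignment[r.index] = cluster_of_member[summary.target_member]
            else:
                leftover.append(r)
    else:
        leftover = list(queries)

    stats = IterationStats(
        iteration=iteration,
        n_input=len(reads),
        L=L,
        n_members=len(pref),
        n_assigned=len(assignment),
        n_leftover=len(leftover),
    )
    logger.info(
        "iteration %d: %d reads, L=%d, |P|=%d, assigned %d, leftover %d",
        iteration, stats.n_input, L, stats.n_members, stats.n_assigned, stats.n_leftover,
    )
    return assignment, leftover, pref, stats


def cluster(
    reads: Iterable[Read],
    config: PipelineConfig | None = None,
    align_fn: AlignFn | None = None,
    workdir: str | os.PathLike | None = None,
) -> ClusterAssignment:
    """Run the full iterative pipeline over ``reads``.

    Iterates up to ``config.iterations`` times, stopping early when no read is
    left over; reads still unassigned at the end get the sentinel -1.  Cluster
    ids are dense and ordered by (iteration, member admission order).
    """
    config = config or PipelineConfig()
    reads = list(reads)
    result = ClusterAssignment()
    current = reads
    next_cid = 0
    for it in range(config.iterations):
        if not current:
            break
        part, leftover, pref, stats = run_iteration(
            current, config, it, cluster_offset=next_cid,
            align_fn=align_fn, workdir=workdir,
        )
        if not pref.members:
            # nothing sketchable is left; further iterations cannot progress
            result.stats.append(stats)
            break
        result.mapping.update(part)
        for pos, member in enumerate(pref.members):
            result.provenance[next_cid + pos] = (it, member.index)
        next_cid += len(pref)
        result.stats.append(stats)
        current = leftover
    for r in current:
        result.mapping[r.index] = -1
    return result
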