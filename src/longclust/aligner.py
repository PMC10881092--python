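"""Spliced alignment of reads against the pseudo-reference and the
proper-alignment acceptance rules.

Alignment is delegated to minimap2 (``-ax splice -k 11``); this module is an
adapter around it: it invokes the binary, parses the resulting SAM with pysam,
distils each record into base-level counts, and decides whether an alignment
is *proper*:

  (i)  it is the primary alignment of its read, and
  (ii) its matched-base count exceeds its mismatch, insertion and deletion
       counts, and exceeds its clipped-base count unless the read has no
       secondary alignment anywhere in the SAM (in which case a dominant clip
       is tolerated — a read much longer than its best target is still
       unambiguous when nothing else attracts it).

Intron skips (N CIGAR ops) are *not* deletions: with spliced alignment a
pseudo-reference member whose isoform lacks one of the read's exons legally
skips it, and counting that skip as a deletion would reject most multi-exon
alignments.  Hard clips are counted together with soft clips so the rule does
not depend on the aligner's clip encoding.

Tests may inject a pre-written SAM file in place of a live minimap2 run; the
parsing path is identical.
"""

from __future__ import annotations

import os
import shutil
import subprocess
from dataclasses import dataclass

import pysam

# CIGAR op codes (pysam convention)
_M, _I, _D, _N, _S, _H, _EQ, _X = 0, 1, 2, 3, 4, 5, 7, 8


@dataclass(frozen=True)
class AlignmentSummary:
    """Base-level counts and flags distilled from one mapped SAM record."""

    query_index: int
    target_member: int
    is_primary: bool
    has_secondary: bool
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    clipped: int


def run_spliced_aligner(
    reads_path: str | os.PathLike,
    reference_path: str | os.PathLike,
    out_sam: str | os.PathLike,
    threads: int = 1,
    aligner_path: str = "minimap2",
) -> str:
    """Run ``minimap2 -ax splice -k 11`` and write SAM (incl. secondaries) to ``out_sam``."""
    exe = shutil.which(aligner_path) or aligner_path
    if not os.path.exists(exe) and shutil.which(aligner_path) is None:
        raise RuntimeError(f"spliced aligner not found: {aligner_path!r}")
    cmd = [
        exe, "-ax", "splice", "-k", "11", "-t", str(threads),
        os.fspath(reference_path), os.fspath(reads_path),
    ]
    with open(out_sam, "wb") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE)
    if proc.returncode != 0:
        raise RuntimeError(
            f"aligner exited with {proc.returncode}: "
            f"{proc.stderr.decode(errors='replace').strip()}"
        )
    return os.fspath(out_sam)


def _maybe_int(name: str | None) -> int:
    try:
        return int(name)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return -1


def summarize_alignment(
    record: pysam.AlignedSegment,
    nm_tag: int | None = None,
    *,
    has_secondary: bool = False,
) -> AlignmentSummary:
    """Distil a mapped SAM record into an :class:`AlignmentSummary`.

    With =/X CIGARs the match/mismatch split is read off directly; with M ops
    it is derived from the NM tag (NM = mismatches + inserted + deleted bases),
    which must then be present.  N (intron) ops are excluded from deletions;
    soft and hard clips are pooled.
    """
    if record.is_unmapped:
        raise ValueError(f"cannot summarize unmapped record {record.query_name!r}")
    cigar = record.cigartuples or []
    ins = sum(ln for op, ln in cigar if op == _I)
    dels = sum(ln for op, ln in cigar if op == _D)
    clipped = sum(ln for op, ln in cigar if op in (_S, _H))
    n_m = sum(ln for op, ln in cigar if op == _M)
    n_eq = sum(ln for op, ln in cigar if op == _EQ)
    n_x = sum(ln for op, ln in cigar if op == _X)

    if n_m > 0:
        if nm_tag is None:
            nm_tag = record.get_tag("NM") if record.has_tag("NM") else None
        if nm_tag is None:
            raise ValueError(
                f"record {record.query_name!r}: M-op CIGAR without NM tag, "
                "cannot split matches from mismatches"
            )
        mismatches = int(nm_tag) - ins - dels
        matches = n_m + n_eq + n_x - mismatches
    else:
        mismatches = n_x
        matches = n_eq
    if mismatches < 0 or matches < 0:
        raise ValueError(
            f"record {record.query_name!r}: inconsistent NM/CIGAR "
            f"(matches={matches}, mismatches={mismatches})"
        )
    return AlignmentSummary(
        query_index=_maybe_int(record.query_name),
        target_member=_maybe_int(record.reference_name),
        is_primary=not record.is_secondary and not record.is_supplementary,
        has_secondary=has_secondary,
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dels,
        clipped=clipped,
    )


def is_proper(a: AlignmentSummary) -> bool:
    """Apply the proper-alignment acceptance rules (see module docstring)."""
    return (
        a.is_primary
        and a.matches > a.mismatches
        and a.matches > a.insertions
        and a.matches > a.deletions
        and (a.matches > a.clipped or not a.has_secondary)
    )


@dataclass
class QueryAlignments:
    """Per-query digest of a SAM: the primary record plus a secondary-existence flag."""

    primary: pysam.AlignedSegment | None = None
    has_secondary: bool = False


def collect_query_alignments(sam_path: str | os.PathLike) -> dict[str, QueryAlignments]:
    """Single streaming pass over a SAM, grouping records by query name.

    ``has_secondary`` is true when any record of the query carries flag 0x100.
    Unmapped queries appear with ``primary=None``.
    """
    out: dict[str, QueryAlignments] = {}
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            qa = out.setdefault(rec.query_name, QueryAlignments())
            if rec.is_secondary:
                qa.has_secondary = True
            elif not rec.is_supplementary and not rec.is_unmapped:
                qa.primary = rec
    return out
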