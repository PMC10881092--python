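"""Reading and writing of reads, cluster tables and truth tables.

Reads are identified throughout the package by their 1-based position in the
input FASTA/FASTQ file; the original header token is carried along for human
consumption only.  Input may be plain or gzip-compressed; wrapped (multi-line)
FASTA is accepted on input, output FASTA is always unwrapped.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """One sequencing read.

    ``index`` is the 1-based position of the record in the input file and is
    the read's stable identity everywhere in this package.  ``quality`` is
    ``None`` for FASTA input and a length-matched string for FASTQ.
    """

    index: int
    name: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.index} ({self.name}): quality length "
                f"{len(self.quality)} != sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    path = os.fspath(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def detect_format(path: str | os.PathLike) -> str:
    """Return ``"fasta"`` or ``"fastq"`` from the first character ('>' vs '@')."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        # Empty file: format is moot, callers get an empty stream.
        return "fasta"
    raise ValueError(f"{path}: cannot detect format from first character {first!r}")


def read_sequences(
    path: str | os.PathLike, format: str = "auto"
) -> Iterator[Read]:
    """Stream :class:`Read` records from a FASTA/FASTQ file (plain or gzip).

    Records are yielded in file order with 1-based indices and uppercased
    sequences.  A malformed FASTQ record (sequence/quality length mismatch)
    raises ``ValueError`` naming the record index; an empty file yields an
    empty stream.
    """
    if format == "auto":
        format = detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path) as fh:
        if format == "fasta":
            for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
                yield Read(i, title.split()[0] if title else f"read{i}", seq.upper())
        else:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ValueError(f"malformed FASTQ record {i + 1}: {exc}") from exc
                i += 1
                yield Read(i, title.split()[0] if title else f"read{i}", seq.upper(), qual)


def write_fasta(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.name}\n{r.sequence}\n")


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * r.length
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def write_cluster_table(
    mapping: dict[int, int], names: dict[int, str], path: str | os.PathLike
) -> None:
    """Write ``clusters.tsv``: ``read_index<TAB>read_name<TAB>cluster_id``."""
    with open(path, "wt") as fh:
        fh.write("#read_index\tread_name\tcluster_id\n")
        for idx in sorted(mapping):
            fh.write(f"{idx}\t{names.get(idx, f'read{idx}')}\t{mapping[idx]}\n")


def read_cluster_table(path: str | os.PathLike) -> tuple[dict[int, int], dict[int, str]]:
    """Read ``clusters.tsv`` back into (index->cluster, index->name)."""
    mapping: dict[int, int] = {}
    names: dict[int, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            idx = int(fields[0])
            mapping[idx] = int(fields[-1])
            if len(fields) >= 3:
                names[idx] = fields[1]
    return mapping, names


def write_truth_table(mapping: dict[int, int], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("#read_index\tclass_id\n")
        for idx in sorted(mapping):
            fh.write(f"{idx}\t{mapping[idx]}\n")


def read_truth_table(path: str | os.PathLike) -> dict[int, int]:
    mapping: dict[int, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            idx, cls = line.split()[:2]
            mapping[int(idx)] = int(cls)
    return mapping


def write_outputs(
    mapping: dict[int, int],
    reads: Iterable[Read],
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Materialize clustering results into ``outdir``.

    Writes ``clusters.tsv`` (one row per read), one sequence file per cluster
    id >= 0 with the sequences retrieved from the original reads, and an
    ``unclustered`` file for sentinel (-1) reads.  Output format follows the
    input: FASTQ when reads carry qualities, FASTA otherwise.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    reads = list(reads)
    names = {r.index: r.name for r in reads}
    by_cluster: dict[int, list[Read]] = {}
    for r in reads:
        by_cluster.setdefault(mapping.get(r.index, -1), []).append(r)

    is_fastq = any(r.quality is not None for r in reads)
    ext = "fq" if is_fastq else "fa"
    writer = write_fastq if is_fastq else write_fasta

    paths: dict[str, Path] = {}
    table = outdir / "clusters.tsv"
    write_cluster_table({r.index: mapping.get(r.index, -1) for r in reads}, names, table)
    paths["clusters.tsv"] = table
    for cid in sorted(by_cluster):
        fname = f"unclustered.{ext}" if cid == -1 else f"cluster_{cid}.{ext}"
        writer(by_cluster[cid], outdir / fname)
        paths[fname] = outdir / fname
    return paths
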