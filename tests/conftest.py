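"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from longclust.io_formats import Read, reverse_complement

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def kmer_set(seq: str, k: int, canonical: bool = False) -> set[str]:
    """Brute-force enumeration of the distinct (optionally canonical) k-mers."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if any(b not in BASES for b in km):
            continue
        if canonical:
            km = min(km, reverse_complement(km))
        out.add(km)
    return out


def kmer_similarity_oracle(a: str, b: str, k: int, canonical: bool = False) -> float:
    """Exact shared-k-mer fraction: |A ∩ B| / min(|A|, |B|) over distinct k-mers."""
    sa, sb = kmer_set(a, k, canonical), kmer_set(b, k, canonical)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Simple independent sub/ins/del channel (equal thirds) for test instances."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 3:
            out.append(BASES[int(rng.integers(0, 4))])  # substitution (may be silent)
        elif r < 2 * rate / 3:
            out.append(ch)
            out.append(BASES[int(rng.integers(0, 4))])  # insertion
        elif r < rate:
            pass  # deletion
        else:
            out.append(ch)
    return "".join(out)


SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 1_000_000}]}
)


def make_record(
    cigar: str,
    nm: int | None = None,
    flag: int = 0,
    name: str = "q1",
    ref_start: int = 0,
) -> pysam.AlignedSegment:
    """Build a synthetic SAM record for summarize_alignment tests."""
    rec = pysam.AlignedSegment(SAM_HEADER)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = ref_start
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    if nm is not None:
        rec.set_tag("NM", nm)
    return rec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240201)
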