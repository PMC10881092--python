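"""Clustering evaluation: alignment-derived ground truth and external metrics.

Ground truth for real data is built from a reads-vs-genome SAM: each read's
primary alignment becomes a genomic interval, and the connected components of
the "overlaps by >= 1 bp on the same chromosome" relation are the true classes.
Overlap is strand-agnostic (overlapping antisense genes therefore merge — a
known limitation of this construction).  Unmapped reads cannot be assigned a
class and are excluded from evaluation.

Four external metrics are computed from the contingency table between the
predicted clustering and the truth:

* ARI    — pair-counting agreement, chance-corrected under the permutation
           model: (Index - E[Index]) / (MaxIndex - E[Index]).
* FMI    — geometric mean of pairwise precision and recall:
           TP / sqrt((TP+FP)(TP+FN)) over read pairs.
* NMI    — mutual information normalized by the arithmetic mean of the two
           partition entropies.
* V-Measure — harmonic mean of homogeneity and completeness (beta = 1);
           with arithmetic NMI normalization the two coincide analytically.

A perfect clustering scores exactly 1 on all four; a random assignment scores
about 0.  Reads the tool left unclustered but that do have a true class are
scored as singleton clusters — dropping them would inflate the scores.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pysam

from .pipeline import ClusterAssignment


@dataclass
class GroundTruth:
    """True classes keyed by read id, plus the reads excluded as unaligned."""

    mapping: dict[Hashable, int] = field(default_factory=dict)
    excluded: set[Hashable] = field(default_factory=set)

    @property
    def n_classes(self) -> int:
        return len(set(self.mapping.values()))


@dataclass(frozen=True)
class MetricReport:
    ari: float
    v_measure: float
    fmi: float
    nmi: float
    n_reads_evaluated: int

    def as_dict(self) -> dict[str, float]:
        return {
            "ari": self.ari,
            "v_measure": self.v_measure,
            "fmi": self.fmi,
            "nmi": self.nmi,
            "n_reads_evaluated": self.n_reads_evaluated,
        }


def _read_key(name: str) -> Hashable:
    # SAM query names that look like our stable read indices become ints
    return int(name) if name.isdigit() else name


def classes_from_intervals(
    intervals: Mapping[Hashable, tuple[str, int, int]],
) -> dict[Hashable, int]:
    """Connected components of half-open interval overlap, per chromosome.

    Intervals are (chrom, start, end) with end exclusive; two intervals are in
    the same class iff they are linked by a chain of >= 1 bp overlaps.  Class
    ids are dense, assigned in (chrom, sweep) order.
    """
    by_chrom: dict[str, list[tuple[int, int, Hashable]]] = {}
    for key, (chrom, start, end) in intervals.items():
        by_chrom.setdefault(chrom, []).append((start, end, key))
    classes: dict[Hashable, int] = {}
    next_class = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1], str(t[2])))
        current_end = None
        for start, end, key in ivs:
            if current_end is None or start >= current_end:
                cls = next_class
                next_class += 1
                current_end = end
            else:
                current_end = max(current_end, end)
            classes[key] = cls
    return classes


def truth_from_genome_sam(sam_path: str | os.PathLike) -> GroundTruth:
    """Build ground truth from a reads-vs-genome SAM.

    Keeps only primary alignments (flag 0x100/0x800 clear); reads with no
    mapped primary record land in ``excluded``.
    """
    intervals: dict[Hashable, tuple[str, int, int]] = {}
    seen: set[Hashable] = set()
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            key = _read_key(rec.query_name)
            seen.add(key)
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            intervals[key] = (rec.reference_name, rec.reference_start, rec.reference_end)
    mapping = classes_from_intervals(intervals)
    return GroundTruth(mapping=mapping, excluded=seen - set(mapping))


def _contingency(labels_true: Sequence[int], labels_pred: Sequence[int]) -> np.ndarray:
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def _comb2_sum(counts: np.ndarray) -> int:
    c = counts[counts > 1].astype(object)
    return int(sum(c * (c - 1) // 2))


def _entropy(counts: np.ndarray, n: int) -> float:
    nz = counts[counts > 0].astype(float)
    return float(-(nz / n * (np.log(nz) - math.log(n))).sum())


def metrics_from_labels(
    labels_true: Sequence[int], labels_pred: Sequence[int]
) -> MetricReport:
    """ARI, V-Measure, FMI, NMI from two label vectors over the same reads."""
    n = len(labels_true)
    if n == 0 or n != len(labels_pred):
        raise ValueError("label vectors must be non-empty and of equal length")
    table = _contingency(labels_true, labels_pred)
    a = table.sum(axis=1)  # true class sizes
    b = table.sum(axis=0)  # predicted cluster sizes

    # identical partitions (up to relabeling): contingency is a permutation
    # pattern; all metrics are exactly 1 and are reported as such
    if ((table > 0).sum(axis=0) == 1).all() and ((table > 0).sum(axis=1) == 1).all():
        return MetricReport(1.0, 1.0, 1.0, 1.0, n)

    s_ij = _comb2_sum(table.ravel())
    s_a = _comb2_sum(a)
    s_b = _comb2_sum(b)
    n_pairs = n * (n - 1) // 2

    # ARI (pair counting, permutation-model expectation)
    expected = s_a * s_b / n_pairs if n_pairs else 0.0
    max_index = (s_a + s_b) / 2.0
    ari = 1.0 if max_index == expected else (s_ij - expected) / (max_index - expected)

    # FMI
    fmi = s_ij / math.sqrt(s_a * s_b) if s_ij > 0 else 0.0

    # entropies and mutual information
    h_true = _entropy(a, n)
    h_pred = _entropy(b, n)
    nzr, nzc = np.nonzero(table)
    nij = table[nzr, nzc].astype(float)
    mi = float(
        (nij / n * (np.log(nij) + math.log(n) - np.log(a[nzr].astype(float))
                    - np.log(b[nzc].astype(float)))).sum()
    )
    mi = max(mi, 0.0)

    # conditional entropies for homogeneity/completeness
    h_true_given_pred = float(-(nij / n * (np.log(nij) - np.log(b[nzc].astype(float)))).sum())
    h_pred_given_true = float(-(nij / n * (np.log(nij) - np.log(a[nzr].astype(float)))).sum())
    homogeneity = 1.0 if h_true == 0 else 1.0 - h_true_given_pred / h_true
    completeness = 1.0 if h_pred == 0 else 1.0 - h_pred_given_true / h_pred
    v = (
        0.0
        if homogeneity + completeness == 0
        else 2.0 * homogeneity * completeness / (homogeneity + completeness)
    )

    if len(a) == 1 and len(b) == 1:
        nmi = 1.0
    elif mi == 0.0:
        nmi = 0.0
    else:
        nmi = mi / ((h_true + h_pred) / 2.0)
    return MetricReport(float(ari), float(v), float(fmi), min(float(nmi), 1.0), n)


def _pred_mapping(pred: ClusterAssignment | Mapping[Hashable, int]) -> Mapping[Hashable, int]:
    return pred.mapping if isinstance(pred, ClusterAssignment) else pred


def _label_vectors(
    pred: Mapping[Hashable, int], truth: GroundTruth, keys: Iterable[Hashable]
) -> tuple[list[int], list[int]]:
    keys = sorted(keys, key=str)
    if not keys:
        raise ValueError("no reads shared between prediction and ground truth")
    labels_true = [truth.mapping[k] for k in keys]
    labels_pred = []
    next_singleton = max((c for c in pred.values() if c >= 0), default=-1) + 1
    for k in keys:
        c = pred.get(k, -1)
        if c == -1:
            # unclustered reads count as singleton clusters
            c = next_singleton
            next_singleton += 1
        labels_pred.append(c)
    return labels_true, labels_pred


def compute_metrics(
    pred: ClusterAssignment | Mapping[Hashable, int], truth: GroundTruth
) -> MetricReport:
    """Score a predicted clustering against the ground truth.

    Evaluation is restricted to reads present in ``truth.mapping`` (unaligned
    reads are excluded by construction); predicted-unclustered reads are
    scored as singleton clusters.
    """
    pred_map = _pred_mapping(pred)
    labels_true, labels_pred = _label_vectors(pred_map, truth, truth.mapping.keys())
    return metrics_from_labels(labels_true, labels_pred)


def stratified_metrics(
    pred: ClusterAssignment | Mapping[Hashable, int],
    truth: GroundTruth,
    bins: int = 5,
) -> list[MetricReport]:
    """Metrics stratified by true class size (expression level).

    Classes are sorted by size ascending (ties by class id) and split into
    ``bins`` contiguous parts of near-equal class count — low through high
    expression; with fewer classes than bins, fewer (never empty) parts are
    returned.  Each part's metrics are computed over the reads whose *true*
    class falls in the part.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    pred_map = _pred_mapping(pred)
    sizes: dict[int, int] = {}
    for cls in truth.mapping.values():
        sizes[cls] = sizes.get(cls, 0) + 1
    order = sorted(sizes, key=lambda c: (sizes[c], c))
    parts = np.array_split(np.asarray(order), min(bins, len(order)))
    reports = []
    for part in parts:
        part_set = set(int(c) for c in part)
        keys = [k for k, cls in truth.mapping.items() if cls in part_set]
        sub_truth = GroundTruth(mapping={k: truth.mapping[k] for k in keys})
        labels_true, labels_pred = _label_vectors(pred_map, sub_truth, keys)
        reports.append(metrics_from_labels(labels_true, labels_pred))
    return reports
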