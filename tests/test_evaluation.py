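"""Ground-truth construction and the ARI/V-Measure/FMI/NMI kernel."""

import itertools
import math

import numpy as np
import pytest

from longclust.evaluation import (
    GroundTruth,
    classes_from_intervals,
    compute_metrics,
    metrics_from_labels,
    stratified_metrics,
    truth_from_genome_sam,
)


def _write_sam(path, records, chroms=("chr1", "chr2")):
    lines = ["@HD\tVN:1.6"]
    for c in chroms:
        lines.append(f"@SQ\tSN:{c}\tLN:100000000")
    for name, flag, chrom, pos, cigar in records:
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


class TestGroundTruth:
    def test_direct_overlap_same_class(self):
        classes = classes_from_intervals(
            {"a": ("chr1", 100, 200), "b": ("chr1", 150, 300)}
        )
        assert classes["a"] == classes["b"]

    def test_transitive_chain_one_class(self):
        classes = classes_from_intervals(
            {"a": ("chr1", 100, 200), "b": ("chr1", 190, 400), "c": ("chr1", 390, 600)}
        )
        assert len(set(classes.values())) == 1

    def test_chromosomes_separate_classes(self):
        classes = classes_from_intervals(
            {"a": ("chr1", 100, 200), "b": ("chr2", 100, 200)}
        )
        assert classes["a"] != classes["b"]

    def test_touching_intervals_do_not_overlap(self):
        # half-open: [100,200) and [200,300) share no base
        classes = classes_from_intervals(
            {"a": ("chr1", 100, 200), "b": ("chr1", 200, 300)}
        )
        assert classes["a"] != classes["b"]

    def test_sam_primary_only_and_unmapped_excluded(self, tmp_path):
        sam = _write_sam(
            tmp_path / "g.sam",
            [
                ("1", 0, "chr1", 101, "100M"),
                ("1", 256, "chr2", 500, "100M"),  # secondary: ignored
                ("2", 0, "chr1", 151, "100M"),
                ("3", 4, "*", 0, "*"),  # unmapped
                ("4", 0, "chr2", 101, "100M"),
            ],
        )
        truth = truth_from_genome_sam(sam)
        assert truth.mapping[1] == truth.mapping[2]
        assert truth.mapping[4] != truth.mapping[1]
        assert truth.excluded == {3}
        assert truth.n_classes == 2


def pair_counting_oracle(labels_true, labels_pred):
    """ARI and FMI by exhaustive enumeration of all read pairs."""
    n = len(labels_true)
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t = labels_true[i] == labels_true[j]
        same_p = labels_pred[i] == labels_pred[j]
        tp += same_t and same_p
        fp += (not same_t) and same_p
        fn += same_t and (not same_p)
        tn += (not same_t) and (not same_p)
    pairs = tp + fp + fn + tn
    index = tp
    expected = (tp + fn) * (tp + fp) / pairs
    max_index = ((tp + fn) + (tp + fp)) / 2
    ari = 1.0 if max_index == expected else (index - expected) / (max_index - expected)
    fmi = tp / math.sqrt((tp + fp) * (tp + fn)) if tp else 0.0
    return ari, fmi


class TestMetricKernel:
    def test_perfect_clustering_is_exactly_one(self):
        rep = metrics_from_labels([0, 0, 1, 1, 2], [5, 5, 9, 9, 7])
        assert (rep.ari, rep.v_measure, rep.fmi, rep.nmi) == (1.0, 1.0, 1.0, 1.0)

    def test_crossed_pairs_worked_example(self):
        # truth {a,b | c,d}, pred {a,c | b,d}
        rep = metrics_from_labels([0, 0, 1, 1], [0, 1, 0, 1])
        ari, fmi = pair_counting_oracle([0, 0, 1, 1], [0, 1, 0, 1])
        assert rep.ari == pytest.approx(ari)
        assert rep.ari == pytest.approx(-0.5)
        assert rep.fmi == pytest.approx(fmi)

    def test_single_predicted_cluster_fmi(self):
        labels_true = [0, 0, 1, 1]
        labels_pred = [9, 9, 9, 9]
        rep = metrics_from_labels(labels_true, labels_pred)
        _, fmi = pair_counting_oracle(labels_true, labels_pred)
        assert rep.fmi == pytest.approx(fmi)
        assert rep.fmi == pytest.approx(2 / math.sqrt(6 * 2))

    def test_pair_counting_oracle_on_random_partitions(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            lt = rng.integers(0, 4, size=n).tolist()
            lp = rng.integers(0, 4, size=n).tolist()
            rep = metrics_from_labels(lt, lp)
            ari, fmi = pair_counting_oracle(lt, lp)
            assert rep.ari == pytest.approx(ari, abs=1e-12)
            assert rep.fmi == pytest.approx(fmi, abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self, rng):
        lt = rng.integers(0, 5, size=40).tolist()
        lp = rng.integers(0, 5, size=40).tolist()
        assert metrics_from_labels(lt, lp).nmi == pytest.approx(
            metrics_from_labels(lp, lt).nmi, abs=1e-12
        )
        relabeled = [c + 100 for c in lp]
        assert metrics_from_labels(lt, lp).ari == pytest.approx(
            metrics_from_labels(lt, relabeled).ari, abs=1e-12
        )

    def test_unclustered_reads_scored_as_singletons(self):
        truth = GroundTruth(mapping={1: 0, 2: 0, 3: 1, 4: 1})
        rep_all_unclustered = compute_metrics({1: -1, 2: -1, 3: -1, 4: -1}, truth)
        # four singletons vs two 2-classes: homogeneous but incomplete
        assert rep_all_unclustered.v_measure < 1.0
        rep_partial = compute_metrics({1: 0, 2: 0, 3: 1, 4: -1}, truth)
        assert rep_partial.ari < 1.0  # the dropped read costs agreement

    def test_disjoint_domains_error(self):
        truth = GroundTruth(mapping={})
        with pytest.raises(ValueError):
            compute_metrics({1: 0}, truth)


class TestStratified:
    def _truth(self, sizes):
        mapping = {}
        idx = 0
        for cls, size in enumerate(sizes):
            for _ in range(size):
                idx += 1
                mapping[idx] = cls
        return GroundTruth(mapping=mapping)

    def test_even_split_of_ten_classes(self):
        truth = self._truth([2] * 10)
        reports = stratified_metrics({k: v for k, v in truth.mapping.items()}, truth, bins=5)
        assert len(reports) == 5
        assert all(r.n_reads_evaluated == 4 for r in reports)

    def test_seven_classes_into_five_parts(self):
        truth = self._truth([1, 2, 3, 4, 5, 6, 7])
        reports = stratified_metrics(dict(truth.mapping), truth, bins=5)
        # near-equal class counts: {2,2,1,1,1}, sorted by ascending class size
        assert [r.n_reads_evaluated for r in reports] == [1 + 2, 3 + 4, 5, 6, 7]

    def test_perfect_prediction_perfect_in_every_bin(self):
        truth = self._truth([3, 5, 8, 2, 6])
        reports = stratified_metrics(dict(truth.mapping), truth, bins=5)
        assert all(r.ari == 1.0 and r.nmi == 1.0 for r in reports)

    def test_fewer_classes_than_bins(self):
        truth = self._truth([4, 4])
        reports = stratified_metrics(dict(truth.mapping), truth, bins=5)
        assert len(reports) == 2
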