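"""Scoring: label matching against an exhaustive permutation oracle,
majority merging, the difference-to-reference statistic and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cytobench import (
    ClusteringResult,
    LabeledDataset,
    difference_to_reference,
    evaluate_dataset,
    match_labels,
    merge_to_k,
    summarize,
)
from cytobench.evaluation import records_frame


def labels_from_contingency(table):
    """Expand a contingency table into (reference, predicted) label arrays."""
    ref, pred = [], []
    for i, row in enumerate(table, start=1):
        for j, count in enumerate(row, start=1):
            ref.extend([i] * count)
            pred.extend([j] * count)
    return np.array(ref), np.array(pred)


def best_overlap_bruteforce(reference, predicted):
    """Oracle: maximum total overlap over all label bijections."""
    ref_vals = sorted(set(reference))
    pred_vals = sorted(set(predicted))
    best = -1
    for perm in itertools.permutations(ref_vals):
        mapping = dict(zip(pred_vals, perm))
        overlap = int(np.sum([mapping[p] == r for r, p in zip(reference, predicted)]))
        best = max(best, overlap)
    return best


class TestMatchLabels:
    def test_dominant_diagonal_identity(self):
        ref, pred = labels_from_contingency([[900, 100], [50, 950]])
        assert match_labels(ref, pred) == {1: 1, 2: 2}

    def test_recovers_permutation_of_perfect_clustering(self):
        ref = np.repeat([1, 2, 3], 50)
        pred = np.choose(ref - 1, [3, 1, 2])  # 1->3, 2->1, 3->2
        mapping = match_labels(ref, pred)
        assert mapping == {3: 1, 1: 2, 2: 3}
        assert np.all(np.array([mapping[p] for p in pred]) == ref)

    def test_symmetric_tie_breaks_to_smallest_reference_label(self):
        ref, pred = labels_from_contingency([[50, 50], [50, 50]])
        assert match_labels(ref, pred) == {1: 1, 2: 2}

    def test_k_mismatch_is_an_error(self):
        ref = np.repeat([1, 2], 10)
        pred = np.ones(20, dtype=int)
        with pytest.raises(ValueError, match="merge_to_k"):
            match_labels(ref, pred)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_optimality_against_permutation_oracle(self, k, rng):
        """Assignment overlap equals the exhaustive-permutation maximum
        on random contingency tables."""
        for _ in range(25):
            table = rng.integers(0, 60, size=(k, k))
            table[np.arange(k), np.arange(k)] += 1  # no empty labels
            ref, pred = labels_from_contingency(table.tolist())
            mapping = match_labels(ref, pred)
            overlap = int(np.sum([mapping[p] == r for r, p in zip(ref, pred)]))
            assert overlap == best_overlap_bruteforce(ref, pred)


class TestMergeToK:
    def test_pure_subclusters_merge_cleanly(self, rng):
        """Eight >=90%-pure sub-clusters merge to k labels with >=90%
        agreement (over-clustering surrogate)."""
        ref = np.repeat([1, 2], 400)
        pred = np.empty_like(ref)
        # sub-clusters 1..4 mostly in ref 1, 5..8 mostly in ref 2
        for i in range(8):
            block = slice(i * 100, (i + 1) * 100)
            pred[block] = i + 1
        # 10% impurity per sub-cluster
        impure = rng.choice(800, size=80, replace=False)
        ref_mixed = ref.copy()
        ref_mixed[impure] = 3 - ref_mixed[impure]
        merged, merge_map = merge_to_k(ref_mixed, pred, 2)
        assert set(merged) <= {1, 2}
        assert len(merge_map) == 8
        assert np.mean(merged == ref_mixed) >= 0.9

    def test_identity_when_already_k(self):
        ref = np.repeat([1, 2], 10)
        merged, merge_map = merge_to_k(ref, ref, 2)
        assert np.array_equal(merged, ref)
        assert merge_map == {1: 1, 2: 2}

    def test_fifty_fifty_subcluster_ties_to_smallest_label(self):
        ref = np.array([1] * 10 + [2] * 10 + [1] * 5 + [2] * 5)
        pred = np.array([1] * 10 + [2] * 10 + [3] * 10)
        merged, merge_map = merge_to_k(ref, pred, 2)
        assert merge_map[3] == 1

    def test_cannot_split(self):
        ref = np.repeat([1, 2], 10)
        with pytest.raises(ValueError, match="split"):
            merge_to_k(ref, np.ones(20, dtype=int), 2)

    def test_merge_never_hurts_constrained_matching(self, rng):
        """Majority merging never lowers the best-bijection overlap
        relative to matching raw sub-clusters truncated to k."""
        for _ in range(50):
            k = int(rng.integers(2, 4))
            sub = int(rng.integers(k, 8))
            ref = rng.integers(1, k + 1, size=300)
            pred = rng.integers(1, sub + 1, size=300)
            if len(np.unique(pred)) < k or len(np.unique(ref)) < k:
                continue
            merged, _ = merge_to_k(ref, pred, k)
            merged_overlap = best_overlap_bruteforce(ref.tolist(), merged.tolist())
            # constrained alternative: keep the k largest sub-clusters as-is,
            # assign the rest arbitrarily to the largest kept label
            vals, counts = np.unique(pred, return_counts=True)
            keep = vals[np.argsort(counts)[-k:]]
            fallback = keep[-1]
            alt = np.where(np.isin(pred, keep), pred, fallback)
            alt_overlap = best_overlap_bruteforce(ref.tolist(), alt.tolist())
            assert merged_overlap >= alt_overlap


class TestDifferenceToReference:
    @pytest.mark.parametrize(
        "a,b,total,expected",
        [(1000, 950, 2000, 2.5), (700, 700, 1400, 0.0), (1000, 1200, 2000, 10.0)],
    )
    def test_worked_arithmetic(self, a, b, total, expected):
        assert difference_to_reference(a, b, total) == pytest.approx(expected)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(100):
            total = int(rng.integers(1, 5000))
            a = int(rng.integers(0, total + 1))
            b = int(rng.integers(0, total + 1))
            d = difference_to_reference(a, b, total)
            assert d == difference_to_reference(b, a, total)
            assert 0.0 <= d <= 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            difference_to_reference(0, 0, 0)


def _toy_dataset(ref_labels):
    events = np.column_stack([ref_labels * 10.0, np.zeros_like(ref_labels, float)])
    return LabeledDataset(
        events=events,
        labels=ref_labels,
        meta={"family": "separation", "k": len(set(ref_labels)), "target_si": 0.2,
              "measured_si": 0.2, "shape_alpha": 0.0, "orientation": "none",
              "replicate": 1, "seed": "0"},
    )


class TestEvaluateDataset:
    def test_perfect_clustering_scores_zero(self):
        ref = np.repeat([1, 2], 1000)
        ds = _toy_dataset(ref)
        rec = evaluate_dataset(ds, ClusteringResult(labels=ref[::-1], source="x"))
        assert rec.difference_pct == 0.0

    def test_single_cluster_output_scores_fifty(self):
        ref = np.repeat([1, 2], 1000)
        ds = _toy_dataset(ref)
        rec = evaluate_dataset(ds, ClusteringResult(labels=np.ones(2000, int),
                                                    source="collapsed"))
        assert rec.difference_pct == 50.0
        assert rec.k_returned == 1

    def test_thirty_swapped_events(self):
        ref = np.repeat([1, 2], 1000)
        pred = ref.copy()
        pred[:30] = 2  # 30 events move from cluster 1 to 2
        ds = _toy_dataset(ref)
        rec = evaluate_dataset(ds, ClusteringResult(labels=pred, source="x"))
        assert rec.reference_count_a == 1000
        assert rec.predicted_count_b == 970
        assert rec.difference_pct == pytest.approx(1.5)

    def test_overclustered_output_is_merged(self):
        ref = np.repeat([1, 2], 1000)
        pred = np.concatenate([
            np.repeat([1, 3], 500),  # two sub-clusters inside ref 1
            np.repeat(2, 1000),
        ])
        ds = _toy_dataset(ref)
        rec = evaluate_dataset(ds, ClusteringResult(labels=pred, source="x"))
        assert rec.k_returned == 3
        assert rec.difference_pct == 0.0
        assert rec.merge_map == {1: 1, 3: 1, 2: 2}

    def test_length_mismatch_rejected(self):
        ds = _toy_dataset(np.repeat([1, 2], 10))
        with pytest.raises(Exception):
            evaluate_dataset(ds, ClusteringResult(labels=np.ones(5, int), source="x"))


class TestSummarize:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({
            "family": ["separation"] * 2,
            "condition": ["SI +0.2"] * 2,
            "source": ["kmeans"] * 2,
            "difference_pct": [2.0, 4.0],
        })
        row = summarize(df).iloc[0]
        assert row["mean_difference_pct"] == pytest.approx(3.0)
        assert row["sd_difference_pct"] == pytest.approx(np.sqrt(2), abs=1e-5)
        assert row["cv_pct"] == pytest.approx(47.14, abs=0.01)
        assert row["n_replicates"] == 2

    def test_single_record_sd_is_missing_not_zero(self):
        df = pd.DataFrame({"family": ["skew"], "condition": ["alpha 10 tail_tail"],
                           "source": ["gmm_em"], "difference_pct": [1.0]})
        row = summarize(df).iloc[0]
        assert np.isnan(row["sd_difference_pct"])
        assert np.isnan(row["cv_pct"])

    def test_identical_records_give_zero_spread(self):
        df = pd.DataFrame({"family": ["s"] * 9, "condition": ["c"] * 9,
                           "source": ["x"] * 9, "difference_pct": [2.5] * 9})
        row = summarize(df).iloc[0]
        assert row["sd_difference_pct"] == 0.0
        assert row["cv_pct"] == 0.0

    def test_records_frame_columns(self):
        ref = np.repeat([1, 2], 10)
        ds = _toy_dataset(ref)
        rec = evaluate_dataset(ds, ClusteringResult(labels=ref, source="x"))
        df = records_frame([rec])
        assert list(df["difference_pct"]) == [0.0]
        assert df.loc[0, "total_events"] == 20
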