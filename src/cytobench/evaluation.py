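"""Score clustering outputs against ground truth.

The accuracy statistic is the difference-to-reference percentage

    difference % = |A - B| / total events x 100

where A is the event count of ground-truth cluster 1 and B the count of
the output cluster matched to it.  Matching is made explicit: output
labels are aligned to reference labels by optimal assignment on the
contingency table, after over-clustered outputs are merged down to the
reference k by majority overlap.  Replicate summaries report the mean,
sample standard deviation (n - 1) and CV of the per-replicate
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ConsistencyError


@dataclass(frozen=True)
class ClusteringResult:
    """Per-event integer labels from one clustering run or tool."""

    labels: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int).ravel()
        if lab.size == 0:
            raise ValueError("labels must be non-empty")
        object.__setattr__(self, "labels", lab)

    @property
    def k_out(self) -> int:
        return len(np.unique(self.labels))


@dataclass(frozen=True)
class EvalRecord:
    """Difference-to-reference for one (dataset, source) pair."""

    dataset_id: str
    source: str
    reference_count_a: int
    predicted_count_b: int
    total_events: int
    difference_pct: float
    k_requested: int
    k_returned: int
    merge_map: dict = field(default_factory=dict)


def _contingency(reference: np.ndarray, predicted: np.ndarray):
    ref_vals = np.unique(reference)
    pred_vals = np.unique(predicted)
    table = np.zeros((len(ref_vals), len(pred_vals)), dtype=np.int64)
    ref_idx = np.searchsorted(ref_vals, reference)
    pred_idx = np.searchsorted(pred_vals, predicted)
    np.add.at(table, (ref_idx, pred_idx), 1)
    return ref_vals, pred_vals, table


def match_labels(reference, predicted) -> dict:
    """One-to-one map predicted label -> reference label maximising the
    total overlap (optimal assignment on the contingency table).

    Requires as many predicted labels as reference labels; over-clustered
    outputs must go through :func:`merge_to_k` first.  Ties are broken
    toward the smallest reference label.
    """
    reference = np.asarray(reference, dtype=int).ravel()
    predicted = np.asarray(predicted, dtype=int).ravel()
    if len(reference) != len(predicted):
        raise ValueError("reference and predicted must have equal length")
    ref_vals, pred_vals, table = _contingency(reference, predicted)
    if len(pred_vals) != len(ref_vals):
        raise ValueError(
            f"{len(pred_vals)} predicted labels vs {len(ref_vals)} reference "
            "labels; apply merge_to_k before matching"
        )
    # tiny index penalty steers exact ties toward small reference labels
    # without ever outweighing a one-event overlap difference
    k = len(ref_vals)
    penalty = (np.arange(k)[:, None] + np.arange(k)[None, :]) / (10.0 * k * k)
    rows, cols = linear_sum_assignment(-(table.astype(float)) + penalty)
    return {int(pred_vals[c]): int(ref_vals[r]) for r, c in zip(rows, cols)}


def merge_to_k(reference, predicted, k: int):
    """Merge predicted sub-clusters down to k by majority overlap.

    Each predicted sub-cluster is relabelled to the reference cluster
    holding the majority of its events (ties to the smallest reference
    label).  Returns ``(merged_labels, merge_map)``; the map records the
    audit trail sub-cluster -> reference cluster.
    """
    reference = np.asarray(reference, dtype=int).ravel()
    predicted = np.asarray(predicted, dtype=int).ravel()
    ref_vals, pred_vals, table = _contingency(reference, predicted)
    if len(pred_vals) < k:
        raise ValueError(
            f"cannot split {len(pred_vals)} predicted clusters into {k}; "
            "the clustering must be re-run with a different configuration"
        )
    merge_map = {
        int(p): int(ref_vals[int(np.argmax(table[:, j]))])
        for j, p in enumerate(pred_vals)
    }
    merged = np.array([merge_map[int(p)] for p in predicted])
    return merged, merge_map


def difference_to_reference(a: int, b: int, total: int) -> float:
    """``|A - B| / total x 100`` — the accuracy statistic, in percent."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= a <= total and 0 <= b <= total):
        raise ValueError("counts must lie in [0, total]")
    return abs(a - b) / total * 100.0


def evaluate_dataset(dataset, result: ClusteringResult, dataset_id=None) -> EvalRecord:
    """Score one clustering output against one labelled dataset.

    Merges over-clustered outputs to the reference k, aligns labels by
    optimal assignment and evaluates the difference-to-reference of
    ground-truth cluster 1 against its matched output cluster.  An output
    with fewer clusters than requested is still scored: the available
    clusters are matched and any unmatched reference cluster counts zero
    predicted events.
    """
    reference = np.asarray(dataset.labels, dtype=int).ravel()
    predicted = np.asarray(result.labels, dtype=int).ravel()
    if len(predicted) != len(reference):
        raise ConsistencyError(
            f"clustering output has {len(predicted)} labels for "
            f"{len(reference)} events"
        )
    k = len(np.unique(reference))
    k_returned = len(np.unique(predicted))
    merge_map: dict = {}
    working = predicted
    if k_returned > k:
        working, merge_map = merge_to_k(reference, predicted, k)
    ref_vals, pred_vals, table = _contingency(reference, working)
    if len(pred_vals) == len(ref_vals):
        mapping = match_labels(reference, working)
    else:
        # under-clustered output: rectangular optimal assignment
        kk = max(len(ref_vals), len(pred_vals))
        penalty = (np.arange(len(ref_vals))[:, None] + np.arange(len(pred_vals))[None, :]) / (
            10.0 * kk * kk
        )
        rows, cols = linear_sum_assignment(-(table.astype(float)) + penalty)
        mapping = {int(pred_vals[c]): int(ref_vals[r]) for r, c in zip(rows, cols)}
    ref_cluster = int(ref_vals.min())
    a = int(np.sum(reference == ref_cluster))
    matched = [p for p, r in mapping.items() if r == ref_cluster]
    b = int(np.sum(np.isin(working, matched))) if matched else 0
    total = len(reference)
    ds_id = dataset_id if dataset_id is not None else _dataset_id(dataset)
    return EvalRecord(
        dataset_id=str(ds_id),
        source=result.source,
        reference_count_a=a,
        predicted_count_b=b,
        total_events=total,
        difference_pct=difference_to_reference(a, b, total),
        k_requested=k,
        k_returned=k_returned,
        merge_map=merge_map,
    )


def _dataset_id(dataset) -> str:
    meta = getattr(dataset, "meta", None)
    if not meta:
        return "dataset"
    if meta.get("family") == "skew":
        return (
            f"skew_a{meta['shape_alpha']:g}_{meta['orientation']}"
            f"_rep{meta['replicate']}"
        )
    return f"sep_k{meta['k']}_si{meta['target_si']:+.1f}_rep{meta['replicate']}"


def records_frame(records) -> pd.DataFrame:
    """Tidy per-record table (one row per dataset x source)."""
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "source": r.source,
                "reference_count_A": r.reference_count_a,
                "predicted_count_B": r.predicted_count_b,
                "total_events": r.total_events,
                "difference_pct": r.difference_pct,
                "k_requested": r.k_requested,
                "k_returned": r.k_returned,
            }
            for r in records
        ]
    )


def summarize(records, by=("family", "condition", "source")) -> pd.DataFrame:
    """Per-condition replicate summary: mean, sample SD and CV of the
    difference-to-reference.

    ``records`` is a DataFrame with at least the grouping columns and
    ``difference_pct``.  SD is reported as missing (not 0) for single
    replicates; CV is missing when the mean is 0.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    by = [c for c in by if c in df.columns]
    if not by:
        raise ValueError("no grouping columns present in records")
    rows = []
    for keys, grp in df.groupby(by, sort=True, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        vals = grp["difference_pct"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        cv = 100.0 * sd / mean if (mean > 0 and np.isfinite(sd)) else np.nan
        rows.append(
            dict(
                zip(by, keys),
                n_replicates=len(vals),
                mean_difference_pct=mean,
                sd_difference_pct=sd,
                cv_pct=cv,
            )
        )
    return pd.DataFrame(rows).sort_values(by).reset_index(drop=True)
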