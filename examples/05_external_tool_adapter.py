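"""Adapt an external clustering tool's output to the evaluation harness.

Any tool that can label events can be scored: export one CSV per dataset
with columns event_index,label (0-based, FCS row order) and load it with
load_external_assignments.  Here the "external tool" is simulated by
perturbing the ground truth: 30 events of cluster 1 are mislabelled,
giving the textbook difference of |1000 - 970| / 2000 x 100 = 1.5%.
"""

import tempfile
from pathlib import Path

import numpy as np

from cytobench import (
    AssemblySpec,
    build_separation_dataset,
    evaluate_dataset,
    load_external_assignments,
)

ds = build_separation_dataset(AssemblySpec(base_seed=5), 0.3, 1)

noisy = ds.labels.copy()
idx_cluster1 = np.flatnonzero(noisy == 1)[:30]
noisy[idx_cluster1] = 2

out = Path(tempfile.mkdtemp()) / "imaginarytool.csv"
out.write_text(
    "event_index,label\n"
    + "\n".join(f"{i},{lab}" for i, lab in enumerate(noisy))
    + "\n"
)

result = load_external_assignments(out, expected_total=ds.n_events)
record = evaluate_dataset(ds, result)
print(f"source:                  {record.source}")
print(f"reference cluster-1 (A): {record.reference_count_a}")
print(f"matched output     (B):  {record.predicted_count_b}")
print(f"difference to reference: {record.difference_pct:.2f}%  "
      f"(= |{record.reference_count_a} - {record.predicted_count_b}| / "
      f"{record.total_events} x 100)")
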