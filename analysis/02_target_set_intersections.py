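#!/usr/bin/env python
"""Set algebra over the four published target-gene lists.

Finding: the four DE-miRNA sets regulate 135 distinct brain-expressed target
genes (58 up / 79 down / 22 substantia nigra / 18 putamen).  Three genes —
CCND1, FOXO3, SIRT1 — are targets of all four sets, and five neuronal-
survival genes (BCL2, CCND1, FOXO3, MYC, SIRT1) are shared between the
substantia nigra and putamen sets.

Writes results/targets/.
"""

from pathlib import Path

from mirnet_pd.fixtures import load_packaged_target_sets
from mirnet_pd.targets import intersect_sets

out = Path("results/targets")
out.mkdir(parents=True, exist_ok=True)

targets = load_packaged_target_sets()
report = intersect_sets(targets.as_dict())

with open(out / "intersection_report.tsv", "w") as fh:
    fh.write("pattern\tcount\n")
    for pattern in sorted(report.bar_counts, key=lambda t: (-len(t), t)):
        fh.write(f"{'&'.join(pattern)}\t{report.bar_counts[pattern]}\n")
print("wrote", out / "intersection_report.tsv")

print("set sizes:", {k: len(v) for k, v in targets.as_dict().items()})
print("union:", report.union_size)
print("all four:", sorted(report.intersection("up", "down", "sn", "putamen")))
print("sn & putamen:", sorted(report.intersection("sn", "putamen")))
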