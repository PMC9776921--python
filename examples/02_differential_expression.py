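"""Per-cohort differential expression and the cross-cohort intersection.

Welch's t-test per gene with Benjamini–Hochberg adjustment; each
cohort's top-500 up/down lists (gated at adjusted p < 0.05) are
intersected to give the common regulated genes — the candidate pool for
all downstream key-gene analysis.
"""

from mdconet import (
    common_pattern_genes,
    default_config,
    select_top_k,
    significant_genes,
    simulate_paired_cohorts,
    two_group_test,
)

cohorts, truth = simulate_paired_cohorts(default_config(seed=1))

tops = []
for i, (matrix, labels) in enumerate(cohorts, start=1):
    de = two_group_test(matrix, labels)
    degs = significant_genes(de, alpha=0.05, fc_threshold=2.0)
    up = select_top_k(de, 500, "up", alpha=0.05)
    down = select_top_k(de, 500, "down", alpha=0.05)
    print(f"cohort {i}: {len(degs)} DEGs (adjusted p < 0.05, fold change > 2); "
          f"top lists: {len(up)} up, {len(down)} down")
    tops.append((up, down))

common = common_pattern_genes(tops[0], tops[1], k=500)
up_truth = truth.shared_de("up")
down_truth = truth.shared_de("down")
print(f"common up: {len(common.common_up)} genes "
      f"({len(common.common_up & up_truth)} of {len(up_truth)} planted shared)")
print(f"common down: {len(common.common_down)} genes "
      f"({len(common.common_down & down_truth)} of {len(down_truth)} planted shared)")
print("cohort-private DE genes are filtered out by the intersection:",
      len(common.common_up & {d.gene for d in truth.de_genes if not d.shared}),
      "private genes leaked")
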