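"""Simulate a small FFPE tumor cohort with known truth.

Draws case subtypes at the published proportions, injects drivers,
passengers, germline polymorphisms and strand-restricted deamination
artifacts, then simulates dual-pool allele counts for the first case.
"""
from collections import Counter

import hsapanel as h

config = h.SimConfig(n_cases=10, seed=7)
panel = h.build_default_panel()
truths = h.sample_cohort(config, panel)

print("subtype composition:", dict(Counter(t.true_subtype for t in truths)))
case = truths[0]
drivers = [f"{v.gene} {v.protein_change} (AF {v.vaf:.2f})"
           for v in case.of_class("somatic_driver")]
print(f"{case.case_id} [{case.true_subtype}] drivers: {drivers}")
print(f"  plus {len(case.of_class('somatic_passenger'))} passengers, "
      f"{len(case.of_class('germline'))} germline SNVs, "
      f"{len(case.of_class('artifact'))} FFPE artifacts")

counts_a, counts_b = h.simulate_counts(case, panel, config)
cov = h.coverage_summary(counts_a, counts_b)
print(f"mean cumulative depth {cov['mean_cumulative_depth']:.0f}X, "
      f"uniformity {cov['uniformity']:.3f}")
# Cumulative depth is pool A + pool B; the assay's QC gate requires 1000X.
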