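"""The full discovery cascade end to end.

MVD screen -> score correlation -> survival scan, on a synthetic cohort
with one planted anti-angiogenic miRNA among fifty nulls. The report
records every threshold next to the count it produced.
"""

from angiomir import generate_cohort, run_screen_on_cohort
from angiomir.synthetic import CohortConfig

cohort = generate_cohort(CohortConfig(seed=1))
report = run_screen_on_cohort(cohort, with_tf=True)

for stage in report.stages:
    print(f"{stage.name:18s} {stage.n_in:3d} -> {stage.n_out:3d}  "
          f"survivors: {list(stage.survivors)}")
print(f"\nshortlist: {list(report.shortlist)}")
# With the default study conditions the shortlist is exactly the planted
# miRNA: it drops >80% between MVD extremes, is the strongest negative
# correlate of the angiogenesis score (p < 1e-4), and its low-expression
# group has significantly worse survival at the optimal cutpoint.
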