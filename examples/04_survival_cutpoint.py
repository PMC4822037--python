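"""Optimal-percentile survival scan for one miRNA.

Expression is dichotomized at every percentile from 0.25 to 0.75 (step
0.01); each split gets a log-rank test, and the split with the smallest
nominal p is reported. Because a minimum over 51 correlated tests is
anti-conservative, a whole-scan permutation-adjusted p accompanies it.
"""

from angiomir import cutpoint_scan, generate_cohort
from angiomir.synthetic import CohortConfig

cohort = generate_cohort(CohortConfig(n_samples=300, seed=5))
scan = cutpoint_scan(
    cohort.mirna_expr.loc["miR-planted"], cohort.survival,
    n_permutations=500, seed=11,
)

print(f"grid points evaluated:  {len(scan.percentiles)}")
print(f"optimal percentile:     {scan.optimal_percentile:.2f}")
print(f"nominal min p:          {scan.optimal_p:.2e}")
print(f"permutation-adjusted p: {scan.adjusted_p:.4f}")
print(f"flagged at alpha=0.05:  {scan.flagged}")
# The planted miRNA is anti-coupled to the hazard-driving activity, so low
# expression marks poor survival: both the nominal and the adjusted p are
# small. On null markers the nominal min-p is inflated while the adjusted p
# stays uniform.
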