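"""Microvessel-density discovery filter on Nanostring-style counts.

Tumours beyond the MVD extremes (>36 or <16 vessels per high-power field)
form the high/low groups; a miRNA passes when its median count drops by
more than 80% in the highly angiogenic group.
"""

from angiomir import assign_mvd_groups, generate_nanostring_counts, median_decrease_screen

counts, mvd = generate_nanostring_counts(
    planted=[("miR-angio-1", 0.95), ("miR-angio-2", 0.85)], n_null=50, seed=3
)
groups = assign_mvd_groups(mvd)  # strict >36 / <16 thresholds
result = median_decrease_screen(counts, groups, decrease_threshold=0.8)

print(result.head(5).to_string(index=False))
print(f"\npassing miRNAs: {result.loc[result['passes'], 'mirna'].tolist()}")
# decrease = 1 - median_high/median_low; only miRNAs with a ratio strictly
# below 0.2 pass. The filter is scale invariant: normalization constants
# shared by all samples cannot change the outcome.
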