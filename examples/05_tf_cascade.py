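"""Transcription-factor target cascade.

Keep TFs predicted (matrix-similarity >= 0.9) to bind the promoters of more
than five angiogenic panel genes, then keep those predicted as direct
targets of the miRNA by at least four prediction algorithms.
"""

from angiomir import generate_tf_tables, tf_cascade
from angiomir.synthetic import CohortConfig
from angiomir.tf import candidates_frame

cfg = CohortConfig(seed=17)
binding, targets, truth = generate_tf_tables(cfg)
panel = [g.name for g in cfg.panel_genes]

candidates, finalists, edges = tf_cascade(binding, targets, truth["mirna"], panel)

print(candidates_frame(candidates).to_string(index=False))
print(f"\nfinalists: {[c.tf for c in finalists]} (truth: {truth['planted']})")
print(f"bipartite edges:\n{edges.head(6).to_string(index=False)}")
# The three decoys each fail exactly one rule (score below cutoff, only five
# targets, only three algorithms); the planted TF survives both filters.
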