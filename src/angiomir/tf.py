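"""Transcription-factor / target intersection cascade.

Two anti-monotone filters applied in sequence to prediction tables consumed
as plain TSVs (the upstream prediction engines themselves are inputs, not
dependencies):

1. binding filter — keep TFs predicted to bind the promoters of strictly
   more than ``min_genes`` angiogenic panel genes at a position-weight-matrix
   match (matrix-similarity score) of at least ``min_score``;
2. targeting filter — of those, keep TFs predicted to be direct targets of
   the miRNA of interest by at least ``min_algorithms`` distinct prediction
   algorithms.

Survivors are emitted together with the bipartite TF -> gene edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from ._util import ValidationError

log = logging.getLogger(__name__)

ALGORITHM_VOCABULARY = ("miranda", "targetscan", "pita", "rna22", "microt", "pictar")


@dataclass(frozen=True)
class TfCandidate:
    tf: str
    n_angio_targets: int
    supporting_algorithms: int
    passes_binding: bool
    passes_targeting: bool
    edges: tuple[tuple[str, float], ...]  # (gene, score) surviving the cutoff

    @property
    def passes(self) -> bool:
        return self.passes_binding and self.passes_targeting


def validate_binding_table(binding: pd.DataFrame) -> pd.DataFrame:
    """Validate (tf, gene, matrix_similarity) rows; deduplicate keeping max score."""
    for col in ("tf", "gene", "matrix_similarity"):
        if col not in binding.columns:
            raise ValidationError(f"binding table missing column {col!r}")
    s = binding["matrix_similarity"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ValidationError("matrix_similarity scores must lie in [0, 1]")
    n_dup = binding.duplicated(["tf", "gene"]).sum()
    if n_dup:
        log.info("binding table: collapsing %d duplicate (tf, gene) pairs (max score kept)", n_dup)
    out = (
        binding.groupby(["tf", "gene"], as_index=False, sort=True)["matrix_similarity"]
        .max()
    )
    return out


def validate_target_table(targets: pd.DataFrame, vocabulary=ALGORITHM_VOCABULARY) -> pd.DataFrame:
    """Validate (mirna, gene, algorithm, predicted) rows against the algorithm vocabulary."""
    for col in ("mirna", "gene", "algorithm", "predicted"):
        if col not in targets.columns:
            raise ValidationError(f"target table missing column {col!r}")
    unknown = sorted(set(targets["algorithm"]) - set(vocabulary))
    if unknown:
        raise ValidationError(f"unknown prediction algorithm(s): {unknown}")
    if targets.duplicated(["mirna", "gene", "algorithm"]).any():
        raise ValidationError("duplicate (mirna, gene, algorithm) rows in target table")
    return targets


def filter_tf_by_binding(
    binding: pd.DataFrame,
    angio_genes,
    min_score: float = 0.9,
    min_genes: int = 5,
) -> list[TfCandidate]:
    """Count, per TF, distinct angiogenic genes bound at >= min_score.

    ``passes_binding`` requires strictly more than ``min_genes`` such genes.
    Every TF in the table is returned (with its pass flag) so the cascade is
    auditable; edges are restricted to surviving (score >= cutoff) pairs.
    """
    angio = list(angio_genes)
    if not angio:
        raise ValidationError("angiogenic gene panel is empty")
    tab = validate_binding_table(binding)
    hits = tab[(tab["gene"].isin(angio)) & (tab["matrix_similarity"] >= min_score)]
    out: list[TfCandidate] = []
    for tf in sorted(tab["tf"].unique()):
        sub = hits[hits["tf"] == tf].sort_values("gene")
        edges = tuple((g, float(s)) for g, s in zip(sub["gene"], sub["matrix_similarity"]))
        n = len(edges)
        out.append(
            TfCandidate(
                tf=tf,
                n_angio_targets=n,
                supporting_algorithms=0,
                passes_binding=n > min_genes,
                passes_targeting=False,
                edges=edges,
            )
        )
    return out


def filter_by_mir_targeting(
    candidates: list[TfCandidate],
    targets: pd.DataFrame,
    mirna: str,
    min_algorithms: int = 4,
) -> list[TfCandidate]:
    """Count distinct algorithms predicting each TF as a target of ``mirna``.

    ``passes_targeting`` requires at least ``min_algorithms`` (inclusive).
    A miRNA absent from the table yields zero counts with a warning.
    """
    tab = validate_target_table(targets)
    sub = tab[(tab["mirna"] == mirna) & tab["predicted"].astype(bool)]
    if mirna not in set(tab["mirna"]):
        log.warning("miRNA %r absent from target table; all algorithm counts are 0", mirna)
    counts = sub.groupby("gene")["algorithm"].nunique()
    out = []
    for c in candidates:
        k = int(counts.get(c.tf, 0))
        out.append(replace(c, supporting_algorithms=k, passes_targeting=k >= min_algorithms))
    return out


def final_candidates(candidates: list[TfCandidate]) -> list[TfCandidate]:
    """TFs surviving both filters."""
    return [c for c in candidates if c.passes]


def build_bipartite_edges(candidates: list[TfCandidate]) -> pd.DataFrame:
    """Deterministic (tf, gene, score) edge list sorted by tf then gene."""
    rows = [
        {"tf": c.tf, "gene": g, "matrix_similarity": s}
        for c in candidates
        for g, s in c.edges
    ]
    out = pd.DataFrame(rows, columns=["tf", "gene", "matrix_similarity"])
    return out.sort_values(["tf", "gene"]).reset_index(drop=True)


def candidates_frame(candidates: list[TfCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": c.tf,
                "n_angio_targets": c.n_angio_targets,
                "supporting_algorithms": c.supporting_algorithms,
                "passes_binding": c.passes_binding,
                "passes_targeting": c.passes_targeting,
                "passes": c.passes,
            }
            for c in candidates
        ],
        columns=[
            "tf", "n_angio_targets", "supporting_algorithms",
            "passes_binding", "passes_targeting", "passes",
        ],
    )


def tf_cascade(
    binding: pd.DataFrame,
    targets: pd.DataFrame,
    mirna: str,
    angio_genes,
    min_score: float = 0.9,
    min_genes: int = 5,
    min_algorithms: int = 4,
):
    """Run both filters; returns (all candidates, finalists, bipartite edges)."""
    cands = filter_tf_by_binding(binding, angio_genes, min_score, min_genes)
    cands = filter_by_mir_targeting(cands, targets, mirna, min_algorithms)
    finals = final_candidates(cands)
    return cands, finals, build_bipartite_edges(finals)
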