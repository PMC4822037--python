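"""Per-sample pro-angiogenic signature score.

The score of a sample is the mean, over a panel of N pro-angiogenic genes, of
+-1 indicators: +1 if the sample's expression of the gene strictly exceeds the
gene's across-all-samples median, -1 otherwise (ties map to -1). Scores
therefore lie in [-1, +1], and score*N is an integer with the parity of N.
Being rank-based, the score is invariant under any strictly increasing
per-gene transform of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._util import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelSelection:
    """Outcome of the consistently-expressed-gene filter."""

    kept: tuple[str, ...]
    dropped: dict[str, str] = field(default_factory=dict)  # gene -> reason

    @property
    def n(self) -> int:
        return len(self.kept)


def _check_panel(genes) -> list[str]:
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValidationError("gene panel contains duplicate symbols")
    if not genes:
        raise ValidationError("gene panel is empty")
    return genes


def select_consistent_genes(
    matrix: pd.DataFrame,
    panel,
    min_fraction_expressed: float = 0.8,
    expression_floor: float = 0.0,
) -> PanelSelection:
    """Keep panel genes present in the matrix and expressed above a floor.

    A gene is retained when it appears among the matrix features and its
    expression exceeds ``expression_floor`` in at least
    ``min_fraction_expressed`` of samples. Dropped genes are logged with a
    reason ("absent" or "low_expression").
    """
    genes = _check_panel(panel)
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for g in genes:
        if g not in matrix.index:
            dropped[g] = "absent"
            continue
        frac = float((matrix.loc[g] > expression_floor).mean())
        if frac >= min_fraction_expressed:
            kept.append(g)
        else:
            dropped[g] = f"low_expression ({frac:.3f} < {min_fraction_expressed})"
    for g, reason in dropped.items():
        log.info("panel gene %s dropped: %s", g, reason)
    if not kept:
        raise ValidationError(
            "no panel gene survives the consistency filter; score undefined"
        )
    return PanelSelection(kept=tuple(kept), dropped=dropped)


def median_sign_matrix(matrix: pd.DataFrame, panel) -> pd.DataFrame:
    """+-1 indicator matrix: +1 where a sample strictly exceeds the gene's median.

    The median of each gene is computed across *all* samples of the input
    matrix (even-n median = mean of the two central order statistics).
    Equality with the median maps to -1.
    """
    genes = _check_panel(panel)
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"panel gene(s) missing from matrix: {missing}")
    sub = matrix.loc[genes]
    if sub.isna().any().any():
        raise ValidationError("missing values in panel gene rows")
    medians = sub.median(axis=1)
    signs = sub.gt(medians, axis=0).astype(int) * 2 - 1
    return signs


def angiogenesis_score(matrix: pd.DataFrame, panel) -> pd.Series:
    """Per-sample signature score: mean of the +-1 median indicators."""
    signs = median_sign_matrix(matrix, panel)
    score = signs.mean(axis=0)
    score.name = "angiogenesis_score"
    return score
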