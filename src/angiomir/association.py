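"""Spearman association layers.

Rank correlations between miRNA expression and (a) the per-sample
angiogenesis score, (b) individual angiogenic genes, (c) per-probe
methylation beta values or any other per-track measurement such as copy
number. Ties receive mid-ranks; two-sided p-values use the t approximation
on n-2 degrees of freedom, with an exact permutation option for tiny n.
Benjamini-Hochberg q-values are reported alongside nominal p.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    ok: bool = True
    reason: str | None = None


def spearman(x, y, exact: bool = False) -> SpearmanResult:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    Incomplete pairs (NaN in either vector) are removed first; at least 3
    complete pairs are required. A constant vector yields a flagged
    (ok=False) result rather than a silent NaN. With ``exact=True`` and
    n <= 9, the two-sided p is the exact permutation tail probability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("spearman: vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"spearman: need >=3 complete pairs, have {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(np.nan, np.nan, n, ok=False, reason="constant input")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if exact:
        if n > 9:
            raise ValidationError("exact permutation p only supported for n <= 9")
        p = _exact_permutation_p(x, y, rho)
    return SpearmanResult(rho, float(p), n)


def _exact_permutation_p(x, y, observed_rho: float) -> float:
    rx = stats.rankdata(x)
    hits = total = 0
    for perm in permutations(stats.rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(observed_rho) - 1e-12:
            hits += 1
    return hits / total


def _rowwise_spearman(rows: np.ndarray, y: np.ndarray):
    """Vectorized Spearman of each matrix row against one vector.

    Returns (rho, p, valid) arrays; rows or targets that are constant are
    marked invalid (rho, p = NaN).
    """
    n = y.size
    ranks = stats.rankdata(rows, axis=1)
    ry = stats.rankdata(y)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    num = rc @ yc
    den = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    valid = den > 0
    rho = np.full(rows.shape[0], np.nan)
    np.divide(num, den, out=rho, where=valid)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(valid, p, np.nan)
    return rho, p, valid


def _bh_q(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum() > 0:
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def _assemble(names, rho, p, valid, n, flag_p) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "feature": list(names),
            "rho": rho,
            "p_value": p,
            "q_value": _bh_q(p),
            "n": n,
            "ok": valid,
        }
    )
    out["flagged"] = out["ok"] & (out["p_value"] < flag_p)
    # most negative rho first; exact ties broken lexicographically by name
    out = out.sort_values(["rho", "feature"], na_position="last").reset_index(drop=True)
    return out


def correlate_with_score(
    mirna_expr: pd.DataFrame, scores: pd.Series, flag_p: float = 1e-4
) -> pd.DataFrame:
    """Spearman correlation of every miRNA with the angiogenesis score.

    Computed over the samples shared between matrix and score vector (>=3
    required); results are ranked ascending by rho so the strongest negative
    correlates come first. ``flagged`` marks p below the shortlist threshold.
    """
    shared = [s for s in mirna_expr.columns if s in scores.index]
    if len(shared) < 3:
        raise ValidationError(f"need >=3 shared samples, have {len(shared)}")
    rows = mirna_expr[shared].to_numpy(dtype=float)
    y = scores.loc[shared].to_numpy(dtype=float)
    rho, p, valid = _rowwise_spearman(rows, y)
    out = _assemble(mirna_expr.index, rho, p, valid, len(shared), flag_p)
    return out.rename(columns={"feature": "mirna"})


def correlate_with_genes(
    mirna: pd.Series, mrna_expr: pd.DataFrame, gene_list, flag_p: float = 1e-4
) -> pd.DataFrame:
    """Spearman correlation of one miRNA against each gene in a list."""
    genes = [g for g in gene_list if g in mrna_expr.index]
    if not list(gene_list):
        return pd.DataFrame(
            columns=["gene", "rho", "p_value", "q_value", "n", "ok", "flagged"]
        )
    missing = sorted(set(gene_list) - set(genes))
    if missing:
        raise ValidationError(f"gene(s) missing from mRNA matrix: {missing}")
    shared = [s for s in mrna_expr.columns if s in mirna.index]
    if len(shared) < 3:
        raise ValidationError(f"need >=3 shared samples, have {len(shared)}")
    rows = mrna_expr.loc[genes, shared].to_numpy(dtype=float)
    y = mirna.loc[shared].to_numpy(dtype=float)
    rho, p, valid = _rowwise_spearman(rows, y)
    out = _assemble(genes, rho, p, valid, len(shared), flag_p)
    return out.rename(columns={"feature": "gene"})


def correlate_tracks(
    mirna: pd.Series, tracks: pd.DataFrame, flag_p: float = 1e-4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-track Spearman correlation (methylation probes, copy number, ...).

    ``tracks`` is track x sample (e.g. methylation beta values per probe).
    Tracks with fewer than 3 complete pairs are skipped and reported in the
    second returned frame with a reason.
    """
    shared = [s for s in tracks.columns if s in mirna.index]
    results = []
    skipped = []
    y_all = mirna.loc[shared].to_numpy(dtype=float) if shared else np.array([])
    for probe in tracks.index:
        v = tracks.loc[probe, shared].to_numpy(dtype=float)
        keep = ~(np.isnan(v) | np.isnan(y_all))
        if keep.sum() < 3:
            skipped.append({"feature": probe, "reason": f"only {int(keep.sum())} complete pairs"})
            continue
        res = spearman(v[keep], y_all[keep])
        results.append(
            {
                "feature": probe,
                "rho": res.rho,
                "p_value": res.p_value,
                "q_value": np.nan,
                "n": res.n,
                "ok": res.ok,
            }
        )
    res_df = pd.DataFrame(
        results, columns=["feature", "rho", "p_value", "q_value", "n", "ok"]
    )
    if len(res_df):
        res_df["q_value"] = _bh_q(res_df["p_value"].to_numpy(dtype=float))
        res_df["flagged"] = res_df["ok"] & (res_df["p_value"] < flag_p)
        res_df = res_df.sort_values(["rho", "feature"], na_position="last").reset_index(drop=True)
    else:
        res_df["flagged"] = pd.Series(dtype=bool)
    skip_df = pd.DataFrame(skipped, columns=["feature", "reason"])
    return res_df, skip_df


# copy-number correlation is the same per-track machinery on a different table
correlate_methylation = correlate_tracks
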