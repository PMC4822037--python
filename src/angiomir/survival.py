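"""Kaplan-Meier estimation, log-rank testing and the optimal-percentile cutpoint scan.

The scan dichotomizes a continuous marker (miRNA expression) at every
percentile on a grid (default 0.25..0.75, step 0.01 — 51 cutoffs), applies an
unweighted two-group log-rank test at each split, and reports the cutoff with
the smallest nominal p. Because a minimum over many correlated tests is
anti-conservative, a permutation-based adjusted p (whole-scan label
permutations) is available alongside — reported separately, never silently
substituted for the nominal value.

Conventions: censored subjects remain at risk at a tied event time; the
dichotomizing quantile uses linear interpolation between order statistics and
samples exactly at the quantile go to the low group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate: survival drops only at distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def _as_time_event(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("time and event arrays must have equal length")
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t <= 0).any():
        raise ValidationError("survival times must be > 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValidationError("event flags must be 0 or 1")
    return t, e


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t: S <- S * (1 - d(t)/n(t)) where n(t) counts
    all subjects with observed time >= t (so a subject censored at t is still
    at risk for the events at t).
    """
    t, e = _as_time_event(time, event)
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if len(event_times) else np.array([])
    return KmCurve(event_times, surv, at_risk, d, n=t.size)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]  # events in (group A, group B)
    expected: tuple[float, float]
    ok: bool = True
    reason: str | None = None


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Unweighted two-group log-rank test.

    Per distinct event time, the expected group-A event count and its
    hypergeometric variance are accumulated; chi-square = (O_A - E_A)^2 / V
    on 1 df, two-sided p from the chi-square(1) tail. With zero total events
    the statistic is undefined and the result is flagged rather than raised.
    """
    ta, ea = _as_time_event(time_a, event_a)
    tb, eb = _as_time_event(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if e.sum() == 0:
        return LogrankResult(np.nan, np.nan, (0.0, 0.0), (np.nan, np.nan),
                             ok=False, reason="zero events")
    chi2, o1, e1 = _logrank_chi2_batch(t, e, g[None, :], return_oe=True)
    chi = float(chi2[0])
    total_events = float(e.sum())
    oa, ea_ = float(o1[0]), float(e1[0])
    p = float(stats.chi2.sf(chi, df=1)) if np.isfinite(chi) else np.nan
    ok = np.isfinite(chi)
    return LogrankResult(
        chi, p,
        observed=(oa, total_events - oa),
        expected=(ea_, total_events - ea_),
        ok=ok, reason=None if ok else "zero log-rank variance",
    )


def _logrank_chi2_batch(time, event, groups, return_oe: bool = False):
    """Log-rank chi-square for many group assignments of one dataset at once.

    ``groups`` is a (B, n) boolean matrix; True marks membership in group A.
    Rows of the result are NaN where the log-rank variance is zero (e.g. a
    degenerate split).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    G = np.asarray(groups, dtype=float)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    Go = G[:, order]
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    n_total = ts.size
    N = n_total - starts  # at risk at each distinct time
    d = np.add.reduceat(es, starts)  # events at each distinct time
    ev = d > 0
    # at-risk counts in group A: suffix sums evaluated at block starts
    suffix = np.cumsum(Go[:, ::-1], axis=1)[:, ::-1]
    N1 = suffix[:, starts][:, ev]
    d1 = np.add.reduceat(Go * es, starts, axis=1)[:, ev]
    Nv = N[ev].astype(float)
    dv = d[ev]
    frac = N1 / Nv
    E1 = dv * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        V = dv * frac * (1.0 - frac) * (Nv - dv) / (Nv - 1.0)
    V = np.where(Nv > 1.0, V, 0.0)
    U = (d1 - E1).sum(axis=1)
    Vs = V.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(Vs > 0, U**2 / Vs, np.nan)
    if return_oe:
        return chi2, d1.sum(axis=1), E1.sum(axis=1)
    return chi2


@dataclass(frozen=True)
class Split:
    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    cut: float
    ok: bool = True
    reason: str | None = None


def dichotomize_at_percentile(values: pd.Series, percentile: float) -> Split:
    """Split samples at a percentile of the marker distribution.

    low = samples with value <= the linear-interpolation quantile; high = the
    complement. If either group would be empty (e.g. a constant marker) the
    split is flagged undefined rather than raised.
    """
    if not 0 < percentile < 1:
        raise ValidationError("percentile must lie in (0, 1)")
    if len(values) < 2:
        raise ValidationError("need >=2 samples to dichotomize")
    v = values.to_numpy(dtype=float)
    cut = float(np.quantile(v, percentile, method="linear"))
    low = values.index[v <= cut]
    high = values.index[v > cut]
    if len(low) == 0 or len(high) == 0:
        return Split((), (), cut, ok=False, reason="degenerate split (empty group)")
    return Split(tuple(low), tuple(high), cut)


@dataclass(frozen=True)
class CutpointScan:
    """Result of the min-p percentile scan for one marker."""

    name: str
    percentiles: np.ndarray
    p_values: np.ndarray  # NaN where the split is degenerate
    chi_squares: np.ndarray
    optimal_percentile: float
    optimal_p: float
    flagged: bool
    alpha: float
    quantile_method: str = "linear"
    adjusted_p: float = float("nan")
    n_permutations: int = 0
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "chi_square": self.chi_squares,
                "p_value": self.p_values,
            }
        )


def percentile_grid(lo: float = 0.25, hi: float = 0.75, step: float = 0.01) -> np.ndarray:
    if not (0 < lo <= hi < 1) or step <= 0:
        raise ValidationError("invalid percentile grid")
    k = int(round((hi - lo) / step))
    grid = np.round(lo + step * np.arange(k + 1), 10)
    return grid[grid <= hi + 1e-12]


def _split_matrix(v: np.ndarray, grid: np.ndarray):
    cuts = np.quantile(v, grid, method="linear")
    low = v[None, :] <= cuts[:, None]
    counts = low.sum(axis=1)
    valid = (counts > 0) & (counts < v.size)
    return low, valid


def cutpoint_scan(
    values: pd.Series,
    clinical: pd.DataFrame,
    lo: float = 0.25,
    hi: float = 0.75,
    step: float = 0.01,
    alpha: float = 0.05,
    n_permutations: int = 0,
    seed: int | None = None,
    name: str | None = None,
) -> CutpointScan:
    """Optimal-percentile log-rank scan for one marker against overall survival.

    Evaluates the log-rank test at every grid percentile; the optimal cutoff
    is the one with the smallest nominal p (ties broken toward the smaller
    percentile). ``flagged`` is True when the optimal nominal p < alpha.
    With ``n_permutations`` > 0, a whole-scan permutation-adjusted p is also
    computed: marker values are permuted against the survival records and the
    minimum p of each permuted scan forms the null.
    """
    grid = percentile_grid(lo, hi, step)
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    shared = [s for s in values.index if s in clin.index]
    if len(shared) < 2:
        raise ValidationError("need >=2 samples shared between marker and clinical table")
    v = values.loc[shared].to_numpy(dtype=float)
    t, e = _as_time_event(
        clin.loc[shared, "time"].to_numpy(), clin.loc[shared, "event"].to_numpy()
    )
    low, valid = _split_matrix(v, grid)
    if not valid.any():
        raise ValidationError("no valid split anywhere on the percentile grid")
    chi2 = np.full(grid.size, np.nan)
    chi2[valid] = _logrank_chi2_batch(t, e, low[valid])
    p = np.full(grid.size, np.nan)
    defined = np.isfinite(chi2)
    p[defined] = stats.chi2.sf(chi2[defined], df=1)
    if not defined.any():
        raise ValidationError("log-rank undefined at every grid percentile")
    imin = int(np.nanargmin(p))
    opt_p = float(p[imin])
    result = dict(
        name=name or (values.name or "marker"),
        percentiles=grid,
        p_values=p,
        chi_squares=chi2,
        optimal_percentile=float(grid[imin]),
        optimal_p=opt_p,
        flagged=bool(opt_p < alpha),
        alpha=alpha,
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        B = int(n_permutations)
        n = v.size
        perm_min = np.empty(B)
        low_valid = low[valid]
        chunk = max(1, min(B, 20_000_000 // (low_valid.shape[0] * n + 1)))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            perms = np.array([rng.permutation(n) for _ in range(b)])
            # permuted marker => permuted split membership per grid percentile
            Gp = low_valid[:, perms].transpose(1, 0, 2).reshape(b * low_valid.shape[0], n)
            c = _logrank_chi2_batch(t, e, Gp).reshape(b, low_valid.shape[0])
            pm = stats.chi2.sf(c, df=1)
            perm_min[done : done + b] = np.nanmin(pm, axis=1)
            done += b
        adj = (1.0 + np.sum(perm_min <= opt_p + 1e-12)) / (B + 1.0)
        result["adjusted_p"] = float(adj)
        result["n_permutations"] = B
    return CutpointScan(**result)
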