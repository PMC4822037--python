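"""End-to-end orchestration of the discovery flow.

Stage order mirrors the screening cascade: (1) MVD-extremes median-decrease
filter on miRNA counts, (2) Spearman correlation of the survivors with the
per-sample angiogenesis score, (3) optimal-percentile survival scan on the
correlation survivors, (4) optional TF cascade. The shortlist is the set of
miRNAs passing every stage. Every threshold that produced a count is recorded
beside it, and the report serializes byte-identically for identical inputs
and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import ValidationError
from .association import correlate_with_score
from .mvd import assign_mvd_groups, median_decrease_screen
from .score import angiogenesis_score, select_consistent_genes
from .survival import cutpoint_scan, dichotomize_at_percentile, logrank_test
from .synthetic import Cohort
from .tf import candidates_frame, tf_cascade

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    mvd_high: float = 36.0
    mvd_low: float = 16.0
    decrease_threshold: float = 0.8
    direction: str = "down"          # down | up | both
    corr_flag_p: float = 1e-4
    scan_lo: float = 0.25
    scan_hi: float = 0.75
    scan_step: float = 0.01
    alpha: float = 0.05
    n_permutations: int = 0
    use_adjusted: bool = False       # flag on the permutation-adjusted p
    require_protective: bool = False  # keep only markers whose high group fares better
    panel_min_fraction: float = 0.8
    panel_floor: float = 0.0
    tf_min_score: float = 0.9
    tf_min_genes: int = 5
    tf_min_algorithms: int = 4

    def __post_init__(self):
        if self.direction not in ("down", "up", "both"):
            raise ValidationError("direction must be 'down', 'up' or 'both'")
        if self.use_adjusted and self.n_permutations <= 0:
            raise ValidationError("use_adjusted requires n_permutations > 0")


@dataclass(frozen=True)
class StageRecord:
    name: str
    params: dict
    n_in: int
    n_out: int
    survivors: tuple[str, ...]


@dataclass(frozen=True)
class PipelineReport:
    version: str
    seed: int
    params: dict
    stages: tuple[StageRecord, ...]
    shortlist: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=_jsonable)


def _jsonable(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _screen_direction(expr, groups, threshold, direction):
    down = median_decrease_screen(expr, groups, threshold)
    if direction == "down":
        return down, down.loc[down["passes"], "mirna"].tolist()
    swapped = groups.copy()
    swapped["group"] = swapped["group"].map(
        {"high": "low", "low": "high", "excluded": "excluded"}
    )
    up = median_decrease_screen(expr, swapped, threshold)
    if direction == "up":
        return up, up.loc[up["passes"], "mirna"].tolist()
    both = sorted(
        set(down.loc[down["passes"], "mirna"]) | set(up.loc[up["passes"], "mirna"])
    )
    return down, both


def run_screen(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    mvd: pd.DataFrame,
    clinical: pd.DataFrame,
    panel,
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    tf_binding: pd.DataFrame | None = None,
    tf_targets: pd.DataFrame | None = None,
) -> PipelineReport:
    """Run the full discovery cascade; returns the machine-readable report.

    With ``out_dir`` set, per-stage TSVs are written whose row counts equal
    the counts recorded in the report.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stages: list[StageRecord] = []

    # stage 1: MVD extremes + median-decrease filter
    groups = assign_mvd_groups(mvd, params.mvd_high, params.mvd_low)
    screen_df, screen_survivors = _screen_direction(
        mirna_expr, groups, params.decrease_threshold, params.direction
    )
    stages.append(
        StageRecord(
            "mvd_screen",
            {
                "mvd_high": params.mvd_high,
                "mvd_low": params.mvd_low,
                "decrease_threshold": params.decrease_threshold,
                "direction": params.direction,
                "n_high": int((groups["group"] == "high").sum()),
                "n_low": int((groups["group"] == "low").sum()),
            },
            n_in=len(mirna_expr),
            n_out=len(screen_survivors),
            survivors=tuple(sorted(screen_survivors)),
        )
    )
    if out is not None:
        screen_df.to_csv(out / "stage1_screen.tsv", sep="\t", index=False)

    # stage 2: angiogenesis score + Spearman correlation of screen survivors
    selection = select_consistent_genes(
        mrna_expr, panel, params.panel_min_fraction, params.panel_floor
    )
    scores = angiogenesis_score(mrna_expr, selection.kept)
    corr_survivors: list[str] = []
    corr_df = pd.DataFrame(
        columns=["mirna", "rho", "p_value", "q_value", "n", "ok", "flagged"]
    )
    if screen_survivors:
        corr_df = correlate_with_score(
            mirna_expr.loc[screen_survivors], scores, flag_p=params.corr_flag_p
        )
        keep = corr_df["flagged"]
        if params.direction == "down":
            keep = keep & (corr_df["rho"] < 0)
        elif params.direction == "up":
            keep = keep & (corr_df["rho"] > 0)
        corr_survivors = corr_df.loc[keep, "mirna"].tolist()
    stages.append(
        StageRecord(
            "score_correlation",
            {
                "panel_size": selection.n,
                "corr_flag_p": params.corr_flag_p,
                "direction": params.direction,
            },
            n_in=len(screen_survivors),
            n_out=len(corr_survivors),
            survivors=tuple(sorted(corr_survivors)),
        )
    )
    if out is not None:
        corr_df.to_csv(out / "stage2_correlation.tsv", sep="\t", index=False)
        scores.rename_axis("sample").to_frame().to_csv(out / "scores.tsv", sep="\t")

    # stage 3: optimal-percentile survival scan
    scan_rows = []
    surv_survivors: list[str] = []
    for mirna in sorted(corr_survivors):
        scan = cutpoint_scan(
            mirna_expr.loc[mirna],
            clinical,
            lo=params.scan_lo,
            hi=params.scan_hi,
            step=params.scan_step,
            alpha=params.alpha,
            n_permutations=params.n_permutations,
            seed=seed,
            name=mirna,
        )
        flag = (
            scan.adjusted_p < params.alpha if params.use_adjusted else scan.flagged
        )
        protective = None
        if flag and params.require_protective:
            protective = _is_protective(mirna_expr.loc[mirna], clinical, scan.optimal_percentile)
            flag = flag and protective
        if flag:
            surv_survivors.append(mirna)
        scan_rows.append(
            {
                "mirna": mirna,
                "optimal_percentile": scan.optimal_percentile,
                "optimal_p": scan.optimal_p,
                "adjusted_p": scan.adjusted_p,
                "flagged": bool(flag),
                "protective": protective,
            }
        )
    scan_df = pd.DataFrame(
        scan_rows,
        columns=["mirna", "optimal_percentile", "optimal_p", "adjusted_p", "flagged", "protective"],
    )
    stages.append(
        StageRecord(
            "survival_scan",
            {
                "grid": [params.scan_lo, params.scan_hi, params.scan_step],
                "alpha": params.alpha,
                "n_permutations": params.n_permutations,
                "use_adjusted": params.use_adjusted,
                "require_protective": params.require_protective,
            },
            n_in=len(corr_survivors),
            n_out=len(surv_survivors),
            survivors=tuple(sorted(surv_survivors)),
        )
    )
    if out is not None:
        scan_df.to_csv(out / "stage3_survival.tsv", sep="\t", index=False)

    shortlist = tuple(sorted(surv_survivors))

    # stage 4 (optional): TF cascade for each shortlisted miRNA
    if tf_binding is not None and tf_targets is not None:
        tf_rows = []
        for mirna in shortlist:
            cands, finals, edges = tf_cascade(
                tf_binding,
                tf_targets,
                mirna,
                panel,
                min_score=params.tf_min_score,
                min_genes=params.tf_min_genes,
                min_algorithms=params.tf_min_algorithms,
            )
            df = candidates_frame(cands)
            df.insert(0, "mirna", mirna)
            tf_rows.append(df)
            if out is not None:
                edges.to_csv(out / f"stage4_edges_{mirna}.tsv", sep="\t", index=False)
        tf_df = (
            pd.concat(tf_rows, ignore_index=True)
            if tf_rows
            else candidates_frame([]).assign(mirna=pd.Series(dtype=str))
        )
        n_final = int(tf_df["passes"].sum()) if len(tf_df) else 0
        stages.append(
            StageRecord(
                "tf_cascade",
                {
                    "min_score": params.tf_min_score,
                    "min_genes": params.tf_min_genes,
                    "min_algorithms": params.tf_min_algorithms,
                },
                n_in=len(shortlist),
                n_out=n_final,
                survivors=tuple(sorted(tf_df.loc[tf_df["passes"], "tf"].unique()))
                if len(tf_df)
                else (),
            )
        )
        if out is not None:
            tf_df.to_csv(out / "stage4_tf_candidates.tsv", sep="\t", index=False)

    report = PipelineReport(
        version=__version__,
        seed=seed,
        params=asdict(params),
        stages=tuple(stages),
        shortlist=shortlist,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report


def _is_protective(values: pd.Series, clinical: pd.DataFrame, percentile: float) -> bool:
    """High-marker group has fewer observed than expected events at the split."""
    split = dichotomize_at_percentile(values, percentile)
    if not split.ok:
        return False
    clin = clinical.set_index("sample")
    hi = clin.loc[list(split.high_ids)]
    lo = clin.loc[list(split.low_ids)]
    res = logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
    return bool(res.ok and res.observed[0] < res.expected[0])


def run_screen_on_cohort(
    cohort: Cohort,
    params: PipelineParams = PipelineParams(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    with_tf: bool = False,
) -> PipelineReport:
    """Convenience wrapper running the cascade on a synthetic cohort."""
    tf_binding = tf_targets = None
    if with_tf:
        from .synthetic import generate_tf_tables

        tf_binding, tf_targets, _ = generate_tf_tables(cohort.config)
    panel = [g.name for g in cohort.config.panel_genes]
    return run_screen(
        cohort.mirna_expr,
        cohort.mrna_expr,
        cohort.mvd,
        cohort.survival,
        panel,
        params=params,
        seed=seed,
        out_dir=out_dir,
        tf_binding=tf_binding,
        tf_targets=tf_targets,
    )
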