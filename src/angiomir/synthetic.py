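"""Seeded synthetic multi-omic cohorts with the statistical structure the screen assumes.

A latent per-sample angiogenic activity A ~ N(0,1) drives everything:

* pro-angiogenic panel gene expression   mu_g + beta_g * A + Gaussian noise;
* planted anti-angiogenic miRNAs, negatively coupled to A — either Gaussian
  (nu_m - gamma_m * A + noise) or negative-binomial counts with mean
  nu_m * exp(-gamma_m * A) (Nanostring-like);
* null miRNAs with no coupling;
* microvessel density  MVD ~ Poisson(exp(alpha0 + alpha1 * A));
* overall survival with proportional hazards h0 * exp(theta * A), censored by
  the minimum of an exponential drop-out time and an administrative horizon;
* methylation beta values inverse-logit(delta0 + delta1 * A) plus bounded
  uniform noise, clipped to [0, 1] (anti-correlated with the planted miRNAs);
* ground-truth TF binding / miRNA-target prediction tables with planted
  survivors and decoys, and node-valued gene networks for the walk scorer.

Every generator draws from a per-component sub-stream derived from
(seed, component name), so identical seeds give byte-identical output and
adding a component never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, component_rng
from .io import write_matrix
from .tf import ALGORITHM_VOCABULARY

# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantedMirna:
    name: str
    gamma: float = 0.8       # coupling to latent activity (>= 0)
    baseline: float = 500.0  # Gaussian level or NB mean, by mirna_mode


@dataclass(frozen=True)
class PanelGene:
    name: str
    beta: float = 1.0       # effect of latent activity (>= 0)
    baseline: float = 8.0   # mean expression (log2-like scale)


@dataclass(frozen=True)
class MethProbe:
    name: str
    delta0: float = 0.0
    delta1: float = 1.0     # slope on latent activity inside the logit


@dataclass(frozen=True)
class PlantedTf:
    name: str
    targets: tuple[str, ...]
    score: float = 0.95
    n_algorithms: int = 4


@dataclass(frozen=True)
class DecoyTf:
    name: str
    n_targets: int = 6
    score: float = 0.85
    n_algorithms: int = 4


@dataclass(frozen=True)
class TfTableConfig:
    gene_universe: tuple[str, ...]
    planted: tuple[PlantedTf, ...]
    decoys: tuple[DecoyTf, ...]
    mirna: str = "miR-planted"
    algorithms: tuple[str, ...] = ALGORITHM_VOCABULARY


@dataclass(frozen=True)
class NetworkConfig:
    kind: str = "random"            # random | k_regular | path
    n_nodes: int = 30
    degree: int = 4                 # k_regular only
    edge_prob: float = 0.15         # random only
    values: tuple[float, ...] = ()  # explicit node values; empty = lognormal draws


def _default_panel() -> tuple[PanelGene, ...]:
    return tuple(PanelGene(f"ANGF{i:02d}") for i in range(1, 21))


def _default_planted() -> tuple[PlantedMirna, ...]:
    return (PlantedMirna("miR-planted", gamma=0.8),)


def _default_probes() -> tuple[MethProbe, ...]:
    return tuple(MethProbe(f"cg_probe_{i:02d}") for i in range(1, 5))


def _default_tf(panel: tuple[PanelGene, ...], mirna: str) -> TfTableConfig:
    genes = tuple(g.name for g in panel)
    return TfTableConfig(
        gene_universe=genes,
        planted=(PlantedTf("TF_PLANTED", targets=genes[:6]),),
        decoys=(
            DecoyTf("TF_DECOY_SCORE", n_targets=6, score=0.85, n_algorithms=4),
            DecoyTf("TF_DECOY_COUNT", n_targets=5, score=0.95, n_algorithms=4),
            DecoyTf("TF_DECOY_ALG", n_targets=6, score=0.95, n_algorithms=3),
        ),
        mirna=mirna,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort. Defaults are the conditions
    every recovery and calibration check in the package runs under."""

    n_samples: int = 400
    n_null_mirnas: int = 50
    planted_mirnas: tuple[PlantedMirna, ...] = field(default_factory=_default_planted)
    panel_genes: tuple[PanelGene, ...] = field(default_factory=_default_panel)
    noise_sd: float = 1.0
    mirna_mode: str = "counts"          # counts | gaussian
    nb_dispersion: float = 0.2
    null_mirna_baseline: float = 500.0
    mvd_intercept: float = math.log(24.0)
    mvd_slope: float = 0.4
    baseline_hazard: float = 0.1
    hazard_coupling: float = 1.0
    censor_rate: float = 0.04            # ~30% censoring with the defaults
    admin_censor_time: float = 15.0
    meth_probes: tuple[MethProbe, ...] = field(default_factory=_default_probes)
    meth_noise: float = 0.2
    seed: int = 0
    tf: TfTableConfig | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        def bad(name, why):
            raise ConfigError(f"CohortConfig.{name}: {why}")

        if self.n_samples < 4:
            bad("n_samples", "must be >= 4")
        if self.n_null_mirnas < 0:
            bad("n_null_mirnas", "must be >= 0")
        if self.noise_sd <= 0:
            bad("noise_sd", "must be > 0")
        if self.mirna_mode not in ("counts", "gaussian"):
            bad("mirna_mode", "must be 'counts' or 'gaussian'")
        if self.nb_dispersion < 0:
            bad("nb_dispersion", "must be >= 0")
        if self.baseline_hazard <= 0:
            bad("baseline_hazard", "must be > 0")
        if self.censor_rate < 0:
            bad("censor_rate", "must be >= 0")
        if self.admin_censor_time <= 0:
            bad("admin_censor_time", "must be > 0")
        if self.meth_noise < 0:
            bad("meth_noise", "must be >= 0")
        for m in self.planted_mirnas:
            if m.gamma < 0:
                bad("planted_mirnas", f"{m.name}: gamma must be >= 0")
            if m.baseline <= 0:
                bad("planted_mirnas", f"{m.name}: baseline must be > 0")
        for g in self.panel_genes:
            if g.beta < 0:
                bad("panel_genes", f"{g.name}: beta must be >= 0")
        names = [m.name for m in self.planted_mirnas]
        if len(set(names)) != len(names):
            bad("planted_mirnas", "duplicate miRNA names")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["planted_mirnas"] = tuple(PlantedMirna(**m) for m in d.get("planted_mirnas", []))
        d["panel_genes"] = tuple(PanelGene(**g) for g in d.get("panel_genes", []))
        d["meth_probes"] = tuple(MethProbe(**p) for p in d.get("meth_probes", []))
        if d.get("tf") is not None:
            t = dict(d["tf"])
            t["gene_universe"] = tuple(t["gene_universe"])
            t["planted"] = tuple(
                PlantedTf(**{**p, "targets": tuple(p["targets"])}) for p in t["planted"]
            )
            t["decoys"] = tuple(DecoyTf(**x) for x in t["decoys"])
            t["algorithms"] = tuple(t["algorithms"])
            d["tf"] = TfTableConfig(**t)
        if d.get("network") is not None:
            n = dict(d["network"])
            n["values"] = tuple(n.get("values", ()))
            d["network"] = NetworkConfig(**n)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def tf_config(self) -> TfTableConfig:
        if self.tf is not None:
            return self.tf
        mirna = self.planted_mirnas[0].name if self.planted_mirnas else "miR-planted"
        return _default_tf(self.panel_genes, mirna)


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    mirna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    latent_activity: pd.Series
    mvd: pd.DataFrame               # sample, vessels_per_hpf
    survival: pd.DataFrame          # sample, time, event
    methylation: pd.DataFrame       # probe x sample beta values
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mirna_expr.columns)

    def to_dir(self, outdir: str | Path) -> None:
        """Write every table as plain TSV plus truth.json (deterministic bytes)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.mirna_expr, out / "mirna.tsv")
        write_matrix(self.mrna_expr, out / "mrna.tsv")
        write_matrix(self.methylation, out / "methylation.tsv")
        self.mvd.to_csv(out / "mvd.tsv", sep="\t", index=False)
        self.survival.to_csv(out / "clinical.tsv", sep="\t", index=False)
        self.latent_activity.rename("latent_activity").to_frame().rename_axis(
            "sample"
        ).to_csv(out / "latent.tsv", sep="\t")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one synthetic cohort under the latent-activity model."""
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    A = component_rng(config.seed, "latent").standard_normal(n)

    rng_mrna = component_rng(config.seed, "mrna")
    mrna_rows = {
        g.name: g.baseline + g.beta * A + rng_mrna.normal(0, config.noise_sd, n)
        for g in config.panel_genes
    }
    mrna = pd.DataFrame(mrna_rows, index=samples).T
    mrna.index.name = "feature"

    rng_mirna = component_rng(config.seed, "mirna")
    mirna_rows = {}
    for m in config.planted_mirnas:
        if config.mirna_mode == "gaussian":
            mirna_rows[m.name] = m.baseline - m.gamma * A + rng_mirna.normal(
                0, config.noise_sd, n
            )
        else:
            mirna_rows[m.name] = _nb_draw(
                rng_mirna, m.baseline * np.exp(-m.gamma * A), config.nb_dispersion
            )
    for i in range(1, config.n_null_mirnas + 1):
        name = f"miR-null-{i:03d}"
        if config.mirna_mode == "gaussian":
            mirna_rows[name] = config.null_mirna_baseline + rng_mirna.normal(
                0, config.noise_sd, n
            )
        else:
            mirna_rows[name] = _nb_draw(
                rng_mirna,
                np.full(n, config.null_mirna_baseline),
                config.nb_dispersion,
            )
    mirna = pd.DataFrame(mirna_rows, index=samples).T
    mirna.index.name = "feature"

    rng_mvd = component_rng(config.seed, "mvd")
    vessels = rng_mvd.poisson(np.exp(config.mvd_intercept + config.mvd_slope * A))
    mvd = pd.DataFrame({"sample": samples, "vessels_per_hpf": vessels})

    rng_surv = component_rng(config.seed, "survival")
    rate = config.baseline_hazard * np.exp(config.hazard_coupling * A)
    t_event = rng_surv.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_drop = rng_surv.exponential(1.0 / config.censor_rate, n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"sample": samples, "time": time, "event": event})

    rng_meth = component_rng(config.seed, "methylation")
    meth_rows = {}
    for p in config.meth_probes:
        base = 1.0 / (1.0 + np.exp(-(p.delta0 + p.delta1 * A)))
        noise = rng_meth.uniform(-config.meth_noise, config.meth_noise, n)
        meth_rows[p.name] = np.clip(base + noise, 0.0, 1.0)
    methylation = pd.DataFrame(meth_rows, index=samples).T
    methylation.index.name = "feature"

    truth = {
        "planted_mirnas": {m.name: m.gamma for m in config.planted_mirnas},
        "panel_genes": {g.name: g.beta for g in config.panel_genes},
        "hazard_coupling": config.hazard_coupling,
        "mvd_slope": config.mvd_slope,
        "meth_probes": {p.name: p.delta1 for p in config.meth_probes},
        "seed": config.seed,
    }
    return Cohort(config, mirna, mrna, pd.Series(A, index=samples, name="latent"),
                  mvd, survival, methylation, truth)


# --------------------------------------------------------------------------
# Nanostring-style count fixture for the MVD screen


def generate_nanostring_counts(
    planted: list[tuple[str, float]],
    n_null: int = 100,
    n_high: int = 12,
    n_low: int = 12,
    base_mean: float = 800.0,
    dispersion: float = 0.15,
    seed: int = 0,
):
    """Counts for an MVD-extremes profiling experiment.

    ``planted`` lists (miRNA name, decrease fraction): the high-MVD group
    mean is ``(1 - decrease)`` times the low-group mean. Null miRNAs share
    one mean across groups (per-miRNA means vary log-normally for realism).
    Returns (count matrix, MVD table with vessels_per_hpf beyond the
    36 / 16 thresholds for the high / low samples).
    """
    rng = component_rng(seed, "nanostring")
    samples = [f"H{i:02d}" for i in range(1, n_high + 1)] + [
        f"L{i:02d}" for i in range(1, n_low + 1)
    ]
    rows = {}
    for name, decrease in planted:
        if not 0 <= decrease < 1:
            raise ConfigError(f"planted decrease for {name!r} must lie in [0, 1)")
        low_mean = base_mean * rng.lognormal(0.0, 0.4)
        high_mean = low_mean * (1.0 - decrease)
        rows[name] = np.concatenate(
            [
                _nb_draw(rng, np.full(n_high, high_mean), dispersion),
                _nb_draw(rng, np.full(n_low, low_mean), dispersion),
            ]
        )
    for i in range(1, n_null + 1):
        mean = base_mean * rng.lognormal(0.0, 0.4)
        rows[f"miR-null-{i:03d}"] = _nb_draw(
            rng, np.full(n_high + n_low, mean), dispersion
        )
    counts = pd.DataFrame(rows, index=samples).T
    counts.index.name = "feature"
    vessels = np.concatenate(
        [rng.integers(37, 61, n_high), rng.integers(2, 16, n_low)]
    )
    mvd = pd.DataFrame({"sample": samples, "vessels_per_hpf": vessels})
    return counts, mvd


# --------------------------------------------------------------------------
# TF prediction tables


def generate_tf_tables(config: CohortConfig):
    """Ground-truth TF binding and miRNA-target prediction tables.

    Planted TFs carry matrix-similarity scores at or above their truth score
    on their true targets and algorithm flags on their truth count of
    algorithms; decoys sit below the cutoff, below the target count, or below
    the algorithm count. Returns (binding table, target table, truth).
    """
    tf_cfg = config.tf_config()
    if not tf_cfg.gene_universe:
        raise ConfigError("TfTableConfig.gene_universe: must be non-empty")
    if not tf_cfg.planted:
        raise ConfigError("TfTableConfig.planted: need at least one planted TF")
    rng = component_rng(config.seed, "tf_tables")
    universe = list(tf_cfg.gene_universe)
    binding_rows = []
    target_rows = []
    truth = {"planted": [], "decoys": [], "mirna": tf_cfg.mirna}

    def add_target_rows(tf_name: str, k: int):
        algs = list(rng.permutation(list(tf_cfg.algorithms)))
        for j, alg in enumerate(algs):
            target_rows.append(
                {
                    "mirna": tf_cfg.mirna,
                    "gene": tf_name,
                    "algorithm": str(alg),
                    "predicted": j < k,
                }
            )

    for p in tf_cfg.planted:
        for g in p.targets:
            jitter = rng.uniform(0.0, (1.0 - p.score) * 0.5)
            binding_rows.append(
                {"tf": p.name, "gene": g, "matrix_similarity": p.score + jitter}
            )
        # sub-cutoff noise edges to other genes
        others = [g for g in universe if g not in p.targets]
        for g in rng.choice(others, size=min(3, len(others)), replace=False):
            binding_rows.append(
                {"tf": p.name, "gene": str(g), "matrix_similarity": rng.uniform(0.3, 0.85)}
            )
        add_target_rows(p.name, p.n_algorithms)
        truth["planted"].append(p.name)

    for d in tf_cfg.decoys:
        genes = rng.choice(universe, size=min(d.n_targets, len(universe)), replace=False)
        for g in genes:
            binding_rows.append(
                {"tf": d.name, "gene": str(g), "matrix_similarity": d.score}
            )
        add_target_rows(d.name, d.n_algorithms)
        truth["decoys"].append(d.name)

    binding = pd.DataFrame(binding_rows, columns=["tf", "gene", "matrix_similarity"])
    targets = pd.DataFrame(target_rows, columns=["mirna", "gene", "algorithm", "predicted"])
    return binding, targets, truth


# --------------------------------------------------------------------------
# gene networks for the walk scorer


def generate_network(config: CohortConfig) -> nx.Graph:
    """Connected node-valued graph per ``config.network``; deterministic under seed."""
    net = config.network
    if net.n_nodes < 2:
        raise ConfigError("NetworkConfig.n_nodes: must be >= 2")
    rng = component_rng(config.seed, "network")
    if net.kind == "path":
        G = nx.path_graph(net.n_nodes)
    elif net.kind == "k_regular":
        for attempt in range(100):
            G = nx.random_regular_graph(
                net.degree, net.n_nodes, seed=int(rng.integers(2**31))
            )
            if nx.is_connected(G):
                break
        else:
            raise ConfigError("NetworkConfig: could not draw a connected regular graph")
    elif net.kind == "random":
        for attempt in range(100):
            G = nx.gnp_random_graph(
                net.n_nodes, net.edge_prob, seed=int(rng.integers(2**31))
            )
            if G.number_of_nodes() >= 2 and nx.is_connected(G):
                break
        else:
            raise ConfigError(
                "NetworkConfig: could not draw a connected random graph; raise edge_prob"
            )
    else:
        raise ConfigError(f"NetworkConfig.kind: unknown kind {net.kind!r}")
    G = nx.relabel_nodes(G, {i: f"G{i:03d}" for i in G.nodes})
    nodes = sorted(G.nodes)
    if net.values:
        if len(net.values) != len(nodes):
            raise ConfigError("NetworkConfig.values: length must equal n_nodes")
        vals = list(net.values)
    else:
        vals = rng.lognormal(0.0, 0.5, len(nodes)).tolist()
    for node, v in zip(nodes, vals):
        if v <= 0:
            raise ConfigError("NetworkConfig.values: node values must be > 0")
        G.nodes[node]["value"] = float(v)
    return G
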