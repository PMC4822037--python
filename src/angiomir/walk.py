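"""Random-walk network relevance scoring.

Node data values (any strictly positive per-gene measure of interest, e.g. a
fold-change magnitude) set the walk's transition probabilities: from node i
the walk moves to neighbour j with probability proportional to j's data
value among i's neighbours. A node's relevance is its stationary visitation
frequency — the long-run fraction of steps the walk spends there — and each
edge receives the stationary probability flux crossing it.

Because a value-weighted walk on a bipartite graph is periodic, a small lazy
(stay-in-place) damping is applied when no restart is used; lazy damping
leaves the stationary distribution of the underlying chain unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import ValidationError

log = logging.getLogger(__name__)

VALUE_ATTR = "value"


def _node_values(network: nx.Graph) -> tuple[list, np.ndarray]:
    if network.number_of_nodes() < 2:
        raise ValidationError("network must have at least 2 nodes")
    if any(u == v for u, v in network.edges):
        raise ValidationError("network must not contain self-loops")
    nodes = list(network.nodes)
    vals = np.array([float(network.nodes[n].get(VALUE_ATTR, np.nan)) for n in nodes])
    if np.isnan(vals).any():
        bad = nodes[int(np.flatnonzero(np.isnan(vals))[0])]
        raise ValidationError(f"node {bad!r} has no {VALUE_ATTR!r} attribute")
    nonpos = vals <= 0
    if nonpos.any():
        pos = vals[~nonpos]
        if pos.size == 0:
            raise ValidationError("all node data values are non-positive")
        floor = 1e-6 * float(np.median(pos))
        log.warning(
            "flooring %d non-positive node value(s) to %.3g", int(nonpos.sum()), floor
        )
        vals = np.where(nonpos, floor, vals)
    return nodes, vals


@dataclass(frozen=True)
class TransitionModel:
    nodes: tuple
    walk: np.ndarray       # value-weighted neighbour-move probabilities
    restart: float
    restart_dist: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """Full transition rule: walk mixed with restart mass."""
        if self.restart == 0:
            return self.walk
        return (1.0 - self.restart) * self.walk + self.restart * self.restart_dist[None, :]


def build_transition(network: nx.Graph, restart: float = 0.0) -> TransitionModel:
    """Row-stochastic transition rule from node data values.

    P(i -> j) = value(j) / sum of values over i's neighbours, mixed with
    ``restart`` mass sent to the data-value-proportional distribution. An
    isolated node is an error unless restart > 0 (its row is then pure
    restart).
    """
    if not 0 <= restart < 1:
        raise ValidationError("restart must lie in [0, 1)")
    nodes, vals = _node_values(network)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    restart_dist = vals / vals.sum()
    for i, u in enumerate(nodes):
        nbrs = [idx[v] for v in network.neighbors(u)]
        if not nbrs:
            if restart == 0:
                raise ValidationError(
                    f"isolated node {u!r} with restart = 0: walk undefined"
                )
            W[i] = restart_dist
            continue
        w = vals[nbrs]
        W[i, nbrs] = w / w.sum()
    return TransitionModel(tuple(nodes), W, restart, restart_dist)


@dataclass(frozen=True)
class NodeRelevance:
    scores: pd.Series  # sums to 1
    iterations: int
    residual: float
    restart: float
    lazy: float


def stationary_scores(
    network: nx.Graph,
    restart: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    lazy: float = 0.01,
) -> NodeRelevance:
    """Stationary visitation frequencies of the value-weighted walk.

    Power iteration from the uniform distribution until the L1 change per
    step falls below ``tol``. When restart = 0 the network must be connected
    and a lazy stay-probability guards against periodicity (it does not
    change the stationary vector).
    """
    model = build_transition(network, restart)
    if restart == 0 and not nx.is_connected(network):
        raise ValidationError("network must be connected when restart = 0")
    P = model.matrix
    eff_lazy = lazy if restart == 0 else 0.0
    if eff_lazy > 0:
        P = eff_lazy * np.eye(P.shape[0]) + (1.0 - eff_lazy) * P
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for it in range(1, max_iter + 1):
        nxt = pi @ P
        nxt /= nxt.sum()
        residual = float(np.abs(nxt - pi).sum())
        pi = nxt
        if residual < tol:
            return NodeRelevance(
                pd.Series(pi, index=list(model.nodes), name="relevance"),
                iterations=it,
                residual=residual,
                restart=restart,
                lazy=eff_lazy,
            )
    raise ValidationError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3g})"
    )


def edge_scores(network: nx.Graph, relevance: NodeRelevance) -> pd.Series:
    """Stationary probability flux per edge.

    score(i, j) = pi_i * P(i -> j) + pi_j * P(j -> i) on the pure walk
    probabilities, normalized so the directed flux sums to 1 (at restart = 0
    the normalization is the identity).
    """
    model = build_transition(network, relevance.restart)
    idx = {n: i for i, n in enumerate(model.nodes)}
    pi = relevance.scores.reindex(list(model.nodes)).to_numpy()
    rows = {}
    total = 0.0
    for u, v in network.edges:
        i, j = idx[u], idx[v]
        flux = pi[i] * model.walk[i, j] + pi[j] * model.walk[j, i]
        rows[(u, v)] = flux
        total += flux
    if total <= 0:
        raise ValidationError("zero total edge flux")
    out = pd.Series(rows, name="edge_flux") / total
    return out


def network_from_tables(edges: pd.DataFrame, values: pd.DataFrame) -> nx.Graph:
    """Assemble a GeneNetwork from an edge list and a node value table.

    ``edges``: columns node_a, node_b; ``values``: columns node, value.
    Duplicate edges and self-loops are rejected.
    """
    for col in ("node_a", "node_b"):
        if col not in edges.columns:
            raise ValidationError(f"edge table missing column {col!r}")
    for col in ("node", "value"):
        if col not in values.columns:
            raise ValidationError(f"value table missing column {col!r}")
    G = nx.Graph()
    for _, row in values.iterrows():
        G.add_node(row["node"], value=float(row["value"]))
    seen = set()
    for _, row in edges.iterrows():
        a, b = row["node_a"], row["node_b"]
        if a == b:
            raise ValidationError(f"self-loop on node {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValidationError(f"duplicate edge {a!r}-{b!r}")
        seen.add(key)
        if a not in G or b not in G:
            missing = a if a not in G else b
            raise ValidationError(f"edge endpoint {missing!r} has no value row")
        G.add_edge(a, b)
    return G
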