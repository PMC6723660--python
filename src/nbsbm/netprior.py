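"""Gene-network prior over feature-inclusion indicators.

A weighted undirected gene network is turned into a Markov random field
(MRF) prior over the binary inclusion vector ``z``: each gene carries an
indicator ``z_i`` saying whether its regression weight is drawn from the
slab (relevant) or pinned at zero (irrelevant).  The unnormalized log
potential is

    log p(z) = lambda * sum_i z_i  -  gamma * z' L z  + const

where ``L`` is the degree-normalized graph Laplacian.  ``lambda`` controls
overall sparsity; ``gamma >= 0`` couples network neighbours so that genes
connected in the network tend to be included or excluded together.

The ``-gamma`` sign makes the quadratic form a *penalty* on disagreement
across edges (the smoothing that motivates using a network prior in the
first place); ``coupling_sign=+1`` flips it for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .exceptions import CapacityError, ParseError, ValidationError

__all__ = [
    "NetworkPrior",
    "PriorTable",
    "read_network",
    "build_laplacian",
    "mrf_log_potential",
    "enumerate_prior",
]

_ENUMERATION_GUARD = 20


@dataclass(frozen=True)
class NetworkPrior:
    """An undirected weighted gene network plus MRF hyperparameters.

    Node order is significant: it must match the gene order of the
    expression matrix the prior is used with (see :meth:`aligned`).
    """

    graph: nx.Graph
    nodes: tuple[str, ...]
    lambda_: float = 0.0
    gamma_: float = 0.0
    coupling_sign: int = -1  # -1 penalizes edge disagreement (default)

    degrees: np.ndarray = field(init=False, repr=False, compare=False)
    laplacian: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.coupling_sign not in (-1, 1):
            raise ValidationError("coupling_sign must be -1 or +1")
        if self.gamma_ < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma_}")
        missing = set(self.graph.nodes) - set(self.nodes)
        if missing:
            raise ValidationError(f"graph nodes absent from node order: {sorted(missing)[:5]}")
        object.__setattr__(self, "degrees", _weighted_degrees(self.graph, self.nodes))
        object.__setattr__(self, "laplacian", build_laplacian(self))

    # -- construction -------------------------------------------------

    @classmethod
    def from_graph(
        cls,
        graph: nx.Graph,
        lambda_: float = 0.0,
        gamma_: float = 0.0,
        nodes: Sequence[str] | None = None,
        coupling_sign: int = -1,
    ) -> "NetworkPrior":
        if nodes is None:
            nodes = tuple(graph.nodes)
        return cls(graph=graph, nodes=tuple(nodes), lambda_=lambda_, gamma_=gamma_,
                   coupling_sign=coupling_sign)

    def with_hyperparams(self, lambda_: float, gamma_: float) -> "NetworkPrior":
        return replace(self, lambda_=lambda_, gamma_=gamma_)

    def aligned(self, gene_names: Sequence[str]) -> "NetworkPrior":
        """Restrict/extend the network to exactly ``gene_names``, in order.

        Genes absent from the network become isolated nodes (only the
        sparsity term applies to them); network nodes absent from the
        gene list are dropped.
        """
        gene_names = tuple(gene_names)
        sub = self.graph.subgraph(n for n in self.graph.nodes if n in set(gene_names)).copy()
        sub.add_nodes_from(gene_names)
        return replace(self, graph=sub, nodes=gene_names)

    # -- derived quantities --------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edges as (index_u, index_v, weight) arrays in node order."""
        idx = {g: i for i, g in enumerate(self.nodes)}
        us, vs, ws = [], [], []
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            us.append(idx[u])
            vs.append(idx[v])
            ws.append(float(w))
        return (np.asarray(us, dtype=int), np.asarray(vs, dtype=int),
                np.asarray(ws, dtype=float))

    def node_field(self) -> np.ndarray:
        """Per-node linear coefficient of the log potential: lambda + s*gamma*L_ii."""
        return self.lambda_ + self.coupling_sign * self.gamma_ * np.diag(self.laplacian)

    def edge_couplings(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pairwise coefficients c_uv on z_u z_v: 2*s*gamma*L_uv (>= 0 by default)."""
        us, vs, _ = self.edge_arrays()
        c = 2.0 * self.coupling_sign * self.gamma_ * self.laplacian[us, vs]
        return us, vs, c


def _weighted_degrees(graph: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    deg = dict(graph.degree(weight="weight"))
    return np.array([float(deg.get(n, 0.0)) for n in nodes])


def build_laplacian(network: NetworkPrior) -> np.ndarray:
    """Degree-normalized Laplacian: unit diagonal on connected nodes,
    ``-w(u,v)/sqrt(d_u d_v)`` off-diagonal, zeros for isolated nodes."""
    nodes = network.nodes
    d = len(nodes)
    deg = _weighted_degrees(network.graph, nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    L = np.zeros((d, d))
    for i in range(d):
        if deg[i] > 0:
            L[i, i] = 1.0  # self-loops are dropped at read time
    for u, v, w in network.graph.edges(data="weight", default=1.0):
        i, j = idx[u], idx[v]
        if i == j:
            continue
        val = -float(w) / np.sqrt(deg[i] * deg[j])
        L[i, j] = val
        L[j, i] = val
    return L


def mrf_log_potential(z: np.ndarray, network: NetworkPrior) -> float:
    """Unnormalized log prior ``lambda*sum(z) + s*gamma*z'Lz`` (s = -1 default)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (network.n_nodes,):
        raise ValidationError(
            f"z has length {z.shape}, network has {network.n_nodes} nodes")
    quad = float(z @ network.laplacian @ z)
    return float(network.lambda_ * z.sum() + network.coupling_sign * network.gamma_ * quad)


@dataclass(frozen=True)
class PriorTable:
    """Exhaustive MRF prior over all 2^d inclusion vectors.

    ``z[k]`` is the k-th configuration (node i is bit i of k, little-endian)
    and ``prob[k]`` its normalized probability.
    """

    z: np.ndarray
    prob: np.ndarray

    @property
    def marginals(self) -> np.ndarray:
        return self.prob @ self.z


def enumerate_prior(network: NetworkPrior) -> PriorTable:
    """Normalize the MRF by explicit enumeration (guarded at 20 nodes)."""
    d = network.n_nodes
    if d > _ENUMERATION_GUARD:
        raise CapacityError(f"enumerate_prior handles at most {_ENUMERATION_GUARD} nodes, got {d}")
    ks = np.arange(2 ** d, dtype=np.int64)
    z = ((ks[:, None] >> np.arange(d)) & 1).astype(float)
    logpot = network.lambda_ * z.sum(axis=1)
    if network.gamma_ != 0.0 and d > 0:
        logpot = logpot + network.coupling_sign * network.gamma_ * np.einsum(
            "ki,ij,kj->k", z, network.laplacian, z)
    logpot -= logpot.max() if d > 0 else 0.0
    w = np.exp(logpot)
    return PriorTable(z=z, prob=w / w.sum())


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path,
    format: str | None = None,
    lambda_: float = 0.0,
    gamma_: float = 0.0,
) -> NetworkPrior:
    """Read an undirected network from an edge-list TSV, SIF or GraphML file.

    Duplicate edges collapse to their maximum weight, self-loops are
    dropped and missing weights default to 1.0.  Negative weights are
    rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".sif": "sif", ".graphml": "graphml", ".xml": "graphml"}.get(suffix, "edge-tsv")
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = [(str(u), str(v), float(data.get("weight", 1.0)))
                 for u, v, data in g.edges(data=True)]
    elif format in ("edge-tsv", "sif"):
        edges = list(_parse_edge_lines(path, sif=(format == "sif")))
    else:
        raise ValidationError(f"unknown network format: {format!r}")

    graph = nx.Graph()
    order: list[str] = []
    seen: set[str] = set()

    def _see(node: str) -> None:
        if node not in seen:
            seen.add(node)
            order.append(node)
            graph.add_node(node)

    for u, v, w in edges:
        if w < 0:
            raise ValidationError(f"negative edge weight {w} on {u}-{v}")
        _see(u)
        _see(v)
        if u == v:
            continue  # self-loop
        if graph.has_edge(u, v):
            graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
        else:
            graph.add_edge(u, v, weight=w)
    return NetworkPrior.from_graph(graph, lambda_=lambda_, gamma_=gamma_, nodes=order)


def _parse_edge_lines(path: Path, sif: bool) -> Iterable[tuple[str, str, float]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if sif:
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF rows need 'node rel node'")
                u, v, w = parts[0], parts[2], 1.0
            else:
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two node names")
                u, v = parts[0], parts[1]
                w = 1.0
                if len(parts) >= 3:
                    try:
                        w = float(parts[2])
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            yield u, v, w
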