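"""Binary-graph topology metrics.

Global measures
---------------
clustering coefficient   C        = mean_i 2 E_i / (k_i (k_i - 1))
characteristic path len  L        = mean over ordered pairs of min hops
global efficiency        E_global = mean over ordered pairs of 1/min hops
local efficiency         E_local  = mean_i E_global(G_i), G_i the subgraph
                                    induced by the neighbors of node i

Nodal measures: degree k_i, triangle count E_i, local clustering term and
raw (unnormalized) betweenness centrality b_i with fractional counting
over multiple shortest paths.

Conventions: nodes with degree < 2 contribute 0 to C (the term is 0/0
there); neighbor subgraphs with < 2 nodes contribute 0 to E_local;
unreachable pairs contribute 0 to both efficiencies, while L is only
defined for connected graphs and raises otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .network import BinaryNetwork

__all__ = [
    "DistanceMatrix",
    "GlobalMetrics",
    "shortest_paths",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "global_metrics",
    "nodal_metrics",
]

GLOBAL_METRIC_NAMES = ("C", "L", "gamma", "lambda", "sigma",
                       "E_local", "E_global")


@dataclass
class DistanceMatrix:
    """Shortest-path hop counts; np.inf marks unreachable pairs.

    ``n_shortest_paths[s, t]`` counts the distinct shortest s-t paths
    (0 for unreachable pairs), as needed for betweenness centrality.
    """

    lengths: np.ndarray
    n_shortest_paths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)

    @property
    def connected(self) -> bool:
        return bool(np.all(np.isfinite(self.lengths)))


@dataclass
class GlobalMetrics:
    C: float
    L: float
    E_global: float
    E_local: float


def shortest_paths(net: BinaryNetwork) -> DistanceMatrix:
    """BFS distances and shortest-path counts between all node pairs."""
    d, sigma = _kernels.bfs_sigma(net.adjacency)
    d = d.astype(float)
    d[d < 0] = np.inf
    return DistanceMatrix(d, sigma)


def clustering_coefficient(net: BinaryNetwork) -> float:
    return float(_kernels.clustering_terms(net.adjacency).mean())


def characteristic_path_length(net: BinaryNetwork) -> float:
    dist = _kernels.bfs_distances(net.adjacency)
    L, _, connected = _kernels.path_stats(dist)
    if not connected:
        sizes = _component_sizes(net)
        raise ValueError(
            "characteristic path length is undefined for a disconnected "
            f"network (sparsity={net.sparsity}, component sizes={sizes})"
        )
    return float(L)


def global_efficiency(net: BinaryNetwork) -> float:
    dist = _kernels.bfs_distances(net.adjacency)
    _, eff, _ = _kernels.path_stats(dist)
    return float(eff)


def local_efficiency(net: BinaryNetwork) -> float:
    return float(_kernels.local_efficiency_bitset(net.adjacency))


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Raw betweenness b_i per node (fraction-weighted shortest paths)."""
    return _kernels.betweenness_values(net.adjacency)


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    """C, L, E_global and E_local in one pass (L NaN when disconnected)."""
    adj = net.adjacency
    C, L, eff, connected = _kernels.graph_cl_stats(adj)
    return GlobalMetrics(
        C=float(C),
        L=float(L) if connected else float("nan"),
        E_global=float(eff),
        E_local=float(_kernels.local_efficiency_bitset(adj)),
    )


def nodal_metrics(net: BinaryNetwork) -> pd.DataFrame:
    """Per-node degree, triangles, local clustering and betweenness."""
    adj = net.adjacency
    deg, tri = _kernels.degree_and_triangles(adj)
    labels = net.roi_labels or [f"R{i + 1:03d}" for i in range(net.n_nodes)]
    return pd.DataFrame(
        {
            "roi": labels,
            "degree": deg,
            "triangles": tri,
            "clustering": _kernels.clustering_terms(adj),
            "betweenness": _kernels.betweenness_values(adj),
        }
    )


def _component_sizes(net: BinaryNetwork) -> list[int]:
    n = net.n_nodes
    seen = np.zeros(n, dtype=bool)
    sizes = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in np.nonzero(net.adjacency[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        sizes.append(size)
    return sorted(sizes, reverse=True)
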