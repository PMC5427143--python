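"""From epoch-level ROI power to binary networks across a sparsity grid.

For every subject, condition (0-back / 2-back) and frequency band
(theta / alpha), one band-power value per epoch and region is available.
Concatenating the epochs gives one power series per region; the Pearson
correlation between every pair of series defines a weighted functional
connectivity matrix, which is proportionally thresholded into binary
networks over a grid of sparsity values (fraction of retained edges).
Thresholding ranks all region pairs once, so the networks of one sweep
are nested: every edge present at a lower sparsity is present at every
higher one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "PowerSeriesMatrix",
    "ConnectivityMatrix",
    "SparsityGrid",
    "BinaryNetwork",
    "NetworkEnsemble",
    "concatenate_epoch_powers",
    "pearson_connectivity",
    "binarize_at_sparsity",
    "sweep_sparsity",
]

Ranking = Literal["absolute", "signed"]

CONDITIONS = ("0back", "2back")
BANDS = ("theta", "alpha")


def _round_half_away(x: float) -> int:
    """round() with halves away from zero, platform-stable edge counts."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class PowerSeriesMatrix:
    """ROI x trial matrix of band power, one value per epoch per region."""

    values: np.ndarray
    roi_labels: list[str]
    band: str = ""
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("power matrix must be 2-D (ROIs x trials)")
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 trials are required")
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for "
                f"{self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("power matrix contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted Pearson connectivity matrix with unit diagonal."""

    weights: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0, atol=1e-12):
            raise ValueError("connectivity diagonal must be 1")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class SparsityGrid:
    """Ordered sparsity fractions; default 10-50% in 1% steps."""

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 0.501, 0.01), 10)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("sparsity grid must be a non-empty 1-D sequence")
        if np.any(np.diff(v) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")
        if v[0] <= 0 or v[-1] > 1:
            raise ValueError("sparsity values must lie in (0, 1]")
        self.values = v

    @classmethod
    def from_step(cls, lo: float = 0.10, hi: float = 0.50,
                  step: float = 0.01) -> "SparsityGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.round(lo + step * np.arange(n), 10))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at one fixed sparsity."""

    adjacency: np.ndarray
    sparsity: float = float("nan")
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        vals = np.unique(a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def is_connected(self) -> bool:
        return bool(_kernels.is_connected(self.adjacency))

    def edge_list(self) -> np.ndarray:
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([iu, ju])

    def neighbor_subgraph(self, node: int) -> "BinaryNetwork":
        """Subgraph induced by the neighbors of ``node`` (node excluded)."""
        nbrs = np.nonzero(self.adjacency[node])[0]
        sub = self.adjacency[np.ix_(nbrs, nbrs)]
        return BinaryNetwork(sub, sparsity=self.sparsity)


@dataclass
class NetworkEnsemble:
    """One binary network per grid point, nested by a shared edge ranking."""

    networks: list[BinaryNetwork]
    grid: SparsityGrid
    ranking: Ranking
    connected: np.ndarray

    def __post_init__(self) -> None:
        if len(self.networks) != len(self.grid):
            raise ValueError("one network per grid point required")
        self.connected = np.asarray(self.connected, dtype=bool)

    @property
    def all_connected(self) -> bool:
        return bool(self.connected.all())

    def disconnected_sparsities(self) -> np.ndarray:
        return self.grid.values[~self.connected]


def concatenate_epoch_powers(
    epoch_powers: Sequence[Sequence[float]],
    roi_labels: Sequence[str] | None = None,
    **meta: str,
) -> PowerSeriesMatrix:
    """Stack per-epoch ROI power vectors into an ROI x trial matrix.

    Epoch ``j`` becomes column ``j``, preserving presentation order; no
    reordering or normalization is applied.
    """
    epochs = [np.asarray(e, dtype=float) for e in epoch_powers]
    if len(epochs) < 2:
        raise ValueError("at least 2 epochs are required")
    n_rois = epochs[0].shape[0]
    for k, e in enumerate(epochs):
        if e.ndim != 1 or e.shape[0] != n_rois:
            raise ValueError(f"epoch {k} has {e.shape} values, expected ({n_rois},)")
    values = np.column_stack(epochs)
    if roi_labels is None:
        roi_labels = [f"R{i + 1:03d}" for i in range(n_rois)]
    return PowerSeriesMatrix(values, list(roi_labels), **meta)


def pearson_connectivity(psm: PowerSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all pairs of ROI power series."""
    values = psm.values
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [psm.roi_labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance power series for ROI(s): {bad}")
    w = np.corrcoef(values)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(w, list(psm.roi_labels))


def _edge_ranking(cm: ConnectivityMatrix, ranking: Ranking) -> np.ndarray:
    """(n_pairs, 2) node-pair array sorted by descending edge strength.

    Strength is |r| ("absolute", default) or r ("signed"); ties are
    broken by ascending (row, col) index so the cut is deterministic.
    """
    n = cm.n_rois
    iu, ju = np.triu_indices(n, 1)
    w = cm.weights[iu, ju]
    key = np.abs(w) if ranking == "absolute" else w
    order = np.lexsort((ju, iu, -key))
    return np.column_stack([iu[order], ju[order]])


def _edge_count(n: int, sparsity: float) -> int:
    return _round_half_away(sparsity * n * (n - 1) / 2.0)


def binarize_at_sparsity(
    cm: ConnectivityMatrix,
    sparsity: float,
    ranking: Ranking = "absolute",
) -> BinaryNetwork:
    """Keep the top-ranked fraction ``sparsity`` of all region pairs."""
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = cm.n_rois
    n_edges = _edge_count(n, sparsity)
    if n_edges == 0:
        raise ValueError(f"sparsity {sparsity} rounds to zero edges for N={n}")
    pairs = _edge_ranking(cm, ranking)[:n_edges]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[pairs[:, 0], pairs[:, 1]] = 1
    adj[pairs[:, 1], pairs[:, 0]] = 1
    return BinaryNetwork(adj, sparsity=float(sparsity),
                         roi_labels=list(cm.roi_labels))


def sweep_sparsity(
    cm: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    ranking: Ranking = "absolute",
) -> NetworkEnsemble:
    """Threshold one connectivity matrix at every grid sparsity.

    The pair ranking is computed once and shared, which guarantees that
    the edge sets are nested across the grid.  Disconnected networks are
    only flagged here; path-based metrics raise on them downstream.
    """
    grid = grid or SparsityGrid()
    n = cm.n_rois
    pairs = _edge_ranking(cm, ranking)
    networks: list[BinaryNetwork] = []
    flags = np.empty(len(grid), dtype=bool)
    adj = np.zeros((n, n), dtype=np.uint8)
    prev = 0
    for k, s in enumerate(grid.values):
        n_edges = _edge_count(n, float(s))
        if n_edges == 0:
            raise ValueError(f"sparsity {s} rounds to zero edges for N={n}")
        new = pairs[prev:n_edges]
        adj[new[:, 0], new[:, 1]] = 1
        adj[new[:, 1], new[:, 0]] = 1
        prev = max(prev, n_edges)
        net = BinaryNetwork(adj.copy(), sparsity=float(s),
                            roi_labels=list(cm.roi_labels))
        flags[k] = net.is_connected()
        networks.append(net)
    return NetworkEnsemble(networks, grid, ranking, flags)
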