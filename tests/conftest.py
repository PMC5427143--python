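"""Shared fixtures: small canonical graphs and a tiny synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from nbacknet import (
    BinaryNetwork,
    CohortConfig,
    ConnectivityMatrix,
    build_condition_covariance,
    generate_cohort,
    pearson_connectivity,
    simulate_power_matrix,
)


def graph_from_edges(n: int, edges) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = 1
        adj[j, i] = 1
    return BinaryNetwork(adj)


def complete_graph(n: int) -> BinaryNetwork:
    adj = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj)


def path_graph(n: int) -> BinaryNetwork:
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n_leaves: int) -> BinaryNetwork:
    return graph_from_edges(n_leaves + 1, [(0, i + 1) for i in range(n_leaves)])


def cycle_graph(n: int) -> BinaryNetwork:
    return graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def triangle_plus_pendant() -> BinaryNetwork:
    """Triangle {0,1,2} with a pendant node 3 attached to node 0."""
    return graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])


@pytest.fixture(scope="session")
def synthetic_connectivity() -> ConnectivityMatrix:
    """One default-scale (80 ROI) connectivity matrix from the generator."""
    config = CohortConfig(n_subjects=1, seed=7)
    corr = build_condition_covariance(config, "theta", "0back")
    psm = simulate_power_matrix(
        corr, 42, config.power_log_mean, config.power_log_sd,
        np.random.default_rng(7),
    )
    return pearson_connectivity(psm)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects x 16 ROIs: full structure at minimal runtime.

    16 nodes cannot be connected at 10% sparsity (12 edges < 15), so the
    reachability conditioning and any analysis grid start at 30%.
    """
    return generate_cohort(
        CohortConfig(n_subjects=4, n_rois=16, n_modules=4, seed=42,
                     min_connected_sparsity=0.30)
    )


TINY_GRID_KWARGS = dict(lo=0.30, hi=0.50, step=0.05)
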