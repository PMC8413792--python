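"""Graph metrics for thresholded connectivity networks: D, C, E.

Three global descriptors summarise each network.  Density D — the mean over
nodes of the local density, i.e. mean connection strength (weighted) or
degree fraction (binary); it measures the network's overall wiring cost.
The binary clustering coefficient C — the mean probability that two
neighbours of a node are themselves connected (functional segregation).
The binary global efficiency E — the mean inverse shortest-path length over
all node pairs (functional integration).  C and E are defined on binary
networks only; to compare them across states at matched wiring cost, they
are summed over a grid of cost thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import COST_GRID, ConnectionMatrix, ThresholdedNetwork, \
    binarize, threshold_cost


@dataclass
class NetworkMetrics:
    """Global (and per-node local) metrics of one thresholded network."""

    local_density: np.ndarray
    global_density: float
    avg_degree: float | None
    clustering: float | None
    efficiency: float | None
    weighted: bool
    n_nodes: int


def local_density(net: ThresholdedNetwork, node: int | None = None):
    """Mean connection strength of a node, sum_j c_ij / (N-1).

    For binary networks the sum is the node degree k_i and the value is
    k_i/(N-1).  With ``node=None`` the vector for all nodes is returned.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("local density needs at least 2 nodes")
    dloc = net.weights.sum(axis=1) / (n - 1)
    if node is None:
        return dloc
    if not 0 <= node < n:
        raise IndexError(f"node {node} out of range for {n}-node network")
    return float(dloc[node])


def global_density(net: ThresholdedNetwork) -> float:
    """Mean of the local densities over all nodes (network wiring cost)."""
    return float(np.mean(local_density(net)))


def average_degree(net: ThresholdedNetwork) -> float:
    """Mean node degree of a binary network, k_bar = D * (N - 1)."""
    if not net.binary:
        raise TypeError("average degree is defined for binary networks")
    return global_density(net) * (net.n_nodes - 1)


def clustering_coefficient(net: ThresholdedNetwork) -> float:
    """Binary global clustering coefficient (mean local transitivity).

    C_loc(i) = (number of triangles through i) / (k_i (k_i - 1) / 2 ... as
    ordered pairs), with C_loc defined as 0 for nodes of degree < 2; C is
    the mean over nodes.
    """
    if not net.binary:
        raise TypeError("clustering coefficient is defined for binary networks")
    a = net.weights
    k = a.sum(axis=1)
    triangles2 = np.einsum("ij,jh,hi->i", a, a, a)  # 2 * triangles, ordered pairs
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loc = np.where(denom > 0, triangles2 / denom, 0.0)
    return float(np.mean(c_loc))


def global_efficiency(net: ThresholdedNetwork) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    if not net.binary:
        raise TypeError("global efficiency is defined for binary networks")
    n = net.n_nodes
    d = shortest_path(net.weights, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def network_metrics(net: ThresholdedNetwork) -> NetworkMetrics:
    """All metrics applicable to one network (C, E for binary input only)."""
    dloc = local_density(net)
    d = float(np.mean(dloc))
    if net.binary:
        return NetworkMetrics(
            local_density=dloc, global_density=d,
            avg_degree=d * (net.n_nodes - 1),
            clustering=clustering_coefficient(net),
            efficiency=global_efficiency(net),
            weighted=False, n_nodes=net.n_nodes,
        )
    return NetworkMetrics(local_density=dloc, global_density=d, avg_degree=None,
                          clustering=None, efficiency=None, weighted=True,
                          n_nodes=net.n_nodes)


def cost_integrated_metrics(
    cm: ConnectionMatrix, cost_grid: tuple[float, ...] = COST_GRID
) -> dict[str, float]:
    """C and E summed over binarised cost-thresholded networks on a grid.

    Summation (rather than averaging) across the grid matches the reported
    cost-integrated statistic; any downstream ANOVA is invariant to that
    scale choice.
    """
    if len(cost_grid) == 0 or not all(0 < c <= 1 for c in cost_grid):
        raise ValueError("cost grid must be nonempty with values in (0, 1]")
    c_sum = 0.0
    e_sum = 0.0
    for cost in cost_grid:
        b = binarize(threshold_cost(cm, cost))
        c_sum += clustering_coefficient(b)
        e_sum += global_efficiency(b)
    return {"clustering_sum": c_sum, "efficiency_sum": e_sum,
            "n_costs": float(len(cost_grid))}
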