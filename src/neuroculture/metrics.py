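"""Graph statistics for structural and effective networks.

All operations accept a directed, binary adjacency in the edge convention
``A[i, j] = 1 <=> i -> j`` (scipy sparse or dense array).  Community structure
is found with Louvain on the symmetrized graph (sum of the adjacency and its
transpose, so reciprocal pairs weigh double), and the modularity of a
partition is evaluated explicitly from its defining sum

    Q = 1/(2m) * sum_ij (A_ij - k_i k_j / (2m)) delta(c_i, c_j)

on that symmetrized weighted graph.  Global efficiency is the mean inverse
shortest-path length over ordered pairs, normalized by the ideal complete
graph (E_id = 1 for unweighted graphs); unreachable pairs contribute zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.sparse.csgraph import shortest_path

from .errors import ConfigurationError

__all__ = [
    "DegreeStats",
    "ModularityResult",
    "EfficiencyResult",
    "SpatialHeatmap",
    "degree_stats",
    "clustering",
    "modularity_q",
    "modularity",
    "global_efficiency",
    "small_worldness",
    "spatial_heatmap",
]


def _as_dense(adjacency) -> np.ndarray:
    a = adjacency.toarray() if sparse.issparse(adjacency) else np.asarray(adjacency)
    a = (a != 0).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


# ---------------------------------------------------------------------------
# degrees


@dataclass(frozen=True)
class DegreeStats:
    k_in: np.ndarray
    k_out: np.ndarray
    mu_in: float        # Gaussian fit to the in-degree histogram
    sigma_in: float
    mu_out: float
    sigma_out: float
    hist_in: tuple[np.ndarray, np.ndarray]
    hist_out: tuple[np.ndarray, np.ndarray]


def degree_stats(adjacency) -> DegreeStats:
    """Exact integer degrees plus a least-squares Gaussian fit to each
    degree histogram (bin width one degree unit)."""
    a = _as_dense(adjacency)
    k_in = a.sum(axis=0).astype(int)
    k_out = a.sum(axis=1).astype(int)
    hi, fit_i = _hist_and_fit(k_in)
    ho, fit_o = _hist_and_fit(k_out)
    return DegreeStats(k_in=k_in, k_out=k_out,
                       mu_in=fit_i[0], sigma_in=fit_i[1],
                       mu_out=fit_o[0], sigma_out=fit_o[1],
                       hist_in=hi, hist_out=ho)


def _hist_and_fit(k: np.ndarray):
    edges = np.arange(-0.5, (k.max() if len(k) else 0) + 1.5)
    counts, edges = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    try:
        p0 = (counts.max(), float(k.mean()), float(k.std()) + 1e-6)
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
        mu, sd = float(popt[1]), float(abs(popt[2]))
    except Exception:  # degenerate histograms: fall back to sample moments
        mu, sd = float(k.mean()) if len(k) else math.nan, float(k.std()) if len(k) else math.nan
    return (counts, edges), (mu, sd)


# ---------------------------------------------------------------------------
# clustering (directed, Fagiolo)


def clustering(adjacency) -> np.ndarray:
    """Per-node directed clustering coefficient (Fagiolo's generalization,
    counting all directed triangle motifs and discounting reciprocal pairs)."""
    a = _as_dense(adjacency)
    s = a + a.T
    triangles = np.diagonal(s @ s @ s) / 2.0
    k_tot = a.sum(axis=0) + a.sum(axis=1)
    k_bi = np.diagonal(a @ a)
    denom = k_tot * (k_tot - 1) - 2.0 * k_bi
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, triangles / denom, 0.0)
    return cc


# ---------------------------------------------------------------------------
# modularity


@dataclass(frozen=True)
class ModularityResult:
    partition: np.ndarray    # community label per node
    q: float
    n_communities: int


def modularity_q(adjacency, labels: np.ndarray) -> float:
    """Evaluate Q of a partition on the symmetrized weighted graph."""
    a = _as_dense(adjacency)
    w = a + a.T
    two_m = w.sum()
    if two_m == 0:
        raise ConfigurationError("modularity is undefined for an empty graph")
    k = w.sum(axis=1)
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / two_m
    return float(q / two_m)


def modularity(adjacency, seed: int = 0, n_restarts: int = 10) -> ModularityResult:
    """Louvain community detection (best of ``n_restarts`` by Q).

    The directed graph is symmetrized for Louvain; the reported Q is evaluated
    by :func:`modularity_q` on the same symmetrized weights, so it is exactly
    reproducible from the partition.
    """
    a = _as_dense(adjacency)
    if a.sum() == 0:
        raise ConfigurationError("modularity is undefined for an empty graph")
    w = a + a.T
    g = nx.from_numpy_array(w)  # undirected, weighted
    best_q, best_labels = -np.inf, None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed + r)
        labels = np.empty(len(a), int)
        for ci, nodes in enumerate(comms):
            labels[list(nodes)] = ci
        q = modularity_q(adjacency, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return ModularityResult(partition=best_labels, q=float(best_q),
                            n_communities=int(len(np.unique(best_labels))))


# ---------------------------------------------------------------------------
# efficiency


@dataclass(frozen=True)
class EfficiencyResult:
    efficiency: float       # mean inverse shortest path length
    ideal_efficiency: float  # 1 for an unweighted complete digraph
    g_eff: float            # efficiency / ideal_efficiency


def global_efficiency(adjacency) -> EfficiencyResult:
    a = _as_dense(adjacency)
    n = len(a)
    if n < 2:
        return EfficiencyResult(0.0, 1.0, 0.0)
    d = shortest_path(sparse.csr_matrix(a), method="D", directed=True,
                      unweighted=True)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    e = inv.sum() / (n * (n - 1))
    return EfficiencyResult(efficiency=float(e), ideal_efficiency=1.0,
                            g_eff=float(e))


# ---------------------------------------------------------------------------
# small-worldness


def small_worldness(adjacency, n_null: int = 10, seed: int = 0) -> float:
    """Humphries-Gurney sigma = (C / C_rand) / (L / L_rand) against
    degree-matched rewired null graphs (edge swaps on the symmetrized graph).

    Paths are measured on the largest connected component of the symmetrized
    graph; C is the mean undirected clustering coefficient.
    """
    a = _as_dense(adjacency)
    g = nx.from_numpy_array(((a + a.T) > 0).astype(int))
    g.remove_edges_from(nx.selfloop_edges(g))
    c, l = _c_and_l(g)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(max(1, n_null)):
        h = g.copy()
        nswap = 10 * h.number_of_edges()
        nx.double_edge_swap(h, nswap=nswap, max_tries=50 * nswap,
                            seed=int(rng.integers(2**31 - 1)))
        cr, lr = _c_and_l(h)
        cs.append(cr)
        ls.append(lr)
    c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    if c_rand == 0 or l_rand == 0 or l == 0:
        return math.nan
    return (c / c_rand) / (l / l_rand)


def _c_and_l(g: nx.Graph) -> tuple[float, float]:
    c = nx.average_clustering(g)
    comp = max(nx.connected_components(g), key=len)
    l = nx.average_shortest_path_length(g.subgraph(comp))
    return float(c), float(l)


# ---------------------------------------------------------------------------
# spatial maps


@dataclass(frozen=True)
class SpatialHeatmap:
    values: np.ndarray       # (ny, nx) cell means, NaN where empty
    cell_size: float         # mm
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


def spatial_heatmap(positions: np.ndarray, values: np.ndarray,
                    diameter: float, cell_size: float | None = None) -> SpatialHeatmap:
    """Average a per-neuron quantity (in-degree, CC, ...) over square cells.

    The default cell side is 0.031 mm on the 2 mm substrate, scaled
    proportionally with the diameter.  Cells containing no neuron are NaN;
    interpolation, if wanted, is a rendering concern.
    """
    if cell_size is None:
        cell_size = 0.031 * (diameter / 2.0)
    R = diameter / 2.0
    n = int(math.ceil(2 * R / cell_size))
    ix = np.clip(((positions[:, 0] + R) / cell_size).astype(int), 0, n - 1)
    iy = np.clip(((positions[:, 1] + R) / cell_size).astype(int), 0, n - 1)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    np.add.at(sums, (iy, ix), values)
    np.add.at(counts, (iy, ix), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return SpatialHeatmap(values=means, cell_size=cell_size,
                          extent=(-R, R, -R, R))
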