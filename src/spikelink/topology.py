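"""Graph-theoretic characterization of thresholded functional networks.

Directed connectivity matrices are projected to simple undirected graphs
before any metric is computed (clustering, path length, small-world index
against random surrogates, rich-club analysis). The electrode-decimation
study reruns the full inference pipeline on regular spatial subgrids to
probe how the small-world index depends on recording density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "graph_from_matrix",
    "clustering_coefficient",
    "path_length",
    "random_equivalents",
    "small_world_index",
    "SmallWorldReport",
    "rich_club_curve",
    "RichClubResult",
    "decimation_study",
]


def graph_from_matrix(matrix: np.ndarray, sign_class: str = "all",
                      node_labels=None) -> nx.Graph:
    """Undirected simple-graph projection of a signed connectivity matrix."""
    matrix = np.asarray(matrix)
    if sign_class == "excitatory":
        adj = matrix > 0
    elif sign_class == "inhibitory":
        adj = matrix < 0
    elif sign_class == "all":
        adj = matrix != 0
    else:
        raise ValueError(f"unknown sign class {sign_class!r}")
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj.astype(int))
    if node_labels is not None:
        g = nx.relabel_nodes(g, dict(enumerate(node_labels)))
    return g


def clustering_coefficient(graph: nx.Graph):
    """Watts-Strogatz clustering per node and its mean over all nodes.

    Nodes with fewer than two neighbours have coefficient 0.
    """
    per_node = nx.clustering(graph)
    mean = float(np.mean(list(per_node.values()))) if per_node else 0.0
    return per_node, mean


def path_length(graph: nx.Graph):
    """Mean shortest-path distance over connected unordered node pairs.

    Disconnected pairs are excluded from both numerator and denominator;
    their fraction is reported alongside. Raises if no pair is connected.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    total = 0
    n_connected = 0
    for src, dists in nx.all_pairs_shortest_path_length(graph):
        for dst, d in dists.items():
            if dst != src:
                total += d
                n_connected += 1
    if n_connected == 0:
        raise ValueError("graph has no connected pairs")
    n_pairs = n * (n - 1)
    return total / n_connected, 1.0 - n_connected / n_pairs


def _surrogate(graph: nx.Graph, mode: str, rng) -> nx.Graph:
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    if mode == "density_matched":
        return nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    g = graph.copy()
    try:
        nx.double_edge_swap(g, nswap=max(10 * m, 1), max_tries=max(200 * m, 10),
                            seed=int(rng.integers(2**31)))
    except nx.NetworkXException:
        warnings.warn("graph cannot be rewired; density-matched surrogate used")
        return nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    return g


def random_equivalents(graph: nx.Graph, n_surrogates: int = 100,
                       mode: str = "degree_preserving", seed=None):
    """Mean clustering and path length over random surrogate graphs.

    `degree_preserving` (default) rewires by double edge swaps, preserving
    every node's degree; `density_matched` draws G(n, m) graphs with the
    same node and edge counts.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if mode not in ("degree_preserving", "density_matched"):
        raise ValueError(f"unknown surrogate mode {mode!r}")
    rng = np.random.default_rng(seed)
    ccs, pls = [], []
    for _ in range(n_surrogates):
        g = _surrogate(graph, mode, rng)
        ccs.append(clustering_coefficient(g)[1])
        try:
            pls.append(path_length(g)[0])
        except ValueError:
            continue
    if not pls:
        raise ValueError("no surrogate had connected pairs")
    return float(np.mean(ccs)), float(np.mean(pls))


@dataclass
class SmallWorldReport:
    c_net: float
    l_net: float
    c_rnd: float
    l_rnd: float
    swi: float
    n_surrogates: int
    surrogate_mode: str


def small_world_index(graph: nx.Graph, n_surrogates: int = 100,
                      mode: str = "degree_preserving",
                      seed=None) -> SmallWorldReport:
    """(C_net / C_rnd) / (L_net / L_rnd); values above 1 indicate
    small-world organization."""
    _, c_net = clustering_coefficient(graph)
    l_net, _ = path_length(graph)
    c_rnd, l_rnd = random_equivalents(graph, n_surrogates, mode, seed)
    if c_rnd == 0 or l_rnd == 0:
        raise ValueError("surrogate clustering or path length is zero")
    swi = (c_net / c_rnd) / (l_net / l_rnd)
    return SmallWorldReport(c_net, l_net, c_rnd, l_rnd, float(swi),
                            n_surrogates, mode)


@dataclass
class RichClubResult:
    k: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    max_normalized: float
    rich_club_nodes: list
    n_surrogates: int


def _raw_rcc(graph: nx.Graph, degrees: dict, k: int):
    """Edge density among nodes of degree > k; None when fewer than 2."""
    nodes = [v for v, deg in degrees.items() if deg > k]
    if len(nodes) < 2:
        return None, nodes
    sub = graph.subgraph(nodes)
    e = sub.number_of_edges()
    nn = len(nodes)
    return 2.0 * e / (nn * (nn - 1)), nodes


def rich_club_curve(graph: nx.Graph, n_surrogates: int = 100,
                    mode: str = "degree_preserving",
                    seed=None) -> RichClubResult:
    """Rich-club coefficient curve, normalized by random surrogates.

    RCC(k) is the edge density of the subgraph induced by nodes of degree
    greater than k; the normalized curve divides by the surrogate-ensemble
    mean at each k. A maximum normalized value above 1 flags a privileged
    (rich-club) sub-network, reported as the node set at the argmax.
    """
    degrees = dict(graph.degree())
    if not degrees or max(degrees.values()) < 2:
        raise ValueError("rich-club analysis needs max degree >= 2")
    max_k = max(degrees.values())
    ks, raw, club_sets = [], [], []
    for k in range(1, max_k + 1):
        r, nodes = _raw_rcc(graph, degrees, k)
        if r is None:
            continue
        ks.append(k)
        raw.append(r)
        club_sets.append(nodes)
    rng = np.random.default_rng(seed)
    surr_sum = np.zeros(len(ks))
    surr_cnt = np.zeros(len(ks))
    for _ in range(n_surrogates):
        g = _surrogate(graph, mode, rng)
        sdeg = dict(g.degree())
        for i, k in enumerate(ks):
            r, _ = _raw_rcc(g, sdeg, k)
            if r is not None:
                surr_sum[i] += r
                surr_cnt[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        surr_mean = np.where(surr_cnt > 0, surr_sum / np.maximum(surr_cnt, 1),
                             np.nan)
        normalized = np.asarray(raw) / surr_mean
    finite = np.isfinite(normalized) & (surr_mean > 0)
    if finite.any():
        arg = int(np.flatnonzero(finite)[np.argmax(normalized[finite])])
        max_norm = float(normalized[arg])
        club = club_sets[arg]
    else:
        max_norm, club = float("nan"), []
    return RichClubResult(np.asarray(ks), np.asarray(raw), normalized,
                          max_norm, club, n_surrogates)


def select_subgrid(layout, n_channels: int):
    """Deterministic uniform-stride spatial subsampling of a grid layout.

    Picks the largest integer stride (from the grid origin) that still
    yields at least `n_channels` electrodes, then trims to exactly
    `n_channels` in row-major order.
    """
    available = len(layout.channel_ids)
    if n_channels > available:
        raise ValueError(f"requested {n_channels} > {available} channels")
    rows, cols = layout.rows, layout.cols
    for stride in range(int(np.sqrt(available)) + 1, 0, -1):
        sel = np.flatnonzero((rows % stride == 0) & (cols % stride == 0))
        if sel.size >= n_channels:
            order = np.lexsort((cols[sel], rows[sel]))
            chosen = sel[order][:n_channels]
            logger.info("decimation: stride %d, %d channels", stride,
                        n_channels)
            return [layout.channel_ids[i] for i in chosen]
    raise ValueError("no stride yields enough channels")


def decimation_study(spike_set, layout, electrode_counts, window=0.050,
                     binwidth=0.001, pruning_params=None, sign_class="excitatory",
                     n_surrogates=20, seed=None, **model_kwargs) -> pd.DataFrame:
    """Small-world index versus electrode count on spatial subgrids.

    For each requested count (descending), a maximally uniform subgrid is
    selected, the inference pipeline (correlogram fit, spatio-temporal
    filter, hard threshold) is rerun on that channel subset, and the SWI of
    the requested sign class is reported together with its components.
    """
    from .connectivity import NcchConnectivity
    from .pruning import PruningParams

    counts = list(electrode_counts)
    if counts != sorted(counts, reverse=True):
        raise ValueError("electrode_counts must be descending")
    pruning_params = pruning_params or PruningParams()
    rows = []
    for m in counts:
        channels = select_subgrid(layout, m)
        sub_set = spike_set.subset(channels)
        sub_layout = layout.subset(channels)
        res = NcchConnectivity(sub_set, window=window, binwidth=binwidth,
                               layout=sub_layout, **model_kwargs).fit()
        res = res.spatiotemporal_filter(pruning_params, sub_layout)
        res = res.hard_threshold(pruning_params)
        g = graph_from_matrix(res.fcm, sign_class)
        row = {"n_electrodes": m,
               "n_links": int(np.count_nonzero(res.fcm))}
        try:
            report = small_world_index(g, n_surrogates=n_surrogates, seed=seed)
            row.update(swi=report.swi, c_net=report.c_net, l_net=report.l_net,
                       c_rnd=report.c_rnd, l_rnd=report.l_rnd)
        except ValueError:
            row.update(swi=float("nan"), c_net=float("nan"),
                       l_net=float("nan"), c_rnd=float("nan"),
                       l_rnd=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
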