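"""Topological characterization of binary undirected networks.

Four measures describe a condition network:

* clustering coefficient C_v — fraction of a node's neighbor pairs that
  are directly connected;
* global efficiency E — mean of inverse shortest-path distances over
  node pairs (disconnected pairs contribute 0), with the characteristic
  path length reported alongside;
* flow coefficient — a local betweenness-like measure: the number
  (``flow_raw``) and fraction (``flow_norm``) of a node's neighbor
  pairs that are NOT directly connected and therefore communicate
  through the length-2 path mediated by the node;
* degree assortativity — Pearson correlation of degrees at edge
  endpoints (Newman's coefficient).

On a binary undirected graph ``flow_norm`` and clustering partition the
neighbor pairs, so flow_norm_v + C_v = 1 for every node of degree >= 2;
group comparisons therefore default to ``flow_raw``, whose node-pair
units also carry the degree scale.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .containers import CooccurrenceNetwork, TopologyProfile


def _adjacency(net: CooccurrenceNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, CooccurrenceNetwork):
        return net.adjacency.astype(np.float64)
    a = np.asarray(net, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T) or np.diagonal(a).any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    return a


def clustering_coefficients(net: CooccurrenceNetwork | np.ndarray) -> np.ndarray:
    """Per-node clustering C_v = 2 T_v / (k_v (k_v - 1)); 0 when k_v < 2."""
    a = _adjacency(net)
    k = a.sum(axis=1)
    # T_v = closed neighbor pairs = (A^3)_vv / 2
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def flow_coefficients(
    net: CooccurrenceNetwork | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node flow coefficient, normalized and raw.

    ``flow_raw_v`` counts unordered neighbor pairs {i, j} of v with no
    direct edge i-j: each such pair exchanges along the mediated path
    i-v-j.  ``flow_norm_v`` divides by the k(k-1)/2 neighbor pairs and
    is 0 for degree < 2.
    """
    a = _adjacency(net)
    k = a.sum(axis=1)
    pairs = k * (k - 1) / 2.0
    closed = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    raw = pairs - closed
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(pairs > 0, raw / pairs, 0.0)
    return norm, raw


def global_efficiency(
    net: CooccurrenceNetwork | np.ndarray,
) -> tuple[float, float]:
    """(global efficiency, characteristic path length).

    Efficiency averages 1/d(i, j) over unordered node pairs with
    1/inf := 0 for disconnected pairs; the characteristic path length
    averages d(i, j) over connected pairs only and is nan when no pair
    is connected (e.g. edgeless or single-node networks).
    """
    a = _adjacency(net)
    n = a.shape[0]
    if n < 2:
        return 0.0, float("nan")
    g = nx.from_numpy_array(a)
    inv_sum = 0.0
    d_sum = 0.0
    n_connected = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst <= src:
                continue
            inv_sum += 1.0 / d
            d_sum += d
            n_connected += 1
    n_pairs = n * (n - 1) / 2
    eff = inv_sum / n_pairs
    cpl = d_sum / n_connected if n_connected else float("nan")
    return eff, cpl


def degree_assortativity(net: CooccurrenceNetwork | np.ndarray) -> float:
    """Newman degree assortativity; nan when endpoint-degree variance is 0.

    Computed as the Pearson correlation of the degrees at the two ends
    of each edge, over both orientations of every edge.  Edgeless
    networks are an error (the quantity is undefined rather than
    degenerate).
    """
    a = _adjacency(net)
    k = a.sum(axis=1)
    ii, jj = np.nonzero(np.triu(a, k=1))
    if len(ii) == 0:
        raise ValueError("assortativity requires at least one edge")
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    if np.ptp(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def topology_profile(net: CooccurrenceNetwork) -> TopologyProfile:
    """Assemble every per-node and global measure for one network."""
    a = net.adjacency.astype(np.float64)
    degree = a.sum(axis=1)
    clustering = clustering_coefficients(a)
    flow_norm, flow_raw = flow_coefficients(a)
    eff, cpl = global_efficiency(a)
    try:
        assort = degree_assortativity(a)
    except ValueError:
        assort = float("nan")
    return TopologyProfile(
        taxon_ids=list(net.taxon_ids),
        degree=degree,
        clustering=clustering,
        flow_norm=flow_norm,
        flow_raw=flow_raw,
        efficiency_global=eff,
        char_path_length=cpl,
        assortativity=assort,
    )
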