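"""Degree-preserving surrogate ensembles and metric normalization.

Observed topology values are put on a common scale by dividing by the
mean of the same metric over an ensemble of randomized networks whose
degree sequence is kept intact (Maslov-Sneppen double-edge swaps).  A
density-only Erdos-Renyi null is available behind a flag for
sensitivity checks.  Everything is reproducible: the ensemble seed is
spawned into independent per-surrogate streams, so the same
(network, n, seed) triple always yields bit-identical samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import CooccurrenceNetwork, TopologyProfile
from .topology import topology_profile

DEFAULT_N_SURROGATES = 1000
SWAP_BUDGET_PER_EDGE = 10

#: metric extractors applied to a surrogate's TopologyProfile
_METRICS: dict[str, Callable[[TopologyProfile], float | np.ndarray]] = {
    "efficiency_global": lambda p: p.efficiency_global,
    "char_path_length": lambda p: p.char_path_length,
    "assortativity": lambda p: p.assortativity,
    "clustering": lambda p: p.clustering.copy(),
    "flow_norm": lambda p: p.flow_norm.copy(),
    "flow_raw": lambda p: p.flow_raw.copy(),
    "mean_clustering": lambda p: float(p.clustering.mean()),
    "mean_flow_raw": lambda p: float(p.flow_raw.mean()),
}


@dataclass
class SurrogateEnsemble:
    source_net: CooccurrenceNetwork
    n_surrogates: int
    seed: int
    metric_samples: dict[str, list] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def samples(self, metric: str) -> np.ndarray:
        if metric not in self.metric_samples:
            raise KeyError(f"metric {metric!r} was not collected")
        return np.asarray(self.metric_samples[metric], dtype=float)


def rewire(
    net: CooccurrenceNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> CooccurrenceNetwork:
    """One degree-preserving randomization of ``net``.

    Attempts ``n_swaps`` double-edge swaps (default 10 per edge); a swap
    replacing edges (a, b), (c, d) with (a, d), (c, b) is rejected when
    it would create a self-loop or a multi-edge.  Edge rho/p attributes
    travel with the endpoint pair that keeps node a (resp. c), which
    preserves the multiset of edge weights.  Networks with fewer than
    two edges cannot be swapped and are returned unchanged with a
    warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if net.n_edges < 2:
        warnings.warn("network has < 2 edges; returning it unrewired", stacklevel=2)
        return net
    if n_swaps is None:
        n_swaps = SWAP_BUDGET_PER_EDGE * net.n_edges
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")

    adj = net.adjacency.astype(bool).copy()
    rho = net.edge_rho.copy()
    pmat = net.edge_p.copy()
    ii, jj = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([ii, jj], axis=1)
    m = len(edges)

    picks = rng.integers(0, m, size=(n_swaps, 2))
    flips = rng.random(n_swaps) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        rho[a, d] = rho[d, a] = rho[a, b]
        pmat[a, d] = pmat[d, a] = pmat[a, b]
        rho[c, b] = rho[b, c] = rho[c, d]
        pmat[c, b] = pmat[b, c] = pmat[c, d]
        rho[a, b] = rho[b, a] = 0.0
        pmat[a, b] = pmat[b, a] = 0.0
        rho[c, d] = rho[d, c] = 0.0
        pmat[c, d] = pmat[d, c] = 0.0
        edges[e1] = sorted((a, d))
        edges[e2] = sorted((c, b))

    return CooccurrenceNetwork(
        taxon_ids=list(net.taxon_ids),
        adjacency=adj.astype(np.int8),
        edge_rho=np.where(adj, rho, 0.0),
        edge_p=np.where(adj, pmat, 0.0),
        condition=net.condition,
    )


def erdos_renyi_surrogate(
    net: CooccurrenceNetwork, seed: int | np.random.Generator = 0
) -> CooccurrenceNetwork:
    """Density-only null: same node count and edge count, random placement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    chosen = rng.choice(n_pairs, size=net.n_edges, replace=False)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][chosen], iu[1][chosen]] = 1
    adj = adj + adj.T
    return CooccurrenceNetwork(
        taxon_ids=list(net.taxon_ids),
        adjacency=adj,
        edge_rho=np.zeros((n, n)),
        edge_p=np.zeros((n, n)),
        condition=net.condition,
    )


def surrogate_ensemble(
    net: CooccurrenceNetwork,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    metrics: tuple[str, ...] = ("efficiency_global", "mean_flow_raw", "mean_clustering"),
    seed: int = 0,
    null_model: str = "degree",
) -> SurrogateEnsemble:
    """Evaluate metrics over ``n_surrogates`` independent randomizations.

    Per-surrogate randomness comes from child streams spawned off
    ``seed``, so surrogates are independent yet the whole ensemble is
    reproducible.  A metric that fails on one surrogate (e.g.
    assortativity on a degenerate draw) is recorded as nan, not fatal.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    unknown = [m for m in metrics if m not in _METRICS]
    if unknown:
        raise KeyError(f"unknown metrics {unknown}; known: {sorted(_METRICS)}")
    if null_model not in ("degree", "erdos-renyi"):
        raise ValueError("null_model must be 'degree' or 'erdos-renyi'")

    ensemble = SurrogateEnsemble(
        source_net=net, n_surrogates=n_surrogates, seed=seed,
        metric_samples={m: [] for m in metrics},
    )
    children = np.random.SeedSequence(seed).spawn(n_surrogates)
    for child in children:
        rng = np.random.default_rng(child)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if null_model == "degree":
                surr = rewire(net, seed=rng)
            else:
                surr = erdos_renyi_surrogate(net, seed=rng)
        profile = topology_profile(surr)
        for m in metrics:
            try:
                ensemble.metric_samples[m].append(_METRICS[m](profile))
            except Exception as exc:  # recorded, not fatal
                ensemble.metric_samples[m].append(float("nan"))
                ensemble.errors.append(f"{m}: {exc}")
    return ensemble


def normalize_metric(
    observed_value: float | np.ndarray,
    ensemble: SurrogateEnsemble,
    metric: str,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """(observed / surrogate mean, z-score) for one metric.

    Returns nan where the surrogate mean is 0 (ratio undefined) or the
    surrogate spread is 0 (z-score undefined).  Raises when the
    ensemble holds no finite sample at all.
    """
    samples = ensemble.samples(metric)
    finite = np.isfinite(samples)
    if not finite.any():
        raise ValueError(f"no finite surrogate samples for {metric!r}")
    samples = samples[np.all(finite, axis=tuple(range(1, samples.ndim)))] if samples.ndim > 1 else samples[finite]
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=0)
    observed_value = np.asarray(observed_value, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean != 0, observed_value / mean, np.nan)
        z = np.where(sd != 0, (observed_value - mean) / sd, np.nan)
    if ratio.ndim == 0:
        return float(ratio), float(z)
    return ratio, z


def normalized_profile(
    net: CooccurrenceNetwork,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    null_model: str = "degree",
) -> TopologyProfile:
    """Topology profile with surrogate-normalized twins attached.

    Both global scalars and per-node vectors are normalized; normalized
    entries live in ``profile.normalized`` under the metric name.
    """
    profile = topology_profile(net)
    metrics = ("efficiency_global", "clustering", "flow_norm", "flow_raw", "assortativity")
    ens = surrogate_ensemble(net, n_surrogates, metrics, seed, null_model)
    observed = {
        "efficiency_global": profile.efficiency_global,
        "clustering": profile.clustering,
        "flow_norm": profile.flow_norm,
        "flow_raw": profile.flow_raw,
        "assortativity": profile.assortativity,
    }
    for m in metrics:
        try:
            ratio, z = normalize_metric(observed[m], ens, m)
        except ValueError:
            ratio, z = float("nan"), float("nan")
        profile.normalized[m] = ratio
        profile.normalized[f"{m}_z"] = z
    return profile
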