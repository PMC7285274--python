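"""Condition-specific co-occurrence network construction.

Pairs of taxa are connected when their abundances co-vary across the
samples of one condition: the association is the pairwise Spearman rank
correlation and an edge survives when its two-sided p-value falls below
a single stringent threshold (default 1e-5).  Because the statistic is
rank-based, the resulting network is invariant under any strictly
monotone per-taxon transform of the counts and under sample reordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CooccurrenceNetwork, OtuTable

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_MIN_PREVALENCE = 0.2


@dataclass
class CorrelationResult:
    """All-pairs Spearman correlation over the taxa of one condition."""

    rho_matrix: np.ndarray
    p_matrix: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        r, p = np.asarray(self.rho_matrix), np.asarray(self.p_matrix)
        if r.shape != p.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho and p must be square matrices of equal shape")
        if not np.allclose(r, r.T) or not np.allclose(p, p.T):
            raise ValueError("rho and p must be symmetric")
        self.rho_matrix, self.p_matrix = r, p


def filter_taxa(
    table: OtuTable,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_mean_count: float = 0.0,
) -> OtuTable:
    """Drop rare taxa before correlation.

    A taxon is kept when it is present (count > 0) in at least
    ``min_prevalence`` of the samples and its mean count is at least
    ``min_mean_count``.  Row order is preserved; removing every taxon is
    an error (the caller should relax the filter, not silently proceed).
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    mean_count = table.counts.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_count >= min_mean_count)
    if not keep.any():
        raise ValueError(
            f"filter removed all {table.n_taxa} taxa "
            f"(min_prevalence={min_prevalence}, min_mean_count={min_mean_count})"
        )
    idx = np.nonzero(keep)[0]
    return OtuTable(
        counts=table.counts[idx],
        taxon_ids=[table.taxon_ids[i] for i in idx],
        sample_ids=table.sample_ids,
        condition=table.condition,
        taxonomy=None
        if table.taxonomy is None
        else [table.taxonomy[i] for i in idx],
    )


def spearman_matrix(
    counts: np.ndarray | OtuTable,
    method: str = "t-approx",
) -> CorrelationResult:
    """All-pairs Spearman rho and two-sided p-values.

    Ranks use midranks for ties; p-values come from the t approximation
    on n - 2 degrees of freedom.  ``method="exact"`` enumerates the
    permutation null instead (only for n <= 8 samples, where full
    enumeration is affordable).  Constant rows carry no rank
    information and are assigned rho = 0, p = 1 by contract.
    """
    if isinstance(counts, OtuTable):
        counts = counts.counts
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a taxa x samples matrix")
    n_taxa, n_samples = x.shape
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if n_samples < 4:
        raise ValueError("need at least 4 samples for meaningful p-values")

    constant = np.ptp(x, axis=1) == 0
    if method == "exact":
        rho, p = _spearman_exact(x)
    else:
        ranks = stats.rankdata(x, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.corrcoef(ranks)  # constant rows yield nan, fixed below
        rho = np.clip(rho, -1.0, 1.0)
        # two-sided p from t = rho * sqrt((n-2)/(1-rho^2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n_samples - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n_samples - 2)
        p[np.isinf(t)] = 0.0
        p = np.where(np.isnan(p), 1.0, p)

    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(rho_matrix=rho, p_matrix=p, n_samples=n_samples)


def _spearman_exact(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation p-values by full enumeration (n <= 8)."""
    n_taxa, n = x.shape
    if n > 8:
        raise ValueError("exact permutation mode is limited to n <= 8 samples")
    ranks = stats.rankdata(x, axis=1)
    rho = np.clip(np.corrcoef(ranks), -1.0, 1.0)
    perms = np.array(list(itertools.permutations(range(n))))
    n_perm = len(perms)
    p = np.ones((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            ri, rj = ranks[i], ranks[j]
            if np.ptp(ri) == 0 or np.ptp(rj) == 0:
                continue
            null = np.array(
                [np.corrcoef(ri, rj[perm])[0, 1] for perm in perms]
            )
            obs = abs(rho[i, j])
            p[i, j] = p[j, i] = (np.abs(null) >= obs - 1e-12).sum() / n_perm
    np.fill_diagonal(p, 0.0)
    return rho, p


def build_network(
    corr: CorrelationResult,
    taxon_ids: list[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    condition: str = "",
) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a binary undirected network.

    An edge (i, j), i != j, exists iff p_ij < ``p_threshold``; the
    signed rho is kept as an edge attribute.  Negative correlations form
    edges exactly like positive ones.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    n = corr.rho_matrix.shape[0]
    if len(taxon_ids) != n:
        raise ValueError("taxon_ids length does not match correlation matrix")
    adjacency = (corr.p_matrix < p_threshold).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    mask = adjacency.astype(bool)
    return CooccurrenceNetwork(
        taxon_ids=list(taxon_ids),
        adjacency=adjacency,
        edge_rho=np.where(mask, corr.rho_matrix, 0.0),
        edge_p=np.where(mask, corr.p_matrix, 0.0),
        condition=condition,
    )


def build_condition_network(
    table: OtuTable,
    condition: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    relative_abundance: bool = False,
) -> CooccurrenceNetwork:
    """Convenience: Spearman + threshold for one condition's samples.

    ``relative_abundance`` divides each sample by its library size
    first; Spearman is rank-based per taxon, so this changes results
    only through the per-sample rescaling, not per-taxon monotonicity.
    """
    counts = table.condition_counts(condition).astype(float)
    if relative_abundance:
        libsize = counts.sum(axis=0, keepdims=True)
        libsize[libsize == 0] = 1.0
        counts = counts / libsize
    corr = spearman_matrix(counts)
    return build_network(corr, table.taxon_ids, p_threshold, condition)
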