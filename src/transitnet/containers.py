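"""In-memory containers shared across the pipeline.

The pipeline passes a small set of typed objects between stages: an
abundance table (:class:`OtuTable`), thresholded co-occurrence networks
(:class:`CooccurrenceNetwork`), per-network topology summaries
(:class:`TopologyProfile`), dense transition matrices
(:class:`TransitionNetwork`) and ranked keystone listings
(:class:`KeystoneReport`).  All containers are plain dataclasses over
numpy arrays; they validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class OtuTable:
    """Taxa-by-samples count table with a two-group sample condition.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per taxon, one column per
        sample.
    taxon_ids
        Unique row labels (OTU ids or collapsed taxon names).
    sample_ids
        Unique column labels.
    condition
        Per-sample group label; exactly two distinct labels must occur
        (e.g. ``ACT``/``SED``).
    taxonomy
        Optional lineage string per taxon.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    condition: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa:
            raise ValueError("taxon_ids length does not match counts rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.taxon_ids)) != n_taxa:
            raise ValueError("taxon_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        if len(self.condition) != n_samples:
            raise ValueError("condition length does not match sample count")
        labels = sorted(set(self.condition))
        if len(labels) != 2:
            raise ValueError(
                f"exactly two condition labels required, got {labels}"
            )
        if self.taxonomy is not None and len(self.taxonomy) != n_taxa:
            raise ValueError("taxonomy length does not match taxon count")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def condition_labels(self) -> tuple[str, str]:
        a, b = sorted(set(self.condition))
        return a, b

    def condition_counts(self, label: str) -> np.ndarray:
        """Counts sub-matrix (taxa x samples) for one condition label."""
        if label not in set(self.condition):
            raise KeyError(f"unknown condition label {label!r}")
        mask = np.array([c == label for c in self.condition])
        return self.counts[:, mask]


@dataclass
class CooccurrenceNetwork:
    """Binary undirected co-occurrence network over taxa.

    ``adjacency`` is symmetric 0/1 with a zero diagonal; each edge
    carries its signed Spearman rho and the p-value that admitted it.
    """

    taxon_ids: list[str]
    adjacency: np.ndarray
    edge_rho: np.ndarray
    edge_p: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.taxon_ids):
            raise ValueError("adjacency dimension does not match taxon_ids")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)
        self.edge_rho = np.asarray(self.edge_rho, dtype=float)
        self.edge_p = np.asarray(self.edge_p, dtype=float)
        if self.edge_rho.shape != a.shape or self.edge_p.shape != a.shape:
            raise ValueError("edge attribute matrices must match adjacency")
        mask = self.adjacency.astype(bool)
        if mask.any():
            if (np.abs(self.edge_rho[mask]) > 1).any():
                raise ValueError("edge rho out of [-1, 1]")
            p = self.edge_p[mask]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("edge p out of [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def to_networkx(self) -> nx.Graph:
        """NetworkX view with rho/p as edge attributes."""
        g = nx.Graph(condition=self.condition)
        g.add_nodes_from(self.taxon_ids)
        idx = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*idx):
            if self.adjacency[i, j]:
                g.add_edge(
                    self.taxon_ids[i],
                    self.taxon_ids[j],
                    rho=float(self.edge_rho[i, j]),
                    p=float(self.edge_p[i, j]),
                    weight=float(self.edge_rho[i, j]),
                )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, condition: str = "") -> "CooccurrenceNetwork":
        nodes = list(g.nodes())
        n = len(nodes)
        pos = {v: i for i, v in enumerate(nodes)}
        adj = np.zeros((n, n), dtype=np.int8)
        rho = np.zeros((n, n))
        pmat = np.zeros((n, n))
        for u, v, data in g.edges(data=True):
            i, j = pos[u], pos[v]
            adj[i, j] = adj[j, i] = 1
            rho[i, j] = rho[j, i] = float(data.get("rho", 0.0))
            pmat[i, j] = pmat[j, i] = float(data.get("p", 0.0))
        return cls(
            taxon_ids=[str(v) for v in nodes],
            adjacency=adj,
            edge_rho=rho,
            edge_p=pmat,
            condition=condition or str(g.graph.get("condition", "")),
        )

    def signed_matrix(self, unit_diagonal: bool = True) -> np.ndarray:
        """Signed-correlation matrix: rho where an edge exists, else 0.

        With ``unit_diagonal`` a 1 is placed on the diagonal, which keeps
        the matrix closer to full rank for the transition-matrix solve.
        """
        m = np.where(self.adjacency.astype(bool), self.edge_rho, 0.0)
        if unit_diagonal:
            np.fill_diagonal(m, 1.0)
        return m


@dataclass
class TopologyProfile:
    """Per-node and global topology measures of one binary network.

    ``flow_raw`` counts mediated open neighbor pairs (units: node
    pairs); ``flow_norm`` is the same count divided by the number of
    neighbor pairs.  ``normalized`` optionally holds surrogate-
    normalized twins keyed by metric name.
    """

    taxon_ids: list[str]
    degree: np.ndarray
    clustering: np.ndarray
    flow_norm: np.ndarray
    flow_raw: np.ndarray
    efficiency_global: float
    char_path_length: float  # nan when undefined
    assortativity: float  # nan when undefined
    normalized: dict[str, float | np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        for name in ("degree", "clustering", "flow_norm", "flow_raw"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have one value per node")
            setattr(self, name, v)
        if not 0.0 <= self.efficiency_global <= 1.0:
            raise ValueError("efficiency_global out of [0, 1]")
        if ((self.clustering < 0) | (self.clustering > 1)).any():
            raise ValueError("clustering out of [0, 1]")
        if ((self.flow_norm < 0) | (self.flow_norm > 1)).any():
            raise ValueError("flow_norm out of [0, 1]")


@dataclass
class TransitionNetwork:
    """Dense transition matrix T relating two condition networks.

    In ``consistent`` mode T solves A @ T = B in the least-squares
    sense (T = pinv(A) @ B); ``literal`` mode applies the printed
    inverse-product form pinv(B) @ A.  ``residual`` is the Frobenius
    norm of A @ T - B for the consistent reading.
    """

    taxon_ids: list[str]
    matrix: np.ndarray
    direction: str
    mode: str
    pinv_tolerance: float
    residual: float = float("nan")
    binarized: "CooccurrenceNetwork | None" = None
    binarized_density: float = float("nan")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        if m.shape[0] != len(self.taxon_ids):
            raise ValueError("matrix dimension does not match taxon_ids")
        if self.mode not in ("literal", "consistent"):
            raise ValueError("mode must be 'literal' or 'consistent'")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_ids)


@dataclass
class KeystoneReport:
    """Taxa in the top flow-coefficient fraction of a transition network."""

    direction: str
    taxa: list[str]
    flow_raw: np.ndarray
    flow_norm: np.ndarray
    fraction: float
    n_selected: int

    def __post_init__(self) -> None:
        self.flow_raw = np.asarray(self.flow_raw, dtype=float)
        self.flow_norm = np.asarray(self.flow_norm, dtype=float)
        if not (len(self.taxa) == len(self.flow_raw) == len(self.flow_norm)):
            raise ValueError("report columns must have equal length")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_selected != len(self.taxa):
            raise ValueError("n_selected must equal the number of rows")
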