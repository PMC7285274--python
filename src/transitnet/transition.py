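"""Transition networks between two condition networks, and keystones.

The reorganization of one condition's co-occurrence network A into the
other's B is modelled as a matrix product: a transition matrix T such
that A @ T = B.  Two readings are implemented:

* ``consistent`` (default) — T = pinv(A) @ B, the least-squares
  solution of the defining relation A @ T = B; when A is full rank the
  residual ||A @ T - B||_F is numerically zero.
* ``literal`` — T = pinv(B) @ A, the inverse-times-source product form
  as conventionally printed for this construction (which satisfies
  B @ T = A instead); kept so both readings can be compared.

Inversion always uses a rank-truncated Moore-Penrose pseudoinverse, so
singular (rank-deficient) condition matrices are handled without
failure.  The dense signed T is turned back into a binary undirected
view at a chosen edge density, on which the flow coefficient is
computed; taxa in the top fraction (default 10%) of raw flow
coefficient are reported as the driving keystones of the transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CooccurrenceNetwork, KeystoneReport, TransitionNetwork
from .topology import flow_coefficients

DEFAULT_KEYSTONE_FRACTION = 0.10


@dataclass
class TransitionConfig:
    """Settings for :func:`run_transition_analysis`."""

    mode: str = "consistent"
    matrix_kind: str = "signed"  # "signed" rho matrix or 0/1 "adjacency"
    align_policy: str = "intersection"
    target_density: float | None = None  # default: mean density of inputs
    fraction: float = DEFAULT_KEYSTONE_FRACTION


def align_networks(
    netA: CooccurrenceNetwork,
    netB: CooccurrenceNetwork,
    policy: str = "intersection",
    matrix_kind: str = "signed",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Put two networks on a shared taxon ordering.

    ``intersection`` keeps taxa present in both networks; ``union``
    zero-pads taxa absent from one network (a padded taxon has no edges
    there).  Returns the two matrices (signed-correlation with unit
    diagonal, or raw adjacency, per ``matrix_kind``) plus the shared
    ordering.
    """
    if policy not in ("intersection", "union"):
        raise ValueError("policy must be 'intersection' or 'union'")
    if matrix_kind not in ("signed", "adjacency"):
        raise ValueError("matrix_kind must be 'signed' or 'adjacency'")
    if netA.n_nodes == 0 or netB.n_nodes == 0:
        raise ValueError("both networks must be nonempty")
    set_a, set_b = set(netA.taxon_ids), set(netB.taxon_ids)
    if policy == "intersection":
        shared = [t for t in netA.taxon_ids if t in set_b]
        if not shared:
            raise ValueError("taxon sets are disjoint; nothing to align")
    else:
        shared = list(netA.taxon_ids) + [t for t in netB.taxon_ids if t not in set_a]

    def extract(net: CooccurrenceNetwork) -> np.ndarray:
        full = (
            net.signed_matrix(unit_diagonal=True)
            if matrix_kind == "signed"
            else net.adjacency.astype(float)
        )
        pos = {t: i for i, t in enumerate(net.taxon_ids)}
        n = len(shared)
        out = np.zeros((n, n))
        present = [k for k, t in enumerate(shared) if t in pos]
        src = np.array([pos[shared[k]] for k in present])
        if len(present):
            out[np.ix_(present, present)] = full[np.ix_(src, src)]
        return out

    return extract(netA), extract(netB), shared


def transition_matrix(
    A: np.ndarray,
    B: np.ndarray,
    taxon_ids: list[str] | None = None,
    mode: str = "consistent",
    direction: str = "A->B",
) -> TransitionNetwork:
    """Transition matrix between aligned square matrices A and B.

    The pseudoinverse truncates singular values below
    ``dim * eps * sigma_max`` (the standard rank-revealing cutoff); the
    tolerance used and the consistency residual ||A @ T - B||_F are
    stored on the result.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of equal shape")
    n = A.shape[0]
    if taxon_ids is None:
        taxon_ids = [f"t{i}" for i in range(n)]
    rcond = n * np.finfo(float).eps
    if mode == "consistent":
        T = np.linalg.pinv(A, rcond=rcond) @ B
    elif mode == "literal":
        T = np.linalg.pinv(B, rcond=rcond) @ A
    else:
        raise ValueError("mode must be 'consistent' or 'literal'")
    sigma_max = np.linalg.norm(A, 2) if n else 0.0
    residual = float(np.linalg.norm(A @ T - B, "fro"))
    return TransitionNetwork(
        taxon_ids=list(taxon_ids),
        matrix=T,
        direction=direction,
        mode=mode,
        pinv_tolerance=float(rcond * sigma_max),
        residual=residual,
    )


def binarize_transition(
    tnet: TransitionNetwork,
    target_density: float,
) -> CooccurrenceNetwork:
    """Binary undirected view of a dense transition matrix.

    The matrix is symmetrized element-wise as max(|T|, |T^T|), the
    diagonal zeroed, and the strongest entries kept until the edge
    density reaches ``target_density``.  Ties at the cut are broken by
    taxon-label lexicographic order so the view is deterministic.  The
    view is attached to ``tnet.binarized`` and also returned.
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    T = tnet.matrix
    n = T.shape[0]
    strength = np.maximum(np.abs(T), np.abs(T.T))
    np.fill_diagonal(strength, 0.0)
    if not strength.any():
        raise ValueError("transition matrix has no off-diagonal signal")
    iu, ju = np.triu_indices(n, k=1)
    n_keep = int(round(target_density * len(iu)))
    n_keep = max(n_keep, 1)
    labels = tnet.taxon_ids
    order = sorted(
        range(len(iu)),
        key=lambda k: (-strength[iu[k], ju[k]], labels[iu[k]], labels[ju[k]]),
    )
    keep = order[:n_keep]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj = adj + adj.T
    # relative signed strength in [-1, 1]: |T| rescaled by the largest entry
    rel = np.sign(T + T.T) * strength / strength.max()
    view = CooccurrenceNetwork(
        taxon_ids=list(labels),
        adjacency=adj,
        edge_rho=np.where(adj.astype(bool), rel, 0.0),
        edge_p=np.zeros((n, n)),
        condition=tnet.direction,
    )
    tnet.binarized = view
    tnet.binarized_density = n_keep / len(iu)
    return view


def keystone_taxa(
    fc_raw: np.ndarray,
    taxon_ids: list[str],
    fraction: float = DEFAULT_KEYSTONE_FRACTION,
    direction: str = "",
    fc_norm: np.ndarray | None = None,
) -> KeystoneReport:
    """Taxa in the top ``fraction`` of raw flow coefficient.

    Selects the ceil(fraction * n) highest-FC taxa; taxa tied with the
    boundary value are all included.  Output is sorted by FC descending,
    then taxon label.
    """
    fc_raw = np.asarray(fc_raw, dtype=float)
    if fc_raw.size == 0:
        raise ValueError("empty flow-coefficient vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(taxon_ids) != fc_raw.size:
        raise ValueError("taxon_ids length does not match FC vector")
    if fc_norm is None:
        fc_norm = np.full_like(fc_raw, np.nan)
    n = fc_raw.size
    n_top = int(np.ceil(fraction * n))
    order = sorted(range(n), key=lambda i: (-fc_raw[i], taxon_ids[i]))
    boundary = fc_raw[order[n_top - 1]]
    selected = [i for i in order if fc_raw[i] > boundary]
    selected += [i for i in order if fc_raw[i] == boundary]
    return KeystoneReport(
        direction=direction,
        taxa=[taxon_ids[i] for i in selected],
        flow_raw=fc_raw[selected],
        flow_norm=np.asarray(fc_norm, dtype=float)[selected],
        fraction=fraction,
        n_selected=len(selected),
    )


def run_transition_analysis(
    netA: CooccurrenceNetwork,
    netB: CooccurrenceNetwork,
    config: TransitionConfig | None = None,
) -> tuple[TransitionNetwork, TransitionNetwork, KeystoneReport, KeystoneReport]:
    """End-to-end transition analysis between two condition networks.

    align -> transition matrices for both directions -> binarize at a
    matched density -> flow coefficients -> keystone reports.  Fully
    deterministic given the config.  Returns
    (T_ab, T_ba, keystones_ab, keystones_ba) where direction ``A->B``
    maps network A's structure onto network B's.
    """
    config = config or TransitionConfig()
    A, B, shared = align_networks(
        netA, netB, policy=config.align_policy, matrix_kind=config.matrix_kind
    )
    label_a = netA.condition or "A"
    label_b = netB.condition or "B"
    t_ab = transition_matrix(A, B, shared, config.mode, f"{label_a}->{label_b}")
    t_ba = transition_matrix(B, A, shared, config.mode, f"{label_b}->{label_a}")
    density = config.target_density
    if density is None:
        density = (netA.density + netB.density) / 2.0
        if density == 0:
            raise ValueError("both input networks are edgeless")
    reports = []
    for tnet in (t_ab, t_ba):
        view = binarize_transition(tnet, density)
        fc_norm, fc_raw = flow_coefficients(view)
        reports.append(
            keystone_taxa(fc_raw, shared, config.fraction, tnet.direction, fc_norm)
        )
    return t_ab, t_ba, reports[0], reports[1]
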