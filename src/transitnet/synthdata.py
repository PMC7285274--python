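"""Two-condition synthetic OTU tables with known ground-truth networks.

The generator emulates the shape of a two-lifestyle 16S cohort: ~100
stool samples split 64/45 between an active-like and a sedentary-like
group, a few hundred taxa, zero-inflated overdispersed counts, and a
planted co-occurrence graph per condition.

Planted structure
-----------------
Taxa are partitioned into modules realized as correlation cliques
(every within-module pair correlated at the planted magnitude —
cliques keep the target correlation matrix positive-definite by
construction; a valid correlation matrix cannot host strongly-coupled
yet incomplete neighborhoods, so open neighbor pairs must come from
degree structure and coupling strength, not from holes punched in
modules).  The sedentary-like graph is module-confined and tightly
coupled (default magnitude 0.8): a subset of whole modules and
sub-modules, sized to hit the requested density exactly.  The
active-like graph is denser, with weaker, more distributed couplings
(default 0.65) and cross-module shortcut edges routed through
designated bottleneck hub taxa, each bridging two modules (hub edges
at 0.55, near the largest value compatible with positive-definiteness
when a hub attaches to two modules).

Counts
------
A Gaussian copula maps the latent multivariate normal through each
taxon's zero-inflated negative-binomial quantile function.  The zero
mass sits at the bottom of the latent ranks (a structural-zero
reading: taxa drop below detection when their latent abundance is
low), so the rank-based network builder sees the planted latent
correlation attenuated only by ties, not destroyed by independent
masking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .containers import CooccurrenceNetwork, OtuTable
from .io import write_otu_table_biom, write_otu_table_tsv, write_network

MIN_TAXA = 10


@dataclass
class SyntheticSpec:
    """Parameters of the two-condition generator (defaults = study shape)."""

    n_taxa: int = 150
    n_active: int = 64
    n_sedentary: int = 45
    labels: tuple[str, str] = ("ACT", "SED")
    density_active: float = 0.08
    density_sedentary: float = 0.05
    rho: float = 0.8  # sedentary-like within-module edge correlation
    rho_active: float = 0.65  # active-like within-module edge correlation
    hub_rho: float = 0.55  # hub shortcut edge correlation
    n_hubs: int = 3
    max_module: int | None = None  # default: max(4, ceil(n_taxa / 10))
    nb_mean_log_mu: float = float(np.log(20.0))
    nb_mean_log_sigma: float = 1.0
    dispersion: float = 0.5  # negative-binomial size parameter
    zero_inflation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_sedentary < 1:
            raise ValueError("sample sizes must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        # magnitude 0 plants a null (independence) structure for calibration
        for r in (self.rho, self.rho_active, self.hub_rho):
            if not 0 <= r < 1:
                raise ValueError("correlation magnitudes must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure behind one synthetic table."""

    taxon_ids: list[str]
    adjacency: dict[str, np.ndarray]  # condition -> planted 0/1 adjacency
    latent_corr: dict[str, np.ndarray]  # condition -> repaired latent R
    hubs: list[str]
    modules: list[list[str]]
    repair_delta: dict[str, float] = field(default_factory=dict)

    def network(self, condition: str) -> CooccurrenceNetwork:
        a = self.adjacency[condition]
        r = self.latent_corr[condition].copy()
        np.fill_diagonal(r, 0.0)
        return CooccurrenceNetwork(
            taxon_ids=list(self.taxon_ids),
            adjacency=a,
            edge_rho=np.where(a.astype(bool), r, 0.0),
            edge_p=np.zeros_like(r),
            condition=condition,
        )


def _greedy_cliques(nodes: list[int], budget: int, cap: int) -> list[list[int]]:
    """Partition as many of ``nodes`` into cliques spending exactly ``budget``
    edges when possible (a size-2 clique spends 1 edge, so any residue
    can be absorbed while at least two nodes remain)."""
    cliques: list[list[int]] = []
    pool = list(nodes)
    remaining = budget
    while remaining > 0 and len(pool) >= 2:
        s = min(cap, len(pool))
        while s >= 2 and s * (s - 1) // 2 > remaining:
            s -= 1
        if s < 2:
            break
        cliques.append(pool[:s])
        pool = pool[s:]
        remaining -= s * (s - 1) // 2
    return cliques


def planted_topology(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, list[int], list[list[int]]]:
    """Ground-truth adjacency for both conditions.

    Returns (active adjacency, sedentary adjacency, hub node indices,
    module node lists).  Realized edge counts match the requested
    densities to within one edge, or a ValueError reports the
    incompatibility.
    """
    n = spec.n_taxa
    if n < MIN_TAXA:
        raise ValueError(f"need at least {MIN_TAXA} taxa, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 101)))
    n_pairs = n * (n - 1) // 2
    e_act = round(spec.density_active * n_pairs)
    e_sed = round(spec.density_sedentary * n_pairs)
    if e_act < 1 or e_sed < 1:
        raise ValueError("requested densities yield no edges")

    cap = spec.max_module
    if cap is None:
        # modules must be large enough that module edges alone can carry
        # the requested density: ~n/cap modules contribute n(cap-1)/2 edges
        cap = max(4, -(-n // 10),
                  int(np.ceil(spec.density_active * (n - 1))) + 2)
    order = list(rng.permutation(n))
    hubs = order[: spec.n_hubs]
    others = order[spec.n_hubs:]

    # The clique budget B and the hub-shortcut edge count are coupled (hub
    # edges attach to whole modules, whose sizes depend on B), so scan B
    # downward and take the largest total not exceeding the target; any
    # residue is absorbed with extra small modules among leftover taxa.
    # Each hub bridges a DISJOINT pair of modules — sharing a module
    # between hubs would push the planted correlation off the positive-
    # definite cone.
    def _act_layout(budget: int):
        cl = _greedy_cliques(others, budget, cap)
        n_eff = min(spec.n_hubs, len(cl) // 2)
        pairs = sorted(
            (min(hubs[i], m), max(hubs[i], m))
            for i in range(n_eff)
            for ci in (2 * i, 2 * i + 1)
            for m in cl[ci]
        )
        spent = sum(len(c) * (len(c) - 1) // 2 for c in cl)
        return cl, pairs, spent + len(pairs)

    chosen = None
    for budget in range(e_act, 0, -1):
        cl, pairs, total = _act_layout(budget)
        if not pairs:
            continue
        if total <= e_act:
            used = set(hubs) | {v for c in cl for v in c}
            leftovers = [v for v in order if v not in used]
            extra = _greedy_cliques(leftovers, e_act - total, cap)
            total += sum(len(c) * (len(c) - 1) // 2 for c in extra)
            if abs(total - e_act) <= 1:
                chosen = (cl + extra, pairs, total)
                break
    if chosen is None:
        raise ValueError(
            f"cannot realize active density {spec.density_active} with "
            f"{n} taxa and {spec.n_hubs} hub(s); adjust densities or sizes"
        )
    cliques, hub_pairs, realized = chosen
    hubs = [h for h in hubs if any(h in p for p in hub_pairs)]

    adj_act = np.zeros((n, n), dtype=np.int8)
    for c in cliques:
        idx = np.array(c)
        adj_act[np.ix_(idx, idx)] = 1
    for a, b in hub_pairs:
        adj_act[a, b] = adj_act[b, a] = 1
    np.fill_diagonal(adj_act, 0)

    # sedentary: module-confined sub-cliques, no hubs, exact budget.
    # The active modules are reused first (so the two conditions differ
    # mainly by the hub shortcuts and module coverage); if they cannot
    # host the whole budget, extra modules are formed from unused taxa.
    adj_sed = np.zeros((n, n), dtype=np.int8)
    remaining = e_sed
    sed_used: set[int] = set()
    for c in cliques:
        if remaining <= 0:
            break
        s = len(c)
        while s >= 2 and s * (s - 1) // 2 > remaining:
            s -= 1
        if s < 2:
            continue
        idx = np.array(c[:s])
        adj_sed[np.ix_(idx, idx)] = 1
        sed_used.update(c[:s])
        remaining -= s * (s - 1) // 2
    if remaining > 0:
        unused = [v for v in order if v not in sed_used and v not in hubs]
        for c in _greedy_cliques(unused, remaining, cap):
            idx = np.array(c)
            adj_sed[np.ix_(idx, idx)] = 1
            remaining -= len(c) * (len(c) - 1) // 2
    np.fill_diagonal(adj_sed, 0)
    if abs(int(adj_sed.sum() // 2) - e_sed) > 1:
        raise ValueError(
            f"sedentary density {spec.density_sedentary} exceeds the "
            f"module-confined capacity with {n} taxa"
        )

    return adj_act, adj_sed, hubs, cliques


def nearest_positive_definite(
    target: np.ndarray, floor: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipping repair of a target correlation matrix.

    Clips eigenvalues below ``floor``, restores the unit diagonal, and
    iterates until positive-definite.  Returns the repaired matrix and
    the repair delta (largest absolute entry change).
    """
    r = np.asarray(target, dtype=float).copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(r)
        if w.min() >= floor / 2:
            break
        w = np.clip(w, floor, None)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    delta = float(np.max(np.abs(r - target)))
    return r, delta


def _latent_correlation(
    adj_modules: np.ndarray,
    adj_hub: np.ndarray,
    module_rho: float,
    hub_rho: float,
) -> tuple[np.ndarray, float]:
    target = np.eye(adj_modules.shape[0])
    target += module_rho * adj_modules + hub_rho * adj_hub
    repaired, delta = nearest_positive_definite(target)
    if delta > 0.05:
        raise ValueError(
            f"planted correlation matrix not repairable to positive-definite "
            f"within delta 0.05 (delta={delta:.3f})"
        )
    return repaired, delta


def _zinb_counts(
    z: np.ndarray, mus: np.ndarray, theta: float, pi: float
) -> np.ndarray:
    """Map latent normals (samples x taxa) to zero-inflated NB counts."""
    u = sps.norm.cdf(z)
    counts = np.zeros_like(u)
    for j, mu in enumerate(mus):
        p = theta / (theta + mu)
        col = u[:, j]
        mask = col >= pi
        counts[mask, j] = sps.nbinom.ppf((col[mask] - pi) / (1.0 - pi), theta, p)
    return counts.astype(np.int64)


def generate_otu_table(spec: SyntheticSpec) -> tuple[OtuTable, GroundTruth]:
    """Draw one paired two-condition table with its ground truth.

    Same spec (including seed) always reproduces the identical table.
    """
    adj_act, adj_sed, hubs, cliques = planted_topology(spec)
    n = spec.n_taxa
    width = len(str(n))
    taxon_ids = [f"taxon_{i:0{width}d}" for i in range(n)]

    hub_mask = np.zeros((n, n), dtype=np.int8)
    for h in hubs:
        hub_mask[h, :] = adj_act[h, :]
        hub_mask[:, h] = adj_act[:, h]
    module_mask = adj_act * (1 - hub_mask)
    r_act, delta_act = _latent_correlation(
        module_mask, hub_mask * adj_act, spec.rho_active, spec.hub_rho
    )
    r_sed, delta_sed = _latent_correlation(
        adj_sed, np.zeros_like(adj_sed), spec.rho, spec.hub_rho
    )

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 202)))
    mus = rng.lognormal(spec.nb_mean_log_mu, spec.nb_mean_log_sigma, size=n)

    blocks = []
    sample_ids: list[str] = []
    condition: list[str] = []
    for label, r, n_samples in (
        (spec.labels[0], r_act, spec.n_active),
        (spec.labels[1], r_sed, spec.n_sedentary),
    ):
        chol = np.linalg.cholesky(r)
        z = rng.standard_normal((n_samples, n)) @ chol.T
        blocks.append(_zinb_counts(z, mus, spec.dispersion, spec.zero_inflation))
        sample_ids += [f"{label}_{k:03d}" for k in range(n_samples)]
        condition += [label] * n_samples
    counts = np.vstack(blocks).T  # taxa x samples

    table = OtuTable(
        counts=counts,
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        condition=condition,
    )
    truth = GroundTruth(
        taxon_ids=taxon_ids,
        adjacency={spec.labels[0]: adj_act, spec.labels[1]: adj_sed},
        latent_corr={spec.labels[0]: r_act, spec.labels[1]: r_sed},
        hubs=[taxon_ids[h] for h in hubs],
        modules=[[taxon_ids[v] for v in c] for c in cliques],
        repair_delta={spec.labels[0]: delta_act, spec.labels[1]: delta_sed},
    )
    return table, truth


def fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the standard on-disk test fixtures and their manifest.

    Produces a small hand-scale TSV/BIOM table pair, a paired
    active/sedentary dataset at the default cohort shape, ground-truth
    edge lists, and a JSON manifest; the same seed always writes
    byte-identical content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    small = SyntheticSpec(n_taxa=12, n_active=8, n_sedentary=6,
                          density_active=0.2, density_sedentary=0.1,
                          n_hubs=1, max_module=4, seed=seed)
    small_table, small_truth = generate_otu_table(small)
    write_otu_table_tsv(small_table, out / "small_table.tsv")
    write_otu_table_biom(small_table, out / "small_table.biom")

    full = SyntheticSpec(seed=seed)
    table, truth = generate_otu_table(full)
    write_otu_table_tsv(table, out / "paired_table.tsv")
    meta_lines = ["sample\tcondition"] + [
        f"{s}\t{c}" for s, c in zip(table.sample_ids, table.condition)
    ]
    (out / "paired_metadata.tsv").write_text("\n".join(meta_lines) + "\n")
    for label in full.labels:
        write_network(truth.network(label), out / f"truth_{label}.edge.tsv",
                      format="edge-tsv")

    manifest = {
        "seed": seed,
        "small": {
            "n_taxa": small.n_taxa,
            "hubs": small_truth.hubs,
            "edges": {
                lbl: int(a.sum() // 2) for lbl, a in small_truth.adjacency.items()
            },
        },
        "paired": {
            "n_taxa": full.n_taxa,
            "n_samples": [full.n_active, full.n_sedentary],
            "hubs": truth.hubs,
            "repair_delta": truth.repair_delta,
            "edges": {
                lbl: int(a.sum() // 2) for lbl, a in truth.adjacency.items()
            },
            "truth_files": [f"truth_{lbl}.edge.tsv" for lbl in full.labels],
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
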