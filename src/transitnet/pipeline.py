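"""End-to-end pipeline: table -> networks -> topology -> comparison ->
transition -> keystones, with one root seed and a machine-readable
manifest.

Every stage draws its randomness from a child of the root seed
(stage-indexed ``numpy.random.SeedSequence``), so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CooccurrenceNetwork, TopologyProfile
from .io import write_keystone_report, write_network
from .netbuild import (
    DEFAULT_MIN_PREVALENCE,
    DEFAULT_P_THRESHOLD,
    build_condition_network,
    filter_taxa,
)
from .stats import DEFAULT_ALPHA_GATE, INDEPENDENCE_CAVEAT, compare_profiles
from .surrogate import DEFAULT_N_SURROGATES, normalized_profile
from .topology import topology_profile
from .transition import (
    DEFAULT_KEYSTONE_FRACTION,
    TransitionConfig,
    run_transition_analysis,
)

# stage tags used to derive per-stage child seeds from the root seed
_STAGES = ("surrogates_a", "surrogates_b")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the published settings."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    min_prevalence: float = DEFAULT_MIN_PREVALENCE
    min_mean_count: float = 0.0
    normalize: bool = False
    n_surrogates: int = DEFAULT_N_SURROGATES
    fraction: float = DEFAULT_KEYSTONE_FRACTION
    transition_mode: str = "consistent"
    alpha_gate: float = DEFAULT_ALPHA_GATE
    seed: int = 0
    metrics: tuple[str, ...] = ("degree", "clustering", "flow_raw")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat JSON config file; keyword overrides win."""
        cfg = json.loads(Path(path).read_text())
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in cfg:
            cfg["metrics"] = tuple(cfg["metrics"])
        return cls(**cfg)


def _stage_seed(root: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence((root, idx)).generate_state(1)[0] % (2**31))


def profile_to_frames(
    profile: TopologyProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-node table, one-row global table) for a topology profile."""
    node = pd.DataFrame(
        {
            "taxon": profile.taxon_ids,
            "degree": profile.degree.astype(int),
            "clustering": profile.clustering,
            "flow_norm": profile.flow_norm,
            "flow_raw": profile.flow_raw,
        }
    )
    for key, val in profile.normalized.items():
        arr = np.asarray(val)
        if arr.ndim == 1:
            node[f"norm_{key}"] = arr
    glob = {
        "efficiency_global": [profile.efficiency_global],
        "char_path_length": [profile.char_path_length],
        "assortativity": [profile.assortativity],
    }
    for key, val in profile.normalized.items():
        arr = np.asarray(val)
        if arr.ndim == 0:
            glob[f"norm_{key}"] = [float(arr)]
    return node, pd.DataFrame(glob)


def profile_from_node_frame(df: pd.DataFrame):
    """Adapter: per-node TSV columns -> object usable by compare_profiles."""

    class _NodeProfile:
        pass

    p = _NodeProfile()
    for col in df.columns:
        if col != "taxon":
            setattr(p, col, df[col].to_numpy(dtype=float))
    p.taxon_ids = df["taxon"].tolist()
    return p


def run_pipeline(
    table,
    out_dir: str | Path,
    config: RunConfig | None = None,
    log=lambda msg: print(msg, file=sys.stderr),
) -> Path:
    """Run every stage on a loaded OtuTable and write the run directory.

    Outputs: one GraphML network, per-node and global topology TSVs per
    condition, a comparison TSV, transition keystone TSV, and
    ``manifest.json`` recording every parameter, seed and version.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label_a, label_b = table.condition_labels

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    log(f"filter: {table.n_taxa} taxa in")
    table = stage("filter", lambda: filter_taxa(
        table, config.min_prevalence, config.min_mean_count))
    log(f"filter: {table.n_taxa} taxa kept")

    nets: dict[str, CooccurrenceNetwork] = {}
    profiles = {}
    for i, label in enumerate((label_a, label_b)):
        net = stage(f"build[{label}]", lambda label=label: build_condition_network(
            table, label, config.p_threshold))
        nets[label] = net
        write_network(net, out / f"network_{label}.graphml")
        log(f"build[{label}]: {net.n_edges} edges over {net.n_nodes} taxa")
        if config.normalize:
            seed = _stage_seed(config.seed, _STAGES[i])
            prof = stage(f"topology[{label}]", lambda net=net, seed=seed:
                         normalized_profile(net, config.n_surrogates, seed))
        else:
            prof = stage(f"topology[{label}]", lambda net=net: topology_profile(net))
        profiles[label] = prof
        node_df, glob_df = profile_to_frames(prof)
        node_df.to_csv(out / f"topology_{label}.tsv", sep="\t", index=False)
        glob_df.to_csv(out / f"global_{label}.tsv", sep="\t", index=False)

    comps = stage("compare", lambda: compare_profiles(
        profiles[label_a], profiles[label_b], config.metrics, config.alpha_gate))
    comp_df = pd.DataFrame(
        [
            {
                "metric": c.metric,
                "H": c.h_statistic,
                "p": c.p_value,
                "critical_alpha": c.critical_alpha,
                "significant": c.significant,
                f"mean_{label_a}": c.group_means[0],
                f"mean_{label_b}": c.group_means[1],
            }
            for c in comps
        ]
    )
    with open(out / "comparison.tsv", "w") as fh:
        fh.write(f"# {INDEPENDENCE_CAVEAT}\n")
        comp_df.to_csv(fh, sep="\t", index=False)

    tcfg = TransitionConfig(mode=config.transition_mode, fraction=config.fraction)
    t_ab, t_ba, keys_ab, keys_ba = stage("transition", lambda: run_transition_analysis(
        nets[label_a], nets[label_b], tcfg))
    np.savetxt(out / f"transition_{label_a}_to_{label_b}.tsv", t_ab.matrix, delimiter="\t")
    np.savetxt(out / f"transition_{label_b}_to_{label_a}.tsv", t_ba.matrix, delimiter="\t")
    write_keystone_report([keys_ab, keys_ba], out / "keystones.tsv")
    log(f"transition: residuals {t_ab.residual:.2e} / {t_ba.residual:.2e}; "
        f"{keys_ab.n_selected}+{keys_ba.n_selected} keystones")

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "conditions": [label_a, label_b],
        "n_taxa": table.n_taxa,
        "n_samples": table.n_samples,
        "networks": {lbl: {"n_edges": nets[lbl].n_edges, "density": nets[lbl].density}
                     for lbl in nets},
        "transition": {
            "mode": t_ab.mode,
            "binarized_density": t_ab.binarized_density,
            "residual_ab": t_ab.residual,
            "residual_ba": t_ba.residual,
        },
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGES},
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
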