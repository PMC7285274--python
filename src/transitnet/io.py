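"""Readers and writers for abundance tables, networks and reports.

Abundance tables come in as tab-separated text (taxa as rows, first
column ``taxon_id``, optional trailing ``taxonomy`` column) or as BIOM
v1 (JSON) / v2 (HDF5) containers.  Networks go out as GraphML or a
4-column edge list (``source  target  rho  p``); both round-trip
exactly through :func:`read_network`.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .containers import CooccurrenceNetwork, KeystoneReport, OtuTable, TransitionNetwork

_TABLE_FORMATS = ("tsv", "biom")
_NETWORK_FORMATS = ("graphml", "edge-tsv")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Sample-to-condition mapping from a 2-column TSV (sample, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("metadata needs at least two columns: sample, condition")
    sample_col, cond_col = df.columns[0], df.columns[1]
    return dict(zip(df[sample_col], df[cond_col]))


def read_otu_table(
    path: str | Path,
    format: str = "tsv",
    metadata_path: str | Path | None = None,
    metadata: dict[str, str] | None = None,
) -> OtuTable:
    """Read an abundance table plus its sample conditions.

    Parameters
    ----------
    path
        Table file (TSV or BIOM).
    format
        ``"tsv"`` or ``"biom"``; BIOM v1 (JSON) and v2 (HDF5) are
        auto-detected.
    metadata_path, metadata
        Sample-to-condition mapping, as a TSV path or an in-memory dict;
        exactly two condition labels must occur among the table's
        samples.  Every table sample must be mapped.
    """
    if format not in _TABLE_FORMATS:
        raise ValueError(f"unknown table format {format!r}; use one of {_TABLE_FORMATS}")
    if metadata is None:
        if metadata_path is None:
            raise ValueError("a metadata mapping (path or dict) is required")
        metadata = read_metadata(metadata_path)

    if format == "tsv":
        counts, taxon_ids, sample_ids, taxonomy = _read_table_tsv(path)
    else:
        counts, taxon_ids, sample_ids, taxonomy = _read_table_biom(path)

    missing = [s for s in sample_ids if s not in metadata]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    condition = [metadata[s] for s in sample_ids]
    return OtuTable(
        counts=counts,
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        condition=condition,
        taxonomy=taxonomy,
    )


def _read_table_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "taxon_id":
        raise ValueError("first TSV column must be 'taxon_id'")
    taxonomy = None
    if df.columns[-1] == "taxonomy":
        taxonomy = df["taxonomy"].tolist()
        df = df.drop(columns=["taxonomy"])
    taxon_ids = df["taxon_id"].tolist()
    sample_ids = list(df.columns[1:])
    raw = df[sample_ids].to_numpy()
    try:
        counts = raw.astype(np.int64)
    except ValueError as exc:
        raise ValueError("counts must be integers") from exc
    return counts, taxon_ids, sample_ids, taxonomy


def _read_table_biom(path):
    path = Path(path)
    if h5py.is_hdf5(path):
        return _read_biom_v2(path)
    return _read_biom_v1(path)


def _read_biom_v1(path):
    with open(path) as fh:
        doc = json.load(fh)
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    taxonomy = None
    if any(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        taxonomy = [
            _join_lineage((r.get("metadata") or {}).get("taxonomy"))
            for r in doc["rows"]
        ]
    n, m = len(taxon_ids), len(sample_ids)
    counts = np.zeros((n, m))
    if doc.get("matrix_type") == "dense":
        counts = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    return _as_int_counts(counts), taxon_ids, sample_ids, taxonomy


def _read_biom_v2(path):
    with h5py.File(path, "r") as fh:
        taxon_ids = [x.decode() for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() for x in fh["sample/ids"][:]]
        # CSR over observations
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
        taxonomy = None
        if "observation/metadata/taxonomy" in fh:
            tax = fh["observation/metadata/taxonomy"][:]
            taxonomy = [
                _join_lineage([t.decode() if isinstance(t, bytes) else t for t in row])
                for row in tax
            ]
    n, m = len(taxon_ids), len(sample_ids)
    counts = np.zeros((n, m))
    for i in range(n):
        sl = slice(indptr[i], indptr[i + 1])
        counts[i, indices[sl]] = data[sl]
    return _as_int_counts(counts), taxon_ids, sample_ids, taxonomy


def _join_lineage(lineage) -> str:
    if lineage is None:
        return ""
    if isinstance(lineage, str):
        return lineage
    return "; ".join(str(x) for x in lineage if str(x))


def _as_int_counts(counts: np.ndarray) -> np.ndarray:
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("counts must be integers")
    return counts.astype(np.int64)


def write_otu_table_tsv(table: OtuTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, columns=table.sample_ids)
    df.insert(0, "taxon_id", table.taxon_ids)
    if table.taxonomy is not None:
        df["taxonomy"] = table.taxonomy
    df.to_csv(path, sep="\t", index=False)


def write_otu_table_biom(table: OtuTable, path: str | Path) -> None:
    """Write a minimal BIOM v1 (JSON, sparse) table."""
    rows = []
    for i, tid in enumerate(table.taxon_ids):
        md = None
        if table.taxonomy is not None:
            md = {"taxonomy": table.taxonomy[i]}
        rows.append({"id": tid, "metadata": md})
    data = [
        [int(i), int(j), int(table.counts[i, j])]
        for i, j in zip(*np.nonzero(table.counts))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "transitnet",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_network(
    net: CooccurrenceNetwork | TransitionNetwork,
    path: str | Path,
    format: str = "graphml",
    taxonomy: dict[str, str] | None = None,
) -> None:
    """Serialize a network; transition networks write their binarized view.

    GraphML carries rho/p/weight edge attributes and optional taxonomy
    node attributes; ``edge-tsv`` writes ``source  target  rho  p``.
    """
    if format not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {_NETWORK_FORMATS}")
    if isinstance(net, TransitionNetwork):
        if net.binarized is None:
            raise ValueError("transition network has no binarized view to serialize")
        net = net.binarized
    g = net.to_networkx()
    if taxonomy:
        nx.set_node_attributes(g, taxonomy, name="taxonomy")
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        lines = ["source\ttarget\trho\tp"]
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f"{u}\t{v}\t{d['rho']!r}\t{d['p']!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path, format: str = "graphml") -> CooccurrenceNetwork:
    """Inverse of :func:`write_network` for co-occurrence networks.

    Note: edge-TSV keeps only nodes incident to at least one edge;
    GraphML preserves isolated nodes too.
    """
    if format not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {_NETWORK_FORMATS}")
    if format == "graphml":
        g = nx.read_graphml(path)
        return CooccurrenceNetwork.from_networkx(g)
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, rho=float(row.rho), p=float(row.p))
    return CooccurrenceNetwork.from_networkx(g)


def write_keystone_report(reports: list[KeystoneReport], path: str | Path) -> None:
    rows = []
    for rep in reports:
        for rank, (taxon, fr, fn) in enumerate(
            zip(rep.taxa, rep.flow_raw, rep.flow_norm), start=1
        ):
            rows.append(
                {
                    "rank": rank,
                    "taxon": taxon,
                    "flow_raw": fr,
                    "flow_norm": fn,
                    "direction": rep.direction,
                }
            )
    pd.DataFrame(rows, columns=["rank", "taxon", "flow_raw", "flow_norm", "direction"]).to_csv(
        path, sep="\t", index=False
    )
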