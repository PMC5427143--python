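"""Tabular file formats and the canonical cortical region table.

All tables are tab-separated UTF-8 text with '.' decimals; nested
reports are JSON.  The packaged region table carries the 116 automated
anatomical labelling (AAL) parcels; dropping the 26 cerebellar and 10
subcortical parcels (EEG source localization is unreliable at depth and
in the cerebellum) leaves the 80 cortical regions of interest whose row
order is the canonical ROI order everywhere in the package.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BinaryNetwork, ConnectivityMatrix, PowerSeriesMatrix

__all__ = [
    "load_region_table",
    "filter_cortical",
    "canonical_roi_labels",
    "read_power_matrix",
    "write_power_matrix",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_edge_list",
    "write_edge_list",
]

_REGION_COLUMNS = ["name", "abbreviation", "hemisphere", "lobe", "group"]


def _packaged_region_path():
    return importlib.resources.files("nbacknet.data") / "aal_regions.tsv"


def filter_cortical(table: pd.DataFrame) -> pd.DataFrame:
    """Drop cerebellar and subcortical rows from a full AAL table."""
    out = table[table["group"] == "cortical"].reset_index(drop=True)
    return out


def _validate_cortical(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) != 80:
        raise ValueError(f"expected 80 cortical regions, got {len(table)}")
    if table["abbreviation"].duplicated().any():
        dup = table["abbreviation"][table["abbreviation"].duplicated()]
        raise ValueError(f"duplicate region abbreviations: {sorted(set(dup))}")
    counts = table["hemisphere"].value_counts()
    if counts.get("L", 0) != counts.get("R", 0):
        raise ValueError("left/right region counts differ")
    return table


def load_region_table(path: str | Path | None = None,
                      full: bool = False) -> pd.DataFrame:
    """The region-of-interest table; packaged AAL fixture by default.

    A 116-row table is filtered by the exclusion rule (drop cerebellar
    and subcortical parcels); the resulting 80 cortical rows are
    validated (unique abbreviations, balanced hemispheres).  With
    ``full=True`` the unfiltered table is returned.
    """
    if path is None:
        with importlib.resources.as_file(_packaged_region_path()) as f:
            table = pd.read_csv(f, sep="\t", dtype=str)
    else:
        table = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in _REGION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"region table is missing columns: {missing}")
    if full:
        return table
    if (table["group"] != "cortical").any():
        table = filter_cortical(table)
    return _validate_cortical(table)


def canonical_roi_labels() -> list[str]:
    return list(load_region_table()["abbreviation"])


def write_power_matrix(psm: PowerSeriesMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        psm.values,
        index=pd.Index(psm.roi_labels, name="roi"),
        columns=[f"trial_{j + 1}" for j in range(psm.n_trials)],
    )
    frame.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_power_matrix(
    path: str | Path,
    roi_labels: list[str] | None = None,
    **meta: str,
) -> PowerSeriesMatrix:
    """Read an ROI x trial power table.

    The first column must hold ROI labels.  When ``roi_labels`` is not
    given and the file has 80 rows, labels and their order are validated
    against the canonical cortical table; any other row count requires
    explicit labels (or is accepted as-is for synthetic ROI sets named
    ``R###``).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    values = frame.to_numpy()
    if frame.isna().any().any():
        rows, cols = np.nonzero(frame.isna().to_numpy())
        cell = (frame.index[rows[0]], frame.columns[cols[0]])
        raise ValueError(f"missing value at {cell} in {path}")
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in {path}")
    if np.any(values <= 0):
        rows, cols = np.nonzero(values <= 0)
        cell = (frame.index[rows[0]], frame.columns[cols[0]])
        raise ValueError(f"non-positive power at {cell} in {path}")
    labels = list(frame.index)
    if roi_labels is not None:
        if labels != list(roi_labels):
            raise ValueError(f"ROI labels in {path} do not match expectation")
    elif len(labels) == 80:
        canonical = canonical_roi_labels()
        if labels != canonical:
            unknown = sorted(set(labels) - set(canonical))
            raise ValueError(
                f"ROI labels in {path} do not match the canonical cortical "
                f"table (first offenders: {unknown[:5]})"
            )
    elif not all(lab.startswith("R") for lab in labels):
        raise ValueError(
            f"{path} has {len(labels)} ROI rows; expected the 80 canonical "
            "cortical regions (or pass roi_labels explicitly)"
        )
    return PowerSeriesMatrix(values, labels, **meta)


def write_connectivity_matrix(cm: ConnectivityMatrix,
                              path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(cm.weights,
                         index=pd.Index(cm.roi_labels, name="roi"),
                         columns=cm.roi_labels)
    frame.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_connectivity_matrix(path: str | Path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"row/column labels differ in {path}")
    return ConnectivityMatrix(frame.to_numpy(), list(frame.index))


def write_edge_list(net: BinaryNetwork, path: str | Path,
                    ranking: str | None = None) -> Path:
    """Two-column TSV of edges plus a JSON sidecar with provenance."""
    path = Path(path)
    labels = net.roi_labels or [f"R{i + 1:03d}" for i in range(net.n_nodes)]
    edges = net.edge_list()
    with path.open("w") as f:
        f.write("source\ttarget\n")
        for i, j in edges:
            f.write(f"{labels[i]}\t{labels[j]}\n")
    sidecar = {
        "n_nodes": net.n_nodes,
        "n_edges": int(len(edges)),
        "sparsity": None if np.isnan(net.sparsity) else net.sparsity,
        "ranking": ranking,
        "tie_break": "equal weights resolved by ascending (row, col) index",
        "nodes": labels,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def read_edge_list(path: str | Path,
                   n_nodes: int | None = None) -> BinaryNetwork:
    """Edge-list TSV back to a binary network.

    Node identity comes from the JSON sidecar if present, otherwise from
    the labels in the file (with ``n_nodes`` allowing isolated nodes).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["source", "target"]:
        raise ValueError(f"{path} must have 'source' and 'target' columns")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sparsity = float("nan")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        labels = list(sidecar["nodes"])
        if sidecar.get("sparsity") is not None:
            sparsity = float(sidecar["sparsity"])
    else:
        labels = sorted(set(frame["source"]) | set(frame["target"]))
        if n_nodes is not None and n_nodes > len(labels):
            labels += [f"isolated_{k}" for k in range(n_nodes - len(labels))]
    index = {lab: k for k, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=np.uint8)
    for _, row in frame.iterrows():
        try:
            i, j = index[row["source"]], index[row["target"]]
        except KeyError as err:
            raise ValueError(f"unknown node {err} in {path}") from None
        if i == j:
            raise ValueError(f"self-loop on {row['source']} in {path}")
        adj[i, j] = 1
        adj[j, i] = 1
    return BinaryNetwork(adj, sparsity=sparsity, roi_labels=labels)
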