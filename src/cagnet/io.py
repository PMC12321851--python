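"""Readers and writers for abundance tables, metadata and results.

Canonical table orientation is samples in rows, features in columns, first
column holding the sample id. Files are tab-separated UTF-8; lines starting
with '#' are ignored except a leading '#OTU ID'-style header, which marks a
features-in-rows layout and triggers transposition.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_abundance",
    "read_metadata",
    "write_table",
    "write_edges",
    "write_graphml",
    "write_json",
]

# First-column headers signalling that features, not samples, occupy rows.
_FEATURE_HEADERS = {"#otu id", "otu id", "feature_id", "feature", "pathway",
                    "genus", "taxon", "#pathway"}
_SAMPLE_HEADERS = {"sample_id", "sample", "#sampleid", "sampleid"}


def _read_tsv(path) -> pd.DataFrame:
    # '#' lines are comments, except a '#OTU ID'-style tabbed header line.
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    keep: list[str] = []
    for ln in lines:
        if ln.startswith("#") and (keep or "\t" not in ln):
            continue
        keep.append(ln)
    from io import StringIO
    return pd.read_csv(StringIO("\n".join(keep)), sep="\t")


def read_abundance(
    path,
    orientation: str = "auto",
    counts: bool = False,
) -> pd.DataFrame:
    """Read a TSV abundance table into canonical samples x features form.

    ``orientation`` is 'samples_rows', 'features_rows', or 'auto' (decide
    from the first-column header, falling back to samples-in-rows).
    ``counts=True`` closes each sample to relative abundances summing to 1.
    Duplicate ids and negative values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_tsv(path)
    first = str(df.columns[0])
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"

    if orientation == "auto":
        key = first.strip().lower()
        if key in _FEATURE_HEADERS:
            orientation = "features_rows"
        elif key in _SAMPLE_HEADERS:
            orientation = "samples_rows"
        else:
            orientation = "samples_rows"
    if orientation == "features_rows":
        df = df.T
        df.index.name = "sample_id"
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()[:3]
        raise ValueError(f"duplicate sample ids: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()[:3]
        raise ValueError(f"duplicate feature ids: {dup}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric abundance value in {path}: {e}") from None
    neg = np.argwhere(df.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative value at sample {df.index[i]!r}, feature {df.columns[j]!r}")
    if counts:
        totals = df.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cannot close samples with zero total counts")
        df = df.div(totals, axis=0)
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (first column = sample id)."""
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


def write_table(df: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def write_edges(edges: pd.DataFrame, path) -> None:
    write_table(edges.reset_index(drop=True), path, index_label="edge")


def write_graphml(graph: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
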