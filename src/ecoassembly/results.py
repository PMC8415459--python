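"""Serialization of analysis results.

Tables go to TSV, summary objects to JSON, networks to edge-list TSV or
GraphML.  Readers are provided so every writer round-trips (exactly for
integers and strings, within float tolerance otherwise).
"""

from __future__ import annotations

import dataclasses
import json

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "write_results",
    "read_table_tsv",
    "read_json",
    "read_edge_list",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(obj.columns), "index": list(obj.index),
                "data": _jsonable(obj.to_numpy().tolist())}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(obj, path, format: str | None = None) -> None:
    """Write a result object to disk.

    ``format`` is inferred from the object when omitted: DataFrames ->
    tsv, graphs -> graphml, everything else -> json.  Supported formats:
    ``tsv``, ``json``, ``graphml``, ``edge-list``.
    """
    if format is None:
        if isinstance(obj, pd.DataFrame):
            format = "tsv"
        elif isinstance(obj, nx.Graph):
            format = "graphml"
        else:
            format = "json"
    if format == "tsv":
        if isinstance(obj, pd.Series):
            obj = obj.to_frame()
        if not isinstance(obj, pd.DataFrame):
            raise ValueError("tsv output requires a DataFrame")
        obj.to_csv(path, sep="\t")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=2, default=str)
    elif format == "graphml":
        if not isinstance(obj, nx.Graph):
            raise ValueError("graphml output requires a networkx graph")
        nx.write_graphml(obj, path)
    elif format == "edge-list":
        if not isinstance(obj, nx.Graph):
            raise ValueError("edge-list output requires a networkx graph")
        rows = [
            {"taxon_a": u, "taxon_b": v, **{k: d.get(k) for k in ("sign", "rho", "weight")}}
            for u, v, d in obj.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_table_tsv(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        attrs = {k: row[k] for k in ("sign", "rho", "weight") if k in row and pd.notna(row[k])}
        g.add_edge(row["taxon_a"], row["taxon_b"], **attrs)
    return g
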