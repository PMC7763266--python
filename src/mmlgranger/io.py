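"""Panel and graph readers/writers and run provenance records.

Panels travel as comma-separated UTF-8 text, one column per series, with a
mandatory header row of series names.  A sidecar YAML/JSON config maps
every series name to its family label (and optionally a dispersion
override).  Graphs are written both as an adjacency CSV and as an edge
list (cause, effect, row_score).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import TimeSeriesPanel
from .search import CausalGraph


def read_families(path: str | Path) -> dict:
    """Read the series-name -> family-label map (YAML or JSON)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"families file {path} must map series names to labels")
    out = {}
    for name, val in cfg.items():
        out[str(name)] = val["family"] if isinstance(val, dict) else str(val)
    return out


def read_panel(path: str | Path, families_path: str | Path, *,
               transpose: bool = False) -> TimeSeriesPanel:
    """Load a delimited-text panel plus its families config into a panel.

    Raises a clear error naming the offending series on family-domain
    violations (e.g. a non-integer value in a poisson column).
    """
    df = pd.read_csv(path)
    if transpose:
        df = df.T
        df.columns = [str(c) for c in df.columns]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in series {bad}")
    fam_map = read_families(families_path)
    missing = [c for c in df.columns if c not in fam_map]
    if missing:
        raise ValueError(f"families file lacks labels for series {missing}")
    names = [str(c) for c in df.columns]
    families = [fam_map[c] for c in names]
    return TimeSeriesPanel(df.to_numpy().T, families, names)


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    pd.DataFrame(panel.values.T, columns=panel.names).to_csv(path, index=False)


def write_graph(graph: CausalGraph, path: str | Path) -> None:
    """Write adjacency CSV at ``path`` and an edge list alongside it."""
    path = Path(path)
    adj = pd.DataFrame(graph.adjacency.astype(int), columns=graph.names,
                       index=graph.names)
    adj.to_csv(path, index_label="series")
    edges = [{"cause": graph.names[j], "effect": graph.names[i],
              "row_score": graph.scores[i]}
             for i in range(graph.p) for j in range(graph.p)
             if graph.adjacency[i, j]]
    edge_path = path.with_name(path.stem + "_edges" + path.suffix)
    pd.DataFrame(edges, columns=["cause", "effect", "row_score"]).to_csv(
        edge_path, index=False)


def read_graph(path: str | Path) -> CausalGraph:
    df = pd.read_csv(path, index_col=0)
    return CausalGraph(df.to_numpy().astype(bool), names=[str(c) for c in df.columns])


def write_provenance(path: str | Path, config: dict) -> None:
    """Machine-readable record of a run (config, seed, package version)."""
    from . import __version__

    record = {"package": "mmlgranger", "version": __version__, "config": config}
    Path(path).write_text(json.dumps(record, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
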