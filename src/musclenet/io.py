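"""Plain-text I/O: wide-CSV trials, JSON events, network tables.

Formats are deliberately diff-able: trials are ``time_s`` plus one column
per muscle (mV), events and metadata live in a JSON sidecar, networks are
written both as a labeled square adjacency CSV and as an edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EmgTrial, PcorNetwork, ProcessedTrial

__all__ = [
    "write_trial",
    "read_trial",
    "write_processed",
    "read_processed",
    "write_network",
    "read_network",
    "adjacency_to_edgelist",
    "edgelist_to_adjacency",
]


class SchemaError(ValueError):
    """A file does not conform to the documented on-disk schema."""


def _trial_stem(trial: EmgTrial | ProcessedTrial) -> str:
    return f"{trial.subject}_{trial.condition}_{trial.trial:02d}"


def write_trial(trial: EmgTrial, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one trial as ``<stem>.csv`` (wide) plus ``<stem>.events.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _trial_stem(trial)
    csv_path = out_dir / f"{stem}.csv"
    events_path = out_dir / f"{stem}.events.json"
    t = np.arange(trial.n_samples) / trial.fs
    df = pd.DataFrame(trial.samples, columns=list(trial.channel_labels))
    df.insert(0, "time_s", t)
    df.to_csv(csv_path, index=False, float_format="%.17g")
    events = {
        "subject": trial.subject,
        "condition": trial.condition,
        "trial": trial.trial,
        "fs": trial.fs,
        "onset_sample": int(trial.onset_sample),
        "offset_sample": int(trial.offset_sample),
    }
    events_path.write_text(json.dumps(events, indent=1))
    return csv_path, events_path


def read_trial(csv_path: str | Path, events_path: str | Path) -> EmgTrial:
    csv_path, events_path = Path(csv_path), Path(events_path)
    if not events_path.exists():
        raise SchemaError(f"missing event file for trial: {events_path}")
    df = pd.read_csv(csv_path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{csv_path}: first column must be 'time_s'")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based incl. header
        raise SchemaError(f"{csv_path}: non-monotone time column at row {row}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2
        raise SchemaError(f"{csv_path}: NaN cell at row {row}")
    events = json.loads(events_path.read_text())
    labels = tuple(c for c in df.columns if c != "time_s")
    return EmgTrial(
        subject=str(events["subject"]),
        condition=str(events["condition"]),
        trial=int(events["trial"]),
        fs=float(events["fs"]),
        channel_labels=labels,
        samples=df[list(labels)].to_numpy(),
        onset_sample=int(events["onset_sample"]),
        offset_sample=int(events["offset_sample"]),
    )


def write_processed(trial: ProcessedTrial, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _trial_stem(trial)
    csv_path = out_dir / f"{stem}.envelope.csv"
    meta_path = out_dir / f"{stem}.provenance.json"
    pd.DataFrame(trial.envelope, columns=list(trial.channel_labels)).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    meta_path.write_text(
        json.dumps(
            {
                "subject": trial.subject,
                "condition": trial.condition,
                "trial": trial.trial,
                "provenance": trial.provenance,
            },
            indent=1,
        )
    )
    return csv_path, meta_path


def read_processed(csv_path: str | Path, meta_path: str | Path) -> ProcessedTrial:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    return ProcessedTrial(
        subject=str(meta["subject"]),
        condition=str(meta["condition"]),
        trial=int(meta["trial"]),
        channel_labels=tuple(df.columns),
        envelope=df.to_numpy(),
        provenance=meta.get("provenance", []),
    )


def adjacency_to_edgelist(adj: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangular non-zero entries as (node_i, node_j, weight) rows."""
    labels = list(adj.columns)
    rows = []
    W = adj.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if W[i, j] != 0.0:
                rows.append(
                    {"node_i": labels[i], "node_j": labels[j], "weight": W[i, j]}
                )
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def edgelist_to_adjacency(edges: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    W = np.zeros((len(labels), len(labels)))
    pos = {lab: i for i, lab in enumerate(labels)}
    for _, row in edges.iterrows():
        for node in (row["node_i"], row["node_j"]):
            if node not in pos:
                raise SchemaError(
                    f"unknown node label {node!r}; expected one of {labels}"
                )
        i, j = pos[row["node_i"]], pos[row["node_j"]]
        W[i, j] = W[j, i] = row["weight"]
    return pd.DataFrame(W, index=labels, columns=labels)


def write_network(net: PcorNetwork, out_dir: str | Path, name: str = "network") -> dict:
    """Adjacency CSV + edge-list CSV + model-selection metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adj = net.to_frame()
    adj_path = out_dir / f"{name}.adjacency.csv"
    adj.to_csv(adj_path, float_format="%.17g")
    edge_path = out_dir / f"{name}.edges.csv"
    adjacency_to_edgelist(adj).to_csv(edge_path, index=False, float_format="%.17g")
    meta = {
        "channel_labels": list(net.channel_labels),
        "rho_selected": net.rho_selected,
        "ebic": net.ebic,
        "gamma": net.gamma,
        "n_obs": net.n_obs,
        "nonzero_edges": net.nonzero_edges,
        "possible_edges": net.possible_edges,
        "precision": net.precision.tolist(),
    }
    meta_path = out_dir / f"{name}.meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"adjacency": adj_path, "edges": edge_path, "meta": meta_path}


def read_network(out_dir: str | Path, name: str = "network") -> PcorNetwork:
    out_dir = Path(out_dir)
    adj = pd.read_csv(out_dir / f"{name}.adjacency.csv", index_col=0)
    meta = json.loads((out_dir / f"{name}.meta.json").read_text())
    return PcorNetwork(
        channel_labels=tuple(meta["channel_labels"]),
        weights=adj.to_numpy(),
        precision=np.asarray(meta["precision"]),
        rho_selected=meta["rho_selected"],
        ebic=meta["ebic"],
        gamma=meta["gamma"],
        n_obs=meta["n_obs"],
    )
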