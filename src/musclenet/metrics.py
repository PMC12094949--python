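"""Centrality of the weighted signed muscle network.

Edges are partial correlations; path-based measures (betweenness,
closeness) run on distances 1/|w| so that strong conditional dependencies
are short hops, the convention of psychometric network tooling.  Degree and
betweenness are normalized to [0, 1]; strength sums |w| by default with the
literal signed sum available as an option.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .types import PcorNetwork

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "strength",
    "centrality_table",
]


def _weights_of(net) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(net, PcorNetwork):
        return net.weights, net.channel_labels
    W = np.asarray(net, dtype=float)
    return W, tuple(f"V{i + 1}" for i in range(W.shape[0]))


def _graph(W: np.ndarray) -> nx.Graph:
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] != 0.0:
                G.add_edge(i, j, weight=W[i, j], distance=1.0 / abs(W[i, j]))
    return G


def degree_centrality(net) -> np.ndarray:
    """Fraction of possible neighbors connected: k_u / (n - 1)."""
    W, _ = _weights_of(net)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k = np.count_nonzero(W, axis=1)
    return k / (n - 1)


def betweenness_centrality(net) -> np.ndarray:
    """Share of weighted shortest paths through each node, in [0, 1].

    Distances are 1/|w|; all shortest paths are counted when several tie.
    Normalization is by (n-1)(n-2)/2 pairs; disconnected pairs contribute 0.
    """
    W, _ = _weights_of(net)
    n = W.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    bc = nx.betweenness_centrality(_graph(W), weight="distance", normalized=True)
    return np.array([bc[i] for i in range(n)])


def closeness_centrality(net) -> np.ndarray:
    """Inverse mean 1/|w| distance to the other nodes.

    For disconnected graphs each node is scored within its component and
    scaled by (component size - 1)/(n - 1) (Wasserman-Faust correction);
    isolated nodes get 0.
    """
    W, _ = _weights_of(net)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    cc = nx.closeness_centrality(_graph(W), distance="distance", wf_improved=True)
    return np.array([cc[i] for i in range(n)])


def strength(net, signed: bool = False) -> np.ndarray:
    """Sum of incident edge weights: sum_v |w_uv| (or the signed sum)."""
    W, _ = _weights_of(net)
    return W.sum(axis=1) if signed else np.abs(W).sum(axis=1)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd <= 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def centrality_table(net, signed_strength: bool = False) -> pd.DataFrame:
    """Degree, betweenness, closeness, strength plus per-measure z-scores.

    z-columns standardize each measure across the nodes (sample SD); a
    measure with zero variance gets an all-zero z-column and is listed in
    ``df.attrs['degenerate']``.
    """
    W, labels = _weights_of(net)
    measures = {
        "degree": degree_centrality(W),
        "betweenness": betweenness_centrality(W),
        "closeness": closeness_centrality(W),
        "strength": strength(W, signed=signed_strength),
    }
    df = pd.DataFrame(measures, index=list(labels))
    degenerate = []
    for name in list(measures):
        z, flat = _zscore(df[name].to_numpy())
        df[f"z_{name}"] = z
        if flat:
            degenerate.append(name)
    df.attrs["degenerate"] = degenerate
    return df
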