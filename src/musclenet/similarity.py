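"""DeltaCon similarity between muscle networks.

Each network is summarized by its node-affinity matrix
S = (I + eps^2 D - eps A)^(-1) (exact fast-belief-propagation smoothing;
at 8 nodes the exact inverse is cheap).  Two networks on the same node set
are compared by the rootED (Matusita) distance between affinities,

    d = sqrt( sum_ij (sqrt(s1_ij) - sqrt(s2_ij))^2 ),   sim = 1 / (1 + d),

so identical networks score exactly 1.  Signed partial-correlation edges
enter through their absolute values, as DeltaCon is defined for
non-negative adjacency.
"""

from __future__ import annotations

import numpy as np

from .types import PcorNetwork, SimilarityResult

__all__ = ["deltacon_affinity", "deltacon_similarity", "paired_difference"]


def _adjacency_of(net) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(net, PcorNetwork):
        return np.abs(net.weights), net.channel_labels
    A = np.abs(np.asarray(net, dtype=float))
    return A, None


def deltacon_affinity(adjacency: np.ndarray, epsilon: float | None = None) -> np.ndarray:
    """Node-affinity matrix S = (I + eps^2 D - eps A)^(-1).

    D is the diagonal (weighted) degree matrix; ``epsilon`` defaults to
    1 / (1 + max degree), which makes the system matrix a diagonally
    dominant M-matrix, hence invertible with non-negative inverse.
    """
    A = np.abs(np.asarray(adjacency, dtype=float))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise ValueError("adjacency must have a zero diagonal")
    deg = A.sum(axis=1)
    if epsilon is None:
        epsilon = 1.0 / (1.0 + float(deg.max()))
    n = A.shape[0]
    M = np.eye(n) + epsilon**2 * np.diag(deg) - epsilon * A
    S = np.linalg.inv(M)
    return 0.5 * (S + S.T)


def deltacon_similarity(net1, net2, epsilon: float | None = None) -> SimilarityResult:
    """DeltaCon similarity of two networks on the same ordered node set.

    Both affinities are computed with a shared propagation constant
    (1 / (1 + max degree over both graphs) unless given), then compared by
    the rootED distance; similarity = 1 / (1 + distance) lies in (0, 1].
    """
    A1, labels1 = _adjacency_of(net1)
    A2, labels2 = _adjacency_of(net2)
    if A1.shape != A2.shape:
        raise ValueError(f"node-set size mismatch: {A1.shape[0]} vs {A2.shape[0]}")
    if labels1 is not None and labels2 is not None and labels1 != labels2:
        raise ValueError("networks must share the same node labels and order")
    if epsilon is None:
        max_deg = max(A1.sum(axis=1).max(), A2.sum(axis=1).max())
        epsilon = 1.0 / (1.0 + float(max_deg))
    S1 = np.clip(deltacon_affinity(A1, epsilon), 0.0, None)
    S2 = np.clip(deltacon_affinity(A2, epsilon), 0.0, None)
    d = float(np.sqrt(np.sum((np.sqrt(S1) - np.sqrt(S2)) ** 2)))
    name1 = getattr(net1, "name", "G1")
    name2 = getattr(net2, "name", "G2")
    return SimilarityResult(
        pair=(name1, name2),
        distance=d,
        similarity=1.0 / (1.0 + d),
        epsilon=float(epsilon),
    )


def paired_difference(sim_ab: SimilarityResult, sim_cd: SimilarityResult) -> float:
    """sim(A, B) - sim(C, D): the paired network-similarity contrast."""
    return sim_ab.similarity - sim_cd.similarity
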