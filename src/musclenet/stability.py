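"""Non-parametric bootstrap stability of the muscle network.

Rows of the spatial-weight observation matrix (subject-trials) are
resampled with replacement; every replicate is pushed through the full
EBIC-glasso selection, yielding percentile confidence intervals per edge
and pairwise bootstrap difference tests for edges and centralities.  The
significance level is tied to the replicate count by alpha = 2 / n_boot
(0.01 at the default 200 replicates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import derive_seed
from . import metrics as _metrics
from .network import GlassoNonConvergence, select_network
from .types import BootstrapSummary, PcorNetwork, WeightObservations

__all__ = [
    "bootstrap_networks",
    "edge_ci",
    "difference_test",
    "bootstrap_summary",
]

_MEASURES = ("degree", "betweenness", "closeness", "strength")


def default_alpha(n_boot: int) -> float:
    return 2.0 / n_boot


def bootstrap_networks(
    X: WeightObservations,
    n_boot: int = 200,
    gamma: float = 0.5,
    seed: int = 0,
    n_points: int = 100,
    ratio: float = 0.01,
    max_redraws: int = 10,
    max_iter: int = 120,
) -> tuple[list[PcorNetwork], int]:
    """Case-resampled replicate networks.

    Each replicate draws n rows with replacement and reruns
    :func:`musclenet.network.select_network`.  Resamples with a constant
    column are redrawn (at most ``max_redraws`` times); replicates where no
    model on the path converges are dropped and counted in the returned
    failure tally.
    """
    M = X.matrix
    n = M.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to bootstrap")
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    nets: list[PcorNetwork] = []
    n_failed = 0
    for b in range(n_boot):
        sample = None
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            cand = M[idx]
            if np.all(cand.std(axis=0) > 0):
                sample = cand
                break
        if sample is None:
            raise RuntimeError(
                f"replicate {b}: constant column persisted after {max_redraws} redraws"
            )
        rep = WeightObservations(
            condition=X.condition,
            synergy_index=X.synergy_index,
            matrix=sample,
            channel_labels=X.channel_labels,
        )
        try:
            nets.append(
                select_network(
                    rep, gamma=gamma, n_points=n_points, ratio=ratio,
                    max_iter=max_iter,
                )
            )
        except GlassoNonConvergence:
            n_failed += 1
    return nets, n_failed


def _edge_vectors(nets: list[PcorNetwork]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    labels = nets[0].channel_labels
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    vals = np.stack([net.weights[iu] for net in nets])
    return vals, pairs


def edge_ci(
    replicates: list[PcorNetwork],
    alpha: float,
    sample_net: PcorNetwork | None = None,
) -> pd.DataFrame:
    """Percentile confidence interval per edge, sorted by sample weight.

    Rows carry the sample estimate (when a sample network is given), the
    bootstrap mean and the [alpha/2, 1-alpha/2] percentile bounds; the
    table is ordered from the strongest sample edge downward.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    vals, pairs = _edge_vectors(replicates)
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    df = pd.DataFrame(
        {
            "node_i": [a for a, _ in pairs],
            "node_j": [b for _, b in pairs],
            "boot_mean": vals.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    if sample_net is not None:
        iu = np.triu_indices(len(sample_net.channel_labels), k=1)
        df.insert(2, "sample", sample_net.weights[iu])
        df = df.sort_values("sample", ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def difference_test(
    replicates: list[PcorNetwork],
    quantity: str = "edge",
    alpha: float = 0.01,
    signed_strength: bool = False,
) -> pd.DataFrame:
    """Pairwise bootstrap difference test.

    For every pair of edges (``quantity='edge'``) or of nodes (a centrality
    measure name), the bootstrap distribution of the difference is formed
    and the pair is flagged significant when its [alpha/2, 1-alpha/2]
    percentile interval excludes zero.  The returned boolean matrix is
    symmetric with a False diagonal.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if quantity == "edge":
        vals, pairs = _edge_vectors(replicates)
        names = [f"{a}--{b}" for a, b in pairs]
    elif quantity in _MEASURES:
        fn = {
            "degree": _metrics.degree_centrality,
            "betweenness": _metrics.betweenness_centrality,
            "closeness": _metrics.closeness_centrality,
            "strength": lambda w: _metrics.strength(w, signed=signed_strength),
        }[quantity]
        vals = np.stack([fn(net.weights) for net in replicates])
        names = list(replicates[0].channel_labels)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    m = vals.shape[1]
    sig = np.zeros((m, m), dtype=bool)
    for a in range(m):
        diff = vals[:, a, None] - vals  # replicates x m
        lo, hi = np.quantile(diff, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
        sig[a] = (lo > 0) | (hi < 0)
    sig &= sig.T  # |difference| is symmetric; enforce exactly
    np.fill_diagonal(sig, False)
    return pd.DataFrame(sig, index=names, columns=names)


def bootstrap_summary(
    X: WeightObservations,
    sample_net: PcorNetwork | None = None,
    n_boot: int = 200,
    gamma: float = 0.5,
    seed: int = 0,
    alpha: float | None = None,
    allow_alpha_override: bool = False,
    n_points: int = 100,
    ratio: float = 0.01,
    signed_strength: bool = False,
) -> BootstrapSummary:
    """Full stability report: edge CIs plus edge and centrality difference tests.

    ``alpha`` defaults to the 2 / n_boot rule; supplying a different value
    requires ``allow_alpha_override=True`` so the level cannot drift from
    the replicate count by accident.
    """
    rule = default_alpha(n_boot)
    if alpha is None:
        alpha = rule
    elif abs(alpha - rule) > 1e-12 and not allow_alpha_override:
        raise ValueError(
            f"alpha={alpha} deviates from 2/n_boot={rule}; "
            "pass allow_alpha_override=True to force it"
        )
    if sample_net is None:
        sample_net = select_network(X, gamma=gamma, n_points=n_points, ratio=ratio)
    nets, n_failed = bootstrap_networks(
        X, n_boot=n_boot, gamma=gamma, seed=seed, n_points=n_points, ratio=ratio
    )
    table = edge_ci(nets, alpha, sample_net=sample_net)
    edge_diff = difference_test(nets, "edge", alpha)
    cent = {
        m: difference_test(nets, m, alpha, signed_strength=signed_strength)
        for m in _MEASURES
    }
    return BootstrapSummary(
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
        edge_table=table,
        edge_diff=edge_diff,
        centrality_diff=cent,
        n_failed=n_failed,
    )
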