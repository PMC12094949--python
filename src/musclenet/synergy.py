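"""Muscle-synergy extraction and synergy-count selection.

The activation matrix M (muscles x time) is factorized as M ~ W C with
non-negative spatial weights W (muscles x k) and temporal activations C
(k x time) by multiplicative-update NMF.  The number of synergies is chosen
by the significant-difference criterion: the per-trial variance accounted
for (VAF) is computed for each candidate k, a Kruskal-Wallis test compares
the VAF distributions across k, and Dunn post-hoc comparisons against the
one-synergy column pick the smallest k whose VAF differs significantly
from k = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .config import derive_seed
from .types import ProcessedTrial, SynergyDecomposition, WeightObservations

__all__ = [
    "nmf",
    "compute_vaf",
    "vaf_curve",
    "kruskal_wallis",
    "dunn_posthoc",
    "select_synergy_count",
    "match_synergies",
    "build_weight_observations",
]

_EPS = 1.0e-12


def compute_vaf(M: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Variance accounted for: 1 - ||M - WC||_F^2 / ||M||_F^2."""
    M = np.asarray(M, dtype=float)
    denom = float(np.sum(M**2))
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    err = M - W @ C
    return 1.0 - float(np.sum(err**2)) / denom


def _mu_fit(
    M: np.ndarray,
    k: int,
    seed: int,
    n_restarts: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Multiplicative-update runs from random non-negative starts.

    Frobenius-error updates of Lee & Seung, with all restarts iterated in
    one batched 3-D array; the objective is non-increasing by construction
    and a restart counts as converged once its relative per-iteration
    decrease falls below ``tol``.  Returns the factors, objective history
    and convergence flag of the restart with the lowest final error.
    """
    m, t = M.shape
    rng = np.random.default_rng(derive_seed(seed, "nmf"))
    scale = np.sqrt(M.mean() / k) + _EPS
    W = scale * (0.5 + rng.uniform(size=(n_restarts, m, k)))
    C = scale * (0.5 + rng.uniform(size=(n_restarts, k, t)))
    Mb = M[None, :, :]
    resid = Mb - W @ C
    obj = [np.einsum("rmt,rmt->r", resid, resid)]
    active = np.ones(n_restarts, dtype=bool)
    for _ in range(max_iter):
        Wt = W.transpose(0, 2, 1)
        C *= (Wt @ Mb) / (Wt @ W @ C + _EPS)
        Ct = C.transpose(0, 2, 1)
        W *= (Mb @ Ct) / (W @ (C @ Ct) + _EPS)
        resid = Mb - W @ C
        f = np.einsum("rmt,rmt->r", resid, resid)
        obj.append(f)
        prev = obj[-2]
        active &= (prev - f) > tol * np.maximum(prev, _EPS)
        if not active.any():
            break
    history = np.stack(obj)  # iterations x restarts
    best = int(np.argmin(history[-1]))
    return W[best], C[best], history[:, best], not active[best]


def nmf(
    M: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1.0e-6,
) -> SynergyDecomposition:
    """Best-of-restarts multiplicative-update NMF of a non-negative matrix.

    The returned factors follow the convention that each temporal row of C
    has unit maximum, with the amplitude absorbed into W — this makes the
    spatial weights comparable across trials, which the network stage
    requires.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D (muscles x time)")
    if np.any(M < 0):
        raise ValueError("M must be non-negative")
    if not (1 <= k <= min(M.shape)):
        raise ValueError(f"k={k} invalid for matrix of shape {M.shape}")
    W, C, obj, conv = _mu_fit(M, k, seed, n_restarts, max_iter, tol)
    # fix the scale indeterminacy: C rows to unit max, amplitude into W
    row_max = C.max(axis=1)
    row_max[row_max <= 0] = 1.0
    W = W * row_max
    C = C / row_max[:, None]
    return SynergyDecomposition(
        W=W,
        C=C,
        k=k,
        vaf=compute_vaf(M, W, C),
        seed=seed,
        n_restarts=n_restarts,
        converged=conv,
        objective_history=obj,
    )


def vaf_curve(
    trials: Sequence[ProcessedTrial],
    k_range: Iterable[int] = range(1, 8),
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 600,
    tol: float = 1.0e-4,
) -> pd.DataFrame:
    """Per-trial VAF for each candidate synergy count.

    Rows are indexed by (subject, condition, trial); columns are k.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need at least two trials for a VAF table")
    ks = sorted(k_range)
    rows = {}
    for tr in trials:
        M = tr.envelope.T  # muscles x time
        rows[tr.key] = [
            nmf(
                M,
                k,
                seed=derive_seed(seed, "vaf", *tr.key, k),
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
            ).vaf
            for k in ks
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=ks)
    table.index = pd.MultiIndex.from_tuples(
        table.index, names=["subject", "condition", "trial"]
    )
    return table


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, chi-square reference.

    Identical data in every group yields H = 0 and p = 1 (no evidence of a
    difference) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    comparisons: Sequence[tuple[int, int]] | None = None,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Dunn's post-hoc z tests on the pooled ranks of a Kruskal-Wallis design.

    For groups i, j with pooled-rank means Rbar_i, Rbar_j,

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) over tie groups.  Two-sided p-values from the
    standard normal; optionally Holm-adjusted (``p_adjust='holm'``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    n_groups = len(groups)
    if comparisons is None:
        comparisons = [(i, j) for i in range(n_groups) for j in range(i + 1, n_groups)]
    for i, j in comparisons:
        if not (0 <= i < n_groups and 0 <= j < n_groups):
            raise ValueError(f"comparison ({i}, {j}) refers to an unknown group")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    rank_means = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(n_groups)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - (T / (12.0 * (N - 1)) if N > 1 else 0.0)
    rows = []
    for i, j in comparisons:
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rank_means[i] - rank_means[j]) / denom if denom > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if p_adjust is not None:
        out["p"] = multipletests(out["p"].to_numpy(), method=p_adjust)[1]
    return out


@dataclass
class SelectionReport:
    """Trace of the significant-difference synergy-count decision."""

    k_selected: int
    kw_H: float
    kw_p: float
    dunn: pd.DataFrame | None
    fallback: bool = False
    notes: list[str] = field(default_factory=list)


def select_synergy_count(
    vaf_table: pd.DataFrame, alpha: float = 0.05, p_adjust: str | None = None
) -> tuple[int, SelectionReport]:
    """Smallest k whose VAF differs significantly from the k = 1 column.

    A Kruskal-Wallis test screens the candidate-k columns; if it rejects,
    Dunn comparisons of every k > 1 against k = 1 are run and the smallest
    significant k wins.  Without any significant comparison the count falls
    back to 1 with a warning flag.
    """
    ks = list(vaf_table.columns)
    if len(ks) < 2:
        raise ValueError("need at least two candidate synergy counts")
    groups = [vaf_table[k].to_numpy(dtype=float) for k in ks]
    H, p = kruskal_wallis(groups)
    if p >= alpha:
        report = SelectionReport(
            k_selected=ks[0], kw_H=H, kw_p=p, dunn=None, fallback=True,
            notes=["Kruskal-Wallis not significant; defaulting to smallest k"],
        )
        return ks[0], report
    comparisons = [(j, 0) for j in range(1, len(ks))]
    dunn = dunn_posthoc(groups, comparisons=comparisons, p_adjust=p_adjust)
    dunn = dunn.assign(k=[ks[j] for j, _ in comparisons])
    sig = dunn[dunn["p"] < alpha]
    if sig.empty:
        report = SelectionReport(
            k_selected=ks[0], kw_H=H, kw_p=p, dunn=dunn, fallback=True,
            notes=["no Dunn comparison against k=1 significant"],
        )
        return ks[0], report
    k_sel = int(sig["k"].min())
    return k_sel, SelectionReport(k_selected=k_sel, kw_H=H, kw_p=p, dunn=dunn)


def match_synergies(reference_W: np.ndarray, trial_W: np.ndarray) -> np.ndarray:
    """Column permutation of trial_W best aligned with reference_W.

    Maximizes total cosine similarity by optimal assignment; returns ``perm``
    such that ``trial_W[:, perm]`` matches the reference column order.
    """
    A = np.asarray(reference_W, dtype=float)
    B = np.asarray(trial_W, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    An = A / (np.linalg.norm(A, axis=0, keepdims=True) + _EPS)
    Bn = B / (np.linalg.norm(B, axis=0, keepdims=True) + _EPS)
    cos = An.T @ Bn  # reference col x trial col
    rows, cols = linear_sum_assignment(-cos)
    perm = np.empty(A.shape[1], dtype=int)
    perm[rows] = cols
    return perm


def build_weight_observations(
    trials: Sequence[ProcessedTrial],
    condition: str,
    k_selected: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[WeightObservations]:
    """Pool matched per-trial spatial weights into one matrix per synergy.

    A reference decomposition is fit on the time-concatenated envelopes of
    the condition; each trial is then decomposed at ``k_selected`` and its
    columns aligned to the reference with :func:`match_synergies`, so row s
    of synergy j's matrix is trial s's weight vector for that synergy.
    """
    cond_trials = [t for t in trials if t.condition == condition]
    if not cond_trials:
        raise ValueError(f"no trials for condition {condition!r}")
    labels = cond_trials[0].channel_labels
    concat = np.concatenate([t.envelope.T for t in cond_trials], axis=1)
    reference = nmf(
        concat, k_selected, seed=derive_seed(seed, "ref", condition),
        n_restarts=n_restarts,
    )
    rows = np.empty((len(cond_trials), k_selected, len(labels)))
    for s, tr in enumerate(cond_trials):
        dec = nmf(
            tr.envelope.T,
            k_selected,
            seed=derive_seed(seed, "obs", *tr.key),
            n_restarts=n_restarts,
        )
        perm = match_synergies(reference.W, dec.W)
        rows[s] = dec.W[:, perm].T
    return [
        WeightObservations(
            condition=condition,
            synergy_index=j + 1,
            matrix=rows[:, j, :],
            channel_labels=labels,
        )
        for j in range(k_selected)
    ]
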