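"""Sparse Gaussian graphical model over muscles (EBIC-glasso).

Spatial-weight observations are summarized by their Pearson correlation
matrix S; the graphical lasso

    Theta_hat = argmax_Theta  ln|Theta| - tr(S Theta) - rho * ||Theta||_1,off

is solved along a log-spaced penalty path and the extended Bayesian
information criterion (EBIC) with hyperparameter gamma picks the penalty.
Edges are reported as partial correlations -theta_ij / sqrt(theta_ii
theta_jj); a zero entry means conditional independence of the two muscles
given the rest.
"""

from __future__ import annotations

import numpy as np

from .types import PcorNetwork, WeightObservations

__all__ = [
    "sample_correlation",
    "glasso",
    "lambda_path",
    "ebic_score",
    "precision_to_partial_corr",
    "select_network",
    "GlassoNonConvergence",
]

#: Off-diagonal entries below this magnitude are treated as exact zeros
#: when counting edges (coordinate-descent numerical dust).
EDGE_TOL = 1.0e-8


class GlassoNonConvergence(RuntimeError):
    """Graphical-lasso coordinate descent failed to converge."""


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, WeightObservations):
        return X.matrix, X.channel_labels
    X = np.asarray(X, dtype=float)
    return X, tuple(f"V{i + 1}" for i in range(X.shape[1]))


def sample_correlation(X) -> np.ndarray:
    """Pearson correlation matrix of observations x muscles data."""
    M, labels = _as_matrix(X)
    if M.shape[0] < 3:
        raise ValueError(f"need at least 3 observations, got {M.shape[0]}")
    sd = M.std(axis=0)
    constant = np.nonzero(sd <= 0.0)[0]
    if constant.size:
        names = ", ".join(labels[i] for i in constant)
        raise ValueError(f"constant column(s): {names}")
    S = np.corrcoef(M, rowvar=False)
    return 0.5 * (S + S.T)


def _glasso_state(
    S: np.ndarray,
    rho: float | np.ndarray,
    tol: float,
    max_iter: int,
    W: np.ndarray | None = None,
    B: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Friedman block coordinate descent with an inner lasso solve.

    Maximizes ln|Theta| - tr(S Theta) - sum_{i != j} rho_ij |theta_ij| by
    cycling over columns of the working covariance W; each column update is
    a lasso regression solved by coordinate descent.  ``rho`` may be a
    scalar or an elementwise penalty matrix (used for support-constrained
    refits).  ``W``/``B`` carry warm starts along a penalty path.  Returns
    (Theta, W, B).
    """
    p = S.shape[0]
    rho_mat = np.broadcast_to(np.asarray(rho, dtype=float), (p, p))
    # off-diagonal-only penalty: the stationarity condition pins the
    # working covariance diagonal at the sample diagonal
    if W is None:
        W = S.copy()
    else:
        W = W.copy()
        np.fill_diagonal(W, np.diag(S))
    B = np.zeros((p, p)) if B is None else B.copy()  # column j: lasso coefs
    idx = np.arange(p)
    thresh = tol * max(np.mean(np.abs(S - np.diag(np.diag(S)))), 1e-12)

    def back_out_theta() -> np.ndarray:
        T = np.empty((p, p))
        for j in range(p):
            rest = idx != j
            T[j, j] = 1.0 / (W[j, j] - W[rest, j] @ B[rest, j])
            T[rest, j] = -B[rest, j] * T[j, j]
        return 0.5 * (T + T.T)

    def duality_gap(T: np.ndarray) -> float:
        # tr(S T) - p + sum_ij rho_ij |T_ij| vanishes at the optimum
        off = np.abs(T).copy()
        np.fill_diagonal(off, 0.0)
        return float(np.sum(S * T) - p + np.sum(rho_mat * off))
    for _ in range(max_iter):
        max_delta = 0.0
        inner_done = True
        for j in range(p):
            rest = idx != j
            W11 = W[np.ix_(rest, rest)]
            s12 = S[rest, j]
            r12 = rho_mat[rest, j]
            b = B[rest, j].copy()
            # inner lasso: min 1/2 b'W11 b - s12'b + sum_k rho_k |b_k|
            for _ in range(40):
                b_max = 0.0
                for k in range(p - 1):
                    r = s12[k] - W11[k] @ b + W11[k, k] * b[k]
                    new = np.sign(r) * max(abs(r) - r12[k], 0.0) / W11[k, k]
                    b_max = max(b_max, abs(new - b[k]))
                    b[k] = new
                if b_max < 0.1 * thresh:
                    break
            else:
                inner_done = False  # truncated; finish in a later sweep
            w12 = W11 @ b
            max_delta = max(max_delta, np.max(np.abs(W[rest, j] - w12)))
            W[rest, j] = w12
            W[j, rest] = w12
            B[rest, j] = b
        if not np.isfinite(max_delta):
            # diverged: the (constrained) MLE does not exist, e.g. a
            # singular resampled correlation matrix with a dense support
            raise GlassoNonConvergence("glasso diverged; no bounded maximizer")
        if max_delta < thresh and inner_done:
            # cheap pre-filter passed; confirm on the duality gap, which
            # controls objective error even for ill-conditioned S
            if abs(duality_gap(back_out_theta())) < tol:
                break
            thresh *= 0.1  # not yet at the optimum: tighten and continue
    else:
        raise GlassoNonConvergence(
            f"glasso did not converge in {max_iter} sweeps "
            f"at rho={np.max(rho_mat):g}"
        )
    Theta = back_out_theta()
    # snap coordinate-descent dust to exact zeros (B carries exact zeros)
    zero = (B == 0.0) & (B.T == 0.0)
    np.fill_diagonal(zero, False)
    Theta[zero] = 0.0
    return Theta, W, B


def glasso(
    S: np.ndarray,
    rho: float,
    tol: float = 1.0e-5,
    max_iter: int = 500,
) -> np.ndarray:
    """L1-penalized precision estimate by block coordinate descent.

    ``rho = 0`` returns the unpenalized maximum-likelihood estimate S^-1.
    The off-diagonal is penalized; the diagonal is left free, which keeps
    the partial-correlation scale of the edges intact.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be >= 0")
    if np.all(np.asarray(rho) == 0.0):
        try:
            Theta = np.linalg.inv(S)
        except np.linalg.LinAlgError as err:
            raise GlassoNonConvergence("S is singular at rho = 0") from err
        return 0.5 * (Theta + Theta.T)
    Theta, _, _ = _glasso_state(S, float(rho), tol, max_iter)
    return Theta


def support_mle(
    S: np.ndarray,
    support: np.ndarray,
    tol: float = 1.0e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Maximum-likelihood precision matrix restricted to an edge set.

    Solves max ln|Theta| - tr(S Theta) subject to theta_ij = 0 off the
    given (boolean, symmetric) support — the maximized log-likelihood
    Theta_hat(E) that the EBIC of an edge set E is defined on.  Implemented
    as the glasso solver with a zero penalty on allowed edges and an
    effectively infinite penalty elsewhere.
    """
    S = np.asarray(S, dtype=float)
    support = np.asarray(support, dtype=bool)
    p = S.shape[0]
    if support.shape != (p, p) or not np.array_equal(support, support.T):
        raise ValueError("support must be a symmetric boolean p x p matrix")
    big = 1.0e3 * float(np.abs(S).max())
    rho_mat = np.where(support, 0.0, big)
    np.fill_diagonal(rho_mat, 0.0)
    if not support.any():
        return np.diag(1.0 / np.diag(S))
    Theta, _, _ = _glasso_state(S, rho_mat, tol, max_iter)
    return Theta


def lambda_path(S: np.ndarray, n_points: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from rho_max down to ratio * rho_max.

    ``rho_max`` is the largest off-diagonal |S|, the screening threshold at
    which the glasso solution is fully disconnected.
    """
    S = np.asarray(S, dtype=float)
    off = np.abs(S - np.diag(np.diag(S)))
    rho_max = float(off.max())
    if rho_max <= 0:
        rho_max = 1.0e-3
    return np.logspace(np.log10(rho_max), np.log10(ratio * rho_max), n_points)


def _edge_count(Theta: np.ndarray) -> int:
    iu = np.triu_indices(Theta.shape[0], k=1)
    return int(np.count_nonzero(np.abs(Theta[iu]) > EDGE_TOL))


def ebic_score(
    Theta: np.ndarray, S: np.ndarray, n_obs: int, gamma: float = 0.5
) -> float:
    """Extended BIC of a precision estimate.

        EBIC = -2 * loglik + |E| log(n) + 4 |E| gamma log(p)

    with loglik the maximized full-sample Gaussian log-likelihood
    (n/2) [ln|Theta| - tr(S Theta)] up to a constant, and |E| the number of
    non-zero off-diagonal (upper-triangular) entries.  gamma = 0 recovers
    the ordinary BIC penalty.
    """
    Theta = np.asarray(Theta, dtype=float)
    S = np.asarray(S, dtype=float)
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    try:
        L = np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as err:
        raise ValueError("Theta must be positive definite") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if not np.isfinite(logdet):
        raise ValueError("Theta must be positive definite")
    p = Theta.shape[0]
    loglik = 0.5 * n_obs * (logdet - float(np.sum(S * Theta)))
    E = _edge_count(Theta)
    return -2.0 * loglik + E * np.log(n_obs) + 4.0 * E * gamma * np.log(p)


def precision_to_partial_corr(Theta: np.ndarray, tol: float = EDGE_TOL) -> np.ndarray:
    """Partial correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).

    The diagonal is zero and the off-diagonal zero pattern matches Theta's
    (entries below ``tol`` in magnitude are snapped to exact zero).
    """
    Theta = np.asarray(Theta, dtype=float)
    eigmin = np.linalg.eigvalsh(Theta).min()
    if eigmin <= 0:
        raise ValueError("Theta must be positive definite")
    d = np.sqrt(np.diag(Theta))
    W = -Theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < tol] = 0.0
    return W


def select_network(
    X,
    gamma: float = 0.5,
    n_points: int = 100,
    ratio: float = 0.01,
    tol: float = 1.0e-5,
    max_iter: int = 500,
) -> PcorNetwork:
    """EBIC-glasso: fit the penalty path and keep the EBIC-minimizing model.

    Each penalty on the path proposes an edge set (the non-zero pattern of
    the penalized estimate); the EBIC of an edge set is computed from its
    maximized log-likelihood, i.e. the unpenalized MLE refit restricted to
    that support, so edge strength is not confounded with shrinkage.  The
    path is traversed from the sparsest model downward, ties break toward
    the larger penalty (the sparser network), and the returned precision is
    the refit of the winning edge set.  Penalties where coordinate descent
    fails are skipped.
    """
    M, labels = _as_matrix(X)
    S = sample_correlation(M)
    n_obs = M.shape[0]
    p = S.shape[0]
    off_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    if off_max > 0.9999:
        # collinear columns: the likelihood is unbounded along that pair
        raise GlassoNonConvergence("collinear columns in the observations")
    best = None
    n_failed = 0
    W = B = None
    scored: dict[bytes, float] = {}
    for rho in lambda_path(S, n_points=n_points, ratio=ratio):
        try:
            # warm-start each fit from the previous (sparser) solution
            Theta_pen, W, B = _glasso_state(S, float(rho), tol, max_iter, W=W, B=B)
        except (GlassoNonConvergence, ValueError):
            n_failed += 1
            W = B = None
            continue
        support = np.abs(Theta_pen) > EDGE_TOL
        np.fill_diagonal(support, False)
        key = np.packbits(support[np.triu_indices(p, k=1)]).tobytes()
        if key in scored:
            continue
        try:
            Theta = support_mle(S, support, tol=tol, max_iter=max_iter)
            score = ebic_score(Theta, S, n_obs, gamma=gamma)
        except (GlassoNonConvergence, ValueError):
            n_failed += 1
            continue
        scored[key] = score
        if best is None or score < best[0] - 1e-12:
            best = (score, float(rho), Theta)
    if best is None:
        raise GlassoNonConvergence("no penalty on the path produced a valid model")
    score, rho_sel, Theta = best
    return PcorNetwork(
        channel_labels=labels,
        weights=precision_to_partial_corr(Theta),
        precision=Theta,
        rho_selected=rho_sel,
        ebic=score,
        gamma=gamma,
        n_obs=n_obs,
    )
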