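"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, direct numerical optimization, explicit rank arithmetic) and
share no code path with the package implementation.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def floyd_warshall_counts(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest 1/|w| distances and shortest-path counts."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] != 0:
                d[i, j] = 1.0 / abs(W[i, j])
                sigma[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if i == j or i == k or j == k:
                    continue
                alt = d[i, k] + d[k, j]
                if alt < d[i, j] - 1e-12:
                    d[i, j] = alt
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif abs(alt - d[i, j]) <= 1e-12 and np.isfinite(alt):
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    return d, sigma


def betweenness_brute(W: np.ndarray) -> np.ndarray:
    """Betweenness from exhaustive simple-path enumeration."""
    n = W.shape[0]
    d = {(i, j): (np.inf, []) for i in range(n) for j in range(n)}

    def paths(s, t):
        # enumerate all simple paths, keep the shortest-distance set
        best, shortest = np.inf, []
        stack = [([s], 0.0)]
        while stack:
            path, dist = stack.pop()
            u = path[-1]
            if u == t:
                if dist < best - 1e-12:
                    best, shortest = dist, [path]
                elif abs(dist - best) <= 1e-12:
                    shortest.append(path)
                continue
            for v in range(n):
                if W[u, v] != 0 and v not in path:
                    stack.append((path + [v], dist + 1.0 / abs(W[u, v])))
        return shortest

    acc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            sp = paths(s, t)
            if not sp:
                continue
            for u in range(n):
                if u in (s, t):
                    continue
                through = sum(1 for p in sp if u in p)
                acc[u] += through / len(sp)
    norm = (n - 1) * (n - 2) / 2.0
    return acc / norm


def closeness_brute(W: np.ndarray) -> np.ndarray:
    """Closeness with the component-size (Wasserman-Faust) correction."""
    n = W.shape[0]
    d, _ = floyd_warshall_counts(W)
    out = np.zeros(n)
    for u in range(n):
        reach = [v for v in range(n) if v != u and np.isfinite(d[u, v])]
        if not reach:
            continue
        total = sum(d[u, v] for v in reach)
        out[u] = (len(reach) / total) * (len(reach) / (n - 1))
    return out


def glasso_direct(S: np.ndarray, rho: float) -> np.ndarray:
    """Direct numerical maximization of the penalized log-likelihood.

    The non-smooth L1 term is replaced by sqrt(t^2 + eps^2) with eps driven
    to 1e-9 under warm-started quasi-Newton steps; independent of the
    coordinate-descent path it checks.
    """
    p = S.shape[0]
    iu = np.triu_indices(p)
    off_mask = np.triu(np.ones((p, p), dtype=bool), k=1)[iu]

    def unpack(x):
        T = np.zeros((p, p))
        T[iu] = x
        return T + T.T - np.diag(np.diag(T))

    scale = np.where(off_mask, 2.0, 1.0)  # symmetric double-counting

    def make_neg(eps):
        def neg(x):
            T = unpack(x)
            ev = np.linalg.eigvalsh(T)
            if ev.min() <= 1e-10:
                return 1e9, np.zeros_like(x)
            smooth = np.sqrt(x**2 + eps**2)
            pen = 2.0 * rho * np.sum(smooth[off_mask])  # both triangles
            f = -(np.linalg.slogdet(T)[1] - np.sum(S * T) - pen)
            G = -np.linalg.inv(T) + S  # d/dT of -(logdet - tr)
            g = scale * G[iu]
            g[off_mask] += 2.0 * rho * (x / smooth)[off_mask]
            return f, g

        return neg

    x = np.linalg.inv(S)[iu]
    for eps in (1e-3, 1e-5, 1e-7, 1e-9):
        res = minimize(
            make_neg(eps), x, jac=True, method="L-BFGS-B",
            options=dict(maxiter=5000, ftol=1e-16, gtol=1e-12),
        )
        x = res.x
    return unpack(x)


def kruskal_by_hand(groups):
    """Explicit rank-sum arithmetic for the Kruskal-Wallis H (tie-corrected)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    N = len(pooled)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie


def dunn_z_by_hand(groups, i, j):
    """Explicit Dunn z for groups i vs j on pooled tie-corrected ranks."""
    from scipy.stats import rankdata

    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    ri = ranks[bounds[i] : bounds[i + 1]].mean()
    rj = ranks[bounds[j] : bounds[j + 1]].mean()
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    T = np.sum(counts**3 - counts)
    var = (N * (N + 1) / 12.0 - T / (12.0 * (N - 1))) * (1 / sizes[i] + 1 / sizes[j])
    return (ri - rj) / np.sqrt(var)


def best_permutation_cosine(ref: np.ndarray, trial: np.ndarray):
    """Exhaustive assignment over all k! column permutations."""
    k = ref.shape[1]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(
            ref[:, c] @ trial[:, perm[c]]
            / (np.linalg.norm(ref[:, c]) * np.linalg.norm(trial[:, perm[c]]))
            for c in range(k)
        )
        if score > best_score:
            best_score, best_perm = score, np.array(perm)
    return best_perm, best_score


def deltacon_by_hand(A1: np.ndarray, A2: np.ndarray) -> float:
    """Step-by-step DeltaCon similarity of two adjacency matrices."""
    A1, A2 = np.abs(A1), np.abs(A2)
    eps = 1.0 / (1.0 + max(A1.sum(axis=1).max(), A2.sum(axis=1).max()))
    n = A1.shape[0]

    def affinity(A):
        return np.linalg.inv(np.eye(n) + eps**2 * np.diag(A.sum(axis=1)) - eps * A)

    S1 = np.clip(affinity(A1), 0, None)
    S2 = np.clip(affinity(A2), 0, None)
    d = np.sqrt(((np.sqrt(S1) - np.sqrt(S2)) ** 2).sum())
    return 1.0 / (1.0 + d)
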