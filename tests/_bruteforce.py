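"""Independent brute-force reference implementations of the graph measures.

Everything here is computed from first principles with explicit loops:
all-pairs shortest paths by exhaustive Floyd-Warshall relaxation with path
counting, centralities by their definition sums, spectral scores by plain
power iteration.  These deliberately avoid igraph / networkx / scipy graph
routines so they can serve as an independent oracle for the package's
implementations on small graphs.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-12


def floyd_warshall_counts(D0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shortest distances and shortest-path counts by exhaustive relaxation.

    D0: per-edge distance matrix, 0 = absent edge (off-diagonal).
    """
    n = D0.shape[0]
    D = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for i in range(n):
        D[i, i] = 0.0
        sigma[i, i] = 1.0
        for j in range(n):
            if i != j and D0[i, j] > 0:
                D[i, j] = D0[i, j]
                sigma[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            if i == k:
                continue
            for j in range(n):
                if j == k or j == i:
                    continue
                alt = D[i, k] + D[k, j]
                if alt < D[i, j] - TOL:
                    D[i, j] = alt
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif np.isfinite(alt) and abs(alt - D[i, j]) <= TOL:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    return D, sigma


def betweenness(D0: np.ndarray) -> np.ndarray:
    """Node betweenness: sum over pairs s<t of the fraction of shortest
    s-t paths passing through the node."""
    n = D0.shape[0]
    D, sigma = floyd_warshall_counts(D0)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v == s or v == t:
                    continue
                if abs(D[s, v] + D[v, t] - D[s, t]) <= TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def power_iteration(M: np.ndarray, iters: int = 50000, tol: float = 1e-15) -> np.ndarray:
    """Perron eigenvector of a symmetric nonnegative matrix, max-normalized.

    Iterates on M + cI (c = max row sum) so the largest *algebraic* eigenvalue
    dominates in magnitude even for bipartite graphs, whose spectrum is
    symmetric about zero.
    """
    n = M.shape[0]
    if not M.any():
        return np.zeros(n)
    c = float(M.sum(axis=1).max())
    S = M + c * np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = S @ v
        w = w / np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return v / v.max() if v.max() > 0 else v


def reference_measures(W: np.ndarray, binary_degrees: bool = False,
                       distance: str = "inverse") -> dict[str, float]:
    """The 17 standard measures by definition sums on a weight matrix."""
    n = W.shape[0]
    present = W > 0
    if binary_degrees:
        deg = np.array([float(present[i].sum()) for i in range(n)])
        adj = present.astype(float)
    else:
        deg = np.array([float(W[i].sum()) for i in range(n)])
        adj = W

    mean_degree = sum(deg) / n
    smd = sum(d * d for d in deg) / n
    complexity = smd / mean_degree if mean_degree > 0 else 0.0

    total = sum(deg)
    entropy = 0.0
    for d in deg:
        if d > 0:
            p = d / total
            entropy -= p * np.log(p)

    knn_vals = []
    for i in range(n):
        if deg[i] > 0:
            knn_vals.append(sum(adj[i, j] * deg[j] for j in range(n)) / deg[i])
    knn = float(np.mean(knn_vals)) if knn_vals else 0.0

    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if present[i, j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    if xs and max(xs) > min(xs):
        xa, ya = np.array(xs), np.array(ys)
        assort = float(((xa - xa.mean()) * (ya - ya.mean())).sum()
                       / np.sqrt(((xa - xa.mean())**2).sum() * ((ya - ya.mean())**2).sum()))
    else:
        assort = 0.0

    ec = float(power_iteration(W).mean())
    hub = ec  # undirected: hub measure equals eigenvector centrality

    closed = 0
    triads = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i != j and j != k and i != k:
                    if present[i, j] and present[j, k]:
                        triads += 1
                        if present[i, k]:
                            closed += 1
    transitivity = closed / triads if triads else 0.0
    density = float(present.sum()) / (n * (n - 1))

    # k-core by iterative peeling on edge presence
    alive = [True] * n
    core = 0
    for k in range(1, n):
        changed = True
        while changed:
            changed = False
            for i in range(n):
                if alive[i]:
                    d = sum(1 for j in range(n) if alive[j] and present[i, j])
                    if d < k:
                        alive[i] = False
                        changed = True
        if any(alive):
            core = k
        else:
            break
    k_core = float(core) if present.any() else 0.0

    D0 = np.zeros_like(W)
    for i in range(n):
        for j in range(n):
            if present[i, j]:
                D0[i, j] = 1.0 / W[i, j] if distance == "inverse" else max(1.0 - W[i, j], 1e-12)
    D, _ = floyd_warshall_counts(D0)

    # largest component by reachability
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if np.isfinite(D[i, j])]
        seen.update(comp)
        comps.append(comp)
    L = max(comps, key=lambda c: (len(c), -min(c)))
    m = len(L)
    if m > 1:
        dists = [D[i, j] for i in L for j in L if i != j]
        apl = float(np.mean(dists))
        diameter = float(max(dists))
        ecc = float(np.mean([max(D[i, j] for j in L if j != i) for i in L]))
        clo = float(np.mean([(m - 1) / sum(D[i, j] for j in L) for i in L]))
    else:
        apl = diameter = ecc = clo = 0.0

    eff = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                eff += 1.0 / D[i, j]
    efficiency = eff / (n * (n - 1))

    bc = float(np.mean(betweenness(D0)))

    return {
        "assortativity": assort,
        "average_path_length": apl,
        "betweenness_centrality": bc,
        "closeness_centrality": clo,
        "eigenvector_centrality": ec,
        "diameter": diameter,
        "hub_score": hub,
        "knn": knn,
        "mean_degree": mean_degree,
        "second_moment_degree": smd,
        "entropy_degree": entropy,
        "transitivity": transitivity,
        "complexity": complexity,
        "k_core": k_core,
        "eccentricity": ecc,
        "density": density,
        "efficiency": efficiency,
    }


def reference_community_apl(W: np.ndarray, members: np.ndarray,
                            distance: str = "inverse") -> float:
    """Mean shortest-path distance over ordered pairs within a node subset,
    on the induced subgraph, reachable pairs only."""
    sub = W[np.ix_(members, members)]
    m = len(members)
    if m < 2:
        return 0.0
    D0 = np.zeros_like(sub)
    for i in range(m):
        for j in range(m):
            if sub[i, j] > 0:
                D0[i, j] = 1.0 / sub[i, j] if distance == "inverse" else max(1.0 - sub[i, j], 1e-12)
    D, _ = floyd_warshall_counts(D0)
    vals = [D[i, j] for i in range(m) for j in range(m) if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else 0.0


def exhaustive_best_modularity(W: np.ndarray) -> tuple[float, list[set[int]]]:
    """Maximum-modularity partition by enumerating all partitions (n <= 10)."""
    n = W.shape[0]
    if n > 10:
        raise ValueError("exhaustive search limited to 10 nodes")
    two_m = W.sum()
    deg = W.sum(axis=1)

    def modularity(assign: list[int]) -> float:
        q = 0.0
        for i in range(n):
            for j in range(n):
                if assign[i] == assign[j]:
                    q += W[i, j] - deg[i] * deg[j] / two_m
        return q / two_m

    best_q, best = -np.inf, None
    assign = [0] * n

    def rec(i: int, n_used: int) -> None:
        nonlocal best_q, best
        if i == n:
            q = modularity(assign)
            nonlocal_best(q)
            return
        for c in range(n_used + 1):
            assign[i] = c
            rec(i + 1, max(n_used, c + 1))

    def nonlocal_best(q: float) -> None:
        nonlocal best_q, best
        if q > best_q + 1e-12:
            best_q = q
            groups: dict[int, set[int]] = {}
            for node, c in enumerate(assign):
                groups.setdefault(c, set()).add(node)
            best = list(groups.values())

    rec(0, 0)
    return best_q, best
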