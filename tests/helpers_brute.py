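"""Independent brute-force centrality oracles for small unweighted graphs.

All shortest-path quantities are obtained by explicit enumeration of every
simple path between every node pair (feasible for n <= 8), completely
independent of the graph-library implementations under test.
"""

from __future__ import annotations

import numpy as np


def _all_simple_paths(A: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = A.shape[0]
    out: list[list[int]] = []

    def dfs(path: list[int], visited: set[int]) -> None:
        v = path[-1]
        if v == t:
            out.append(list(path))
            return
        for u in range(n):
            if A[v, u] > 0 and u not in visited:
                visited.add(u)
                path.append(u)
                dfs(path, visited)
                path.pop()
                visited.remove(u)

    dfs([s], {s})
    return out


def shortest_paths(A: np.ndarray, s: int, t: int):
    """(min length, list of minimal simple paths) with unit edge lengths."""
    paths = _all_simple_paths(A, s, t)
    if not paths:
        return np.inf, []
    best = min(len(p) - 1 for p in paths)
    return best, [p for p in paths if len(p) - 1 == best]


def degree(A: np.ndarray) -> np.ndarray:
    return A.sum(axis=0).astype(float)


def closeness(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for v in range(n):
        dists = []
        for u in range(n):
            if u == v:
                continue
            d, _ = shortest_paths(A, v, u)
            if np.isfinite(d):
                dists.append(d)
        if dists:
            out[v] = len(dists) / sum(dists)
    return out


def betweenness(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            _, paths = shortest_paths(A, s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                out[v] += through / len(paths)
    return out


def edge_betweenness(A: np.ndarray, universe) -> np.ndarray:
    n = A.shape[0]
    scores = {pair: 0.0 for pair in universe}
    for s in range(n):
        for t in range(s + 1, n):
            _, paths = shortest_paths(A, s, t)
            if not paths:
                continue
            for pair in universe:
                i, j = pair
                through = sum(
                    1
                    for p in paths
                    if any(
                        (p[k], p[k + 1]) in ((i, j), (j, i))
                        for k in range(len(p) - 1)
                    )
                )
                scores[pair] += through / len(paths)
    return np.array([scores[pair] for pair in universe])


def clustering(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if A[nbrs[a], nbrs[b]] > 0
        )
        out[i] = closed / (k * (k - 1) / 2)
    return out


def eigenvector(A: np.ndarray) -> np.ndarray:
    """Projection of the uniform vector onto the top eigenspace, max = 1."""
    n = A.shape[0]
    if A.sum() == 0:
        return np.zeros(n)
    w, V = np.linalg.eigh(A)
    top = w > w[-1] - 1e-9
    proj = V[:, top] @ (V[:, top].T @ np.ones(n))
    v = np.abs(proj)
    return v / v.max()
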