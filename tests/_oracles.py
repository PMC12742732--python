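"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the library:
textbook dense GF(2) boundary-matrix reduction for persistence (no
union-find, no clearing), rank-nullity Betti numbers, O(N^2) double-loop
template counting for sample entropy, and exhaustive rank-assignment
enumeration for the Mann-Whitney exact p-value.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform


def _all_simplices(n_points: int, dmat: np.ndarray, max_radius: float,
                   up_to_dim: int = 3):
    """Every simplex up to the given dimension with VR filtration value."""
    simplices = []
    for dim in range(up_to_dim + 1):
        for verts in itertools.combinations(range(n_points), dim + 1):
            if dim == 0:
                value = 0.0
            else:
                value = max(dmat[a, b] for a, b in itertools.combinations(verts, 2))
            if value <= max_radius:
                simplices.append((value, dim, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    return simplices


def brute_persistence(points: np.ndarray, max_radius: float,
                      up_to_dim: int = 3) -> dict[int, list[tuple[float, float]]]:
    """Textbook persistence: one global boundary matrix, left-to-right
    column reduction over GF(2) with dense boolean columns."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dmat = squareform(pdist(points))
    simplices = _all_simplices(n, dmat, max_radius, up_to_dim)
    index = {s[2]: i for i, s in enumerate(simplices)}
    m = len(simplices)
    cols = np.zeros((m, m), dtype=bool)
    for j, (_, dim, verts) in enumerate(simplices):
        if dim == 0:
            continue
        for k in range(len(verts)):
            face = verts[:k] + verts[k + 1:]
            cols[index[face], j] = True

    def low(j):
        rows = np.nonzero(cols[:, j])[0]
        return int(rows[-1]) if len(rows) else -1

    pivot_owner: dict[int, int] = {}
    for j in range(m):
        piv = low(j)
        while piv >= 0 and piv in pivot_owner:
            cols[:, j] ^= cols[:, pivot_owner[piv]]
            piv = low(j)
        if piv >= 0:
            pivot_owner[piv] = j

    paired = {}
    for piv, j in pivot_owner.items():
        paired[piv] = j
    diagrams: dict[int, list[tuple[float, float]]] = {k: [] for k in range(up_to_dim)}
    dead_rows = set(pivot_owner.keys())
    death_cols = set(pivot_owner.values())
    for i, (value, dim, _) in enumerate(simplices):
        if i in death_cols:
            continue  # this simplex kills a class, it does not create one
        if i in dead_rows:
            j = paired[i]
            death = simplices[j][0]
            if death > value:
                diagrams[dim].append((value, death))
        else:
            if dim < up_to_dim:
                diagrams[dim].append((value, np.inf))
    for k in diagrams:
        diagrams[k].sort()
    return diagrams


def gf2_rank(mat: np.ndarray) -> int:
    """Rank of a boolean matrix over GF(2) by Gaussian elimination."""
    a = mat.astype(bool).copy()
    rank = 0
    n_rows, n_cols = a.shape
    for col in range(n_cols):
        pivots = np.nonzero(a[rank:, col])[0]
        if len(pivots) == 0:
            continue
        piv = rank + pivots[0]
        a[[rank, piv]] = a[[piv, rank]]
        others = np.nonzero(a[:, col])[0]
        for r in others:
            if r != rank:
                a[r] ^= a[rank]
        rank += 1
        if rank == n_rows:
            break
    return rank


def betti_numbers_at(points: np.ndarray, radius: float,
                     up_to_dim: int = 2) -> list[int]:
    """Betti numbers of the VR complex at one radius via rank-nullity."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dmat = squareform(pdist(points))
    by_dim: dict[int, list[tuple[int, ...]]] = {k: [] for k in range(up_to_dim + 2)}
    for value, dim, verts in _all_simplices(n, dmat, radius, up_to_dim + 1):
        by_dim[dim].append(verts)
    bettis = []
    for k in range(up_to_dim + 1):
        n_k = len(by_dim[k])
        if n_k == 0:
            bettis.append(0)
            continue
        rank_k = 0
        if k > 0 and by_dim[k - 1]:
            idx = {f: i for i, f in enumerate(by_dim[k - 1])}
            B = np.zeros((len(by_dim[k - 1]), n_k), dtype=bool)
            for j, s in enumerate(by_dim[k]):
                for drop in range(len(s)):
                    B[idx[s[:drop] + s[drop + 1:]], j] = True
            rank_k = gf2_rank(B)
        rank_k1 = 0
        if by_dim[k + 1]:
            idx = {f: i for i, f in enumerate(by_dim[k])}
            B = np.zeros((n_k, len(by_dim[k + 1])), dtype=bool)
            for j, s in enumerate(by_dim[k + 1]):
                for drop in range(len(s)):
                    B[idx[s[:drop] + s[drop + 1:]], j] = True
            rank_k1 = gf2_rank(B)
        bettis.append(n_k - rank_k - rank_k1)
    return bettis


def mst_edge_lengths(points: np.ndarray) -> np.ndarray:
    """Sorted minimum-spanning-tree edge lengths (scipy route)."""
    from scipy.sparse.csgraph import minimum_spanning_tree

    dmat = squareform(pdist(np.asarray(points, dtype=float)))
    mst = minimum_spanning_tree(dmat).toarray()
    return np.sort(mst[mst > 0])


def sampen_bruteforce(x: np.ndarray, m: int, r: float,
                      sd: float | None = None) -> float:
    """O(N^2) double-loop sample entropy with Chebyshev matching."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if sd is None:
        sd = float(np.std(x))
    if not sd > 0 or n < m + 2:
        return float("nan")
    tol = r * sd
    n_templates = n - m

    def count(length):
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mwu_exact_p(a, b, tail: str) -> float:
    """Exact Mann-Whitney p by enumerating all rank assignments (no ties)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)

    def u_of(rank_set):
        r = sum(rank_set)
        return r - n_a * (n_a + 1) / 2

    observed = u_of([ranks[v] for v in a])
    us = [u_of(c) for c in itertools.combinations(range(1, n_a + n_b + 1), n_a)]
    total = comb(n_a + n_b, n_a)
    if tail == "less":
        return sum(u <= observed for u in us) / total
    if tail == "greater":
        return sum(u >= observed for u in us) / total
    p = 2 * min(sum(u <= observed for u in us),
                sum(u >= observed for u in us)) / total
    return min(1.0, p)
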