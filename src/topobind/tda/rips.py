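"""Vietoris-Rips persistent homology for small point clouds (k <= 2).

A simplex enters the filtration at its largest pairwise distance (the VR
rule). Connected-component (H0) pairs come from Kruskal union-find, so
finite H0 deaths are exactly the minimum-spanning-tree edge lengths. Loop
(H1) and void (H2) pairs come from the standard boundary-matrix column
reduction over GF(2), run per dimension from the top down with the
clearing optimization; columns are Python integers used as bitsets, with
rows indexed in filtration order so the pivot is the latest facet.

Bars still alive at ``max_radius`` are reported with death = inf; the
complex is truncated at that radius, so such a bar may in truth die just
beyond the cap (recorded in the diagram metadata).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PersistencePair:
    """One birth/death pair; death = inf marks a bar alive at the cap."""

    dim: int
    birth: float
    death: float

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Birth/death pairs per homology dimension for one filtration."""

    diagrams: dict[int, np.ndarray]   # dim -> (n, 2) array, death may be inf
    max_dim: int
    max_radius: float
    n_points: int
    notes: dict = field(default_factory=dict)

    def pairs(self, dim: int) -> np.ndarray:
        """(n, 2) array of (birth, death) for one dimension."""
        return self.diagrams.get(dim, np.empty((0, 2)))

    def finite_pairs(self, dim: int) -> np.ndarray:
        d = self.pairs(dim)
        return d[np.isfinite(d[:, 1])]

    def all_pairs(self) -> list[PersistencePair]:
        out = []
        for dim in sorted(self.diagrams):
            for b, d in self.diagrams[dim]:
                out.append(PersistencePair(dim, float(b), float(d)))
        return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def _enumerate_cofaces(adj, dmat, base, base_vals):
    """Extend each simplex in ``base`` by one later vertex within the graph."""
    out_simplices, out_vals = [], []
    for s, sval in zip(base, base_vals):
        common = np.ones(adj.shape[0], dtype=bool)
        for v in s:
            common &= adj[v]
        candidates = np.nonzero(common)[0]
        candidates = candidates[candidates > s[-1]]
        for c in candidates:
            val = max(sval, max(dmat[v, c] for v in s))
            out_simplices.append(s + (int(c),))
            out_vals.append(val)
    return out_simplices, np.array(out_vals, dtype=float)


def _sort_simplices(simplices, values):
    """Filtration order: by value, then lexicographically by vertices."""
    order = sorted(range(len(simplices)),
                   key=lambda i: (values[i], simplices[i]))
    return ([simplices[i] for i in order],
            np.array([values[i] for i in order], dtype=float))


def _reduce(columns, skip=frozenset()):
    """GF(2) column reduction; columns are int bitsets in filtration order.

    Returns (pairs, positives): ``pairs`` maps pivot row -> column index;
    ``positives`` are columns that reduced to zero (excluding ``skip``,
    which are known-zero via clearing).
    """
    pivot: dict[int, int] = {}
    reduced: list[int] = []
    pairs: list[tuple[int, int]] = []
    positives: list[int] = []
    for j, col in enumerate(columns):
        if j in skip:
            reduced.append(0)
            continue
        low = col.bit_length() - 1
        while col and low in pivot:
            col ^= reduced[pivot[low]]
            low = col.bit_length() - 1
        reduced.append(col)
        if col:
            pivot[low] = j
            pairs.append((low, j))
        else:
            positives.append(j)
    return pairs, positives


def vr_persistence(cloud, max_dim: int = 2, max_radius: float | None = None,
                   max_simplices: int = 5_000_000) -> PersistenceDiagram:
    """Persistence diagrams (k = 0..max_dim) of the Euclidean VR filtration.

    Parameters
    ----------
    cloud : PointCloud or (N, m) array
    max_dim : int
        Highest homology dimension (2 at most); simplices one dimension
        higher are enumerated to resolve deaths.
    max_radius : float, optional
        Filtration cap; default is twice the median pairwise distance.
    max_simplices : int
        Guard against combinatorial blow-up; exceeded -> ValueError.
    """
    points = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need an (N, m) cloud with N >= 2 points")
    if not 0 <= max_dim <= 2:
        raise ValueError("max_dim must be 0, 1 or 2")
    n = len(points)
    dvec = pdist(points)
    if max_radius is None:
        max_radius = 2.0 * float(np.median(dvec))
    dmat = squareform(dvec)

    # --- edges ---------------------------------------------------------
    iu = np.triu_indices(n, 1)
    keep = dmat[iu] <= max_radius
    edge_list = [(int(a), int(b)) for a, b in zip(iu[0][keep], iu[1][keep])]
    edge_vals = dmat[iu][keep]
    edges, edge_vals = _sort_simplices(edge_list, edge_vals)
    adj = np.zeros((n, n), dtype=bool)
    for (a, b) in edges:
        adj[a, b] = adj[b, a] = True

    diagrams: dict[int, np.ndarray] = {}
    notes: dict = {"max_radius": max_radius}

    # --- H0 by Kruskal union-find -------------------------------------
    uf = _UnionFind(n)
    h0_deaths = []
    mst_ranks = set()
    for rank, ((a, b), val) in enumerate(zip(edges, edge_vals)):
        if uf.union(a, b):
            h0_deaths.append(val)
            mst_ranks.add(rank)
    n_components = len({uf.find(i) for i in range(n)})
    d0 = [(0.0, d) for d in h0_deaths if d > 0.0]
    d0 += [(0.0, np.inf)] * n_components
    diagrams[0] = np.array(d0, dtype=float).reshape(-1, 2)
    notes["n_infinite_h0"] = n_components

    if max_dim >= 1:
        # --- triangles --------------------------------------------------
        tris, tri_vals = _enumerate_cofaces(adj, dmat, edges, edge_vals)
        tris, tri_vals = _sort_simplices(tris, tri_vals)
        if len(edges) + len(tris) > max_simplices:
            raise ValueError(
                f"complex too large ({len(tris)} triangles); subsample the "
                "cloud or lower max_radius")
        edge_rank = {e: r for r, e in enumerate(edges)}
        tri_rank = {t: r for r, t in enumerate(tris)}

        tet_pairs: list[tuple[int, int]] = []
        tet_vals = np.empty(0)
        cleared: frozenset[int] = frozenset()
        if max_dim >= 2 and tris:
            # --- tetrahedra, reduce boundary_3 first (clearing) ---------
            tets, tv = _enumerate_cofaces(adj, dmat, tris, tri_vals)
            tets, tet_vals = _sort_simplices(tets, tv)
            if len(tets) + len(tris) + len(edges) > max_simplices:
                raise ValueError(
                    f"complex too large ({len(tets)} tetrahedra); subsample "
                    "the cloud or lower max_radius")
            cols3 = []
            for t in tets:
                bits = 0
                for facet in itertools.combinations(t, 3):
                    bits |= 1 << tri_rank[facet]
                cols3.append(bits)
            tet_pairs, _ = _reduce(cols3)
            cleared = frozenset(row for (row, _) in tet_pairs)

        # --- reduce boundary_2 ------------------------------------------
        cols2 = []
        for t in tris:
            bits = 0
            for facet in itertools.combinations(t, 2):
                bits |= 1 << edge_rank[facet]
            cols2.append(bits)
        tri_pairs, tri_positive = _reduce(cols2, skip=cleared)

        # H1: positive (non-MST) edges born, killed by paired triangles
        d1 = []
        paired_edges = set()
        for edge_row, tri_col in tri_pairs:
            paired_edges.add(edge_row)
            birth, death = edge_vals[edge_row], tri_vals[tri_col]
            if death > birth:
                d1.append((birth, death))
        for rank in range(len(edges)):
            if rank not in mst_ranks and rank not in paired_edges:
                d1.append((edge_vals[rank], np.inf))
        diagrams[1] = np.array(sorted(d1), dtype=float).reshape(-1, 2)

        if max_dim >= 2:
            # H2: positive triangles born, killed by paired tetrahedra
            d2 = []
            paired_tris = set()
            for tri_row, tet_col in tet_pairs:
                paired_tris.add(tri_row)
                birth, death = tri_vals[tri_row], tet_vals[tet_col]
                if death > birth:
                    d2.append((birth, death))
            for rank in tri_positive:
                d2.append((tri_vals[rank], np.inf))
            diagrams[2] = np.array(sorted(d2), dtype=float).reshape(-1, 2)

    return PersistenceDiagram(diagrams=diagrams, max_dim=max_dim,
                              max_radius=float(max_radius), n_points=n,
                              notes=notes)
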