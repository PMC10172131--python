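"""Persistent cohomology of embedding point clouds and Betti numbers.

Vietoris–Rips persistence over Z/2 up to dimension 2 with the filtration
ceiling at infinity.  The default path reduces the *coboundary* matrix in
reverse filtration order — columns are d-simplices whose cofacet lists are
generated on the fly, so the (d+1)-simplices are never enumerated — with
clearing between dimensions.  Three facts keep this fast at desk scale:
(i) the filtration can be truncated at the enclosing radius
``min_i max_j d(i, j)`` without changing any diagram, because the complex is
a cone beyond it; (ii) enumerating cofacets by increasing added vertex
produces them already sorted by combinatorial (colex) rank; and (iii) in
reverse filtration order almost every column finds an unclaimed pivot
immediately, so column additions are rare.  A direct boundary-matrix
(homology) reduction is retained as an independent oracle for small inputs;
both paths produce identical diagrams.

Betti numbers are read off the diagrams by counting lifespans that exceed a
per-dimension threshold; thresholds come from a shuffled-label null (refit
the embedding with permuted context labels and take the maximum lifespan per
dimension across shuffles) or, for bare point clouds without labels, from a
cross-dimension prominence rule.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit, types
from numba.typed import Dict
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist


# -- shared helpers --------------------------------------------------------

def _binom_table(n: int, kmax: int = 5) -> np.ndarray:
    b = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    b[:, 0] = 1
    for v in range(1, n + 1):
        for k in range(1, kmax + 1):
            b[v, k] = b[v - 1, k - 1] + b[v - 1, k]
    return b


@njit(cache=True)
def _count_triangles(dist, thresh):
    n = dist.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = dist[i, j]
            if dij > thresh:
                continue
            for k in range(j + 1, n):
                d = dij
                if dist[i, k] > d:
                    d = dist[i, k]
                if dist[j, k] > d:
                    d = dist[j, k]
                if d <= thresh:
                    m += 1
    return m


@njit(cache=True)
def _fill_triangles(dist, thresh, verts, diam):
    n = dist.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = dist[i, j]
            if dij > thresh:
                continue
            for k in range(j + 1, n):
                d = dij
                if dist[i, k] > d:
                    d = dist[i, k]
                if dist[j, k] > d:
                    d = dist[j, k]
                if d <= thresh:
                    verts[m, 0], verts[m, 1], verts[m, 2] = i, j, k
                    diam[m] = d
                    m += 1


# -- cohomology reduction (default path) -----------------------------------

@njit(cache=True)
def _cofacets(sv, sd, dist, r_enc, binom, n, out_rank, out_diam):
    """Cofacets of the simplex with sorted vertices `sv` and diameter `sd`.

    Enumerating the added vertex in increasing order yields cofacets in
    increasing colex rank.  Returns the count; fills rank and diameter.
    """
    k1 = sv.size
    cnt = 0
    for w in range(n):
        member = False
        for i in range(k1):
            if sv[i] == w:
                member = True
                break
        if member:
            continue
        dmax = sd
        for i in range(k1):
            dd = dist[w, sv[i]]
            if dd > dmax:
                dmax = dd
        if dmax > r_enc:
            continue
        r = 0
        j = 0
        placed = False
        for i in range(k1 + 1):
            if not placed and (j >= k1 or w < sv[j]):
                v = w
                placed = True
            else:
                v = sv[j]
                j += 1
            r += binom[v, i + 1]
        out_rank[cnt] = r
        out_diam[cnt] = dmax
        cnt += 1
    return cnt


@njit(cache=True)
def _cohom_reduce(cols_verts, cols_diam, skip, dist, r_enc, binom, n):
    """Reduce the coboundary matrix; columns already in reverse filtration.

    Pivot = cofacet minimal in (diameter, rank).  Returns, per persistence
    pair, the column index, the death diameter and the death simplex rank.
    """
    m = cols_verts.shape[0]
    pivot_owner = Dict.empty(types.int64, types.int64)
    own_start = np.full(m, -1, dtype=np.int64)
    own_len = np.zeros(m, dtype=np.int64)
    pool_rank = np.empty(1 << 16, dtype=np.int64)
    pool_diam = np.empty(1 << 16, dtype=np.float64)
    pool_top = 0
    pair_col = np.empty(m, dtype=np.int64)
    pair_death = np.empty(m, dtype=np.float64)
    pair_rank = np.empty(m, dtype=np.int64)
    n_pairs = 0
    buf_rank = np.empty(n, dtype=np.int64)
    buf_diam = np.empty(n, dtype=np.float64)
    tmp_rank = np.empty(n, dtype=np.int64)
    tmp_diam = np.empty(n, dtype=np.float64)

    for j in range(m):
        if skip[j]:
            continue
        cnt = _cofacets(cols_verts[j], cols_diam[j], dist, r_enc, binom, n,
                        buf_rank, buf_diam)
        # stable sort by diameter keeps the rank order within ties
        order = np.argsort(buf_diam[:cnt], kind="mergesort")
        cur_rank = buf_rank[:cnt][order].copy()
        cur_diam = buf_diam[:cnt][order].copy()
        ln = cnt
        modified = False
        while ln > 0:
            pr = cur_rank[0]
            pd = cur_diam[0]
            if pr in pivot_owner:
                owner = pivot_owner[pr]
                # fetch the owner's reduced column
                if own_start[owner] >= 0:
                    o_rank = pool_rank[own_start[owner]:
                                       own_start[owner] + own_len[owner]]
                    o_diam = pool_diam[own_start[owner]:
                                       own_start[owner] + own_len[owner]]
                    ol = own_len[owner]
                else:
                    ol = _cofacets(cols_verts[owner], cols_diam[owner], dist,
                                   r_enc, binom, n, tmp_rank, tmp_diam)
                    oorder = np.argsort(tmp_diam[:ol], kind="mergesort")
                    o_rank = tmp_rank[:ol][oorder].copy()
                    o_diam = tmp_diam[:ol][oorder].copy()
                # symmetric difference of (diam, rank)-sorted sequences
                mr = np.empty(ln + ol, dtype=np.int64)
                md = np.empty(ln + ol, dtype=np.float64)
                a = b = c = 0
                while a < ln and b < ol:
                    if cur_rank[a] == o_rank[b]:
                        a += 1
                        b += 1
                    elif (cur_diam[a] < o_diam[b]
                          or (cur_diam[a] == o_diam[b]
                              and cur_rank[a] < o_rank[b])):
                        mr[c] = cur_rank[a]
                        md[c] = cur_diam[a]
                        a += 1
                        c += 1
                    else:
                        mr[c] = o_rank[b]
                        md[c] = o_diam[b]
                        b += 1
                        c += 1
                while a < ln:
                    mr[c] = cur_rank[a]
                    md[c] = cur_diam[a]
                    a += 1
                    c += 1
                while b < ol:
                    mr[c] = o_rank[b]
                    md[c] = o_diam[b]
                    b += 1
                    c += 1
                cur_rank, cur_diam, ln = mr, md, c
                modified = True
            else:
                pivot_owner[pr] = j
                if modified:
                    while pool_top + ln > pool_rank.size:
                        new_r = np.empty(pool_rank.size * 2, dtype=np.int64)
                        new_d = np.empty(pool_rank.size * 2, dtype=np.float64)
                        new_r[:pool_top] = pool_rank[:pool_top]
                        new_d[:pool_top] = pool_diam[:pool_top]
                        pool_rank, pool_diam = new_r, new_d
                    pool_rank[pool_top:pool_top + ln] = cur_rank[:ln]
                    pool_diam[pool_top:pool_top + ln] = cur_diam[:ln]
                    own_start[j] = pool_top
                    own_len[j] = ln
                    pool_top += ln
                pair_col[n_pairs] = j
                pair_death[n_pairs] = pd
                pair_rank[n_pairs] = pr
                n_pairs += 1
                break
    return (pair_col[:n_pairs], pair_death[:n_pairs], pair_rank[:n_pairs])


def _cohom_dimension(verts: np.ndarray, diam: np.ndarray, rank: np.ndarray,
                     cleared_ranks: np.ndarray, dist: np.ndarray,
                     r_enc: float, binom: np.ndarray):
    """One dimension of the cohomology computation.

    Returns (diagram [k x 2], death_ranks) where death_ranks feed the
    clearing of the next dimension up.
    """
    n = dist.shape[0]
    order = np.lexsort((rank, diam))[::-1]  # reverse filtration
    verts_o = np.ascontiguousarray(verts[order])
    diam_o = diam[order]
    skip = np.isin(rank[order], cleared_ranks)
    cols, deaths, death_ranks = _cohom_reduce(
        verts_o, diam_o, skip, dist, r_enc, binom, n)
    births = diam_o[cols]
    keep = deaths > births
    diagram = np.stack([births[keep], deaths[keep]], axis=1)
    return diagram, death_ranks


# -- homology reduction (independent oracle path) --------------------------

@njit(cache=True)
def _hom_reduce(faces, n_rows):
    """Plain Z/2 boundary reduction; columns already in filtration order."""
    m, f = faces.shape
    pivot_owner = np.full(n_rows, -1, dtype=np.int64)
    own_start = np.full(m, -1, dtype=np.int64)
    own_len = np.zeros(m, dtype=np.int64)
    pool = np.empty(1 << 16, dtype=np.int64)
    pool_top = 0
    pair_row = np.empty(min(m, n_rows), dtype=np.int64)
    pair_col = np.empty(min(m, n_rows), dtype=np.int64)
    n_pairs = 0
    for j in range(m):
        cur = faces[j].copy()
        ln = f
        modified = False
        while ln > 0:
            piv = cur[ln - 1]
            owner = pivot_owner[piv]
            if owner < 0:
                pivot_owner[piv] = j
                if modified:
                    while pool_top + ln > pool.size:
                        new_pool = np.empty(pool.size * 2, dtype=np.int64)
                        new_pool[:pool_top] = pool[:pool_top]
                        pool = new_pool
                    pool[pool_top:pool_top + ln] = cur[:ln]
                    own_start[j] = pool_top
                    own_len[j] = ln
                    pool_top += ln
                pair_row[n_pairs] = piv
                pair_col[n_pairs] = j
                n_pairs += 1
                break
            if own_start[owner] >= 0:
                other = pool[own_start[owner]:own_start[owner]
                             + own_len[owner]]
            else:
                other = faces[owner]
            merged = np.empty(ln + other.size, dtype=np.int64)
            a = b = c = 0
            while a < ln and b < other.size:
                va, vb = cur[a], other[b]
                if va < vb:
                    merged[c] = va
                    a += 1
                    c += 1
                elif vb < va:
                    merged[c] = vb
                    b += 1
                    c += 1
                else:
                    a += 1
                    b += 1
            while a < ln:
                merged[c] = cur[a]
                a += 1
                c += 1
            while b < other.size:
                merged[c] = other[b]
                b += 1
                c += 1
            cur = merged
            ln = c
            modified = True
    return pair_row[:n_pairs], pair_col[:n_pairs]


def _enumerate(dist: np.ndarray, dim: int, thresh: float, binom: np.ndarray):
    """All dim-simplices with diameter <= thresh: (verts, diam, rank)."""
    n = dist.shape[0]
    if dim == 1:
        iu = np.triu_indices(n, k=1)
        keep = dist[iu] <= thresh
        i, j = iu[0][keep], iu[1][keep]
        verts = np.stack([i, j], axis=1).astype(np.int64)
        diam = dist[i, j]
    elif dim == 2:
        m = _count_triangles(dist, thresh)
        verts = np.empty((m, 3), dtype=np.int64)
        diam = np.empty(m, dtype=np.float64)
        _fill_triangles(dist, thresh, verts, diam)
    else:
        raise ValueError("only dims 1 and 2 are enumerated")
    rank = np.zeros(verts.shape[0], dtype=np.int64)
    for i in range(dim + 1):
        rank += binom[verts[:, i], i + 1]
    return verts, diam, rank


def _hom_persistence(points: np.ndarray, maxdim: int) -> list[np.ndarray]:
    """Boundary-matrix path (oracle; quadratic-ish, for small inputs)."""
    from itertools import combinations
    dist = squareform(pdist(np.asarray(points, dtype=np.float64)))
    n = dist.shape[0]
    r_enc = dist.max(axis=1).min()
    diagrams = [_dim0_diagram(dist)]
    if maxdim == 0:
        return diagrams
    simplices = {}
    for d in range(1, maxdim + 2):
        items = []
        for vs in combinations(range(n), d + 1):
            vv = np.array(vs)
            dd = dist[np.ix_(vv, vv)].max()
            if dd <= r_enc:
                items.append((dd, vs))
        items.sort()
        simplices[d] = items
    for d in range(1, maxdim + 1):
        pos = {vs: k for k, (_, vs) in enumerate(simplices[d])}
        cols = simplices[d + 1]
        faces = np.empty((len(cols), d + 2), dtype=np.int64)
        for k, (_, vs) in enumerate(cols):
            fp = sorted(pos[tuple(v for idx, v in enumerate(vs) if idx != drop)]
                        for drop in range(d + 2))
            faces[k] = fp
        rows, col_idx = _hom_reduce(faces, len(simplices[d]))
        births = np.array([simplices[d][r][0] for r in rows])
        deaths = np.array([cols[c][0] for c in col_idx])
        keep = deaths > births
        diagrams.append(np.stack([births[keep], deaths[keep]], axis=1)
                        if keep.any() else np.zeros((0, 2)))
    return diagrams


# -- public interface ------------------------------------------------------

def _dim0_diagram(dist: np.ndarray) -> np.ndarray:
    mst = minimum_spanning_tree(dist)
    deaths = np.sort(mst.data)
    return np.concatenate([
        np.stack([np.zeros(deaths.size), deaths], axis=1),
        [[0.0, np.inf]]])


def _mst_edge_ranks(dist: np.ndarray, binom: np.ndarray) -> np.ndarray:
    mst = minimum_spanning_tree(dist).tocoo()
    i = np.minimum(mst.row, mst.col).astype(np.int64)
    j = np.maximum(mst.row, mst.col).astype(np.int64)
    return binom[i, 1] + binom[j, 2]


def rips_persistence(points: np.ndarray, maxdim: int = 2,
                     method: str = "cohomology") -> list[np.ndarray]:
    """Persistence diagrams (birth, death) of the Rips filtration.

    Dimension 0 always contains one essential class with infinite death; in
    dimensions >= 1 every class dies by the enclosing radius, so all bars
    are finite.  Zero-lifespan pairs are omitted.  ``method="homology"``
    uses the direct boundary reduction (small inputs only).
    """
    if maxdim not in (0, 1, 2):
        raise ValueError("maxdim must be 0, 1 or 2")
    if method == "homology":
        return _hom_persistence(points, maxdim)
    points = np.asarray(points, dtype=np.float64)
    dist = squareform(pdist(points))
    n = dist.shape[0]
    diagrams = [_dim0_diagram(dist)]
    if maxdim == 0:
        return diagrams
    binom = _binom_table(n)
    r_enc = dist.max(axis=1).min()
    cleared = np.sort(_mst_edge_ranks(dist, binom))
    for d in range(1, maxdim + 1):
        verts, diam, rank = _enumerate(dist, d, r_enc, binom)
        diagram, death_ranks = _cohom_dimension(
            verts, diam, rank, cleared, dist, r_enc, binom)
        diagrams.append(diagram)
        cleared = np.sort(death_ranks)
    return diagrams


def fibonacci_sphere(n: int) -> np.ndarray:
    """A deterministic uniform covering of the unit two-sphere.

    The Fibonacci (golden-angle) lattice distributes n points with nearly
    equal areas; it is the canonical test cloud for the Betti-(1, 0, 1)
    signature because its covering radius is far smaller than that of a
    random sample of the same size.
    """
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def persistence_summary(embedding: np.ndarray, n_points: int = 100,
                        maxdim: int = 2,
                        rng: np.random.Generator | int | None = None
                        ) -> list[np.ndarray]:
    """Diagrams of a uniform random subsample of an embedding point cloud."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    embedding = np.asarray(embedding, dtype=np.float64)
    if n_points > embedding.shape[0]:
        warnings.warn(
            f"n_points={n_points} exceeds the {embedding.shape[0]} available "
            f"rows; using all rows")
        n_points = embedding.shape[0]
    idx = rng.choice(embedding.shape[0], size=n_points, replace=False)
    return rips_persistence(embedding[idx], maxdim=maxdim)


def lifespans(diagram: np.ndarray) -> np.ndarray:
    """Finite lifespans (death - birth) of one diagram."""
    d = np.asarray(diagram)
    if d.size == 0:
        return np.zeros(0)
    finite = np.isfinite(d[:, 1])
    return d[finite, 1] - d[finite, 0]


def betti_numbers(diagrams: list[np.ndarray],
                  thresholds: np.ndarray) -> tuple[int, ...]:
    """Count classes whose lifespan strictly exceeds the dimension threshold.

    Classes with infinite death (the essential connected component) are
    always counted.
    """
    out = []
    for d, thr in zip(diagrams, thresholds):
        d = np.asarray(d)
        if d.size == 0:
            out.append(0)
            continue
        infinite = int(np.sum(~np.isfinite(d[:, 1])))
        out.append(infinite + int(np.sum(lifespans(d) > thr)))
    return tuple(out)


def prominence_thresholds(diagrams: list[np.ndarray],
                          factor: float = 0.5) -> np.ndarray:
    """Cross-dimension prominence rule for label-free point clouds.

    The threshold for dimensions >= 1 is ``factor`` times the longest finite
    lifespan found in any dimension >= 1: genuinely long-lived classes stand
    clear of it while sampling-noise bars fall below.  Dimension 0 counts
    only essential (never-dying) components, since without a null model the
    finite merge events of a connected sample are indistinguishable from
    sampling noise.
    """
    longest = 0.0
    for d in diagrams[1:]:
        ls = lifespans(d)
        if ls.size:
            longest = max(longest, float(ls.max()))
    thresholds = np.full(len(diagrams), factor * longest)
    thresholds[0] = np.inf
    return thresholds


def shuffled_null_thresholds(recipe, n_shuffles: int, maxdim: int = 2,
                             base_seed: int = 0) -> np.ndarray:
    """Null lifespan thresholds from shuffled-label refits.

    ``recipe(seed)`` must refit the embedding pipeline with context labels
    permuted by the given seed and return the resulting point cloud.  The
    threshold for each dimension is the maximum lifespan observed across the
    shuffled runs (monotone non-decreasing in ``n_shuffles``).

    Shuffled refits sometimes produce *no* cycles at all in dimension 2 at
    desk-scale subsamples, which would leave a zero threshold and count
    arbitrarily small sampling-noise bars as real.  Because noise lifespans
    in Rips filtrations shrink with dimension, thresholds for dimensions
    >= 2 are floored by the threshold of the dimension below; the floor is
    inactive whenever the null itself produced bars of the usual ordering.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    thresholds = np.zeros(maxdim + 1)
    for s in range(n_shuffles):
        points = recipe(base_seed + s)
        diagrams = rips_persistence(np.asarray(points), maxdim=maxdim)
        for d in range(maxdim + 1):
            ls = lifespans(diagrams[d])
            if ls.size:
                thresholds[d] = max(thresholds[d], float(ls.max()))
    for d in range(2, maxdim + 1):
        thresholds[d] = max(thresholds[d], thresholds[d - 1])
    return thresholds
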