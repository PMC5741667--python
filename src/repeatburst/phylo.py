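"""Neighbor-joining phylogeny with midpoint rooting.

Classic Saitou-Nei agglomeration (Studier-Keppler Q criterion). Ties in
the Q matrix are broken by the smallest (row, column) index pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sibling branch so the joined pair's path length is preserved. The
resulting unrooted tree is rooted at the midpoint of its longest
leaf-to-leaf path and returned as a ``Bio.Phylo`` tree.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from Bio.Phylo.BaseTree import Clade, Tree

from .errors import InputError, InsufficientDataError
from .landscape import DistanceMatrix


def _nj_graph(labels: list[str], D: np.ndarray) -> nx.Graph:
    n = len(labels)
    g = nx.Graph()
    active = list(range(n))
    names = {i: labels[i] for i in range(n)}
    D = D.astype(float).copy()
    next_inner = 1
    # grow D in place by appending rows/columns for internal nodes
    size = n
    while len(active) > 2:
        N = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (N - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties by smallest (i, j) position pair (row-major scan)
        flat = np.argmin(Q)
        ai, aj = divmod(int(flat), N)
        if ai > aj:
            ai, aj = aj, ai
        i, j = int(idx[ai]), int(idx[aj])
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (N - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = size
        names[u] = f"inner_{next_inner}"
        next_inner += 1
        newcol = np.zeros(size + 1)
        for m in active:
            if m in (i, j):
                continue
            newcol[m] = 0.5 * (D[i, m] + D[j, m] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, :size] = newcol[:size]
        D[:size, u] = newcol[:size]
        size += 1
        g.add_edge(names[i], names[u], length=float(li))
        g.add_edge(names[j], names[u], length=float(lj))
        active = [m for m in active if m not in (i, j)] + [u]
    a, b = active
    g.add_edge(names[a], names[b], length=float(max(D[a, b], 0.0)))
    return g


def midpoint_root(g: nx.Graph, leaf_names: list[str]) -> Tree:
    """Root an unrooted weighted tree at the midpoint of its diameter path."""
    # farthest leaf pair (ties: lexicographic name pair)
    best = None
    for a in sorted(leaf_names):
        lengths = nx.single_source_dijkstra_path_length(g, a, weight="length")
        for b in sorted(leaf_names):
            if b <= a:
                continue
            d = lengths[b]
            if best is None or d > best[0] + 1e-15:
                best = (d, a, b)
    assert best is not None
    total, a, b = best
    path = nx.shortest_path(g, a, b, weight="length")
    half = total / 2.0
    cum = 0.0
    g2 = g.copy()
    root = "__root__"
    for u, v in zip(path, path[1:]):
        w = g2[u][v]["length"]
        if cum + w >= half - 1e-15:
            g2.remove_edge(u, v)
            g2.add_edge(u, root, length=half - cum)
            g2.add_edge(root, v, length=w - (half - cum))
            break
        cum += w

    leaf_set = set(leaf_names)

    def build(node: str, parent: str | None, length: float | None) -> Clade:
        children = [n for n in g2.neighbors(node) if n != parent]
        clade = Clade(
            branch_length=length,
            name=node if node in leaf_set else None,
        )
        clade.clades = [build(c, node, float(g2[node][c]["length"])) for c in children]
        return clade

    return Tree(root=build(root, None, None), rooted=True)


def nj_tree(dm: DistanceMatrix | tuple[list[str], np.ndarray]) -> Tree:
    """Neighbor-joining tree from a distance matrix, midpoint rooted."""
    if isinstance(dm, DistanceMatrix):
        labels, D = dm.labels, dm.values
    else:
        labels, D = dm
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise InputError("distance matrix shape does not match labels")
    if len(labels) < 3:
        raise InsufficientDataError("need at least 3 leaves")
    if not np.allclose(D, D.T, atol=1e-12):
        raise InputError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise InputError("distance matrix diagonal is not zero")
    g = _nj_graph(list(labels), D)
    return midpoint_root(g, list(labels))


def leaf_depths(tree: Tree) -> dict[str, float]:
    """Root-to-leaf path lengths."""
    out: dict[str, float] = {}

    def walk(clade: Clade, depth: float) -> None:
        d = depth + (clade.branch_length or 0.0)
        if clade.is_terminal():
            out[clade.name] = d
        for c in clade.clades:
            walk(c, d)

    for c in tree.root.clades:
        walk(c, 0.0)
    return out


def simulate_additive_matrix(
    n_leaves: int, seed: int = 0, min_branch: float = 0.05, max_branch: float = 1.0
) -> tuple[list[str], np.ndarray, nx.Graph]:
    """Random unrooted binary tree and its (exactly additive) leaf matrix.

    Useful as an oracle: neighbor joining recovers the generating topology
    and branch lengths exactly from an additive matrix.
    """
    if n_leaves < 3:
        raise InputError("need at least 3 leaves")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    g = nx.Graph()
    g.add_edge("L1", "c0", length=blen())
    g.add_edge("L2", "c0", length=blen())
    g.add_edge("L3", "c0", length=blen())
    inner = 1
    for i in range(4, n_leaves + 1):
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["length"]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = f"c{inner}"
        inner += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=w - split)
        g.add_edge(mid, f"L{i}", length=blen())
    labels = [f"L{i}" for i in range(1, n_leaves + 1)]
    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        lengths = nx.single_source_dijkstra_path_length(g, a, weight="length")
        for j, b in enumerate(labels):
            D[i, j] = lengths[b]
    return labels, D, g
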