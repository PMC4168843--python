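"""Neighbor-joining tree construction (Saitou-Nei agglomeration).

At each step the pair (i, j) minimizing

    Q(i, j) = (r - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined (r = number of active nodes), with branch lengths from the
standard two-point formulas; ties are broken by the smallest (i, j) index
pair in the current node order. On an additive (tree-like) matrix the
method recovers the generating tree exactly. Negative branch lengths can be
clamped to zero with the deficit moved onto the sister branch, preserving
tip-to-tip path lengths.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .distances import FLAG_OK, DistanceMatrix
from .errors import IncompleteMatrixError, ParameterError
from .seqio import TreeNode


def drop_incomplete(matrix: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Greedily drop the fewest sequences needed for a complete matrix.

    Repeatedly removes the label with the most missing/saturated pairs
    (ties by label order) until no incomplete pair remains. Returns the
    reduced matrix and the dropped labels.
    """
    bad = ~np.isfinite(matrix.d) | (matrix.flags != FLAG_OK)
    np.fill_diagonal(bad, False)
    keep = list(range(len(matrix.labels)))
    dropped: list[str] = []
    while True:
        sub = bad[np.ix_(keep, keep)]
        per_node = sub.sum(axis=1)
        worst = int(per_node.argmax())
        if per_node[worst] == 0:
            break
        dropped.append(matrix.labels[keep[worst]])
        keep.pop(worst)
    return matrix.submatrix([matrix.labels[i] for i in keep]), dropped


def neighbor_joining(matrix: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Build the NJ tree of a complete distance matrix (>= 3 labels).

    Raises :class:`IncompleteMatrixError` listing the offending pairs when
    the matrix has missing or saturated entries; use :func:`drop_incomplete`
    upstream to obtain a complete submatrix.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 labels")
    incomplete = matrix.incomplete_pairs()
    if incomplete:
        raise IncompleteMatrixError(
            f"matrix has {len(incomplete)} missing/saturated pairs",
            offending_pairs=incomplete,
        )

    D = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in matrix.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = smallest (i, j) pair on ties
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)

        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = duk
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    # connect the last three nodes through a central (trifurcating) node
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def tree_path_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path-length matrix of a tree (labels in leaf order)."""
    # adjacency over all nodes, then BFS from each tip
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}

    def walk(node: TreeNode):
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf:
            labels[nid] = node.label
        for child, length in node.children:
            cid = id(child)
            adj.setdefault(cid, []).append((nid, length))
            adj[nid].append((cid, length))
            walk(child)

    walk(tree)
    tips = [id(leaf) for leaf in tree.leaves()]
    tip_index = {t: k for k, t in enumerate(tips)}
    m = len(tips)
    out = np.zeros((m, m))
    for t in tips:
        dist = {t: 0.0}
        stack = [t]
        while stack:
            cur = stack.pop()
            for nb, length in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + length
                    stack.append(nb)
        for other in tips:
            out[tip_index[t], tip_index[other]] = dist[other]
    return [labels[t] for t in tips], out
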