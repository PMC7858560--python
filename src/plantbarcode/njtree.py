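"""Unrooted neighbour-joining trees.

The NJ algorithm (Saitou & Nei) joins, at each step, the pair minimising
the rate-corrected Q criterion, with deterministic lexicographic
tie-breaking so repeated runs and label permutations give the same
unrooted topology. Trees are held in a small adjacency-map container that
supports Newick serialisation, patristic distances, bipartition (split)
extraction and induced subtrees — the substrates for monophyly testing
and phylogeographic scoring.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Callable, Iterable

import numpy as np

from .distmodel import DistanceMatrix

Node = "str | int"  # leaves are labelled by strings, internal nodes by ints


class PhyloTree:
    """Unrooted tree with branch lengths: leaves are string labels, internal nodes ints."""

    def __init__(self) -> None:
        self.adj: dict = {}
        self._next_internal = 0

    # -- construction -------------------------------------------------------

    def _ensure_node(self, node) -> None:
        if node not in self.adj:
            self.adj[node] = {}
            if isinstance(node, int):
                self._next_internal = max(self._next_internal, node + 1)

    def new_internal(self) -> int:
        node = self._next_internal
        self._ensure_node(node)
        return node

    def add_edge(self, u, v, length: float) -> None:
        self._ensure_node(u)
        self._ensure_node(v)
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t._next_internal = self._next_internal
        return t

    # -- basic queries -------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.adj if isinstance(n, str))

    def degree(self, node) -> int:
        return len(self.adj[node])

    @property
    def edges(self) -> list[tuple]:
        return list(self._edge_iter())

    def _edge_iter(self):
        done = set()
        for u in self.adj:
            for v, length in self.adj[u].items():
                pair = frozenset(((type(u).__name__, u), (type(v).__name__, v)))
                if pair in done:
                    continue
                done.add(pair)
                yield u, v, length

    @property
    def total_length(self) -> float:
        return sum(length for _, _, length in self._edge_iter())

    # -- topology operations ---------------------------------------------------

    def _side_leaves(self, u, v) -> frozenset:
        """Leaf labels reachable from v when the edge (u, v) is removed."""
        out = []
        stack = [v]
        seen = {u, v}
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.append(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    def bipartitions(self) -> set:
        """Non-trivial splits, one per internal edge, canonically represented.

        Each split is the frozenset of leaf labels on the side NOT
        containing the lexicographically smallest leaf.
        """
        leaves = set(self.leaves)
        if not leaves:
            return set()
        anchor = min(leaves)
        out = set()
        for u, v, _ in self._edge_iter():
            side = self._side_leaves(u, v)
            if anchor in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    def clade_sides(self) -> set:
        """All edge sides (including trivial singleton/cofull sides) as leaf-label sets."""
        out = set()
        for u, v, _ in self._edge_iter():
            side = self._side_leaves(u, v)
            out.add(side)
            out.add(frozenset(set(self.leaves) - side))
        return out

    def patristic_distances(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaf pairs."""
        labels = self.leaves
        index = {lbl: i for i, lbl in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))
        for src in labels:
            dist = {src: 0.0}
            dq = deque([src])
            while dq:
                node = dq.popleft()
                for nb, length in self.adj[node].items():
                    if nb not in dist:
                        dist[nb] = dist[node] + length
                        dq.append(nb)
            for lbl in labels:
                values[index[src], index[lbl]] = dist[lbl]
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(labels, values, "patristic")

    def extract_subtree(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on a leaf subset, with degree-2 nodes suppressed."""
        keep = set(keep)
        missing = keep - set(self.leaves)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        t = self.copy()
        # iteratively strip non-kept leaves and dangling internals
        changed = True
        while changed:
            changed = False
            for node in list(t.adj):
                if t.degree(node) <= 1 and not (isinstance(node, str) and node in keep):
                    for nb in list(t.adj[node]):
                        del t.adj[nb][node]
                    del t.adj[node]
                    changed = True
        t._suppress_degree_two(min_leaves=3)
        return t

    def _suppress_degree_two(self, min_leaves: int = 3) -> None:
        if self.n_leaves < min_leaves:
            return
        for node in list(self.adj):
            if isinstance(node, int) and node in self.adj and self.degree(node) == 2:
                (a, la), (b, lb) = self.adj[node].items()
                del self.adj[a][node]
                del self.adj[b][node]
                del self.adj[node]
                self.adj[a][b] = la + lb
                self.adj[b][a] = la + lb

    # -- serialisation -----------------------------------------------------------

    def to_newick(self, label_fn: Callable[[str], str] = lambda s: s) -> str:
        nodes = list(self.adj)
        if not nodes:
            raise ValueError("empty tree")
        if len(nodes) == 1:
            return f"{label_fn(nodes[0])};"
        internals = [n for n in self.adj if isinstance(n, int)]
        if internals:
            # deterministic root: the internal node adjacent to the smallest leaf,
            # falling back to the smallest internal id
            anchor = min(self.leaves)
            root = next((nb for nb in self.adj[anchor] if isinstance(nb, int)), min(internals))
        else:
            # two leaves joined by a bare edge: emit a root joining them
            a, b = sorted(nodes)
            length = self.adj[a][b]
            return f"({label_fn(a)}:{length:.6f},{label_fn(b)}:0.000000);"

        def render(node, parent) -> str:
            children = sorted(
                (nb for nb in self.adj[node] if nb != parent),
                key=lambda x: (not isinstance(x, str), str(x)),
            )
            if not children:  # leaf
                return label_fn(node)
            inner = ",".join(
                f"{render(ch, node)}:{self.adj[node][ch]:.6f}" for ch in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def nj_build(dm: DistanceMatrix, *, allow_negative_branches: bool = False) -> PhyloTree:
    """Neighbour-joining tree from a distance matrix (Saitou & Nei).

    Iteratively joins the pair minimising Q_ij = (r-2) d_ij - R_i - R_j;
    branch lengths follow the standard rate-corrected formulas. Ties in Q
    are broken by the lexicographically smallest pair of cluster labels
    (each cluster is keyed by its smallest leaf). Negative branch lengths
    are clamped to zero with the deficit moved to the sibling branch so
    the joined pair's total length is preserved; ``allow_negative_branches``
    disables the clamp. UNDEFINED matrix entries are a hard error.
    """
    if dm.n_undefined_pairs:
        raise ValueError(
            f"{dm.n_undefined_pairs} UNDEFINED pair(s) in distance matrix; "
            "resolve saturation (e.g. more data or an explicit cap) before NJ"
        )
    tree = PhyloTree()
    labels = list(dm.labels)
    if dm.n < 3:
        warnings.warn(f"NJ on {dm.n} leaves is trivial", stacklevel=2)
        if dm.n == 1:
            tree._ensure_node(labels[0])
        elif dm.n == 2:
            u = tree.new_internal()
            half = float(dm.values[0, 1]) / 2.0
            tree.add_edge(u, labels[0], half)
            tree.add_edge(u, labels[1], half)
        return tree

    D = dm.values.astype(float).copy()
    nodes: list = list(labels)  # active cluster handles (leaf label or internal id)
    key: dict = {lbl: lbl for lbl in labels}  # smallest leaf label in each cluster

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if allow_negative_branches:
            return li, lj
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        iu = np.triu_indices(r, 1)
        qmin = Q[iu].min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cands = [
            (i, j)
            for i, j in zip(*iu)
            if Q[i, j] <= qmin + tol
        ]
        i, j = min(cands, key=lambda p: tuple(sorted((key[nodes[p[0]]], key[nodes[p[1]]]))))
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        u = tree.new_internal()
        tree.add_edge(u, nodes[i], li)
        tree.add_edge(u, nodes[j], lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D_next = np.zeros((r - 1, r - 1))
        D_next[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D_next[-1, : r - 2] = D_next[: r - 2, -1] = d_new[keep]
        key[u] = min(key[nodes[i]], key[nodes[j]])
        nodes = [nodes[k] for k in keep] + [u]
        D = D_next

    # final three clusters joined at a trifurcating hub
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if not allow_negative_branches:
        la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    hub = tree.new_internal()
    tree.add_edge(hub, a, la)
    tree.add_edge(hub, b, lb)
    tree.add_edge(hub, c, lc)
    return tree


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Module-level alias for :meth:`PhyloTree.patristic_distances`."""
    return tree.patristic_distances()


def bipartitions(tree: PhyloTree) -> set:
    """Module-level alias for :meth:`PhyloTree.bipartitions`."""
    return tree.bipartitions()
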