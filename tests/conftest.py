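"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from plantbarcode.njtree import PhyloTree


def random_binary_tree(labels, rng, low=0.05, high=1.0) -> PhyloTree:
    """Random unrooted binary tree with branch lengths ~ U(low, high)."""
    t = PhyloTree()
    nodes = list(labels)
    if len(nodes) == 1:
        t._ensure_node(nodes[0])
        return t
    if len(nodes) == 2:
        t.add_edge(nodes[0], nodes[1], float(rng.uniform(low, high)))
        return t
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        u = t.new_internal()
        t.add_edge(u, nodes[i], float(rng.uniform(low, high)))
        t.add_edge(u, nodes[j], float(rng.uniform(low, high)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [u]
    hub = t.new_internal()
    for n in nodes:
        t.add_edge(hub, n, float(rng.uniform(low, high)))
    return t


def steiner_monophyly(tree: PhyloTree, members: frozenset) -> bool:
    """Independent monophyly oracle: connected-subtree check.

    The Steiner subgraph spanning the member leaves must contain no
    foreign leaf and attach to the rest of the tree through at most one
    node.
    """
    members = frozenset(members)
    if len(members) <= 1 or len(members) >= tree.n_leaves:
        return True

    def path(a, b):
        prev = {a: None}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nb in tree.adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        out = []
        node = b
        while node is not None:
            out.append(node)
            node = prev[node]
        return out

    span: set = set()
    mlist = sorted(members)
    for a, b in itertools.combinations(mlist, 2):
        span.update(path(a, b))
    foreign_leaves = {n for n in span if isinstance(n, str)} - members
    if foreign_leaves:
        return False
    attachment = {
        n for n in span if any(nb not in span for nb in tree.adj[n])
    }
    return len(attachment) <= 1


def brute_force_parsimony(tree: PhyloTree, states: dict) -> int:
    """Exhaustive minimum-change count over all internal state labelings."""
    internals = [n for n in tree.adj if isinstance(n, int)]
    values = sorted(set(states.values()))
    best = None
    for combo in itertools.product(values, repeat=len(internals)):
        lab = dict(zip(internals, combo))
        lab.update(states)
        cost = sum(1 for u, v, _ in tree._edge_iter() if lab[u] != lab[v])
        best = cost if best is None else min(best, cost)
    return best


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
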