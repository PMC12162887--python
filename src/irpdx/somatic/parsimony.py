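"""Maximum-parsimony trees over binary mutation matrices.

Sample relatedness is reconstructed from the binary mutation matrix by
minimum-change (Fitch) parsimony.  Two search modes are provided:

- exhaustive enumeration of all unrooted binary topologies (feasible up to
  ~7 leaves; (2n-5)!! topologies), returning every optimal tree;
- a parsimony-ratchet heuristic (iterated character up-weighting with
  nearest-neighbour-interchange hill climbing) for larger label sets.

Ancestral states are assigned by accelerated transformation (acctran):
a unit-cost Sankoff pass rooted at the all-zero outgroup, with ties in the
preorder state choice resolved towards placing changes on the earlier
(rootward) branch.  Branch changes always sum to the parsimony score.

Trees are handled internally as adjacency dicts over integer nodes (leaves
``0..n-1`` indexing the label list, internal nodes from ``n`` upward).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Adjacency = dict[int, set]


# ---------------------------------------------------------------------------
# basic tree plumbing


def _edges(adj: Adjacency) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _copy(adj: Adjacency) -> Adjacency:
    return {u: set(vs) for u, vs in adj.items()}


def _star3(next_id: int) -> Adjacency:
    c = next_id
    return {0: {c}, 1: {c}, 2: {c}, c: {0, 1, 2}}


def _insert_leaf(adj: Adjacency, leaf: int, edge: tuple[int, int], new_internal: int) -> Adjacency:
    u, v = edge
    out = _copy(adj)
    out[u].discard(v)
    out[v].discard(u)
    out[new_internal] = {u, v, leaf}
    out[u].add(new_internal)
    out[v].add(new_internal)
    out[leaf] = {new_internal}
    return out


def all_topologies(n_leaves: int):
    """Yield every unrooted binary topology over leaves 0..n_leaves-1."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    trees = [_star3(n_leaves)]
    for leaf in range(3, n_leaves):
        new_internal = n_leaves + leaf - 2
        trees = [
            _insert_leaf(t, leaf, e, new_internal) for t in trees for e in _edges(t)
        ]
    yield from trees


def random_tree(n_leaves: int, rng: np.random.Generator) -> Adjacency:
    """Random stepwise-addition topology."""
    adj = _star3(n_leaves)
    for leaf in range(3, n_leaves):
        edges = _edges(adj)
        e = edges[rng.integers(len(edges))]
        adj = _insert_leaf(adj, leaf, e, n_leaves + leaf - 2)
    return adj


def tree_splits(adj: Adjacency, n_leaves: int) -> frozenset:
    """Canonical identity of an unrooted tree: its nontrivial splits.

    Each split is the frozenset of leaves on the side not containing leaf 0.
    """
    splits = set()
    for u, v in _edges(adj):
        # leaves reachable from v without crossing u
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


def _rooted_order(adj: Adjacency, root_leaf: int = 0):
    """Postorder of (node, children) pairs for the tree rooted at the
    neighbour of ``root_leaf`` (the root leaf itself is excluded)."""
    (start,) = adj[root_leaf]
    order = []
    stack = [(start, root_leaf)]
    visit = []
    while stack:
        node, parent = stack.pop()
        visit.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(visit):
        children = [nb for nb in adj[node] if nb != parent]
        order.append((node, parent, children))
    return order  # postorder: children before parents


# ---------------------------------------------------------------------------
# Fitch scoring


def fitch_score(
    adj: Adjacency,
    states: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Fitch small-parsimony score of an unrooted tree.

    ``states`` is a (n_leaves, n_characters) 0/1 array; ``weights`` an
    optional per-character weight vector.
    """
    states = np.asarray(states)
    n_leaves, n_chars = states.shape
    if weights is None:
        weights = np.ones(n_chars)
    leaf_mask = (1 << states.astype(np.uint8)).astype(np.uint8)
    masks: dict[int, np.ndarray] = {}
    score = np.zeros(n_chars)
    for node, _parent, children in _rooted_order(adj):
        if not children:  # leaf
            masks[node] = leaf_mask[node]
            continue
        cur = masks[children[0]]
        for ch in children[1:]:
            inter = cur & masks[ch]
            union = cur | masks[ch]
            empty = inter == 0
            score += weights * empty
            cur = np.where(empty, union, inter)
        masks[node] = cur
    # fold in the root leaf itself
    (start,) = adj[0]
    empty = (masks[start] & leaf_mask[0]) == 0
    score += weights * empty
    return float(score.sum())


# ---------------------------------------------------------------------------
# search


def _nni_neighbors(adj: Adjacency, n_leaves: int):
    """Yield all nearest-neighbour-interchange rearrangements."""
    for u, v in _edges(adj):
        if u < n_leaves or v < n_leaves:
            continue  # internal edges only
        a, b = sorted(adj[u] - {v})
        c, d = sorted(adj[v] - {u})
        for x, y in ((b, c), (b, d)):
            out = _copy(adj)
            out[u].discard(x)
            out[x].discard(u)
            out[v].discard(y)
            out[y].discard(v)
            out[u].add(y)
            out[y].add(u)
            out[v].add(x)
            out[x].add(v)
            yield out


def _spr_neighbors(adj: Adjacency, n_leaves: int):
    """Yield all subtree-prune-and-regraft rearrangements (superset of NNI)."""
    for u in adj:
        for v in list(adj[u]):
            if len(adj[v]) != 3:
                continue  # attachment node must be internal
            # subtree on u's side of edge (u, v)
            sub = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y != v and y not in sub:
                        sub.add(y)
                        stack.append(y)
            a, b = sorted(adj[v] - {u})
            pruned = _copy(adj)
            for nb in (u, a, b):
                pruned[nb].discard(v)
            pruned[a].add(b)
            pruned[b].add(a)
            rest = [n for n in pruned if n not in sub and n != v]
            for x in rest:
                for y in pruned[x]:
                    if y < x or y in sub or y == v:
                        continue
                    if {x, y} == {a, b}:
                        continue  # would recreate the original tree
                    out = _copy(pruned)
                    del out[v]
                    out[x].discard(y)
                    out[y].discard(x)
                    out[v] = {x, y, u}
                    out[x].add(v)
                    out[y].add(v)
                    out[u].add(v)
                    yield out


def _hill_climb(adj, states, weights, n_leaves):
    cur, cur_score = adj, fitch_score(adj, states, weights)
    while True:
        best, best_score = None, cur_score
        for cand in _spr_neighbors(cur, n_leaves):
            s = fitch_score(cand, states, weights)
            if s < best_score:
                best, best_score = cand, s
        if best is None:
            return cur, cur_score
        cur, cur_score = best, best_score


def exhaustive_search(states: np.ndarray) -> tuple[float, list[Adjacency]]:
    """Score every unrooted topology; return optimum and all optimal trees."""
    states = np.asarray(states)
    n_leaves = states.shape[0]
    if n_leaves > 8:
        raise ValueError("exhaustive search limited to 8 leaves")
    best_score, best = np.inf, []
    seen = set()
    for adj in all_topologies(n_leaves):
        s = fitch_score(adj, states)
        if s < best_score - 1e-9:
            best_score, best, seen = s, [adj], {tree_splits(adj, n_leaves)}
        elif abs(s - best_score) < 1e-9:
            key = tree_splits(adj, n_leaves)
            if key not in seen:
                seen.add(key)
                best.append(adj)
    return float(best_score), best


def ratchet_search(
    states: np.ndarray,
    n_iter: int = 50,
    upweight_frac: float = 0.25,
    seed: int = 0,
) -> tuple[float, list[Adjacency]]:
    """Parsimony-ratchet heuristic search.

    Each iteration up-weights a random ``upweight_frac`` of characters
    (weight 2), hill-climbs under the perturbed weights, then hill-climbs
    under unit weights; improvements are accepted, ties are collected.
    """
    states = np.asarray(states)
    n_leaves, n_chars = states.shape
    rng = np.random.default_rng(seed)
    unit = np.ones(n_chars)
    cur = random_tree(n_leaves, rng)
    cur, cur_score = _hill_climb(cur, states, unit, n_leaves)
    best_score = cur_score
    best = [cur]
    best_keys = {tree_splits(cur, n_leaves)}
    for _ in range(n_iter):
        w = unit + (rng.random(n_chars) < upweight_frac)
        t, _ = _hill_climb(cur, states, w, n_leaves)
        t, s = _hill_climb(t, states, unit, n_leaves)
        if s < best_score - 1e-9:
            best_score, best = s, [t]
            best_keys = {tree_splits(t, n_leaves)}
            cur = t
        elif abs(s - best_score) < 1e-9:
            key = tree_splits(t, n_leaves)
            if key not in best_keys:
                best_keys.add(key)
                best.append(t)
            cur = t
    return float(best_score), best


def strict_consensus_splits(trees: list[Adjacency], n_leaves: int) -> frozenset:
    """Splits present in every tree (strict consensus)."""
    split_sets = [tree_splits(t, n_leaves) for t in trees]
    return frozenset(frozenset.intersection(*split_sets)) if split_sets else frozenset()


# ---------------------------------------------------------------------------
# public result type


@dataclass
class ParsimonyTree:
    """Best parsimony tree(s) over a binary mutation matrix."""

    labels: list[str]
    score: float
    trees: list[Adjacency]
    method: str
    consensus_splits: frozenset = field(default_factory=frozenset)

    @property
    def best(self) -> Adjacency:
        return self.trees[0]

    def splits(self, which: int = 0) -> frozenset:
        return tree_splits(self.trees[which], len(self.labels))

    def newick(self, which: int = 0, branch_lengths: dict | None = None, root_label: str | None = None) -> str:
        return tree_to_newick(
            self.trees[which], self.labels, branch_lengths=branch_lengths, root_label=root_label
        )


def parsimony_tree(
    matrix: pd.DataFrame,
    method: str = "auto",
    ratchet_iterations: int = 50,
    upweight_frac: float = 0.25,
    seed: int = 0,
) -> ParsimonyTree:
    """Search for minimum-change trees over a samples x variants 0/1 matrix.

    ``method`` is "exhaustive", "ratchet" or "auto" (exhaustive for <= 6
    leaves, ratchet above).  All equally parsimonious trees found are
    returned, along with their strict consensus splits.
    """
    labels = list(matrix.index)
    states = matrix.to_numpy(dtype=np.uint8)
    if len(labels) < 3:
        raise ValueError("parsimony search needs at least 3 samples")
    if not np.isin(states, [0, 1]).all():
        raise ValueError("mutation matrix must be binary")
    if method == "auto":
        method = "exhaustive" if len(labels) <= 6 else "ratchet"
    if method == "exhaustive":
        score, trees = exhaustive_search(states)
    elif method == "ratchet":
        score, trees = ratchet_search(
            states, n_iter=ratchet_iterations, upweight_frac=upweight_frac, seed=seed
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    consensus = strict_consensus_splits(trees, len(labels))
    return ParsimonyTree(labels=labels, score=score, trees=trees, method=method, consensus_splits=consensus)


# ---------------------------------------------------------------------------
# acctran ancestral states


def acctran_states(
    tree: ParsimonyTree | Adjacency,
    matrix: pd.DataFrame,
    outgroup: str = "outgroup",
    which: int = 0,
) -> pd.DataFrame:
    """Per-branch state changes under accelerated transformation.

    The tree is rooted at the outgroup leaf.  For each character a
    unit-cost Sankoff down-pass computes subtree costs and a preorder pass
    assigns states, breaking ties towards a change on the current branch
    (changes as early/rootward as possible).  Returns a table with columns
    ``parent, child, changes`` (node names: sample labels for leaves,
    ``node<i>`` for internal nodes); ``changes`` sums to the parsimony
    score of the tree.
    """
    if isinstance(tree, ParsimonyTree):
        labels, adj = tree.labels, tree.trees[which]
    else:
        labels, adj = list(matrix.index), tree
    if list(matrix.index) != labels:
        matrix = matrix.reindex(labels)
        if matrix.isna().any().any():
            raise ValueError("tree leaves do not match matrix rows")
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among the matrix rows")
    states = matrix.to_numpy(dtype=np.uint8)
    n_leaves, n_chars = states.shape
    og = labels.index(outgroup)

    # reroot the traversal at the outgroup leaf
    (start,) = adj[og]
    order = []
    stack = [(start, og)]
    visit = []
    while stack:
        node, parent = stack.pop()
        visit.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(visit):
        children = [nb for nb in adj[node] if nb != parent]
        order.append((node, parent, children))

    inf = np.inf
    cost: dict[int, np.ndarray] = {}
    for node, _parent, children in order:
        if not children:
            c = np.full((n_chars, 2), inf)
            c[np.arange(n_chars), states[node]] = 0.0
        else:
            c = np.zeros((n_chars, 2))
            for ch in children:
                cc = cost[ch]
                # min over child state t of cc[:, t] + (s != t)
                c[:, 0] += np.minimum(cc[:, 0], cc[:, 1] + 1)
                c[:, 1] += np.minimum(cc[:, 1], cc[:, 0] + 1)
        cost[node] = c

    assign: dict[int, np.ndarray] = {og: states[og].astype(np.int64)}
    children_of = {node: children for node, _p, children in order}
    # preorder: parents before children
    for node, parent, _children in reversed(order):
        pstate = assign[parent]
        c = cost[node]
        stay = c[np.arange(n_chars), pstate]
        move = c[np.arange(n_chars), 1 - pstate] + 1
        # acctran: on ties prefer the change on this (rootward) branch
        take_move = move <= stay
        assign[node] = np.where(take_move, 1 - pstate, pstate)

    def name(node: int) -> str:
        return labels[node] if node < n_leaves else f"node{node}"

    rows = []
    for node, parent, _children in order:
        changes = int((assign[node] != assign[parent]).sum())
        rows.append((name(parent), name(node), changes))
    return pd.DataFrame(rows, columns=["parent", "child", "changes"])


# ---------------------------------------------------------------------------
# newick export


def tree_to_newick(
    adj: Adjacency,
    labels: list[str],
    branch_lengths: dict | None = None,
    root_label: str | None = None,
) -> str:
    """Newick string, rooted at ``root_label`` (default: first label).

    ``branch_lengths`` optionally maps (parent_name, child_name) pairs --
    as produced by :func:`acctran_states` -- to branch annotations.
    """
    n_leaves = len(labels)
    root = labels.index(root_label) if root_label is not None else 0

    def name(node: int) -> str:
        return labels[node] if node < n_leaves else ""

    def blen(parent: int, child: int) -> str:
        if branch_lengths is None:
            return ""
        pn = labels[parent] if parent < n_leaves else f"node{parent}"
        cn = labels[child] if child < n_leaves else f"node{child}"
        val = branch_lengths.get((pn, cn), branch_lengths.get((cn, pn)))
        return "" if val is None else f":{val}"

    def render(node: int, parent: int) -> str:
        children = [nb for nb in adj[node] if nb != parent]
        if not children:
            return name(node) + blen(parent, node)
        inner = ",".join(render(ch, node) for ch in sorted(children))
        return f"({inner})" + name(node) + blen(parent, node)

    (start,) = (adj[root] if len(adj[root]) == 1 else (next(iter(adj[root])),))
    inner = render(start, root)
    return f"({name(root)},{inner});"
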