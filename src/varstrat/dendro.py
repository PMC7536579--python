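"""Binary merge trees, Newick export, tanglegram alignment and entanglement.

A :class:`Dendrogram` wraps a rooted binary tree with ultrametric node
heights (leaves at height 0, merges at the linkage height).  Child order is
presentation, not semantics: rotating branches changes the leaf order drawn
in a tanglegram but not the clustering, so the untangling search only ever
swaps children.

Entanglement between two trees over the same leaves is the normalized
leaf-rank discordance

    sum_s |rank_a(s) - rank_b(s)|^L  /  sum_i |i - (n + 1 - i)|^L ,

i.e. the observed L-norm discrepancy divided by its value for an order
against its own reversal (the anti-aligned worst case), giving a coefficient
in [0, 1] with 0 for perfectly aligned leaf orders.  L defaults to 1.5, the
convention of the tanglegram method family.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DendroNode",
    "Dendrogram",
    "Tanglegram",
    "restrict_to_shared",
    "entanglement",
    "untangle",
    "exhaustive_minimum",
]


class DendroNode:
    """Leaf (label, height 0) or internal node (two children, merge height)."""

    __slots__ = ("label", "height", "left", "right")

    def __init__(self, label=None, height=0.0, left=None, right=None):
        self.label = label
        self.height = float(height)
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class Dendrogram:
    root: DendroNode
    labels: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.labels = tuple(sorted(self.leaf_order()))
        self._validate()

    def _validate(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate leaf labels")

        def check(node: DendroNode) -> None:
            if node.is_leaf:
                return
            if node.left is None or node.right is None:
                raise ValueError("internal nodes must be binary")
            for child in (node.left, node.right):
                if child.height > node.height + 1e-9:
                    raise ValueError("heights must be non-decreasing toward the root")
                check(child)

        check(self.root)

    # -- structure ---------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list:
        order = []

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                order.append(node.label)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return order

    def internal_nodes_postorder(self) -> list[DendroNode]:
        nodes: list[DendroNode] = []

        def walk(node: DendroNode) -> None:
            if not node.is_leaf:
                walk(node.left)
                walk(node.right)
                nodes.append(node)

        walk(self.root)
        return nodes

    def merges(self) -> list[tuple[frozenset, float]]:
        """(leaf set, height) for every internal node, sorted by height then
        by leaf set for determinism."""
        out: list[tuple[frozenset, float]] = []

        def walk(node: DendroNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            leaves = walk(node.left) | walk(node.right)
            out.append((leaves, node.height))
            return leaves

        walk(self.root)
        return sorted(out, key=lambda item: (item[1], sorted(map(str, item[0]))))

    def copy(self) -> "Dendrogram":
        return Dendrogram(copy.deepcopy(self.root))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: list) -> "Dendrogram":
        """Build from a SciPy linkage matrix."""
        Z = np.asarray(Z, dtype=float)
        n = Z.shape[0] + 1
        if len(labels) != n:
            raise ValueError(f"expected {n} labels, got {len(labels)}")
        nodes: dict[int, DendroNode] = {
            i: DendroNode(label=labels[i], height=0.0) for i in range(n)
        }
        for i, (a, b, height, _) in enumerate(Z):
            nodes[n + i] = DendroNode(
                height=float(height), left=nodes[int(a)], right=nodes[int(b)]
            )
        return cls(nodes[n + len(Z) - 1])

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        """Parse a rooted binary Newick string with branch lengths into an
        ultrametric tree (node height = max distance to a descendant leaf)."""
        text = text.strip().rstrip(";")
        pos = 0

        def parse() -> tuple[DendroNode, float]:
            nonlocal pos
            if text[pos] == "(":
                pos += 1
                left, bl_left = parse()
                if text[pos] != ",":
                    raise ValueError("expected ',' in newick (binary trees only)")
                pos += 1
                right, bl_right = parse()
                if text[pos] != ")":
                    raise ValueError("expected ')' in newick")
                pos += 1
                # internal: skip optional name
                while pos < len(text) and text[pos] not in ":,()":
                    pos += 1
                height = max(left.height + bl_left, right.height + bl_right)
                node = DendroNode(height=height, left=left, right=right)
            else:
                start = pos
                while pos < len(text) and text[pos] not in ":,()":
                    pos += 1
                node = DendroNode(label=text[start:pos].strip())
            branch = 0.0
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",()":
                    pos += 1
                branch = float(text[start:pos])
            return node, branch

        root, _ = parse()
        return cls(root)

    def to_newick(self) -> str:
        def fmt(node: DendroNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{branch:.10g}"
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            return f"{inner}:{branch:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = f"({fmt(self.root.left, self.root.height)},{fmt(self.root.right, self.root.height)})"
        return inner + ";"

    # -- operations --------------------------------------------------------
    def cut(self, k: int) -> dict:
        """Partition into k clusters by removing the k-1 highest merges.

        Height ties are resolved by merge order (the later-listed merge is
        removed first); the chosen cut height is recorded by the caller via
        :meth:`merges`.  Returns label -> 0-based cluster id, ids assigned in
        leaf order.
        """
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in 1..{self.n_leaves}, got {k}")
        merges = self.merges()
        kept_sets = {s for s, _ in merges[: len(merges) - (k - 1)]}

        assignment: dict = {}
        next_id = [0]

        def collect(node: DendroNode, cluster: int) -> None:
            if node.is_leaf:
                assignment[node.label] = cluster
            else:
                collect(node.left, cluster)
                collect(node.right, cluster)

        def leaves_of(node: DendroNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            return leaves_of(node.left) | leaves_of(node.right)

        def walk(node: DendroNode) -> None:
            if node.is_leaf or leaves_of(node) in kept_sets:
                collect(node, next_id[0])
                next_id[0] += 1
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        assert next_id[0] == k
        return assignment


def restrict_to_shared(dend_a: Dendrogram, dend_b: Dendrogram) -> tuple[Dendrogram, Dendrogram]:
    """Prune both trees to their shared leaf set, collapsing unary nodes and
    preserving the heights of the surviving merges."""
    shared = set(dend_a.labels) & set(dend_b.labels)
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared labels, got {len(shared)}")

    def prune(node: DendroNode) -> DendroNode | None:
        if node.is_leaf:
            return node if node.label in shared else None
        left = prune(node.left)
        right = prune(node.right)
        if left is None:
            return right
        if right is None:
            return left
        return DendroNode(height=node.height, left=left, right=right)

    out = []
    for dend in (dend_a, dend_b):
        root = prune(copy.deepcopy(dend.root))
        assert root is not None
        out.append(Dendrogram(root))
    return out[0], out[1]


def entanglement(order_a: list, order_b: list, L: float = 1.5) -> float:
    """Normalized leaf-rank discordance in [0, 1]; 0 = aligned, 1 = reversed."""
    if sorted(map(str, order_a)) != sorted(map(str, order_b)):
        raise ValueError("orders must be permutations of the same label set")
    n = len(order_a)
    if n < 2:
        raise ValueError("need at least 2 labels")
    rank_a = {label: i for i, label in enumerate(order_a)}
    ranks = np.array([rank_a[label] for label in order_b], dtype=float)
    observed = np.abs(ranks - np.arange(n)) ** L
    worst = np.abs(np.arange(n) - np.arange(n)[::-1]) ** L
    return float(observed.sum() / worst.sum())


@dataclass
class Tanglegram:
    tree_a: Dendrogram
    tree_b: Dendrogram
    leaf_order_a: list
    leaf_order_b: list
    entanglement: float
    initial_entanglement: float
    L: float
    rounds: int


#: Shared-leaf count up to which the rotation search is exact (2^(n-1)
#: configurations per tree are enumerable); larger tanglegrams use the
#: greedy swap search.
EXACT_SEARCH_MAX_LEAVES = 10


def _orders_by_mask(dend: Dendrogram) -> tuple[np.ndarray, list[DendroNode]]:
    """Rank vectors (indexed by sorted label) for every flip mask over the
    internal nodes in post-order; row i corresponds to mask i."""
    internals = dend.internal_nodes_postorder()
    index = {label: i for i, label in enumerate(dend.labels)}
    node_bit = {id(node): bit for bit, node in enumerate(internals)}
    n_masks = 1 << len(internals)
    ranks = np.empty((n_masks, len(index)), dtype=float)
    for mask in range(n_masks):
        pos = [0]

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                ranks[mask, index[node.label]] = pos[0]
                pos[0] += 1
                return
            first, second = node.left, node.right
            if mask >> node_bit[id(node)] & 1:
                first, second = second, first
            walk(first)
            walk(second)

        walk(dend.root)
    return ranks, internals


def _apply_mask(internals: list[DendroNode], mask: int) -> None:
    for bit, node in enumerate(internals):
        if mask >> bit & 1:
            node.left, node.right = node.right, node.left


def untangle(
    dend_a: Dendrogram,
    dend_b: Dendrogram,
    L: float = 1.5,
    max_rounds: int = 20,
) -> Tanglegram:
    """Branch-rotation search minimizing entanglement.

    For up to ``EXACT_SEARCH_MAX_LEAVES`` shared leaves the search is exact:
    every rotation configuration of both trees is enumerated and the first
    minimizer (lowest mask pair) is applied, making the result the global
    optimum.  Beyond that, a greedy search runs: each round traverses the
    internal nodes of one tree in post-order accepting a child-swap iff
    entanglement strictly decreases, then switches sides (A side first);
    when no single swap helps, simultaneous pair swaps (one node per side)
    are tried to escape one-sided local minima, stopping after a full round
    with no improvement or ``max_rounds``.  Tree topology and heights are
    never modified, only child order, so the final entanglement is <= the
    initial one by construction.
    """
    tree_a, tree_b = restrict_to_shared(dend_a, dend_b)
    if tree_a.n_leaves <= EXACT_SEARCH_MAX_LEAVES:
        initial = entanglement(tree_a.leaf_order(), tree_b.leaf_order(), L)
        ranks_a, internals_a = _orders_by_mask(tree_a)
        ranks_b, internals_b = _orders_by_mask(tree_b)
        n = tree_a.n_leaves
        worst = float((np.abs(np.arange(n) - np.arange(n)[::-1]) ** L).sum())
        best_val, best_pair = np.inf, (0, 0)
        for mask_a, row in enumerate(ranks_a):
            totals = (np.abs(ranks_b - row) ** L).sum(axis=1)
            mask_b = int(np.argmin(totals))
            if totals[mask_b] < best_val - 1e-15:
                best_val, best_pair = float(totals[mask_b]), (mask_a, mask_b)
        _apply_mask(internals_a, best_pair[0])
        _apply_mask(internals_b, best_pair[1])
        current = best_val / worst
        return Tanglegram(
            tree_a=tree_a,
            tree_b=tree_b,
            leaf_order_a=tree_a.leaf_order(),
            leaf_order_b=tree_b.leaf_order(),
            entanglement=min(current, initial),
            initial_entanglement=initial,
            L=L,
            rounds=0,
        )

    def score() -> float:
        return entanglement(tree_a.leaf_order(), tree_b.leaf_order(), L)

    current = initial = score()
    rounds = 0
    for _ in range(max_rounds):
        rounds += 1
        improved = False
        # phase 1: one-sided swaps, A side first
        for tree in (tree_a, tree_b):
            for node in tree.internal_nodes_postorder():
                node.left, node.right = node.right, node.left
                candidate = score()
                if candidate < current:
                    current = candidate
                    improved = True
                else:
                    node.left, node.right = node.right, node.left
        # phase 2: simultaneous pair swaps (one node per side) to escape
        # single-swap local minima; still greedy and deterministic
        if not improved:
            for node_a in tree_a.internal_nodes_postorder():
                node_a.left, node_a.right = node_a.right, node_a.left
                for node_b in tree_b.internal_nodes_postorder():
                    node_b.left, node_b.right = node_b.right, node_b.left
                    candidate = score()
                    if candidate < current:
                        current = candidate
                        improved = True
                    else:
                        node_b.left, node_b.right = node_b.right, node_b.left
                if improved:
                    break
                node_a.left, node_a.right = node_a.right, node_a.left
        if not improved:
            break
    return Tanglegram(
        tree_a=tree_a,
        tree_b=tree_b,
        leaf_order_a=tree_a.leaf_order(),
        leaf_order_b=tree_b.leaf_order(),
        entanglement=current,
        initial_entanglement=initial,
        L=L,
        rounds=rounds,
    )


def _all_orders(dend: Dendrogram) -> np.ndarray:
    """Leaf orders over every combination of child flips (2^(n-1) sequences,
    possibly with duplicates), as an array of rank vectors indexed by the
    sorted label list."""
    index = {label: i for i, label in enumerate(dend.labels)}

    def orders(node: DendroNode) -> list[list]:
        if node.is_leaf:
            return [[node.label]]
        lefts = orders(node.left)
        rights = orders(node.right)
        out = []
        for a, b in itertools.product(lefts, rights):
            out.append(a + b)
            out.append(b + a)
        return out

    seqs = orders(dend.root)
    ranks = np.empty((len(seqs), len(index)), dtype=float)
    for i, seq in enumerate(seqs):
        for pos, label in enumerate(seq):
            ranks[i, index[label]] = pos
    return ranks


def exhaustive_minimum(dend_a: Dendrogram, dend_b: Dendrogram, L: float = 1.5) -> float:
    """Exact minimum entanglement over every branch-rotation configuration of
    both trees (feasible for small leaf counts; cost 4^(n-1) pairs)."""
    tree_a, tree_b = restrict_to_shared(dend_a, dend_b)
    ra = _all_orders(tree_a)
    rb = _all_orders(tree_b)
    n = tree_a.n_leaves
    worst = float((np.abs(np.arange(n) - np.arange(n)[::-1]) ** L).sum())
    best = np.inf
    for row in ra:
        diffs = np.abs(rb - row) ** L
        best = min(best, float(diffs.sum(axis=1).min()))
    return best / worst
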