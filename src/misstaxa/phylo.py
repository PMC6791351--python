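"""Rooted bifurcating trees: Newick I/O, depths, MRCA matrices, pruning, rescaling.

The tree container is deliberately minimal and array-backed.  Node ids are
stable and deterministic: tips occupy ids ``0 .. n_tips-1`` in sorted
tip-label order, internal nodes follow in postorder, and the root always has
the highest id.  All matrix-valued queries (MRCA depths, covariances built on
top of them) use the sorted tip-label order, so results are reproducible
across runs and platforms.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "rescale_to_unit_height",
    "node_depths",
    "mrca_depths",
    "prune_tips",
]

#: absolute tolerance for ultrametricity checks
ULTRAMETRIC_TOL = 1e-9

_NEWICK_META = set("(),:;[]'\"")


class TreeError(ValueError):
    pass


class NewickParseError(TreeError):
    pass


class _Node:
    """Mutable node used only while building a :class:`Tree`."""

    __slots__ = ("children", "length", "label", "meta")

    def __init__(self, length=0.0, label=None, meta=None):
        self.children = []
        self.length = float(length)
        self.label = label
        self.meta = meta


class Tree:
    """Rooted, bifurcating, edge-length-bearing phylogeny.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[root] == -1``.
    blen : (n_nodes,) float array; length of the edge above each node
        (``blen[root]`` is a root stem, 0 unless created by pruning).
    children : list of lists of child ids (empty for tips).
    tip_labels : tip labels in sorted order; tip ``i`` has id ``i``.
    postorder : node ids in postorder (children before parents, root last).
    """

    __slots__ = ("parent", "blen", "children", "tip_labels", "postorder", "_tip_index")

    def __init__(self, parent, blen, children, tip_labels, postorder):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.children = children
        self.tip_labels = list(tip_labels)
        self.postorder = np.asarray(postorder, dtype=np.int64)
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self):
        return len(self.tip_labels)

    @property
    def n_nodes(self):
        return len(self.parent)

    @property
    def root(self):
        return int(self.postorder[-1])

    def tip_id(self, label):
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def is_tip(self, node):
        return node < self.n_tips

    # ------------------------------------------------------------ construction
    @classmethod
    def _from_node(cls, root, return_ids=False):
        # iterative postorder over the builder-node graph
        order = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))

        tips = [n for n in order if not n.children]
        labels = [n.label for n in tips]
        if any(lab in (None, "") for lab in labels):
            raise TreeError("every tip must carry a non-empty label")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise TreeError(f"duplicate tip label: {lab!r}")
            seen.add(lab)

        sorted_labels = sorted(labels)
        tip_rank = {lab: i for i, lab in enumerate(sorted_labels)}
        n_tips = len(sorted_labels)

        ids = {}
        next_internal = n_tips
        for n in order:
            if n.children:
                ids[id(n)] = next_internal
                next_internal += 1
            else:
                ids[id(n)] = tip_rank[n.label]

        n_nodes = next_internal
        parent = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes, dtype=float)
        children = [[] for _ in range(n_nodes)]
        for n in order:
            i = ids[id(n)]
            if n.length < 0:
                raise TreeError(f"negative branch length {n.length} on node {i}")
            blen[i] = n.length
            for c in n.children:
                j = ids[id(c)]
                parent[j] = i
                children[i].append(j)

        root_id = ids[id(root)]
        for i in range(n_tips, n_nodes):
            k = len(children[i])
            if k == 2:
                continue
            if k == 1 and i == root_id:
                continue  # unary root from pruning / single-tip degenerate tree
            raise TreeError(
                f"tree must be strictly bifurcating; internal node {i} has {k} children"
            )

        postorder = np.fromiter((ids[id(n)] for n in order), dtype=np.int64)
        tree = cls(parent, blen, children, sorted_labels, postorder)
        if return_ids:
            return tree, ids
        return tree

    def _copy_with_blen(self, blen):
        return Tree(self.parent.copy(), blen, [list(c) for c in self.children],
                    self.tip_labels, self.postorder.copy())

    # ------------------------------------------------------------------ queries
    def node_depths(self):
        """Distance from the root for every node; depth(root) = 0."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1][1:]:  # parents before children
            depth[v] = depth[self.parent[v]] + self.blen[v]
        return depth

    def tip_depths(self):
        return self.node_depths()[: self.n_tips]

    def height(self):
        return float(self.tip_depths().max())

    def is_ultrametric(self, tol=ULTRAMETRIC_TOL):
        d = self.tip_depths()
        return bool(np.ptp(d) <= tol)

    def mrca_depths(self, tips=None):
        """Symmetric matrix of MRCA depths t_a(i, j).

        The diagonal holds tip depths.  ``tips`` defaults to the sorted
        tip-label order; any explicit order is honoured.
        """
        if tips is None:
            sel = np.arange(self.n_tips)
        else:
            sel = np.array([self.tip_id(t) for t in tips], dtype=np.int64)
        pos = {int(t): i for i, t in enumerate(sel)}
        k = len(sel)
        depth = self.node_depths()
        M = np.zeros((k, k))
        M[np.arange(k), np.arange(k)] = depth[sel]
        below = [[] for _ in range(self.n_nodes)]
        for t, i in pos.items():
            below[t].append(i)
        for v in self.postorder:
            ch = self.children[v]
            if not ch:
                continue
            acc = below[ch[0]]
            for c in ch[1:]:
                rows = below[c]
                if acc and rows:
                    M[np.ix_(acc, rows)] = depth[v]
                    M[np.ix_(rows, acc)] = depth[v]
                acc = acc + rows
            below[v] = acc
        return M

    def _mrca_nodes(self):
        """Full tips-by-tips matrix of MRCA node ids (diag: the tip itself)."""
        n = self.n_tips
        M = np.zeros((n, n), dtype=np.int64)
        M[np.arange(n), np.arange(n)] = np.arange(n)
        below = [[i] if i < n else [] for i in range(self.n_nodes)]
        for v in self.postorder:
            ch = self.children[v]
            if not ch:
                continue
            acc = below[ch[0]]
            for c in ch[1:]:
                rows = below[c]
                if acc and rows:
                    M[np.ix_(acc, rows)] = v
                    M[np.ix_(rows, acc)] = v
                acc = acc + rows
            below[v] = acc
        return M


# ---------------------------------------------------------------------- Newick


def read_newick(text):
    """Parse a Newick string into a :class:`Tree`.

    Branch lengths are required on all non-root edges; internal node labels
    are ignored; multifurcations are rejected.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise NewickParseError(f"malformed Newick string: {exc}") from exc

    def convert_one(dnode):
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is None:
                length = 0.0
            else:
                tok = dnode.taxon.label if dnode.taxon else "<internal node>"
                raise NewickParseError(f"missing branch length on edge above {tok}")
        is_leaf = dnode.is_leaf()
        label = dnode.taxon.label if dnode.taxon is not None else None
        if is_leaf and label is None:
            raise NewickParseError("unlabeled tip in Newick string")
        return _Node(length=length, label=label if is_leaf else None)

    built = {}
    for dnode in dt.postorder_node_iter():
        node = convert_one(dnode)
        node.children = [built[id(c)] for c in dnode.child_nodes()]
        built[id(dnode)] = node

    tree = Tree._from_node(built[id(dt.seed_node)])
    if tree.n_tips >= 2 and not tree.is_ultrametric():
        warnings.warn(
            "tree is not ultrametric within 1e-9; OU formulas remain valid "
            "but simulated-study assumptions do not hold",
            stacklevel=2,
        )
    return tree


def write_newick(tree):
    """Serialize a :class:`Tree` to Newick (full-precision branch lengths)."""
    for lab in tree.tip_labels:
        if any(ch in _NEWICK_META or ch.isspace() for ch in lab):
            raise TreeError(f"tip label {lab!r} contains Newick metacharacters")

    parts = {}
    for v in tree.postorder:
        ch = tree.children[v]
        if not ch:
            parts[v] = tree.tip_labels[v]
        else:
            parts[v] = "(" + ",".join(f"{parts[c]}:{float(tree.blen[c])!r}" for c in ch) + ")"
    root = tree.root
    if tree.blen[root] > 0:
        return f"{parts[root]}:{float(tree.blen[root])!r};"
    return parts[root] + ";"


# ------------------------------------------------------------------ operations


def rescale_to_unit_height(tree):
    """Multiply all edge lengths by 1/height so the deepest tip sits at 1."""
    h = tree.height()
    if h <= 0:
        raise TreeError("cannot rescale a zero-height tree")
    return tree._copy_with_blen(tree.blen / h)


def node_depths(tree):
    return tree.node_depths()


def mrca_depths(tree, tips=None):
    return tree.mrca_depths(tips)


def prune_tips(tree, drop, return_map=False):
    """Remove the tips in ``drop``; suppress resulting unary internal nodes.

    Suppressed nodes contribute their edge length to the surviving child, so
    every retained tip keeps its root-to-tip depth exactly.  The original root
    is never suppressed (it may become unary), because the trait-evolution
    process starts there.

    With ``return_map=True`` also returns an array mapping each new node id to
    the id of the original node it represents (a suppressed chain maps to its
    surviving rootward endpoint's original child).
    """
    drop = set(drop)
    unknown = drop - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"cannot drop unknown tips: {sorted(unknown)}")
    n_keep = tree.n_tips - len(drop)
    if n_keep < 2:
        raise TreeError("pruning must leave at least 2 tips")

    rep = [None] * tree.n_nodes  # node id -> builder _Node or None
    for v in tree.postorder:
        ch = tree.children[v]
        if not ch:
            lab = tree.tip_labels[v]
            if lab not in drop:
                rep[v] = _Node(length=tree.blen[v], label=lab, meta=v)
            continue
        kept = [rep[c] for c in ch if rep[c] is not None]
        if not kept:
            rep[v] = None
        elif len(kept) == 1 and v != tree.root:
            kept[0].length += tree.blen[v]  # suppress unary node
            rep[v] = kept[0]
        else:
            node = _Node(length=tree.blen[v], meta=v)
            node.children = kept
            rep[v] = node

    new_root = rep[tree.root]
    new_tree, ids = Tree._from_node(new_root, return_ids=True)
    if not return_map:
        return new_tree
    node_map = np.full(new_tree.n_nodes, -1, dtype=np.int64)
    stack = [new_root]
    while stack:
        n = stack.pop()
        node_map[ids[id(n)]] = n.meta
        stack.extend(n.children)
    return new_tree, node_map
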