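"""Unrooted phylogenetic trees: simulation, neighbor joining, distances.

Provides the simulation substrate of the congruence experiments: uniformly
random unrooted binary topologies with i.i.d. branch lengths (whose leaf-to-
leaf path lengths are additive distances by construction), partial-congruence
taxon permutation, Saitou-Nei neighbor joining, and extraction of path-length
(patristic) or topological (all branch lengths set to 1) distance matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .matrices import DistanceMatrix

__all__ = [
    "PhyloTree",
    "random_additive_tree",
    "tree_to_distances",
    "permute_taxa_partial",
    "neighbor_joining",
    "read_newick",
    "write_newick",
]


class PhyloTree:
    """Unrooted tree with labelled leaves and non-negative branch lengths.

    Nodes are opaque integer ids; leaves carry taxon labels. Internal nodes of
    a binary unrooted tree have degree 3 (a degree-2 rooting artifact from a
    rooted Newick source is suppressed on construction).
    """

    def __init__(self):
        self._adj: dict[int, dict[int, float]] = {}
        self.leaf_labels: dict[int, str] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = {}
        if label is not None:
            self.leaf_labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValueError("negative branch length")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    # -- basic queries ----------------------------------------------------
    @property
    def nodes(self) -> list[int]:
        return list(self._adj)

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels, key=self.leaf_labels.__getitem__)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def degree(self, nid: int) -> int:
        return len(self._adj[nid])

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self._adj.items():
            for v, ln in nbrs.items():
                if u < v:
                    out.append((u, v, ln))
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(n) for n in self._adj.values()) // 2

    def neighbors(self, nid: int):
        return self._adj[nid].items()

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {u: dict(n) for u, n in self._adj.items()}
        t.leaf_labels = dict(self.leaf_labels)
        t._next_id = self._next_id
        return t

    # -- canonicalization --------------------------------------------------
    def suppress_degree_two(self) -> None:
        """Splice out degree-2 nodes (rooting artifacts), summing the two
        incident branch lengths."""
        for nid in list(self._adj):
            if nid not in self.leaf_labels and len(self._adj[nid]) == 2:
                (a, la), (b, lb) = self._adj[nid].items()
                self.remove_edge(nid, a)
                self.remove_edge(nid, b)
                del self._adj[nid]
                self.add_edge(a, b, la + lb)

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("tree needs at least 2 leaves")
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        for nid in self._adj:
            deg = self.degree(nid)
            if nid in self.leaf_labels:
                if deg != 1:
                    raise ValueError(f"leaf {self.leaf_labels[nid]!r} has degree {deg}")
            elif deg != 3:
                raise ValueError(f"internal node of degree {deg} (expected 3)")

    # -- traversal ---------------------------------------------------------
    def _root_for_traversal(self) -> int:
        """Deterministic traversal root: the neighbor of the smallest leaf
        (an internal node whenever the tree has one)."""
        smallest = min(self.leaf_labels, key=self.leaf_labels.__getitem__)
        return next(iter(self._adj[smallest]))

    def rooted_edges(self, root: int | None = None) -> tuple[int, list[tuple[int, int, float]]]:
        """Preorder (parent, child, length) list from a traversal root."""
        root = self._root_for_traversal() if root is None else root
        out: list[tuple[int, int, float]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            for child, ln in sorted(self._adj[node].items(), reverse=True):
                if child != parent:
                    out.append((node, child, ln))
                    stack.append((child, node))
        return root, out

    # -- distances ---------------------------------------------------------
    def distance_matrix(self, topological: bool = False) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path lengths (sums of branch lengths along
        the unique path); in topological mode every branch counts 1."""
        labels = self.taxa
        index = {lab: i for i, lab in enumerate(labels)}
        m = len(labels)
        values = np.zeros((m, m))
        for leaf in self.leaf_labels:
            i = index[self.leaf_labels[leaf]]
            dist = {leaf: 0.0}
            stack = [(leaf, -1)]
            while stack:
                node, parent = stack.pop()
                for nbr, ln in self._adj[node].items():
                    if nbr != parent:
                        dist[nbr] = dist[node] + (1.0 if topological else ln)
                        stack.append((nbr, node))
            for other, lab in self.leaf_labels.items():
                if other != leaf:
                    values[i, index[lab]] = dist[other]
        return DistanceMatrix(values, list(labels))


def random_additive_tree(
    m: int,
    rng: np.random.Generator,
    branch_length_mean: float = 0.1,
    branch_length_sampler=None,
    label_template: str = "t{:03d}",
) -> PhyloTree:
    """Random unrooted binary tree whose path lengths form an additive matrix.

    The topology is sampled uniformly over the (2m-5)!! unrooted binary
    labelled topologies by sequential random leaf addition to a uniformly
    chosen edge; taxon labels are then assigned by a uniform random
    permutation, and branch lengths drawn i.i.d. — exponential with mean
    ``branch_length_mean`` (default 0.1 substitutions/site) unless a custom
    ``branch_length_sampler(rng, n_edges)`` is given.
    """
    if m < 4:
        raise ValueError("need at least 4 taxa")
    tree = PhyloTree()
    leaves = [tree.add_node(f"L{i}") for i in range(3)]
    center = tree.add_node()
    edge_list: list[tuple[int, int]] = []
    for lf in leaves:
        tree.add_edge(lf, center, 1.0)
        edge_list.append((lf, center))
    for i in range(3, m):
        u, v = edge_list[rng.integers(len(edge_list))]
        w = tree.add_node()
        ln = tree._adj[u][v]
        tree.remove_edge(u, v)
        tree.add_edge(u, w, ln)
        tree.add_edge(w, v, ln)
        leaf = tree.add_node(f"L{i}")
        tree.add_edge(leaf, w, 1.0)
        edge_list.remove((u, v))
        edge_list += [(u, w), (w, v), (leaf, w)]
        leaves.append(leaf)
    # labels by uniform random permutation
    labels = [label_template.format(i + 1) for i in range(m)]
    for leaf, k in zip(leaves, rng.permutation(m)):
        tree.leaf_labels[leaf] = labels[k]
    # branch lengths i.i.d.
    edges = tree.edges()
    if branch_length_sampler is None:
        lengths = rng.exponential(branch_length_mean, size=len(edges))
    else:
        lengths = np.asarray(branch_length_sampler(rng, len(edges)), dtype=float)
    for (u, v, _), ln in zip(edges, lengths):
        tree.add_edge(u, v, ln)
    tree.validate()
    return tree


def tree_to_distances(tree: PhyloTree, mode: str = "path_length") -> DistanceMatrix:
    """Distance matrix of a tree: ``"path_length"`` sums branch lengths along
    leaf-to-leaf paths; ``"topological"`` first sets every branch length to 1."""
    if mode not in ("path_length", "topological"):
        raise ValueError(f"unknown mode {mode!r}")
    return tree.distance_matrix(topological=(mode == "topological"))


def _derangement(k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement of 0..k-1 by rejection."""
    if k < 2:
        raise ValueError("derangements need k >= 2")
    while True:
        perm = rng.permutation(k)
        if not np.any(perm == np.arange(k)):
            return perm


def permute_taxa_partial(
    matrix: DistanceMatrix,
    proportion: float,
    rng: np.random.Generator,
    scheme: str = "uniform",
) -> DistanceMatrix:
    """Permute a random subset of taxa to build a partially congruent matrix.

    k = round(proportion * m) taxa are chosen uniformly and their labels
    permuted among themselves, distances relabeled accordingly; for an
    additive input the output is the same tree with permuted leaves, hence
    still additive. ``proportion`` 0 (or k < 2) returns the matrix unchanged.

    ``scheme`` selects how the chosen labels move: ``"uniform"`` (default)
    draws a uniform random permutation of the k chosen labels, so some of
    them may stay in place — the classical row/column permutation of a
    selected block; ``"derangement"`` additionally conditions on every chosen
    taxon moving.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if scheme not in ("uniform", "derangement"):
        raise ValueError(f"unknown scheme {scheme!r}")
    m = matrix.n_taxa
    k = int(round(proportion * m))
    if k < 2:
        return matrix
    chosen = np.sort(rng.choice(m, size=k, replace=False))
    sub = _derangement(k, rng) if scheme == "derangement" else rng.permutation(k)
    perm = np.arange(m)
    perm[chosen] = chosen[sub]
    return matrix.permuted(perm)


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Agglomerates by the Q-criterion (ties broken toward the lowest-index
    pair); negative branch-length estimates are clamped to zero with the
    excess transferred to the sister branch so the pair's summed length is
    preserved. On an additive input the generating tree is recovered exactly.
    """
    m = matrix.n_taxa
    if m < 4:
        raise ValueError("need at least 4 taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite distances")
    tree = PhyloTree()
    # full working matrix indexed by node slot; slots are never reused
    size = 2 * m - 2
    D = np.zeros((size, size))
    D[:m, :m] = matrix.values
    node_of = {i: tree.add_node(matrix.labels[i]) for i in range(m)}
    active = list(range(m))
    next_slot = m
    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        N = len(active)
        r = sub.sum(axis=1)
        Q = (N - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major scan -> lowest-index pair on ties
        a, b = divmod(flat, N)
        if a > b:
            a, b = b, a
        d_ab = sub[a, b]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2.0 * (N - 2))
        lb = d_ab - la
        if la < 0.0:
            la, lb = 0.0, d_ab
        elif lb < 0.0:
            la, lb = d_ab, 0.0
        u = tree.add_node()
        tree.add_edge(node_of[idx[a]], u, la)
        tree.add_edge(node_of[idx[b]], u, lb)
        node_of[next_slot] = u
        others = [s for t, s in enumerate(idx) if t not in (a, b)]
        D[next_slot, others] = D[others, next_slot] = 0.5 * (
            D[idx[a], others] + D[idx[b], others] - d_ab
        )
        active = [s for s in active if s not in (idx[a], idx[b])] + [next_slot]
        next_slot += 1
    # join the last three around a central node
    a, b, c = active
    center = tree.add_node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for slot, ln in ((a, la), (b, lb), (c, lc)):
        tree.add_edge(node_of[slot], center, max(ln, 0.0))
    tree.validate()
    return tree


# -- Newick ----------------------------------------------------------------

def read_newick(source) -> PhyloTree:
    """Parse a Newick string (or file path) with branch lengths."""
    import dendropy

    text = str(source)
    if isinstance(source, Path) or ("(" not in text and "\n" not in text):
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
            f" (first '(' at offset {text.find('(')})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    tree = PhyloTree()
    ids: dict = {}
    for node in dtree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else None
        ids[node] = tree.add_node(label)
        if node.parent_node is not None:
            ln = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(ids[node.parent_node], ids[node], ln)
    labels = [lab for lab in tree.leaf_labels.values()]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate taxon labels: {dup}")
    tree.suppress_degree_two()
    tree.validate()
    return tree


def write_newick(tree: PhyloTree, path=None) -> str:
    """Canonical Newick: rooted for output at the neighbor of the smallest
    leaf, children sorted by their smallest descendant taxon label."""
    root = tree._root_for_traversal()

    def min_label(node: int, parent: int) -> str:
        if node in tree.leaf_labels:
            return tree.leaf_labels[node]
        return min(min_label(c, node) for c, _ in tree.neighbors(node) if c != parent)

    def render(node: int, parent: int) -> str:
        if node in tree.leaf_labels:
            return tree.leaf_labels[node]
        kids = sorted(
            (c for c, _ in tree.neighbors(node) if c != parent),
            key=lambda c: min_label(c, node),
        )
        parts = [f"{render(c, node)}:{tree._adj[node][c]:.10g}" for c in kids]
        return "(" + ",".join(parts) + ")"

    text = render(root, -1) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
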