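"""Phylogenetic tree structures and topology metrics.

The evaluation framework scores alignments by the accuracy of the trees
inferred from them, so everything here is topological: splits
(bipartitions), the Robinson-Foulds distance, the proportion of wrong
splits, rooting enumeration (needed to minimise duplication counts over
unknown root positions) and exhaustive enumeration of unrooted binary
topologies (needed for exact parsimony search and for exact baselines).

Branch lengths are carried through I/O but ignored by every metric.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafSetMismatchError",
    "StarTreeError",
    "UnsupportedTopologyError",
    "TreeNode",
    "Tree",
    "Split",
    "parse_newick",
    "write_newick",
    "nontrivial_splits",
    "robinson_foulds",
    "proportion_wrong_splits",
    "tree_accuracy",
    "enumerate_rootings",
    "enumerate_topologies",
    "random_binary_tree",
    "comb_tree",
    "relabel_leaves",
]


class TreeError(ValueError):
    """Base class for tree-related errors."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class LeafSetMismatchError(TreeError):
    """Two trees being compared do not share the same leaf-label set."""


class StarTreeError(TreeError):
    """An operation requiring non-trivial splits received a star tree."""


class UnsupportedTopologyError(TreeError):
    """Operation requires a (rooted or unrooted) strictly binary tree."""


class TreeNode:
    """A node in a rooted representation of a tree."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[List["TreeNode"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: List[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone


class Tree:
    """A phylogeny with unique leaf labels.

    Internally always stored as a rooted structure.  ``rooted`` records
    whether the basal node is a genuine root (two children) or merely the
    anchor of an unrooted tree (three or more children at the base).
    """

    def __init__(self, root: TreeNode, rooted: bool) -> None:
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = [leaf.label for leaf in self.root.leaves()]
        if any(label is None or label == "" for label in labels):
            raise TreeError("every leaf must carry a non-empty label")
        seen: Set[str] = set()
        dupes = sorted({l for l in labels if l in seen or seen.add(l)})  # type: ignore[func-returns-value]
        if dupes:
            raise TreeError(f"duplicate leaf labels: {', '.join(dupes)}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise TreeError("negative branch length")

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(leaf.label for leaf in self.root.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def is_binary(self) -> bool:
        """Strictly binary: rooted → every internal node has 2 children;
        unrooted → basal anchor has 3 children, all other internals 2."""
        root_ok = len(self.root.children) == (2 if self.rooted else 3)
        if self.n_leaves <= (2 if self.rooted else 3):
            root_ok = len(self.root.children) == min(self.n_leaves, 2 if self.rooted else 3) or root_ok
        others_ok = all(
            len(node.children) in (0, 2)
            for node in self.root.postorder()
            if node is not self.root
        )
        return root_ok and others_ok

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tree({write_newick(self)!r}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(node: dendropy.Node) -> TreeNode:
    label = node.taxon.label if node.taxon is not None else None
    out = TreeNode(label=label, length=node.edge.length)
    for child in node.child_nodes():
        out.add_child(_from_dendropy(child))
    return out


def parse_newick(text: str) -> Tree:
    """Parse a newick string.

    A basal bifurcation is read as a rooted tree, a basal trifurcation (or
    higher) as unrooted.  Branch lengths are preserved.
    """
    if not text.strip():
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" at line {line}, column {col}" if line is not None else ""
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    if root.is_leaf:
        raise NewickParseError("newick string contains no tree structure")
    rooted = len(root.children) == 2
    return Tree(root, rooted=rooted)


def _min_leaf(node: TreeNode) -> str:
    return min(leaf.label for leaf in node.leaves())  # type: ignore[type-var]


def _format_node(node: TreeNode, with_lengths: bool) -> str:
    if node.is_leaf:
        text = node.label or ""
    else:
        kids = sorted(node.children, key=_min_leaf)
        text = "(" + ",".join(_format_node(c, with_lengths) for c in kids) + ")"
    if with_lengths and node.length is not None:
        text += f":{node.length:g}"
    return text


def write_newick(tree: Tree, with_lengths: bool = True) -> str:
    """Serialise to newick with children ordered by smallest descendant
    label, so equal topologies always serialise identically."""
    has_lengths = any(
        n.length is not None for n in tree.root.postorder() if n is not tree.root
    )
    return _format_node(tree.root, with_lengths and has_lengths) + ";"


# ---------------------------------------------------------------------------
# splits and split metrics
# ---------------------------------------------------------------------------

class Split:
    """An unordered bipartition of the full leaf set.

    Canonical orientation: the block containing the lexicographically
    smallest label is stored first.
    """

    __slots__ = ("blocks",)

    def __init__(self, block_a: FrozenSet[str], block_b: FrozenSet[str]) -> None:
        if not block_a or not block_b or block_a & block_b:
            raise TreeError("split blocks must be disjoint and non-empty")
        if min(block_a) > min(block_b):
            block_a, block_b = block_b, block_a
        self.blocks: Tuple[FrozenSet[str], FrozenSet[str]] = (block_a, block_b)

    @property
    def is_trivial(self) -> bool:
        return min(len(b) for b in self.blocks) == 1

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Split) and self.blocks == other.blocks

    def __hash__(self) -> int:
        return hash(self.blocks)

    def __repr__(self) -> str:
        a, b = self.blocks
        return "{%s}|{%s}" % (",".join(sorted(a)), ",".join(sorted(b)))


def _unrooted_adjacency(
    tree: Tree,
) -> Tuple[Dict[int, List[Tuple[int, Optional[float]]]], Dict[int, str]]:
    """Adjacency map of the unrooted version of ``tree``.

    Returns (adjacency, leaf-labels-by-node-id).  A rooted tree's root is
    suppressed by joining its two children (lengths summed when present).
    """
    ids: Dict[int, TreeNode] = {}
    adj: Dict[int, List[Tuple[int, Optional[float]]]] = {}
    labels: Dict[int, str] = {}

    def nid(node: TreeNode) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = node
            adj[key] = []
            if node.is_leaf:
                labels[key] = node.label  # type: ignore[assignment]
        return key

    def connect(a: TreeNode, b: TreeNode, length: Optional[float]) -> None:
        adj[nid(a)].append((nid(b), length))
        adj[nid(b)].append((nid(a), length))

    root = tree.root
    suppress = tree.rooted and len(root.children) == 2 and tree.n_leaves > 2
    for node in root.postorder():
        if node is root:
            continue
        if suppress and node.parent is root:
            continue
        connect(node.parent, node, node.length)  # type: ignore[arg-type]
    if suppress:
        a, b = root.children
        total = None
        if a.length is not None or b.length is not None:
            total = (a.length or 0.0) + (b.length or 0.0)
        connect(a, b, total)
    else:
        nid(root)  # ensure present even if isolated (single-leaf edge case)
    return adj, labels


def nontrivial_splits(tree: Tree) -> Set[Split]:
    """All non-trivial splits (one per internal edge of the unrooted tree)."""
    adj, labels = _unrooted_adjacency(tree)
    all_leaves = frozenset(labels.values())
    splits: Set[Split] = set()

    anchor = next(iter(adj))

    def below(node: int, parent: int) -> FrozenSet[str]:
        if node in labels:
            return frozenset((labels[node],))
        acc: Set[str] = set()
        for nbr, _ in adj[node]:
            if nbr != parent:
                acc |= below(nbr, node)
        side = frozenset(acc)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(Split(side, all_leaves - side))
        return side

    if anchor in labels and len(adj[anchor]) == 1:
        # anchor is a leaf: start from its single neighbour instead
        nbr = adj[anchor][0][0]
        below(nbr, anchor)
    else:
        for nbr, _ in adj[anchor]:
            below(nbr, anchor)
    return splits


def _require_same_leaves(t1: Tree, t2: Tree) -> None:
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise LeafSetMismatchError(
            f"leaf sets differ (only in first: {only1}; only in second: {only2})"
        )


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial split sets."""
    _require_same_leaves(t1, t2)
    return len(nontrivial_splits(t1) ^ nontrivial_splits(t2))


def proportion_wrong_splits(inferred: Tree, reference: Tree) -> float:
    """Fraction of the inferred tree's non-trivial splits that do not occur
    in the reference topology."""
    _require_same_leaves(inferred, reference)
    s_inf = nontrivial_splits(inferred)
    if not s_inf:
        raise StarTreeError(
            "inferred tree has no non-trivial splits; sample must be excluded"
        )
    s_ref = nontrivial_splits(reference)
    return len(s_inf - s_ref) / len(s_inf)


def tree_accuracy(inferred: Tree, reference: Tree) -> float:
    """One minus the normalised Robinson-Foulds distance.

    Normalisation is by the total number of non-trivial splits in the two
    trees, which equals 2(n-3) when both are binary.
    """
    _require_same_leaves(inferred, reference)
    s_inf = nontrivial_splits(inferred)
    s_ref = nontrivial_splits(reference)
    denom = len(s_inf) + len(s_ref)
    if denom == 0:
        return 1.0
    return 1.0 - len(s_inf ^ s_ref) / denom


# ---------------------------------------------------------------------------
# rootings and topology enumeration
# ---------------------------------------------------------------------------

def _require_unrooted_binary(tree: Tree) -> None:
    if tree.rooted and len(tree.root.children) == 2 and tree.n_leaves > 3:
        raise UnsupportedTopologyError("expected an unrooted tree")
    adj, labels = _unrooted_adjacency(tree)
    for node, nbrs in adj.items():
        deg = len(nbrs)
        if node in labels:
            if deg not in (1, 0) and len(adj) > 1:
                raise UnsupportedTopologyError("leaf with internal degree")
        elif deg != 3:
            raise UnsupportedTopologyError(
                f"multifurcating or degenerate internal node (degree {deg})"
            )


def _grow(
    node: int,
    avoid: int,
    adj: Dict[int, List[Tuple[int, Optional[float]]]],
    labels: Dict[int, str],
    length: Optional[float],
) -> TreeNode:
    out = TreeNode(label=labels.get(node), length=length)
    for nbr, edge_len in adj[node]:
        if nbr != avoid:
            out.add_child(_grow(nbr, node, adj, labels, edge_len))
    return out


def enumerate_rootings(tree: Tree) -> List[Tree]:
    """All rooted binary trees obtained by rooting the (unrooted, binary)
    input on each of its 2n-3 edges."""
    adj, labels = _unrooted_adjacency(tree)
    for node, nbrs in adj.items():
        if node not in labels and len(nbrs) not in (2, 3):
            raise UnsupportedTopologyError(
                "rooting enumeration requires a binary tree"
            )
    edges: List[Tuple[int, int, Optional[float]]] = []
    seen: Set[Tuple[int, int]] = set()
    for node, nbrs in adj.items():
        for nbr, length in nbrs:
            key = (min(node, nbr), max(node, nbr))
            if key not in seen:
                seen.add(key)
                edges.append((node, nbr, length))
    rootings: List[Tree] = []
    for u, v, length in edges:
        half = None if length is None else length / 2.0
        root = TreeNode()
        root.add_child(_grow(u, v, adj, labels, half))
        root.add_child(_grow(v, u, adj, labels, half))
        rootings.append(Tree(root, rooted=True))
    return rootings


_MAX_ENUM_LEAVES = 8


def enumerate_topologies(labels: Sequence[str]) -> List[Tree]:
    """All (2n-5)!! distinct unrooted binary topologies on ``labels``.

    Refuses more than 8 labels; use the heuristic parsimony search for
    larger problems.
    """
    labs = sorted(set(labels))
    if len(labs) != len(list(labels)):
        raise TreeError("labels must be unique")
    n = len(labs)
    if n < 3:
        raise TreeError("need at least 3 labels")
    if n > _MAX_ENUM_LEAVES:
        raise TreeError(
            f"{n} labels would give {_double_factorial(2 * n - 5)} topologies; "
            "refusing (use the heuristic search instead)"
        )
    # edge-list construction: insert leaf k into every edge of every
    # (k-1)-leaf topology.  Node ids: 0..n-1 leaves, n.. internals.
    first_internal = n
    trees: List[List[Tuple[int, int]]] = [[(0, 1)]]
    for k in range(2, n):
        new_internal = first_internal + (k - 2)
        grown: List[List[Tuple[int, int]]] = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                new_edges = edges[:i] + edges[i + 1 :]
                new_edges += [(u, new_internal), (new_internal, v), (new_internal, k)]
                grown.append(new_edges)
        trees = grown
    return [_edges_to_tree(edges, labs) for edges in trees]


def _edges_to_tree(edges: List[Tuple[int, int]], labs: List[str]) -> Tree:
    adj: Dict[int, List[Tuple[int, Optional[float]]]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append((v, None))
        adj.setdefault(v, []).append((u, None))
    labels = {i: lab for i, lab in enumerate(labs) if i in adj}
    if len(labs) == 3:
        anchor = next(i for i in adj if i not in labels)
    else:
        anchor = next(i for i in adj if i not in labels and len(adj[i]) == 3)
    root = TreeNode()
    for nbr, _ in adj[anchor]:
        root.add_child(_grow(nbr, anchor, adj, labels, None))
    return Tree(root, rooted=False)


def _double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def n_unrooted_topologies(n_leaves: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n leaves."""
    return _double_factorial(2 * n_leaves - 5)


# ---------------------------------------------------------------------------
# constructors used throughout the benchmark
# ---------------------------------------------------------------------------

def random_binary_tree(
    labels: Sequence[str],
    rng,
    rooted: bool = True,
    branch_lengths: Optional[Tuple[float, float]] = None,
) -> Tree:
    """Random rooted binary tree by sequential random joining.

    ``rng`` is a numpy Generator.  With ``rooted=False`` the result is the
    unrooted version (basal trifurcation).  Optional branch lengths are
    drawn uniformly from the given (low, high) interval.
    """
    labs = list(labels)
    if len(set(labs)) != len(labs) or len(labs) < 2:
        raise TreeError("need >= 2 unique labels")

    def blen() -> Optional[float]:
        if branch_lengths is None:
            return None
        low, high = branch_lengths
        return float(rng.uniform(low, high))

    nodes = [TreeNode(label=lab, length=blen()) for lab in labs]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(length=blen(), children=[a, b])
        nodes.append(parent)
    root = TreeNode(children=nodes)
    tree = Tree(root, rooted=True)
    if not rooted and len(labs) >= 3:
        return unroot(tree)
    return tree


def unroot(tree: Tree) -> Tree:
    """Unrooted version of a tree (basal trifurcation anchor)."""
    if not tree.rooted or len(tree.root.children) != 2 or tree.n_leaves < 3:
        return tree.copy()
    adj, labels = _unrooted_adjacency(tree)
    anchor = next((i for i in adj if i not in labels and len(adj[i]) >= 3), None)
    if anchor is None:  # 3-leaf tree: anchor at the single internal node
        anchor = next(i for i in adj if i not in labels)
    root = TreeNode()
    for nbr, length in adj[anchor]:
        root.add_child(_grow(nbr, anchor, adj, labels, length))
    return Tree(root, rooted=False)


def comb_tree(
    labels: Sequence[str],
    rng=None,
    branch_lengths: Optional[Tuple[float, float]] = None,
) -> Tree:
    """Rooted comb (caterpillar) tree: (((L1,L2),L3),...,Ln).

    The first label is the innermost leaf.  Branch lengths, when requested,
    are drawn uniformly from (low, high) with ``rng``.
    """
    labs = list(labels)
    if len(labs) < 2:
        raise TreeError("comb needs >= 2 labels")

    def blen() -> Optional[float]:
        if branch_lengths is None:
            return None
        low, high = branch_lengths
        return float(rng.uniform(low, high))

    node = TreeNode(
        children=[TreeNode(labs[0], blen()), TreeNode(labs[1], blen())],
        length=blen(),
    )
    for lab in labs[2:]:
        node = TreeNode(children=[node, TreeNode(lab, blen())], length=blen())
    node.length = None
    return Tree(node, rooted=True)


def relabel_leaves(tree: Tree, mapping: Dict[str, str]) -> Tree:
    """Return a copy with every leaf label replaced via ``mapping``.

    The mapped labels must be unique (one leaf per target label).
    """
    out = tree.copy()
    for leaf in out.root.leaves():
        if leaf.label not in mapping:
            raise TreeError(f"no mapping for leaf {leaf.label!r}")
        leaf.label = mapping[leaf.label]
    return Tree(out.root, out.rooted)  # re-validates uniqueness
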