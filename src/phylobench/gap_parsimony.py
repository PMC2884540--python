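"""Parsimony trees from gap presence/absence patterns.

Gaps carry phylogenetic signal that substitution-based tree builders
ignore.  This module turns every alignment column containing at least one
gap into a binary character (1 = gap present), optionally collapses runs of
neighbouring columns with identical gap patterns into single characters to
avoid over-counting a single indel event, scores trees by Wagner parsimony
(equivalent to Fitch counting on two-state characters) and searches for the
most parsimonious topologies — exactly for up to 8 taxa, by deterministic
stepwise addition plus nearest-neighbour interchange above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .alignments import GAP, Alignment
from .trees import (
    Tree,
    TreeError,
    enumerate_topologies,
    tree_accuracy,
    write_newick,
    _MAX_ENUM_LEAVES,
)

__all__ = [
    "NoGapSignalError",
    "GapCharacterMatrix",
    "extract_gap_characters",
    "parsimony_score",
    "most_parsimonious_trees",
    "gap_tree_accuracy",
]


class NoGapSignalError(ValueError):
    """The alignment carries no informative gap characters."""


@dataclass
class GapCharacterMatrix:
    """Taxa × binary gap characters with per-character weights.

    ``provenance`` records, per character, the half-open interval of
    alignment columns it summarises.
    """

    taxa: List[str]
    characters: List[Tuple[int, ...]]  # one state per taxon, 0/1
    weights: List[int]
    provenance: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        for states in self.characters:
            if len(states) != len(self.taxa):
                raise ValueError("character length does not match taxon count")
            if not set(states) <= {0, 1}:
                raise ValueError("characters must be binary")
        if any(w < 1 for w in self.weights):
            raise ValueError("weights must be >= 1")

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def informative(self) -> bool:
        """At least one character shows both states."""
        return any(0 in c and 1 in c for c in self.characters)

    def state_array(self) -> np.ndarray:
        """(n_taxa, n_characters) 0/1 array."""
        if not self.characters:
            return np.zeros((len(self.taxa), 0), dtype=np.int8)
        return np.array(self.characters, dtype=np.int8).T


def extract_gap_characters(aln: Alignment, collapse: bool = True) -> GapCharacterMatrix:
    """Binary gap characters from an alignment.

    Every column containing at least one gap becomes a character whose
    state per taxon is gap present (1) or absent (0).  With
    ``collapse=True``, maximal runs of *consecutive* gap-containing columns
    sharing an identical pattern are combined into one character of weight
    1; a gap-free column breaks a run.  With ``collapse=False`` every
    gap-containing column is its own character (the no-collapse control).
    """
    characters: List[Tuple[int, ...]] = []
    weights: List[int] = []
    provenance: List[Tuple[int, int]] = []
    prev_pattern: Optional[Tuple[int, ...]] = None
    for j in range(aln.width):
        col = aln.column(j)
        if GAP not in col:
            prev_pattern = None
            continue
        pattern = tuple(1 if ch == GAP else 0 for ch in col)
        if collapse and pattern == prev_pattern:
            start, _ = provenance[-1]
            provenance[-1] = (start, j + 1)
        else:
            characters.append(pattern)
            weights.append(1)
            provenance.append((j, j + 1))
        prev_pattern = pattern if collapse else None
    return GapCharacterMatrix(
        taxa=list(aln.ids),
        characters=characters,
        weights=weights,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Fitch counting
# ---------------------------------------------------------------------------

def _postorder_structure(tree: Tree, taxa: Sequence[str]) -> List[Tuple[int, int, int]]:
    """Compile a binary tree into a postorder merge program.

    Returns a list of (left_slot, right_slot, out_slot) operating on a slot
    array whose first len(taxa) entries are the leaves in ``taxa`` order.
    Works on rooted binary trees and on unrooted trees (trifurcating anchor
    rooted implicitly on one of its edges — parsimony counts are invariant
    to that choice).
    """
    index = {t: i for i, t in enumerate(taxa)}
    program: List[Tuple[int, int, int]] = []
    next_slot = len(taxa)

    def visit(node) -> int:
        nonlocal next_slot
        if node.is_leaf:
            if node.label not in index:
                raise TreeError(f"tree leaf {node.label!r} not among matrix taxa")
            return index[node.label]
        slots = [visit(child) for child in node.children]
        out = slots[0]
        for other in slots[1:]:
            program.append((out, other, next_slot))
            out = next_slot
            next_slot += 1
        return out

    visit(tree.root)
    return program


def _fitch_scores(program: List[Tuple[int, int, int]], states: np.ndarray) -> np.ndarray:
    """Per-character minimum state-change counts.

    ``states``: (n_taxa, n_characters) with values 0/1.  State sets are
    encoded as bitmasks (1 = {0}, 2 = {1}, 3 = {0,1}).
    """
    n_taxa, n_chars = states.shape
    n_slots = n_taxa + len(program)
    sets = np.zeros((n_slots, n_chars), dtype=np.int8)
    sets[:n_taxa] = np.where(states == 0, 1, 2)
    cost = np.zeros(n_chars, dtype=np.int64)
    for left, right, out in program:
        inter = sets[left] & sets[right]
        empty = inter == 0
        cost += empty
        sets[out] = np.where(empty, sets[left] | sets[right], inter)
    return cost


def parsimony_score(tree: Tree, m: GapCharacterMatrix) -> int:
    """Weighted minimum number of gap gain/loss events on ``tree``.

    Rooting-invariant; the tree's leaf set must equal the matrix taxa.
    """
    tree_leaves = set(tree.leaf_labels)
    if tree_leaves != set(m.taxa):
        raise TreeError(
            f"tree/matrix taxa mismatch: {sorted(tree_leaves ^ set(m.taxa))}"
        )
    if m.n_characters == 0:
        return 0
    program = _postorder_structure(tree, m.taxa)
    unit = _fitch_scores(program, m.state_array())
    return int(np.dot(unit, np.asarray(m.weights, dtype=np.int64)))


# ---------------------------------------------------------------------------
# parsimony tree search
# ---------------------------------------------------------------------------

def most_parsimonious_trees(m: GapCharacterMatrix) -> Tuple[List[Tree], int]:
    """Unrooted binary topologies minimising the parsimony score.

    Exact (exhaustive topology enumeration) for up to 8 taxa; deterministic
    stepwise addition followed by nearest-neighbour interchange to a local
    optimum above that.  Raises :class:`NoGapSignalError` when no character
    is informative (including the no-characters case).
    """
    if len(m.taxa) < 4:
        raise ValueError("parsimony tree search needs >= 4 taxa")
    if not m.informative():
        raise NoGapSignalError("no gap character with both states present")
    if len(m.taxa) <= _MAX_ENUM_LEAVES:
        return _exact_search(m)
    return _heuristic_search(m)


def _exact_search(m: GapCharacterMatrix) -> Tuple[List[Tree], int]:
    states = m.state_array()
    weights = np.asarray(m.weights, dtype=np.int64)
    taxa = sorted(m.taxa)
    order = [m.taxa.index(t) for t in taxa]
    states = states[order]
    best_score: Optional[int] = None
    best: List[Tree] = []
    for tree in enumerate_topologies(taxa):
        program = _postorder_structure(tree, taxa)
        score = int(np.dot(_fitch_scores(program, states), weights))
        if best_score is None or score < best_score:
            best_score = score
            best = [tree]
        elif score == best_score:
            best.append(tree)
    assert best_score is not None
    return best, best_score


def _nni_neighbours(tree: Tree) -> List[Tree]:
    """All nearest-neighbour-interchange rearrangements of an unrooted
    binary tree (two per internal edge), deduplicated by canonical newick."""
    from .trees import _unrooted_adjacency, _grow, TreeNode

    adj, labels = _unrooted_adjacency(tree)
    out: List[Tree] = []
    seen: Set[str] = set()
    internal_edges = [
        (u, v)
        for u in adj
        for v, _ in adj[u]
        if u < v and u not in labels and v not in labels
    ]
    for u, v in internal_edges:
        u_sides = [w for w, _ in adj[u] if w != v]
        v_sides = [w for w, _ in adj[v] if w != u]
        # swap one subtree from each side; two distinct exchanges
        for vi in range(2):
            a, b = u_sides[0], v_sides[vi]
            root = TreeNode()
            root.add_child(_grow(b, v, adj, labels, None))
            root.add_child(_grow(u_sides[1], u, adj, labels, None))
            mid = TreeNode()
            mid.add_child(_grow(a, u, adj, labels, None))
            other = v_sides[1 - vi]
            mid.add_child(_grow(other, v, adj, labels, None))
            root.add_child(mid)
            cand = Tree(root, rooted=False)
            key = write_newick(cand, with_lengths=False)
            if key not in seen:
                seen.add(key)
                out.append(cand)
    return out


def _heuristic_search(m: GapCharacterMatrix) -> Tuple[List[Tree], int]:
    from .trees import TreeNode

    taxa = sorted(m.taxa)
    states = m.state_array()[[m.taxa.index(t) for t in taxa]]
    weights = np.asarray(m.weights, dtype=np.int64)

    def score_of(tree: Tree) -> int:
        program = _postorder_structure(tree, taxa)
        return int(np.dot(_fitch_scores(program, states), weights))

    # stepwise addition in sorted-id order
    current = _edges_star(taxa[:3])
    for taxon in taxa[3:]:
        candidates = _attachments(current, taxon)
        scored = sorted(
            ((score_of(t), write_newick(t, with_lengths=False), t) for t in candidates)
        )
        current = scored[0][2]
    best_score = score_of(current)
    best: Dict[str, Tree] = {write_newick(current, with_lengths=False): current}
    frontier = [current]
    max_plateau = 50  # bound tie exploration on flat score plateaus
    while frontier:
        nxt: List[Tree] = []
        for tree in frontier:
            for cand in _nni_neighbours(tree):
                s = score_of(cand)
                key = write_newick(cand, with_lengths=False)
                if s < best_score:
                    best_score = s
                    best = {key: cand}
                    nxt = [cand]
                elif s == best_score and key not in best and len(best) < max_plateau:
                    best[key] = cand
                    nxt.append(cand)
        frontier = nxt
    return list(best.values()), best_score


def _edges_star(labels: Sequence[str]) -> Tree:
    from .trees import TreeNode

    root = TreeNode(children=[TreeNode(lab) for lab in labels])
    return Tree(root, rooted=False)


def _attachments(tree: Tree, taxon: str) -> List[Tree]:
    """All trees obtained by attaching ``taxon`` to each edge of an
    unrooted tree."""
    from .trees import TreeNode, _unrooted_adjacency, _grow

    adj, labels = _unrooted_adjacency(tree)
    edges = [(u, v) for u in adj for v, _ in adj[u] if u < v]
    out: List[Tree] = []
    for u, v in edges:
        # the new internal node subdividing (u,v) becomes the anchor
        root = TreeNode()
        root.add_child(_grow(u, v, adj, labels, None))
        root.add_child(_grow(v, u, adj, labels, None))
        root.add_child(TreeNode(taxon))
        out.append(Tree(root, rooted=False))
    return out


def gap_tree_accuracy(
    aln: Alignment, reference: Tree, collapse: bool = True
) -> float:
    """Accuracy of gap-parsimony trees against a reference topology.

    Builds the gap character matrix, finds all most parsimonious trees and
    returns their mean tree accuracy versus ``reference``.  Propagates
    :class:`NoGapSignalError` when the alignment has no informative gap
    pattern (the caller excludes the sample).
    """
    matrix = extract_gap_characters(aln, collapse=collapse)
    trees, _ = most_parsimonious_trees(matrix)
    scores = [tree_accuracy(t, reference) for t in trees]
    return sum(scores) / len(scores)
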