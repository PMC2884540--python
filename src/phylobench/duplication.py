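"""Minimum-duplication scoring of gene trees via species overlap.

A gene-tree node whose two child subtrees contain overlapping species sets
certifies a duplication.  Counting such nodes gives a conservative
(lower-bound) estimate of the number of duplication events implied by a
rooted gene tree.  Because the root position is usually unknown, the count
is minimised over all possible rootings, and then normalised by
subtracting the absolute minimum number of duplications m−1, where m is
the largest number of same-species genes in the family — a data-level
bound no tree can evade.  Lower normalised scores indicate gene trees (and
hence alignments) implying fewer spurious duplications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional

from .trees import Tree, TreeError, UnsupportedTopologyError, enumerate_rootings

__all__ = [
    "GeneFamily",
    "read_species_map",
    "species_map_from_headers",
    "absolute_min_duplications",
    "species_overlap_duplications",
    "min_duplications_over_rootings",
    "normalized_duplication_score",
]


@dataclass
class GeneFamily:
    """A set of homologous genes with their species of origin."""

    genes: List[str]
    species: Dict[str, str]  # gene id -> species id
    sequences: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if len(self.genes) < 2:
            raise ValueError("a gene family needs at least 2 genes")
        missing = [g for g in self.genes if g not in self.species]
        if missing:
            raise ValueError(f"genes without species mapping: {missing}")

    def species_counts(self) -> Counter:
        return Counter(self.species[g] for g in self.genes)


def read_species_map(path) -> Dict[str, str]:
    """Read a gene→species TSV mapping (two columns, no header)."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        gene, species = parts
        if gene in out:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        out[gene] = species
    return out


def species_map_from_headers(gene_ids) -> Dict[str, str]:
    """Fallback ``species|gene`` header convention: the species id is the
    text before the first ``|``."""
    out: Dict[str, str] = {}
    for gid in gene_ids:
        if "|" not in gid:
            raise ValueError(f"gene id {gid!r} lacks the species|gene separator")
        out[gid] = gid.split("|", 1)[0]
    return out


def absolute_min_duplications(family: GeneFamily) -> int:
    """m − 1, where m is the maximum number of same-species genes.

    Observing m paralogs in one genome requires at least m − 1 duplications
    regardless of the tree.
    """
    return max(family.species_counts().values()) - 1


def species_overlap_duplications(tree: Tree, species: Dict[str, str]) -> int:
    """Number of duplication nodes under the species-overlap rule.

    ``tree`` must be rooted and binary; a node is a duplication when its two
    children's descendant species sets intersect.
    """
    if not tree.rooted:
        raise UnsupportedTopologyError("species-overlap counting needs a rooted tree")
    missing = sorted(set(tree.leaf_labels) - set(species))
    if missing:
        raise TreeError(f"leaves without species mapping: {missing}")

    count = 0

    def species_below(node) -> FrozenSet[str]:
        nonlocal count
        if node.is_leaf:
            return frozenset((species[node.label],))
        if len(node.children) != 2:
            raise UnsupportedTopologyError(
                "species-overlap counting requires a binary tree"
            )
        left = species_below(node.children[0])
        right = species_below(node.children[1])
        if left & right:
            count += 1
        return left | right

    species_below(tree.root)
    return count


def min_duplications_over_rootings(tree: Tree, species: Dict[str, str]) -> int:
    """Minimum species-overlap duplication count over all 2n−3 rootings of
    an unrooted binary gene tree."""
    return min(
        species_overlap_duplications(rooted, species)
        for rooted in enumerate_rootings(tree)
    )


def normalized_duplication_score(
    tree: Tree, family: GeneFamily
) -> int:
    """Rooting-minimised duplication count minus the absolute minimum m−1.

    Non-negative by construction; 0 means the tree implies no duplications
    beyond those forced by the paralog counts themselves.
    """
    leaf_set = set(tree.leaf_labels)
    if leaf_set != set(family.genes):
        raise TreeError(
            f"tree leaves and family genes differ: {sorted(leaf_set ^ set(family.genes))}"
        )
    return min_duplications_over_rootings(tree, family.species) - absolute_min_duplications(
        family
    )
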