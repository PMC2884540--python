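"""Synthetic sequence families with known trees and true alignments.

Sequences evolve root-to-tips along a known species (or gene) tree under
the simplest exchangeable substitution model (a site hit by at least one
event is replaced uniformly by another residue) plus an insertion/deletion
process: indel events arrive in proportion to branch length × sequence
length × indel rate, insertions and deletions equally likely, lengths
geometric.  Site identities are tracked through the whole simulation, so
the generator knows the *true* alignment — the full homology relation —
against which aligner output can be scored exactly.

Gene families with duplications are generated by grafting copied subtrees
onto the species tree before sequence evolution, so the true duplication
count is known by construction.

Aligner emulators perturb the true alignment to a controllable degree
while preserving the ungapped sequences, standing in for alignment
programs of graded quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alignments import GAP, Alignment
from .duplication import GeneFamily
from .trees import Tree, TreeNode, comb_tree, random_binary_tree

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_orthologs",
    "simulate_family_with_duplications",
    "emulate_aligner",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated family.

    Branch lengths are in expected substitutions per site; the indel rate
    is expressed per substitution (expected indel events on a branch =
    indel_rate × branch length × sequence length).
    """

    n_taxa: int = 6
    topology: str = "comb"  # "comb" | "random"
    branch_length_range: Tuple[float, float] = (0.05, 0.3)
    sequence_length: int = 500
    indel_rate: float = 0.1
    indel_mean_length: float = 3.0
    duplications: int = 0
    alphabet: str = "aa"  # "aa" | "nt"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        if self.sequence_length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.indel_rate < 0 or self.indel_mean_length < 1:
            raise ValueError("invalid indel parameters")
        if self.topology not in ("comb", "random"):
            raise ValueError(f"unknown topology shape {self.topology!r}")
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


@dataclass
class SimulatedFamily:
    """Ground truth for one simulated gene family."""

    tree: Tree  # true rooted gene tree (leaves = gene ids)
    true_alignment: Alignment
    sequences: Dict[str, str]  # unaligned tip sequences
    species: Dict[str, str]  # gene id -> species id
    duplications: int

    @property
    def gene_family(self) -> GeneFamily:
        return GeneFamily(
            genes=list(self.true_alignment.ids),
            species=dict(self.species),
            sequences=dict(self.sequences),
        )


# ---------------------------------------------------------------------------
# sequence evolution with homology tracking
# ---------------------------------------------------------------------------

class _Master:
    """Global ordered registry of alignment columns.

    Every site ever created (ancestrally or by insertion) owns a column id;
    the registry keeps the left-to-right order in which columns appear in
    the true alignment.
    """

    def __init__(self, n: int) -> None:
        self.order: List[int] = list(range(n))
        self.next_id = n

    def insert_after(self, left_id: Optional[int], count: int) -> List[int]:
        """New column ids placed directly after ``left_id`` (or at the far
        left when ``left_id`` is None)."""
        ids = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        pos = 0 if left_id is None else self.order.index(left_id) + 1
        self.order[pos:pos] = ids
        return ids


def _evolve_branch(
    sites: List[Tuple[int, str]],
    length: float,
    cfg: SimulationConfig,
    master: _Master,
    rng: np.random.Generator,
    alphabet: str,
) -> List[Tuple[int, str]]:
    """Evolve a (column id, residue) sequence along one branch."""
    out = list(sites)
    if length <= 0:
        return out
    # substitutions: a site hit by >=1 Poisson event is replaced uniformly
    # by one of the other residues
    p_sub = 1.0 - np.exp(-length)
    if out and p_sub > 0:
        hits = np.nonzero(rng.random(len(out)) < p_sub)[0]
        for i in hits:
            col, res = out[i]
            choices = alphabet.replace(res, "")
            out[i] = (col, choices[rng.integers(len(choices))])
    # indels
    n_events = rng.poisson(cfg.indel_rate * length * max(len(out), 1))
    for _ in range(n_events):
        size = int(rng.geometric(1.0 / cfg.indel_mean_length))
        if rng.random() < 0.5 and out:  # deletion
            start = int(rng.integers(len(out)))
            del out[start : start + size]
        else:  # insertion
            pos = int(rng.integers(len(out) + 1))
            left = out[pos - 1][0] if pos > 0 else None
            cols = master.insert_after(left, size)
            residues = [alphabet[rng.integers(len(alphabet))] for _ in cols]
            out[pos:pos] = list(zip(cols, residues))
    return out


def _simulate_on_tree(
    tree: Tree, cfg: SimulationConfig, rng: np.random.Generator
) -> Tuple[Alignment, Dict[str, str]]:
    alphabet = AA_ALPHABET if cfg.alphabet == "aa" else NT_ALPHABET
    master = _Master(cfg.sequence_length)
    root_seq = [
        (i, alphabet[rng.integers(len(alphabet))]) for i in range(cfg.sequence_length)
    ]
    tip_sites: Dict[str, List[Tuple[int, str]]] = {}

    def walk(node: TreeNode, sites: List[Tuple[int, str]]) -> None:
        for child in node.children:
            evolved = _evolve_branch(
                sites, child.length or 0.0, cfg, master, rng, alphabet
            )
            if child.is_leaf:
                tip_sites[child.label] = evolved  # type: ignore[index]
            else:
                walk(child, evolved)

    walk(tree.root, root_seq)

    ids = sorted(tip_sites)
    position = {col: i for i, col in enumerate(master.order)}
    used = sorted(
        {col for sites in tip_sites.values() for col, _ in sites},
        key=position.__getitem__,
    )
    col_index = {col: i for i, col in enumerate(used)}
    rows: List[str] = []
    for gid in ids:
        row = [GAP] * len(used)
        for col, res in tip_sites[gid]:
            row[col_index[col]] = res
        rows.append("".join(row))
    aln = Alignment(ids=ids, rows=rows, alphabet=cfg.alphabet)
    return aln, aln.ungapped()


# ---------------------------------------------------------------------------
# family generators
# ---------------------------------------------------------------------------

def _species_tree(cfg: SimulationConfig, rng: np.random.Generator) -> Tree:
    labels = [f"s{i + 1}" for i in range(cfg.n_taxa)]
    if cfg.topology == "comb":
        return comb_tree(labels, rng=rng, branch_lengths=cfg.branch_length_range)
    return random_binary_tree(
        labels, rng, rooted=True, branch_lengths=cfg.branch_length_range
    )


def simulate_orthologs(cfg: SimulationConfig) -> SimulatedFamily:
    """One orthologous family: gene tree = species tree, one gene/species."""
    if cfg.duplications != 0:
        raise ValueError("ortholog simulation requires duplications = 0")
    rng = np.random.default_rng(cfg.seed)
    tree = _species_tree(cfg, rng)
    aln, seqs = _simulate_on_tree(tree, cfg, rng)
    species = {gid: gid for gid in aln.ids}
    return SimulatedFamily(
        tree=tree,
        true_alignment=aln,
        sequences=seqs,
        species=species,
        duplications=0,
    )


def _eligible_edges(root: TreeNode, dup_nodes: set) -> List[TreeNode]:
    """Branches a new duplication may act on: nodes whose subtree contains
    no earlier duplication node.  Duplicating above an existing duplication
    would copy that node and inflate the event count beyond the intended
    one-node-per-event bookkeeping."""
    eligible: List[TreeNode] = []

    def clean(node: TreeNode) -> bool:
        ok = id(node) not in dup_nodes
        for child in node.children:
            ok = clean(child) and ok
        if ok:
            eligible.append(node)
        return ok

    clean(root)
    return eligible


def simulate_family_with_duplications(cfg: SimulationConfig) -> SimulatedFamily:
    """A gene family whose true history contains ``cfg.duplications`` events.

    Each event picks a branch of the current gene tree uniformly (the root
    branch included), splits it at its midpoint and grafts a copy of the
    subtree below, so on the true rooted tree the duplication nodes are
    exactly the species-overlap nodes.
    """
    rng = np.random.default_rng(cfg.seed)
    species_tree = _species_tree(cfg, rng)
    gene_root = species_tree.root.copy()
    mean_len = float(np.mean(cfg.branch_length_range))
    gene_root.length = mean_len  # root branch: a duplication may predate the family

    holder = TreeNode(children=[gene_root])  # synthetic handle above the root branch
    dup_nodes: set = set()
    for _ in range(cfg.duplications):
        edges = _eligible_edges(holder.children[0], dup_nodes)
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        assert parent is not None
        half = (target.length or mean_len) / 2.0
        copy = target.copy()
        target.length = half
        copy.length = half
        dup = TreeNode(length=half, children=[target, copy])
        parent.children[parent.children.index(target)] = dup
        dup.parent = parent
        dup_nodes.add(id(dup))

    gene_root = holder.children[0]
    gene_root.parent = None
    # relabel leaves: unique gene ids carrying their species
    species: Dict[str, str] = {}
    counters: Dict[str, int] = {}
    for leaf in gene_root.leaves():
        sp = leaf.label
        counters[sp] = counters.get(sp, 0) + 1
        gid = f"{sp}g{counters[sp]}"
        species[gid] = sp
        leaf.label = gid
    gene_root.length = None
    tree = Tree(gene_root, rooted=True)
    aln, seqs = _simulate_on_tree(tree, cfg, rng)
    return SimulatedFamily(
        tree=tree,
        true_alignment=aln,
        sequences=seqs,
        species=species,
        duplications=cfg.duplications,
    )


# ---------------------------------------------------------------------------
# aligner emulators
# ---------------------------------------------------------------------------

def emulate_aligner(
    family: SimulatedFamily,
    degradation: float,
    rng_seed: int,
) -> Alignment:
    """An alignment of controllably degraded homology.

    ``degradation`` q = 0 returns the true alignment; q > 0 relocates each
    gap within a local window with probability q and additionally inserts
    per-row jittered gap columns (a fraction q of rows' worth per pass),
    mis-columning residues while preserving every ungapped sequence
    exactly.  The expected distance to the true alignment grows with q.
    """
    if not 0.0 <= degradation <= 1.0:
        raise ValueError("degradation must be in [0, 1]")
    truth = family.true_alignment
    if degradation == 0.0:
        return Alignment(
            ids=list(truth.ids), rows=list(truth.rows), alphabet=truth.alphabet
        )
    rng = np.random.default_rng(rng_seed)
    # displacement scale grows with q: a poor aligner misplaces whole
    # regions, not single columns
    window = max(3, int(round(40 * degradation)))
    rows = [list(r) for r in truth.rows]

    # 1) relocate individual gap characters within a local window;
    # positions of the remaining gaps are kept consistent as gaps move
    for row in rows:
        positions = [i for i, ch in enumerate(row) if ch == GAP]
        for k in range(len(positions)):
            if rng.random() >= degradation:
                continue
            offset = int(rng.integers(-window, window + 1))
            if offset == 0:
                continue
            p = positions[k]
            row.pop(p)
            for j in range(len(positions)):
                if j != k and positions[j] > p:
                    positions[j] -= 1
            new_p = min(max(p + offset, 0), len(row))
            row.insert(new_p, GAP)
            for j in range(len(positions)):
                if j != k and positions[j] >= new_p:
                    positions[j] += 1
            positions[k] = new_p

    # 2) jittered gap-column insertions: shear residues across rows
    n_shears = int(round(degradation * 0.05 * truth.width))
    for _ in range(n_shears):
        width = len(rows[0])
        centre = int(rng.integers(width + 1))
        for row in rows:
            pos = min(max(centre + int(rng.integers(-window, window + 1)), 0), len(row))
            row.insert(pos, GAP)

    out_rows = ["".join(r) for r in rows]
    # drop all-gap columns introduced by coinciding insertions
    keep = [
        j for j in range(len(out_rows[0])) if any(r[j] != GAP for r in out_rows)
    ]
    out_rows = ["".join(r[j] for j in keep) for r in out_rows]
    return Alignment(ids=list(truth.ids), rows=out_rows, alphabet=truth.alphabet)
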