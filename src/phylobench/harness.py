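"""The two alignment-evaluation pipelines and their statistics.

The species-tree discordance test scores an aligner by the average
topological accuracy (against a trusted reference species topology) of
trees built from its alignments of orthologous families.  The minimum
duplication test scores an aligner on homologous families by the average
number of duplications its trees imply beyond the data-level minimum —
fewer is better, no reference topology needed.

Aligners and tree builders are pluggable: the package ships aligner
emulators of graded quality and a neighbour-joining distance builder so
the whole pipeline runs without external programs, and a command-template
wrapper for real aligner/builder executables.
"""

from __future__ import annotations

import logging
import math
import re
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .alignments import (
    GAP,
    Alignment,
    AlignmentError,
    read_fasta,
    write_fasta,
)
from .duplication import GeneFamily, normalized_duplication_score
from .simdata import SimulatedFamily, emulate_aligner
from .trees import (
    StarTreeError,
    Tree,
    TreeError,
    parse_newick,
    relabel_leaves,
    tree_accuracy,
    unroot,
    write_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationRecord",
    "ReferenceTopology",
    "OrthologTable",
    "SampleFailure",
    "EmulatorAligner",
    "ExternalAligner",
    "DistanceTreeBuilder",
    "ExternalTreeBuilder",
    "builtin_distance_tree",
    "bootstrap_support",
    "sample_ortholog_set",
    "build_homolog_families",
    "run_discordance_test",
    "run_minimum_duplication_test",
    "summarize_records",
    "compare_methods",
    "MethodComparison",
]

SATURATION_CAP = 3.0  # substitutions/site assigned to undefined distances


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    """Per-sample, per-method outcome of one of the two tests."""

    sample_id: str
    method_id: str
    score: Optional[float] = None
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.score is None) == (not self.excluded):
            raise ValueError("a record carries a score xor an exclusion reason")


class SampleFailure(RuntimeError):
    """Raised when a sample cannot be drawn; the caller retries or skips."""


# ---------------------------------------------------------------------------
# aligner / builder interfaces
# ---------------------------------------------------------------------------

class EmulatorAligner:
    """Aligner emulator of controllable quality (0 = the true alignment)."""

    def __init__(self, method_id: str, degradation: float) -> None:
        self.method_id = method_id
        self.degradation = degradation

    def align(
        self,
        sample: SimulatedFamily,
        guide_tree: Optional[Tree] = None,
        seed: int = 0,
    ) -> Alignment:
        return emulate_aligner(sample, self.degradation, rng_seed=seed)


class ExternalAligner:
    """Shell out to an alignment program via a command template.

    The template must contain ``{input}`` and ``{output}`` placeholders
    (unaligned and aligned FASTA); ``{guidetree}`` is substituted when a
    guide tree is supplied.
    """

    def __init__(self, method_id: str, command_template: str) -> None:
        self.method_id = method_id
        self.command_template = command_template

    def align(
        self,
        sample: SimulatedFamily,
        guide_tree: Optional[Tree] = None,
        seed: int = 0,
    ) -> Alignment:
        with tempfile.TemporaryDirectory(prefix="phylobench-aln-") as tmp:
            tmpdir = Path(tmp)
            in_path = tmpdir / "in.fasta"
            out_path = tmpdir / "out.fasta"
            write_fasta(sample.sequences, in_path)
            mapping = {"input": str(in_path), "output": str(out_path)}
            if "{guidetree}" in self.command_template:
                guide_path = tmpdir / "guide.nwk"
                if guide_tree is None:
                    raise SampleFailure(
                        f"{self.method_id}: command requires a guide tree"
                    )
                guide_path.write_text(write_newick(guide_tree) + "\n")
                mapping["guidetree"] = str(guide_path)
            command = self.command_template.format(**mapping)
            proc = subprocess.run(
                command, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise SampleFailure(
                    f"{self.method_id}: exit {proc.returncode}: {proc.stderr[-500:]}"
                )
            aln = read_fasta(out_path)
        if aln.ungapped() != {k: v for k, v in sample.sequences.items()}:
            raise SampleFailure(
                f"{self.method_id}: aligner altered the input sequences"
            )
        return aln


# ---------------------------------------------------------------------------
# distance tree builder
# ---------------------------------------------------------------------------

def _corrected_distance(p: float, alphabet: str) -> float:
    """Poisson (amino acids) or Jukes-Cantor (nucleotides) correction of an
    observed mismatch fraction, capped at SATURATION_CAP."""
    try:
        if alphabet == "nt":
            if p >= 0.75:
                return SATURATION_CAP
            d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        else:
            if p >= 1.0:
                return SATURATION_CAP
            d = -math.log(1.0 - p)
    except ValueError:
        return SATURATION_CAP
    return min(d, SATURATION_CAP)


def _distance_matrix(aln: Alignment) -> np.ndarray:
    alphabet = aln.alphabet or "aa"
    n = aln.n_rows
    rows = np.array([list(r) for r in aln.rows])
    gaps = rows == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[i] & ~gaps[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                dist = SATURATION_CAP
                logger.debug(
                    "no shared ungapped sites for %s/%s; capped distance",
                    aln.ids[i],
                    aln.ids[j],
                )
            else:
                p = float((rows[i][shared] != rows[j][shared]).sum()) / n_shared
                dist = _corrected_distance(p, alphabet)
            d[i, j] = d[j, i] = dist
    return d


_LENGTH_RE = re.compile(r":[0-9eE.+-]+")


def builtin_distance_tree(aln: Alignment) -> Tree:
    """Neighbour-joining tree from corrected pairwise distances.

    Mismatch fractions use pairwise deletion of gap sites, corrected by the
    Poisson formula for amino acids or Jukes-Cantor for nucleotides, with
    undefined/saturated pairs capped at 3.0 substitutions/site.  The result
    is an unrooted topology (branch lengths dropped: every downstream
    metric is topological).  Deterministic for a given alignment.
    """
    if aln.n_rows < 3:
        raise AlignmentError("distance tree needs >= 3 sequences")
    if aln.width < 1:
        raise AlignmentError("distance tree needs alignment width >= 1")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(_distance_matrix(aln), ids=aln.ids)
    newick = str(nj(dm))
    return parse_newick(_LENGTH_RE.sub("", newick))


class DistanceTreeBuilder:
    """Pluggable wrapper around :func:`builtin_distance_tree`."""

    builder_id = "nj-builtin"

    def build(self, aln: Alignment) -> Tree:
        return builtin_distance_tree(aln)


class ExternalTreeBuilder:
    """Shell out to a tree program: ``{input}`` aligned FASTA, ``{output}``
    newick."""

    def __init__(self, builder_id: str, command_template: str) -> None:
        self.builder_id = builder_id
        self.command_template = command_template

    def build(self, aln: Alignment) -> Tree:
        with tempfile.TemporaryDirectory(prefix="phylobench-tree-") as tmp:
            tmpdir = Path(tmp)
            in_path = tmpdir / "in.fasta"
            out_path = tmpdir / "out.nwk"
            write_fasta(aln, in_path)
            command = self.command_template.format(
                input=str(in_path), output=str(out_path)
            )
            proc = subprocess.run(
                command, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise SampleFailure(
                    f"{self.builder_id}: exit {proc.returncode}: {proc.stderr[-500:]}"
                )
            tree = parse_newick(out_path.read_text())
        if tree.leaf_labels != frozenset(aln.ids):
            raise SampleFailure(f"{self.builder_id}: tree leaves != alignment ids")
        return tree


def bootstrap_support(
    aln: Alignment,
    builder,
    replicates: int,
    rng_seed: int,
) -> float:
    """Fraction of column-resampled replicate trees whose unrooted topology
    matches the tree inferred from the original alignment."""
    if replicates < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    base_tree = builder.build(aln)
    base_splits = None
    rng = np.random.default_rng(rng_seed)
    agree = 0
    done = 0
    from .trees import nontrivial_splits, robinson_foulds

    base_splits = nontrivial_splits(base_tree)
    for _ in range(replicates):
        cols = rng.integers(aln.width, size=aln.width)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep_aln = Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)
        try:
            rep_tree = builder.build(rep_aln)
        except (SampleFailure, AlignmentError, TreeError) as exc:
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        done += 1
        if nontrivial_splits(rep_tree) == base_splits:
            agree += 1
    if done == 0:
        raise SampleFailure("all bootstrap replicates failed")
    return agree / done


# ---------------------------------------------------------------------------
# sampling inputs
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTopology:
    """A rooted comb reference tree over clade names, with the candidate
    species allowed at each leaf."""

    tree: Tree
    candidates: Dict[str, List[str]]  # leaf label -> candidate species ids

    def __post_init__(self) -> None:
        leaves = set(self.tree.leaf_labels)
        if set(self.candidates) != leaves:
            raise ValueError("candidate sets must cover exactly the tree leaves")
        seen: Set[str] = set()
        for species in self.candidates.values():
            overlap = seen & set(species)
            if overlap:
                raise ValueError(f"candidate sets overlap: {sorted(overlap)}")
            seen |= set(species)

    def innermost_leaf(self) -> str:
        """The deepest leaf (ties: lexicographically smallest)."""
        best: Tuple[int, str] = (-1, "")

        def walk(node, depth: int) -> None:
            nonlocal best
            if node.is_leaf:
                key = (depth, node.label)
                if depth > best[0] or (depth == best[0] and node.label < best[1]):
                    best = (depth, node.label)
            for child in node.children:
                walk(child, depth + 1)

        walk(self.tree.root, 0)
        return best[1]


@dataclass
class OrthologTable:
    """Available sequences per species plus the pairwise orthology relation."""

    species_sequences: Dict[str, List[str]]
    orthologs: Set[frozenset]

    def species_of(self, seq_id: str) -> str:
        for sp, seqs in self.species_sequences.items():
            if seq_id in seqs:
                return sp
        raise KeyError(seq_id)

    def are_orthologous(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.orthologs


def sample_ortholog_set(
    ref: ReferenceTopology,
    table: OrthologTable,
    rng_seed: int,
) -> GeneFamily:
    """Draw one ortholog per reference leaf.

    A starting sequence is drawn uniformly from a uniformly chosen species
    of the innermost leaf; every remaining leaf then contributes a sequence
    drawn uniformly among its candidates orthologous to the starting
    sequence.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    inner = ref.innermost_leaf()
    inner_species = [
        sp for sp in ref.candidates[inner] if table.species_sequences.get(sp)
    ]
    if not inner_species:
        raise SampleFailure(f"no sequences available for innermost leaf {inner!r}")
    sp = inner_species[int(rng.integers(len(inner_species)))]
    seqs = table.species_sequences[sp]
    start = seqs[int(rng.integers(len(seqs)))]

    chosen: Dict[str, str] = {inner: start}
    for leaf in sorted(set(ref.tree.leaf_labels) - {inner}):
        pool = [
            seq
            for species in ref.candidates[leaf]
            for seq in table.species_sequences.get(species, [])
            if table.are_orthologous(start, seq)
        ]
        if not pool:
            raise SampleFailure(
                f"no ortholog of {start!r} among candidates of leaf {leaf!r}"
            )
        chosen[leaf] = pool[int(rng.integers(len(pool)))]
    genes = [chosen[leaf] for leaf in sorted(chosen)]
    species_map = {g: table.species_of(g) for g in genes}
    return GeneFamily(genes=genes, species=species_map)


def build_homolog_families(
    graph: nx.Graph,
    species: Dict[str, str],
    evalue_threshold: float = 1e-10,
    cap: int = 60,
    rng_seed: int = 0,
) -> List[GeneFamily]:
    """Homologous families as the transitive closure of significant hits.

    Keeps edges with E-value below the threshold, takes connected
    components, uniformly down-samples components above ``cap`` sequences
    (seeded) and drops singletons.
    """
    rng = np.random.default_rng(rng_seed)
    sub = nx.Graph()
    sub.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue
        evalue = data.get("evalue")
        if evalue is None or evalue <= 0:
            raise ValueError(f"edge {u}-{v} lacks a positive E-value")
        if evalue < evalue_threshold:
            sub.add_edge(u, v)
    families: List[GeneFamily] = []
    for component in sorted(nx.connected_components(sub), key=lambda c: sorted(c)[0]):
        members = sorted(component)
        if len(members) < 2:
            continue
        if len(members) > cap:
            keep = rng.choice(len(members), size=cap, replace=False)
            members = sorted(members[i] for i in keep)
        families.append(
            GeneFamily(genes=members, species={g: species[g] for g in members})
        )
    return families


# ---------------------------------------------------------------------------
# the two tests
# ---------------------------------------------------------------------------

def _per_call_seed(base_seed: int, sample_index: int, method_index: int) -> int:
    ss = np.random.SeedSequence((base_seed, sample_index, method_index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_discordance_test(
    samples: Sequence[SimulatedFamily],
    reference: Tree,
    aligners: Sequence,
    builder,
    base_seed: int = 0,
    postprocess: Optional[Callable[[Alignment], Alignment]] = None,
) -> List[EvaluationRecord]:
    """Species-tree discordance test over simulated ortholog families.

    Per sample × aligner: align, optionally post-process the alignment
    (e.g. gap filtering), build a tree, map gene leaves to species and
    score tree accuracy against the reference topology.  Failures become
    exclusion records; they never abort the run.
    """
    records: List[EvaluationRecord] = []
    for s_idx, sample in enumerate(samples):
        sample_id = f"sample{s_idx:04d}"
        for m_idx, aligner in enumerate(aligners):
            seed = _per_call_seed(base_seed, s_idx, m_idx)
            try:
                aln = aligner.align(sample, seed=seed)
                if postprocess is not None:
                    aln = postprocess(aln)
                if aln.width == 0:
                    raise SampleFailure("null-length alignment after filtering")
                tree = builder.build(aln)
                species_tree = relabel_leaves(tree, sample.species)
                score = tree_accuracy(species_tree, reference)
            except (SampleFailure, AlignmentError, TreeError, StarTreeError) as exc:
                logger.info("%s/%s excluded: %s", sample_id, aligner.method_id, exc)
                records.append(
                    EvaluationRecord(
                        sample_id=sample_id,
                        method_id=aligner.method_id,
                        excluded=True,
                        reason=str(exc),
                    )
                )
                continue
            records.append(
                EvaluationRecord(
                    sample_id=sample_id, method_id=aligner.method_id, score=score
                )
            )
    return records


def run_minimum_duplication_test(
    samples: Sequence[SimulatedFamily],
    aligners: Sequence,
    builder,
    base_seed: int = 0,
    postprocess: Optional[Callable[[Alignment], Alignment]] = None,
) -> List[EvaluationRecord]:
    """Minimum duplication test: per family × aligner, the normalised
    duplication score of the inferred tree (lower = better)."""
    records: List[EvaluationRecord] = []
    for s_idx, sample in enumerate(samples):
        sample_id = f"family{s_idx:04d}"
        family = sample.gene_family
        for m_idx, aligner in enumerate(aligners):
            seed = _per_call_seed(base_seed, s_idx, m_idx)
            try:
                aln = aligner.align(sample, seed=seed)
                if postprocess is not None:
                    aln = postprocess(aln)
                if aln.width == 0:
                    raise SampleFailure("null-length alignment after filtering")
                tree = unroot(builder.build(aln))
                score = float(normalized_duplication_score(tree, family))
            except (SampleFailure, AlignmentError, TreeError) as exc:
                logger.info("%s/%s excluded: %s", sample_id, aligner.method_id, exc)
                records.append(
                    EvaluationRecord(
                        sample_id=sample_id,
                        method_id=aligner.method_id,
                        excluded=True,
                        reason=str(exc),
                    )
                )
                continue
            records.append(
                EvaluationRecord(
                    sample_id=sample_id, method_id=aligner.method_id, score=score
                )
            )
    return records


# ---------------------------------------------------------------------------
# aggregation and method comparison
# ---------------------------------------------------------------------------

def records_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "method": [r.method_id for r in records],
            "score": [r.score if r.score is not None else np.nan for r in records],
            "excluded": [r.excluded for r in records],
            "reason": [r.reason for r in records],
        }
    )


def summarize_records(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Per-method mean ± standard deviation over included samples."""
    frame = records_frame(records)
    grouped = frame.groupby("method", sort=True)
    out = grouped.agg(
        n=("score", "count"),
        n_excluded=("excluded", "sum"),
        mean=("score", "mean"),
        sd=("score", lambda s: float(np.std(s.dropna(), ddof=1)) if s.count() > 1 else np.nan),
    ).reset_index()
    return out


@dataclass
class MethodComparison:
    """Paired Wilcoxon signed-rank comparison of two methods."""

    n_pairs: int  # informative (non-zero-difference) pairs
    statistic: Optional[float]
    p_value: Optional[float]
    insufficient: bool = False


def compare_methods(
    records_a: Sequence[EvaluationRecord],
    records_b: Sequence[EvaluationRecord],
    min_pairs: int = 6,
) -> MethodComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-sample scores.

    Samples excluded by either method are dropped pairwise; zero
    differences are dropped before ranking; the exact null is used for up
    to 25 informative pairs, a continuity-corrected normal approximation
    above that.  Fewer than ``min_pairs`` informative pairs yields an
    insufficient-data result instead of a p-value.
    """
    a = {r.sample_id: r.score for r in records_a if not r.excluded}
    b = {r.sample_id: r.score for r in records_b if not r.excluded}
    shared = sorted(set(a) & set(b))
    diffs = [a[s] - b[s] for s in shared]
    informative = [d for d in diffs if d != 0]
    if len(informative) < min_pairs:
        return MethodComparison(
            n_pairs=len(informative), statistic=None, p_value=None, insufficient=True
        )
    method = "exact" if len(informative) <= 25 else "approx"
    res = stats.wilcoxon(
        informative,
        zero_method="wilcox",
        alternative="two-sided",
        correction=(method == "approx"),
        method=method,
    )
    return MethodComparison(
        n_pairs=len(informative),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
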