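"""Alignment I/O, gap filtering, back-translation and alignment distances.

An :class:`Alignment` is an ordered set of equal-length rows over a residue
alphabet plus the gap symbol ``-`` (``.`` is normalised to ``-`` on input).
The alignment-to-alignment distance is the shared-homology-pair distance:
two alignments of the same sequences are compared by the residue-residue
pairs they place in the same column, which is the quantity an aligner
actually asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GAP = "-"
_GAP_CHARS = {"-", "."}
_STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = [
    "AlignmentError",
    "Alignment",
    "read_fasta",
    "read_sequences",
    "write_fasta",
    "backtranslate",
    "remove_gap_columns",
    "exclude_null",
    "homology_pairs",
    "alignment_distance",
    "average_alignment_variability",
]


class AlignmentError(ValueError):
    """Invalid alignment input."""


@dataclass
class Alignment:
    """Equal-length character rows with unique, ordered sequence ids."""

    ids: List[str]
    rows: List[str]
    alphabet: Optional[str] = None  # "aa" | "nt" | None (unknown)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {', '.join(dupes)}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self) -> Dict[str, str]:
        return {i: r.replace(GAP, "") for i, r in zip(self.ids, self.rows)}

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _normalise(seq: str) -> str:
    out = seq.upper()
    for ch in _GAP_CHARS:
        if ch != GAP:
            out = out.replace(ch, GAP)
    return out


def read_fasta(path, alphabet: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA file.

    Residues are uppercased and ``.`` gaps normalised to ``-``; records must
    all have the same length.
    """
    ids: List[str] = []
    rows: List[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(_normalise(str(record.seq)))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)


def read_sequences(path) -> Dict[str, str]:
    """Read unaligned FASTA sequences (gap characters stripped)."""
    out: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise AlignmentError(f"duplicate sequence id {record.id!r}")
        out[record.id] = _normalise(str(record.seq)).replace(GAP, "")
    if not out:
        raise AlignmentError(f"no FASTA records in {path}")
    return out


def write_fasta(aln_or_seqs, path) -> None:
    """Write an Alignment or an id→sequence mapping as FASTA."""
    if isinstance(aln_or_seqs, Alignment):
        items: Iterable[Tuple[str, str]] = zip(aln_or_seqs.ids, aln_or_seqs.rows)
    else:
        items = aln_or_seqs.items()
    with open(path, "w") as handle:
        for seq_id, seq in items:
            handle.write(f">{seq_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def backtranslate(
    aa_alignment: Alignment,
    cds: Dict[str, str],
    strict: bool = False,
) -> Alignment:
    """Rewrite an amino-acid alignment in codon space.

    Each residue is replaced by its actual codon from the coding sequence,
    each gap by ``---``; a terminal stop codon on the CDS is tolerated and
    dropped.  Codon/residue disagreements under the standard genetic code
    are logged (or raised with ``strict=True``).
    """
    rows: List[str] = []
    for seq_id, row in zip(aa_alignment.ids, aa_alignment.rows):
        if seq_id not in cds:
            raise AlignmentError(f"no coding sequence for {seq_id!r}")
        nt = _normalise(cds[seq_id]).replace(GAP, "")
        n_res = len(row) - row.count(GAP)
        if len(nt) == 3 * (n_res + 1) and nt[-3:] in _STOP_CODONS:
            nt = nt[:-3]
        if len(nt) != 3 * n_res:
            raise AlignmentError(
                f"coding sequence for {seq_id!r} has {len(nt)} nt; "
                f"expected {3 * n_res} for {n_res} residues"
            )
        out: List[str] = []
        pos = 0
        for res in row:
            if res == GAP:
                out.append("---")
                continue
            codon = nt[3 * pos : 3 * pos + 3]
            translated = str(Seq(codon).translate())
            if translated != res:
                msg = (
                    f"{seq_id!r} residue {pos}: codon {codon} translates to "
                    f"{translated}, alignment has {res}"
                )
                if strict:
                    raise AlignmentError(msg)
                logger.warning(msg)
            out.append(codon)
            pos += 1
        rows.append("".join(out))
    return Alignment(ids=list(aa_alignment.ids), rows=rows, alphabet="nt")


# ---------------------------------------------------------------------------
# gap-column filtering
# ---------------------------------------------------------------------------

def gap_columns(aln: Alignment) -> List[int]:
    """Indices of columns in which at least one sequence has a gap."""
    return [j for j in range(aln.width) if GAP in aln.column(j)]


def remove_gap_columns(aln: Alignment) -> Alignment:
    """Drop every column containing at least one gap character.

    The result may have width 0 (see :func:`exclude_null`).
    """
    drop = set(gap_columns(aln))
    keep = [j for j in range(aln.width) if j not in drop]
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)


def exclude_null(aln: Alignment) -> bool:
    """True when filtering left no columns, i.e. the sample must be dropped."""
    return aln.width == 0


# ---------------------------------------------------------------------------
# alignment distance
# ---------------------------------------------------------------------------

def homology_pairs(aln: Alignment) -> Set[Tuple[str, int, str, int]]:
    """Residue-residue pairs asserted by the alignment.

    Each element is (id_a, residue_index_a, id_b, residue_index_b) with
    id_a < id_b and residue indices 0-based over the ungapped sequences.
    Gap-residue pairs are not counted.
    """
    counters = [0] * aln.n_rows
    pairs: Set[Tuple[str, int, str, int]] = set()
    for j in range(aln.width):
        present = []
        for i in range(aln.n_rows):
            if aln.rows[i][j] != GAP:
                present.append(i)
        for i in present:
            counters[i] += 1
        for a, b in combinations(sorted(present, key=lambda i: aln.ids[i]), 2):
            pairs.add((aln.ids[a], counters[a] - 1, aln.ids[b], counters[b] - 1))
    return pairs


def _require_same_sequences(a1: Alignment, a2: Alignment) -> None:
    u1, u2 = a1.ungapped(), a2.ungapped()
    if set(u1) != set(u2):
        raise AlignmentError(
            f"alignments cover different ids: {sorted(set(u1) ^ set(u2))}"
        )
    for seq_id in u1:
        if u1[seq_id] != u2[seq_id]:
            raise AlignmentError(
                f"ungapped sequences differ for {seq_id!r}; the two alignments "
                "do not align the same sequences"
            )


def alignment_distance(a1: Alignment, a2: Alignment) -> float:
    """Shared-homology-pair distance between two alignments of the same
    sequences: 1 − |H1 ∩ H2| / max(|H1|, |H2|), in [0, 1]."""
    _require_same_sequences(a1, a2)
    h1, h2 = homology_pairs(a1), homology_pairs(a2)
    denom = max(len(h1), len(h2))
    if denom == 0:
        return 0.0
    return 1.0 - len(h1 & h2) / denom


def average_alignment_variability(alignments: Sequence[Alignment]) -> float:
    """Mean pairwise alignment distance — the alignment-variability measure."""
    if len(alignments) < 2:
        raise AlignmentError("need at least 2 alignments")
    dists = [
        alignment_distance(a, b) for a, b in combinations(alignments, 2)
    ]
    return sum(dists) / len(dists)
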