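"""Pairwise global alignment, protein-guided codon alignment, identity.

Pairwise alignment is Needleman-Wunsch with affine gaps via
Bio.Align.PairwiseAligner; a gap of length k costs open + (k-1)*extend.
Three-way codon alignments are built centre-star on the translated
proteins and back-translated, so gaps only ever occur as whole codons —
a requirement of the Li-method counting downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import GAP_CODON
from .io import CodingSequence

__all__ = [
    "ScoringParams",
    "PairwiseAlignment",
    "CodonAlignment",
    "global_align",
    "build_codon_alignment",
    "percent_identity",
    "nt_identity",
]


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring for :func:`global_align`.

    For nucleotides the defaults are match +1 / mismatch -1 with gap open
    -8 and extension -1 (deliberately indel-averse for whole-genome
    identity); set ``protein=True`` to score with BLOSUM62 instead.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    protein: bool = False

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        if self.protein:
            a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        else:
            a.match_score = self.match
            a.mismatch_score = self.mismatch
        # PairwiseAligner convention: first gap residue costs open_gap_score
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


PROTEIN_SCORING = ScoringParams(gap_open=-10.0, gap_extend=-1.0, protein=True)


@dataclass
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    columns: list[tuple[str, str]]  # residue or '-' per row; never ('-','-')
    score: float

    @property
    def aligned_a(self) -> str:
        return "".join(a for a, _ in self.columns)

    @property
    def aligned_b(self) -> str:
        return "".join(b for _, b in self.columns)


def global_align(
    a: str,
    b: str,
    params: ScoringParams | None = None,
    ids: tuple[str, str] = ("a", "b"),
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences.

    Deterministic: of co-optimal alignments the aligner's first traceback
    is returned, which is stable for a fixed Biopython version.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or ScoringParams()
    aln = params.aligner().align(a, b)
    best = aln[0]
    rows = (str(best[0]), str(best[1]))
    columns = list(zip(*rows))
    return PairwiseAlignment(ids[0], ids[1], columns, float(best.score))


def percent_identity(aln: PairwiseAlignment, mode: str = "nt") -> float:
    """Fraction of identical columns.

    Columns containing a gap count in the denominator but never the
    numerator, so 'overall' identity between sequences of unequal length
    is penalised for indels.  ``mode`` is cosmetic (nt vs aa alignments
    share the definition).
    """
    if not aln.columns:
        raise ValueError("empty alignment")
    matches = sum(1 for x, y in aln.columns if x == y and x != "-")
    return matches / len(aln.columns)


def nt_identity(a: str, b: str, params: ScoringParams | None = None) -> float:
    """Whole-sequence nucleotide identity from one global alignment."""
    return percent_identity(global_align(a, b, params))


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Gap-aware codon alignment of three tips (plus, elsewhere, their
    reconstructed ancestor); gaps occur only as whole codons."""

    gene: str
    rows: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def __post_init__(self):
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged codon alignment for gene {self.gene!r}")

    def row_codons(self, seq_id: str) -> list[str]:
        """The ungapped codons of one row (back-projection)."""
        return [c for c in self.rows[seq_id] if c != GAP_CODON]

    def row_nt(self, seq_id: str) -> str:
        return "".join(self.rows[seq_id])

    def subset(self, codon_range: tuple[int, int]) -> "CodonAlignment":
        lo, hi = codon_range
        return CodonAlignment(
            self.gene, {k: v[lo - 1 : hi] for k, v in self.rows.items()}
        )

    def permuted(self, perm: np.ndarray) -> "CodonAlignment":
        """Reorder codon columns jointly across all rows."""
        return CodonAlignment(
            self.gene, {k: [v[i] for i in perm] for k, v in self.rows.items()}
        )


def _segments(center_aligned: str, other_aligned: str) -> list[list[str]]:
    """Split a (center, other) pairwise alignment into, per center residue,
    the other-row insertions preceding it; the final list holds trailing
    insertions."""
    n_center = sum(1 for c in center_aligned if c != "-")
    segs: list[list[str]] = [[] for _ in range(n_center + 1)]
    matched: list[str] = [""] * n_center
    i = 0
    for c, o in zip(center_aligned, other_aligned):
        if c == "-":
            segs[i].append(o)
        else:
            matched[i] = o
            i += 1
    return [segs[k] + ([matched[k]] if k < n_center else [])
            for k in range(n_center + 1)]


def build_codon_alignment(
    cds_by_genome: Mapping[str, CodingSequence],
    params: ScoringParams = PROTEIN_SCORING,
    gene: str | None = None,
) -> CodonAlignment:
    """Centre-star protein-guided codon alignment of exactly three CDSs.

    Proteins are aligned pairwise; the centre is the sequence with the
    highest summed pairwise score (ties to the lexicographically smallest
    id).  The two outer proteins are merged through the centre's
    coordinates, and each aligned residue is replaced by its source codon
    (protein gaps become gap triplets).
    """
    from .io import translate  # local import to avoid cycle at import time

    if len(cds_by_genome) != 3:
        raise ValueError(f"need exactly 3 coding sequences, got {len(cds_by_genome)}")
    ids = sorted(cds_by_genome)
    gene = gene or next(iter(cds_by_genome.values())).orf_name
    prot = {i: translate(cds_by_genome[i]) for i in ids}

    score_sum = {i: 0.0 for i in ids}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        s = global_align(prot[ids[i]], prot[ids[j]], params).score
        score_sum[ids[i]] += s
        score_sum[ids[j]] += s
    best = max(score_sum.values())
    center = min(i for i in ids if score_sum[i] == best)
    others = [i for i in ids if i != center]

    alns = {o: global_align(prot[center], prot[o], params) for o in others}
    segs = {o: _segments(alns[o].aligned_a, alns[o].aligned_b) for o in others}
    n_center = len(prot[center])

    merged: dict[str, list[str]] = {center: [], others[0]: [], others[1]: []}
    for k in range(n_center + 1):
        s0, s1 = segs[others[0]][k], segs[others[1]][k]
        has_center = k < n_center
        ins0 = s0[:-1] if has_center else s0
        ins1 = s1[:-1] if has_center else s1
        width = max(len(ins0), len(ins1))
        merged[center] += ["-"] * width
        merged[others[0]] += ["-"] * (width - len(ins0)) + ins0
        merged[others[1]] += ["-"] * (width - len(ins1)) + ins1
        if has_center:
            merged[center].append(prot[center][k])
            merged[others[0]].append(s0[-1])
            merged[others[1]].append(s1[-1])

    rows: dict[str, list[str]] = {}
    for i in ids:
        codons = iter(cds_by_genome[i].codons)
        rows[i] = [next(codons) if aa != "-" else GAP_CODON for aa in merged[i]]
    return CodonAlignment(gene, rows)


def concat_alignments(alns: Sequence[CodonAlignment]) -> CodonAlignment:
    """Concatenate per-gene alignments sharing the same row ids."""
    ids = alns[0].ids
    rows = {i: [] for i in ids}
    for a in alns:
        if a.ids != ids:
            raise ValueError("alignments have mismatched row ids")
        for i in ids:
            rows[i] = rows[i] + a.rows[i]
    return CodonAlignment("+".join(a.gene for a in alns), rows)
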