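"""Star-tree ancestral sequence inference under the Kimura 2-parameter model.

The three viral lineages are treated as tips of an unresolved star tree
with a single internal node.  Branch lengths come from pairwise K2P
distances via the three-point formula; the ancestral state at each
nucleotide column is the marginal maximum-likelihood state under K2P with
uniform root frequencies.  Per-site independence keeps every column
exactly checkable by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import CodonAlignment
from .codons import BASES, GAP_CODON, STOP_CODONS

__all__ = [
    "StarTree",
    "AncestralSequence",
    "k2p_transition_matrix",
    "k2p_distance",
    "estimate_branch_lengths",
    "reconstruct_ancestor",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
ANCESTOR_ID = "ancestor"


@dataclass(frozen=True)
class StarTree:
    tip_ids: tuple[str, str, str]
    branch_lengths: tuple[float, float, float]  # expected nt subst/site
    kappa: float

    def __post_init__(self):
        if any(b < 0 for b in self.branch_lengths):
            raise ValueError("branch lengths must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def length_of(self, tip_id: str) -> float:
        return self.branch_lengths[self.tip_ids.index(tip_id)]


@dataclass
class AncestralSequence:
    """Marginal-ML ancestor: per-nucleotide states (with gaps) plus the
    normalized likelihood of each chosen state."""

    states: str  # over ACGT-
    support: np.ndarray  # in (0, 1]; 1.0 at gap columns by convention

    @property
    def codons(self) -> list[str]:
        out = []
        for i in range(0, len(self.states), 3):
            c = self.states[i : i + 3]
            out.append(GAP_CODON if "-" in c else c)
        return out

    @property
    def stop_codon_mask(self) -> np.ndarray:
        """Codons where the reconstruction is a stop; excluded downstream."""
        return np.array([c in STOP_CODONS for c in self.codons])


def k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """P(x -> y | t) under K2P, rates scaled so t is substitutions/site.

    Closed form with transition rate alpha = kappa/(kappa+2) and
    transversion rate beta = 1/(kappa+2) (so alpha + 2*beta = 1).
    Base order A, C, G, T; transitions are A<->G and C<->T.
    """
    if t < 0:
        raise ValueError("negative branch length")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    M = np.full((4, 4), p_tv)
    for i in range(4):
        M[i, i] = p_same
    M[_BASE_INDEX["A"], _BASE_INDEX["G"]] = p_ts
    M[_BASE_INDEX["G"], _BASE_INDEX["A"]] = p_ts
    M[_BASE_INDEX["C"], _BASE_INDEX["T"]] = p_ts
    M[_BASE_INDEX["T"], _BASE_INDEX["C"]] = p_ts
    return M


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two equal-length gap-free nucleotide strings."""
    if len(a) != len(b) or not a:
        raise ValueError("sequences must be non-empty and equal length")
    from .codons import is_transition

    n = len(a)
    ts = sum(1 for x, y in zip(a, b) if x != y and is_transition(x, y))
    tv = sum(1 for x, y in zip(a, b) if x != y and not is_transition(x, y))
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"saturated K2P distance (P={P:.3f}, Q={Q:.3f})")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def _gap_free_nt(alns: Sequence[CodonAlignment]) -> dict[str, str]:
    """Concatenated nucleotide columns at which no row has a gap or N."""
    ids = alns[0].ids
    rows = {i: [] for i in ids}
    for aln in alns:
        mat = [aln.rows[i] for i in ids]
        for col in zip(*mat):
            if any(c == GAP_CODON or "N" in c for c in col):
                continue
            for i, c in zip(ids, col):
                rows[i].append(c)
    return {i: "".join(v) for i, v in rows.items()}


def three_point_branch_lengths(
    d_12: float, d_13: float, d_23: float
) -> tuple[float, float, float]:
    """Star-tree branch lengths from the three pairwise distances:
    b_i = (d_ij + d_ik - d_jk) / 2, clamped at zero."""
    b1 = max(0.0, (d_12 + d_13 - d_23) / 2.0)
    b2 = max(0.0, (d_12 + d_23 - d_13) / 2.0)
    b3 = max(0.0, (d_13 + d_23 - d_12) / 2.0)
    return b1, b2, b3


def estimate_branch_lengths(
    alns: CodonAlignment | Sequence[CodonAlignment], kappa: float = 2.0
) -> StarTree:
    """Star-tree branch lengths from pairwise K2P distances.

    Uses gap-free nucleotide columns only.  For tips i, j, k the
    three-point formula gives b_i = (d_ij + d_ik - d_jk) / 2, clamped at
    zero.  Saturated pairs raise, naming the pair.
    """
    if isinstance(alns, CodonAlignment):
        alns = [alns]
    ids = [i for i in alns[0].ids if i != ANCESTOR_ID]
    if len(ids) != 3:
        raise ValueError(f"need a 3-tip alignment, got tips {ids}")
    nt = _gap_free_nt([CodonAlignment(a.gene, {i: a.rows[i] for i in ids})
                       for a in alns])
    if not nt[ids[0]]:
        raise ValueError("no gap-free columns to estimate distances from")
    d = {}
    for x in range(3):
        for y in range(x + 1, 3):
            try:
                d[(x, y)] = d[(y, x)] = k2p_distance(nt[ids[x]], nt[ids[y]])
            except ValueError as e:
                raise ValueError(
                    f"K2P distance {ids[x]}-{ids[y]} failed: {e}"
                ) from e
    b = three_point_branch_lengths(d[(0, 1)], d[(0, 2)], d[(1, 2)])
    return StarTree(tuple(ids), b, kappa)


def reconstruct_ancestor(aln: CodonAlignment, tree: StarTree) -> AncestralSequence:
    """Marginal ML ancestral states, column by column.

    Root frequencies are uniform; the chosen state maximises the product of
    tip transition probabilities, ties broken in A<C<G<T order.  A column
    is reconstructed as a gap when two or more tips are gapped; a
    single-tip gap (or N) simply drops that tip's factor.  Support is the
    normalized likelihood of the chosen state.
    """
    tips = tree.tip_ids
    missing = set(tips) - set(aln.rows)
    if missing:
        raise ValueError(f"alignment lacks rows for tips {sorted(missing)}")
    mats = [k2p_transition_matrix(b, tree.kappa) for b in tree.branch_lengths]
    # factor matrices with an extra column for missing data (gap or N)
    fm = []
    for M in mats:
        F = np.ones((4, 5))
        F[:, :4] = M
        fm.append(F)

    n_nt = 3 * aln.n_columns
    codes = np.empty((3, n_nt), dtype=np.int64)
    is_gap = np.zeros((3, n_nt), dtype=bool)
    for r, tip in enumerate(tips):
        s = aln.row_nt(tip)
        codes[r] = [_BASE_INDEX.get(c, 4) for c in s]
        is_gap[r] = np.frombuffer(s.encode(), dtype=np.uint8) == ord("-")

    like = fm[0][:, codes[0]] * fm[1][:, codes[1]] * fm[2][:, codes[2]]  # (4, n)
    choice = np.argmax(like, axis=0)  # first max == A<C<G<T tie order
    total = like.sum(axis=0)
    support = like[choice, np.arange(n_nt)] / total

    gap_cols = is_gap.sum(axis=0) >= 2
    states = np.array(list(BASES))[choice]
    states[gap_cols] = "-"
    support = np.where(gap_cols, 1.0, support)
    return AncestralSequence("".join(states), support)
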