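"""Nonsynonymous/synonymous divergence between codon sequences, after Li.

This module implements the counting estimator of Li (1993) / Pamilo &
Bianchi (1993).  Each codon position is assigned a degeneracy class —
nondegenerate (0-fold), twofold or fourfold — by enumerating its three
single-nucleotide alternatives against the standard genetic code (changes
to stop codons count as nonsynonymous).  Differences between two aligned
codons are classified as transitions or transversions, assigned half-weight
to each codon's site class when the two classes disagree, and corrected for
multiple hits with Kimura's two-parameter formulae:

    A = 1/2 ln(1/(1-2P-Q)) - 1/4 ln(1/(1-2Q))        (transitions)
    B = 1/2 ln(1/(1-2Q))                             (transversions)

per class i with site counts L_i and difference proportions P_i, Q_i.  The
rate estimates are

    Ka = A_0 + (L_0 B_0 + L_2 B_2) / (L_0 + L_2)
    Ks = (L_2 A_2 + L_4 A_4) / (L_2 + L_4) + B_4

For codons differing at more than one position the per-step classifications
are averaged over all orderings of the single changes; orderings passing
through a stop codon are excluded, and pairs for which every ordering is
excluded are skipped (and tallied) rather than guessed at.

Saturated comparisons (any required log argument <= 0) are reported as
invalid, never clipped: silently clipping them would bias the
genome-wide randomization null built on top of these numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .codons import (
    AMINO_ACID,
    BASES,
    GAP_CODON,
    SENSE_CODONS,
    SENSE_INDEX,
    is_stop,
    is_transition,
)

__all__ = [
    "SaturationError",
    "SiteClassProfile",
    "SubstitutionCounts",
    "DivergenceEstimate",
    "classify_sites",
    "count_codon_pair",
    "k2p_correct",
    "compute_ka_ks",
    "branch_ka",
    "encode_codons",
    "pair_tables",
    "column_stats",
    "ka_from_sums",
    "ka_ks_from_sums",
]

# degeneracy class values and their index into the per-class arrays
CLASSES = (0, 2, 4)
_CLASS_INDEX = {0: 0, 2: 1, 4: 2}


class SaturationError(ValueError):
    """Raised when observed difference proportions exceed the K2P ceiling."""


# ---------------------------------------------------------------------------
# site degeneracy
# ---------------------------------------------------------------------------

SiteClassProfile = tuple[int, int, int]


@lru_cache(maxsize=None)
def classify_sites(codon: str) -> SiteClassProfile:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon.

    A position is fourfold if all three single-nucleotide alternatives are
    synonymous, nondegenerate if none is, and twofold otherwise (this folds
    the threefold isoleucine third position into the twofold class, the
    standard Li-method convention).  Changes to stop codons are
    nonsynonymous.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site-class profile")
    if codon not in AMINO_ACID:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = AMINO_ACID[codon]
    profile = []
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if not is_stop(mutant) and AMINO_ACID[mutant] == aa:
                syn += 1
        profile.append(0 if syn == 0 else 4 if syn == 3 else 2)
    return tuple(profile)  # type: ignore[return-value]


def _stop_free_ordering_exists(a: str, b: str, diffs: Sequence[int]) -> bool:
    """Whether some ordering of the single changes a->b avoids stop codons.

    Only intermediate codons matter: a and b are sense by precondition.
    """
    if len(diffs) <= 1:
        return True
    for order in itertools.permutations(diffs):
        current = a
        ok = True
        for pos in order[:-1]:  # the final step lands on b itself
            current = current[:pos] + b[pos] + current[pos + 1 :]
            if is_stop(current):
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# pair counting
# ---------------------------------------------------------------------------


@dataclass
class PairCounts:
    """Increments contributed by one aligned codon pair."""

    sites: np.ndarray  # shape (3,): L increments per class
    transitions: np.ndarray  # shape (3,)
    transversions: np.ndarray  # shape (3,)
    comparable: bool  # False when every mutational ordering passes a stop


def count_codon_pair(a: str, b: str) -> PairCounts:
    """Per-class site and difference increments for one codon pair.

    The site class of a position is averaged over the two codons (half
    weight each when they differ), which keeps the total site count exactly
    3 per compared pair.  Because classes and the transition/transversion
    type of each changed position depend only on the two end-point codons,
    every stop-free ordering contributes identical increments; ordering
    enumeration therefore only decides whether the pair is comparable at
    all.
    """
    prof_a = classify_sites(a)
    prof_b = classify_sites(b)
    sites = np.zeros(3)
    ts = np.zeros(3)
    tv = np.zeros(3)
    for pos in range(3):
        sites[_CLASS_INDEX[prof_a[pos]]] += 0.5
        sites[_CLASS_INDEX[prof_b[pos]]] += 0.5
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not _stop_free_ordering_exists(a, b, diffs):
        return PairCounts(np.zeros(3), np.zeros(3), np.zeros(3), comparable=False)
    for pos in diffs:
        target = ts if is_transition(a[pos], b[pos]) else tv
        target[_CLASS_INDEX[prof_a[pos]]] += 0.5
        target[_CLASS_INDEX[prof_b[pos]]] += 0.5
    return PairCounts(sites, ts, tv, comparable=True)


@lru_cache(maxsize=1)
def pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """Vectorised lookup tables over all 61x61 sense-codon pairs.

    Returns ``(stats, ok)`` where ``stats[i, j]`` is the length-9 vector
    ``[L0, L2, L4, ts0, ts2, ts4, tv0, tv2, tv4]`` for codon pair
    ``(SENSE_CODONS[i], SENSE_CODONS[j])`` and ``ok[i, j]`` is False for
    the (rare) pairs whose every mutational pathway crosses a stop codon.
    """
    n = len(SENSE_CODONS)
    stats = np.zeros((n, n, 9))
    ok = np.ones((n, n), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            pc = count_codon_pair(a, b)
            if not pc.comparable:
                ok[i, j] = False
                continue
            stats[i, j, 0:3] = pc.sites
            stats[i, j, 3:6] = pc.transitions
            stats[i, j, 6:9] = pc.transversions
    stats.setflags(write=False)
    ok.setflags(write=False)
    return stats, ok


def encode_codons(codons: Iterable[str]) -> np.ndarray:
    """Map codons to sense-codon indices; gaps, stops and ambiguous codons
    become -1 (excluded from comparison)."""
    return np.array([SENSE_INDEX.get(c, -1) for c in codons], dtype=np.int64)


def column_stats(a_idx: np.ndarray, b_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Li increments for two encoded codon rows.

    Returns ``(stats, usable)``: ``stats`` has shape (n, 9) with zero rows
    at unusable columns, ``usable`` flags columns where both codons are
    sense and the pair is comparable.  Column stats are independent of
    column order, the property the codon-shuffling null relies on.
    """
    stats_tab, ok_tab = pair_tables()
    both = (a_idx >= 0) & (b_idx >= 0)
    usable = both.copy()
    usable[both] = ok_tab[a_idx[both], b_idx[both]]
    out = np.zeros((len(a_idx), 9))
    out[usable] = stats_tab[a_idx[usable], b_idx[usable]]
    return out, usable


# ---------------------------------------------------------------------------
# K2P correction and the Ka/Ks estimates
# ---------------------------------------------------------------------------


def k2p_correct(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter distances from transition/transversion
    proportions.

    Raises :class:`SaturationError` when a log argument is non-positive;
    callers mark the estimate invalid rather than clipping.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError(f"invalid proportions P={P}, Q={Q}")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P:.4f}, Q={Q:.4f}")
    A = 0.5 * np.log(1.0 / w1) - 0.25 * np.log(1.0 / w2)
    B = 0.5 * np.log(1.0 / w2)
    return float(A), float(B)


@dataclass
class SubstitutionCounts:
    """Aggregated per-class site counts and raw difference counts."""

    sites: np.ndarray = field(default_factory=lambda: np.zeros(3))  # L0, L2, L4
    transitions: np.ndarray = field(default_factory=lambda: np.zeros(3))
    transversions: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_pairs: int = 0  # comparable codon pairs
    n_skipped: int = 0  # sense pairs whose every pathway crossed a stop

    def add(self, pc: PairCounts) -> None:
        if not pc.comparable:
            self.n_skipped += 1
            return
        self.sites += pc.sites
        self.transitions += pc.transitions
        self.transversions += pc.transversions
        self.n_pairs += 1

    @property
    def P(self) -> np.ndarray:
        """Transitional difference proportion per class (0 where L_i = 0)."""
        return np.divide(
            self.transitions, self.sites,
            out=np.zeros(3), where=self.sites > 0,
        )

    @property
    def Q(self) -> np.ndarray:
        return np.divide(
            self.transversions, self.sites,
            out=np.zeros(3), where=self.sites > 0,
        )


@dataclass
class DivergenceEstimate:
    counts: SubstitutionCounts
    A: np.ndarray  # per class; nan where saturated
    B: np.ndarray
    ka: float  # nan when invalid
    ks: float
    valid: bool
    invalid_reason: str = ""

    @property
    def ka_ks(self) -> float:
        if not np.isfinite(self.ka) or not np.isfinite(self.ks) or self.ks == 0:
            return float("nan")
        return self.ka / self.ks


def compute_ka_ks(counts: SubstitutionCounts) -> DivergenceEstimate:
    """Li-method Ka and Ks from aggregated counts.

    Classes with L_i = 0 contribute zero at zero weight; the estimate is
    invalid when a required denominator (L0+L2 for Ka, L2+L4 for Ks) is
    zero or a required correction saturates.
    """
    L = counts.sites
    P = counts.P
    Q = counts.Q
    A = np.full(3, np.nan)
    B = np.full(3, np.nan)
    sat = [False, False, False]
    for i in range(3):
        if L[i] == 0:
            A[i] = B[i] = 0.0
            continue
        try:
            A[i], B[i] = k2p_correct(P[i], Q[i])
        except SaturationError:
            sat[i] = True
            w2 = 1.0 - 2.0 * Q[i]
            if w2 > 0:  # B only needs the transversion log
                B[i] = 0.5 * np.log(1.0 / w2)
    reasons = []
    if counts.n_pairs == 0:
        return DivergenceEstimate(
            counts, A, B, float("nan"), float("nan"), False, "no comparable codons"
        )

    ka = float("nan")
    if L[0] + L[1] == 0:
        reasons.append("no nonsynonymous sites (L0+L2 = 0)")
    elif not (np.isfinite(A[0]) and np.isfinite(B[0]) and np.isfinite(B[1])):
        reasons.append("saturation in a class required for Ka")
    else:
        ka = float(A[0] + (L[0] * B[0] + L[1] * B[1]) / (L[0] + L[1]))

    ks = float("nan")
    if L[1] + L[2] == 0:
        reasons.append("no synonymous sites (L2+L4 = 0)")
    elif not (np.isfinite(A[1]) and np.isfinite(A[2]) and np.isfinite(B[2])):
        reasons.append("saturation in a class required for Ks")
    else:
        ks = float((L[1] * A[1] + L[2] * A[2]) / (L[1] + L[2]) + B[2])

    valid = np.isfinite(ka) and np.isfinite(ks)
    return DivergenceEstimate(counts, A, B, ka, ks, bool(valid), "; ".join(reasons))


def estimate_pair(
    codons_a: Sequence[str], codons_b: Sequence[str]
) -> DivergenceEstimate:
    """Ka/Ks between two equal-length codon sequences (gap/N columns
    skipped)."""
    if len(codons_a) != len(codons_b):
        raise ValueError("codon sequences differ in length")
    counts = SubstitutionCounts()
    for a, b in zip(codons_a, codons_b):
        if a == GAP_CODON or b == GAP_CODON:
            continue
        if a not in SENSE_INDEX or b not in SENSE_INDEX:
            continue
        counts.add(count_codon_pair(a, b))
    return compute_ka_ks(counts)


def branch_ka(
    aln,
    ancestor,
    tip_id: str,
    codon_range: tuple[int, int] | None = None,
) -> DivergenceEstimate:
    """Divergence of one tip from the inferred ancestor over a codon range.

    ``codon_range`` is 1-based inclusive in alignment-codon coordinates;
    None means the full alignment.  Columns where either the tip or the
    ancestor holds a gap, an ambiguous codon or a (reconstructed) stop are
    skipped.
    """
    tip = aln.rows[tip_id]
    anc = ancestor.codons
    if len(anc) != len(tip):
        raise ValueError("ancestor length does not match alignment")
    if codon_range is None:
        codon_range = (1, len(tip))
    lo, hi = codon_range
    if not (1 <= lo <= hi <= len(tip)):
        raise ValueError(f"codon range {codon_range} outside alignment")
    return estimate_pair(tip[lo - 1 : hi], anc[lo - 1 : hi])


# ---------------------------------------------------------------------------
# vectorised window evaluation
# ---------------------------------------------------------------------------


def ka_ks_from_sums(sums: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Ka and Ks from summed column stats.

    ``sums[..., 0:9]`` holds [L0, L2, L4, ts0, ts2, ts4, tv0, tv2, tv4];
    invalid (saturated or empty-class) entries come back as nan.  Matches
    :func:`compute_ka_ks` exactly on valid input — asserted in the tests.
    """
    L = sums[..., 0:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, sums[..., 3:6] / np.where(L > 0, L, 1.0), 0.0)
        Q = np.where(L > 0, sums[..., 6:9] / np.where(L > 0, L, 1.0), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        okA = (w1 > 0) & (w2 > 0)
        okB = w2 > 0
        A = np.where(okA, 0.5 * np.log(1.0 / np.where(okA, w1, 1.0))
                     - 0.25 * np.log(1.0 / np.where(okB, w2, 1.0)), np.nan)
        B = np.where(okB, 0.5 * np.log(1.0 / np.where(okB, w2, 1.0)), np.nan)
        A = np.where(L > 0, A, 0.0)
        B = np.where(L > 0, B, 0.0)
        dn_den = L[..., 0] + L[..., 1]
        ka = np.where(
            dn_den > 0,
            A[..., 0] + (L[..., 0] * B[..., 0] + L[..., 1] * B[..., 1])
            / np.where(dn_den > 0, dn_den, 1.0),
            np.nan,
        )
        ds_den = L[..., 1] + L[..., 2]
        ks = np.where(
            ds_den > 0,
            (L[..., 1] * A[..., 1] + L[..., 2] * A[..., 2])
            / np.where(ds_den > 0, ds_den, 1.0) + B[..., 2],
            np.nan,
        )
    return ka, ks


def ka_from_sums(sums: np.ndarray) -> np.ndarray:
    return ka_ks_from_sums(sums)[0]
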