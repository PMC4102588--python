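"""Genome-wide peak significance by codon-column randomization.

The null model asks how large the largest window Ka would be if the
observed per-codon divergence were spread randomly along the genome:
codon columns are shuffled jointly across tips and ancestor (within each
gene, since windows never span genes), the window scan is repeated, and
the per-branch maximum window Ka is recorded per replicate.  The
genome-wide 95% threshold is the empirical 0.95 quantile of those maxima
— a max-statistic null giving family-wise control over all windows.

Because the ancestor is not re-inferred per replicate, per-column branch
statistics are permutation-invariant; only their spatial arrangement
changes, which is what makes the replicate scans cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import CodonAlignment
from .ancestral import ANCESTOR_ID, AncestralSequence
from .windows import WindowResult, WindowSpec, make_windows, _branch_column_stats, _windows_from_stats
from . import li

__all__ = [
    "NullDistribution",
    "ThresholdSet",
    "Peak",
    "permute_codon_columns",
    "genomewide_threshold",
    "call_peaks",
]


@dataclass
class NullDistribution:
    branch: str
    replicate_maxima: np.ndarray
    R: int
    alpha: float
    seed: int | None
    n_dropped: int = 0


@dataclass
class ThresholdSet:
    thresholds: dict[str, float]
    null: dict[str, NullDistribution]
    R: int
    alpha: float
    seed: int | None

    def __getitem__(self, branch: str) -> float:
        return self.thresholds[branch]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": list(self.thresholds),
                "alpha": self.alpha,
                "R": self.R,
                "threshold": list(self.thresholds.values()),
                "n_dropped": [self.null[b].n_dropped for b in self.thresholds],
                "seed": self.seed,
            }
        )


@dataclass
class Peak:
    branch: str
    gene: str
    start_codon: int
    end_codon: int
    max_ka: float
    threshold: float
    n_windows: int


def permute_codon_columns(
    aln: CodonAlignment, rng: np.random.Generator
) -> CodonAlignment:
    """One random joint permutation of codon-column order (all rows,
    ancestor included).  The column multiset is preserved exactly."""
    if ANCESTOR_ID not in aln.rows:
        raise ValueError("alignment must include the ancestor row")
    return aln.permuted(rng.permutation(aln.n_columns))


def with_ancestor_row(
    aln: CodonAlignment, ancestor: AncestralSequence
) -> CodonAlignment:
    rows = dict(aln.rows)
    rows[ANCESTOR_ID] = ancestor.codons
    return CodonAlignment(aln.gene, rows)


def genomewide_threshold(
    alns: Sequence[CodonAlignment],
    ancestors: Mapping[str, AncestralSequence],
    tips: Sequence[str],
    spec: WindowSpec = WindowSpec(),
    R: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_usable_frac: float = 0.5,
) -> ThresholdSet:
    """Per-branch genome-wide (1 - alpha) peak thresholds.

    A master seed spawns one RNG stream per replicate, so the result is
    bit-reproducible and insensitive to evaluation order.  Replicates in
    which a branch has no assessable window are dropped for that branch;
    more than 10% dropped is an error (the null would be unreliable).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    per_gene = []
    min_usable = int(np.ceil(min_usable_frac * spec.width))
    for aln in alns:
        ranges = make_windows(aln.n_columns, spec)
        if not ranges:
            continue
        stats = _branch_column_stats(aln, ancestors[aln.gene], tips)
        per_gene.append((aln.n_columns, ranges, stats))
    if not per_gene:
        raise ValueError("no gene long enough for a single window")

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(R)]
    maxima: dict[str, list[float]] = {t: [] for t in tips}
    dropped = {t: 0 for t in tips}
    for rng in streams:
        best = {t: -np.inf for t in tips}
        for n_cols, ranges, stats in per_gene:
            perm = rng.permutation(n_cols)
            for tip in tips:
                col_stats, usable = stats[tip]
                sums, counts = _windows_from_stats(
                    col_stats[perm], usable[perm], ranges
                )
                ka = li.ka_from_sums(sums)
                ka = np.where(counts >= min_usable, ka, np.nan)
                if np.any(np.isfinite(ka)):
                    best[tip] = max(best[tip], float(np.nanmax(ka)))
        for tip in tips:
            if np.isfinite(best[tip]):
                maxima[tip].append(best[tip])
            else:
                dropped[tip] += 1

    null = {}
    thresholds = {}
    for tip in tips:
        if dropped[tip] > 0.1 * R:
            raise ValueError(
                f"{dropped[tip]}/{R} null replicates unusable for branch "
                f"{tip!r} (> 10%)"
            )
        arr = np.asarray(maxima[tip])
        thresholds[tip] = float(np.quantile(arr, 1.0 - alpha))  # type-7
        null[tip] = NullDistribution(tip, arr, R, alpha, seed, dropped[tip])
    return ThresholdSet(thresholds, null, R, alpha, seed)


def call_peaks(
    scan_results: Sequence[WindowResult], thresholds: ThresholdSet
) -> list[Peak]:
    """Windows exceeding their branch threshold, merged when overlapping.

    Merging is per branch and per gene; each merged peak reports the span
    of its member windows and the maximum window Ka inside it.
    """
    peaks: list[Peak] = []
    branches = list(thresholds.thresholds)
    for branch in branches:
        thr = thresholds[branch]
        sig = [
            r
            for r in scan_results
            if np.isfinite(r.ka[branch]) and r.ka[branch] > thr
        ]
        sig.sort(key=lambda r: (r.gene, r.start_codon))
        current: Peak | None = None
        for r in sig:
            if (
                current is not None
                and r.gene == current.gene
                and r.start_codon <= current.end_codon + 1
            ):
                current.end_codon = max(current.end_codon, r.end_codon)
                current.max_ka = max(current.max_ka, r.ka[branch])
                current.n_windows += 1
            else:
                if current is not None:
                    peaks.append(current)
                current = Peak(
                    branch, r.gene, r.start_codon, r.end_codon,
                    r.ka[branch], thr, 1,
                )
        if current is not None:
            peaks.append(current)
    return peaks


def peaks_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in peaks]) if peaks else pd.DataFrame(
        columns=["branch", "gene", "start_codon", "end_codon",
                 "max_ka", "threshold", "n_windows"]
    )
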