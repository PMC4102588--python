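"""Sliding-window nonsynonymous divergence scan.

Windows of 50 codons placed every 30 codons (both configurable) are laid
within each gene independently — the viral ORFs overlap slightly, so a
single concatenated reading frame is ill-defined at gene boundaries —
and per-branch Ka is computed for each window against the reconstructed
star-tree ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import CodonAlignment
from .ancestral import AncestralSequence
from .codons import GAP_CODON
from . import li

__all__ = ["WindowSpec", "WindowResult", "make_windows", "scan", "scan_frame"]


@dataclass(frozen=True)
class WindowSpec:
    width: int = 50  # codons
    step: int = 30  # codons

    def __post_init__(self):
        if self.width < 2:
            raise ValueError("window width must be >= 2 codons")
        if not (1 <= self.step <= self.width):
            raise ValueError("step must be in [1, width]")


@dataclass
class WindowResult:
    gene: str
    start_codon: int  # 1-based inclusive, gene-local alignment coordinates
    end_codon: int
    genome_start: int  # 1-based start in the concatenated coordinate system
    ka: dict[str, float]  # per branch; nan = not assessable
    n_usable: dict[str, int] = field(default_factory=dict)


def make_windows(n_codons: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """1-based inclusive codon ranges; partial trailing windows dropped."""
    if n_codons < spec.width:
        warnings.warn(
            f"sequence of {n_codons} codons shorter than window "
            f"({spec.width}); no windows placed"
        )
        return []
    return [
        (s, s + spec.width - 1)
        for s in range(1, n_codons - spec.width + 2, spec.step)
    ]


def _branch_column_stats(
    aln: CodonAlignment, ancestor: AncestralSequence, tips: Sequence[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-branch (column stats, usable mask); order-independent per column."""
    anc_idx = li.encode_codons(ancestor.codons)
    out = {}
    for tip in tips:
        tip_idx = li.encode_codons(aln.rows[tip])
        out[tip] = li.column_stats(tip_idx, anc_idx)
    return out


def _windows_from_stats(
    stats: np.ndarray, usable: np.ndarray, ranges: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Window-summed stats and usable counts via cumulative sums."""
    cs = np.vstack([np.zeros(9), np.cumsum(stats, axis=0)])
    cu = np.concatenate([[0], np.cumsum(usable)])
    lo = np.array([r[0] - 1 for r in ranges])
    hi = np.array([r[1] for r in ranges])
    return cs[hi] - cs[lo], cu[hi] - cu[lo]


def scan(
    alns: Sequence[CodonAlignment],
    ancestors: Mapping[str, AncestralSequence],
    tips: Sequence[str],
    spec: WindowSpec = WindowSpec(),
    min_usable_frac: float = 0.5,
) -> list[WindowResult]:
    """Per-window, per-branch Ka across one or more gene alignments.

    A branch reports nan in a window when fewer than ``min_usable_frac``
    of the window's codon pairs are comparable (gaps, ambiguity or
    reconstructed stops), or when the Li estimate saturates.
    """
    results: list[WindowResult] = []
    offset = 0
    min_usable = int(np.ceil(min_usable_frac * spec.width))
    for aln in alns:
        ranges = make_windows(aln.n_columns, spec)
        if ranges:
            per_branch = _branch_column_stats(aln, ancestors[aln.gene], tips)
            win: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for tip, (stats, usable) in per_branch.items():
                sums, counts = _windows_from_stats(stats, usable, ranges)
                ka = li.ka_from_sums(sums)
                ka = np.where(counts >= min_usable, ka, np.nan)
                win[tip] = (ka, counts)
            for w, (lo, hi) in enumerate(ranges):
                results.append(
                    WindowResult(
                        gene=aln.gene,
                        start_codon=lo,
                        end_codon=hi,
                        genome_start=offset + lo,
                        ka={t: float(win[t][0][w]) for t in tips},
                        n_usable={t: int(win[t][1][w]) for t in tips},
                    )
                )
        offset += aln.n_columns
    return results


def scan_frame(results: Sequence[WindowResult]) -> pd.DataFrame:
    """Long-format scan table: one row per (window, branch)."""
    rows = []
    for r in results:
        for branch, ka in r.ka.items():
            rows.append(
                {
                    "gene": r.gene,
                    "start_codon": r.start_codon,
                    "end_codon": r.end_codon,
                    "genome_start": r.genome_start,
                    "branch": branch,
                    "ka": ka,
                    "n_usable": r.n_usable.get(branch),
                }
            )
    return pd.DataFrame(rows)
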