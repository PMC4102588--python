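"""Model/Results interface for the divergence scan.

:class:`DivergenceScanModel` holds the data (per-gene three-tip codon
alignments) and configuration; :meth:`~DivergenceScanModel.fit` runs the
inference chain — star-tree branch lengths, marginal-ML ancestor,
genome-wide Li-method Ka/Ks, the sliding-window scan, the
codon-randomization null — and returns a :class:`DivergenceScanResults`
carrying every table plus a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import li
from .align import CodonAlignment, build_codon_alignment
from .ancestral import (
    AncestralSequence,
    StarTree,
    estimate_branch_lengths,
    reconstruct_ancestor,
)
from .null import Peak, ThresholdSet, call_peaks, genomewide_threshold, peaks_frame
from .windows import WindowResult, WindowSpec, scan, scan_frame

__all__ = ["DivergenceScanModel", "DivergenceScanResults"]


class DivergenceScanModel:
    """Branch-specific nonsynonymous divergence scan for three lineages.

    Parameters
    ----------
    alignments
        One :class:`CodonAlignment` per gene (three tips each, same tip
        ids throughout).
    kappa
        Transition/transversion rate ratio of the K2P model used for
        branch lengths and ancestral reconstruction.
    window
        Sliding-window geometry (default: 50 codons every 30).
    min_usable_frac
        Minimum fraction of comparable codon pairs for a window/branch to
        be assessed at all.
    """

    def __init__(
        self,
        alignments: CodonAlignment | Sequence[CodonAlignment],
        kappa: float = 2.0,
        window: WindowSpec = WindowSpec(),
        min_usable_frac: float = 0.5,
    ):
        if isinstance(alignments, CodonAlignment):
            alignments = [alignments]
        if not alignments:
            raise ValueError("no alignments given")
        tips = alignments[0].ids
        if len(tips) != 3:
            raise ValueError(f"need exactly 3 tips, got {tips}")
        for a in alignments:
            if a.ids != tips:
                raise ValueError("all gene alignments must share tip ids")
        self.alignments = list(alignments)
        self.tips = tuple(tips)
        self.kappa = kappa
        self.window = window
        self.min_usable_frac = min_usable_frac

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(cls, genomes_fasta, orf_table, **kwargs) -> "DivergenceScanModel":
        """Build gene alignments from a genome FASTA and an ORF table
        (TSV or GFF3); every gene must be annotated in all three genomes."""
        from .io import extract_orf, read_fasta, read_orf_table

        genomes = {g.id: g for g in read_fasta(genomes_fasta)}
        if len(genomes) != 3:
            raise ValueError(f"need exactly 3 genomes, got {len(genomes)}")
        anns = read_orf_table(orf_table)
        by_gene: dict[str, dict] = {}
        for ann in anns:
            if ann.genome_id not in genomes:
                raise ValueError(f"annotation for unknown genome {ann.genome_id!r}")
            cds = extract_orf(genomes[ann.genome_id], ann)
            by_gene.setdefault(ann.orf_name, {})[ann.genome_id] = cds
        alns = []
        for gene in by_gene:  # preserve annotation order
            if len(by_gene[gene]) != 3:
                raise ValueError(f"gene {gene!r} not annotated in all 3 genomes")
            alns.append(build_codon_alignment(by_gene[gene], gene=gene))
        return cls(alns, **kwargs)

    @classmethod
    def from_simulation(cls, sim, **kwargs) -> "DivergenceScanModel":
        return cls(sim.alignments, kappa=sim.config.kappa, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
        ancestors: Mapping[str, AncestralSequence] | None = None,
        tree: StarTree | None = None,
    ) -> "DivergenceScanResults":
        """Run the full inference chain.

        ``ancestors``/``tree`` may be supplied (e.g. simulator ground
        truth) to bypass estimation; by default both are inferred from
        the alignments.
        """
        if tree is None:
            tree = estimate_branch_lengths(self.alignments, self.kappa)
        if ancestors is None:
            ancestors = {
                a.gene: reconstruct_ancestor(a, tree) for a in self.alignments
            }
        genomewide = {}
        for tip in self.tips:
            counts = li.SubstitutionCounts()
            for a in self.alignments:
                est = li.branch_ka(a, ancestors[a.gene], tip)
                counts.sites += est.counts.sites
                counts.transitions += est.counts.transitions
                counts.transversions += est.counts.transversions
                counts.n_pairs += est.counts.n_pairs
                counts.n_skipped += est.counts.n_skipped
            genomewide[tip] = li.compute_ka_ks(counts)
        windows = scan(
            self.alignments, ancestors, self.tips, self.window,
            self.min_usable_frac,
        )
        thresholds = genomewide_threshold(
            self.alignments, ancestors, self.tips, self.window,
            R=n_permutations, alpha=alpha, seed=seed,
            min_usable_frac=self.min_usable_frac,
        )
        peaks = call_peaks(windows, thresholds)
        return DivergenceScanResults(
            model=self, tree=tree, ancestors=dict(ancestors),
            genomewide=genomewide, windows=windows,
            thresholds=thresholds, peaks=peaks, seed=seed,
        )


@dataclass
class DivergenceScanResults:
    model: DivergenceScanModel
    tree: StarTree
    ancestors: dict[str, AncestralSequence]
    genomewide: dict[str, li.DivergenceEstimate]
    windows: list[WindowResult]
    thresholds: ThresholdSet
    peaks: list[Peak]
    seed: int | None

    @property
    def windows_frame(self) -> pd.DataFrame:
        return scan_frame(self.windows)

    @property
    def peaks_frame(self) -> pd.DataFrame:
        return peaks_frame(self.peaks)

    @property
    def genomewide_frame(self) -> pd.DataFrame:
        rows = []
        for tip, est in self.genomewide.items():
            L = est.counts.sites
            rows.append(
                {
                    "branch": tip,
                    "L0": L[0], "L2": L[1], "L4": L[2],
                    "Ka": est.ka, "Ks": est.ks, "Ka/Ks": est.ka_ks,
                    "n_codons": est.counts.n_pairs,
                    "n_skipped": est.counts.n_skipped,
                    "valid": est.valid,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels tradition."""
        lines = []
        w = self.model.window
        lines.append("Nonsynonymous Divergence Scan")
        lines.append("=" * 64)
        lines.append(
            f"Genes: {', '.join(a.gene for a in self.model.alignments)}"
            f"   codon columns: "
            f"{sum(a.n_columns for a in self.model.alignments)}"
        )
        lines.append(
            f"Window: {w.width} codons every {w.step}"
            f"   permutations: {self.thresholds.R}"
            f"   alpha: {self.thresholds.alpha}   seed: {self.seed}"
        )
        lines.append(f"K2P kappa: {self.tree.kappa}")
        lines.append("-" * 64)
        lines.append(f"{'branch':<12}{'length':>8}{'Ka':>9}{'Ks':>9}"
                     f"{'Ka/Ks':>9}{'95% thr':>10}")
        for tip in self.model.tips:
            est = self.genomewide[tip]
            lines.append(
                f"{tip:<12}{self.tree.length_of(tip):>8.4f}"
                f"{est.ka:>9.4f}{est.ks:>9.4f}{est.ka_ks:>9.4f}"
                f"{self.thresholds[tip]:>10.4f}"
            )
        lines.append("-" * 64)
        if self.peaks:
            lines.append("Peaks above the genome-wide threshold:")
            for p in self.peaks:
                lines.append(
                    f"  {p.branch:<10} {p.gene:<8} codons "
                    f"{p.start_codon}-{p.end_codon}  max Ka = {p.max_ka:.4f}"
                    f"  (threshold {p.threshold:.4f})"
                )
        else:
            lines.append("No window exceeds its genome-wide threshold.")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Ka traces per branch with dashed genome-wide thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        df = self.windows_frame
        mid = (df["genome_start"] + self.model.window.width / 2.0)
        for i, tip in enumerate(self.model.tips):
            sub = df[df["branch"] == tip]
            color = f"C{i}"
            ax.plot(mid[df["branch"] == tip], sub["ka"], color=color, label=tip)
            ax.axhline(self.thresholds[tip], color=color, ls="--", lw=0.8)
        ax.set_xlabel("alignment codon")
        ax.set_ylabel("Ka")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def save_tables(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scan": outdir / "scan.tsv",
            "thresholds": outdir / "thresholds.tsv",
            "null_maxima": outdir / "null_maxima.tsv",
            "peaks": outdir / "peaks.tsv",
            "genomewide": outdir / "genomewide.tsv",
        }
        self.windows_frame.to_csv(paths["scan"], sep="\t", index=False)
        self.thresholds.frame().to_csv(paths["thresholds"], sep="\t", index=False)
        pd.DataFrame(
            {b: nd.replicate_maxima for b, nd in self.thresholds.null.items()}
        ).to_csv(paths["null_maxima"], sep="\t", index=False)
        self.peaks_frame.to_csv(paths["peaks"], sep="\t", index=False)
        self.genomewide_frame.to_csv(paths["genomewide"], sep="\t", index=False)
        return paths
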