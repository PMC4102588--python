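"""End-to-end orchestration: genomes + ORFs -> report, with persistence.

Everything stochastic is governed by the single seed in
:class:`RunConfig`; rerunning with the same inputs and seed is
byte-identical.  Every number in the report JSON is also persisted as a
TSV intermediate so the report is regenerable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import ScoringParams, global_align, nt_identity, percent_identity
from .io import (
    GenomeRecord,
    extract_orf,
    find_iupac_motif,
    read_fasta,
    read_orf_table,
    translate,
    write_fasta,
)
from .model import DivergenceScanModel
from .windows import WindowSpec

__all__ = ["RunConfig", "RunReport", "run_scan", "report_identities"]

log = logging.getLogger("norascan")

NORA_UTR_MOTIF = "CCTGGGSGGGGGTTA"


@dataclass
class RunConfig:
    genomes_fasta: str
    orf_table: str
    outdir: str
    window: WindowSpec = field(default_factory=WindowSpec)
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = 0
    kappa: float = 2.0
    min_usable_frac: float = 0.5
    motif: str = NORA_UTR_MOTIF
    nt_scoring: ScoringParams = field(default_factory=ScoringParams)
    skip_nt_identity: bool = False  # whole-genome DP is the slow step


@dataclass
class RunReport:
    genome_lengths: dict[str, int]
    nt_identity: dict[str, float]  # "idA|idB" -> percent
    aa_identity: dict[str, dict[str, float]]  # gene -> pair -> percent
    motif_hits: dict[str, list[int]]
    genomewide: list[dict]
    peaks: list[dict]
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=1, sort_keys=True, default=str)


def report_identities(
    genomes: dict[str, GenomeRecord],
    orfs,
    nt_scoring: ScoringParams | None = None,
    skip_nt: bool = False,
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Whole-genome nucleotide identity and per-gene protein identity for
    every genome pair, as percentages (full precision; round for display)."""
    ids = sorted(genomes)
    nt_id: dict[str, float] = {}
    if not skip_nt:
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                frac = nt_identity(
                    genomes[ids[i]].sequence, genomes[ids[j]].sequence, nt_scoring
                )
                nt_id[f"{ids[i]}|{ids[j]}"] = 100.0 * frac
    by_gene: dict[str, dict[str, str]] = {}
    for ann in orfs:
        prot = translate(extract_orf(genomes[ann.genome_id], ann))
        by_gene.setdefault(ann.orf_name, {})[ann.genome_id] = prot
    from .align import PROTEIN_SCORING

    aa_id: dict[str, dict[str, float]] = {}
    for gene, prots in by_gene.items():
        aa_id[gene] = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair = f"{ids[i]}|{ids[j]}"
                if ids[i] not in prots or ids[j] not in prots:
                    log.warning("gene %s missing in one of %s; NA", gene, pair)
                    aa_id[gene][pair] = float("nan")
                    continue
                aln = global_align(prots[ids[i]], prots[ids[j]], PROTEIN_SCORING)
                aa_id[gene][pair] = 100.0 * percent_identity(aln, mode="aa")
    return nt_id, aa_id


def run_scan(config: RunConfig) -> RunReport:
    """Run the complete analysis and persist every intermediate.

    On failure a FAILED marker naming the stage is left in the output
    directory alongside whatever intermediates were produced.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "read inputs"
        genomes = {g.id: g for g in read_fasta(config.genomes_fasta)}
        orfs = read_orf_table(config.orf_table)
        log.info("loaded %d genomes, %d ORF annotations", len(genomes), len(orfs))

        stage = "identity statistics"
        nt_id, aa_id = report_identities(
            genomes, orfs, config.nt_scoring, config.skip_nt_identity
        )

        stage = "motif scan"
        motif_hits = {
            gid: find_iupac_motif(g, config.motif) for gid, g in genomes.items()
        }

        stage = "codon alignment"
        model = DivergenceScanModel.from_files(
            config.genomes_fasta, config.orf_table,
            kappa=config.kappa, window=config.window,
            min_usable_frac=config.min_usable_frac,
        )
        for aln in model.alignments:
            _write_alignment_fasta(aln, outdir / f"codon_aln_{aln.gene}.fasta")

        stage = "fit (ancestor, scan, randomization null)"
        res = model.fit(
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=config.seed,
        )
        res.save_tables(outdir)
        for gene, anc in res.ancestors.items():
            with open(outdir / f"ancestor_{gene}.fasta", "w") as fh:
                fh.write(f">ancestor_{gene}\n{anc.states}\n")
            pd.DataFrame(
                {"position": range(1, len(anc.support) + 1),
                 "support": anc.support}
            ).to_csv(outdir / f"ancestor_{gene}_support.tsv", sep="\t",
                     index=False)

        stage = "report"
        report = RunReport(
            genome_lengths={gid: len(g) for gid, g in genomes.items()},
            nt_identity=nt_id,
            aa_identity=aa_id,
            motif_hits=motif_hits,
            genomewide=res.genomewide_frame.to_dict(orient="records"),
            peaks=res.peaks_frame.to_dict(orient="records"),
            provenance={
                "version": __version__,
                "seed": config.seed,
                "n_permutations": config.n_permutations,
                "alpha": config.alpha,
                "kappa": config.kappa,
                "window_width": config.window.width,
                "window_step": config.window.step,
                "motif": config.motif,
                "genomes_fasta": str(config.genomes_fasta),
                "orf_table": str(config.orf_table),
            },
        )
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "summary.txt").write_text(res.summary() + "\n")
        return report
    except Exception as e:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e


def _write_alignment_fasta(aln, path) -> None:
    with open(path, "w") as fh:
        for rid in aln.ids:
            fh.write(f">{rid}\n{aln.row_nt(rid)}\n")
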