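"""Synthetic three-lineage codon evolution with a plantable selection shift.

Three coding sequences descend independently from a common ancestor on a
star tree.  Mutation is K2P-like: each nucleotide site receives a
Poisson(t) number of proposals on a branch of length t (t in expected
neutral substitutions per site), each proposal being a transition with
probability kappa/(kappa+2) and otherwise a uniformly chosen
transversion.  Selection is acceptance-thinning: proposals creating a
stop codon are rejected outright; synonymous proposals are accepted with
probability min(1, 1/omega) and nonsynonymous ones with probability
min(1, omega), so realized dN/dS equals the codon's omega on both sides
of 1.  (For omega <= 1 this reduces to "synonymous always accepted,
nonsynonymous accepted with probability omega".)

The genome-wide default omega is 0.076 — the strong purifying constraint
reported for the Nora-virus lineages — and an optional contiguous region
of elevated omega on one branch emulates the VP1/VP2 divergence peak of
the most divergent lineage.  Every accepted event is recorded, so tips
are exactly replayable from the root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import CodonAlignment
from .codons import AMINO_ACID, BASES, SENSE_CODONS, is_stop, is_transition

__all__ = ["RegionSpec", "SimConfig", "Substitution", "SimResult",
           "sample_root", "evolve_branch", "simulate"]

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class RegionSpec:
    """A contiguous block of codons with shifted omega on one branch."""

    branch: int  # 0-based index into the tip list
    start_codon: int  # 1-based inclusive
    length: int
    omega: float

    @property
    def end_codon(self) -> int:
        return self.start_codon + self.length - 1


@dataclass(frozen=True)
class SimConfig:
    n_codons: int = 1200
    branch_lengths: tuple[float, float, float] = (0.3, 0.3, 0.3)
    kappa: float = 2.0
    omega_background: float = 0.076
    region: RegionSpec | None = None
    genes: tuple[tuple[str, int, int], ...] | None = None  # (name, start, end)
    tip_ids: tuple[str, str, str] = ("tip1", "tip2", "tip3")
    seed: int | None = None

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if any(t < 0 for t in self.branch_lengths):
            raise ValueError("branch lengths must be non-negative")
        if self.omega_background < 0:
            raise ValueError("omega must be non-negative")
        if self.region is not None:
            r = self.region
            if not (0 <= r.branch <= 2):
                raise ValueError("region branch index must be 0, 1 or 2")
            if not (1 <= r.start_codon and r.end_codon <= self.n_codons):
                raise ValueError("region outside [1, n_codons]")

    def omega_map(self, branch: int) -> np.ndarray:
        omega = np.full(self.n_codons, self.omega_background)
        if self.region is not None and self.region.branch == branch:
            r = self.region
            omega[r.start_codon - 1 : r.end_codon] = r.omega
        return omega

    def gene_partition(self) -> tuple[tuple[str, int, int], ...]:
        if self.genes is not None:
            return self.genes
        return (("gene1", 1, self.n_codons),)


@dataclass(frozen=True)
class Substitution:
    site: int  # 0-based nucleotide position
    from_base: str
    to_base: str
    time: float
    synonymous: bool


@dataclass
class SimResult:
    config: SimConfig
    root: tuple[str, ...]  # codons
    tips: dict[str, tuple[str, ...]]
    events: dict[str, tuple[Substitution, ...]]

    @property
    def alignments(self) -> list[CodonAlignment]:
        """Gap-free per-gene codon alignments of the three tips."""
        out = []
        for name, start, end in self.config.gene_partition():
            rows = {t: list(self.tips[t][start - 1 : end])
                    for t in self.config.tip_ids}
            out.append(CodonAlignment(name, rows))
        return out

    def true_ancestors(self) -> dict[str, list[str]]:
        return {
            name: list(self.root[start - 1 : end])
            for name, start, end in self.config.gene_partition()
        }

    def nonsynonymous_counts(self, codon_range: tuple[int, int] | None = None
                             ) -> dict[str, int]:
        """Realized nonsynonymous substitutions per branch, optionally
        restricted to a 1-based inclusive codon range."""
        out = {}
        for tip, evs in self.events.items():
            if codon_range is None:
                out[tip] = sum(1 for e in evs if not e.synonymous)
            else:
                lo, hi = codon_range
                out[tip] = sum(
                    1 for e in evs
                    if not e.synonymous and lo <= e.site // 3 + 1 <= hi
                )
        return out

    # -- file emission so the main pipeline can consume a simulation -------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        class _Rec:
            def __init__(self, id_, seq):
                self.id, self.description, self.sequence = id_, "", seq

        paths = {
            "tips_fasta": outdir / "tips.fasta",
            "ancestor_fasta": outdir / "true_ancestor.fasta",
            "orf_tsv": outdir / "orfs.tsv",
            "truth_json": outdir / "truth.json",
        }
        write_fasta(
            [_Rec(t, "".join(self.tips[t])) for t in self.config.tip_ids],
            paths["tips_fasta"],
        )
        write_fasta([_Rec("true_ancestor", "".join(self.root))],
                    paths["ancestor_fasta"])
        with open(paths["orf_tsv"], "w") as fh:
            for name, start, end in self.config.gene_partition():
                for t in self.config.tip_ids:
                    fh.write(f"{t}\t{name}\t{3 * start - 2}\t{3 * end}\n")
        truth = {
            "config": {
                "n_codons": self.config.n_codons,
                "branch_lengths": list(self.config.branch_lengths),
                "kappa": self.config.kappa,
                "omega_background": self.config.omega_background,
                "region": None if self.config.region is None else vars(self.config.region) | {"end_codon": self.config.region.end_codon},
                "seed": self.config.seed,
            },
            "events": {
                t: [
                    [e.site, e.from_base, e.to_base, round(e.time, 9),
                     e.synonymous]
                    for e in evs
                ]
                for t, evs in self.events.items()
            },
        }
        with open(paths["truth_json"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        return paths


def sample_root(n_codons: int, rng: np.random.Generator) -> tuple[str, ...]:
    """i.i.d. uniform draws over the 61 sense codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return tuple(SENSE_CODONS[i] for i in idx)


def evolve_branch(
    root: Sequence[str],
    t: float,
    kappa: float,
    omega_map: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], tuple[Substitution, ...]]:
    """Evolve one branch; returns (tip codons, accepted substitutions).

    Proposals are ordered by uniform event times over the branch so that
    within-codon interactions (a second hit seeing the first) are resolved
    consistently.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    n_nt = 3 * len(root)
    seq = list("".join(root))
    counts = rng.poisson(t, size=n_nt)
    sites = np.repeat(np.arange(n_nt), counts)
    # times are relative positions along the branch, used only for ordering
    times = rng.uniform(0.0, 1.0, size=sites.size)
    order = np.argsort(times, kind="stable")
    p_ts = kappa / (kappa + 2.0)
    events: list[Substitution] = []
    for k in order:
        site = int(sites[k])
        old = seq[site]
        if rng.random() < p_ts:
            new = _TS_PARTNER[old]
        else:
            new = _TV_PARTNERS[old][rng.integers(0, 2)]
        ci = site // 3
        off = site - 3 * ci
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        mutant = codon[:off] + new + codon[off + 1 :]
        if is_stop(mutant):
            continue
        syn = AMINO_ACID[mutant] == AMINO_ACID[codon]
        omega = float(omega_map[ci])
        if syn:
            accept = omega <= 1.0 or rng.random() < 1.0 / omega
        else:
            accept = rng.random() < omega if omega < 1.0 else True
        if not accept:
            continue
        seq[site] = new
        events.append(Substitution(site, old, new, float(times[k]), syn))
    tip = tuple("".join(seq[i : i + 3]) for i in range(0, n_nt, 3))
    return tip, tuple(events)


def simulate(config: SimConfig) -> SimResult:
    """Sample a root and evolve the three tips independently."""
    rng = np.random.default_rng(config.seed)
    root = sample_root(config.n_codons, rng)
    tips: dict[str, tuple[str, ...]] = {}
    events: dict[str, tuple[Substitution, ...]] = {}
    for b, tip_id in enumerate(config.tip_ids):
        tips[tip_id], events[tip_id] = evolve_branch(
            root, config.branch_lengths[b], config.kappa,
            config.omega_map(b), rng,
        )
    return SimResult(config, root, tips, events)
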