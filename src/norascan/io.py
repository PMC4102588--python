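"""Genome and annotation I/O: FASTA, ORF tables (TSV/GFF3), motif scans.

Coordinates are 1-based inclusive on the forward strand throughout (the
GenBank convention; all Nora-virus ORFs are forward-strand).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import re

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import GAP_CODON, STOP_CODONS, translate_codon

__all__ = [
    "GenomeRecord",
    "OrfAnnotation",
    "CodingSequence",
    "read_fasta",
    "write_fasta",
    "read_orf_table",
    "extract_orf",
    "translate",
    "find_iupac_motif",
]

# Ambiguity codes beyond N are collapsed to N on read: downstream site
# counting treats any ambiguity as missing, so nothing is lost.
_AMBIGUITY = set("RYSWKMBDHV")
_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise ValueError(
                f"record {self.id!r}: non-IUPAC character "
                f"{self.sequence[pos - 1]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    genome_id: str
    orf_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self):
        if self.strand != "+":
            raise ValueError("only forward-strand ORFs are supported")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.orf_name}: invalid coordinates {self.start}..{self.end}"
            )
        if (self.end - self.start + 1) % 3:
            raise ValueError(
                f"{self.orf_name}: length {self.end - self.start + 1} "
                "not divisible by 3"
            )


@dataclass(frozen=True)
class CodingSequence:
    orf_name: str
    genome_id: str
    codons: tuple[str, ...]
    includes_terminal_stop: bool = False

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)


def _normalize(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    out = []
    for i, c in enumerate(s, 1):
        if c in _ALPHABET:
            out.append(c)
        elif c in _AMBIGUITY:
            out.append("N")
        else:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {c!r} at position {i}"
            )
    return "".join(out)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a nucleotide FASTA into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T; ambiguity codes other
    than N are collapsed to N; any other letter is an error naming the
    offending position.  Duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(
            GenomeRecord(rec.id, rec.description, _normalize(str(rec.seq), rec.id))
        )
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write GenomeRecords (or any objects with .id/.sequence) as FASTA."""
    seqrecs = []
    for r in records:
        desc = getattr(r, "description", "")
        if desc.startswith(r.id):  # Biopython prepends the id itself
            desc = desc[len(r.id):].strip()
        seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_orf_table(path: str | Path) -> list[OrfAnnotation]:
    """Read ORF annotations from 4-column TSV or GFF3.

    TSV columns: genome_id, orf_name, start, end (header optional).  GFF3:
    CDS features, seqid = genome id, ID attribute = ORF name.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 tab-separated columns")
    # tolerate a header row
    if not str(df.iloc[0, 2]).isdigit():
        df = df.iloc[1:]
    return [
        OrfAnnotation(row[0], row[1], int(row[2]), int(row[3]))
        for row in df.itertuples(index=False)
    ]


def _read_gff3(path: Path) -> list[OrfAnnotation]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        name = feat.attributes.get("ID", [feat.id])[0]
        out.append(OrfAnnotation(feat.seqid, name, feat.start, feat.end,
                                 feat.strand or "+"))
    if not out:
        raise ValueError(f"{path}: no CDS features")
    return out


def extract_orf(genome: GenomeRecord, ann: OrfAnnotation) -> CodingSequence:
    """Extract an annotated ORF as a codon list.

    A terminal stop codon is recorded on the result and excluded from the
    codon list (downstream site counting is defined for sense codons only);
    an internal stop is an error naming the codon index.
    """
    if ann.genome_id != genome.id:
        raise ValueError(
            f"annotation {ann.orf_name} is for genome {ann.genome_id!r}, "
            f"not {genome.id!r}"
        )
    if ann.end > len(genome):
        raise ValueError(
            f"{ann.orf_name}: end {ann.end} beyond genome length {len(genome)}"
        )
    nt = genome.sequence[ann.start - 1 : ann.end]
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    terminal_stop = bool(codons) and codons[-1] in STOP_CODONS
    if terminal_stop:
        codons = codons[:-1]
    for idx, c in enumerate(codons, 1):
        if c in STOP_CODONS:
            raise ValueError(f"{ann.orf_name}: internal stop codon at codon {idx}")
    return CodingSequence(ann.orf_name, genome.id, tuple(codons), terminal_stop)


def translate(cds: CodingSequence) -> str:
    """Standard-code translation; codons containing N give 'X'."""
    return "".join(translate_codon(c) for c in cds.codons if c != GAP_CODON)


def find_iupac_motif(genome: GenomeRecord, motif: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) motif matches.

    The motif may use IUPAC nucleotide ambiguity codes (S = C or G, etc.).
    """
    motif = motif.upper().replace("U", "T")
    parts = []
    for c in motif:
        if c not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC nucleotide code {c!r} in motif")
        expansion = ambiguous_dna_values[c]
        parts.append(c if len(expansion) == 1 else f"[{expansion}]")
    pattern = re.compile("(?=" + "".join(parts) + ")")
    return [m.start() + 1 for m in pattern.finditer(genome.sequence)]
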