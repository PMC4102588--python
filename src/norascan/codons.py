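"""Standard genetic code constants shared across the package.

Everything here is derived from Biopython's unambiguous DNA codon table 1
(the standard nuclear code), which is the code used by Nora-like picorna-like
viruses.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

BASES = "ACGT"
GAP_CODON = "---"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: The 61 sense codons in lexicographic order; index order is the canonical
#: encoding used by the vectorised Li-method tables.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        "".join(c)
        for c in itertools.product(BASES, repeat=3)
        if "".join(c) not in STOP_CODONS
    )
)

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> one-letter amino acid, sense codons only.
AMINO_ACID: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    if a == b:
        raise ValueError("identical bases are not a substitution")
    return ({a, b} <= _PURINES) or ({a, b} <= _PYRIMIDINES)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter translation; codons with ambiguity (N etc.) give 'X',
    stops give '*'."""
    aa = AMINO_ACID.get(codon)
    if aa is not None:
        return aa
    if codon in STOP_CODONS:
        return "*"
    return "X"
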