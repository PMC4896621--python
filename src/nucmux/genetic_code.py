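"""Standard genetic code tables in the package's integer encodings.

Codons are encoded as ``16*b0 + 4*b1 + b2`` with base codes A=0, C=1, G=2,
T=3.  The synonymous-move proposal tables exclude the identity codon and
never propose stop codons; no sense codon is synonymous with a stop under
the standard code, so stops simply have no proposals.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

from .mechanics import BASES

__all__ = [
    "AMINO_ACIDS",
    "CODON_STRINGS",
    "STOP_CODON_CODES",
    "aa_of_codon",
    "codon_code",
    "codon_string",
    "synonymous_tables",
    "translate",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard code

CODON_STRINGS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: the 20 amino acids, one-letter, alphabetical
AMINO_ACIDS = tuple(sorted(set(_TABLE.forward_table.values())))


def codon_code(codon: str) -> int:
    return CODON_STRINGS.index(codon.upper())


def codon_string(code: int) -> str:
    return CODON_STRINGS[code]


def aa_of_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for stop codons."""
    c = codon.upper()
    if c in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[c]


STOP_CODON_CODES = tuple(codon_code(c) for c in _TABLE.stop_codons)

#: codon code -> amino-acid index in AMINO_ACIDS, or -1 for stops
CODON_AA_INDEX = np.array(
    [-1 if aa_of_codon(c) == "*" else AMINO_ACIDS.index(aa_of_codon(c))
     for c in CODON_STRINGS],
    dtype=np.int64,
)


def synonymous_tables() -> tuple[np.ndarray, np.ndarray]:
    """(syn_n, syn_codons): per codon, the number of synonymous alternatives
    and their codes (padded with -1).  Stops have zero alternatives."""
    syn_n = np.zeros(64, dtype=np.int64)
    syn_codons = np.full((64, 6), -1, dtype=np.int64)
    for c, codon in enumerate(CODON_STRINGS):
        aa = aa_of_codon(codon)
        if aa == "*":
            continue
        alts = [codon_code(k) for k in CODON_STRINGS
                if k != codon and aa_of_codon(k) == aa]
        syn_n[c] = len(alts)
        syn_codons[c, : len(alts)] = alts
    return syn_n, syn_codons


def translate(seq: str) -> str:
    """Translate an in-frame DNA string (length a multiple of 3)."""
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    return "".join(aa_of_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))
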