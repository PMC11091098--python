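"""Fixed codon tables for reverse translation.

Oligo design and simulated construct sequences need nucleotide sequences only
for length accounting and exact read matching, so a single fixed codon per
amino acid suffices (the study's vendor-optimized codons are not public). A
second, distinct codon per degenerate amino acid supports generating
synonymous variants; methionine and tryptophan have no alternate codon.
"""

from __future__ import annotations

from typing import Dict, Optional

# one high-usage human codon per amino acid; TAA for stop
PREFERRED_CODON: Dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "*": "TAA",
}

# a second codon for every degenerate amino acid (M and W have none)
ALTERNATE_CODON: Dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGA", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTC",
    "N": "AAT", "P": "CCT", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACA", "V": "GTC", "Y": "TAT",
    "*": "TGA",
}


def reverse_translate(protein_seq: str) -> str:
    """Protein → CDS using the fixed preferred-codon table (no stop appended)."""
    return "".join(PREFERRED_CODON[aa] for aa in protein_seq)


def alternate_codon(aa: str) -> Optional[str]:
    """A synonymous codon differing from the preferred one, or None."""
    return ALTERNATE_CODON.get(aa)


def mutate_codon(cds: str, position: int, alt_aa: str) -> str:
    """Replace the codon at 1-based residue ``position`` with ``alt_aa``'s codon."""
    i = (position - 1) * 3
    return cds[:i] + PREFERRED_CODON[alt_aa] + cds[i + 3:]
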