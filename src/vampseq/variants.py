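"""Amino-acid variant identities, string conventions and universe enumeration.

A single-site protein variant is identified by a 1-based residue position, the
wild-type residue, and the substituted residue (``*`` for a premature stop).
String forms follow the compact convention used throughout deep mutational
scanning score sets:

* ``C152W`` — missense,
* ``W64*`` — nonsense,
* ``C152=`` — a synonymous (silent) codon change,
* ``WT`` — the unmutated protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_VARIANT_RE = re.compile(r"^([A-Y])([1-9]\d*)([A-Y*=])$")

VALID_CLASSES = ("wt", "synonymous", "missense", "nonsense")


class VariantParseError(ValueError):
    """Raised when a variant string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class VariantId:
    """A single amino-acid-level variant of a reference protein.

    Attributes
    ----------
    position : int
        1-based residue index; 0 for the wild-type entry.
    wt_aa : str
        One-letter wild-type residue ('' for the wild-type entry).
    alt_aa : str
        One-letter substituted residue, ``*`` for stop, ``=`` for synonymous.
    var_class : str
        One of ``wt``, ``synonymous``, ``missense``, ``nonsense``.
    """

    position: int
    wt_aa: str
    alt_aa: str
    var_class: str

    def __post_init__(self) -> None:
        if self.var_class not in VALID_CLASSES:
            raise ValueError(f"invalid variant class {self.var_class!r}")
        if self.var_class == "wt":
            return
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.wt_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid wild-type residue {self.wt_aa!r}")
        if self.var_class == "nonsense" and self.alt_aa != STOP:
            raise ValueError("nonsense variants must substitute to '*'")
        if self.var_class == "missense":
            if self.alt_aa not in AMINO_ACIDS:
                raise ValueError(f"invalid substituted residue {self.alt_aa!r}")
            if self.alt_aa == self.wt_aa:
                raise ValueError("missense variant cannot keep the wild-type residue")
        if self.var_class == "synonymous" and self.alt_aa != "=":
            raise ValueError("synonymous variants use alt_aa '='")

    def __str__(self) -> str:
        return format_variant(self)

    @property
    def is_scored_as_wt(self) -> bool:
        """Whether the variant encodes the wild-type protein sequence."""
        return self.var_class in ("wt", "synonymous")


WT_VARIANT = VariantId(0, "", "", "wt")


def format_variant(variant: VariantId) -> str:
    if variant.var_class == "wt":
        return "WT"
    return f"{variant.wt_aa}{variant.position}{variant.alt_aa}"


def parse_variant(string: str) -> VariantId:
    """Parse a compact variant string (``C152W``, ``W64*``, ``C152=``, ``WT``).

    Raises
    ------
    VariantParseError
        If the string is malformed, or the substituted residue equals the
        wild-type residue outside the explicit synonymous form.
    """
    if not string:
        raise VariantParseError("empty variant string")
    if string == "WT":
        return WT_VARIANT
    m = _VARIANT_RE.match(string)
    if m is None:
        raise VariantParseError(f"malformed variant string {string!r}")
    wt_aa, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if wt_aa not in AMINO_ACIDS:
        raise VariantParseError(f"invalid wild-type residue in {string!r}")
    if alt == "=":
        return VariantId(pos, wt_aa, "=", "synonymous")
    if alt == STOP:
        return VariantId(pos, wt_aa, STOP, "nonsense")
    if alt == wt_aa:
        raise VariantParseError(
            f"{string!r}: substituted residue equals wild type; use {wt_aa}{pos}= "
            "for a synonymous variant"
        )
    return VariantId(pos, wt_aa, alt, "missense")


def validate_protein(protein_seq: str) -> str:
    protein_seq = protein_seq.strip().upper()
    bad = set(protein_seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues in protein sequence: {sorted(bad)}")
    return protein_seq


def enumerate_variant_universe(protein_seq: str) -> List[VariantId]:
    """Enumerate every single amino-acid substitution and premature stop.

    For a protein of length L the universe holds 19·L missense variants, L−1
    nonsense variants (stops at positions 1..L−1; a stop at the final residue
    leaves the protein intact), and one wild-type entry — 20·L in total.
    """
    protein_seq = validate_protein(protein_seq)
    length = len(protein_seq)
    if length < 2:
        raise ValueError("protein sequence must have length >= 2")
    universe: List[VariantId] = [WT_VARIANT]
    for pos0, wt_aa in enumerate(protein_seq):
        pos = pos0 + 1
        for alt in AMINO_ACIDS:
            if alt != wt_aa:
                universe.append(VariantId(pos, wt_aa, alt, "missense"))
        if pos < length:
            universe.append(VariantId(pos, wt_aa, STOP, "nonsense"))
    return universe


def variant_strings(variants: Iterable[VariantId]) -> List[str]:
    return [format_variant(v) for v in variants]
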