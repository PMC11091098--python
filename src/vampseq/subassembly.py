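"""Barcode–variant subassembly from long reads of barcode+CDS constructs.

Long reads of the plasmid library associate each random 18-nt barcode with the
coding sequence it marks. Reads are located by exact constant flanks, the CDS
is compared globally to the reference (indels and heavily mutated reads are
discarded), translated, and reads are grouped by barcode under a strict
majority rule to produce the barcode → variant map used by all downstream
counting.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from Bio.Seq import Seq

from .variants import STOP, VariantId, WT_VARIANT, format_variant

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


@dataclass(frozen=True)
class FlankSpec:
    """Constant sequences bounding the barcode and the CDS within a read.

    Read layout: ``... upstream BARCODE spacer CDS downstream ...``. An empty
    ``downstream`` means the CDS runs to the end of the read.
    """

    upstream: str
    spacer: str
    downstream: str = ""
    barcode_length: int = 18


@dataclass
class LongReadRecord:
    barcode: str
    cds_seq: str
    n_subs: int = 0
    has_indel: bool = False
    variant: Optional[VariantId] = None


@dataclass
class SubassemblyStats:
    """Per-filter accounting for the subassembly stage."""

    n_reads: int = 0
    n_rejected_flank: int = 0
    n_rejected_barcode_length: int = 0
    n_rejected_non_acgt: int = 0
    n_rejected_indel: int = 0
    n_rejected_substitutions: int = 0
    n_rejected_multi_variant: int = 0
    n_reads_mapped: int = 0
    n_barcodes_total: int = 0
    n_barcodes_dropped_tie: int = 0
    n_barcodes_mapped: int = 0
    reject_reasons: Counter = field(default_factory=Counter)

    def log_summary(self) -> None:
        logger.info(
            "subassembly: %d reads in, %d mapped; rejected flank=%d barcode-length=%d "
            "non-ACGT=%d indel=%d >=%d-substitutions=%d multi-variant=%d; "
            "%d barcodes seen, %d dropped (tie), %d mapped",
            self.n_reads, self.n_reads_mapped, self.n_rejected_flank,
            self.n_rejected_barcode_length, self.n_rejected_non_acgt,
            self.n_rejected_indel, 10, self.n_rejected_substitutions,
            self.n_rejected_multi_variant, self.n_barcodes_total,
            self.n_barcodes_dropped_tie, self.n_barcodes_mapped,
        )


@dataclass(frozen=True)
class BarcodeEntry:
    variant: VariantId
    n_supporting_reads: int
    n_total_reads: int

    @property
    def dominant_fraction(self) -> float:
        return self.n_supporting_reads / self.n_total_reads


class BarcodeMap:
    """Barcode string → variant with read-support evidence."""

    def __init__(self, entries: Optional[Dict[str, BarcodeEntry]] = None):
        self.entries: Dict[str, BarcodeEntry] = entries or {}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def __getitem__(self, barcode: str) -> BarcodeEntry:
        return self.entries[barcode]

    def variant_of(self, barcode: str) -> VariantId:
        return self.entries[barcode].variant

    def barcodes_by_variant(self) -> Dict[VariantId, List[str]]:
        out: Dict[VariantId, List[str]] = defaultdict(list)
        for bc, entry in self.entries.items():
            out[entry.variant].append(bc)
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "barcode": bc,
                "variant": format_variant(e.variant),
                "var_class": e.variant.var_class,
                "n_reads": e.n_total_reads,
                "dominant_fraction": e.dominant_fraction,
            }
            for bc, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["barcode", "variant", "var_class", "n_reads", "dominant_fraction"],
        )


class ReadReject(Exception):
    """A read failed a subassembly filter; ``reason`` is a stable code."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def extract_barcode_and_cds(raw_read: str, flank_spec: FlankSpec) -> Tuple[str, str]:
    """Locate the barcode and CDS substrings by exact constant flanks.

    Raises :class:`ReadReject` with reason ``missing-flank``,
    ``ambiguous-flank`` or ``barcode-length`` when the read cannot be
    decomposed.
    """
    read = raw_read.upper()

    def find_unique(sub: str, start: int) -> int:
        first = read.find(sub, start)
        if first < 0:
            raise ReadReject("missing-flank")
        if read.find(sub, first + 1) >= 0:
            raise ReadReject("ambiguous-flank")
        return first

    up = find_unique(flank_spec.upstream, 0)
    bc_start = up + len(flank_spec.upstream)
    sp = find_unique(flank_spec.spacer, bc_start)
    barcode = read[bc_start:sp]
    if len(barcode) != flank_spec.barcode_length:
        raise ReadReject("barcode-length")
    cds_start = sp + len(flank_spec.spacer)
    if flank_spec.downstream:
        down = find_unique(flank_spec.downstream, cds_start)
        cds = read[cds_start:down]
    else:
        cds = read[cds_start:]
    if not cds:
        raise ReadReject("missing-flank")
    return barcode, cds


def call_variant(
    cds_seq: str,
    reference_cds: str,
    max_substitutions: int = 10,
) -> Tuple[VariantId, int]:
    """Call the encoded amino-acid variant from a global CDS comparison.

    Reads whose length differs from the reference (indels), reads carrying
    ``max_substitutions`` or more nucleotide changes, and reads encoding two
    or more amino-acid changes are rejected. Returns the variant and the
    nucleotide substitution count.
    """
    cds_seq = cds_seq.upper()
    reference_cds = reference_cds.upper()
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if set(cds_seq) - _DNA:
        raise ReadReject("non-acgt")
    if len(cds_seq) != len(reference_cds):
        raise ReadReject("indel")
    n_subs = sum(a != b for a, b in zip(cds_seq, reference_cds))
    if n_subs >= max_substitutions:
        raise ReadReject("substitutions")
    if n_subs == 0:
        return WT_VARIANT, 0
    ref_prot = str(Seq(reference_cds).translate())
    read_prot = str(Seq(cds_seq).translate())
    diffs = [
        (i + 1, wt, alt)
        for i, (wt, alt) in enumerate(zip(ref_prot, read_prot))
        if wt != alt
    ]
    if len(diffs) == 0:
        # nucleotide changes, identical protein
        pos = next(i for i, (a, b) in enumerate(zip(cds_seq, reference_cds)) if a != b)
        codon = pos // 3 + 1
        return VariantId(codon, ref_prot[codon - 1], "=", "synonymous"), n_subs
    if len(diffs) > 1:
        raise ReadReject("multi-variant")
    pos, wt_aa, alt_aa = diffs[0]
    if alt_aa == STOP:
        return VariantId(pos, wt_aa, STOP, "nonsense"), n_subs
    return VariantId(pos, wt_aa, alt_aa, "missense"), n_subs


def build_barcode_map(
    records: Iterable[LongReadRecord],
    stats: Optional[SubassemblyStats] = None,
) -> BarcodeMap:
    """Group variant-called reads by barcode under a strict majority rule.

    A barcode maps to the variant supported by more than half of its reads;
    barcodes with no strict majority are dropped and counted in ``stats``.
    """
    stats = stats if stats is not None else SubassemblyStats()
    by_barcode: Dict[str, Counter] = defaultdict(Counter)
    totals: Dict[str, int] = defaultdict(int)
    for rec in records:
        if rec.variant is None:
            raise ValueError("records must be variant-called before mapping")
        by_barcode[rec.barcode][rec.variant] += 1
        totals[rec.barcode] += 1
    entries: Dict[str, BarcodeEntry] = {}
    for barcode, votes in by_barcode.items():
        stats.n_barcodes_total += 1
        total = totals[barcode]
        variant, support = votes.most_common(1)[0]
        if support * 2 <= total:  # no strict majority
            stats.n_barcodes_dropped_tie += 1
            continue
        entries[barcode] = BarcodeEntry(variant, support, total)
    stats.n_barcodes_mapped = len(entries)
    return BarcodeMap(entries)


def subassemble(
    raw_reads: Iterable[str],
    reference_cds: str,
    flank_spec: FlankSpec,
    max_substitutions: int = 10,
) -> Tuple[BarcodeMap, SubassemblyStats]:
    """Full subassembly: extract, variant-call, and map reads to barcodes."""
    stats = SubassemblyStats()
    records: List[LongReadRecord] = []
    for raw in raw_reads:
        stats.n_reads += 1
        try:
            barcode, cds = extract_barcode_and_cds(raw, flank_spec)
        except ReadReject as exc:
            stats.reject_reasons[exc.reason] += 1
            if exc.reason == "barcode-length":
                stats.n_rejected_barcode_length += 1
            else:
                stats.n_rejected_flank += 1
            continue
        try:
            variant, n_subs = call_variant(cds, reference_cds, max_substitutions)
        except ReadReject as exc:
            stats.reject_reasons[exc.reason] += 1
            if exc.reason == "indel":
                stats.n_rejected_indel += 1
            elif exc.reason == "substitutions":
                stats.n_rejected_substitutions += 1
            elif exc.reason == "multi-variant":
                stats.n_rejected_multi_variant += 1
            else:
                stats.n_rejected_non_acgt += 1
            continue
        stats.n_reads_mapped += 1
        records.append(
            LongReadRecord(barcode, cds, n_subs=n_subs, variant=variant)
        )
    barcode_map = build_barcode_map(records, stats)
    stats.log_summary()
    return barcode_map, stats
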