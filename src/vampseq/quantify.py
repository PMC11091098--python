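"""Barcode counting, variant merging and frequency normalization.

Short reads are abstracted to their extracted barcodes; only barcodes that
match the barcode map exactly are counted. Counts from technical replicates
and from barcodes sharing an amino-acid variant are summed, then normalized to
frequencies within each (replicate, FACS bin) or (replicate, day) — with no
pseudocounts.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .subassembly import BarcodeMap
from .variants import format_variant


def count_barcodes(
    sample_barcodes: Iterable[str],
    barcode_map: BarcodeMap,
) -> Tuple[pd.Series, int]:
    """Count exact-match barcodes against the map.

    Returns a Series of counts indexed by every map barcode (zeros included)
    and the number of unmatched reads. A read one nucleotide away from a map
    key does not count.
    """
    if len(barcode_map) == 0:
        raise ValueError("barcode map is empty")
    counts = pd.Series(0, index=sorted(barcode_map.entries), dtype=np.int64)
    observed = pd.Series(list(sample_barcodes), dtype=object).value_counts()
    matched = observed.index.intersection(counts.index)
    counts.loc[matched] = observed.loc[matched].astype(np.int64)
    n_unmatched = int(observed.sum() - observed.loc[matched].sum())
    return counts, n_unmatched


def attach_variants(
    counts: pd.DataFrame,
    barcode_map: BarcodeMap,
    merge_synonymous_into_wt: bool = True,
) -> pd.DataFrame:
    """Replace barcodes with variant strings using the map.

    Synonymous barcodes encode the wild-type protein; by default they merge
    into the WT entry so the wild-type score reflects the wild-type amino-acid
    sequence regardless of codon usage.
    """
    lookup = {}
    for bc, entry in barcode_map.entries.items():
        v = entry.variant
        if merge_synonymous_into_wt and v.var_class == "synonymous":
            lookup[bc] = "WT"
        else:
            lookup[bc] = format_variant(v)
    out = counts.copy()
    out["variant"] = out["barcode"].map(lookup)
    out = out.dropna(subset=["variant"])
    return out.drop(columns=["barcode"])


def merge_and_normalize(
    counts: pd.DataFrame,
    unit: str,
    barcode_map: Optional[BarcodeMap] = None,
    merge_synonymous_into_wt: bool = True,
) -> pd.DataFrame:
    """Merge technical replicates and barcodes, then normalize to frequencies.

    Parameters
    ----------
    counts : DataFrame
        Tidy counts with columns ``replicate``, ``unit`` (``bin`` or ``day``),
        ``count`` and either ``barcode`` (with ``barcode_map`` given) or
        ``variant``. An optional ``technical_replicate`` column is summed out.
    unit : str
        ``"bin"`` for FACS sorting counts, ``"day"`` for time-course counts.

    Returns a tidy table with columns ``replicate``, ``unit``, ``variant``,
    ``count``, ``frequency`` where frequencies sum to one within each
    (replicate, unit) over variants with nonzero count; no pseudocounts are
    added.
    """
    if unit not in ("bin", "day"):
        raise ValueError("unit must be 'bin' or 'day'")
    required = {"replicate", unit, "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    if "variant" not in counts.columns:
        if barcode_map is None:
            raise ValueError("counts keyed by barcode require a barcode map")
        counts = attach_variants(counts, barcode_map, merge_synonymous_into_wt)
    elif merge_synonymous_into_wt:
        syn = {v: "WT" for v in counts["variant"].unique() if str(v).endswith("=")}
        if syn:
            counts = counts.copy()
            counts["variant"] = counts["variant"].replace(syn)
    merged = (
        counts.groupby(["replicate", unit, "variant"], as_index=False, sort=True)
        ["count"].sum()
    )
    totals = merged.groupby(["replicate", unit])["count"].transform("sum")
    if (totals == 0).any():
        raise ValueError(f"a (replicate, {unit}) group has zero total reads")
    merged["frequency"] = merged["count"] / totals
    return merged


def apply_read_threshold(
    table: pd.DataFrame,
    unit: str,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Keep variants with at least ``min_reads`` reads summed over bins/days.

    The filter acts per replicate: a variant may be scored in some replicates
    and not in others. ``min_reads=0`` leaves the table unchanged.
    """
    if min_reads <= 0:
        return table.copy()
    totals = (
        table.groupby(["replicate", "variant"])["count"].transform("sum")
    )
    return table.loc[totals >= min_reads].reset_index(drop=True)
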