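"""Shared readers and writers.

All user-facing tables are plain text: tab-separated for maps, counts and
metrics; comma-separated (MaveDB-style score-set dialect: header row, UTF-8,
'.' decimal) for score tables. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .subassembly import BarcodeEntry, BarcodeMap
from .variants import parse_variant


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_single_fasta(path) -> str:
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(seqs)}")
    return next(iter(seqs.values()))


def read_reads(path) -> List[str]:
    """Raw reads from FASTA or FASTQ (format chosen by extension)."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_barcode_map(barcode_map: BarcodeMap, path) -> None:
    barcode_map.to_frame().to_csv(path, sep="\t", index=False)


def read_barcode_map(path) -> BarcodeMap:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "variant": str})
    entries = {}
    for row in df.itertuples(index=False):
        n_total = int(getattr(row, "n_reads", 1))
        dominant = float(getattr(row, "dominant_fraction", 1.0))
        support = max(1, round(dominant * n_total))
        entries[row.barcode] = BarcodeEntry(parse_variant(row.variant), support, n_total)
    return BarcodeMap(entries)


def write_table(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scores(score_table: pd.DataFrame, path) -> None:
    """Score CSV with columns variant, score, sd, n_replicates."""
    cols = [c for c in ("variant", "score", "sd", "n_replicates") if c in score_table]
    score_table[cols].to_csv(path, index=False, encoding="utf-8")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_predictor_track(path, value_column: Optional[str] = None) -> pd.Series:
    """A per-variant predictor TSV (variant + one value column) as a Series."""
    df = pd.read_csv(path, sep="\t")
    if value_column is None:
        candidates = [c for c in df.columns if c != "variant"]
        if len(candidates) != 1:
            raise ValueError(f"{path}: specify value_column among {candidates}")
        value_column = candidates[0]
    return df.set_index("variant")[value_column]


def write_manifest(path, seed: int, config: dict, outputs: Iterable[str]) -> None:
    import numpy
    import pandas
    import scipy

    manifest = {
        "seed": seed,
        "config": config,
        "outputs": sorted(outputs),
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
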