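"""Peptide-tile (degron scanning) library design and tile stability scoring.

The protein is split into 24-residue tiles overlapping by 12 residues; if the
last regular tile does not reach the final residue, a C-terminal (CT) tile
spanning the last 24 residues is appended. Tiles are partitioned by serial
parity into Odds and Evens pools — with the CT tile in its own pool — so
overlapping oligos never share a tube, and each 72-nt tile insert is flanked
by two 30-nt Gibson adapters (132-nt oligos; the 22-residue control peptides
give 126-nt oligos).

Each pool carries three control peptides modeled on a well-characterized
C-terminal degron and its stabilized point variants (strong degron ``-RLLL``,
mildly stabilized ``-RAAA``, strongly stabilized ``-DAAA``). The tile
stability index (TSI) is the same frequency-weighted mean bin index used for
full-length variants; the shared RLLL and DAAA controls define the affine map
that renormalizes the Evens and CT pools onto the Odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from sklearn.base import BaseEstimator

from .abundance import compute_psi
from .codons import reverse_translate
from .variants import validate_protein

# Synthetic 30-nt Gibson adapters (the study's adapter sequences are not
# public; only their length matters for oligo accounting).
ADAPTER_5 = "GGAGGTGGAGGTTCTGGCGCAAGCACTAGT"
ADAPTER_3 = "TGAACTAGCAGGCGCGCCTAAGGATCCGGC"

# Synthetic 22-residue control peptides: a neutral linker scaffold carrying
# the degron-defining C-terminal four residues.
_CONTROL_SCAFFOLD = "GSGSGSGSGSGSGSGSGS"
CONTROL_PEPTIDES: Dict[str, str] = {
    "RLLL": _CONTROL_SCAFFOLD + "RLLL",
    "RAAA": _CONTROL_SCAFFOLD + "RAAA",
    "DAAA": _CONTROL_SCAFFOLD + "DAAA",
}

LIBRARIES = ("odds", "evens", "ct")


@dataclass(frozen=True)
class Tile:
    """One oligo of the tile library, with residue coordinates (1-based, inclusive)."""

    index: int
    start: int
    end: int
    aa_seq: str
    nt_seq: str
    library: str
    oligo_seq: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def name(self) -> str:
        if self.library == "control":
            return f"control_{self.aa_seq[-4:]}"
        return f"tile_{self.index:02d}"


def _make_tile(index: int, start: int, end: int, aa_seq: str, library: str) -> Tile:
    nt = reverse_translate(aa_seq)
    return Tile(index, start, end, aa_seq, nt, library, ADAPTER_5 + nt + ADAPTER_3)


def design_tiles(
    protein_seq: str, tile_len: int = 24, step: int = 12
) -> List[Tile]:
    """Tile the protein with ``tile_len``-mers advancing by ``step`` residues.

    Regular tiles start at 1, 1+step, … while they fit; a CT tile covering the
    last ``tile_len`` residues is appended when the last regular tile stops
    short of the protein's end. Odd/even serial tiles go to the Odds/Evens
    pools; the CT tile goes to its own pool.
    """
    protein_seq = validate_protein(protein_seq)
    length = len(protein_seq)
    if length < tile_len:
        raise ValueError(f"protein shorter than one tile ({length} < {tile_len})")
    tiles: List[Tile] = []
    start = 1
    while start + tile_len - 1 <= length:
        end = start + tile_len - 1
        index = len(tiles) + 1
        library = "odds" if index % 2 == 1 else "evens"
        tiles.append(_make_tile(index, start, end, protein_seq[start - 1:end], library))
        start += step
    if tiles[-1].end != length:
        start = length - tile_len + 1
        index = len(tiles) + 1
        tiles.append(
            Tile(
                index, start, length,
                protein_seq[start - 1:],
                reverse_translate(protein_seq[start - 1:]),
                "ct",
                ADAPTER_5 + reverse_translate(protein_seq[start - 1:]) + ADAPTER_3,
            )
        )
    elif len(tiles) > 1:
        # last regular tile reaches the terminus: it is the CT tile
        last = tiles.pop()
        tiles.append(
            Tile(last.index, last.start, last.end, last.aa_seq, last.nt_seq,
                 "ct", last.oligo_seq)
        )
    return tiles


def control_tiles() -> List[Tile]:
    """The three control oligos, present in every library pool."""
    out = []
    for i, (name, pep) in enumerate(CONTROL_PEPTIDES.items(), start=1):
        nt = reverse_translate(pep)
        out.append(Tile(-i, 0, 0, pep, nt, "control", ADAPTER_5 + nt + ADAPTER_3))
    return out


def tiles_to_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": t.name, "index": t.index, "start": t.start, "end": t.end,
                "aa_seq": t.aa_seq, "library": t.library, "oligo_seq": t.oligo_seq,
            }
            for t in tiles
        ]
    )


def compute_tsi(frequencies: Sequence[float], bins: Optional[Sequence[int]] = None) -> float:
    """Weighted-mean bin index of one tile in one replicate (same form as PSI)."""
    return compute_psi(frequencies, bins)


def tsi_from_frequencies(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(replicate, tile) TSI from tidy columns replicate/bin/tile/frequency."""
    df = freq_table.loc[freq_table["frequency"] > 0]
    grouped = df.assign(weighted=df["bin"] * df["frequency"]).groupby(
        ["replicate", "tile"], as_index=False, sort=True
    )[["weighted", "frequency"]].sum()
    grouped["tsi"] = grouped["weighted"] / grouped["frequency"]
    return grouped[["replicate", "tile", "tsi"]]


def drop_cross_library_contaminants(
    counts: pd.DataFrame, tile_library: Dict[str, str]
) -> pd.DataFrame:
    """Drop tiles observed in a pool they were not assigned to.

    ``counts`` must carry ``tile`` and ``pool`` columns; control tiles belong
    to every pool. Contaminant reads are assumed non-sorted and ignored.
    """
    designed = counts["tile"].map(tile_library)
    is_control = (designed == "control") | counts["tile"].str.startswith("control_")
    keep = (designed == counts["pool"]) | is_control
    return counts.loc[keep].reset_index(drop=True)


def fit_control_renormalization(
    ref_controls: Dict[str, float], target_controls: Dict[str, float]
) -> Tuple[float, float]:
    """Affine map (a, b), m(x) = a + b·x, sending target controls onto reference.

    Uses the RLLL and DAAA controls; the map interpolates both exactly.
    """
    for key in ("RLLL", "DAAA"):
        if key not in ref_controls or key not in target_controls:
            raise ValueError(f"control {key!r} missing from a library")
    x1, x2 = target_controls["RLLL"], target_controls["DAAA"]
    y1, y2 = ref_controls["RLLL"], ref_controls["DAAA"]
    if x1 == x2:
        raise ValueError("degenerate fit: target control TSIs coincide")
    b = (y1 - y2) / (x1 - x2)
    a = y1 - b * x1
    return a, b


class TileRenormalizer(BaseEstimator):
    """Control-anchored affine renormalization of one library pool onto another.

    ``fit`` solves m(x) = a + b·x from the shared RLLL/DAAA control TSIs;
    ``transform`` applies the fitted map to TSI values of the target pool.

    Attributes
    ----------
    a_, b_ : float
        Fitted intercept and slope.
    """

    def __init__(self, controls: Tuple[str, str] = ("RLLL", "DAAA")):
        self.controls = controls

    def fit(self, target_controls: Dict[str, float], ref_controls: Dict[str, float]):
        self.a_, self.b_ = fit_control_renormalization(ref_controls, target_controls)
        return self

    def transform(self, tsi_values):
        import numpy as np

        return self.a_ + self.b_ * np.asarray(tsi_values, dtype=float)


def score_tiles(
    freq_table: pd.DataFrame,
    tile_library: Dict[str, str],
    reference_pool: str = "odds",
) -> pd.DataFrame:
    """TSI scoring across pools with per-replicate control renormalization.

    ``freq_table`` is tidy with columns ``pool``, ``replicate``, ``bin``,
    ``tile``, ``frequency`` (contaminants already dropped or still present —
    they are removed here). Evens and CT replicate TSIs are renormalized onto
    the reference (Odds) pool via the RLLL/DAAA controls of the same
    replicate, then tiles are aggregated over replicates (mean, SD, n).
    """
    counts = drop_cross_library_contaminants(freq_table, tile_library)
    per_pool: Dict[str, pd.DataFrame] = {}
    for pool, sub in counts.groupby("pool"):
        per_pool[pool] = tsi_from_frequencies(sub)
    if reference_pool not in per_pool:
        raise ValueError(f"reference pool {reference_pool!r} has no data")

    def controls_of(table: pd.DataFrame, replicate) -> Dict[str, float]:
        sub = table.loc[table["replicate"] == replicate]
        return {
            name[len("control_"):]: float(sub.loc[sub["tile"] == name, "tsi"].iloc[0])
            for name in sub["tile"]
            if name.startswith("control_")
        }

    pieces = []
    ref_table = per_pool[reference_pool]
    for pool, table in per_pool.items():
        if pool == reference_pool:
            pieces.append(table.assign(tsi_norm=table["tsi"]))
            continue
        normed = []
        for replicate in table["replicate"].unique():
            ref_ctrl = controls_of(ref_table, replicate)
            tgt_ctrl = controls_of(table, replicate)
            a, b = fit_control_renormalization(ref_ctrl, tgt_ctrl)
            sub = table.loc[table["replicate"] == replicate].copy()
            sub["tsi_norm"] = a + b * sub["tsi"]
            normed.append(sub)
        pieces.append(pd.concat(normed, ignore_index=True))
    all_tsi = pd.concat(pieces, ignore_index=True)
    scored = all_tsi.loc[~all_tsi["tile"].str.startswith("control_")]
    agg = scored.groupby("tile", sort=True)["tsi_norm"].agg(
        tsi="mean", sd="std", n_replicates="count"
    )
    return agg.reset_index()
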