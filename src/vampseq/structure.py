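"""Residue-level structural and evolutionary covariates.

Provides the weighted contact number (WCN) as a burial/packing proxy,
post-processing of predicted folding-stability changes (ΔΔG), and gap-based
filtering of multiple sequence alignments. WCN for residue i is the canonical
inverse-square sum over all other residue representatives (Cα),

    WCN_i = Σ_{j≠i} 1 / r_ij²,

with no distance cutoff; on a multimer the sum runs over all chains, so
interface residues gain contacts.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def compute_wcn(coordinates: np.ndarray) -> np.ndarray:
    """Weighted contact number per residue from representative coordinates.

    Parameters
    ----------
    coordinates : (n, 3) array
        One representative point (Cα) per residue, in Å.

    Raises
    ------
    ValueError
        If two residues share identical coordinates (zero distance).
    """
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("coordinates must be an (n, 3) array")
    n = len(xyz)
    if n < 2:
        return np.zeros(n)
    d2 = squareform(pdist(xyz, metric="sqeuclidean"))
    off_diag = d2[~np.eye(n, dtype=bool)]
    if np.any(off_diag == 0):
        raise ValueError("duplicate residue coordinates (zero inter-residue distance)")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d2
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1)


def calpha_coordinates(
    pdb_path, chains: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[Tuple[str, int]]]:
    """Cα coordinates and (chain, author residue number) labels from a PDB file.

    All chains are used unless ``chains`` restricts the selection; residues
    without a Cα atom (or non-amino-acid heterogens) are skipped, so
    unresolved residues are simply absent rather than zero-filled.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    model = next(structure.get_models())
    coords, labels = [], []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            if residue.id[0] != " " or "CA" not in residue:
                continue
            coords.append(residue["CA"].coord)
            labels.append((chain.id, residue.id[1]))
    return np.asarray(coords, dtype=float), labels


def wcn_from_pdb(
    pdb_path, chains: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-residue WCN table (chain, position, wcn) from a structure file."""
    coords, labels = calpha_coordinates(pdb_path, chains)
    wcn = compute_wcn(coords)
    return pd.DataFrame(
        {"chain": [c for c, _ in labels],
         "position": [p for _, p in labels],
         "wcn": wcn}
    )


def postprocess_ddg(
    raw_values, scale: float = 2.9, clamp: Tuple[float, float] = (0.0, 5.0)
):
    """Rescale predicted stability changes from model energy units to kcal/mol.

    Values are divided by ``scale`` and truncated to ``clamp`` (default
    0–5 kcal/mol), so strongly stabilizing predictions floor at 0 and
    strongly destabilizing ones cap at 5.
    """
    arr = np.asarray(raw_values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ΔΔG inputs must be finite")
    return np.clip(arr / scale, clamp[0], clamp[1])


def filter_msa(
    alignment: Sequence[str], max_gap_fraction: float = 0.5, gap_chars: str = "-."
) -> List[str]:
    """Drop alignment sequences with more than ``max_gap_fraction`` gaps.

    The inequality is strict: a sequence with exactly the threshold fraction
    of gaps is retained. Columns are untouched. Accepts any rectangular list
    of aligned strings (or Biopython SeqRecords, via ``str(seq.seq)``).
    """
    seqs = [
        str(s.seq) if hasattr(s, "seq") else str(s)
        for s in alignment
    ]
    if not seqs:
        return []
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("alignment is not rectangular")
    gap_set = set(gap_chars)
    kept = [
        s for s in seqs
        if sum(c in gap_set for c in s) / width <= max_gap_fraction
    ]
    if not kept:
        warnings.warn("all sequences removed by the gap filter; returning empty alignment")
    return kept


def residue_metrics(
    wcn_table: pd.DataFrame,
    abundance_scores: Optional[pd.DataFrame] = None,
    toxicity_scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join WCN with per-position median scores into one residue-level table.

    ``wcn_table`` may span several chains of a multimer; positions are
    collapsed by mean WCN over chains (homomer subunits see near-identical
    environments). Score tables are aggregated to per-position medians over
    missense variants.
    """
    from .analyze import per_position_median

    metrics = (
        wcn_table.groupby("position", as_index=False)["wcn"].mean()
    )
    if abundance_scores is not None:
        med = per_position_median(abundance_scores)
        med = med.rename(columns={"median_score": "median_abundance"})
        metrics = metrics.merge(med, on="position", how="outer")
    if toxicity_scores is not None:
        med = per_position_median(toxicity_scores)
        med = med.rename(columns={"median_score": "median_toxicity"})
        metrics = metrics.merge(med, on="position", how="outer")
    return metrics.sort_values("position").reset_index(drop=True)
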