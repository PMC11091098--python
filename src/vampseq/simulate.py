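"""Synthetic libraries, FACS-bin counts and growth time courses.

The generator reproduces the statistical structure the scoring pipeline
assumes, so every downstream stage is testable without any sequencing data:

* a site-saturated single-substitution library in which each amino-acid entry
  carries a Poisson number (mean ~21) of random 18-nt barcodes, with half of
  the wild-type entry's barcodes carrying synonymous codon changes;
* a bimodal latent abundance on [0, 1] — a WT-like mode near 1 anchored by
  the wild type and synonymous variants, and a stop-like mode near 0 that all
  nonsense variants join;
* FACS sorting of cells whose fluorescence log-ratio is Gaussian around the
  latent abundance, split at the empirical occupancy quantiles into four
  equal bins, each sequenced to a fixed multinomial read depth;
* exponential depletion over culture days for variants with a growth-rate
  deficit, which only low-abundance variants can have;
* predictor tracks (ΔΔG, conservation) rank-coupled to the latent abundance
  through a Gaussian copula at configured Spearman targets.

One global seed drives every sub-generator through numpy ``SeedSequence``
spawning (library, FACS, time course, predictors, tiles — in that order), so
identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SimulationConfig
from .subassembly import BarcodeEntry, BarcodeMap, FlankSpec
from .codons import ALTERNATE_CODON, alternate_codon, mutate_codon, reverse_translate
from .tiles import CONTROL_PEPTIDES, Tile, control_tiles, design_tiles
from .variants import (
    AMINO_ACIDS,
    VariantId,
    enumerate_variant_universe,
    format_variant,
    parse_variant,
)

_BASES = np.array(list("ACGT"))

# default flanks for simulated long reads of barcode+CDS constructs
DEFAULT_FLANKS = FlankSpec(
    upstream="GGCTAACTAGAGAACCCACT",
    spacer="CGTACGCTGCAGGTCGAC",
    downstream="TGATAATGAGTTTAAACCCG",
)


@dataclass
class LatentTruth:
    """Ground truth behind a simulated experiment.

    ``table`` has one row per variant (including synonymous entries, which
    share the wild type's latent values): columns ``variant``, ``var_class``,
    ``latent_abundance``, ``growth_deficit`` and — once predictor tracks are
    attached — ``ddg`` and ``conservation``.
    """

    table: pd.DataFrame
    protein_seq: str
    toxic_anchor: str

    def latent_of(self) -> pd.Series:
        return self.table.set_index("variant")["latent_abundance"]

    def deficit_of(self) -> pd.Series:
        return self.table.set_index("variant")["growth_deficit"]


def _rng_children(config: SimulationConfig, n: int = 5):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> List[str]:
    """Draw ``n`` distinct random ACGT strings of the given length."""
    space = 4 ** length
    if n > space:
        raise ValueError(f"requested {n} barcodes exceeds the 4^{length} barcode space")
    codes: np.ndarray = np.empty(0, dtype=np.int64)
    while len(codes) < n:
        extra = rng.integers(0, space, size=n - len(codes) + 64, dtype=np.int64)
        codes = np.unique(np.concatenate([codes, extra]))
    codes = rng.permutation(codes)[:n]
    digits = np.empty((n, length), dtype=np.int64)
    rem = codes.copy()
    for i in range(length - 1, -1, -1):
        digits[:, i] = rem % 4
        rem //= 4
    return ["".join(row) for row in _BASES[digits]]


def _random_protein(length: int, anchor_pos: int, anchor_wt: str,
                    rng: np.random.Generator) -> str:
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    seq[anchor_pos - 1] = anchor_wt
    return "".join(seq)


def resolve_toxic_anchor(config: SimulationConfig) -> VariantId:
    """The toxic reference variant, relocated if it falls outside the protein."""
    anchor = parse_variant(config.toxicity_link.toxic_anchor)
    if anchor.position > config.protein_length:
        anchor = VariantId(
            max(2, config.protein_length // 2), anchor.wt_aa, anchor.alt_aa, "missense"
        )
    return anchor


def simulate_library(config: SimulationConfig) -> Tuple[BarcodeMap, LatentTruth]:
    """Generate the barcode→variant map and the latent truth behind it.

    Every variant of the universe receives at least one barcode; the number
    of barcodes per entry is Poisson with the configured mean (scaled by
    ``wt_barcode_multiplier`` for the wild-type entry, a configurable share
    of whose barcodes carry synonymous codon changes). Stop variants draw
    their latent abundance from the low mode and the wild type from the high
    mode; a missense variant joins the high mode with a position-specific
    probability (Beta-distributed per-position tolerance whose marginal mean
    is ``stable_fraction`` and whose concentration ``position_concentration``
    sets how strongly position determines the outcome). Growth-rate deficits
    afflict only variants whose latent abundance sits below the toxicity
    threshold.
    """
    rng = _rng_children(config, 5)[0]
    anchor = resolve_toxic_anchor(config)
    if config.protein_seq is not None:
        protein_seq = config.protein_seq
        if protein_seq[anchor.position - 1] != anchor.wt_aa:
            raise ValueError(
                f"toxic anchor {format_variant(anchor)} does not match the protein "
                f"sequence at position {anchor.position}"
            )
    else:
        protein_seq = _random_protein(
            config.protein_length, anchor.position, anchor.wt_aa, rng
        )
    universe = enumerate_variant_universe(protein_seq)
    anchor_str = format_variant(anchor)
    mp = config.mode_params

    # latent abundance per universe entry; the probability that a missense
    # variant joins the stable mode is position-specific (Beta-distributed
    # tolerance with marginal mean stable_fraction), so mutational tolerance
    # depends more on position than on the substituted amino acid
    classes = np.array([v.var_class for v in universe])
    positions = np.array([v.position for v in universe])
    n_univ = len(universe)
    kappa = config.position_concentration
    tolerance = rng.beta(
        config.stable_fraction * kappa,
        (1.0 - config.stable_fraction) * kappa,
        size=config.protein_length,
    )
    p_high = np.where(positions > 0, tolerance[np.maximum(positions - 1, 0)], 0.5)
    high = rng.random(n_univ) < p_high
    high[classes == "wt"] = True
    high[classes == "nonsense"] = False
    strings = np.array([format_variant(v) for v in universe])
    high[strings == anchor_str] = False
    latent = np.where(
        high,
        rng.normal(mp.high_mean, mp.high_sd, n_univ),
        rng.normal(mp.low_mean, mp.low_sd, n_univ),
    )
    latent = np.clip(latent, 0.0, 1.0)

    # growth-rate deficit, confined to low-abundance variants
    link = config.toxicity_link
    room = np.clip(1.0 - latent / link.abundance_threshold, 0.0, None)
    jitter = rng.uniform(link.jitter_low, link.jitter_high, n_univ)
    deficit = link.max_deficit * room * jitter
    deficit[strings == anchor_str] = link.anchor_deficit

    # barcodes per entry
    means = np.full(n_univ, float(config.n_barcodes_per_variant))
    means[classes == "wt"] *= config.wt_barcode_multiplier
    n_bc = np.maximum(1, rng.poisson(means))
    barcodes = random_barcodes(int(n_bc.sum()), config.barcode_length, rng)

    syn_positions = [
        p for p in range(1, config.protein_length + 1)
        if protein_seq[p - 1] in ALTERNATE_CODON
    ]
    entries: Dict[str, BarcodeEntry] = {}
    truth_rows = []
    cursor = 0
    for idx, variant in enumerate(universe):
        truth_rows.append(
            {
                "variant": strings[idx],
                "var_class": variant.var_class,
                "latent_abundance": float(latent[idx]),
                "growth_deficit": float(deficit[idx]),
            }
        )
        for bc in barcodes[cursor:cursor + n_bc[idx]]:
            assigned = variant
            if variant.var_class == "wt" and syn_positions and (
                rng.random() < config.synonymous_fraction
            ):
                pos = int(rng.choice(syn_positions))
                assigned = VariantId(pos, protein_seq[pos - 1], "=", "synonymous")
            entries[bc] = BarcodeEntry(assigned, 1, 1)
        cursor += n_bc[idx]

    # synonymous entries share the wild type's latent values
    wt_latent = float(latent[classes == "wt"][0])
    seen = {r["variant"] for r in truth_rows}
    for entry in entries.values():
        if entry.variant.var_class == "synonymous":
            name = format_variant(entry.variant)
            if name not in seen:
                seen.add(name)
                truth_rows.append(
                    {
                        "variant": name,
                        "var_class": "synonymous",
                        "latent_abundance": wt_latent,
                        "growth_deficit": 0.0,
                    }
                )

    truth = LatentTruth(pd.DataFrame(truth_rows), protein_seq, anchor_str)
    return BarcodeMap(entries), truth


def _sort_and_sequence(
    latents: np.ndarray,
    cell_weights: np.ndarray,
    config: SimulationConfig,
    reads_per_bin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sort cells into occupancy bins and sequence each bin.

    ``latents`` and ``cell_weights`` are per sequencing unit (barcode or
    tile). Returns an integer count matrix of shape (n_units, n_bins) whose
    column sums equal ``reads_per_bin`` exactly.
    """
    n_units = len(latents)
    if n_units == 0 or config.n_cells <= 0 or reads_per_bin <= 0:
        raise ValueError("need at least one unit, one cell and one read per bin")
    weights = cell_weights / cell_weights.sum()
    cells = rng.multinomial(config.n_cells, weights)

    # empirical occupancy quantiles of the pooled fluorescence mixture
    m = min(config.n_cells, 200_000)
    sample_units = rng.choice(n_units, size=m, p=weights)
    sample = rng.normal(latents[sample_units], config.noise_sd)
    cum = np.cumsum(config.bin_occupancy)[:-1]
    cuts = np.quantile(sample, cum)

    # per-unit bin probabilities from the Gaussian noise model
    z = (cuts[None, :] - latents[:, None]) / config.noise_sd
    cdf = np.concatenate(
        [np.zeros((n_units, 1)), norm.cdf(z), np.ones((n_units, 1))], axis=1
    )
    p_bins = np.diff(cdf, axis=1)

    # multinomial split of each unit's cells across bins (binomial chain)
    n_bins = config.n_bins
    cells_in_bin = np.zeros((n_units, n_bins), dtype=np.int64)
    remaining = cells.copy()
    tail = np.ones(n_units)
    for g in range(n_bins - 1):
        p_rel = np.clip(np.divide(p_bins[:, g], tail, out=np.zeros(n_units),
                                  where=tail > 0), 0.0, 1.0)
        drawn = rng.binomial(remaining, p_rel)
        cells_in_bin[:, g] = drawn
        remaining -= drawn
        tail = np.clip(tail - p_bins[:, g], 1e-300, None)
    cells_in_bin[:, n_bins - 1] = remaining

    # sequencing: fixed read depth per bin, reads multinomial over units
    counts = np.zeros((n_units, n_bins), dtype=np.int64)
    for g in range(n_bins):
        total = cells_in_bin[:, g].sum()
        if total == 0:
            raise ValueError(f"bin {g + 1} received no cells; increase n_cells")
        counts[:, g] = rng.multinomial(
            reads_per_bin, cells_in_bin[:, g] / total
        )
    return counts


def simulate_facs_counts(
    truth: LatentTruth,
    barcode_map: BarcodeMap,
    config: SimulationConfig,
    collapse_to_variants: bool = True,
    n_replicates: Optional[int] = None,
) -> pd.DataFrame:
    """Per-replicate, per-bin read counts from simulated FACS sorting.

    Each cell carries one barcode and a fluorescence ratio Gaussian around
    its variant's latent abundance; cells are split at the empirical
    occupancy quantiles and each bin is sequenced to ``reads_per_bin`` reads.
    Returns a tidy table (replicate, bin, variant-or-barcode, count) with
    zero-count rows omitted.
    """
    rng = _rng_children(config, 5)[1]
    n_replicates = n_replicates or config.replicates_abundance
    barcodes = np.array(sorted(barcode_map.entries))
    variants = np.array(
        [format_variant(barcode_map.entries[b].variant) for b in barcodes]
    )
    latent_lookup = truth.latent_of()
    latents = latent_lookup.loc[variants].to_numpy(float)
    key = "variant" if collapse_to_variants else "barcode"
    if collapse_to_variants:
        labels, codes = np.unique(variants, return_inverse=True)
    frames = []
    for rep in range(1, n_replicates + 1):
        counts = _sort_and_sequence(
            latents, np.ones(len(barcodes)), config, config.reads_per_bin, rng
        )
        if collapse_to_variants:
            agg = np.zeros((len(labels), config.n_bins), dtype=np.int64)
            np.add.at(agg, codes, counts)
            counts, names = agg, labels
        else:
            names = barcodes
        units, bins = np.nonzero(counts)
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "bin": bins + 1,
                    key: names[units],
                    "count": counts[units, bins],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_timecourse(
    truth: LatentTruth,
    barcode_map: BarcodeMap,
    config: SimulationConfig,
    n_replicates: Optional[int] = None,
) -> pd.DataFrame:
    """Per-replicate, per-day read counts under exponential depletion.

    Variant cell fractions evolve as exponential growth at a common base rate
    minus the variant's deficit (the base rate cancels in frequencies); the
    same number of cells is sequenced each day, so reads are multinomial with
    ``reads_per_day`` total.
    """
    rng = _rng_children(config, 5)[2]
    n_replicates = n_replicates or config.replicates_toxicity
    days = np.asarray(config.days, dtype=float)
    variant_of_bc = pd.Series(
        {bc: format_variant(e.variant) for bc, e in barcode_map.entries.items()}
    )
    bc_per_variant = variant_of_bc.value_counts().sort_index()
    names = bc_per_variant.index.to_numpy()
    deficits = truth.deficit_of().loc[names].to_numpy(float)
    if np.any(deficits < 0):
        raise ValueError("growth-rate deficits must be non-negative")
    base_weights = bc_per_variant.to_numpy(float)
    frames = []
    for rep in range(1, n_replicates + 1):
        n0 = rng.multinomial(config.n_cells, base_weights / base_weights.sum())
        for day in days:
            w = n0 * np.exp(-deficits * day)
            reads = rng.multinomial(config.reads_per_day, w / w.sum())
            nz = reads > 0
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "day": int(day),
                        "variant": names[nz],
                        "count": reads[nz],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_predictor_tracks(
    truth: LatentTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Synthetic ΔΔG and conservation tracks rank-coupled to latent abundance.

    A Gaussian copula on the latent-abundance ranks hits the configured
    Spearman targets (ΔΔG decreasing in abundance, conservation increasing);
    ΔΔG is mapped onto [0, 5] kcal/mol and conservation onto [-scale, 0].
    Setting a target of ±1 removes the noise entirely. Tracks cover missense
    variants only.
    """
    rng = _rng_children(config, 5)[3]
    link = config.predictor_link
    missense = truth.table.loc[truth.table["var_class"] == "missense"]
    a = missense["latent_abundance"].to_numpy(float)
    n = len(a)
    ranks = pd.Series(a).rank(method="average").to_numpy()
    z = norm.ppf((ranks - 0.5 + rng.uniform(-0.25, 0.25, n)) / n)

    def coupled(target_spearman: float) -> np.ndarray:
        from scipy.stats import spearmanr

        rho = float(np.clip(2.0 * np.sin(np.pi * target_spearman / 6.0), -0.999, 0.999))
        eps = rng.standard_normal(n)
        y = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        # ties in the clipped latent attenuate the realized coefficient; two
        # fixed-point corrections re-center it on the configured target
        for _ in range(2):
            realized = spearmanr(y, a).correlation
            if not np.isfinite(realized) or realized == 0.0:
                break
            if abs(realized - target_spearman) < 0.005:
                break
            rho = float(np.clip(rho * target_spearman / realized, -0.999, 0.999))
            y = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        return y

    ddg = np.clip(link.ddg_scale * norm.cdf(coupled(link.spearman_ddg)), 0.0, 5.0)
    conservation = link.conservation_scale * (
        norm.cdf(coupled(link.spearman_conservation)) - 1.0
    )
    return pd.DataFrame(
        {
            "variant": missense["variant"].to_numpy(),
            "ddg": ddg,
            "conservation": conservation,
        }
    )


# Kyte-Doolittle hydropathy, used to give simulated tiles a degron-like latent
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CONTROL_LATENTS = {"RLLL": 0.10, "RAAA": 0.50, "DAAA": 0.90}


def tile_latent_stability(aa_seq: str, midpoint: float = -0.5, scale: float = 0.7) -> float:
    """Latent tile stability decreasing with mean hydrophobicity.

    Hydrophobic tiles behave like quality-control degrons and deplete the
    reporter; hydrophilic tiles are stable. Logistic link on the mean
    Kyte-Doolittle hydropathy.
    """
    hydro = float(np.mean([_KD[aa] for aa in aa_seq]))
    return float(1.0 / (1.0 + np.exp((hydro - midpoint) / scale)))


def simulate_tile_counts(
    tiles: Sequence[Tile],
    config: SimulationConfig,
    n_replicates: int = 3,
    reads_per_bin: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Sorting counts for the three tile pools (odds, evens, CT + controls).

    Each pool is sorted and sequenced separately with the same FACS model as
    the full-length library. Returns the tidy counts (pool, replicate, bin,
    tile, count) and the latent tile stabilities used.
    """
    rng = _rng_children(config, 5)[4]
    reads_per_bin = reads_per_bin or max(1000, config.reads_per_bin // 100)
    controls = control_tiles()
    latents: Dict[str, float] = {}
    for t in tiles:
        latents[t.name] = tile_latent_stability(t.aa_seq)
    for c in controls:
        latents[c.name] = CONTROL_LATENTS[c.aa_seq[-4:]]
    frames = []
    for pool in ("odds", "evens", "ct"):
        members = [t for t in tiles if t.library == pool] + controls
        names = np.array([t.name for t in members])
        lat = np.array([latents[n] for n in names])
        for rep in range(1, n_replicates + 1):
            counts = _sort_and_sequence(
                lat, np.ones(len(members)), config, reads_per_bin, rng
            )
            units, bins = np.nonzero(counts)
            frames.append(
                pd.DataFrame(
                    {
                        "pool": pool,
                        "replicate": rep,
                        "bin": bins + 1,
                        "tile": names[units],
                        "count": counts[units, bins],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), pd.Series(latents)


def long_reads_from_map(
    barcode_map: BarcodeMap,
    protein_seq: str,
    flank_spec: FlankSpec = DEFAULT_FLANKS,
    reads_per_barcode: int = 1,
) -> List[str]:
    """Error-free long reads reproducing the map's barcode+CDS constructs.

    Used to close the loop between the simulator and the subassembly stage:
    feeding these reads back through subassembly recovers the map exactly.
    """
    ref_cds = reverse_translate(protein_seq)
    reads = []
    for bc in sorted(barcode_map.entries):
        variant = barcode_map.entries[bc].variant
        if variant.var_class == "wt":
            cds = ref_cds
        elif variant.var_class == "synonymous":
            alt = alternate_codon(protein_seq[variant.position - 1])
            if alt is None:
                raise ValueError(
                    f"no synonymous codon available at position {variant.position}"
                )
            i = (variant.position - 1) * 3
            cds = ref_cds[:i] + alt + ref_cds[i + 3:]
        else:
            cds = mutate_codon(ref_cds, variant.position, variant.alt_aa)
        read = (
            flank_spec.upstream + bc + flank_spec.spacer + cds + flank_spec.downstream
        )
        reads.extend([read] * reads_per_barcode)
    return reads


def simulate_globule_coordinates(
    n_residues: int, rng: np.random.Generator, min_distance: float = 3.5
) -> np.ndarray:
    """Random compact globule: points in a ball with a hard-core distance.

    A stand-in for folded-protein Cα coordinates when exercising the contact
    density metrics; interior points end up with higher contact numbers than
    surface points, as in a real fold.
    """
    radius = 3.0 * n_residues ** (1.0 / 3.0)
    points: List[np.ndarray] = []
    attempts = 0
    while len(points) < n_residues:
        attempts += 1
        if attempts > 200 * n_residues:
            raise RuntimeError("could not pack the globule; lower min_distance")
        p = rng.uniform(-radius, radius, 3)
        if p @ p > radius * radius:
            continue
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < min_distance:
            continue
        points.append(p)
    return np.array(points)
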