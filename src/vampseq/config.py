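"""Simulation configuration.

The defaults describe the experiment the scoring pipeline was built for: a
site-saturated single-substitution library over a 313-residue protein, ~21
random 18-nt barcodes per variant, FACS sorting of ~5 million cells into four
equal-occupancy bins sequenced to 10^6 reads each across 11 replicates, and a
competitive-growth time course sampled on days 0, 5, 7 and 9 in four
replicates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import yaml


@dataclass
class ModeParams:
    """Two-component latent-abundance mixture on the GFP:mCherry log-ratio.

    Latent abundance lives on [0, 1] with the stop-like mode near 0 and the
    WT-like mode near 1; values are clipped to the unit interval.
    """

    high_mean: float = 1.0
    high_sd: float = 0.08
    low_mean: float = 0.0
    low_sd: float = 0.10


@dataclass
class ToxicityLink:
    """Map from latent abundance to growth-rate deficit (per day).

    Only variants below ``abundance_threshold`` can be toxic; the deficit
    scales linearly with how far below the threshold a variant sits, jittered
    multiplicatively, so toxicity is coupled to — but not determined by — low
    abundance. The designated toxic anchor variant receives ``anchor_deficit``
    exactly.
    """

    abundance_threshold: float = 0.3
    max_deficit: float = 0.4
    jitter_low: float = 0.6
    jitter_high: float = 1.0
    anchor_deficit: float = 0.35
    toxic_anchor: str = "C152W"


@dataclass
class PredictorLink:
    """Rank-coupling targets for the synthetic predictor tracks.

    Spearman targets are achieved with a Gaussian copula on the latent
    abundance ranks, so the realized coefficient concentrates on the target
    as the number of variants grows.
    """

    spearman_ddg: float = -0.47
    spearman_conservation: float = 0.45
    ddg_scale: float = 5.0
    conservation_scale: float = 8.0


@dataclass
class SimulationConfig:
    seed: int = 0
    protein_length: int = 313
    protein_seq: Optional[str] = None
    n_barcodes_per_variant: float = 21.0
    wt_barcode_multiplier: float = 1.0
    synonymous_fraction: float = 0.5
    barcode_length: int = 18
    n_bins: int = 4
    bin_occupancy: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    n_cells: int = 5_000_000
    reads_per_bin: int = 1_000_000
    reads_per_day: int = 1_000_000
    replicates_abundance: int = 11
    replicates_toxicity: int = 4
    days: Sequence[int] = (0, 5, 7, 9)
    stable_fraction: float = 0.5
    position_concentration: float = 0.8
    mode_params: ModeParams = field(default_factory=ModeParams)
    noise_sd: float = 0.25
    toxicity_link: ToxicityLink = field(default_factory=ToxicityLink)
    predictor_link: PredictorLink = field(default_factory=PredictorLink)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.protein_length < 2:
            raise ValueError("protein_length must be >= 2")
        if self.n_barcodes_per_variant <= 0:
            raise ValueError("n_barcodes_per_variant must be positive")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        occ = list(self.bin_occupancy)
        if len(occ) != self.n_bins:
            raise ValueError("bin_occupancy length must equal n_bins")
        if abs(sum(occ) - 1.0) > 1e-9:
            raise ValueError("bin occupancies must sum to 1")
        if any(o <= 0 for o in occ):
            raise ValueError("bin occupancies must be positive")
        for name in ("n_cells", "reads_per_bin", "reads_per_day",
                     "replicates_abundance", "replicates_toxicity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        days = list(self.days)
        if len(days) < 2 or days != sorted(days) or len(set(days)) != len(days):
            raise ValueError("days must be strictly increasing")
        if days[0] != 0:
            raise ValueError("day 0 must be present")
        if not 0.0 < self.stable_fraction < 1.0:
            raise ValueError("stable_fraction must be in (0, 1)")
        if self.position_concentration <= 0:
            raise ValueError("position_concentration must be positive")
        if not 0.0 <= self.synonymous_fraction <= 1.0:
            raise ValueError("synonymous_fraction must be in [0, 1]")
        if self.toxicity_link.max_deficit < 0 or self.toxicity_link.anchor_deficit < 0:
            raise ValueError("growth-rate deficits must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bin_occupancy"] = list(self.bin_occupancy)
        d["days"] = list(self.days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "mode_params" in d and isinstance(d["mode_params"], dict):
            d["mode_params"] = ModeParams(**d["mode_params"])
        if "toxicity_link" in d and isinstance(d["toxicity_link"], dict):
            d["toxicity_link"] = ToxicityLink(**d["toxicity_link"])
        if "predictor_link" in d and isinstance(d["predictor_link"], dict):
            d["predictor_link"] = PredictorLink(**d["predictor_link"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down configuration for quick runs and tests."""
    defaults = dict(
        protein_length=40,
        n_barcodes_per_variant=5.0,
        n_cells=200_000,
        reads_per_bin=50_000,
        reads_per_day=50_000,
        replicates_abundance=3,
        replicates_toxicity=3,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
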