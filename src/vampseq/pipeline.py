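"""End-to-end pipeline: simulate → subassemble → count → score → analyze.

Runs every stage from one seed and writes all artifacts plus a manifest into
an output directory. Deterministic stages are byte-identical across reruns
with the same configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import analyze, io, quantify
from .abundance import AbundanceScorer
from .config import SimulationConfig
from .simulate import (
    LatentTruth,
    simulate_facs_counts,
    simulate_globule_coordinates,
    simulate_library,
    simulate_predictor_tracks,
    simulate_tile_counts,
    simulate_timecourse,
)
from .structure import compute_wcn, residue_metrics
from .tiles import design_tiles, score_tiles, tiles_to_frame
from .toxicity import ToxicityScorer

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {reason}")


def _tile_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.groupby(["pool", "replicate", "bin"])["count"].transform("sum")
    out = counts.copy()
    out["frequency"] = out["count"] / totals
    return out


def run_pipeline(
    config: SimulationConfig,
    outdir,
    min_reads: int = 20,
    tile_replicates: int = 3,
) -> Dict[str, Path]:
    """Execute all stages and return the paths of the written artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    name = stage("simulate-library")
    try:
        barcode_map, truth = simulate_library(config)
        paths["barcode_map"] = outdir / "barcode_map.tsv"
        io.write_barcode_map(barcode_map, paths["barcode_map"])
        tracks = simulate_predictor_tracks(truth, config)
        truth.table = truth.table.merge(tracks, on="variant", how="left")
        paths["truth"] = outdir / "latent_truth.tsv"
        io.write_table(truth.table, paths["truth"])
        paths["predictors"] = outdir / "predictors.tsv"
        io.write_table(tracks, paths["predictors"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    name = stage("abundance")
    try:
        facs_counts = simulate_facs_counts(truth, barcode_map, config)
        freq = quantify.merge_and_normalize(facs_counts, unit="bin")
        freq = quantify.apply_read_threshold(freq, unit="bin", min_reads=min_reads)
        ab_scorer = AbundanceScorer().fit(freq)
        ab_per_rep = ab_scorer.transform(freq)
        ab_scores = ab_scorer.score_table(freq)
        paths["abundance"] = outdir / "abundance_scores.csv"
        io.write_scores(ab_scores, paths["abundance"])
        paths["abundance_replicates"] = outdir / "abundance_per_replicate.tsv"
        io.write_table(ab_per_rep, paths["abundance_replicates"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    name = stage("toxicity")
    try:
        tc_counts = simulate_timecourse(truth, barcode_map, config)
        tc_freq = quantify.merge_and_normalize(tc_counts, unit="day")
        tc_freq = quantify.apply_read_threshold(tc_freq, unit="day", min_reads=min_reads)
        tox_scorer = ToxicityScorer(
            toxic_anchor=truth.toxic_anchor, days=list(config.days)
        ).fit(tc_freq)
        tox_per_rep = tox_scorer._normalize(tox_scorer.slope_table_)
        tox_scores = tox_scorer.score_table()
        paths["toxicity"] = outdir / "toxicity_scores.csv"
        io.write_scores(tox_scores, paths["toxicity"])
        paths["toxicity_replicates"] = outdir / "toxicity_per_replicate.tsv"
        io.write_table(tox_per_rep, paths["toxicity_replicates"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    name = stage("tiles")
    try:
        tile_set = design_tiles(truth.protein_seq)
        paths["tile_design"] = outdir / "tile_design.tsv"
        io.write_table(tiles_to_frame(tile_set), paths["tile_design"])
        tile_counts, _ = simulate_tile_counts(
            tile_set, config, n_replicates=tile_replicates
        )
        tile_freq = _tile_frequencies(tile_counts)
        library_of = {t.name: t.library for t in tile_set}
        tsi = score_tiles(tile_freq, library_of)
        paths["tsi"] = outdir / "tsi_scores.tsv"
        io.write_table(tsi, paths["tsi"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    name = stage("structure-metrics")
    try:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        coords = simulate_globule_coordinates(len(truth.protein_seq), rng)
        wcn_table = pd.DataFrame(
            {
                "chain": "A",
                "position": np.arange(1, len(coords) + 1),
                "wcn": compute_wcn(coords),
            }
        )
        metrics = residue_metrics(wcn_table, ab_scores, tox_scores)
        paths["metrics"] = outdir / "residue_metrics.tsv"
        io.write_table(metrics, paths["metrics"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    name = stage("analyze")
    try:
        summary = summarize(truth, ab_scores, ab_per_rep, tox_scores, tox_per_rep,
                            tracks, seed=config.seed)
        paths["summary"] = outdir / "summary.json"
        with open(paths["summary"], "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    paths["manifest"] = outdir / "manifest.json"
    io.write_manifest(
        paths["manifest"], config.seed, config.to_dict(),
        [str(p.name) for p in paths.values()],
    )
    return paths


def summarize(
    truth: LatentTruth,
    ab_scores: pd.DataFrame,
    ab_per_rep: pd.DataFrame,
    tox_scores: pd.DataFrame,
    tox_per_rep: pd.DataFrame,
    tracks: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> dict:
    """Headline analytics of one simulated run as a JSON-serializable dict."""
    latent = truth.latent_of()
    deficit = truth.deficit_of()
    ab = ab_scores.set_index("variant")["score"]
    tox = tox_scores.set_index("variant")["score"]
    summary: dict = {}
    summary["abundance_recovery_spearman"] = analyze.correlate(
        ab, latent, "spearman", seed=seed
    ).to_dict()
    summary["toxicity_recovery_spearman"] = analyze.correlate(
        tox, deficit, "spearman", seed=seed
    ).to_dict()
    summary["replicates_abundance"] = analyze.replicate_stats(ab_per_rep)
    summary["replicates_toxicity"] = analyze.replicate_stats(tox_per_rep)
    summary["variance_explained"] = analyze.variance_explained(ab_scores)
    if tracks is not None:
        track_idx = tracks.set_index("variant")
        summary["abundance_vs_ddg"] = analyze.correlate(
            ab, track_idx["ddg"], "spearman", seed=seed
        ).to_dict()
        summary["abundance_vs_conservation"] = analyze.correlate(
            ab, track_idx["conservation"], "spearman", seed=seed
        ).to_dict()
        summary["toxicity_vs_ddg"] = analyze.correlate(
            tox, track_idx["ddg"], "spearman", seed=seed
        ).to_dict()
    return summary
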