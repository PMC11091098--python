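"""Statistical contracts of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from vampseq.config import SimulationConfig, small_config
from vampseq.simulate import (
    random_barcodes,
    simulate_facs_counts,
    simulate_library,
    simulate_predictor_tracks,
    simulate_timecourse,
)
from vampseq.variants import enumerate_variant_universe, format_variant


class TestLibrary:
    def test_same_seed_gives_identical_map_and_truth(self):
        cfg = small_config(seed=9)
        map1, truth1 = simulate_library(cfg)
        map2, truth2 = simulate_library(cfg)
        assert map1.entries == map2.entries
        pd.testing.assert_frame_equal(truth1.table, truth2.table)
        assert truth1.protein_seq == truth2.protein_seq

    def test_every_universe_variant_has_a_barcode(self, small_library):
        barcode_map, truth = small_library
        mapped = {format_variant(e.variant) for e in barcode_map.entries.values()}
        universe = {
            format_variant(v)
            for v in enumerate_variant_universe(truth.protein_seq)
        }
        assert universe <= mapped

    def test_dipeptide_universe_fully_covered(self):
        cfg = small_config(seed=2, protein_length=2)
        barcode_map, truth = simulate_library(cfg)
        universe = {
            format_variant(v) for v in enumerate_variant_universe(truth.protein_seq)
        }
        for entry in barcode_map.entries.values():
            name = format_variant(entry.variant)
            assert name in universe or name.endswith("=")

    def test_barcodes_unique_and_18nt(self, small_library):
        barcode_map, _ = small_library
        assert all(len(bc) == 18 for bc in barcode_map.entries)
        assert all(set(bc) <= set("ACGT") for bc in barcode_map.entries)

    def test_mean_barcode_count_follows_sampling_law(self):
        """Monte-Carlo mean over seeds matches the Poisson-per-entry law."""
        mean_bc, length = 21.0, 10
        totals = [
            len(
                simulate_library(
                    small_config(
                        seed=s, protein_length=length, n_barcodes_per_variant=mean_bc
                    )
                )[0]
            )
            for s in range(20)
        ]
        expected = mean_bc * 20 * length  # 20·L universe entries
        assert np.mean(totals) == pytest.approx(expected, rel=0.03)

    def test_barcode_space_exhaustion_rejected(self, rng):
        with pytest.raises(ValueError, match="barcode space"):
            random_barcodes(100, 3, rng)  # 4^3 = 64 < 100

    def test_mode_anchoring_of_stops_and_wt(self, small_library):
        _, truth = small_library
        t = truth.table.set_index("variant")
        stops = t.loc[t["var_class"] == "nonsense", "latent_abundance"]
        assert stops.mean() < 0.2
        assert t.loc["WT", "latent_abundance"] > 0.7

    def test_deficit_zero_above_abundance_threshold(self, small_library):
        _, truth = small_library
        t = truth.table
        thr = small_config().toxicity_link.abundance_threshold
        above = t.loc[t["latent_abundance"] >= thr, "growth_deficit"]
        assert (above == 0).all()


class TestFacsCounts:
    def test_bin_read_totals_exact(self, small_cfg, small_library):
        barcode_map, truth = small_library
        counts = simulate_facs_counts(truth, barcode_map, small_cfg, n_replicates=2)
        totals = counts.groupby(["replicate", "bin"])["count"].sum()
        assert (totals == small_cfg.reads_per_bin).all()

    def test_identical_latents_spread_evenly_across_bins(self):
        cfg = small_config(
            seed=6, protein_length=5, reads_per_bin=200_000,
            mode_params=__import__("vampseq.config", fromlist=["ModeParams"]).ModeParams(
                high_mean=0.5, high_sd=0.0, low_mean=0.5, low_sd=0.0
            ),
        )
        barcode_map, truth = simulate_library(cfg)
        counts = simulate_facs_counts(truth, barcode_map, cfg, n_replicates=1)
        share = counts.pivot_table(index="variant", columns="bin", values="count",
                                   aggfunc="sum", fill_value=0)
        share = share.div(share.sum(axis=0), axis=1)
        # every variant's read share is bin-independent up to sampling noise
        assert float(share.std(axis=1).max()) < 0.2 * float(share.mean().mean())

    def test_high_mode_concentrates_in_upper_bins(self, small_cfg, small_library):
        """Downstream PSI rank-tracks the latent abundance across the two modes."""
        from vampseq.abundance import psi_from_frequencies
        from vampseq.quantify import merge_and_normalize

        barcode_map, truth = small_library
        counts = simulate_facs_counts(truth, barcode_map, small_cfg, n_replicates=1)
        freq = merge_and_normalize(counts, unit="bin", merge_synonymous_into_wt=False)
        psi = psi_from_frequencies(freq).set_index("variant")["psi"]
        latent = truth.table.set_index("variant").loc[psi.index, "latent_abundance"]
        assert spearmanr(psi, latent).correlation > 0.9
        high = latent > 0.7
        assert psi[high.values].mean() > psi[(~high).values].mean() + 1.0


class TestTimecourse:
    def test_zero_deficits_give_flat_trajectories(self):
        cfg = small_config(seed=8, protein_length=10)
        cfg.toxicity_link.max_deficit = 0.0
        cfg.toxicity_link.anchor_deficit = 0.0
        barcode_map, truth = simulate_library(cfg)
        counts = simulate_timecourse(truth, barcode_map, cfg, n_replicates=1)
        wide = counts.pivot_table(index="variant", columns="day", values="count",
                                  fill_value=0)
        rel = wide.div(wide.sum(axis=0), axis=1)
        drift = (rel[9] - rel[0]).abs()
        assert float(drift.mean()) < 0.1 * float(rel[0].mean())

    def test_high_deficit_variant_depletes_by_day9(self, small_cfg, small_library):
        barcode_map, truth = small_library
        counts = simulate_timecourse(truth, barcode_map, small_cfg, n_replicates=2)
        anchor = truth.toxic_anchor
        wide = counts.loc[counts["variant"] == anchor].pivot_table(
            index="replicate", columns="day", values="count", fill_value=0
        )
        assert (wide[9] < wide[0]).all()

    def test_negative_deficit_rejected(self, small_cfg, small_library):
        barcode_map, truth = small_library
        bad = truth.table.copy()
        bad.loc[0, "growth_deficit"] = -0.1
        broken = type(truth)(bad, truth.protein_seq, truth.toxic_anchor)
        with pytest.raises(ValueError, match="non-negative"):
            simulate_timecourse(broken, barcode_map, small_cfg)

    def test_nontoxic_variants_slightly_enriched(self, small_cfg, small_library):
        """As toxic variants deplete, neutral variants gain relative frequency."""
        from vampseq.quantify import merge_and_normalize
        from vampseq.toxicity import slopes_from_frequencies

        barcode_map, truth = small_library
        counts = simulate_timecourse(truth, barcode_map, small_cfg, n_replicates=2)
        freq = merge_and_normalize(counts, unit="day")
        slopes = slopes_from_frequencies(freq, list(small_cfg.days))
        deficits = truth.deficit_of()
        merged = slopes.merge(
            deficits.rename("deficit"), left_on="variant", right_index=True
        )
        neutral = merged.loc[merged["deficit"] == 0, "alpha"]
        assert neutral.mean() > 0


class TestPredictorTracks:
    def test_zero_noise_gives_perfect_rank_coupling(self):
        cfg = small_config(seed=12, protein_length=30)
        cfg.predictor_link.spearman_ddg = -1.0
        _, truth = simulate_library(cfg)
        tracks = simulate_predictor_tracks(truth, cfg)
        merged = tracks.merge(truth.table, on="variant")
        rho = spearmanr(merged["ddg"], merged["latent_abundance"]).correlation
        assert rho == pytest.approx(-1.0, abs=0.02)

    def test_ddg_clamped_to_zero_five(self, small_cfg, small_library):
        _, truth = small_library
        tracks = simulate_predictor_tracks(truth, small_cfg)
        assert tracks["ddg"].between(0.0, 5.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_configured_spearman_target_realized(self, seed):
        """At full universe size the realized ρ sits within ±0.05 of −0.47."""
        cfg = SimulationConfig(seed=seed)
        _, truth = simulate_library(cfg)
        tracks = simulate_predictor_tracks(truth, cfg)
        merged = tracks.merge(truth.table, on="variant")
        assert len(merged) == 5947
        rho = spearmanr(merged["ddg"], merged["latent_abundance"]).correlation
        assert -0.52 <= rho <= -0.42

    def test_tracks_cover_missense_only(self, small_library, small_cfg):
        _, truth = small_library
        tracks = simulate_predictor_tracks(truth, small_cfg)
        classes = truth.table.set_index("variant")["var_class"]
        assert (classes.loc[tracks["variant"]] == "missense").all()
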