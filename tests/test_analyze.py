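"""Positional medians, variance explained, correlations and replicate statistics."""

import numpy as np
import pandas as pd
import pytest

from vampseq.analyze import (
    abundance_toxicity_strata,
    clinical_summary,
    correlate,
    per_position_median,
    replicate_stats,
    stratified_replicate_correlation,
    variance_explained,
)


def _scores(pairs):
    return pd.DataFrame(pairs, columns=["variant", "score"])


class TestPositionalMedian:
    def test_constant_position_scores(self):
        table = _scores([("A1C", 0.3), ("A1D", 0.3), ("K2R", 0.8)])
        med = per_position_median(table).set_index("position")["median_score"]
        assert med[1] == pytest.approx(0.3)
        assert med[2] == pytest.approx(0.8)

    def test_even_count_median(self):
        table = _scores([("A1C", 0.1), ("A1D", 0.9)])
        med = per_position_median(table)
        assert med["median_score"].item() == pytest.approx(0.5)

    def test_nonsense_excluded_by_default(self):
        table = _scores([("A1C", 0.9), ("A1*", 0.0)])
        med = per_position_median(table)
        assert med["median_score"].item() == pytest.approx(0.9)
        med_all = per_position_median(table, missense_only=False)
        assert med_all["median_score"].item() == pytest.approx(0.45)

    def test_position_with_no_scored_variants_absent(self):
        table = _scores([("A1C", 0.9)])
        assert 2 not in per_position_median(table)["position"].values


class TestVarianceExplained:
    def test_scores_equal_to_medians_explain_everything(self):
        table = _scores(
            [("A1C", 0.2), ("A1D", 0.2), ("K2R", 0.7), ("K2E", 0.7)]
        )
        out = variance_explained(table)
        assert out["fraction_sse"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_shuffled_scores_explain_almost_nothing(self, rng):
        variants, scores = [], []
        aas = "CDEFGHIKLMNPQRSTVWY"
        values = rng.normal(size=19 * 50)
        k = 0
        for pos in range(1, 51):
            for aa in aas:
                variants.append(f"A{pos}{aa}")
                scores.append(values[k])
                k += 1
        table = _scores(list(zip(variants, scores)))
        out = variance_explained(table)
        assert abs(out["r_squared"]) < 0.1

    def test_r_and_r_squared_consistent(self):
        table = _scores(
            [("A1C", 0.1), ("A1D", 0.3), ("K2R", 0.6), ("K2E", 1.0)]
        )
        out = variance_explained(table)
        assert out["r_squared"] == pytest.approx(out["r"] ** 2)


class TestCorrelate:
    def test_monotone_pairs(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        assert correlate(a, a * 3 + 1).coefficient == pytest.approx(1.0)
        assert correlate(a, -a).coefficient == pytest.approx(-1.0)

    def test_hand_computed_spearman(self):
        a = pd.Series([1, 2, 3], index=list("xyz"))
        b = pd.Series([2, 1, 3], index=list("xyz"))
        assert correlate(a, b).coefficient == pytest.approx(0.5)

    def test_operates_on_intersection_and_reports_n(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("wxy"))
        res = correlate(a, b)
        assert res.n == 3

    def test_bootstrap_ci_is_seed_reproducible(self, rng):
        a = pd.Series(rng.normal(size=50))
        b = a + rng.normal(size=50)
        r1 = correlate(a, b, seed=42)
        r2 = correlate(a, b, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        r3 = correlate(a, b, seed=43)
        assert (r1.ci_low, r1.ci_high) != (r3.ci_low, r3.ci_high)

    def test_too_few_pairs_rejected(self):
        a = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            correlate(a, a)


class TestClinicalSummary:
    def _annotations(self):
        return pd.DataFrame(
            {
                "variant": ["A1C", "A1D", "K2R", "K2E"],
                "label": ["pathogenic", "pathogenic", "benign", "vus"],
                "allele_frequency": [1e-5, np.nan, 1e-3, np.nan],
            }
        )

    def test_all_pathogenic_below_threshold(self):
        scores = _scores([("A1C", 0.1), ("A1D", 0.2), ("K2R", 0.9), ("K2E", 0.6)])
        out = clinical_summary(scores, self._annotations()).set_index("label")
        assert out.loc["pathogenic", "n_below_threshold"] == 2
        assert out.loc["pathogenic", "n"] == 2

    def test_threshold_is_strictly_below(self):
        scores = _scores([("A1C", 0.4), ("A1D", 0.5), ("K2R", 0.9), ("K2E", 0.6)])
        out = clinical_summary(scores, self._annotations()).set_index("label")
        assert out.loc["pathogenic", "n_below_threshold"] == 1  # 0.5 not < 0.5


class TestReplicateStats:
    def _per_rep(self, offsets):
        rows = []
        base = {"A1C": 0.1, "A1D": 0.5, "K2R": 0.9, "K2E": 0.3}
        for rep, off in enumerate(offsets, start=1):
            for v, s in base.items():
                rows.append({"replicate": rep, "variant": v, "score": s + off})
        return pd.DataFrame(rows)

    def test_identical_replicates(self):
        out = replicate_stats(self._per_rep([0.0, 0.0]))
        assert out["mean_pearson"] == pytest.approx(1.0)
        assert out["mean_absolute_error"] == pytest.approx(0.0)

    def test_affine_shift_keeps_r_but_shows_mae(self):
        out = replicate_stats(self._per_rep([0.0, 0.1]))
        assert out["mean_pearson"] == pytest.approx(1.0)
        assert out["mean_absolute_error"] == pytest.approx(0.1)

    def test_one_discordant_variant_gives_mae_delta_over_n(self):
        table = self._per_rep([0.0, 0.0])
        mask = (table["replicate"] == 2) & (table["variant"] == "A1C")
        table.loc[mask, "score"] += 0.4
        out = replicate_stats(table)
        assert out["mean_absolute_error"] == pytest.approx(0.4 / 4)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats(self._per_rep([0.0]))


class TestStratifiedCorrelation:
    def test_single_stratum_matches_overall(self, rng):
        rows = []
        for rep in (1, 2):
            for i in range(20):
                rows.append(
                    {
                        "replicate": rep,
                        "variant": f"A{i + 1}C",
                        "score": i / 20 + rng.normal(0, 0.01),
                    }
                )
        table = pd.DataFrame(rows)
        out = stratified_replicate_correlation(
            table, {"all": pd.Index(table["variant"].unique())}
        )
        assert out["mean_correlation"].item() > 0.9
        assert out["n_pairs"].item() == 1

    def test_zero_variance_stratum_flagged_not_perfect(self):
        rows = [
            {"replicate": r, "variant": v, "score": 0.5}
            for r in (1, 2)
            for v in ("A1C", "A1D", "K2R")
        ]
        out = stratified_replicate_correlation(
            pd.DataFrame(rows), {"flat": pd.Index(["A1C", "A1D", "K2R"])}
        )
        assert np.isnan(out["mean_correlation"].item())
        assert out["n_degenerate_pairs"].item() == 1

    def test_strata_thresholds(self):
        ab = _scores([("A1C", 0.1), ("A1D", 0.15), ("K2R", 0.5)])
        tox = _scores([("A1C", 0.1), ("A1D", 0.9), ("K2R", 0.9)])
        strata = abundance_toxicity_strata(ab, tox)
        assert list(strata["nontoxic_low_abundance"]) == ["A1C"]
        assert list(strata["toxic_low_abundance"]) == ["A1D"]
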