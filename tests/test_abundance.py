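"""PSI computation and anchor-normalized abundance scoring."""

import numpy as np
import pandas as pd
import pytest

from vampseq.abundance import (
    AbundanceScorer,
    aggregate_scores,
    compute_psi,
    compute_psi_stop,
    compute_psi_wt,
    normalize_abundance,
    psi_from_frequencies,
)


class TestPsi:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.5),
            ((0, 0, 0, 0.02), 4.0),
            ((0.1, 0.2, 0.3, 0.4), 3.0),
        ],
    )
    def test_weighted_mean_bin_index(self, freqs, expected):
        assert compute_psi(freqs) == pytest.approx(expected)

    def test_all_zero_frequencies_undefined(self):
        with pytest.raises(ValueError):
            compute_psi((0, 0, 0, 0))

    def test_psi_bounded_by_bin_range(self, rng):
        for _ in range(100):
            f = rng.random(4)
            assert 1.0 <= compute_psi(f) <= 4.0

    def test_matches_direct_weighted_mean_on_table(self, rng):
        rows = []
        for rep in (1, 2):
            for v in ("A1C", "A1D"):
                for g in (1, 2, 3, 4):
                    rows.append(
                        {"replicate": rep, "bin": g, "variant": v,
                         "frequency": rng.random()}
                    )
        table = pd.DataFrame(rows)
        psi = psi_from_frequencies(table).set_index(["replicate", "variant"])["psi"]
        for (rep, v), sub in table.groupby(["replicate", "variant"]):
            direct = (sub["bin"] * sub["frequency"]).sum() / sub["frequency"].sum()
            assert psi[(rep, v)] == pytest.approx(direct, abs=1e-12)


class TestStopAnchor:
    def _psi(self, rows):
        return pd.DataFrame(rows, columns=["replicate", "variant", "psi"])

    def test_constant_stop_psi_is_fixed_point(self):
        table = self._psi([(r, v, 1.7) for r in (1, 2) for v in ("K2*", "M1*")])
        assert compute_psi_stop(table) == pytest.approx(1.7)

    def test_single_replicate_median(self):
        table = self._psi([(1, "A1*", 1.0), (1, "K2*", 1.2), (1, "L3*", 2.0)])
        assert compute_psi_stop(table) == pytest.approx(1.2)

    def test_replicate_medians_averaged(self):
        table = self._psi(
            [(1, "A1*", 1.0), (1, "K2*", 1.2), (1, "L3*", 2.0),
             (2, "A1*", 1.4), (2, "K2*", 1.4), (2, "L3*", 1.4)]
        )
        assert compute_psi_stop(table) == pytest.approx((1.2 + 1.4) / 2)

    def test_no_nonsense_variants_is_an_error(self):
        with pytest.raises(ValueError, match="anchors"):
            compute_psi_stop(self._psi([(1, "A1C", 2.0)]))


class TestNormalization:
    def _psi(self, value):
        return pd.DataFrame({"replicate": [1], "variant": ["A1C"], "psi": [value]})

    def test_wt_psi_maps_to_one(self):
        out = normalize_abundance(self._psi(3.6), psi_wt=3.6, psi_stop=1.6)
        assert out["score"].item() == pytest.approx(1.0)

    def test_stop_psi_maps_to_zero(self):
        out = normalize_abundance(self._psi(1.6), psi_wt=3.6, psi_stop=1.6)
        assert out["score"].item() == pytest.approx(0.0)

    def test_midpoint_interpolates_linearly(self):
        out = normalize_abundance(self._psi(2.6), psi_wt=3.6, psi_stop=1.6)
        assert out["score"].item() == pytest.approx(0.5)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_abundance(self._psi(2.0), psi_wt=1.6, psi_stop=1.6)

    def test_scores_are_not_clamped(self):
        out = normalize_abundance(self._psi(4.0), psi_wt=3.6, psi_stop=1.6)
        assert out["score"].item() > 1.0


def _frequency_table(rng, n_variants=30, n_reps=3, bins=(1, 2, 3, 4)):
    rows = []
    variants = ["WT"] + [f"A1{a}" for a in "CDEFGHIKLMN"][: n_variants - 4]
    variants += ["K2*", "L3*", "M4*"]
    for rep in range(1, n_reps + 1):
        for v in variants:
            f = rng.dirichlet(np.ones(len(bins)))
            for g, freq in zip(bins, f):
                rows.append({"replicate": rep, "bin": g, "variant": v, "frequency": freq})
    return pd.DataFrame(rows)


class TestScorer:
    def test_wt_mean_score_is_exactly_one(self, rng):
        table = _frequency_table(rng)
        scores = AbundanceScorer().fit(table).score_table(table)
        wt = scores.set_index("variant").loc["WT"]
        assert wt["score"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_bin_relabeling_leaves_scores_unchanged(self, rng):
        """Anchor normalization cancels any affine map of the bin labels."""
        table = _frequency_table(rng)
        base = AbundanceScorer().fit(table).score_table(table)
        relabeled = table.assign(bin=3 * table["bin"] + 2)
        other = AbundanceScorer().fit(relabeled).score_table(relabeled)
        pd.testing.assert_series_equal(
            base.set_index("variant")["score"],
            other.set_index("variant")["score"],
            atol=1e-10, rtol=0,
        )

    def test_per_replicate_anchoring_pins_wt_in_every_replicate(self, rng):
        table = _frequency_table(rng)
        scorer = AbundanceScorer(per_replicate_anchors=True).fit(table)
        per_rep = scorer.transform(table)
        wt = per_rep.loc[per_rep["variant"] == "WT", "score"]
        assert np.allclose(wt, 1.0)

    def test_sd_and_replicate_count_reported(self, rng):
        table = _frequency_table(rng, n_reps=4)
        scores = AbundanceScorer().fit(table).score_table(table)
        assert (scores["n_replicates"] == 4).all()
        assert (scores["sd"] >= 0).all()

    def test_sklearn_param_interface(self):
        scorer = AbundanceScorer(per_replicate_anchors=True)
        assert scorer.get_params()["per_replicate_anchors"] is True
        scorer.set_params(psi_wt=3.5)
        assert scorer.psi_wt == 3.5


def test_aggregate_handles_variants_missing_from_some_replicates():
    per_rep = pd.DataFrame(
        {
            "replicate": [1, 2, 1],
            "variant": ["A1C", "A1C", "A1D"],
            "score": [0.4, 0.6, 0.9],
        }
    )
    agg = aggregate_scores(per_rep).set_index("variant")
    assert agg.loc["A1C", "n_replicates"] == 2
    assert agg.loc["A1C", "score"] == pytest.approx(0.5)
    assert agg.loc["A1D", "n_replicates"] == 1


def test_psi_wt_averages_over_replicates():
    table = pd.DataFrame(
        {"replicate": [1, 2], "variant": ["WT", "WT"], "psi": [3.0, 3.4]}
    )
    assert compute_psi_wt(table) == pytest.approx(3.2)
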