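"""Protein stability index (PSI) and anchored abundance scores.

For each variant and replicate the PSI is the frequency-weighted mean FACS-bin
index,

    PSI_i = Σ_g g · f_{i,g} / Σ_g f_{i,g},

with f_{i,g} the variant's frequency in bin g. Scores are then anchored so
that the wild-type amino-acid sequence scores 1 and the nonsense (premature
stop) variants score 0:

    abundance_i = (PSI_i − PSI_stop) / (PSI_WT − PSI_stop),

where PSI_stop is the per-replicate median PSI over stop variants and PSI_WT
the wild-type PSI, both averaged over replicates before the transform is
applied to every replicate. Scores are reported as the mean and standard
deviation over replicates; values below 0 or above 1 are kept (no clamping).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variants import parse_variant


def compute_psi(frequencies: Sequence[float], bins: Optional[Sequence[int]] = None) -> float:
    """Weighted-mean bin index of one variant in one replicate."""
    f = np.asarray(frequencies, dtype=float)
    if bins is None:
        g = np.arange(1, len(f) + 1, dtype=float)
    else:
        g = np.asarray(bins, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("PSI undefined: variant has no reads in any bin")
    return float((g * f).sum() / total)


def psi_from_frequencies(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(replicate, variant) PSI from a tidy frequency table.

    Expects columns ``replicate``, ``bin``, ``variant``, ``frequency``; rows
    with zero frequency contribute nothing, and variants absent from a
    replicate are absent from the output.
    """
    df = freq_table.loc[freq_table["frequency"] > 0]
    grouped = df.assign(weighted=df["bin"] * df["frequency"]).groupby(
        ["replicate", "variant"], as_index=False, sort=True
    )[["weighted", "frequency"]].sum()
    grouped["psi"] = grouped["weighted"] / grouped["frequency"]
    return grouped[["replicate", "variant", "psi"]]


def _classes(series: pd.Series) -> pd.Series:
    lookup = {v: parse_variant(v).var_class for v in series.unique()}
    return series.map(lookup)


def compute_psi_stop(psi_table: pd.DataFrame) -> float:
    """Stop anchor: per-replicate median over nonsense PSIs, averaged over replicates."""
    classes = _classes(psi_table["variant"])
    stops = psi_table.loc[classes == "nonsense"]
    if stops.empty:
        raise ValueError(
            "no nonsense variants scored; supply explicit anchors instead"
        )
    return float(stops.groupby("replicate")["psi"].median().mean())


def compute_psi_wt(psi_table: pd.DataFrame, wt_variant: str = "WT") -> float:
    wt = psi_table.loc[psi_table["variant"] == wt_variant, ["replicate", "psi"]]
    if wt.empty:
        raise ValueError("wild-type entry absent from PSI table")
    return float(wt["psi"].mean())


def normalize_abundance(
    psi_table: pd.DataFrame, psi_wt: float, psi_stop: float
) -> pd.DataFrame:
    """Anchor per-replicate PSIs to the WT=1 / stop=0 scale."""
    if psi_wt == psi_stop:
        raise ValueError("degenerate anchors: PSI_WT equals PSI_stop")
    out = psi_table.copy()
    out["score"] = (out["psi"] - psi_stop) / (psi_wt - psi_stop)
    return out


def aggregate_scores(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (over replicates) and replicate count per variant."""
    agg = per_replicate.groupby("variant", sort=True)["score"].agg(
        score="mean", sd="std", n_replicates="count"
    )
    return agg.reset_index()


class AbundanceScorer(BaseEstimator, TransformerMixin):
    """Anchor-normalized abundance scoring as a transformer.

    ``fit`` learns the WT and stop PSI anchors from a tidy frequency table
    (columns ``replicate``, ``bin``, ``variant``, ``frequency``); ``transform``
    maps PSIs of the same — or any other — table onto the anchored scale.

    Parameters
    ----------
    per_replicate_anchors : bool
        If True, anchor each replicate with its own WT/stop PSI values instead
        of the replicate-averaged anchors.
    psi_wt, psi_stop : float, optional
        Explicit anchors overriding the data-derived ones (useful when no
        nonsense variants are present).

    Attributes
    ----------
    psi_wt_, psi_stop_ : float
        Fitted anchors (replicate-averaged).
    psi_table_ : DataFrame
        Per-(replicate, variant) PSIs seen during fit.
    """

    def __init__(
        self,
        per_replicate_anchors: bool = False,
        psi_wt: Optional[float] = None,
        psi_stop: Optional[float] = None,
        wt_variant: str = "WT",
    ):
        self.per_replicate_anchors = per_replicate_anchors
        self.psi_wt = psi_wt
        self.psi_stop = psi_stop
        self.wt_variant = wt_variant

    def fit(self, X: pd.DataFrame, y=None) -> "AbundanceScorer":
        psi = psi_from_frequencies(X)
        self.psi_table_ = psi
        self.psi_wt_ = (
            self.psi_wt if self.psi_wt is not None
            else compute_psi_wt(psi, self.wt_variant)
        )
        self.psi_stop_ = (
            self.psi_stop if self.psi_stop is not None else compute_psi_stop(psi)
        )
        if self.psi_wt_ == self.psi_stop_:
            raise ValueError("degenerate anchors: PSI_WT equals PSI_stop")
        if self.per_replicate_anchors:
            classes = _classes(psi["variant"])
            stop_by_rep = (
                psi.loc[classes == "nonsense"].groupby("replicate")["psi"].median()
            )
            wt_by_rep = (
                psi.loc[psi["variant"] == self.wt_variant]
                .set_index("replicate")["psi"]
            )
            self.anchors_by_replicate_ = pd.DataFrame(
                {"psi_wt": wt_by_rep, "psi_stop": stop_by_rep}
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-replicate anchored scores for a tidy frequency table."""
        psi = psi_from_frequencies(X)
        if self.per_replicate_anchors:
            merged = psi.merge(
                self.anchors_by_replicate_, left_on="replicate", right_index=True
            )
            merged["score"] = (merged["psi"] - merged["psi_stop"]) / (
                merged["psi_wt"] - merged["psi_stop"]
            )
            return merged[["replicate", "variant", "psi", "score"]]
        return normalize_abundance(psi, self.psi_wt_, self.psi_stop_)

    def score_table(self, X: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Aggregated per-variant scores (mean, SD, replicate count)."""
        if X is None:
            per_rep = normalize_abundance(
                self.psi_table_, self.psi_wt_, self.psi_stop_
            ) if not self.per_replicate_anchors else self.transform_fitted_()
        else:
            per_rep = self.transform(X)
        return aggregate_scores(per_rep)

    def transform_fitted_(self) -> pd.DataFrame:
        psi = self.psi_table_
        merged = psi.merge(
            self.anchors_by_replicate_, left_on="replicate", right_index=True
        )
        merged["score"] = (merged["psi"] - merged["psi_stop"]) / (
            merged["psi_wt"] - merged["psi_stop"]
        )
        return merged[["replicate", "variant", "psi", "score"]]


def score_abundance(
    freq_table: pd.DataFrame,
    per_replicate_anchors: bool = False,
    psi_wt: Optional[float] = None,
    psi_stop: Optional[float] = None,
) -> pd.DataFrame:
    """One-call abundance scoring: frequencies in, aggregated scores out."""
    scorer = AbundanceScorer(
        per_replicate_anchors=per_replicate_anchors,
        psi_wt=psi_wt,
        psi_stop=psi_stop,
    )
    scorer.fit(freq_table)
    return scorer.score_table(freq_table)
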