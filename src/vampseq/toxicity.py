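"""Slope-based toxicity scores from competitive-growth time courses.

A variant's frequency trajectory f_{i,t} over culture days is first
normalized like a distribution over time points (each value divided by the
trajectory's sum — the sequenced pools contain the same number of cells, so
no further normalization is applied), then summarized by the slope α_i of an
ordinary least-squares fit against day. Weighted least squares is deliberately
avoided: the Poisson uncertainty of a frequency is correlated with the
frequency itself, so weighting would systematically discount the late, low
time points of exactly the toxic variants. Days with zero observed count
enter as zeros (no pseudocounts). The slope is anchored so the neutral
reference (wild type) scores 0 and a designated toxic reference scores 1:

    toxicity_i = (α_i − α_WT) / (α_toxic − α_WT).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .abundance import aggregate_scores


def normalize_trajectory(frequencies: Sequence[float]) -> np.ndarray:
    """Scale a frequency trajectory to sum to one over days."""
    f = np.asarray(frequencies, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("trajectory has zero total frequency; variant unscored")
    return f / total


def fit_slope(trajectory: Sequence[float], days: Sequence[float] = (0, 5, 7, 9)) -> float:
    """Ordinary (unweighted) least-squares slope of trajectory against day."""
    y = np.asarray(trajectory, dtype=float)
    t = np.asarray(days, dtype=float)
    if y.shape != t.shape:
        raise ValueError("trajectory and days must have equal length")
    if len(np.unique(t)) < 2:
        raise ValueError("slope undefined with fewer than two distinct days")
    t_c = t - t.mean()
    return float((t_c * (y - y.mean())).sum() / (t_c * t_c).sum())


def slopes_from_frequencies(
    freq_table: pd.DataFrame, days: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Per-(replicate, variant) OLS slopes of time-normalized frequencies.

    Expects tidy columns ``replicate``, ``day``, ``variant``, ``frequency``.
    Days at which a variant has no row count as frequency zero; variants with
    zero frequency at every day are left unscored in that replicate.
    """
    if days is None:
        days = sorted(freq_table["day"].unique())
    days = np.asarray(days, dtype=float)
    wide = freq_table.pivot_table(
        index=["replicate", "variant"],
        columns="day",
        values="frequency",
        fill_value=0.0,
        aggfunc="sum",
    ).reindex(columns=days, fill_value=0.0)
    values = wide.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    keep = totals > 0
    norm = values[keep] / totals[keep, None]
    t_c = days - days.mean()
    denom = (t_c * t_c).sum()
    alphas = (norm - norm.mean(axis=1, keepdims=True)) @ t_c / denom
    out = wide.index.to_frame(index=False).loc[keep].reset_index(drop=True)
    out["alpha"] = alphas
    return out


def normalize_toxicity(
    slope_table: pd.DataFrame, alpha_wt: float, alpha_toxic: float
) -> pd.DataFrame:
    if alpha_wt == alpha_toxic:
        raise ValueError("degenerate anchors: neutral and toxic slopes coincide")
    out = slope_table.copy()
    out["score"] = (out["alpha"] - alpha_wt) / (alpha_toxic - alpha_wt)
    return out


class ToxicityScorer(BaseEstimator, TransformerMixin):
    """Anchored toxicity scoring as a transformer.

    ``fit`` computes per-replicate slopes from a tidy time-course frequency
    table and learns the anchor slopes; ``transform`` maps slopes onto the
    0 (neutral) … 1 (toxic reference) scale. Anchoring is per replicate by
    default, so the anchor variants score exactly 0 and 1 in every replicate.

    Parameters
    ----------
    wt_anchor, toxic_anchor : str
        Variant strings of the neutral and toxic reference variants.
    days : sequence of int, optional
        Time points to fit; defaults to the days present in the data.
    per_replicate_anchors : bool
        Anchor each replicate with its own reference slopes (default) or with
        replicate-averaged slopes.
    """

    def __init__(
        self,
        wt_anchor: str = "WT",
        toxic_anchor: str = "C152W",
        days: Optional[Sequence[int]] = None,
        per_replicate_anchors: bool = True,
    ):
        self.wt_anchor = wt_anchor
        self.toxic_anchor = toxic_anchor
        self.days = days
        self.per_replicate_anchors = per_replicate_anchors

    def fit(self, X: pd.DataFrame, y=None) -> "ToxicityScorer":
        slopes = slopes_from_frequencies(X, self.days)
        self.slope_table_ = slopes
        for name in (self.wt_anchor, self.toxic_anchor):
            if name not in set(slopes["variant"]):
                raise ValueError(f"anchor variant {name!r} has no scored slope")
        wt = slopes.loc[slopes["variant"] == self.wt_anchor].set_index("replicate")["alpha"]
        tox = slopes.loc[slopes["variant"] == self.toxic_anchor].set_index("replicate")["alpha"]
        self.anchors_by_replicate_ = pd.DataFrame({"alpha_wt": wt, "alpha_toxic": tox})
        self.alpha_wt_ = float(wt.mean())
        self.alpha_toxic_ = float(tox.mean())
        if self.alpha_wt_ == self.alpha_toxic_:
            raise ValueError("degenerate anchors: neutral and toxic slopes coincide")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        slopes = slopes_from_frequencies(X, self.days)
        return self._normalize(slopes)

    def _normalize(self, slopes: pd.DataFrame) -> pd.DataFrame:
        if self.per_replicate_anchors:
            merged = slopes.merge(
                self.anchors_by_replicate_, left_on="replicate", right_index=True
            )
            merged["score"] = (merged["alpha"] - merged["alpha_wt"]) / (
                merged["alpha_toxic"] - merged["alpha_wt"]
            )
            return merged[["replicate", "variant", "alpha", "score"]]
        return normalize_toxicity(slopes, self.alpha_wt_, self.alpha_toxic_)

    def score_table(self, X: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        per_rep = self._normalize(self.slope_table_) if X is None else self.transform(X)
        return aggregate_scores(per_rep)


def score_toxicity(
    freq_table: pd.DataFrame,
    wt_anchor: str = "WT",
    toxic_anchor: str = "C152W",
    days: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """One-call toxicity scoring: time-course frequencies in, scores out."""
    scorer = ToxicityScorer(wt_anchor=wt_anchor, toxic_anchor=toxic_anchor, days=days)
    scorer.fit(freq_table)
    return scorer.score_table()
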