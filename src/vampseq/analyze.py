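"""Downstream analytics over variant score tables.

Per-position medians, the fraction of score variance explained by position,
score–predictor correlations with bootstrap confidence intervals, comparisons
against clinical annotations, and replicate-agreement statistics. All
operations work on the intersection of defined values and report the number
of observations used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import parse_variant


def _positions_and_classes(variants: pd.Series) -> pd.DataFrame:
    parsed = {v: parse_variant(v) for v in variants.unique()}
    return pd.DataFrame(
        {
            "position": variants.map(lambda v: parsed[v].position),
            "var_class": variants.map(lambda v: parsed[v].var_class),
        }
    )


def per_position_median(
    score_table: pd.DataFrame, missense_only: bool = True
) -> pd.DataFrame:
    """Median score per residue position.

    By default only missense variants enter the positional median (the stop
    row of a variant-effect map is anchored near zero by construction and
    would otherwise drag every position down).
    """
    info = _positions_and_classes(score_table["variant"])
    df = score_table.assign(
        position=info["position"].values, var_class=info["var_class"].values
    )
    df = df.loc[df["position"] > 0]
    if missense_only:
        df = df.loc[df["var_class"] == "missense"]
    med = df.groupby("position", as_index=False)["score"].median()
    return med.rename(columns={"score": "median_score"})


def variance_explained(
    score_table: pd.DataFrame, missense_only: bool = True
) -> Dict[str, float]:
    """How much of the variant-score variance the positional medians capture.

    Returns both common estimators: the squared Pearson correlation between
    each variant's score and its position's median (``r_squared``, with ``r``
    alongside), and the regression-style ``1 − SSE/SST`` using the medians as
    point predictions. The two coincide only when the medians are an exact
    linear fit.
    """
    info = _positions_and_classes(score_table["variant"])
    df = score_table.assign(
        position=info["position"].values, var_class=info["var_class"].values
    )
    df = df.loc[df["position"] > 0]
    if missense_only:
        df = df.loc[df["var_class"] == "missense"]
    med = df.groupby("position")["score"].transform("median")
    mask = df["score"].notna() & med.notna()
    y = df.loc[mask, "score"].to_numpy(float)
    yhat = med.loc[mask].to_numpy(float)
    if len(np.unique(df.loc[mask, "position"])) < 2:
        raise ValueError("variance explained needs at least two positions")
    r = float(stats.pearsonr(y, yhat).statistic)
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return {
        "r": r,
        "r_squared": r * r,
        "fraction_sse": 1.0 - sse / sst,
        "n": int(mask.sum()),
    }


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self) -> Dict[str, float]:
        return {
            "method": self.method,
            "coefficient": self.coefficient,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
        }


def correlate(
    scores_a: pd.Series,
    scores_b: pd.Series,
    method: str = "spearman",
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation over shared defined values, with a percentile bootstrap CI.

    ``scores_a`` and ``scores_b`` are aligned on their indices (variant
    strings); rows missing from either side are dropped.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    joined = pd.concat({"a": scores_a, "b": scores_b}, axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    a = joined["a"].to_numpy(float)
    b = joined["b"].to_numpy(float)
    fn: Callable = stats.spearmanr if method == "spearman" else stats.pearsonr
    coef = float(fn(a, b).statistic if method == "pearson" else fn(a, b).correlation)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty(n_boot)
    import warnings

    with warnings.catch_warnings():
        # tiny resamples can be constant; those draws become NaN and are
        # ignored by the percentile step
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for k in range(n_boot):
            i = idx[k]
            if method == "pearson":
                boots[k] = stats.pearsonr(a[i], b[i]).statistic
            else:
                boots[k] = stats.spearmanr(a[i], b[i]).correlation
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CorrelationResult(method, coef, float(lo), float(hi), n)


def clinical_summary(
    score_table: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score distributions per clinical class, with a below-threshold count.

    ``annotations`` carries columns ``variant``, ``label`` (pathogenic /
    benign / vus) and optionally ``allele_frequency``. The below-threshold
    rule is strict (< threshold). Quartiles follow the usual box-plot
    convention.
    """
    merged = annotations.merge(score_table[["variant", "score"]], on="variant")
    rows = []
    for label, sub in merged.groupby("label"):
        s = sub["score"].dropna()
        q1, q2, q3 = s.quantile([0.25, 0.5, 0.75]) if len(s) else (np.nan,) * 3
        iqr = q3 - q1
        rows.append(
            {
                "label": label,
                "n": int(len(s)),
                "n_below_threshold": int((s < threshold).sum()),
                "median": float(q2) if len(s) else np.nan,
                "q1": float(q1) if len(s) else np.nan,
                "q3": float(q3) if len(s) else np.nan,
                "n_outliers": int(
                    ((s < q1 - 1.5 * iqr) | (s > q3 + 1.5 * iqr)).sum()
                ) if len(s) else 0,
            }
        )
    return pd.DataFrame(rows)


def _replicate_matrix(per_replicate: pd.DataFrame, value: str = "score") -> pd.DataFrame:
    return per_replicate.pivot_table(
        index="variant", columns="replicate", values=value, aggfunc="mean"
    )


def replicate_stats(per_replicate: pd.DataFrame, value: str = "score") -> Dict[str, float]:
    """Mean pairwise Pearson correlation and mean absolute error over replicates.

    Each replicate pair is compared on the variants scored in both members.
    """
    mat = _replicate_matrix(per_replicate, value)
    reps = list(mat.columns)
    if len(reps) < 2:
        raise ValueError("replicate statistics need at least two replicates")
    rs, maes = [], []
    for r1, r2 in combinations(reps, 2):
        pair = mat[[r1, r2]].dropna()
        if len(pair) < 3:
            continue
        rs.append(stats.pearsonr(pair[r1], pair[r2]).statistic)
        maes.append((pair[r1] - pair[r2]).abs().mean())
    if not rs:
        raise ValueError("no replicate pair shares enough scored variants")
    return {
        "mean_pearson": float(np.mean(rs)),
        "mean_absolute_error": float(np.mean(maes)),
        "n_pairs": len(rs),
    }


def stratified_replicate_correlation(
    per_replicate: pd.DataFrame,
    strata: Dict[str, pd.Index],
    method: str = "spearman",
) -> pd.DataFrame:
    """Mean pairwise replicate correlation within named variant strata.

    ``strata`` maps stratum name → variant index. Replicate pairs with zero
    variance in a stratum are flagged (NaN with ``n_degenerate_pairs``
    counted), never silently reported as perfect correlation.
    """
    mat = _replicate_matrix(per_replicate)
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for name, variants in strata.items():
        sub = mat.loc[mat.index.intersection(variants)]
        coefs, degenerate = [], 0
        for r1, r2 in combinations(sub.columns, 2):
            pair = sub[[r1, r2]].dropna()
            if len(pair) < 3:
                continue
            if pair[r1].nunique() < 2 or pair[r2].nunique() < 2:
                degenerate += 1
                continue
            res = fn(pair[r1], pair[r2])
            coefs.append(res.correlation if method == "spearman" else res.statistic)
        rows.append(
            {
                "stratum": name,
                "n_variants": int(len(sub)),
                "mean_correlation": float(np.mean(coefs)) if coefs else np.nan,
                "n_pairs": len(coefs),
                "n_degenerate_pairs": degenerate,
            }
        )
    return pd.DataFrame(rows)


def abundance_toxicity_strata(
    abundance_scores: pd.DataFrame,
    toxicity_scores: pd.DataFrame,
    abundance_cut: float = 0.2,
    nontoxic_cut: float = 0.4,
    toxic_cut: float = 0.6,
) -> Dict[str, pd.Index]:
    """Low-abundance variants split into non-toxic and toxic strata.

    Mirrors the stratification used to show that toxicity degrades the
    replicate agreement of low-abundance scores: non-toxic means toxicity
    score below ``nontoxic_cut``, toxic means above ``toxic_cut``, both within
    abundance score below ``abundance_cut``.
    """
    ab = abundance_scores.set_index("variant")["score"]
    tox = toxicity_scores.set_index("variant")["score"]
    common = ab.index.intersection(tox.index)
    ab, tox = ab.loc[common], tox.loc[common]
    low = ab < abundance_cut
    return {
        "nontoxic_low_abundance": ab.index[low & (tox < nontoxic_cut)],
        "toxic_low_abundance": ab.index[low & (tox > toxic_cut)],
    }
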