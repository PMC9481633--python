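"""Cross-validation of synthesized use estimates against an independent survey.

The independent survey reports, per state-crop-year-compound, total kg
applied, the application rate on *treated* acres, and the percent of area
treated.  Its rate is not directly comparable to a whole-area kg/ha
estimate, so two reconstructions bridge the gap: Method 1 divides the
survey's total kg by the harmonized crop area, and Method 2 multiplies
the rate on treated acres by the treated fraction (with the acre ->
hectare conversion applied once).  Agreement is summarized per pesticide
category by the relative percent difference

    RD = (a - b) / ((a + b) / 2) * 100,    RD in [-200, 200],

its median and quartiles, a two-sided one-sample Wilcoxon signed-rank
test of median RD = 0, and Spearman / Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from beeload.area import HA_PER_ACRE

logger = logging.getLogger(__name__)

#: n at or below which the signed-rank test uses the exact distribution.
WILCOXON_EXACT_MAX_N = 25

COMPARISON_COLUMNS = [
    "state",
    "crop",
    "year",
    "compound",
    "category",
    "est_a",
    "est_b",
]


class ValidationError(ValueError):
    pass


def relative_difference(a, b):
    """Relative percent difference (a - b) / mean(a, b) * 100.

    Antisymmetric and bounded in [-200, 200] for nonnegative inputs.
    Undefined when a = b = 0 (NaN; callers exclude and count these).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rd = (a - b) / ((a + b) / 2.0) * 100.0
    rd = np.where((a == 0) & (b == 0), np.nan, rd)
    return float(rd) if rd.ndim == 0 else rd


def method1_rate(reference_kg, hectares):
    """Reference whole-area rate: survey total kg / harmonized crop area (ha)."""
    kg = np.asarray(reference_kg, dtype=float)
    ha = np.asarray(hectares, dtype=float)
    if np.any(ha <= 0):
        raise ValidationError("hectares must be positive for Method 1")
    out = kg / ha
    return float(out) if out.ndim == 0 else out


def method2_rate(rate_on_treated_kg_per_acre, pct_treated):
    """Reference rate from rate-on-treated-acres x treated fraction, in kg/ha.

    The survey rate is kg per treated *acre*; the result is converted to
    per-hectare once, after down-weighting by the treated fraction.
    """
    rate = np.asarray(rate_on_treated_kg_per_acre, dtype=float)
    pct = np.asarray(pct_treated, dtype=float)
    if np.any(pct > 100) or np.any(pct < 0):
        raise ValidationError("percent treated must lie in [0, 100]")
    out = rate * (pct / 100.0) / HA_PER_ACRE
    return float(out) if out.ndim == 0 else out


def _signed_rank_p(values: np.ndarray) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p for median = 0.

    Zero differences are dropped; exact distribution for small n, normal
    approximation with continuity correction otherwise.
    """
    nonzero = values[values != 0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= WILCOXON_EXACT_MAX_N else "approx"
    try:
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", correction=True, method=method
        )
    except ValueError:
        res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True, method="approx")
    return float(res.pvalue)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Tie-free data uses the classical rank-difference form
    1 - 6 sum(d^2) / (n (n^2 - 1)), which is exact (1.0, not 1 - ulp) for
    perfectly concordant rankings; tied data falls back to the Pearson
    correlation of the average ranks.
    """
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = ra.size
    if np.unique(ra).size == n and np.unique(rb).size == n:
        d = ra - rb
        return float(1.0 - 6.0 * float(d @ d) / (n * (n * n - 1)))
    return float(stats.pearsonr(ra, rb).statistic)


@dataclass
class CategorySummary:
    """Agreement summary for one pesticide category and comparison type."""

    category: str
    comparison: str
    n: int
    n_undefined: int
    median_rd: float
    q25_rd: float
    q75_rd: float
    wilcoxon_p: float
    spearman_rho: float
    pearson_r: float
    insufficient: bool


def compare_category(
    records: pd.DataFrame,
    exclusions: Sequence[tuple[str, str]] | None = None,
    comparison: str = "kg_applied",
) -> pd.DataFrame:
    """Per-category agreement between paired estimates.

    Parameters
    ----------
    records:
        Columns state, crop, year, compound, category, est_a (pipeline
        estimate), est_b (reference estimate), same units within a pair.
    exclusions:
        (compound, crop) pairs removed before computation (e.g. known
        outliers), logged.

    Categories with fewer than 3 usable pairs are marked ``insufficient``
    with NaN statistics.
    """
    df = records.copy()
    if exclusions:
        mask = pd.Series(False, index=df.index)
        for compound, crop in exclusions:
            mask |= (df["compound"] == compound) & (df["crop"] == crop)
        logger.info("excluding %d record(s) for %s", int(mask.sum()), list(exclusions))
        df = df[~mask]

    rows = []
    for category, grp in df.groupby("category", sort=True):
        rd = relative_difference(grp["est_a"].to_numpy(), grp["est_b"].to_numpy())
        undefined = np.isnan(rd)
        n_undefined = int(undefined.sum())
        if n_undefined:
            logger.info(
                "%s/%s: excluded %d pair(s) with both estimates zero",
                category,
                comparison,
                n_undefined,
            )
        rd = rd[~undefined]
        a = grp["est_a"].to_numpy()[~undefined]
        b = grp["est_b"].to_numpy()[~undefined]
        n = rd.size
        if n < 3:
            rows.append(
                CategorySummary(
                    category, comparison, n, n_undefined,
                    *(float("nan"),) * 6, insufficient=True,
                )
            )
            continue
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            spearman = pearson = float("nan")  # correlation undefined, constant column
        else:
            spearman = _spearman(a, b)
            # identical columns correlate exactly; avoids last-ulp rounding
            pearson = 1.0 if np.array_equal(a, b) else float(stats.pearsonr(a, b).statistic)
        rows.append(
            CategorySummary(
                category=category,
                comparison=comparison,
                n=int(n),
                n_undefined=n_undefined,
                median_rd=float(np.median(rd)),
                q25_rd=float(np.percentile(rd, 25)),
                q75_rd=float(np.percentile(rd, 75)),
                wilcoxon_p=_signed_rank_p(rd),
                spearman_rho=spearman,
                pearson_r=pearson,
                insufficient=False,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def treated_fraction_trend(
    records: pd.DataFrame,
    bins: Sequence[float] = (0, 20, 40, 60, 80, 100),
) -> tuple[pd.DataFrame, float]:
    """Absolute relative difference versus percent of area treated.

    Summarizes |RD| in bins of percent treated and returns the Spearman
    rank correlation of |RD| with percent treated as a monotone-trend
    statistic (negative when agreement improves with wider use).
    """
    if "pct_area_treated" not in records:
        raise ValidationError("records lack pct_area_treated")
    df = records.dropna(subset=["pct_area_treated"]).copy()
    rd = relative_difference(df["est_a"].to_numpy(), df["est_b"].to_numpy())
    keep = ~np.isnan(rd)
    df = df[keep]
    abs_rd = np.abs(rd[keep])
    df["abs_rd"] = abs_rd
    df["bin"] = pd.cut(df["pct_area_treated"], bins=list(bins), include_lowest=True)
    summary = (
        df.groupby("bin", observed=False)["abs_rd"]
        .agg(n="size", median_abs_rd="median")
        .reset_index()
    )
    if df["pct_area_treated"].nunique() > 1 and len(df) >= 3:
        trend = float(stats.spearmanr(df["abs_rd"], df["pct_area_treated"]).statistic)
    else:
        trend = float("nan")
    return summary, trend
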