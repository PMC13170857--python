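"""Simpson diversity, its diachronic trends, and between-slice tests.

Simpson's index D = 1 − Σ p_i² is the probability that two specimens
drawn at random from an assemblage belong to different categories; it is
bounded by 1 − 1/S for S categories and equals 0 for a monoculture. We
compute it per site at three taxonomic levels (species group, family,
class) on both count bases (NISP, MNI), regress family-level on
class-level diversity to expose assemblages dominated by a single family
despite a broad class spectrum, smooth diversity through time with
LOESS, and compare chronological slices with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
import statsmodels.api as sm

from .assemblage import AssemblageTable, aggregate_counts, apply_fish_mni_convention
from .chronology import ChronoGrouping, assign_time_slice, bp_to_bce

__all__ = [
    "simpson_index",
    "diversity_profile",
    "RegressionFit",
    "fit_family_class_regression",
    "loess_trend",
    "TestResult",
    "welch_ttest",
    "levene_test",
]

LEVELS = ("group", "family", "class")
BASES = ("NISP", "MNI")


def simpson_index(counts) -> float:
    """Simpson's diversity D = 1 − Σ (count_i / total)².

    Higher values indicate higher diversity; the index is invariant to
    scaling every count by the same factor.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Simpson index undefined for an all-zero vector")
    p = c / total
    return float(1.0 - np.sum(p * p))


def diversity_profile(
    table: AssemblageTable,
    chrono: ChronoGrouping | None = None,
    *,
    median_unit: str = "BCE",
) -> pd.DataFrame:
    """Per-site Simpson D at every (level, basis) combination.

    One row per (site_id, level, basis) with columns D, S (nonzero
    categories), total, median_cal and slice. The MNI basis applies the
    fish-MNI=1 convention first, which mechanically favours terrestrial
    fauna — a known property of the basis, not a bug. Sites missing from
    ``chrono`` get NaN medians and slice "unplaced" (flagged, kept).
    """
    mni_table = apply_fish_mni_convention(table)
    rows = []
    for level in LEVELS:
        for basis in BASES:
            src = mni_table if basis == "MNI" else table
            cm = aggregate_counts(src, level, basis)
            for site in cm.values.index:
                vec = cm.values.loc[site].to_numpy(dtype=float)
                total = vec.sum()
                if total <= 0:
                    continue
                if chrono is not None and site in chrono.site_medians:
                    med = chrono.site_medians[site]
                    med_bce = bp_to_bce(med) if median_unit.upper() == "BP" else med
                    sl = assign_time_slice(med_bce)
                else:
                    med_bce, sl = float("nan"), "unplaced"
                rows.append(
                    {
                        "site_id": site,
                        "level": level,
                        "basis": basis,
                        "D": simpson_index(vec),
                        "S": int((vec > 0).sum()),
                        "total": int(total),
                        "median_bce": med_bce,
                        "slice": sl,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    """OLS of family-level D on class-level D with a 95% mean-response band."""

    slope: float
    intercept: float
    resid_var: float
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    outside: np.ndarray  # True where the observed point leaves the band
    sites: list[str]


def fit_family_class_regression(div: pd.DataFrame, basis: str = "NISP") -> RegressionFit:
    """Regress family-level on class-level Simpson D across sites.

    Sites outside the pointwise 95% confidence band for the mean response
    show an imbalance between the family and class spectra — e.g. many
    classes present but one family dominating.
    """
    sub = div[div["basis"] == basis.upper()]
    fam = sub[sub["level"] == "family"].set_index("site_id")["D"]
    cls = sub[sub["level"] == "class"].set_index("site_id")["D"]
    sites = [s for s in fam.index if s in cls.index]
    if len(sites) < 3:
        raise ValueError("need ≥3 sites with both family- and class-level D")
    x = cls.loc[sites].to_numpy(dtype=float)
    y = fam.loc[sites].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: class-level D has zero variance")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    ci_low = pred["mean_ci_lower"].to_numpy()
    ci_high = pred["mean_ci_upper"].to_numpy()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        resid_var=float(fit.mse_resid) if fit.df_resid > 0 else 0.0,
        x=x,
        y=y,
        fitted=pred["mean"].to_numpy(),
        ci_low=ci_low,
        ci_high=ci_high,
        outside=(y < ci_low - 1e-12) | (y > ci_high + 1e-12),
        sites=sites,
    )


def loess_trend(x, y, span: float = 0.75):
    """LOESS smooth of diversity against time, evaluated at the input x.

    Degree-1 local fits with tricube weights and no robustness iterations;
    ``span`` is the fraction of points in each local window. Returns the
    smoothed values aligned with ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("loess_trend needs at least 5 points")
    if int(np.ceil(span * len(x))) < 2:
        raise ValueError(f"span={span} leaves fewer than 2 points per local fit")
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    return fitted


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    group_summaries: dict


def welch_ttest(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    The paper-style slice comparisons never guarantee equal variances
    across chronological groups, so Welch is the default; pair with
    :func:`levene_test` if a variance diagnostic is wanted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n ≥ 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_summaries={
            "a": {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
            "b": {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        },
    )


def student_ttest(a, b) -> TestResult:
    """Classical equal-variance two-sample t-test (option, not default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n ≥ 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(a) + len(b) - 2),
        p_value=float(res.pvalue),
        group_summaries={
            "a": {"n": len(a), "mean": float(a.mean())},
            "b": {"n": len(b), "mean": float(b.mean())},
        },
    )


def levene_test(a, b, center: str = "median") -> TestResult:
    """Brown–Forsythe/Levene variance-homogeneity diagnostic."""
    stat, p = stats.levene(np.asarray(a, float), np.asarray(b, float), center=center)
    return TestResult(statistic=float(stat), df=float(len(a) + len(b) - 2), p_value=float(p), group_summaries={})
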