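"""Group-level statistics: effect sizes, site comparisons, apnea analyses.

Sign convention for Cohen's d follows the study's figures: *positive* d
means the TBI group has *lower* values than sham (d = (mean_sham -
mean_TBI) / s_pooled), so demyelination-like FA drops appear positive and
diffusivity increases appear negative.

Site differences in apnea are assessed with a Kruskal-Wallis test followed
by pairwise rank-sum tests with Bonferroni correction; apnea-metric
relationships with Spearman correlation and Benjamini-Hochberg FDR across
the submitted family; apnea-stratified group differences with one-way ANOVA
plus Tukey's HSD.  A fixed-effects linear model of metric on site + group
quantifies how much site signal harmonization leaves behind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectSizeResult",
    "StratifiedGroups",
    "cohens_d",
    "kruskal_wallis_posthoc",
    "spearman_fdr",
    "stratify_median",
    "anova_tukey",
    "site_effect_check",
]


@dataclass
class EffectSizeResult:
    d: float
    mean_sham: float
    mean_tbi: float
    sd_sham: float
    sd_tbi: float
    n_sham: int
    n_tbi: int
    bundle: str = ""
    metric: str = ""
    timepoint: str = ""


def cohens_d(
    sham: np.ndarray, tbi: np.ndarray, bundle: str = "", metric: str = "",
    timepoint: str = "",
) -> EffectSizeResult:
    """Pooled-SD Cohen's d, positive when TBI is lower than sham."""
    sham = np.asarray(sham, float)
    tbi = np.asarray(tbi, float)
    sham, tbi = sham[np.isfinite(sham)], tbi[np.isfinite(tbi)]
    n1, n2 = sham.size, tbi.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s1, s2 = sham.std(ddof=1), tbi.std(ddof=1)
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    d = (sham.mean() - tbi.mean()) / sp
    return EffectSizeResult(
        d=float(d), mean_sham=float(sham.mean()), mean_tbi=float(tbi.mean()),
        sd_sham=float(s1), sd_tbi=float(s2), n_sham=n1, n_tbi=n2,
        bundle=bundle, metric=metric, timepoint=timepoint,
    )


def kruskal_wallis_posthoc(groups: dict[str, np.ndarray]) -> dict:
    """Tie-corrected Kruskal-Wallis H with pairwise Bonferroni post hoc.

    Post hoc comparisons are two-sided Mann-Whitney rank-sum tests whose
    p-values are multiplied by the number of pairs (capped at 1).  All
    values identical gives H = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*arrays)
    pairs = {}
    n_pairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            if np.all(np.concatenate([a, b]) == a[0]):
                praw = 1.0
            else:
                praw = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            pairs[(names[i], names[j])] = {
                "p_raw": praw,
                "p_bonferroni": min(1.0, praw * n_pairs),
            }
    return {"H": float(H), "p": float(p), "pairs": pairs}


def spearman_fdr(analyses: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Spearman rho per analysis with BH adjustment across the family.

    Each entry maps an analysis label to an (apnea, metric) pair of equal-
    length series (n >= 5).  Ties get average ranks; p-values use the
    t approximation; adjusted p-values are Benjamini-Hochberg step-up.
    """
    rows = []
    for label, (x, yv) in analyses.items():
        x = np.asarray(x, float)
        yv = np.asarray(yv, float)
        keep = np.isfinite(x) & np.isfinite(yv)
        x, yv = x[keep], yv[keep]
        if x.size < 5:
            raise ValueError(f"analysis {label!r}: need n >= 5")
        if np.all(x == x[0]) or np.all(yv == yv[0]):
            raise ValueError(f"analysis {label!r}: constant series")
        rho, p = sps.spearmanr(x, yv)
        rows.append({"analysis": label, "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


@dataclass
class StratifiedGroups:
    threshold: float  # the median apnea (s)
    low: list  # apnea <= median
    high: list  # apnea > median


def stratify_median(apnea: pd.Series) -> StratifiedGroups:
    """Split TBI subjects at the median apnea; ties go to Low."""
    if apnea.isna().any():
        missing = list(apnea.index[apnea.isna()])
        raise ValueError(f"missing apnea for subjects {missing}")
    med = float(apnea.median())
    low = list(apnea.index[apnea <= med])
    high = list(apnea.index[apnea > med])
    if not high:
        warnings.warn("all apnea values at or below the median: High group empty",
                      stacklevel=2)
    return StratifiedGroups(threshold=med, low=low, high=high)


def anova_tukey(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD post hoc over all group pairs."""
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere")
    F, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    pairs = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs[(names[i], names[j])] = float(tk.pvalue[i, j])
    return {"F": float(F), "p": float(p), "tukey": pairs}


def site_effect_check(
    table: pd.DataFrame, column: str
) -> pd.DataFrame:
    """Fixed-effects OLS of one feature column on site (dummy) + group.

    Returns a tidy frame of coefficients, standard errors, t and p per term.
    A site containing only one group makes the design confounded and raises.
    """
    import statsmodels.api as sm

    df = table[["site", "group", column]].dropna()
    for site, sub in df.groupby("site"):
        if sub["group"].nunique() < 2:
            raise ValueError(f"site {site!r} contains a single group: confounded")
    sites = sorted(df["site"].unique())
    X = pd.DataFrame(index=df.index)
    for s in sites[1:]:
        X[f"site[{s}]"] = (df["site"] == s).astype(float)
    X["group[TBI]"] = (df["group"] == "TBI").astype(float)
    X = sm.add_constant(X)
    fit = sm.OLS(df[column].astype(float), X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
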