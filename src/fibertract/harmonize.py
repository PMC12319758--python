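"""Multi-site harmonization and sham-referenced standardization.

Scanner and field-strength differences show up as a multiplicative offset on
DTI metrics.  Harmonization removes it with a global-statistics rule: for
each (site, metric), build one intensity histogram per subject on common
bins, average them with equal subject weight, smooth, and locate the peak
(mode) — which reflects normal-appearing tissue.  Every value from that site
is then multiplied by the reciprocal of the mode, bringing all sites to a
common reference where the mode sits at 1.

After harmonization, features are standardized against the sham group:
z = (x - mu) / sigma with mu, sigma computed per feature from sham rows only.
Signed z-scores are the default; absolute z-scores are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import METRICS
from .features import bundle_of, split_covariates

__all__ = [
    "AveragedHistogram",
    "HarmonizationFactors",
    "ReferenceStats",
    "averaged_site_histogram",
    "mode_scaling_factor",
    "fit_harmonization",
    "apply_harmonization",
    "zscore_standardize",
]


@dataclass
class AveragedHistogram:
    """Equal-subject-weight average of per-subject density histograms."""

    bin_edges: np.ndarray  # (n_bins + 1,) strictly increasing
    counts: np.ndarray  # (n_bins,) averaged densities

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class HarmonizationFactors:
    """Per (site, metric): averaged histogram, mode location and the scaling
    factor 1/mode."""

    histograms: dict  # (site, metric) -> AveragedHistogram
    modes: dict  # (site, metric) -> float
    factors: dict  # (site, metric) -> float (= 1/mode exactly)
    smoothing_window: int = 5

    def factor(self, site: str, metric: str) -> float:
        key = (site, metric)
        if key not in self.factors:
            raise KeyError(f"no harmonization factor for site {site!r}, {metric}")
        return self.factors[key]

    def save(self, path: str | Path) -> None:
        payload = {
            f"{s}::{m}": {"mode": self.modes[(s, m)], "factor": self.factors[(s, m)]}
            for (s, m) in self.factors
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def averaged_site_histogram(
    values_per_subject: list[np.ndarray],
    bin_edges: np.ndarray,
) -> AveragedHistogram:
    """Average the per-subject normalized (density) histograms of one site.

    Subjects with no finite values are skipped with a warning; zero usable
    subjects is an error.  Common bin edges must be supplied so sites share
    a grid.
    """
    import warnings

    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    densities = []
    for i, vals in enumerate(values_per_subject):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"subject {i} has no finite values; skipped", stacklevel=2)
            continue
        dens, _ = np.histogram(vals, bins=bin_edges, density=True)
        densities.append(dens)
    if not densities:
        raise ValueError("no subjects with finite values")
    return AveragedHistogram(bin_edges=bin_edges, counts=np.mean(densities, axis=0))


def mode_scaling_factor(
    hist: AveragedHistogram, smoothing_window: int = 5
) -> tuple[float, float]:
    """Locate the histogram mode and return (mode, factor = 1/mode).

    The averaged counts are smoothed with a centred moving average of
    ``smoothing_window`` bins before taking the maximum; ties break toward
    the lowest bin centre.  The mode must be positive.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if not np.any(counts > 0):
        raise ValueError("all histogram counts are zero")
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(counts, kernel, mode="same")
    peak = int(np.argmax(smooth))  # argmax returns the first (lowest) maximum
    mode = float(hist.centers[peak])
    if mode <= 0:
        raise ValueError(f"histogram mode {mode} is not positive")
    return mode, 1.0 / mode


def _common_edges(values: np.ndarray, n_bins: int, is_fa: bool) -> np.ndarray:
    vals = values[np.isfinite(values)]
    vals = vals[vals > 0]  # exclude masked-background zeros
    if vals.size == 0:
        raise ValueError("no positive finite values to bin")
    lo, hi = np.percentile(vals, [1, 99])
    if is_fa and hi <= 1.0:
        # FA support clamp applies only when the data actually lives in
        # (0, 1]; unconstrained otherwise so global rescaling stays legal
        lo = max(lo, 1e-6)
    if hi <= lo:
        hi = lo * (1 + 1e-6) + 1e-12
    return np.linspace(lo, hi, n_bins + 1)


def fit_harmonization_values(
    samples: dict,
    n_bins: int = 128,
    smoothing_window: int = 21,
) -> HarmonizationFactors:
    """Fit factors from map-granularity intensity samples.

    ``samples`` maps metric name to {site: [per-subject 1D value arrays]},
    e.g. masked voxel values of each subject's FA/MD/RD/AD map.  This is the
    preferred granularity: with thousands of values per subject the intensity
    density is smooth and its mode (normal-appearing tissue) is estimated
    accurately, unlike the 36-value bundle-summary route.
    """
    factors: dict = {}
    modes: dict = {}
    hists: dict = {}
    for m, by_site in samples.items():
        pooled = np.concatenate(
            [np.concatenate(vs) for vs in by_site.values()]
        ).astype(float)
        edges = _common_edges(pooled, n_bins, is_fa=(m == "FA"))
        for site in sorted(by_site):
            hist = averaged_site_histogram(by_site[site], edges)
            mode, fac = mode_scaling_factor(hist, smoothing_window)
            hists[(site, m)] = hist
            modes[(site, m)] = mode
            factors[(site, m)] = fac
    return HarmonizationFactors(
        histograms=hists, modes=modes, factors=factors,
        smoothing_window=smoothing_window,
    )


def fit_harmonization(
    table: pd.DataFrame,
    n_bins: int = 128,
    smoothing_window: int = 5,
) -> HarmonizationFactors:
    """Fit per-(site, metric) scaling factors from a feature table.

    Each subject contributes one histogram per metric, built from its bundle
    values; bins span the pooled 1st-99th percentile range per metric so all
    sites share the same grid.
    """
    _, feats = split_covariates(table)
    factors: dict = {}
    modes: dict = {}
    hists: dict = {}
    for m in METRICS:
        cols = [c for c in feats if c.endswith(f"__{m}")]
        if not cols:
            continue
        pooled = table[cols].to_numpy(dtype=float).ravel()
        edges = _common_edges(pooled, n_bins, is_fa=(m == "FA"))
        for site, sub in table.groupby("site", sort=True):
            per_subj = [row for row in sub[cols].to_numpy(dtype=float)]
            hist = averaged_site_histogram(per_subj, edges)
            mode, fac = mode_scaling_factor(hist, smoothing_window)
            hists[(site, m)] = hist
            modes[(site, m)] = mode
            factors[(site, m)] = fac
    return HarmonizationFactors(
        histograms=hists, modes=modes, factors=factors,
        smoothing_window=smoothing_window,
    )


def apply_harmonization(
    table: pd.DataFrame, factors: HarmonizationFactors
) -> pd.DataFrame:
    """Multiply every feature value by its site-metric factor.

    Missing cells stay missing; an unknown site raises.
    """
    _, feats = split_covariates(table)
    out = table.copy()
    for site, sub in table.groupby("site", sort=False):
        for m in METRICS:
            cols = [c for c in feats if c.endswith(f"__{m}")]
            if not cols:
                continue
            fac = factors.factor(site, m)
            out.loc[sub.index, cols] = sub[cols] * fac
    return out


@dataclass
class ReferenceStats:
    """Sham-group mean and standard deviation per feature column."""

    mu: pd.Series
    sigma: pd.Series
    zmode: str = "signed"

    def save(self, path: str | Path) -> None:
        payload = {
            "zmode": self.zmode,
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def zscore_standardize(
    table: pd.DataFrame,
    reference: ReferenceStats | None = None,
    zmode: str = "signed",
) -> tuple[pd.DataFrame, ReferenceStats]:
    """Standardize features against the sham group.

    mu and sigma come from sham rows only (NaNs ignored) unless a precomputed
    reference is given; z = (x - mu) / sigma is applied to every row.
    ``zmode='absolute'`` returns |z|.  A zero-sigma feature is an error.
    """
    if zmode not in ("signed", "absolute"):
        raise ValueError("zmode must be 'signed' or 'absolute'")
    _, feats = split_covariates(table)
    if reference is None:
        sham = table[table["group"] == "sham"]
        if sham.empty:
            raise ValueError("no sham rows to compute reference stats from")
        mu = sham[feats].mean(skipna=True)
        sigma = sham[feats].std(skipna=True, ddof=1)
        reference = ReferenceStats(mu=mu, sigma=sigma, zmode=zmode)
    else:
        reference = ReferenceStats(
            mu=reference.mu, sigma=reference.sigma, zmode=zmode
        )
    zero = reference.sigma[reference.sigma <= 0]
    if len(zero):
        raise ValueError(f"zero sham standard deviation for {list(zero.index)[:5]}")
    out = table.copy()
    z = (table[feats] - reference.mu) / reference.sigma
    out[feats] = z.abs() if zmode == "absolute" else z
    return out, reference
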