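"""Feature-table assembly, missingness filtering and k-NN imputation.

The analysis table is wide: one row per subject, covariate columns
(``subject, site, group, timepoint, apnea``) followed by ``bundle__metric``
feature columns.  Bundles fail as a unit in tractography, so missingness is
pooled over the four metrics of a bundle; any bundle missing in more than
``max_fraction`` of its cells (strict inequality) loses all four columns.
Remaining gaps are filled with k-nearest-neighbour imputation (k = 5,
nan-aware Euclidean distances, unweighted neighbour mean) — covariates are
never used as imputation inputs, so group labels cannot leak into features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .cohort import METRICS
from .tracking import BundleSummary

__all__ = [
    "COVARIATE_COLUMNS",
    "MissingnessReport",
    "assemble_table",
    "missingness_filter",
    "knn_impute",
    "split_covariates",
]

COVARIATE_COLUMNS = ("subject", "site", "group", "timepoint", "apnea")


def split_covariates(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Return (covariate frame, feature column names)."""
    feats = [c for c in table.columns if c not in COVARIATE_COLUMNS]
    return table[[c for c in COVARIATE_COLUMNS if c in table.columns]], feats


@dataclass
class MissingnessReport:
    """Per-bundle missing fractions and the resulting exclusions."""

    fractions: pd.DataFrame  # bundles x [overall, sham, TBI]
    threshold: float
    excluded: list

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "excluded": list(self.excluded),
            "fractions": self.fractions.round(6).to_dict(orient="index"),
        }


def assemble_table(
    summaries: dict[str, list[BundleSummary]],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Build the wide table from per-subject bundle summaries.

    ``summaries`` maps subject id to its list of :class:`BundleSummary`;
    ``covariates`` must carry one row per subject.  A missing-flagged summary
    yields NaN in all four metric cells of that bundle.
    """
    if covariates["subject"].duplicated().any():
        raise ValueError("duplicate subject identifiers in covariates")
    atlas: list[str] | None = None
    rows = {}
    for sid, summs in summaries.items():
        names = [s.bundle for s in summs]
        if atlas is None:
            atlas = names
        elif set(names) - set(atlas):
            unknown = sorted(set(names) - set(atlas))
            raise ValueError(f"subject {sid!r} has unknown bundle keys {unknown}")
        feats = {}
        for s in summs:
            for m in METRICS:
                feats[f"{s.bundle}__{m}"] = (
                    np.nan if s.missing else s.means[m]
                )
        rows[sid] = feats
    feat_df = pd.DataFrame.from_dict(rows, orient="index")
    feat_df.index.name = "subject"
    out = covariates.merge(feat_df, left_on="subject", right_index=True, how="inner")
    return out.reset_index(drop=True)


def bundle_of(column: str) -> str:
    return column.rsplit("__", 1)[0]


def missingness_filter(
    table: pd.DataFrame, max_fraction: float = 0.10
) -> tuple[pd.DataFrame, MissingnessReport]:
    """Drop every bundle whose pooled missing fraction exceeds the threshold.

    The fraction is pooled over the bundle's four metric columns and all
    subjects; a bundle at exactly the threshold is retained (strict
    inequality).
    """
    if table.empty:
        raise ValueError("empty table")
    _, feats = split_covariates(table)
    bundles = sorted({bundle_of(c) for c in feats})
    frac_rows = {}
    excluded = []
    grp = table["group"] if "group" in table.columns else None
    for b in bundles:
        cols = [c for c in feats if bundle_of(c) == b]
        cells = table[cols]
        overall = float(cells.isna().to_numpy().mean())
        row = {"overall": overall}
        if grp is not None:
            for g in ("sham", "TBI"):
                sub = cells[grp == g]
                row[g] = float(sub.isna().to_numpy().mean()) if len(sub) else np.nan
        frac_rows[b] = row
        if overall > max_fraction:
            excluded.append(b)
    if len(excluded) == len(bundles):
        raise ValueError("all bundles excluded by the missingness filter")
    drop_cols = [c for c in feats if bundle_of(c) in set(excluded)]
    report = MissingnessReport(
        fractions=pd.DataFrame.from_dict(frac_rows, orient="index"),
        threshold=max_fraction,
        excluded=excluded,
    )
    return table.drop(columns=drop_cols), report


def knn_impute(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing feature cells with the unweighted mean of the k nearest
    subjects.

    Distances are nan-aware Euclidean on mutually observed features, rescaled
    by the fraction of observed coordinates; ties are broken by subject
    order.  Covariates are excluded from the distance computation.  Observed
    cells are never altered.
    """
    _, feats = split_covariates(table)
    X = table[feats].to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(X), axis=0)
    if np.any(n_obs < k):
        bad = [feats[i] for i in np.nonzero(n_obs < k)[0]]
        raise ValueError(f"features with fewer than k={k} observed values: {bad[:5]}")
    if np.any(np.all(np.isnan(X), axis=1)):
        raise ValueError("a subject has no observed features")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(X)
    out = table.copy()
    out[feats] = filled
    return out
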