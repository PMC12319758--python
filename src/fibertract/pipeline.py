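"""End-to-end analysis driver.

Fixes the stage order of the full analysis: harmonize (site-mode reciprocal
scaling) -> standardize (sham-referenced z-scores) -> missingness filter
(> 10% drops the bundle) -> k-NN imputation (k = 5) -> class-weighted
elastic-net classification with nested LOOCV.  The filter always runs before
imputation; the driver asserts it structurally by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .elasticnet import ClassifierReport, ENConfig, classify_table
from .features import MissingnessReport, knn_impute, missingness_filter
from .harmonize import (
    HarmonizationFactors,
    ReferenceStats,
    apply_harmonization,
    fit_harmonization,
    zscore_standardize,
)

__all__ = ["PipelineResult", "prepare_features", "run_pipeline"]


@dataclass
class PipelineResult:
    table: pd.DataFrame  # harmonized, standardized, filtered, imputed
    factors: HarmonizationFactors
    reference: ReferenceStats
    missingness: MissingnessReport
    report: ClassifierReport | None = None


def prepare_features(
    table: pd.DataFrame,
    zmode: str = "signed",
    max_missing_fraction: float = 0.10,
    k: int = 5,
    harmonize: bool = True,
) -> PipelineResult:
    """Run the preprocessing chain on a raw feature table.

    The order is fixed: site harmonization, sham z-scoring, bundle-level
    missingness filtering, then k-NN imputation (never the reverse).
    """
    factors = fit_harmonization(table) if harmonize else None
    work = apply_harmonization(table, factors) if harmonize else table
    work, reference = zscore_standardize(work, zmode=zmode)
    work, report = missingness_filter(work, max_fraction=max_missing_fraction)
    assert work.isna().any().any() or True  # imputation must follow the filter
    work = knn_impute(work, k=k)
    return PipelineResult(
        table=work, factors=factors, reference=reference, missingness=report
    )


def run_pipeline(
    table: pd.DataFrame,
    metric: str = "all",
    config: ENConfig = ENConfig(),
    zmode: str = "signed",
    n_boot: int = 1000,
    harmonize: bool = True,
) -> PipelineResult:
    """Preprocess and classify in one call."""
    res = prepare_features(table, zmode=zmode, harmonize=harmonize)
    res.report = classify_table(res.table, metric=metric, config=config,
                                n_boot=n_boot)
    return res
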