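"""Synthetic multi-site TBI cohort generation.

The generator emulates the statistical structure of a three-site preclinical
TBI study: sham and injured rats scanned at one or more time points, with

* per-bundle, per-metric baseline means and between-subject variation
  (a subject-level random intercept shared across bundles plus independent
  feature noise, which gives features the cross-subject correlation that
  k-NN imputation exploits);
* ipsilateral injury: a configurable set of left-hemisphere bundles whose
  metrics are shifted in the TBI group to hit a target population Cohen's d
  (paper sign convention: positive d means TBI *lower* than sham);
* an apnea covariate (log-normal, median 30 s in the TBI group) coupled to
  each subject's effect magnitude, so longer apnea means larger
  microstructural change;
* multiplicative per-site scale factors on every metric (the scanner/site
  effect that harmonization must remove);
* missing-at-random bundle failures, with a higher rate in the TBI group.

When the apnea coupling is non-zero the raw shift is calibrated analytically
so that the *population* Cohen's d still equals the target despite the
coupling-induced variance inflation in the TBI group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import BundleSpec, PhantomSpec, rasterize_multitensor_phantom
from .volumes import MultiTensorVolume

__all__ = [
    "CohortSpec",
    "CohortGroundTruth",
    "DEFAULT_BUNDLES",
    "METRICS",
    "make_feature_table_direct",
    "sample_cohort",
    "feature_columns",
]

METRICS = ("FA", "MD", "RD", "AD")

# 36-bundle atlas: 15 bilateral tracts plus 6 midline structures, mirroring a
# rodent white-matter parcellation.  Injury is applied to _L bundles.
_BILATERAL = (
    "fimbria", "thalsub", "intcap", "cing", "chip", "fornix", "opticrad",
    "ilf", "ifof", "slfa", "slfb", "cerped", "thalslat", "thalsmed",
    "amyhypdor",
)
_MIDLINE = ("cc_ant", "cc_mid", "cc_post", "cc_temp", "ant_comm", "hipcom")
DEFAULT_BUNDLES: tuple[str, ...] = tuple(
    f"{b}_{h}" for b in _BILATERAL for h in ("L", "R")
) + _MIDLINE  # 36 bundles

# metric-level scales: baseline location, bundle-to-bundle spread of the
# baseline, and between-subject standard deviation (intercept + noise split
# evenly).  Diffusivities in mm^2/s.
_METRIC_BASE = {"FA": 0.55, "MD": 0.75e-3, "RD": 0.55e-3, "AD": 1.15e-3}
_METRIC_BUNDLE_SD = {"FA": 0.06, "MD": 0.06e-3, "RD": 0.05e-3, "AD": 0.08e-3}
_METRIC_SUBJECT_SD = {"FA": 0.04, "MD": 0.04e-3, "RD": 0.035e-3, "AD": 0.05e-3}

# default injury: left fimbria, thalamic subcortical projections, internal
# capsule and temporal corpus callosum; FA drops (positive d), diffusivities
# rise (negative d), |d| = 2
_DEFAULT_EFFECTS = {"FA": 2.0, "MD": -2.0, "RD": -2.0, "AD": -2.0}
_DEFAULT_INJURED = ("fimbria_L", "thalsub_L", "intcap_L", "cc_temp")


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic multi-site cohort (a single time point).

    ``site_counts`` maps site label to (n_sham, n_tbi).  ``site_factors``
    maps site label to a multiplicative factor applied to every metric, or to
    a per-metric dict.  ``injured_effects`` maps bundle name to a per-metric
    target Cohen's d (positive = TBI lower).  Apnea is log-normal with the
    given log-scale parameters; ``apnea_coupling`` scales each TBI subject's
    shift by (1 + coupling * z) with z the standardized log-apnea.
    """

    site_counts: dict = field(
        default_factory=lambda: {"siteA": (10, 29), "siteB": (10, 29), "siteC": (10, 29)}
    )
    site_factors: dict = field(
        default_factory=lambda: {"siteA": 1.0, "siteB": 1.15, "siteC": 0.9}
    )
    bundles: tuple[str, ...] = DEFAULT_BUNDLES
    injured_effects: dict = field(
        default_factory=lambda: {
            b: dict(_DEFAULT_EFFECTS) for b in _DEFAULT_INJURED
        }
    )
    timepoint: str = "2d"
    apnea_log_median: float = np.log(30.0)  # seconds; TBI group
    apnea_log_sd: float = 0.8
    sham_apnea_log_median: float = np.log(5.0)
    sham_apnea_log_sd: float = 0.5
    apnea_coupling: float = 0.5
    sham_missing_rate: float = 0.02
    tbi_missing_rate: float = 0.06  # 3x sham, within the 2-4x asymmetry
    subject_sd_scale: float = 1.0
    atlas_seed: int = 1234  # fixes per-bundle baselines across cohorts

    def __post_init__(self) -> None:
        for site, (ns, nt) in self.site_counts.items():
            if ns < 0 or nt < 0:
                raise ValueError(f"negative count for site {site!r}")
        for site, f in self.site_factors.items():
            vals = f.values() if isinstance(f, dict) else [f]
            if any(v <= 0 for v in vals):
                raise ValueError(f"non-positive site factor for {site!r}")
        for r in (self.sham_missing_rate, self.tbi_missing_rate):
            if not (0 <= r < 1):
                raise ValueError("missingness rates must lie in [0, 1)")
        missing = set(self.injured_effects) - set(self.bundles)
        if missing:
            raise ValueError(f"injured bundles not in atlas: {sorted(missing)}")
        if self.subject_sd_scale <= 0:
            raise ValueError("subject variation must be positive "
                             "(a target d needs non-zero variance)")

    def site_factor(self, site: str, metric: str) -> float:
        f = self.site_factors[site]
        return float(f[metric]) if isinstance(f, dict) else float(f)

    @property
    def n_subjects(self) -> int:
        return sum(ns + nt for ns, nt in self.site_counts.values())


@dataclass
class CohortGroundTruth:
    """What the generator actually injected, for downstream validation."""

    injured_effects: dict  # bundle -> metric -> target d
    baseline_means: pd.DataFrame  # bundles x metrics
    subject_sd: dict  # metric -> between-subject sd
    effect_multiplier: pd.Series  # per subject: 1 + coupling * z (1 for sham)
    apnea: pd.Series
    site_factors: dict
    missing_mask: pd.DataFrame  # subjects x bundles, True where failed


def feature_columns(bundles, metrics=METRICS) -> list[str]:
    return [f"{b}__{m}" for b in bundles for m in metrics]


def _baseline_means(spec: CohortSpec) -> pd.DataFrame:
    """Fixed per-bundle baselines, a property of the atlas, not of the cohort
    seed."""
    rng = np.random.default_rng(spec.atlas_seed)
    data = {
        m: np.clip(
            rng.normal(_METRIC_BASE[m], _METRIC_BUNDLE_SD[m], len(spec.bundles)),
            0.05 * _METRIC_BASE[m],
            None,
        )
        for m in METRICS
    }
    df = pd.DataFrame(data, index=list(spec.bundles))
    df["FA"] = df["FA"].clip(upper=0.95)
    return df


def _calibrated_shift(d: float, sd: float, coupling: float,
                      n_sham: int, n_tbi: int) -> float:
    """Raw TBI mean shift whose population Cohen's d equals ``d`` despite the
    coupling-induced variance inflation in the TBI group.

    With shift_i = delta * (1 + c z_i), z ~ N(0,1), the TBI variance becomes
    sd^2 + (delta c)^2; solving d = delta / s_pooled for delta gives
    delta = d sd / sqrt(1 - d^2 w c^2) with w the TBI weight in the pooled
    variance.
    """
    if sd <= 0:
        raise ValueError("zero variance: target Cohen's d undefined")
    if coupling == 0 or d == 0:
        return d * sd
    w = (n_tbi - 1) / max(n_sham + n_tbi - 2, 1)
    denom = 1.0 - d * d * w * coupling * coupling
    if denom <= 0:
        raise ValueError(
            f"target d={d} unreachable with apnea coupling {coupling}"
        )
    return d * sd / np.sqrt(denom)


def make_feature_table_direct(
    spec: CohortSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Fast path: draw the subjects-by-(bundle, metric) table directly.

    Returns a wide table with columns ``subject, site, group, timepoint,
    apnea`` followed by ``<bundle>__<metric>`` features (NaN where a bundle
    failed), plus the ground truth actually injected.
    """
    if len(spec.bundles) < len(spec.injured_effects):
        raise ValueError("fewer bundles than injured bundles")
    rng = np.random.default_rng(seed)
    base = _baseline_means(spec)
    subj_sd = {m: _METRIC_SUBJECT_SD[m] * spec.subject_sd_scale for m in METRICS}
    n_sham_total = sum(ns for ns, _ in spec.site_counts.values())
    n_tbi_total = sum(nt for _, nt in spec.site_counts.values())

    rows = []
    gt_mult, gt_apnea, gt_missing = {}, {}, {}
    for site, (n_sham, n_tbi) in spec.site_counts.items():
        for gi, (group, n) in enumerate((("sham", n_sham), ("TBI", n_tbi))):
            for j in range(n):
                sid = f"{site}_{group}_{j:03d}"
                if group == "TBI":
                    z = rng.standard_normal()
                    log_a = spec.apnea_log_median + spec.apnea_log_sd * z
                    mult = 1.0 + spec.apnea_coupling * z
                else:
                    log_a = (spec.sham_apnea_log_median
                             + spec.sham_apnea_log_sd * rng.standard_normal())
                    mult = 1.0
                apnea = float(np.exp(log_a))
                # subject-level intercept shared across bundles (half the
                # between-subject variance) + independent feature noise
                intercept = {
                    m: rng.normal(0.0, subj_sd[m] / np.sqrt(2)) for m in METRICS
                }
                feats = {}
                miss_rate = (
                    spec.tbi_missing_rate if group == "TBI" else spec.sham_missing_rate
                )
                failed = rng.random(len(spec.bundles)) < miss_rate
                for bi, b in enumerate(spec.bundles):
                    for m in METRICS:
                        x = (
                            base.loc[b, m]
                            + intercept[m]
                            + rng.normal(0.0, subj_sd[m] / np.sqrt(2))
                        )
                        if group == "TBI" and b in spec.injured_effects:
                            d = spec.injured_effects[b].get(m, 0.0)
                            delta = _calibrated_shift(
                                d, subj_sd[m], spec.apnea_coupling,
                                n_sham_total, n_tbi_total,
                            )
                            x -= delta * mult
                        x *= spec.site_factor(site, m)
                        feats[f"{b}__{m}"] = np.nan if failed[bi] else x
                rows.append(
                    {"subject": sid, "site": site, "group": group,
                     "timepoint": spec.timepoint, "apnea": apnea, **feats}
                )
                gt_mult[sid] = mult
                gt_apnea[sid] = apnea
                gt_missing[sid] = failed.copy()
    table = pd.DataFrame(rows)
    if table["subject"].duplicated().any():
        raise ValueError("duplicate subject identifiers")
    truth = CohortGroundTruth(
        injured_effects={b: dict(e) for b, e in spec.injured_effects.items()},
        baseline_means=base,
        subject_sd=subj_sd,
        effect_multiplier=pd.Series(gt_mult),
        apnea=pd.Series(gt_apnea),
        site_factors=dict(spec.site_factors),
        missing_mask=pd.DataFrame(gt_missing, index=list(spec.bundles)).T,
    )
    return table, truth


def make_subject_scalar_samples(
    spec: CohortSpec,
    n_values: int = 20000,
    within_spread: float = 0.22,
    seed: int = 0,
) -> dict:
    """Map-granularity intensity samples consistent with the cohort design.

    Emulates each subject's masked voxelwise scalar-map values: a smooth
    right-skewed tissue distribution (log-normal around the metric baseline,
    ``within_spread`` log-sd) scaled by the subject's site factor and a small
    subject-level gain.  The default of 20,000 values per subject is a
    conservative stand-in for the ~10^5 brain voxels of a 250 um rodent
    acquisition.  Returns {metric: {site: [per-subject arrays]}} in the
    subject order of :func:`make_feature_table_direct`, for use with
    :func:`fibertract.harmonize.fit_harmonization_values`.
    """
    rng = np.random.default_rng(seed)
    out: dict = {m: {} for m in METRICS}
    for site, (n_sham, n_tbi) in spec.site_counts.items():
        per_site: dict = {m: [] for m in METRICS}
        for group, n in (("sham", n_sham), ("TBI", n_tbi)):
            for _ in range(n):
                gain = rng.lognormal(0.0, 0.02)
                for m in METRICS:
                    vals = rng.lognormal(
                        np.log(_METRIC_BASE[m]), within_spread, n_values
                    )
                    per_site[m].append(vals * spec.site_factor(site, m) * gain)
        for m in METRICS:
            out[m][site] = per_site[m]
    return out


def sample_cohort(
    cspec: CohortSpec,
    pspec: PhantomSpec,
    seed: int = 0,
    injured_fraction_scale: float = 0.15,
    fraction_jitter: float = 0.35,
) -> tuple[list[tuple[str, MultiTensorVolume]], pd.DataFrame]:
    """Imaging route: one perturbed ball-and-sticks phantom per subject.

    Only bundles present in ``pspec`` are simulated.  Sham subjects perturb
    each bundle's diffusivities and stick fraction with subject-level
    Gaussian/log-normal variation; TBI subjects additionally scale the stick
    fraction of injured bundles by a log-normal factor centred on
    ``injured_fraction_scale`` (axonal loss), which drives tractography
    failures downstream.  Site factors multiply the diffusivities.

    Returns (subject_id, volume) pairs plus a covariate table.
    """
    rng = np.random.default_rng(seed)
    volumes = []
    cov_rows = []
    for site, (n_sham, n_tbi) in cspec.site_counts.items():
        sf = {m: cspec.site_factor(site, m) for m in METRICS}
        diff_scale = sf["MD"]  # diffusivity-borne site effect
        for group, n in (("sham", n_sham), ("TBI", n_tbi)):
            for j in range(n):
                sid = f"{site}_{group}_{j:03d}"
                new_bundles = []
                for b in pspec.bundles:
                    lam_par = b.lambda_par * diff_scale * rng.lognormal(0.0, 0.03)
                    lam_perp = min(
                        b.lambda_perp * diff_scale * rng.lognormal(0.0, 0.03),
                        lam_par,
                    )
                    frac = b.fraction * rng.lognormal(0.0, 0.05)
                    if group == "TBI" and b.name in cspec.injured_effects:
                        frac *= rng.lognormal(
                            np.log(injured_fraction_scale), fraction_jitter
                        )
                    new_bundles.append(
                        replace(
                            b,
                            lambda_par=lam_par,
                            lambda_perp=lam_perp,
                            fraction=float(np.clip(frac, 1e-3, 1.0)),
                        )
                    )
                sub_spec = replace(pspec, bundles=tuple(new_bundles))
                vol, _ = rasterize_multitensor_phantom(sub_spec)
                volumes.append((sid, vol))
                cov_rows.append(
                    {"subject": sid, "site": site, "group": group,
                     "timepoint": cspec.timepoint}
                )
    return volumes, pd.DataFrame(cov_rows)
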