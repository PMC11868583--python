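"""Seeded simulator for morphometry cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes in real
FreeSurfer/MRIQC tables:

* smooth age effects on relative volumes (linear + quadratic, negative for
  cortex, positive for ventricles),
* a small multiplicative sex offset and a sex-dependent log-normal total
  intracranial volume,
* per-scanner additive and multiplicative batch effects driven by a latent
  per-scanner "quality" factor,
* image-quality metrics (8 named IQMs plus a Beta-distributed probability
  that the scan is unusable) correlated with that same latent factor, so a
  regressor can learn corrections from IQMs alone,
* optional regional disease effects (atrophy or enlargement) whose severity
  drives a noisy symptom score.

Everything is drawn from one :class:`numpy.random.Generator`, so a config
with the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Cohort, RoiSchema, default_schema

IQM_NAMES = ("cjv", "cnr", "snr", "efc", "fber", "fwhm_avg", "qi1", "wm2max")

# Baseline relative volume (fraction of TIV) by high-level group; cortical
# regions dominate, callosal segments are small. Values are in the range of
# adult FreeSurfer aparc/aseg output.
_GROUP_BASE = {
    "frontal": 4.0e-3, "temporal": 3.5e-3, "parietal": 3.6e-3,
    "occipital": 3.0e-3, "insula": 4.2e-3, "cingulate": 2.6e-3,
    "subcortical": 2.2e-3, "cerebellum": 8.0e-3,
    "corpus callosum": 6.0e-4, "ventricles": 3.0e-3,
}
# Fractional change per year of age, by group (centred at age 50).
_GROUP_AGE_SLOPE = {
    "frontal": -3.0e-3, "temporal": -2.5e-3, "parietal": -2.5e-3,
    "occipital": -1.5e-3, "insula": -2.0e-3, "cingulate": -2.0e-3,
    "subcortical": -2.0e-3, "cerebellum": -1.5e-3,
    "corpus callosum": -1.0e-3, "ventricles": +1.5e-2,
}


@dataclass
class DiseaseSpec:
    """Regional alteration linked to a symptom scale.

    ``atrophy_fraction`` is the fractional volume loss at severity 1 for the
    affected regions; a negative value models enlargement (ventricles).
    Severity is drawn per patient and mapped to a symptom score as
    ``symptom = symptom_intercept + symptom_slope * severity + noise``.
    """

    affected_rois: Sequence[str]
    atrophy_fraction: float = 0.3
    prevalence: float = 0.5
    severity_mean: float = 1.0
    severity_sd: float = 0.25
    symptom_name: str = "severity"
    symptom_slope: float = 20.0
    symptom_intercept: float = 10.0
    symptom_noise_sd: float = 2.0
    label: str = "patient"

    def __post_init__(self) -> None:
        if not -1.0 < self.atrophy_fraction < 1.0:
            raise ValueError("atrophy_fraction must lie in (-1, 1)")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Per-scanner effect sizes may be given explicitly (arrays indexed
    scanner x ROI) or left ``None`` to be drawn from the latent-quality model
    controlled by ``scanner_effect_sd`` / ``scanner_scale_sd``.
    """

    n_per_scanner: Sequence[int] = (200, 200)
    scanner_names: Sequence[str] | None = None
    age_range: tuple[float, float] = (20.0, 80.0)
    sex_effect_sd: float = 0.02            # per-ROI fractional F/M offset
    noise_frac: float = 0.06               # per-ROI noise SD as fraction of baseline
    scanner_effect_sd: float = 0.4         # additive shift, units of within-scanner SD
    scanner_scale_sd: float = 0.05         # log-scale multiplicative spread
    scanner_additive: np.ndarray | None = None
    scanner_multiplicative: np.ndarray | None = None
    scanner_quality: Sequence[float] | None = None  # fix the latent factors
    iqm_noise_sd: float = 0.3              # within-scanner IQM spread
    iqm_loading_sd: float = 1.0            # how strongly IQMs track the latent factor
    prob_unusable_bad_fraction: float = 0.05
    tiv_mean_f: float = 1.38e6             # mm^3, log-normal location by sex
    tiv_mean_m: float = 1.55e6
    tiv_log_sd: float = 0.07
    disease: DiseaseSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_scanner) == 0:
            raise ValueError("at least one scanner is required")
        if any(n < 1 for n in self.n_per_scanner):
            raise ValueError("n_per_scanner entries must be >= 1")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.scanner_names is None:
            self.scanner_names = tuple(
                f"scanner_{chr(ord('A') + i)}" for i in range(len(self.n_per_scanner))
            )
        if len(self.scanner_names) != len(self.n_per_scanner):
            raise ValueError("scanner_names and n_per_scanner lengths differ")


@dataclass
class GroundTruth:
    """What the simulator injected, for recovery checks."""

    baseline: np.ndarray                   # k baseline relative volumes
    age_slope: np.ndarray                  # k fractional change / year
    age_quad: np.ndarray                   # k fractional change / year^2
    sex_effect: np.ndarray                 # k fractional M-F offset
    noise_sd: np.ndarray                   # k additive noise SD (relative units)
    scanner_additive: np.ndarray           # s x k additive shifts (relative units)
    scanner_multiplicative: np.ndarray     # s x k multiplicative factors
    scanner_quality: np.ndarray            # s latent quality factors
    iqm_loadings: np.ndarray               # n_iqm loadings on the latent factor
    disease_ids: list[str] = field(default_factory=list)
    severities: dict[str, float] = field(default_factory=dict)


def _roi_profile(schema: RoiSchema, rng: np.random.Generator):
    """Deterministic per-ROI baseline/age/sex parameters for the schema."""
    k = len(schema)
    base = np.empty(k)
    slope = np.empty(k)
    for j, name in enumerate(schema.names):
        g = schema.group[name]
        base[j] = _GROUP_BASE[g]
        slope[j] = _GROUP_AGE_SLOPE[g]
    # mild per-ROI jitter so regions are not exact copies of their group
    base *= rng.lognormal(0.0, 0.15, size=k)
    slope *= rng.lognormal(0.0, 0.2, size=k)
    quad = slope * rng.uniform(0.0, 0.01, size=k)  # gentle curvature, same sign
    return base, slope, quad


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort of raw volumes plus IQMs from the configured conditions.

    Returns the cohort with ``feature_kind="raw"`` (relative patterns
    multiplied back by each participant's drawn TIV) and the ground truth of
    every injected effect.
    """
    schema = default_schema()
    rng = np.random.default_rng(config.seed)
    k = len(schema)
    n_scanners = len(config.n_per_scanner)

    base, slope, quad = _roi_profile(schema, rng)
    sex_eff = rng.normal(0.0, config.sex_effect_sd, size=k)
    noise_sd = config.noise_frac * base

    if config.scanner_quality is not None:
        if len(config.scanner_quality) != n_scanners:
            raise ValueError("scanner_quality must have one entry per scanner")
        quality = np.asarray(config.scanner_quality, dtype=float)
        rng.normal(0.0, 1.0, size=n_scanners)  # keep the draw sequence stable
    else:
        quality = rng.normal(0.0, 1.0, size=n_scanners)
    if config.scanner_additive is None:
        # additive shift proportional to the scanner's latent quality factor,
        # expressed in units of the within-scanner noise SD
        add = config.scanner_effect_sd * quality[:, None] * noise_sd[None, :]
    else:
        add = np.asarray(config.scanner_additive, dtype=float)
        if add.shape != (n_scanners, k):
            raise ValueError(f"scanner_additive must have shape {(n_scanners, k)}")
    if config.scanner_multiplicative is None:
        mult = np.exp(config.scanner_scale_sd * rng.normal(size=(n_scanners, k)))
    else:
        mult = np.asarray(config.scanner_multiplicative, dtype=float)
        if (mult <= 0).any():
            raise ValueError("scanner_multiplicative must be positive")
    iqm_load = rng.normal(0.0, config.iqm_loading_sd, size=len(IQM_NAMES))

    rows = []
    uid = 0
    for s, (scanner, n) in enumerate(zip(config.scanner_names, config.n_per_scanner)):
        ages = rng.uniform(*config.age_range, size=n)
        sexes = rng.integers(0, 2, size=n)  # 0=F, 1=M
        tiv_mu = np.where(sexes == 1, config.tiv_mean_m, config.tiv_mean_f)
        tiv = np.exp(np.log(tiv_mu) + config.tiv_log_sd * rng.normal(size=n))

        da = ages - 50.0
        rel = base[None, :] * (1.0 + slope[None, :] * da[:, None]
                               + quad[None, :] * da[:, None] ** 2)
        rel *= 1.0 + sex_eff[None, :] * sexes[:, None]
        rel += noise_sd[None, :] * rng.normal(size=(n, k))
        rel = rel * mult[s][None, :] + add[s][None, :]
        rel = np.clip(rel, 1e-8, None)

        iqms = (iqm_load[None, :] * quality[s]
                + config.iqm_noise_sd * rng.normal(size=(n, len(IQM_NAMES))))
        bad = rng.random(n) < config.prob_unusable_bad_fraction
        prob_unusable = np.where(bad, rng.beta(8.0, 2.0, size=n), rng.beta(2.0, 18.0, size=n))

        lead = pd.DataFrame({
            "id": [f"sub-{uid + i:05d}" for i in range(n)],
            "age": ages,
            "sex": np.where(sexes == 1, "M", "F"),
            "scanner": scanner,
            "tiv": tiv,
            "diagnosis": "HC",
        })
        uid += n
        vols = pd.DataFrame(rel * tiv[:, None], columns=list(schema.names))
        iqm_frame = pd.DataFrame(iqms, columns=[f"iqm_{m}" for m in IQM_NAMES])
        iqm_frame["iqm_prob_unusable"] = prob_unusable
        rows.append(pd.concat([lead, vols, iqm_frame], axis=1))

    data = pd.concat(rows, ignore_index=True)
    cohort = Cohort(schema, data, feature_kind="raw")
    truth = GroundTruth(
        baseline=base, age_slope=slope, age_quad=quad, sex_effect=sex_eff,
        noise_sd=noise_sd, scanner_additive=add, scanner_multiplicative=mult,
        scanner_quality=quality, iqm_loadings=iqm_load,
    )
    if config.disease is not None:
        cohort, truth = _apply_disease(cohort, truth, config.disease,
                                       rng.integers(0, 2**31 - 1))
    return cohort, truth


def inject_disease(cohort: Cohort, spec: DiseaseSpec, seed: int) -> tuple[Cohort, GroundTruth | None]:
    """Scale affected ROIs down (or up) in a random patient subset.

    Works on raw or relative volumes: the scaling is multiplicative, so it
    commutes with the TIV division. Patients get ``diagnosis = spec.label``
    and a ``symptom_<name>`` column tied to their drawn severity.
    """
    truth = GroundTruth(
        baseline=np.array([]), age_slope=np.array([]), age_quad=np.array([]),
        sex_effect=np.array([]), noise_sd=np.array([]),
        scanner_additive=np.zeros((0, 0)), scanner_multiplicative=np.zeros((0, 0)),
        scanner_quality=np.array([]), iqm_loadings=np.array([]),
    )
    cohort, truth = _apply_disease(cohort, truth, spec, seed)
    return cohort, truth


def _apply_disease(cohort: Cohort, truth: GroundTruth, spec: DiseaseSpec, seed: int):
    if cohort.feature_kind == "harmonized":
        raise ValueError("disease injection applies to raw or relative volumes")
    unknown = [r for r in spec.affected_rois if r not in cohort.schema.names]
    if unknown:
        raise KeyError(f"unknown ROI names in disease spec: {unknown}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    sick = rng.random(n) < spec.prevalence
    severity = np.abs(rng.normal(spec.severity_mean, spec.severity_sd, size=n))
    data = cohort.data.copy()
    cols = list(spec.affected_rois)
    scale = 1.0 - spec.atrophy_fraction * severity[sick, None]
    data.loc[sick, cols] = data.loc[sick, cols].to_numpy() * np.clip(scale, 1e-6, None)
    data.loc[sick, "diagnosis"] = spec.label
    symptom = (spec.symptom_intercept + spec.symptom_slope * severity
               + spec.symptom_noise_sd * rng.normal(size=n))
    data[f"symptom_{spec.symptom_name}"] = np.where(sick, symptom, np.nan)
    out = Cohort(cohort.schema, data, cohort.feature_kind)
    truth.disease_ids = data.loc[sick, "id"].tolist()
    truth.severities = dict(zip(truth.disease_ids, severity[sick]))
    return out, truth
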