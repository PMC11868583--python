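"""Training-cohort cleaning rules.

Four filters, applied in the order quality -> age -> undersample -> outliers:

* discard scans whose MRIQC-style probability of being unusable exceeds 0.7
  (strictly greater; 0.7 itself is kept),
* keep ages in the closed window [20, 80] years,
* cap the number of participants per age bin within one (typically the
  largest) scanner at 55, sampling at random with a fixed seed,
* iteratively exclude, within each scanner, participants with at least 10
  relative volumes more than 3 SD from the scanner mean, recomputing the
  moments until a pass excludes nobody.

Each filter returns the retained cohort plus an :class:`ExclusionLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Cohort


@dataclass
class ExclusionLog:
    """Per-participant record of which rule removed them and when."""

    rule: str
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "rule", "iteration", "n_extreme_rois"]))

    @property
    def excluded_ids(self) -> list[str]:
        return self.entries["id"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def build(rule: str, ids, iterations=None, n_extreme=None) -> "ExclusionLog":
        ids = list(ids)
        entries = pd.DataFrame({
            "id": ids,
            "rule": rule,
            "iteration": iterations if iterations is not None else [pd.NA] * len(ids),
            "n_extreme_rois": n_extreme if n_extreme is not None else [pd.NA] * len(ids),
        })
        if entries["id"].duplicated().any():
            raise AssertionError("an excluded id appears more than once")
        return ExclusionLog(rule, entries)


def filter_quality(cohort: Cohort, threshold: float = 0.7) -> tuple[Cohort, ExclusionLog]:
    """Drop scans with probability-unusable strictly above ``threshold``."""
    col = "iqm_prob_unusable"
    if col not in cohort.data.columns:
        raise KeyError("cohort has no iqm_prob_unusable column; cannot quality-filter")
    prob = cohort.data[col].to_numpy(dtype=float)
    keep = prob <= threshold
    log = ExclusionLog.build("quality", cohort.data.loc[~keep, "id"])
    return cohort.subset(keep), log


def filter_age(cohort: Cohort, lo: float = 20.0, hi: float = 80.0) -> tuple[Cohort, ExclusionLog]:
    """Keep participants with lo <= age <= hi (both bounds inclusive)."""
    age = cohort.data["age"].to_numpy(dtype=float)
    keep = (age >= lo) & (age <= hi)
    log = ExclusionLog.build("age", cohort.data.loc[~keep, "id"])
    return cohort.subset(keep), log


def undersample_age_bins(cohort: Cohort, scanner: str, cap: int = 55,
                         bin_width: float = 5.0, seed: int = 0) -> tuple[Cohort, ExclusionLog]:
    """Cap each age bin of one scanner at ``cap`` participants.

    Bins are half-open ``[lo, lo + bin_width)`` anchored at the configured
    minimum training age (20 by default elsewhere; here anchored at the floor
    of the scanner's minimum age rounded down to a bin edge). Participants
    within an over-full bin are retained by a seeded uniform draw without
    replacement; the draw is made on id-sorted rows so the result does not
    depend on input row order. Other scanners are untouched.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if scanner not in set(cohort.data["scanner"]):
        raise KeyError(f"scanner {scanner!r} not present in cohort")
    data = cohort.data
    in_scanner = data["scanner"] == scanner
    ages = data.loc[in_scanner, "age"]
    bins = np.floor(ages / bin_width).astype(int)
    rng = np.random.default_rng(seed)
    drop_ids: list[str] = []
    for b in sorted(bins.unique()):
        members = data.loc[in_scanner & (bins == b), "id"].sort_values()
        if len(members) <= cap:
            continue
        kept = rng.choice(members.to_numpy(), size=cap, replace=False)
        drop_ids.extend(sorted(set(members) - set(kept)))
    keep = ~data["id"].isin(drop_ids)
    log = ExclusionLog.build("undersample", data.loc[~keep, "id"])
    return cohort.subset(keep), log


def exclude_multivariate_outliers(cohort: Cohort, min_rois: int = 10,
                                  z: float = 3.0) -> tuple[Cohort, ExclusionLog]:
    """Iterative per-scanner exclusion of multivariate outliers.

    On each pass, per scanner and per ROI, the sample mean and SD (ddof=1)
    are computed over currently retained rows; a participant with at least
    ``min_rois`` relative volumes strictly beyond ``z`` SDs is excluded. The
    pass repeats with recomputed moments until no exclusion fires. Scanners
    with fewer than 3 retained participants are skipped (moments would be
    meaningless).
    """
    if cohort.feature_kind != "relative":
        raise ValueError("outlier exclusion expects relative volumes")
    data = cohort.data
    vols = cohort.volumes.to_numpy(dtype=float)
    retained = np.ones(len(data), dtype=bool)
    records: list[tuple[str, int, int]] = []
    iteration = 0
    while True:
        iteration += 1
        newly = np.zeros(len(data), dtype=bool)
        for scanner, grp in data.groupby("scanner", sort=True):
            idx = grp.index[retained[grp.index]]
            if len(idx) < 3:
                continue
            x = vols[idx]
            mu = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                extreme = np.abs(x - mu) > z * sd
            counts = extreme.sum(axis=1)
            out = counts >= min_rois
            for i, c in zip(idx[out], counts[out]):
                records.append((data.at[i, "id"], iteration, int(c)))
                newly[i] = True
        if not newly.any():
            break
        retained &= ~newly
    log = ExclusionLog.build(
        "outlier",
        [r[0] for r in records],
        iterations=[r[1] for r in records],
        n_extreme=[r[2] for r in records],
    )
    return cohort.subset(retained), log


def prepare_training_cohort(cohort: Cohort, *, qc_threshold: float = 0.7,
                            age_min: float = 20.0, age_max: float = 80.0,
                            undersample_scanner: str | None = None, cap: int = 55,
                            bin_width: float = 5.0, min_rois: int = 10,
                            z: float = 3.0, seed: int = 0
                            ) -> tuple[Cohort, list[ExclusionLog]]:
    """Run the full cleaning sequence on a cohort of relative volumes."""
    logs = []
    cohort, log = filter_quality(cohort, qc_threshold)
    logs.append(log)
    cohort, log = filter_age(cohort, age_min, age_max)
    logs.append(log)
    if undersample_scanner is not None:
        cohort, log = undersample_age_bins(cohort, undersample_scanner, cap, bin_width, seed)
        logs.append(log)
    cohort, log = exclude_multivariate_outliers(cohort, min_rois, z)
    logs.append(log)
    return cohort, logs
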