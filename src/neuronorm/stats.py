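"""Cohort-level statistics for deviation scores and brain-age gaps.

Group comparisons follow a normality gate: Shapiro-Wilk on each group, and
only if both look Gaussian (p > alpha) is the independent-samples t-test
used, otherwise the Mann-Whitney U test. Region-wise p-values are adjusted
with Benjamini-Hochberg. Symptom scales are min-max normalized to their
allowed range and then z-scored so different instruments pool comparably.
Deviation-symptom associations use a Shapiro-gated Pearson/Spearman choice.
Cohort heterogeneity is the mean pairwise cosine similarity between
participants' region-level OIS vectors, overall and within each high-level
anatomical group. Confidence intervals for group median differences come
from a seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import RoiSchema


@dataclass
class GroupTestResult:
    variable: str
    test: str                  # "t" or "mann-whitney"
    statistic: float
    p: float
    adjusted_p: float | None
    summary_a: dict
    summary_b: dict
    note: str = ""


@dataclass
class HeterogeneityResult:
    region_group: str          # a high-level group name or "all"
    mean_cs: float
    sd_cs: float
    n_pairs: int
    n_skipped: int = 0


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "iqr": float(np.subtract(*np.percentile(x, [75, 25]))),
    }


def _shapiro_p(x: np.ndarray) -> float | None:
    """Shapiro-Wilk p, or None when the test is undefined (constant input)."""
    if np.ptp(x) == 0:
        return None
    return float(sps.shapiro(x).pvalue)


def gated_group_test(a, b, alpha: float = 0.05, variable: str = "") -> GroupTestResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha`` -> independent-samples t-test; otherwise
    (or if Shapiro is undefined for a constant group) the two-sided
    Mann-Whitney U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    note = ""
    if pa is None or pb is None:
        normal = False
        note = "constant group; normality test undefined, fell back to Mann-Whitney"
    else:
        normal = pa > alpha and pb > alpha
    if normal:
        res = sps.ttest_ind(a, b)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        u, p = mann_whitney_u(a, b)
        test, stat = "mann-whitney", u
    return GroupTestResult(variable, test, stat, float(p), None,
                           _summary(a), _summary(b), note)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U for the first group with a two-sided p.

    U counts pairs where a beats b (ties count one half). The p-value is
    exact for small samples without ties (min n <= 8) and otherwise uses the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_symptoms(raw, scale_min: float, scale_max: float) -> np.ndarray:
    """Min-max scale symptom scores to [0, 1], then z-score the sample.

    ``scale_min``/``scale_max`` are the lowest and highest scores the
    instrument allows (not the observed extremes), so the same instrument
    maps identically across sites; the z-step makes different instruments
    comparable when pooled.
    """
    x = np.asarray(raw, dtype=float)
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    if (x < scale_min).any() or (x > scale_max).any():
        bad = int(np.argwhere((x < scale_min) | (x > scale_max))[0, 0])
        raise ValueError(f"raw score outside the allowed range at index {bad}")
    unit = (x - scale_min) / (scale_max - scale_min)
    sd = unit.std(ddof=0)
    if sd == 0:
        raise ValueError("symptom scores are constant; cannot z-normalize")
    return (unit - unit.mean()) / sd


def correlate_symptoms(deviations: np.ndarray, symptoms, alpha: float = 0.05,
                       roi_names=None) -> pd.DataFrame:
    """Shapiro-gated per-region correlation between OIS and a symptom score.

    Symptoms normal at ``alpha`` -> Pearson's r, otherwise Spearman's rho.
    Returns a tidy frame (roi, type, coefficient, p, adjusted_p) with
    Benjamini-Hochberg adjustment across regions; zero-variance columns get
    a flagged NaN row.
    """
    dev = np.atleast_2d(np.asarray(deviations, dtype=float))
    s = np.asarray(symptoms, dtype=float)
    if dev.shape[0] != len(s):
        raise ValueError("deviations and symptoms must have the same n")
    if len(s) < 5:
        raise ValueError("need at least 5 paired observations")
    p_shapiro = _shapiro_p(s)
    use_pearson = p_shapiro is not None and p_shapiro > alpha
    kind = "pearson" if use_pearson else "spearman"
    rows = []
    names = roi_names if roi_names is not None else [f"roi_{j}" for j in range(dev.shape[1])]
    for j, name in enumerate(names):
        col = dev[:, j]
        if np.ptp(col) == 0 or np.ptp(s) == 0:
            rows.append((name, kind, np.nan, np.nan, "zero variance"))
            continue
        if use_pearson:
            r, p = sps.pearsonr(col, s)
        else:
            r, p = sps.spearmanr(col, s)
        rows.append((name, kind, float(r), float(p), ""))
    out = pd.DataFrame(rows, columns=["roi", "type", "coefficient", "p", "note"])
    valid = out["p"].notna()
    adjusted = np.full(len(out), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["adjusted_p"] = adjusted
    return out.loc[:, ["roi", "type", "coefficient", "p", "adjusted_p", "note"]]


def _pairwise_cosine(rows: np.ndarray) -> tuple[np.ndarray, int]:
    """Cosine similarity over all unordered row pairs; zero rows skipped."""
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    skipped_rows = (~ok).sum()
    x = rows[ok] / norms[ok][:, None]
    sims = x @ x.T
    iu = np.triu_indices(len(x), k=1)
    n_total_pairs = len(rows) * (len(rows) - 1) // 2
    n_kept_pairs = len(x) * (len(x) - 1) // 2
    return sims[iu], n_total_pairs - n_kept_pairs


def heterogeneity_cs(ois_matrix: np.ndarray, schema: RoiSchema
                     ) -> list[HeterogeneityResult]:
    """Mean pairwise cosine similarity of OIS profiles, overall and by group.

    Higher values mean participants deviate from the norm in more similar
    directions (a more homogeneous group). Cosines are computed on the
    signed OIS vectors, so negative similarities can occur.
    """
    x = np.asarray(ois_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an n x k matrix with n >= 2")
    if x.shape[1] != len(schema):
        raise ValueError(f"expected {len(schema)} columns, got {x.shape[1]}")
    name_to_col = {n: j for j, n in enumerate(schema.names)}
    results = []
    blocks = {"all": list(range(x.shape[1]))}
    blocks.update({g: [name_to_col[n] for n in names]
                   for g, names in schema.groups().items()})
    for label, cols in blocks.items():
        sims, n_skipped = _pairwise_cosine(x[:, cols])
        results.append(HeterogeneityResult(
            label,
            float(sims.mean()) if sims.size else np.nan,
            float(sims.std(ddof=1)) if sims.size > 1 else np.nan,
            x.shape[0] * (x.shape[0] - 1) // 2,
            int(n_skipped),
        ))
    return results


def bootstrap_median_diff_ci(a, b, reps: int = 1000, seed: int = 0,
                             level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Median difference a - b with a seeded percentile bootstrap CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs at least 5 observations")
    rng = np.random.default_rng(seed)
    diffs = np.empty(reps)
    for r in range(reps):
        diffs[r] = (np.median(rng.choice(a, size=len(a), replace=True))
                    - np.median(rng.choice(b, size=len(b), replace=True)))
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(diffs, [tail, 100 - tail])
    return float(np.median(a) - np.median(b)), (float(lo), float(hi))


def category_proportions(categories, groups=None) -> pd.DataFrame:
    """Proportion of participants in each OIS category, per group.

    Returns a frame indexed by group with one column per category present;
    rows sum to 1.
    """
    from .outliers import CATEGORY_NAMES
    cats = pd.Series(categories, dtype="object")
    grp = pd.Series(groups, dtype="object") if groups is not None else pd.Series(
        ["all"] * len(cats))
    frame = pd.crosstab(grp.to_numpy(), cats.to_numpy(), normalize="index")
    ordered = [c for c in CATEGORY_NAMES if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    frame = frame.loc[:, ordered + extra]
    frame.index.name = "group"
    return frame


def roi_group_tests(ois_a: np.ndarray, ois_b: np.ndarray, roi_names,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Region-wise gated group tests with Benjamini-Hochberg adjustment."""
    a = np.atleast_2d(np.asarray(ois_a, dtype=float))
    b = np.atleast_2d(np.asarray(ois_b, dtype=float))
    results = [gated_group_test(a[:, j], b[:, j], alpha, variable=name)
               for j, name in enumerate(roi_names)]
    adjusted = bh_adjust([r.p for r in results])
    rows = []
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
        rows.append((r.variable, r.test, r.statistic, r.p, r.adjusted_p,
                     r.summary_a["median"], r.summary_b["median"]))
    return pd.DataFrame(rows, columns=["roi", "test", "statistic", "p",
                                       "adjusted_p", "median_a", "median_b"])
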