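"""Scanner harmonization: empirical-Bayes ComBat and IQM-based correction
prediction for unseen scanners.

ComBat models each feature as grand mean + covariate effects + an additive
(location) and multiplicative (scale) batch effect, shrinks the per-batch
location/scale estimates toward pooled priors with parametric empirical
Bayes, and removes them while preserving the covariate effects.

ComBat needs every scanner represented at fit time. To harmonize data from
scanners never seen in training, a per-ROI random-forest regressor is trained
to predict the ComBat correction (corrected minus uncorrected value) from
image quality metrics plus covariates; at apply time only the IQMs are
needed, no batch label. Predictions are trustworthy only while the incoming
IQMs stay inside the range spanned in training, so out-of-range rows are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import Cohort


# ---------------------------------------------------------------------------
# ComBat

@dataclass
class CombatModel:
    """Fitted parametric EB ComBat parameters.

    All arrays are indexed over the k features; batch-level arrays over
    (n_batches, k). ``var_pooled`` is the pooled residual variance used for
    standardization; ``gamma_star``/``delta_star`` are the EB-shrunk additive
    and multiplicative batch effects in standardized units.
    """

    batches: list[str]
    grand_mean: np.ndarray
    beta: np.ndarray                 # (n_covariates, k) covariate coefficients
    var_pooled: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    covariate_names: list[str]

    def batch_index(self, labels) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.batches)}
        try:
            return np.array([lookup[b] for b in labels])
        except KeyError as err:
            raise KeyError(
                f"batch {err.args[0]!r} was not seen when ComBat was fitted; "
                "use the IQM-based harmonizer for unseen scanners"
            ) from None


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.zeros((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, tol=1e-6, max_iter=500):
    """Iterative conditional EB estimates for one batch (all features at once)."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0,
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def fit_combat(features: np.ndarray, batch, covariates=None,
               eb: bool = True) -> CombatModel:
    """Fit parametric empirical-Bayes ComBat.

    Parameters
    ----------
    features
        n x k matrix of (relative) volumes.
    batch
        length-n batch labels (scanner identifiers).
    covariates
        optional n x p biological covariate design (no intercept column;
        one is handled internally). Covariate effects are estimated jointly
        with batch means and preserved by the correction.
    eb
        if False, use the raw per-batch location/scale estimates without
        empirical-Bayes shrinkage (the "diffuse prior" limit).
    """
    y = np.asarray(features, dtype=float)
    batch = np.asarray(batch)
    n, k = y.shape
    batches = sorted(pd.unique(batch).tolist())
    if len(batches) < 2:
        import warnings
        warnings.warn("ComBat fitted on a single batch; corrections will be ~0",
                      stacklevel=2)
    counts = np.array([(batch == b).sum() for b in batches])
    if (counts < 3).any():
        small = [b for b, c in zip(batches, counts) if c < 3]
        raise ValueError(f"each batch needs >= 3 rows, too small: {small}")

    x_cov, cov_names = _design_matrix(covariates)
    onehot = np.stack([(batch == b).astype(float) for b in batches], axis=1)
    design = np.hstack([onehot, x_cov]) if x_cov.size else onehot
    # least-squares fit of batch means + covariate slopes
    bhat, *_ = np.linalg.lstsq(design, y, rcond=None)
    if x_cov.size:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError("rank-deficient covariate design")
    n_b = len(batches)
    grand_mean = (counts / n) @ bhat[:n_b]
    beta = bhat[n_b:]
    fitted = design @ bhat
    var_pooled = ((y - fitted) ** 2).mean(axis=0)
    if (var_pooled <= 0).any():
        raise ValueError("zero pooled variance on some feature; cannot standardize")

    stand_mean = grand_mean[None, :] + (x_cov @ beta if x_cov.size else 0.0)
    z = (y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.stack([z[batch == b].mean(axis=0) for b in batches])
    delta_hat = np.stack([z[batch == b].var(axis=0, ddof=1) for b in batches])
    if eb and n_b >= 2:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        g_bar = gamma_hat.mean(axis=0)
        t2 = gamma_hat.var(axis=0, ddof=1)
        for i, b in enumerate(batches):
            a, bb = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            gamma_star[i], delta_star[i] = _it_sol(
                z[batch == b], gamma_hat[i], delta_hat[i], g_bar, t2, a, bb)
    else:
        gamma_star, delta_star = gamma_hat, delta_hat
    return CombatModel(batches, grand_mean, beta, var_pooled,
                       gamma_star, delta_star, cov_names)


def apply_combat(model: CombatModel, features: np.ndarray, batch,
                 covariates=None) -> np.ndarray:
    """Remove fitted batch effects from ``features`` (batches must be seen)."""
    y = np.asarray(features, dtype=float)
    idx = model.batch_index(np.asarray(batch))
    x_cov, _ = _design_matrix(covariates)
    if len(model.covariate_names) != (x_cov.shape[1] if x_cov.size else 0):
        raise ValueError("covariates at apply time must match those at fit time")
    stand_mean = model.grand_mean[None, :] + (x_cov @ model.beta if x_cov.size else 0.0)
    z = (y - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    z_adj = (z - model.gamma_star[idx]) / np.sqrt(model.delta_star[idx])
    return z_adj * np.sqrt(model.var_pooled)[None, :] + stand_mean


# ---------------------------------------------------------------------------
# IQM-based correction prediction (Neuroharmony-style)

@dataclass
class HarmonizerModel:
    """Per-ROI random forests mapping IQMs (+ covariates) to ComBat corrections."""

    roi_names: list[str]
    predictor_names: list[str]
    covariate_set: tuple[str, ...]
    forests: list[RandomForestRegressor]
    iqm_ranges: pd.DataFrame          # index = IQM predictors, columns min/max
    mean_correction: np.ndarray       # per-ROI mean training correction


def _predictor_frame(cohort: Cohort, covariate_set) -> pd.DataFrame:
    cols = list(cohort.iqm_columns)
    if not cols:
        raise KeyError("cohort has no iqm_* columns")
    frame = cohort.data.loc[:, cols].copy()
    for cov in covariate_set:
        if cov == "age":
            frame["age"] = cohort.data["age"].to_numpy(dtype=float)
        elif cov == "sex":
            frame["sex"] = cohort.sex_codes().astype(float)
        else:
            raise ValueError(f"unsupported covariate {cov!r}; use 'age' and/or 'sex'")
    return frame


def fit_harmonizer(cohort: Cohort, combat_model: CombatModel,
                   covariate_set: tuple[str, ...] = ("age", "sex"),
                   n_estimators: int = 500, seed: int = 0,
                   n_jobs: int = 1) -> HarmonizerModel:
    """Learn to predict ComBat corrections from image quality metrics.

    The target for ROI j is the ComBat-corrected minus the uncorrected value
    on the training rows; one forest is trained per ROI on the shared
    predictor block (all IQMs plus the chosen covariates). Two variants are
    conventional: ``("age", "sex")`` for the outlier-model path and
    ``("sex",)`` for the brain-age path.
    """
    x = _predictor_frame(cohort, covariate_set)
    cov_frame = x.loc[:, list(covariate_set)] if covariate_set else None
    raw = cohort.volumes.to_numpy(dtype=float)
    corrected = apply_combat(combat_model, raw, cohort.data["scanner"].to_numpy(),
                             covariates=cov_frame)
    target = corrected - raw
    forests = []
    xv = x.to_numpy(dtype=float)
    for j in range(raw.shape[1]):
        rf = RandomForestRegressor(n_estimators=n_estimators,
                                   random_state=seed + j, n_jobs=n_jobs)
        rf.fit(xv, target[:, j])
        forests.append(rf)
    iqm_cols = [c for c in x.columns if c.startswith("iqm_")]
    ranges = pd.DataFrame({"min": x[iqm_cols].min(), "max": x[iqm_cols].max()})
    return HarmonizerModel(list(cohort.schema.names), list(x.columns),
                           tuple(covariate_set), forests, ranges,
                           target.mean(axis=0))


def apply_harmonizer(model: HarmonizerModel, cohort: Cohort
                     ) -> tuple[Cohort, pd.DataFrame]:
    """Predict and add per-ROI corrections; flag out-of-range IQMs.

    Returns the harmonized cohort and a report with one row per participant:
    ``out_of_range`` (any IQM outside the training envelope) and the names of
    offending metrics. Rows are corrected regardless of the flag — the flag
    is a warning that the predicted correction is an extrapolation.
    """
    x = _predictor_frame(cohort, model.covariate_set)
    missing = [c for c in model.predictor_names if c not in x.columns]
    if missing:
        raise KeyError(f"cohort lacks predictors required by the harmonizer: {missing}")
    x = x.loc[:, model.predictor_names]
    xv = x.to_numpy(dtype=float)
    corrections = np.column_stack([rf.predict(xv) for rf in model.forests])
    harmonized = cohort.volumes.to_numpy(dtype=float) + corrections
    out = cohort.with_volumes(harmonized, "harmonized")

    iqm_cols = model.iqm_ranges.index
    lo = model.iqm_ranges["min"].to_numpy()
    hi = model.iqm_ranges["max"].to_numpy()
    vals = x.loc[:, iqm_cols].to_numpy(dtype=float)
    outside = (vals < lo[None, :]) | (vals > hi[None, :])
    report = pd.DataFrame({
        "id": cohort.ids.to_numpy(),
        "out_of_range": outside.any(axis=1),
        "offending_iqms": [
            ",".join(np.asarray(iqm_cols)[row]) if row.any() else ""
            for row in outside
        ],
    })
    return out, report
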