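"""Brain-age prediction with linear support vector regression.

Harmonized, z-scaled relative volumes are regressed on chronological age
with an epsilon-insensitive linear SVR (epsilon = 0.1, stopping tolerance
1e-3). The regularization constant C is chosen by seeded ten-fold
cross-validated grid search over {2^-7, 2^-5, 2^-3, 2^-2, 2^-1, 2^0, 2^1},
scored by mean absolute error; ties go to the smaller C (stronger
regularization). The brain-age gap (BAG) is predicted minus chronological
age, and is additionally z-normalized by the training-set BAG mean and SD.

No age-bias correction is applied by default: because the SVR shrinks
predictions toward the mean age, young ages are over- and old ages
under-predicted, so raw BAG correlates negatively with age. A helper to
residualize BAG on age is provided for downstream analyses that want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

C_GRID = (2.0**-7, 2.0**-5, 2.0**-3, 2.0**-2, 2.0**-1, 2.0**0, 2.0**1)
EPSILON = 0.1
TOL = 1e-3


@dataclass
class BrainAgeModel:
    scaler: StandardScaler
    svr: SVR
    selected_c: float
    cv_results: dict[float, float]      # C -> mean CV MAE
    bag_mean: float                     # training-set raw BAG moments
    bag_sd: float

    def __post_init__(self) -> None:
        if self.bag_sd <= 0:
            raise ValueError("training BAG SD must be positive")


def _check_features(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if not np.isfinite(x).all():
        bad = int(np.argwhere(~np.isfinite(x).all(axis=1))[0, 0])
        raise ValueError(f"non-finite feature in row {bad}")
    return x


def train_brain_age(features: np.ndarray, ages: np.ndarray, seed: int = 0,
                    n_folds: int = 10, c_grid=C_GRID) -> BrainAgeModel:
    """Fit the scaler and SVR with cross-validated C selection."""
    x = _check_features(features)
    y = np.asarray(ages, dtype=float)
    if len(x) != len(y):
        raise ValueError("features and ages length mismatch")
    if len(x) < 20:
        raise ValueError("need at least 20 training rows")
    if not np.isfinite(y).all():
        raise ValueError("ages must be finite")
    if len(x) < n_folds:
        import warnings
        warnings.warn(f"reducing folds from {n_folds} to {len(x)}", stacklevel=2)
        n_folds = len(x)

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xs))
    cv_results: dict[float, float] = {}
    for c in c_grid:
        fold_mae = []
        for tr, te in splits:
            model = SVR(kernel="linear", C=c, epsilon=EPSILON, tol=TOL)
            model.fit(xs[tr], y[tr])
            fold_mae.append(np.abs(model.predict(xs[te]) - y[te]).mean())
        cv_results[c] = float(np.mean(fold_mae))
    # ties broken toward the smaller C: iterate the grid in ascending order
    best_c = min(sorted(cv_results), key=lambda c: (cv_results[c], c))
    svr = SVR(kernel="linear", C=best_c, epsilon=EPSILON, tol=TOL)
    svr.fit(xs, y)
    train_bag = svr.predict(xs) - y
    sd = float(train_bag.std(ddof=0))
    return BrainAgeModel(scaler, svr, best_c, cv_results,
                         float(train_bag.mean()), sd)


def predict_brain_age(model: BrainAgeModel, features: np.ndarray) -> np.ndarray:
    """Predicted ages; a pure, order-equivariant function of the features."""
    x = _check_features(features)
    return model.svr.predict(model.scaler.transform(x))


def compute_bag(predicted: np.ndarray, chronological: np.ndarray,
                model: BrainAgeModel) -> tuple[np.ndarray, np.ndarray]:
    """Raw and train-normalized brain-age gap.

    Raw BAG = predicted - chronological (positive = older-appearing brain,
    'accelerated' ageing). Normalized BAG is the raw gap z-scored with the
    training-set BAG mean and SD stored in the model.
    """
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if pred.shape != chron.shape:
        raise ValueError("predicted and chronological ages must align")
    raw = pred - chron
    return raw, (raw - model.bag_mean) / model.bag_sd


def evaluate_mae(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and the SD of the absolute errors (MAE ± SD)."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.size == 0 or pred.shape != act.shape:
        raise ValueError("need equal-length, non-empty prediction/actual vectors")
    abs_err = np.abs(pred - act)
    return float(abs_err.mean()), float(abs_err.std(ddof=0))


def residualize_bag_on_age(raw_bag: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Optional age-bias adjustment: residuals of BAG regressed on age.

    Off by default in all pipelines; intended for downstream analyses that
    need BAG decorrelated from chronological age.
    """
    a = np.asarray(ages, dtype=float)
    b = np.asarray(raw_bag, dtype=float)
    slope, intercept = np.polyfit(a, b, 1)
    return b - (slope * a + intercept)
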