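"""Model persistence: JSON metadata next to array/estimator containers.

Each model saves into a directory holding a human-readable ``model.json``
(versioned metadata: what the model is, its configuration, covariates,
cut-offs) plus the numeric payload — an ``.npz`` archive for the numpy
networks and scalings, a joblib file for scikit-learn estimators.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from . import __version__
from .brain_age import BrainAgeModel
from .harmonize import CombatModel, HarmonizerModel
from .outliers import AAEConfig, AAEModel, OisScaling, RobustScaler, _MLP


def _write_meta(path: Path, kind: str, extra: dict) -> None:
    meta = {"kind": kind, "neuronorm_version": __version__, **extra}
    (path / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_meta(path: Path, kind: str) -> dict:
    meta = json.loads((path / "model.json").read_text())
    if meta.get("kind") != kind:
        raise ValueError(f"{path} holds a {meta.get('kind')!r} model, expected {kind!r}")
    return meta


def _mlp_arrays(prefix: str, mlp: _MLP) -> dict:
    out = {}
    for i, (w, b) in enumerate(zip(mlp.W, mlp.b)):
        out[f"{prefix}_W{i}"] = w
        out[f"{prefix}_b{i}"] = b
    return out


def _mlp_from_arrays(prefix: str, payload) -> _MLP:
    mlp = _MLP.__new__(_MLP)
    mlp.W, mlp.b = [], []
    i = 0
    while f"{prefix}_W{i}" in payload:
        mlp.W.append(payload[f"{prefix}_W{i}"])
        mlp.b.append(payload[f"{prefix}_b{i}"])
        i += 1
    return mlp


def save_aae(model: AAEModel, scaling: OisScaling | None, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"scaler_center": model.scaler.center, "scaler_scale": model.scaler.scale}
    for prefix, net in (("enc", model.encoder), ("dec", model.decoder),
                        ("disc", model.discriminator)):
        arrays.update(_mlp_arrays(prefix, net))
    meta = {"config": model.config.__dict__.copy(), "loss_history": model.loss_history,
            "has_scaling": scaling is not None}
    meta["config"]["encoder_hidden"] = list(model.config.encoder_hidden)
    meta["config"]["discriminator_hidden"] = list(model.config.discriminator_hidden)
    if scaling is not None:
        arrays.update(roi_median=scaling.roi_median, roi_iqr=scaling.roi_iqr)
        meta["ois"] = {"overall_median": scaling.overall_median,
                       "overall_iqr": scaling.overall_iqr,
                       "cutoffs": list(scaling.cutoffs)}
    np.savez(path / "arrays.npz", **arrays)
    _write_meta(path, "aae", meta)


def load_aae(path) -> tuple[AAEModel, OisScaling | None]:
    path = Path(path)
    meta = _read_meta(path, "aae")
    payload = np.load(path / "arrays.npz")
    cfg = dict(meta["config"])
    cfg["encoder_hidden"] = tuple(cfg["encoder_hidden"])
    cfg["discriminator_hidden"] = tuple(cfg["discriminator_hidden"])
    model = AAEModel(
        scaler=RobustScaler(payload["scaler_center"], payload["scaler_scale"]),
        encoder=_mlp_from_arrays("enc", payload),
        decoder=_mlp_from_arrays("dec", payload),
        discriminator=_mlp_from_arrays("disc", payload),
        config=AAEConfig(**cfg),
        loss_history=meta.get("loss_history", {}),
    )
    scaling = None
    if meta.get("has_scaling"):
        o = meta["ois"]
        scaling = OisScaling(payload["roi_median"], payload["roi_iqr"],
                             o["overall_median"], o["overall_iqr"],
                             tuple(o["cutoffs"]))
    return model, scaling


def save_combat(model: CombatModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "arrays.npz", grand_mean=model.grand_mean, beta=model.beta,
             var_pooled=model.var_pooled, gamma_star=model.gamma_star,
             delta_star=model.delta_star)
    _write_meta(path, "combat", {"batches": model.batches,
                                 "covariates": model.covariate_names})


def load_combat(path) -> CombatModel:
    path = Path(path)
    meta = _read_meta(path, "combat")
    p = np.load(path / "arrays.npz")
    return CombatModel(meta["batches"], p["grand_mean"], p["beta"], p["var_pooled"],
                       p["gamma_star"], p["delta_star"], meta["covariates"])


def save_harmonizer(model: HarmonizerModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump({"forests": model.forests, "iqm_ranges": model.iqm_ranges,
                 "mean_correction": model.mean_correction}, path / "estimators.joblib")
    _write_meta(path, "harmonizer", {
        "roi_names": model.roi_names, "predictors": model.predictor_names,
        "covariate_set": list(model.covariate_set)})


def load_harmonizer(path) -> HarmonizerModel:
    path = Path(path)
    meta = _read_meta(path, "harmonizer")
    blob = joblib.load(path / "estimators.joblib")
    return HarmonizerModel(meta["roi_names"], meta["predictors"],
                           tuple(meta["covariate_set"]), blob["forests"],
                           blob["iqm_ranges"], blob["mean_correction"])


def save_brain_age(model: BrainAgeModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump({"scaler": model.scaler, "svr": model.svr}, path / "estimators.joblib")
    _write_meta(path, "brain_age", {
        "selected_c": model.selected_c,
        "cv_results": {str(c): mae for c, mae in model.cv_results.items()},
        "bag_mean": model.bag_mean, "bag_sd": model.bag_sd})


def load_brain_age(path) -> BrainAgeModel:
    path = Path(path)
    meta = _read_meta(path, "brain_age")
    blob = joblib.load(path / "estimators.joblib")
    return BrainAgeModel(blob["scaler"], blob["svr"], float(meta["selected_c"]),
                         {float(c): m for c, m in meta["cv_results"].items()},
                         float(meta["bag_mean"]), float(meta["bag_sd"]))
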