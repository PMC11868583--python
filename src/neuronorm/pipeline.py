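"""End-to-end orchestration: simulate -> prep -> harmonize -> train -> score
-> analyze -> report, driven by one config mapping and one seed.

The pipeline trains on the healthy-control portion of the cohort (after the
standard cleaning rules) and scores every participant not used in training.
Two harmonizer variants are fitted, as the two downstream models require
different covariate handling: age+sex for the outlier path, sex only for
brain age.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .brain_age import BrainAgeModel, compute_bag, predict_brain_age, train_brain_age
from .core import Cohort, compute_relative_volumes, write_cohort
from .harmonize import (CombatModel, HarmonizerModel, apply_harmonizer,
                        fit_combat, fit_harmonizer)
from .outliers import (AAEConfig, AAEModel, OisScaling, categorize_ois,
                       compute_ois, fit_ois_scaling, reconstruction_errors,
                       train_aae)
from .prep import prepare_training_cohort
from .report import build_report, render_report
from .simulate import DiseaseSpec, SimConfig, simulate_cohort
from .stats import (bootstrap_median_diff_ci, category_proportions,
                    gated_group_test, heterogeneity_cs, roi_group_tests)

log = logging.getLogger("neuronorm")


@dataclass
class TrainedModels:
    combat_ois: CombatModel
    harmonizer_ois: HarmonizerModel
    combat_ba: CombatModel
    harmonizer_ba: HarmonizerModel
    aae: AAEModel
    ois_scaling: OisScaling
    brain_age: BrainAgeModel


def train_models(train_rel: Cohort, seed: int = 0,
                 aae_config: AAEConfig | None = None,
                 n_estimators: int = 500, n_folds: int = 10) -> TrainedModels:
    """Fit harmonization, the normative AAE and the brain-age model.

    ``train_rel`` must hold relative volumes from a cleaned healthy cohort
    spanning at least two scanners.
    """
    if train_rel.feature_kind != "relative":
        raise ValueError("training cohort must hold relative volumes")
    scanners = train_rel.data["scanner"].to_numpy()
    rel = train_rel.volumes.to_numpy(dtype=float)
    age = train_rel.data["age"].to_numpy(dtype=float)
    sex = train_rel.sex_codes().astype(float)

    log.info("fitting ComBat + harmonizer (age+sex covariates) on %d rows", len(train_rel))
    cov_ois = pd.DataFrame({"age": age, "sex": sex})
    combat_ois = fit_combat(rel, scanners, cov_ois)
    harm_ois = fit_harmonizer(train_rel, combat_ois, ("age", "sex"),
                              n_estimators=n_estimators, seed=seed)

    log.info("fitting ComBat + harmonizer (sex covariate) for brain age")
    cov_ba = pd.DataFrame({"sex": sex})
    combat_ba = fit_combat(rel, scanners, cov_ba)
    harm_ba = fit_harmonizer(train_rel, combat_ba, ("sex",),
                             n_estimators=n_estimators, seed=seed + 1)

    train_ois, _ = apply_harmonizer(harm_ois, train_rel)
    train_ba, _ = apply_harmonizer(harm_ba, train_rel)

    cfg = aae_config or AAEConfig(seed=seed)
    log.info("training AAE (latent %d, epochs <= %d)", cfg.latent_dim, cfg.epochs)
    aae = train_aae(train_ois.volumes.to_numpy(dtype=float), cfg)
    roi_err, overall_err = reconstruction_errors(aae, train_ois.volumes.to_numpy(dtype=float))
    scaling = fit_ois_scaling(roi_err, overall_err)

    log.info("training brain-age SVR with %d-fold CV", n_folds)
    ba_model = train_brain_age(train_ba.volumes.to_numpy(dtype=float), age,
                               seed=seed, n_folds=n_folds)
    return TrainedModels(combat_ois, harm_ois, combat_ba, harm_ba, aae,
                         scaling, ba_model)


def score_cohort(models: TrainedModels, cohort_rel: Cohort) -> pd.DataFrame:
    """Score a relative-volume cohort: OIS (overall, per ROI) and brain age."""
    harm_ois, flags = apply_harmonizer(models.harmonizer_ois, cohort_rel)
    harm_ba, _ = apply_harmonizer(models.harmonizer_ba, cohort_rel)
    roi_err, overall_err = reconstruction_errors(
        models.aae, harm_ois.volumes.to_numpy(dtype=float))
    roi_ois, overall_ois = compute_ois(roi_err, overall_err, models.ois_scaling)
    predicted = predict_brain_age(models.brain_age, harm_ba.volumes.to_numpy(dtype=float))
    raw_bag, norm_bag = compute_bag(predicted, cohort_rel.data["age"].to_numpy(dtype=float),
                                    models.brain_age)
    out = pd.DataFrame({
        "id": cohort_rel.ids.to_numpy(),
        "age": cohort_rel.data["age"].to_numpy(dtype=float),
        "diagnosis": cohort_rel.data["diagnosis"].to_numpy(),
        "predicted_age": predicted,
        "raw_bag": raw_bag,
        "normalized_bag": norm_bag,
        "overall_ois": overall_ois,
        "category": categorize_ois(overall_ois, models.ois_scaling.cutoffs),
        "iqm_out_of_range": flags["out_of_range"].to_numpy(),
    })
    roi_frame = pd.DataFrame(roi_ois,
                             columns=[f"ois_{n}" for n in cohort_rel.schema.names])
    return pd.concat([out, roi_frame], axis=1)


def analyze_scores(scores: pd.DataFrame, schema, patient_label: str,
                   control_label: str = "HC", seed: int = 0,
                   bootstrap_reps: int = 1000) -> dict:
    """Patient-vs-control statistics on a score table from :func:`score_cohort`."""
    pat = scores[scores["diagnosis"] == patient_label]
    ctl = scores[scores["diagnosis"] == control_label]
    if len(pat) < 5 or len(ctl) < 5:
        raise ValueError("need at least 5 patients and 5 controls to analyze")
    ois_cols = [f"ois_{n}" for n in schema.names]

    overall = gated_group_test(pat["overall_ois"], ctl["overall_ois"],
                               variable="overall_ois")
    bag = gated_group_test(pat["normalized_bag"], ctl["normalized_bag"],
                           variable="normalized_bag")
    roi = roi_group_tests(pat[ois_cols].to_numpy(), ctl[ois_cols].to_numpy(),
                          list(schema.names))
    med_diff, ci = bootstrap_median_diff_ci(
        pat["overall_ois"].to_numpy(), ctl["overall_ois"].to_numpy(),
        reps=bootstrap_reps, seed=seed)
    props = category_proportions(scores["category"], scores["diagnosis"])
    het = {
        label: [dataclasses.asdict(h) for h in
                heterogeneity_cs(grp[ois_cols].to_numpy(), schema)]
        for label, grp in (("patients", pat), ("controls", ctl)) if len(grp) >= 2
    }
    return {
        "overall_ois": dataclasses.asdict(overall),
        "normalized_bag": dataclasses.asdict(bag),
        "roi_tests": roi.to_dict(orient="records"),
        "overall_ois_median_difference": {"estimate": med_diff, "ci95": list(ci)},
        "category_proportions": {str(g): row.to_dict() for g, row in props.iterrows()},
        "heterogeneity": het,
    }


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the whole pipeline from a config mapping; returns a summary dict.

    Writes, under ``out_dir``: the simulated cohort, the cleaned training
    cohort, the score table for held-out participants, the analysis JSON and
    one JSON report per scored participant. Fixed config + seed reproduce
    every output byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg.get("seed", 0))
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
    log.info("pipeline start (seed=%d, config sha256:%s)", seed, cfg_hash)

    sim_kwargs = dict(cfg.get("simulate", {}))
    disease = sim_kwargs.pop("disease", None)
    if disease is not None and not isinstance(disease, DiseaseSpec):
        disease = DiseaseSpec(**disease)
    sim = SimConfig(seed=seed, disease=disease, **sim_kwargs)
    cohort, truth = simulate_cohort(sim)
    write_cohort(cohort, out_dir / "cohort.csv")

    rel = compute_relative_volumes(cohort)
    hc = rel.subset((rel.data["diagnosis"] == "HC").to_numpy())
    prep_kwargs = dict(cfg.get("prep", {}))
    train_rel, logs = prepare_training_cohort(hc, seed=seed, **prep_kwargs)
    write_cohort(train_rel, out_dir / "train_clean.csv")
    (out_dir / "exclusions.json").write_text(json.dumps(
        {lg.rule: lg.excluded_ids for lg in logs}, indent=1))

    # hold out a fraction of clean HC for scoring alongside patients
    rng = np.random.default_rng(seed)
    ids = train_rel.ids.sort_values().to_numpy()
    holdout_frac = float(cfg.get("holdout_fraction", 0.2))
    n_hold = int(round(holdout_frac * len(ids)))
    holdout_ids = set(rng.choice(ids, size=n_hold, replace=False))
    fit_cohort = train_rel.subset(~train_rel.ids.isin(holdout_ids).to_numpy())

    models = train_models(
        fit_cohort, seed=seed,
        aae_config=AAEConfig(seed=seed, **cfg.get("outlier", {})),
        n_estimators=int(cfg.get("harmonize", {}).get("n_estimators", 500)),
        n_folds=int(cfg.get("brain_age", {}).get("n_folds", 10)),
    )

    scored_mask = (rel.ids.isin(holdout_ids) | (rel.data["diagnosis"] != "HC")).to_numpy()
    score_rel = rel.subset(scored_mask)
    scores = score_cohort(models, score_rel)
    scores.to_csv(out_dir / "scores.csv", index=False, float_format="%.17g")

    summary = {"seed": seed, "config_hash": cfg_hash,
               "n_simulated": len(cohort), "n_train": len(fit_cohort),
               "n_scored": len(scores),
               "selected_c": models.brain_age.selected_c}
    labels = [l for l in pd.unique(scores["diagnosis"]) if l != "HC" and pd.notna(l)]
    if labels and (scores["diagnosis"] == "HC").sum() >= 5:
        analysis = analyze_scores(scores, rel.schema, patient_label=labels[0],
                                  seed=seed,
                                  bootstrap_reps=int(cfg.get("analyze", {})
                                                     .get("bootstrap_reps", 1000)))
        (out_dir / "analysis.json").write_text(
            json.dumps(analysis, indent=1, sort_keys=True, default=float))
        summary["analysis"] = {"overall_ois_p": analysis["overall_ois"]["p"]}

    top_n = int(cfg.get("report", {}).get("top_n", 10))
    report_dir = out_dir / "reports"
    report_dir.mkdir(exist_ok=True)
    ois_cols = [f"ois_{n}" for n in rel.schema.names]
    for _, row in scores.iterrows():
        rep = build_report(
            row["id"], chronological_age=row["age"],
            predicted_age=row["predicted_age"], raw_bag=row["raw_bag"],
            normalized_bag=row["normalized_bag"], overall_ois=row["overall_ois"],
            roi_ois=row[ois_cols].to_numpy(dtype=float),
            roi_names=list(rel.schema.names),
            cutoffs=models.ois_scaling.cutoffs, top_n=top_n,
            metadata={"seed": seed, "config_hash": cfg_hash},
        )
        (report_dir / f"{row['id']}.json").write_text(render_report(rep, "json"))

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    log.info("pipeline done: %d scored", len(scores))
    return summary
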