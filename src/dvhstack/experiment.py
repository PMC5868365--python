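"""Replicated robustness experiments over the four scenario presets.

For each replicate a fresh contaminated training cohort and clean
validation cohort are drawn, the stacked ensemble and each individual base
learner are trained, and validation wRMSE is recorded per (replicate,
model). Individual learners are trained conventionally — penalty chosen by
cross-validation on the whole (unfiltered) training set — so the comparison
isolates what stacking plus filtering buys.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import DVHPrincipalComponents, WeightScheme
from .ensemble import compare_models, _fold_seed
from .learners import (
    FeatureStandardizer,
    make_learner,
    penalty_magnitude_grid,
    select_penalty,
)
from .io import RunConfig
from .synthetic import CohortConfig, ScenarioData, scenario_preset

logger = logging.getLogger("dvhstack")

__all__ = ["fit_individual_models", "predict_individual", "run_replicate",
           "run_experiment"]


def fit_individual_models(X: np.ndarray, V: np.ndarray, config: RunConfig,
                          seed: int, dose_grid: np.ndarray):
    """Fit each base learner standalone (no filtering, no stacking).

    Shares one PCA basis fitted to the training curves; returns
    (basis, standardizer, {name: [model per component]}).
    """
    basis = DVHPrincipalComponents(n_components=config.n_pc).fit(
        V, dose_grid=dose_grid)
    Y = basis.transform(V)
    sc = FeatureStandardizer().fit(X)
    Xz = sc.transform(X)
    banks: dict[str, list] = {}
    for j, spec in enumerate(config.learner_specs()):
        bank = []
        for c in range(config.n_pc):
            grid = penalty_magnitude_grid(Xz, Y[:, c], config.penalty_grid_size)
            resolved = select_penalty(Xz, Y[:, c], spec, grid=grid,
                                      n_folds=min(config.penalty_cv_folds, X.shape[0]),
                                      seed=_fold_seed(seed, 3, c, j))
            bank.append(make_learner(resolved).fit(Xz, Y[:, c]))
        banks[spec.name] = bank
    return basis, sc, banks


def predict_individual(basis, scaler, bank, X_new: np.ndarray) -> np.ndarray:
    """Decode one standalone learner's predicted PCS into curves."""
    Xz = scaler.transform(X_new)
    S = np.column_stack([m.predict(Xz) for m in bank])
    return basis.inverse_transform(S)


def run_replicate(scenario: ScenarioData, config: RunConfig, seed: int):
    """Train ensemble + individual models on one replicate; return predictions.

    Returns (models dict name -> validation curve matrix, fitted ensemble).
    """
    train, val = scenario.train, scenario.validation
    est = config.make_estimator(seed=seed)
    est.fit(train.features, train.curves, dose_grid=train.dose_grid,
            prescription_dose=train.prescription_dose,
            case_ids=train.case_ids)
    models = {"ensemble": est.predict(val.features)}
    basis, sc, banks = fit_individual_models(
        train.features, train.curves, config, seed, train.dose_grid)
    for name, bank in banks.items():
        models[name] = predict_individual(basis, sc, bank, val.features)
    return models, est


def run_experiment(scenario_name: str, config: RunConfig, n_replicates: int = 20,
                   base_config: CohortConfig | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Run one scenario for several seeded replicates.

    Replicate r uses seed ``config.seed + r``. Returns a dict with a
    per-(replicate, model) wRMSE table, per-replicate filter recall, and
    paired-test summaries; optionally writes them under ``out_dir``.
    """
    rows, recall_rows, test_rows = [], [], []
    for r in range(n_replicates):
        seed = config.seed + r
        scenario = scenario_preset(scenario_name, seed=seed, base_config=base_config)
        scheme = WeightScheme(kind=scenario.scheme_kind)
        models, est = run_replicate(scenario, config, seed)
        val = scenario.validation
        per_case, summary, tests = compare_models(
            models, val.curves, val.dose_grid, scheme,
            prescription_dose=val.prescription_dose, reference="ensemble")
        for name in per_case.columns:
            rows.append({"replicate": r, "seed": seed, "model": name,
                         "mean_wrmse": float(per_case[name].mean()),
                         "median_wrmse": float(per_case[name].median())})
        for rec in tests.to_dict(orient="records"):
            rec.update(replicate=r, seed=seed)
            test_rows.append(rec)
        injected = set(scenario.train.case_ids[scenario.outlier_indices])
        removed = set(est.filter_report_["case_id"])
        n_inj = len(injected)
        recall_rows.append({
            "replicate": r, "seed": seed, "n_injected": n_inj,
            "n_removed": len(removed),
            "n_recovered": len(injected & removed),
            "recall": (len(injected & removed) / n_inj) if n_inj else np.nan})
        logger.info("scenario=%s replicate=%d seed=%d ensemble_mean_wrmse=%.5f",
                    scenario_name, r, seed,
                    rows[-len(per_case.columns)]["mean_wrmse"])
    report = pd.DataFrame(rows)
    recall = pd.DataFrame(recall_rows)
    tests = pd.DataFrame(test_rows)
    summary = {
        "scenario": scenario_name,
        "n_replicates": n_replicates,
        "seed": config.seed,
        "mean_wrmse_by_model": report.groupby("model")["mean_wrmse"].mean().to_dict(),
        "mean_filter_recall": float(recall["recall"].mean()) if n_replicates else None,
    }
    result = {"report": report, "filter_recall": recall, "tests": tests,
              "summary": summary}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / f"{scenario_name}_wrmse.csv", index=False)
        recall.to_csv(out / f"{scenario_name}_filter_recall.csv", index=False)
        tests.to_csv(out / f"{scenario_name}_paired_tests.csv", index=False)
        (out / f"{scenario_name}_summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1))
    return result
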