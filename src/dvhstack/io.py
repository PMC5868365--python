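"""Delimited-text readers/writers, model serialization, and run configuration.

Feature tables, DVH tables and label files are plain CSV with a case-ID
first column; DVH column headers carry the dose grid in Gy. Fitted models
serialize to a single human-auditable JSON document (basis, standardization,
per-component learner banks and stacking weights). Floats are written with
17 significant digits so write-then-read round trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dvh import DVHPrincipalComponents, WeightScheme
from .ensemble import DVHStackingEnsemble
from .learners import (
    BaseLearnerSpec,
    FeatureStandardizer,
    ForwardStepwiseOLS,
    PenalizedLinearModel,
    default_learner_bank,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_dvh_table",
    "write_dvh_table",
    "read_labels",
    "write_labels",
    "check_case_ids",
    "save_model",
    "load_model",
    "save_basis",
    "load_basis",
    "load_config",
    "save_config",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A delimited input file is malformed; the message names the line."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "case_id":
        raise ParseError(f"{path}: first column must be 'case_id', got {df.columns[0]!r}")
    return df


def _numeric(df: pd.DataFrame, path, skip: tuple[str, ...] = ()) -> pd.DataFrame:
    out = df.copy()
    for col in df.columns:
        if col == "case_id" or col in skip:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ParseError(
                f"{path}, line {line}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r}")
        out[col] = vals
    return out


def read_feature_table(path) -> pd.DataFrame:
    """CSV with header ``case_id,<feature names...>`` -> DataFrame indexed by case."""
    df = _numeric(_read_csv(path), path)
    return df.set_index("case_id")


def write_feature_table(path, features: np.ndarray, case_ids,
                        feature_names: list[str] | None = None) -> None:
    features = np.atleast_2d(np.asarray(features, dtype=float))
    names = feature_names or [f"f{j + 1}" for j in range(features.shape[1])]
    df = pd.DataFrame(features, columns=names)
    df.insert(0, "case_id", list(case_ids))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dvh_table(path) -> tuple[pd.DataFrame, np.ndarray]:
    """DVH CSV -> (DataFrame indexed by case with a prescription_gy column
    plus one column per grid point, dose grid array)."""
    df = _numeric(_read_csv(path), path)
    if "prescription_gy" not in df.columns:
        raise ParseError(f"{path}: missing 'prescription_gy' column")
    dose_cols = [c for c in df.columns if c not in ("case_id", "prescription_gy")]
    try:
        grid = np.array([float(c) for c in dose_cols])
    except ValueError as exc:
        raise ParseError(f"{path}: DVH column headers must be dose values in Gy") from exc
    if np.any(np.diff(grid) <= 0):
        raise ParseError(f"{path}: dose-grid headers must be strictly increasing")
    return df.set_index("case_id"), grid


def write_dvh_table(path, curves: np.ndarray, dose_grid: np.ndarray,
                    case_ids, prescription_dose) -> None:
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    grid = np.asarray(dose_grid, dtype=float)
    df = pd.DataFrame(curves, columns=[_FLOAT_FMT % d for d in grid])
    df.insert(0, "prescription_gy", np.broadcast_to(
        np.asarray(prescription_dose, dtype=float), (curves.shape[0],)).copy())
    df.insert(0, "case_id", list(case_ids))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path) -> pd.Series:
    df = _read_csv(path)
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing 'label' column")
    return df.set_index("case_id")["label"]


def write_labels(path, labels, case_ids) -> None:
    pd.DataFrame({"case_id": list(case_ids), "label": list(labels)}).to_csv(
        path, index=False)


def check_case_ids(*indexed) -> None:
    """Raise if the case-ID sets of several tables differ, naming offenders."""
    sets = [set(obj.index) for obj in indexed]
    union = set.union(*sets)
    common = set.intersection(*sets)
    if union != common:
        raise ParseError(
            f"case-ID mismatch across files; not shared by all: "
            f"{sorted(union - common)}")


# ---------------------------------------------------------------------------
# model serialization

def _learner_to_dict(model) -> dict:
    d = {"coef": list(model.coef_), "intercept": model.intercept_}
    if isinstance(model, ForwardStepwiseOLS):
        d["kind"] = "stepwise"
        d["p_enter"] = model.p_enter
        d["selected_features"] = list(model.selected_features_)
    else:
        d["kind"] = model.kind
        d["lambda1"] = model.lambda1
        d["lambda2"] = model.lambda2
    return d


def _learner_from_dict(d: dict):
    if d["kind"] == "stepwise":
        m = ForwardStepwiseOLS(p_enter=d["p_enter"])
        m.selected_features_ = tuple(d["selected_features"])
    else:
        m = PenalizedLinearModel(kind=d["kind"], lambda1=d["lambda1"],
                                 lambda2=d["lambda2"])
    m.coef_ = np.asarray(d["coef"], dtype=float)
    m.intercept_ = float(d["intercept"])
    m.n_features_in_ = len(d["coef"])
    return m


def save_model(path, model: DVHStackingEnsemble) -> None:
    """Serialize a fitted ensemble to an auditable JSON document."""
    doc = {
        "format": "dvhstack-ensemble-v1",
        "dose_grid": list(model.dose_grid_),
        "prescription_dose": model.prescription_dose_,
        "basis": {
            "n_components": int(model.basis_.components_.shape[0]),
            "mean": list(model.basis_.mean_),
            "components": [list(c) for c in model.basis_.components_],
            "explained_variance": list(model.basis_.explained_variance_),
        },
        "scaler": {"mean": list(model.scaler_.mean_),
                   "scale": list(model.scaler_.scale_)},
        "alpha": [list(a) for a in model.alpha_],
        "learner_names": list(model.learner_names_),
        "learners": [[_learner_to_dict(m) for m in bank] for bank in model.learners_],
        "filter_report": model.filter_report_.to_dict(orient="list"),
        "retained_indices": [int(i) for i in model.retained_indices_],
        "params": {"n_components": model.n_components,
                   "s_percent": model.s_percent,
                   "penalty_mode": model.penalty_mode,
                   "random_state": model.random_state},
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def load_model(path) -> DVHStackingEnsemble:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dvhstack-ensemble-v1":
        raise ParseError(f"{path}: not a dvhstack ensemble model file")
    p = doc["params"]
    est = DVHStackingEnsemble(n_components=p["n_components"],
                              s_percent=p["s_percent"],
                              penalty_mode=p["penalty_mode"],
                              random_state=p["random_state"])
    basis = DVHPrincipalComponents(n_components=doc["basis"]["n_components"])
    basis.mean_ = np.asarray(doc["basis"]["mean"], dtype=float)
    basis.components_ = np.asarray(doc["basis"]["components"], dtype=float)
    basis.explained_variance_ = np.asarray(doc["basis"]["explained_variance"],
                                           dtype=float)
    basis.dose_grid_ = np.asarray(doc["dose_grid"], dtype=float)
    basis.n_features_in_ = basis.mean_.shape[0]
    sc = FeatureStandardizer()
    sc.mean_ = np.asarray(doc["scaler"]["mean"], dtype=float)
    sc.scale_ = np.asarray(doc["scaler"]["scale"], dtype=float)
    sc.constant_mask_ = sc.scale_ == 1.0
    sc.n_features_in_ = sc.mean_.shape[0]
    est.basis_ = basis
    est.scaler_ = sc
    est.alpha_ = np.asarray(doc["alpha"], dtype=float)
    est.learner_names_ = tuple(doc["learner_names"])
    est.learners_ = [[_learner_from_dict(d) for d in bank] for bank in doc["learners"]]
    est.filter_report_ = pd.DataFrame(doc["filter_report"])
    est.retained_indices_ = np.asarray(doc["retained_indices"], dtype=int)
    est.dose_grid_ = np.asarray(doc["dose_grid"], dtype=float)
    est.prescription_dose_ = float(doc["prescription_dose"])
    est.n_features_in_ = sc.mean_.shape[0]
    return est


def save_basis(path, basis: DVHPrincipalComponents) -> None:
    """Basis as delimited text (mean row + component rows) with a JSON sidecar."""
    path = Path(path)
    rows = np.vstack([basis.mean_, basis.components_])
    np.savetxt(path, rows, delimiter=",", fmt=_FLOAT_FMT)
    sidecar = {"n_components": int(basis.components_.shape[0]),
               "explained_variance": list(basis.explained_variance_),
               "dose_grid": None if basis.dose_grid_ is None
               else list(basis.dose_grid_)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True))


def load_basis(path) -> DVHPrincipalComponents:
    path = Path(path)
    rows = np.atleast_2d(np.loadtxt(path, delimiter=","))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    k = sidecar["n_components"]
    basis = DVHPrincipalComponents(n_components=k)
    basis.mean_ = rows[0]
    basis.components_ = rows[1:1 + k]
    basis.explained_variance_ = np.asarray(sidecar["explained_variance"], dtype=float)
    basis.dose_grid_ = (None if sidecar["dose_grid"] is None
                        else np.asarray(sidecar["dose_grid"], dtype=float))
    basis.n_features_in_ = basis.mean_.shape[0]
    return basis


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Training configuration; the defaults are the reference setup
    (nine learners, 3 PCS, 10% filtering, leave-one-out metadata)."""

    learners: list[dict] | None = None  # None -> default nine-model bank
    s_percent: float = 10.0
    n_pc: int = 3
    scheme: str = "linear_relative"
    metadata_folds: int | None = None  # None = leave-one-out
    penalty_mode: str = "per_fold"
    penalty_grid_size: int = 20
    penalty_cv_folds: int = 5
    seed: int = 0

    def learner_specs(self) -> list[BaseLearnerSpec]:
        if self.learners is None:
            return default_learner_bank()
        return [BaseLearnerSpec(**d) for d in self.learners]

    def weight_scheme(self) -> WeightScheme:
        return WeightScheme(kind=self.scheme)

    def make_estimator(self, seed: int | None = None) -> DVHStackingEnsemble:
        return DVHStackingEnsemble(
            learner_specs=self.learner_specs(), n_components=self.n_pc,
            s_percent=self.s_percent, weight_scheme=self.weight_scheme(),
            penalty_mode=self.penalty_mode,
            penalty_grid_size=self.penalty_grid_size,
            penalty_cv_folds=self.penalty_cv_folds,
            metadata_folds=self.metadata_folds,
            random_state=self.seed if seed is None else seed)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
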