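"""Random-forest models mapping molecular descriptors to zero-intercept coefficients.

Five independent forests are trained, one per coefficient (e0, s0, a0, b0,
v0), on 2-D molecular descriptors computed with RDKit.  Because measured
coefficient tables are small (under a hundred solvents), validation uses the
out-of-bag (OOB) predictions that bootstrap forests generate for free instead
of holding out a test split.  Forest defaults follow the common R practice
for regression forests: 500 trees and one third of the features tried per
split.

The descriptor table always contains a computed logP-type descriptor
(``MolLogP``), topological polar surface area (``TPSA``), an H-bond acceptor
count (``NumHAcceptors``) and an explicit hydroxyl-group count (``NumOH``),
the features most diagnostic of solvation behaviour; the remaining RDKit 2-D
descriptors ride along and the forests weight them via impurity importances.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import SimpleImputer

from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors
from rdkit import RDLogger

from .core import COEFF_KEYS, ZERO_INTERCEPT, SolventCoefficients
from .errors import InsufficientDataError, InvalidInputError, ModelFormatError, SchemaError

__all__ = [
    "DescriptorError",
    "CoefficientModelSet",
    "compute_descriptors",
    "train",
    "predict_coefficients",
    "save_models",
    "load_models",
]

_FORMAT_VERSION = 1
_OH_PATTERN = Chem.MolFromSmarts("[OX2H]")

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class DescriptorError:
    """Per-row failure record from descriptor computation."""

    index: int
    name: str
    smiles: str
    reason: str


def compute_descriptors(
    smiles: Sequence[str],
    names: Sequence[str] | None = None,
    drop_constant: bool = True,
) -> tuple[pd.DataFrame, list[DescriptorError]]:
    """RDKit 2-D descriptor table for a list of SMILES.

    Rows follow input order (failed rows are omitted and reported in the
    second return value rather than aborting the batch).  Mixtures
    (multi-component SMILES containing '.') are rejected since a single
    structure is required.  Constant-valued descriptor columns are dropped by
    default; pass ``drop_constant=False`` when computing descriptors for
    prediction so that training feature names can be re-selected.
    """
    if names is None:
        names = [f"mol-{i:04d}" for i in range(len(smiles))]
    if len(names) != len(smiles):
        raise InvalidInputError("names and smiles must have equal length")
    records: list[dict] = []
    errors: list[DescriptorError] = []
    kept_names: list[str] = []
    for i, (smi, name) in enumerate(zip(smiles, names)):
        if "." in smi:
            errors.append(DescriptorError(i, name, smi, "mixture (multi-component SMILES) rejected"))
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors.append(DescriptorError(i, name, smi, "unparseable SMILES"))
            continue
        try:
            desc = _RDDescriptors.CalcMolDescriptors(mol)
        except Exception as exc:  # descriptor-level failure on an exotic structure
            errors.append(DescriptorError(i, name, smi, f"descriptor computation failed: {exc}"))
            continue
        desc["NumOH"] = len(mol.GetSubstructMatches(_OH_PATTERN))
        records.append(desc)
        kept_names.append(name)
    frame = pd.DataFrame.from_records(records, index=pd.Index(kept_names, name="name"))
    frame = frame.replace([np.inf, -np.inf], np.nan)
    if drop_constant and len(frame):
        nunique = frame.nunique(dropna=False)
        frame = frame.loc[:, nunique > 1]
    return frame, errors


@dataclass
class CoefficientModelSet:
    """Five fitted forests plus their OOB and resubstitution statistics."""

    models: dict[str, RandomForestRegressor]
    imputer: SimpleImputer
    feature_names: list[str]
    oob_rmse: dict[str, float]
    oob_r2: dict[str, float]
    train_rmse: dict[str, float]
    train_r2: dict[str, float]
    top_descriptor: dict[str, str]
    training_names: list[str]
    target_range: dict[str, tuple[float, float]]
    seed: int
    format_version: int = _FORMAT_VERSION

    def __post_init__(self) -> None:
        if set(self.models) != set(COEFF_KEYS):
            raise InvalidInputError("model set must contain exactly the five coefficient models")

    def summary(self) -> pd.DataFrame:
        """Per-coefficient statistics in canonical order (rows e0..v0)."""
        return pd.DataFrame(
            {
                "N": len(self.training_names),
                "oob_rmse": pd.Series(self.oob_rmse),
                "oob_r2": pd.Series(self.oob_r2),
                "rmse": pd.Series(self.train_rmse),
                "r2": pd.Series(self.train_r2),
                "top_descriptor": pd.Series(self.top_descriptor),
            }
        ).loc[list(COEFF_KEYS)]


def _normalize_target_frame(targets: pd.DataFrame) -> pd.DataFrame:
    """Accept e0..v0 or e..v column names; return a frame keyed e..v."""
    frame = targets.copy()
    rename = {}
    for k in COEFF_KEYS:
        if k + "0" in frame.columns:
            rename[k + "0"] = k
        elif k not in frame.columns:
            raise SchemaError(f"target table missing coefficient column {k!r}/{k + '0'!r}")
    return frame.rename(columns=rename)


def train(
    descriptors: pd.DataFrame,
    targets: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
    max_features: float = 1 / 3,
) -> CoefficientModelSet:
    """Fit the five coefficient forests and collect OOB statistics.

    ``descriptors`` and ``targets`` must be row-aligned (same length; when both
    carry names, the names must agree).  OOB statistics come exclusively from
    bootstrap-excluded predictions; a constant target column gets ``nan`` R2.
    """
    targets = _normalize_target_frame(targets)
    desc = descriptors.copy()
    if "name" in desc.columns:
        desc = desc.set_index("name")
    if "name" in targets.columns:
        targets = targets.set_index("name")
    if len(desc) != len(targets):
        raise InvalidInputError(
            f"descriptor table ({len(desc)} rows) and target table ({len(targets)} rows) are misaligned"
        )
    if desc.index.name == "name" and targets.index.name == "name":
        if list(desc.index) != list(targets.index):
            raise InvalidInputError("descriptor and target tables carry different molecule names")
    if len(desc) < 10:
        raise InsufficientDataError(f"need at least 10 training rows, got {len(desc)}")

    desc = desc.loc[:, desc.notna().any(axis=0)]  # drop all-NaN descriptor columns
    feature_names = [str(c) for c in desc.columns]
    imputer = SimpleImputer(strategy="median")
    X = imputer.fit_transform(desc.to_numpy(dtype=float))

    models, oob_rmse, oob_r2, train_rmse, train_r2, top = {}, {}, {}, {}, {}, {}
    target_range: dict[str, tuple[float, float]] = {}
    for j, k in enumerate(COEFF_KEYS):
        y = targets[k].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise InvalidInputError(f"target column {k!r} contains non-finite values")
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            bootstrap=True,
            oob_score=True,
            random_state=seed + j,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-OOB warning at small n
            forest.fit(X, y)
        oob_pred = forest.oob_prediction_
        resid = y - oob_pred
        oob_rmse[k] = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        oob_r2[k] = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else float("nan")
        fit_pred = forest.predict(X)
        train_rmse[k] = float(np.sqrt(np.mean((y - fit_pred) ** 2)))
        ss_res = float(np.sum((y - fit_pred) ** 2))
        train_r2[k] = float(1 - ss_res / ss_tot) if ss_tot > 0 else float("nan")
        top[k] = feature_names[int(np.argmax(forest.feature_importances_))]
        target_range[k] = (float(y.min()), float(y.max()))
        models[k] = forest
    return CoefficientModelSet(
        models=models,
        imputer=imputer,
        feature_names=feature_names,
        oob_rmse=oob_rmse,
        oob_r2=oob_r2,
        train_rmse=train_rmse,
        train_r2=train_r2,
        top_descriptor=top,
        training_names=[str(i) for i in desc.index],
        target_range=target_range,
        seed=seed,
    )


def predict_coefficients(
    model_set: CoefficientModelSet,
    descriptors: pd.DataFrame | Mapping[str, float],
    name: str | None = None,
) -> list[SolventCoefficients] | SolventCoefficients:
    """Assemble zero-intercept coefficient rows from descriptor vectors.

    Accepts a descriptor DataFrame (one row per solvent, named index or
    ``name`` column) or a single mapping.  Missing training features raise a
    schema error naming the first absent feature; extra columns are ignored.
    """
    single = False
    if isinstance(descriptors, Mapping):
        descriptors = pd.DataFrame([descriptors], index=[name or "solvent"])
        single = True
    frame = descriptors.copy()
    if "name" in frame.columns:
        frame = frame.set_index("name")
    missing = [f for f in model_set.feature_names if f not in frame.columns]
    if missing:
        raise SchemaError(f"descriptor table missing training feature {missing[0]!r} "
                          f"({len(missing)} features absent in total)")
    X = model_set.imputer.transform(frame[model_set.feature_names].to_numpy(dtype=float))
    predictions = {k: model_set.models[k].predict(X) for k in COEFF_KEYS}
    rows = [
        SolventCoefficients(
            str(frame.index[i]),
            *(float(predictions[k][i]) for k in COEFF_KEYS),
            convention=ZERO_INTERCEPT,
            provenance="predicted",
        )
        for i in range(len(frame))
    ]
    return rows[0] if single else rows


def save_models(model_set: CoefficientModelSet, path) -> None:
    """Serialize a model set (joblib) with a format-version stamp."""
    joblib.dump({"format_version": model_set.format_version, "model_set": model_set}, path)


def load_models(path) -> CoefficientModelSet:
    """Load a model set, refusing corrupt files or incompatible versions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a solvcoef model artifact")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']} incompatible with {_FORMAT_VERSION}"
        )
    return payload["model_set"]
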