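"""Property evaluators over molecules and latent vectors.

Three descriptors are computed directly from structure: SlogP (Crippen
atomic-contribution octanol/water partition), QED (weighted-desirability
drug-likeness, in [0, 1]) and the fragment-contribution synthetic
accessibility score (SA, ~1 easy to 10 hard).  ADMET-style endpoints are
covered by a training harness that fits gradient-boosted tree ensembles
(XGBoost) on 512-dimensional latent features, reporting 5-fold
cross-validation and held-out metrics.  The train/test split can be a
plain random split or a maximum-diversity (MaxMin on Tanimoto distance)
sweep so the training set spans chemical space.

Endpoint definitions (name, task, editable default ranges) for the nine
customary ADMET endpoints ship here; trained weights do not — labeled
data is always supplied by the caller (or planted synthetically by
:mod:`latentmol.fixtures`).
"""

from __future__ import annotations

import json
import math
import os
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb
from rdkit import Chem
from rdkit.Chem import Crippen, QED, RDConfig, rdFingerprintGenerator
from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .chem_io import LATENT_DIM, MoleculeRecord
from .errors import DegenerateLabels, DimensionError, TooFewRecords

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, resolved above)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

_BUILTINS = ("SlogP", "QED", "SA")


def compute_builtin(molecule, name: str) -> float:
    """Directly computed descriptor: SlogP, QED or SA."""
    if isinstance(molecule, MoleculeRecord):
        mol = molecule.mol()
    elif isinstance(molecule, Chem.Mol):
        mol = molecule
    else:
        mol = MoleculeRecord.from_smiles(molecule).mol()
    if name == "SlogP":
        return float(Crippen.MolLogP(mol))
    if name == "QED":
        return float(QED.qed(mol))
    if name == "SA":
        return float(sascorer.calculateScore(mol))
    raise ValueError(f"unknown builtin {name!r}; choose from {_BUILTINS}")


@dataclass(frozen=True)
class EndpointDefinition:
    """One ADMET-style endpoint: task type and editable default ranges.

    The ranges are starting points for desirability scoring, not asserted
    reference values; edit them per optimization task.  Classification
    endpoints are scored on their positive-class probability, for which
    lower is better on toxicity endpoints (default optimal [0, 0.3],
    recommended [0, 0.7]).
    """

    name: str
    task: str  # "regression" | "classification"
    description: str
    optimal_range: tuple[float, float]
    recommended_range: tuple[float, float]


_TOX_OPT = (0.0, 0.3)
_TOX_REC = (0.0, 0.7)

#: The twelve objective functions: nine trainable endpoints plus the
#: three computed descriptors.
ENDPOINTS: dict[str, EndpointDefinition] = {
    e.name: e
    for e in [
        EndpointDefinition("logD7.4", "regression",
                           "log octanol/water distribution at pH 7.4",
                           (1.0, 3.0), (-2.0, 5.0)),
        EndpointDefinition("logS", "regression", "log aqueous solubility",
                           (-4.0, 0.5), (-6.0, 1.0)),
        EndpointDefinition("Caco-2", "regression", "Caco-2 permeability",
                           (-4.7, -4.0), (-6.0, -3.5)),
        EndpointDefinition("MDCK", "regression", "MDCK permeability",
                           (-4.7, -4.0), (-6.0, -3.5)),
        EndpointDefinition("PPB", "regression",
                           "plasma protein bound fraction",
                           (0.0, 0.9), (0.0, 0.98)),
        EndpointDefinition("AMES", "classification",
                           "probability of Ames mutagenicity",
                           _TOX_OPT, _TOX_REC),
        EndpointDefinition("hERG", "classification",
                           "probability of hERG blockade",
                           _TOX_OPT, _TOX_REC),
        EndpointDefinition("hepatotoxicity", "classification",
                           "probability of liver toxicity",
                           _TOX_OPT, _TOX_REC),
        EndpointDefinition("LD50", "classification",
                           "acute-toxicity class probability",
                           _TOX_OPT, _TOX_REC),
        EndpointDefinition("SlogP", "computed",
                           "Crippen octanol/water partition",
                           (1.0, 3.0), (-0.4, 5.6)),
        EndpointDefinition("QED", "computed",
                           "quantitative estimate of drug-likeness",
                           (0.67, 1.0), (0.3, 1.0)),
        EndpointDefinition("SA", "computed",
                           "synthetic accessibility score",
                           (1.0, 3.5), (1.0, 6.0)),
    ]
}


@dataclass
class LabeledSet:
    """Latent features plus labels for one endpoint."""

    X: np.ndarray  # (n, 512)
    y: np.ndarray  # (n,)
    endpoint: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != LATENT_DIM:
            raise DimensionError(
                f"features must be (n, {LATENT_DIM}), got {self.X.shape}"
            )
        if len(self.X) != len(self.y):
            raise ValueError("feature/label counts differ")
        if np.isnan(self.y).any():
            raise ValueError("labels contain missing values")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class PropertyModelCard:
    """CV and held-out metrics in the customary endpoint-report layout:
    RMSE/MAE/R2 for regression, accuracy/sensitivity/AUC for
    classification, each as mean and sd over 5 folds plus the held-out
    value."""

    endpoint: str
    task: str
    cv_metrics: dict[str, tuple[float, float]] = field(default_factory=dict)
    test_metrics: dict[str, float] = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class GBTConfig:
    """Gradient-boosted tree hyperparameters (all exposed).

    Shallow trees are the default: with a few hundred training rows and
    512 correlated latent features, depth-2 boosting recovers additive
    structure well where deep trees overfit.
    """

    n_estimators: int = 800
    max_depth: int = 2
    learning_rate: float = 0.1
    early_stopping_rounds: int = 30
    validation_fraction: float = 0.1


def diverse_split(
    fingerprints, test_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Diverse training-set split.

    Picks the training set by a MaxMin maximum-diversity sweep on
    Tanimoto distance over the supplied bit-vector fingerprints, so the
    retained training compounds span chemical space; the remainder is
    the test set.  Returns (train indices, test indices): disjoint,
    exhaustive, sizes within one of the requested fractions.
    """
    n = len(fingerprints)
    if n < 4:
        raise TooFewRecords(f"need at least 4 records, got {n}")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n_train = int(round((1.0 - test_fraction) * n))
    n_train = min(max(n_train, 1), n - 1)
    picker = MaxMinPicker()
    picks = picker.LazyBitVectorPick(
        list(fingerprints), n, n_train, seed=seed
    )
    train_idx = np.array(sorted(picks), dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    mask[train_idx] = False
    return train_idx, np.flatnonzero(mask)


def morgan_fingerprints(records: list[MoleculeRecord]):
    """2048-bit radius-2 Morgan fingerprints for valid records."""
    return [_MORGAN.GetFingerprint(r.mol()) for r in records]


def _xgb_model(task: str, cfg: GBTConfig, seed: int):
    common = dict(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        early_stopping_rounds=cfg.early_stopping_rounds,
        verbosity=0,
    )
    if task == "regression":
        return xgb.XGBRegressor(**common)
    return xgb.XGBClassifier(**common, eval_metric="logloss")


def _fit(model, X, y, cfg: GBTConfig, seed: int):
    """Fit with an internal validation carve-out for early stopping."""
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(cfg.validation_fraction * len(y))))
    order = rng.permutation(len(y))
    val, tr = order[:n_val], order[n_val:]
    model.fit(X[tr], y[tr], eval_set=[(X[val], y[val])], verbose=False)
    return model


def _regression_metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "RMSE": float(np.sqrt(mean_squared_error(y_true, y_pred))),
        "MAE": float(mean_absolute_error(y_true, y_pred)),
        "R2": float(r2_score(y_true, y_pred)),
    }


def _classification_metrics(y_true, proba) -> dict[str, float]:
    pred = (proba >= 0.5).astype(int)
    pos = y_true == 1
    sens = float((pred[pos] == 1).mean()) if pos.any() else math.nan
    return {
        "accuracy": float((pred == y_true).mean()),
        "sensitivity": sens,
        "AUC": float(roc_auc_score(y_true, proba)),
    }


def train_property_model(
    data: LabeledSet,
    task: str,
    seed: int = 0,
    config: GBTConfig | None = None,
    n_folds: int = 5,
    test_fraction: float = 0.25,
    split_indices: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Fit a gradient-boosted tree model on latent features.

    Splits the data 75/25 (random by default; pass ``split_indices`` from
    :func:`diverse_split` for the diversity protocol), reports 5-fold CV
    metrics on the training portion and held-out metrics on the test
    portion, then refits on the full training portion.  Deterministic for
    a fixed seed.  Returns (fitted model, PropertyModelCard).
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    cfg = config or GBTConfig()
    X, y = data.X, data.y
    if task == "classification":
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise DegenerateLabels("classification labels contain one class")
    rng = np.random.default_rng(seed)
    if split_indices is None:
        order = rng.permutation(len(y))
        n_test = max(1, int(round(test_fraction * len(y))))
        test_idx, train_idx = order[:n_test], order[n_test:]
    else:
        train_idx, test_idx = split_indices
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    metric_fn = (_regression_metrics if task == "regression"
                 else _classification_metrics)
    splitter = (
        KFold(n_folds, shuffle=True, random_state=seed)
        if task == "regression"
        else StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    )
    fold_metrics: list[dict[str, float]] = []
    for k, (tr, va) in enumerate(splitter.split(X_tr, y_tr)):
        m = _fit(_xgb_model(task, cfg, seed + k), X_tr[tr], y_tr[tr], cfg,
                 seed + k)
        pred = (m.predict(X_tr[va]) if task == "regression"
                else m.predict_proba(X_tr[va])[:, 1])
        fold_metrics.append(metric_fn(y_tr[va], pred))

    card = PropertyModelCard(endpoint=data.endpoint or "unnamed", task=task,
                             n_train=len(train_idx), n_test=len(test_idx),
                             seed=seed)
    for key in fold_metrics[0]:
        vals = np.array([fm[key] for fm in fold_metrics])
        card.cv_metrics[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))

    model = _fit(_xgb_model(task, cfg, seed), X_tr, y_tr, cfg, seed)
    pred = (model.predict(X_te) if task == "regression"
            else model.predict_proba(X_te)[:, 1])
    card.test_metrics = metric_fn(y_te, pred)
    return model, card


def predict_property(model, z) -> float:
    """Prediction for one latent vector: regression value, or
    positive-class probability for a classifier."""
    z = np.asarray(z, dtype=np.float64).reshape(1, -1)
    if z.shape[1] != LATENT_DIM:
        raise DimensionError(
            f"latent vector has {z.shape[1]} components, expected {LATENT_DIM}"
        )
    if isinstance(model, xgb.XGBClassifier):
        return float(model.predict_proba(z)[0, 1])
    return float(model.predict(z)[0])


def augment_labeled_set(
    translator,
    smiles: list[str],
    labels: np.ndarray,
    enumerations: int = 5,
    seed: int = 0,
    endpoint: str = "",
) -> LabeledSet:
    """Training-time augmentation: encode several enumerated renderings of
    each molecule, copying its label to every latent row.  Off the
    default path; opt in for small permeability-style datasets."""
    from .chem_io import enumerate_smiles

    rng = np.random.default_rng(seed)
    all_smiles, all_labels = [], []
    for smi, lab in zip(smiles, labels):
        renders = enumerate_smiles(smi, enumerations,
                                   seed=int(rng.integers(2**31)))
        all_smiles.extend(renders)
        all_labels.extend([lab] * len(renders))
    Z = translator.encode(all_smiles)
    return LabeledSet(Z, np.asarray(all_labels), endpoint=endpoint)
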