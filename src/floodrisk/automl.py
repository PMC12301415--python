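"""Joint feature selection and hyperparameter tuning via the flood optimizers.

A candidate model is encoded as a genome in [0, 1]^(F + H): the first F
genes are a soft feature mask (gene >= 0.5 selects the feature; if none
clears the threshold the single largest gene is selected so the mask is
never empty), the remaining H genes map onto hyperparameter ranges on a
linear or log scale with integers rounded half-up.  Fitness is

    (1 - mean out-of-fold ROC-AUC over stratified k folds) + lambda * |mask| / F

so the optimizer minimizes cross-validated ranking error with a small
sparsity pressure (lambda = 0.01 by default) that rewards compact panels
without forcing them.  The base learner is a gradient-boosted decision
tree ensemble (LightGBM); four fixed-configuration baselines (logistic
regression, SVM, XGBoost, LightGBM) provide the comparison models.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cohort import Cohort, impute, training_fill_values
from .optimizer import ObjectiveFunction, OptimizerConfig, OptimizationResult, optimize

__all__ = [
    "HyperparameterSpec",
    "SearchSpace",
    "ModelConfig",
    "FittedModel",
    "default_search_space",
    "decode",
    "cv_fitness",
    "fit_automl",
    "fit_baselines",
    "predict_proba",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HyperparameterSpec:
    name: str
    lo: float
    hi: float
    scale: str = "linear"  # "linear" | "log"
    type: str = "real"  # "real" | "integer"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError(f"{self.name}: log scale requires lo > 0")
        if self.type not in ("real", "integer"):
            raise ValueError(f"{self.name}: unknown type {self.type!r}")

    def from_gene(self, gene: float):
        if self.scale == "log":
            value = math.exp(
                math.log(self.lo) + gene * (math.log(self.hi) - math.log(self.lo))
            )
        else:
            value = self.lo + gene * (self.hi - self.lo)
        if self.type == "integer":
            return int(math.floor(value + 0.5))
        return value


@dataclass(frozen=True)
class SearchSpace:
    feature_names: tuple[str, ...]
    hyperparameters: tuple[HyperparameterSpec, ...]
    sparsity_penalty: float = 0.01

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def genome_length(self) -> int:
        return self.n_features + len(self.hyperparameters)


@dataclass(frozen=True)
class ModelConfig:
    selected_features: tuple[int, ...]
    hyperparameter_values: dict

    def __post_init__(self) -> None:
        if len(self.selected_features) == 0:
            raise ValueError("selected_features must be non-empty")


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to reapply it.

    ``learner`` is either a fitted estimator exposing ``predict_proba`` /
    a decision-score wrapper, or a raw LightGBM Booster (after reloading
    from disk).  ``train_fill_values`` are the training-partition
    imputation statistics, reused verbatim at prediction time.
    """

    learner: object
    config: ModelConfig
    feature_names: tuple[str, ...]
    train_fill_values: dict
    cv_score: float = math.nan
    optimization: OptimizationResult | None = None
    name: str = "model"

    @property
    def selected_feature_names(self) -> tuple[str, ...]:
        return tuple(self.feature_names[i] for i in self.config.selected_features)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return predict_proba(self, frame)


DEFAULT_FEATURES = (
    "age", "sex", "bmi", "cfs", "charlson", "smoking", "alcohol", "sbp",
    "gcs", "heart_rate", "temperature", "hemoglobin", "fibrinogen", "fdp",
    "lactate", "crp", "rts", "iss", "tbi",
)


def default_search_space() -> SearchSpace:
    """The 19 candidate predictors plus a boosted-tree hyperparameter box."""
    return SearchSpace(
        feature_names=DEFAULT_FEATURES,
        hyperparameters=(
            HyperparameterSpec("learning_rate", 0.01, 0.3, scale="log"),
            HyperparameterSpec("n_estimators", 50, 500, type="integer"),
            HyperparameterSpec("max_depth", 2, 8, type="integer"),
            HyperparameterSpec("min_child_samples", 5, 50, type="integer"),
            HyperparameterSpec("subsample", 0.5, 1.0),
            HyperparameterSpec("colsample", 0.5, 1.0),
        ),
        sparsity_penalty=0.01,
    )


def decode(genome, space: SearchSpace) -> ModelConfig:
    """Map a genome in [0,1]^(F+H) to a model configuration.

    Feature i is selected iff gene_i >= 0.5; an all-below-threshold mask
    falls back to the single argmax gene.  Hyperparameter genes stretch
    linearly (or geometrically for log-scaled ranges) across their box.
    """
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (space.genome_length,):
        raise ValueError(
            f"genome length {genome.size} != expected {space.genome_length}"
        )
    mask_genes = genome[: space.n_features]
    selected = tuple(int(i) for i in np.flatnonzero(mask_genes >= 0.5))
    if not selected:
        selected = (int(np.argmax(mask_genes)),)
    values = {
        hp.name: hp.from_gene(float(g))
        for hp, g in zip(space.hyperparameters, genome[space.n_features:])
    }
    return ModelConfig(selected_features=selected, hyperparameter_values=values)


def _make_learner(values: dict, seed: int = 0) -> lgb.LGBMClassifier:
    params = dict(values)
    if "colsample" in params:
        params["colsample_bytree"] = params.pop("colsample")
    if "subsample" in params:
        params["subsample_freq"] = 1
    # small-bin histograms keep desk-scale wrapper search affordable
    return lgb.LGBMClassifier(
        random_state=seed, n_jobs=1, verbosity=-1, max_bin=63, **params
    )


def _prepare_training_arrays(train: Cohort) -> tuple[pd.DataFrame, np.ndarray, tuple, dict]:
    complete = impute(train)
    fills = training_fill_values(train)
    predictors = complete.frame[complete.frame["partition"] == "train"]
    X = predictors.drop(columns=["delirium", "partition"]).astype(float)
    X = X.reset_index(drop=True)
    y = predictors["delirium"].to_numpy(dtype=int)
    return X, y, tuple(X.columns), fills


def _cv_fitness_arrays(
    genome, X: pd.DataFrame, y: np.ndarray, space: SearchSpace,
    folds: int, seed: int,
) -> float:
    config = decode(genome, space)
    Xs = X.iloc[:, list(config.selected_features)]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in splitter.split(Xs, y):
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError("a cross-validation fold contains a single class")
        learner = _make_learner(config.hyperparameter_values, seed=seed)
        learner.fit(Xs.iloc[train_idx], y[train_idx])
        probs = learner.predict_proba(Xs.iloc[test_idx])[:, 1]
        aucs.append(roc_auc_score(y[test_idx], probs))
    penalty = space.sparsity_penalty * len(config.selected_features) / space.n_features
    return (1.0 - float(np.mean(aucs))) + penalty


def cv_fitness(
    genome, train: Cohort, space: SearchSpace | None = None,
    folds: int = 5, seed: int = 0,
) -> float:
    """Cross-validated wrapper fitness of one genome (lower is better)."""
    if space is None:
        space = default_search_space()
    X, y, columns, _ = _prepare_training_arrays(train)
    return _cv_fitness_arrays(genome, X[list(space.feature_names)], y, space, folds, seed)


def fit_automl(
    train: Cohort,
    space: SearchSpace | None = None,
    opt: OptimizerConfig | None = None,
    folds: int = 5,
) -> FittedModel:
    """Optimize the joint genome with IFLA and refit at the best configuration.

    The default optimizer budget (population 20, 60 iterations) is the
    desk-scale setting; the benchmark-scale 30/500 budget remains available
    through ``opt``.
    """
    if space is None:
        space = default_search_space()
    if opt is None:
        opt = OptimizerConfig(population_size=20, max_iterations=60, variant="ifla")
    X, y, columns, fills = _prepare_training_arrays(train)
    X = X[list(space.feature_names)]

    def evaluate(genomes: np.ndarray) -> np.ndarray:
        return np.array(
            [
                _cv_fitness_arrays(g, X, y, space, folds, opt.seed)
                for g in genomes
            ]
        )

    objective = ObjectiveFunction(
        dim=space.genome_length,
        lower=np.zeros(space.genome_length),
        upper=np.ones(space.genome_length),
        evaluate=evaluate,
        name="cv_fitness",
    )
    result = optimize(objective, opt)
    config = decode(result.best_position, space)
    learner = _make_learner(config.hyperparameter_values, seed=opt.seed)
    learner.fit(X.iloc[:, list(config.selected_features)], y)
    return FittedModel(
        learner=learner,
        config=config,
        feature_names=space.feature_names,
        train_fill_values=fills,
        cv_score=result.best_fitness,
        optimization=result,
        name="AutoML",
    )


class _RankScoreSVM:
    """SVC scored by its min-max-normalized decision function.

    A hard-margin-style SVC on an imbalanced cohort may emit no positive
    class probabilities at all; ranking its decision function instead
    yields usable scores in [0, 1] for ROC/PR analysis.
    """

    def __init__(self, seed: int = 0):
        self._pipeline = make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
        self._lo = 0.0
        self._hi = 1.0

    def fit(self, X, y):
        self._pipeline.fit(X, y)
        scores = self._pipeline.decision_function(X)
        self._lo = float(scores.min())
        self._hi = float(scores.max())
        return self

    def predict_proba(self, X):
        scores = self._pipeline.decision_function(X)
        span = self._hi - self._lo
        p = np.clip((scores - self._lo) / span if span > 0 else scores * 0.0, 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


def fit_baselines(train: Cohort, seed: int = 0) -> dict[str, FittedModel]:
    """The four fixed comparison models on all candidate predictors."""
    X, y, columns, fills = _prepare_training_arrays(train)
    all_features = tuple(range(len(columns)))
    learners = {
        "LR": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        ),
        "SVM": _RankScoreSVM(seed=seed),
        "XGBoost": XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, eval_metric="logloss"
        ),
        "LightGBM": lgb.LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1),
    }
    models = {}
    for name, learner in learners.items():
        learner.fit(X, y)
        models[name] = FittedModel(
            learner=learner,
            config=ModelConfig(selected_features=all_features, hyperparameter_values={}),
            feature_names=columns,
            train_fill_values=fills,
            name=name,
        )
    return models


def predict_proba(model: FittedModel, rows) -> np.ndarray:
    """Delirium probability per row, applying stored imputation statistics.

    ``rows`` may be a Cohort or a DataFrame; missing cells in selected
    feature columns are filled with the training medians/modes the model
    was fitted with.  A selected feature column absent from ``rows``
    entirely is an error.
    """
    if isinstance(rows, Cohort):
        frame = rows.predictors
    else:
        frame = rows
    names = model.selected_feature_names
    missing_cols = [c for c in names if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"rows lack selected feature column(s): {missing_cols}")
    X = frame[list(names)].astype(float).copy()
    for col in names:
        X[col] = X[col].fillna(model.train_fill_values[col])
    learner = model.learner
    if isinstance(learner, lgb.Booster):
        probs = np.asarray(learner.predict(X.to_numpy(dtype=float)), dtype=float)
    else:
        probs = np.asarray(learner.predict_proba(X)[:, 1], dtype=float)
    return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Persistence (LightGBM-backed models)
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, directory) -> None:
    """Persist a LightGBM-backed model as a directory of text artifacts."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    learner = model.learner
    booster = learner if isinstance(learner, lgb.Booster) else learner.booster_
    booster.save_model(str(directory / "model.txt"))
    metadata = {
        "name": model.name,
        "feature_names": list(model.feature_names),
        "selected_features": list(model.config.selected_features),
        "selected_feature_names": list(model.selected_feature_names),
        "hyperparameter_values": model.config.hyperparameter_values,
        "train_fill_values": model.train_fill_values,
        "cv_score": model.cv_score,
    }
    with open(directory / "config.json", "w") as fh:
        json.dump(metadata, fh, indent=2)


def load_model(directory) -> FittedModel:
    directory = pathlib.Path(directory)
    with open(directory / "config.json") as fh:
        metadata = json.load(fh)
    booster = lgb.Booster(model_file=str(directory / "model.txt"))
    return FittedModel(
        learner=booster,
        config=ModelConfig(
            selected_features=tuple(metadata["selected_features"]),
            hyperparameter_values=metadata["hyperparameter_values"],
        ),
        feature_names=tuple(metadata["feature_names"]),
        train_fill_values=metadata["train_fill_values"],
        cv_score=metadata["cv_score"],
        name=metadata.get("name", "AutoML"),
    )
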