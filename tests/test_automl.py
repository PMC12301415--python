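"""Genome decoding, cross-validated wrapper fitness, baselines, persistence."""

import numpy as np
import pandas as pd
import pytest

import floodrisk as fr
from floodrisk.automl import (
    HyperparameterSpec,
    SearchSpace,
    cv_fitness,
    decode,
    default_search_space,
    fit_automl,
    fit_baselines,
    load_model,
    predict_proba,
    save_model,
)
from floodrisk.cohort import Cohort
from floodrisk.optimizer import OptimizerConfig


def toy_cohort(n=120, informative=True, seed=0, permute_labels=False):
    """Single-signal toy: feature x separates classes (or is pure noise)."""
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 3) + [0] * (n - n // 3))
    x = np.where(labels == 1, rng.normal(3.0, 1.0, n), rng.normal(-3.0, 1.0, n))
    if not informative:
        x = rng.normal(size=n)
    if permute_labels:
        labels = rng.permutation(labels)
    frame = pd.DataFrame(
        {"x": x, "noise": rng.normal(size=n), "delirium": labels, "partition": "train"}
    )
    return Cohort(frame)


def toy_space(n_features=2, penalty=0.0):
    return SearchSpace(
        feature_names=("x", "noise")[:n_features],
        hyperparameters=(HyperparameterSpec("n_estimators", 20, 40, type="integer"),),
        sparsity_penalty=penalty,
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def test_decode_threshold_rule():
    space = default_search_space()
    genome = np.full(space.genome_length, 0.1)
    genome[0], genome[2] = 0.7, 0.5
    config = decode(genome, space)
    assert config.selected_features == (0, 2)


def test_decode_falls_back_to_argmax_when_mask_empty():
    space = default_search_space()
    genome = np.full(space.genome_length, 0.4)
    genome[3] = 0.45
    assert decode(genome, space).selected_features == (3,)


def test_decode_log_scale_geometric_midpoint():
    space = SearchSpace(
        feature_names=("a",),
        hyperparameters=(HyperparameterSpec("lr", 1e-3, 1e-1, scale="log"),),
    )
    config = decode(np.array([0.9, 0.5]), space)
    assert config.hyperparameter_values["lr"] == pytest.approx(1e-2)


def test_decode_integer_rounds_half_up():
    space = SearchSpace(
        feature_names=("a",),
        hyperparameters=(HyperparameterSpec("n", 0, 10, type="integer"),),
    )
    assert decode(np.array([1.0, 0.25]), space).hyperparameter_values["n"] == 3  # 2.5 -> 3


def test_decode_rejects_wrong_length():
    with pytest.raises(ValueError, match="length"):
        decode(np.zeros(3), default_search_space())


def test_decode_total_and_never_empty(rng):
    space = default_search_space()
    for _ in range(200):
        config = decode(rng.random(space.genome_length), space)
        assert len(config.selected_features) >= 1
        for hp in space.hyperparameters:
            value = config.hyperparameter_values[hp.name]
            assert hp.lo <= value <= hp.hi


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def test_cv_fitness_near_zero_on_separable_data():
    cohort = toy_cohort(informative=True)
    fitness = cv_fitness(np.array([1.0, 0.0, 0.5]), cohort, toy_space(), seed=0)
    assert fitness < 0.02


def test_cv_fitness_near_half_under_label_permutation():
    values = [
        cv_fitness(
            np.array([1.0, 0.0, 0.5]),
            toy_cohort(informative=True, permute_labels=True, seed=s),
            toy_space(),
            seed=0,
        )
        for s in range(10)
    ]
    assert np.mean(values) == pytest.approx(0.5, abs=0.1)


def test_cv_fitness_deterministic():
    cohort = toy_cohort()
    genome = np.array([0.8, 0.6, 0.3])
    assert cv_fitness(genome, cohort, toy_space(), seed=4) == cv_fitness(
        genome, cohort, toy_space(), seed=4
    )


def test_sparsity_penalty_orders_equal_auc_masks():
    cohort = toy_cohort(informative=True)
    space = toy_space(penalty=0.5)
    one = cv_fitness(np.array([1.0, 0.0, 0.5]), cohort, space, seed=0)
    both = cv_fitness(np.array([1.0, 1.0, 0.5]), cohort, space, seed=0)
    assert both > one  # the noise feature costs penalty without adding AUC


# ---------------------------------------------------------------------------
# AutoML fit
# ---------------------------------------------------------------------------

def test_forced_single_feature_space():
    cohort = toy_cohort()
    space = toy_space(n_features=1)
    model = fit_automl(
        cohort, space=space,
        opt=OptimizerConfig(population_size=4, max_iterations=2, seed=0, variant="ifla"),
    )
    assert model.selected_feature_names == ("x",)


def test_automl_selects_strongest_published_separators(automl_model):
    assert {"fdp", "age"} <= set(automl_model.selected_feature_names)


def test_automl_beats_random_genome(automl_model, cohort_with_missing):
    space = default_search_space()
    random_genome = np.random.default_rng(0).random(space.genome_length)
    random_fitness = cv_fitness(random_genome, cohort_with_missing, space, seed=0)
    assert automl_model.cv_score <= random_fitness


def test_automl_history_non_increasing(automl_model):
    assert np.all(np.diff(automl_model.optimization.history) <= 0)


# ---------------------------------------------------------------------------
# Baselines and prediction
# ---------------------------------------------------------------------------

def test_baselines_contract(cohort_with_missing):
    models = fit_baselines(cohort_with_missing, seed=0)
    assert set(models) == {"LR", "SVM", "XGBoost", "LightGBM"}
    test = cohort_with_missing.subset("test")
    labels = test.label.to_numpy()
    for model in models.values():
        probs = predict_proba(model, test)
        assert probs.shape == (192,)
        assert np.all((probs >= 0) & (probs <= 1))
        auc = fr.roc_pr_curves(labels, probs).roc_auc
        assert auc > 0.5


def test_logistic_regression_separates_toy():
    cohort = toy_cohort()
    models = fit_baselines(cohort, seed=0)
    probs = predict_proba(models["LR"], cohort)
    assert fr.roc_pr_curves(cohort.label.to_numpy(), probs).roc_auc == 1.0


def test_predict_proba_contracts(automl_model, cohort_with_missing):
    train = cohort_with_missing.subset("train")
    probs = predict_proba(automl_model, train)
    assert probs.shape == (764,)
    row = train.predictors.iloc[[0]]
    duplicated = pd.concat([row, row], ignore_index=True)
    p = predict_proba(automl_model, duplicated)
    assert p[0] == p[1]


def test_predict_proba_imputes_missing_with_train_median(automl_model, cohort_with_missing):
    feature = automl_model.selected_feature_names[0]
    row = fr.impute(cohort_with_missing).subset("test").predictors.iloc[[0]].copy()
    masked = row.copy()
    masked[feature] = np.nan
    filled = row.copy()
    filled[feature] = automl_model.train_fill_values[feature]
    assert predict_proba(automl_model, masked)[0] == predict_proba(automl_model, filled)[0]


def test_predict_proba_rejects_absent_column(automl_model):
    with pytest.raises(ValueError, match="lack"):
        predict_proba(automl_model, pd.DataFrame({"bogus": [1.0]}))


def test_model_persistence_roundtrip(automl_model, cohort_with_missing, tmp_path):
    save_model(automl_model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    assert loaded.selected_feature_names == automl_model.selected_feature_names
    test = cohort_with_missing.subset("test")
    assert np.allclose(
        predict_proba(loaded, test), predict_proba(automl_model, test), atol=1e-12
    )
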