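"""Synthetic cohort generator: counts, marginals, missingness, imputation."""

import io

import numpy as np
import pandas as pd
import pytest

import floodrisk as fr
from floodrisk.cohort import (
    Cohort,
    CohortSpec,
    ConfigurationError,
    VariableSpec,
    spec_from_yaml,
    spec_to_yaml,
    training_fill_values,
)

from conftest import COHORT_SEED, MISSING_SEED


# ---------------------------------------------------------------------------
# Default spec parameterization
# ---------------------------------------------------------------------------

def test_default_spec_carries_published_group_parameters(default_spec):
    fdp = default_spec.variable("fdp")
    assert fdp.params_delirium == {"mean": 60.56, "sd": 18.79}
    assert fdp.params_nodelirium == {"mean": 16.74, "sd": 8.22}
    tbi = default_spec.variable("tbi")
    assert tbi.params_delirium["p"] == pytest.approx(0.468)
    age = default_spec.variable("age")
    assert age.params_delirium == {"mean": 77.37, "sd": 8.42}
    assert default_spec.n_total == 956
    assert len(default_spec.variables) == 19


def test_default_missing_rates_peak_at_fdp(default_spec):
    rates = default_spec.missing_rates
    assert rates["fdp"] == pytest.approx(0.026)
    others = [r for name, r in rates.items() if name != "fdp"]
    assert all(r < rates["fdp"] for r in others)


def test_variable_spec_validation():
    with pytest.raises(ConfigurationError):
        VariableSpec("x", "continuous", "normal", {"mean": 0, "sd": 0}, {"mean": 0, "sd": 1}, (0, 1), 1)
    with pytest.raises(ConfigurationError):
        VariableSpec("x", "binary", "bernoulli", {"p": 1.2}, {"p": 0.5}, (0, 1), 0)
    with pytest.raises(ConfigurationError):
        VariableSpec("x", "continuous", "normal", {"mean": 0, "sd": 1}, {"mean": 0, "sd": 1}, (2, 1), 1)
    with pytest.raises(ConfigurationError):
        VariableSpec("x", "continuous", "gamma", {"a": 1}, {"a": 1}, (0, 1), 1)


# ---------------------------------------------------------------------------
# Generation and split
# ---------------------------------------------------------------------------

def test_exact_cohort_composition(default_cohort):
    frame = default_cohort.frame
    assert len(frame) == 956
    assert int(frame["delirium"].sum()) == 326
    train = frame[frame["partition"] == "train"]
    test = frame[frame["partition"] == "test"]
    assert (len(train), int(train["delirium"].sum())) == (764, 250)
    assert (len(test), int(test["delirium"].sum())) == (192, 76)


def test_split_is_disjoint_and_exhaustive(default_cohort, default_spec):
    partition = fr.split_cohort(default_cohort, default_spec)
    assert set(partition.unique()) == {"train", "test"}
    assert (partition == "train").sum() + (partition == "test").sum() == 956


def test_split_rejects_inconsistent_counts(default_spec):
    frame = pd.DataFrame({"age": [70, 71], "delirium": [1, 0], "partition": ["train"] * 2})
    with pytest.raises(ValueError, match="do not match"):
        fr.split_cohort(Cohort(frame), default_spec)


def test_seed_determinism_bit_identical_csv(default_spec, default_cohort):
    again = fr.generate_cohort(default_spec, seed=COHORT_SEED)
    assert default_cohort.to_csv_bytes() == again.to_csv_bytes()
    other = fr.generate_cohort(default_spec, seed=COHORT_SEED + 1)
    assert default_cohort.to_csv_bytes() != other.to_csv_bytes()


def test_csv_roundtrip_preserves_missing_cells(cohort_with_missing, tmp_path):
    path = tmp_path / "cohort.csv"
    cohort_with_missing.to_csv(path)
    back = Cohort.from_csv(path)
    assert back.predictors.isna().sum().sum() == cohort_with_missing.predictors.isna().sum().sum()
    pd.testing.assert_frame_equal(back.frame, cohort_with_missing.frame)


def test_degenerate_bernoulli_yields_constant_column():
    var = VariableSpec("flag", "binary", "bernoulli", {"p": 1.0}, {"p": 1.0}, (0, 1), 0)
    spec = CohortSpec(variables=(var,), n_train_delirium=5, n_train_control=5,
                      n_test_delirium=2, n_test_control=2)
    cohort = fr.generate_cohort(spec, seed=1)
    assert (cohort.frame["flag"] == 1.0).all()


def test_unknown_family_rejected_at_spec_construction():
    with pytest.raises(ConfigurationError, match="family"):
        VariableSpec("x", "continuous", "weibull", {}, {}, (0, 1), 1)


def test_values_respect_clip_bounds(default_cohort, default_spec):
    for var in default_spec.variables:
        column = default_cohort.frame[var.name]
        assert column.min() >= var.clip[0]
        assert column.max() <= var.clip[1]


@pytest.mark.parametrize("name,group,label", [
    ("fdp", "delirium", 1), ("age", "delirium", 1), ("cfs", "delirium", 1),
    ("bmi", "nodelirium", 0), ("hemoglobin", "nodelirium", 0),
    ("sbp", "delirium", 1), ("fibrinogen", "delirium", 1),
])
def test_normal_marginals_within_three_standard_errors(default_cohort, default_spec, name, group, label):
    var = default_spec.variable(name)
    params = var.params_delirium if group == "delirium" else var.params_nodelirium
    rows = default_cohort.frame[default_cohort.frame["delirium"] == label]
    se = params["sd"] / np.sqrt(len(rows))
    assert abs(rows[name].mean() - params["mean"]) < 3 * se


@pytest.mark.parametrize("name", ["lactate", "iss", "heart_rate", "temperature", "crp"])
def test_lognormal_fit_reproduces_printed_median_analytically(default_spec, name):
    var = default_spec.variable(name)
    for group in ("delirium", "nodelirium"):
        params = var.params_delirium if group == "delirium" else var.params_nodelirium
        mu, _, shift = var.lognormal_mu_sigma(group)
        assert np.exp(mu) + shift == pytest.approx(params["median"], abs=1e-9)


# ---------------------------------------------------------------------------
# Missingness and imputation
# ---------------------------------------------------------------------------

def test_zero_rates_leave_cohort_unchanged(default_cohort, default_spec):
    import dataclasses
    spec = dataclasses.replace(
        default_spec, missing_rates={v.name: 0.0 for v in default_spec.variables}
    )
    unchanged = fr.inject_missingness(default_cohort, spec, seed=3)
    pd.testing.assert_frame_equal(unchanged.frame, default_cohort.frame)


def test_overall_completeness_matches_documented_rate(cohort_with_missing):
    cells = cohort_with_missing.predictors
    completeness = 100.0 * (1.0 - cells.isna().to_numpy().mean())
    assert completeness == pytest.approx(97.43, abs=0.3)


def test_fdp_missing_count_near_binomial_expectation(cohort_with_missing):
    # n=956, rate 0.026 -> mean ~24.9, sd ~4.9; allow +/- 4 sd
    n_missing = int(cohort_with_missing.frame["fdp"].isna().sum())
    assert 5 <= n_missing <= 45


def test_excessive_missing_rate_rejected(default_cohort, default_spec):
    import dataclasses
    with pytest.raises(ConfigurationError):
        dataclasses.replace(default_spec, missing_rates={"fdp": 0.2})


def test_impute_median_and_mode_rules():
    frame = pd.DataFrame(
        {
            "cont": [1.0, 2.0, np.nan, 4.0],
            "flag": [1.0, 1.0, 0.0, np.nan],
            "delirium": [1, 0, 1, 0],
            "partition": ["train"] * 4,
        }
    )
    filled = fr.impute(Cohort(frame))
    assert filled.frame.loc[2, "cont"] == 2.0  # median of {1,2,4}
    assert filled.frame.loc[3, "flag"] == 1.0  # mode of {1,1,0}


def test_impute_uses_training_statistics_only():
    frame = pd.DataFrame(
        {
            "cont": [1.0, 2.0, 3.0, 100.0, 200.0, np.nan],
            "delirium": [1, 0, 1, 0, 1, 0],
            "partition": ["train"] * 3 + ["test"] * 3,
        }
    )
    filled = fr.impute(Cohort(frame))
    assert filled.frame.loc[5, "cont"] == 2.0  # train median, not pooled


def test_impute_is_idempotent_and_identity_on_complete(cohort_with_missing, default_cohort):
    once = fr.impute(cohort_with_missing)
    twice = fr.impute(once)
    pd.testing.assert_frame_equal(once.frame, twice.frame)
    untouched = fr.impute(default_cohort)
    pd.testing.assert_frame_equal(untouched.frame, default_cohort.frame)


def test_entirely_missing_column_raises_naming_it():
    frame = pd.DataFrame(
        {
            "ghost": [np.nan, np.nan],
            "delirium": [1, 0],
            "partition": ["train", "train"],
        }
    )
    with pytest.raises(ValueError, match="ghost"):
        training_fill_values(Cohort(frame))


# ---------------------------------------------------------------------------
# Spec serialization
# ---------------------------------------------------------------------------

def test_spec_yaml_roundtrip(default_spec, tmp_path):
    path = tmp_path / "spec.yaml"
    spec_to_yaml(default_spec, path)
    back = spec_from_yaml(str(path))
    assert back.n_total == default_spec.n_total
    assert back.missing_rates == pytest.approx(default_spec.missing_rates)
    for original, loaded in zip(default_spec.variables, back.variables):
        assert loaded.name == original.name
        assert loaded.family == original.family
        assert loaded.params_delirium == pytest.approx(original.params_delirium)
    regenerated = fr.generate_cohort(back, seed=COHORT_SEED)
    reference = fr.generate_cohort(default_spec, seed=COHORT_SEED)
    assert regenerated.to_csv_bytes() == reference.to_csv_bytes()
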