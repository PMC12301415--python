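"""Shapley-value feature attribution for fitted risk models.

Attributions use the interventional value function

    v(S) = mean over background rows b of f(x_S, b_{~S})

i.e. features in the coalition S take their values from the explained row
and the rest are drawn from a background sample of training patients.
Two estimators are provided:

- exact enumeration over all 2^d coalitions (budgeted at d <= 12), which
  satisfies the efficiency axiom to machine precision: base value plus
  the sum of contributions equals the model's prediction for the row;
- a permutation-sampling Monte Carlo estimator for larger panels, which
  is unbiased for the exact values and seeded for reproducibility.

Global importance ranks features by the mean absolute contribution across
explained rows and emits the per-row (feature, contribution, value)
triples a beeswarm/summary plot is drawn from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "Attribution",
    "shapley_exact",
    "shapley_mc",
    "global_importance",
    "background_sample",
]

EXACT_BUDGET = 12


@dataclass
class Attribution:
    """Per-feature contributions to one prediction.

    ``base_value`` is the mean background prediction; for the exact
    estimator ``base_value + sum(per_feature.values())`` equals
    ``prediction`` to numerical precision.
    """

    per_feature: dict
    base_value: float
    prediction: float

    @property
    def total(self) -> float:
        return self.base_value + sum(self.per_feature.values())


def _as_predictor(model):
    """Accept a FittedModel-like object or a DataFrame -> probs callable."""
    if hasattr(model, "predict_frame"):
        return model.predict_frame, tuple(model.selected_feature_names)
    if callable(model):
        return model, None
    raise TypeError("model must expose predict_frame or be callable on a DataFrame")


def _background_frame(background, feature_names) -> pd.DataFrame:
    if isinstance(background, Cohort):
        frame = background.predictors
    else:
        frame = background
    if feature_names is not None:
        frame = frame[list(feature_names)]
    if frame.isna().any().any():
        raise ValueError("background rows must be complete (impute first)")
    return frame.reset_index(drop=True)


def background_sample(cohort: Cohort, n: int = 100, seed: int = 0) -> pd.DataFrame:
    """Seeded sample of training rows used as the attribution background."""
    train = cohort.frame[cohort.frame["partition"] == "train"]
    predictors = train.drop(columns=["delirium", "partition"])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(predictors), size=min(n, len(predictors)), replace=False)
    return predictors.iloc[np.sort(idx)].reset_index(drop=True)


def _row_values(row, columns) -> np.ndarray:
    if isinstance(row, pd.DataFrame):
        row = row.iloc[0]
    if isinstance(row, pd.Series):
        return row[list(columns)].to_numpy(dtype=float)
    return np.asarray([row[c] for c in columns], dtype=float)


def shapley_exact(model, row, background) -> Attribution:
    """Exact Shapley attribution by coalition enumeration (d <= 12).

    contribution_j = sum over coalitions S not containing j of
    |S|! (d-|S|-1)! / d! * [v(S + j) - v(S)].
    """
    predict, names = _as_predictor(model)
    bg = _background_frame(background, names)
    columns = list(bg.columns)
    d = len(columns)
    if d > EXACT_BUDGET:
        raise ValueError(
            f"{d} features exceeds the exact-enumeration budget of "
            f"{EXACT_BUDGET}; use shapley_mc"
        )
    x = _row_values(row, columns)
    n_bg = len(bg)
    bg_values = bg.to_numpy(dtype=float)

    # v(S) for every coalition, one batched model call
    n_masks = 1 << d
    tiles = np.tile(bg_values, (n_masks, 1))
    for mask in range(n_masks):
        block = slice(mask * n_bg, (mask + 1) * n_bg)
        for j in range(d):
            if mask >> j & 1:
                tiles[block, j] = x[j]
    values = predict(pd.DataFrame(tiles, columns=columns))
    v = np.asarray(values, dtype=float).reshape(n_masks, n_bg).mean(axis=1)

    fact = [math.factorial(k) for k in range(d + 1)]
    denominator = fact[d]
    contributions = np.zeros(d)
    for mask in range(n_masks):
        size = bin(mask).count("1")
        for j in range(d):
            if mask >> j & 1:
                continue
            weight = fact[size] * fact[d - size - 1] / denominator
            contributions[j] += weight * (v[mask | (1 << j)] - v[mask])
    return Attribution(
        per_feature=dict(zip(columns, contributions.tolist())),
        base_value=float(v[0]),
        prediction=float(v[n_masks - 1]),
    )


def shapley_mc(model, row, background, n_permutations: int = 200, seed: int = 0) -> Attribution:
    """Permutation-sampling Shapley estimate.

    Each iteration samples one background row and one feature ordering and
    walks the ordering, switching features from the background value to
    the explained row's value; the change in prediction at each step is
    that feature's marginal contribution.  Averaging over iterations gives
    an unbiased estimate of the exact Shapley values.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    predict, names = _as_predictor(model)
    bg = _background_frame(background, names)
    columns = list(bg.columns)
    d = len(columns)
    x = _row_values(row, columns)
    bg_values = bg.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # build all evaluation points, then one batched model call
    points = np.empty((n_permutations * (d + 1), d))
    orders = np.empty((n_permutations, d), dtype=int)
    for p in range(n_permutations):
        base_row = bg_values[rng.integers(len(bg_values))].copy()
        order = rng.permutation(d)
        orders[p] = order
        block = p * (d + 1)
        current = base_row.copy()
        points[block] = current
        for step, j in enumerate(order, start=1):
            current = current.copy()
            current[j] = x[j]
            points[block + step] = current
    values = np.asarray(predict(pd.DataFrame(points, columns=columns)), dtype=float)

    contributions = np.zeros(d)
    for p in range(n_permutations):
        block = p * (d + 1)
        deltas = np.diff(values[block : block + d + 1])
        contributions[orders[p]] += deltas
    contributions /= n_permutations

    base_value = float(np.asarray(predict(bg), dtype=float).mean())
    prediction = float(
        np.asarray(predict(pd.DataFrame(x[None, :], columns=columns)), dtype=float)[0]
    )
    return Attribution(
        per_feature=dict(zip(columns, contributions.tolist())),
        base_value=base_value,
        prediction=prediction,
    )


def global_importance(
    attributions: list[Attribution], rows: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank features by mean |contribution| and emit summary-plot data.

    Returns ``(ranking, summary)``: ``ranking`` has one row per feature
    (mean absolute contribution, descending); ``summary`` holds one row
    per (explained row, feature) with the contribution and, when ``rows``
    is given, the raw feature value for summary-plot coloring.
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    features = list(attributions[0].per_feature)
    matrix = np.array([[a.per_feature[f] for f in features] for a in attributions])
    mean_abs = np.abs(matrix).mean(axis=0)
    order = np.argsort(-mean_abs)
    ranking = pd.DataFrame(
        {
            "feature": [features[i] for i in order],
            "mean_abs_contribution": mean_abs[order],
            "rank": np.arange(1, len(features) + 1),
        }
    )
    records = []
    for r, attribution in enumerate(attributions):
        for f in features:
            value = math.nan
            if rows is not None and f in rows.columns:
                value = float(rows.iloc[r][f])
            records.append(
                {
                    "row": r,
                    "feature": f,
                    "contribution": attribution.per_feature[f],
                    "value": value,
                }
            )
    return ranking, pd.DataFrame(records)
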