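"""Exact Shapley attribution of service predictions to driver features.

A surrogate regression model f (a random forest by default, but any
object with a ``predict`` contract works) is fitted per service; each
feature's Shapley value for an instance x is the exact weighted average
of its marginal contributions over all feature subsets:

    phi_i = sum_{S subseteq N\\{i}} |S|! (|N|-|S|-1)! / |N|!  [f_x(S u {i}) - f_x(S)]

where the value function f_x(S) is the interventional expectation over a
background sample: features in S take the instance's values, the rest
take the background row's values, and predictions are averaged.  Full
subset enumeration is exact up to 15 features (2^15 coalitions); the
twelve standard drivers (TEM, PRE, ET, SPEI_F, EL, SL, NDVI, WUE, SOC,
RSMC, GDP, POP) are well inside that bound.

The axioms (efficiency, symmetry, dummy, linearity) hold by construction
and are exercised by the test suite against a permutation-averaged
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .exceptions import ConfigurationError, InsufficientDataError

#: the twelve standard driver features
DRIVER_FEATURES: tuple[str, ...] = (
    "TEM", "PRE", "ET", "SPEI_F", "EL", "SL", "NDVI", "WUE", "SOC", "RSMC", "GDP", "POP",
)

MAX_ENUM_FEATURES = 15


@dataclass
class SurrogatePredictor:
    """A fitted per-service regression predictor with name-bound features."""

    target: str
    feature_names: list[str]
    model: object  # anything with .predict(ndarray)
    seed: int
    holdout_r2: float

    def predict(self, X) -> np.ndarray:
        """Predict; DataFrame columns are re-ordered by feature name."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy()
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)))


@dataclass
class ShapleyAttribution:
    """Exact per-feature Shapley values for one instance."""

    feature_names: list[str]
    phi: np.ndarray
    baseline: float  # E[f] over the background
    fx: float  # prediction at the instance
    background_size: int


class _ConstantModel:
    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)


def fit_surrogate(
    features: pd.DataFrame,
    target: np.ndarray,
    target_name: str = "ES",
    seed: int = 0,
    n_estimators: int = 100,
    test_fraction: float = 0.25,
) -> SurrogatePredictor:
    """Fit a seeded random-forest surrogate with a held-out R² score.

    A constant target degenerates gracefully to a constant predictor
    (held-out R² reported as 1 since predictions are exact).
    """
    if len(features) < 50:
        raise InsufficientDataError("need at least 50 rows to fit a surrogate")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ConfigurationError("surrogate inputs contain missing values")
    names = list(features.columns)
    if np.ptp(y) == 0:
        import warnings

        warnings.warn("constant target: surrogate degenerates to the baseline", stacklevel=2)
        return SurrogatePredictor(target_name, names, _ConstantModel(y[0]), seed, 1.0)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_fraction, random_state=seed)
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(X_tr, y_tr)
    r2 = float(model.score(X_te, y_te))
    return SurrogatePredictor(target_name, names, model, seed, r2)


def value_function(
    predictor: SurrogatePredictor,
    instance: np.ndarray,
    subset: set[int] | frozenset[int] | list[int],
    background: np.ndarray,
) -> float:
    """Interventional value f_x(S): background rows with S set to the instance."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ConfigurationError("background set must be non-empty")
    rows = background.copy()
    idx = list(subset)
    rows[:, idx] = np.asarray(instance, dtype=float)[idx]
    return float(predictor.predict(rows).mean())


def _subset_values(
    predictor: SurrogatePredictor, instance: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """f_x(S) for every subset bitmask 0..2^n-1, one batched predict call."""
    n = len(instance)
    n_sub = 1 << n
    bits = ((np.arange(n_sub)[:, None] >> np.arange(n)) & 1).astype(bool)  # (n_sub, n)
    B = len(background)
    tiled = np.repeat(background[None, :, :], n_sub, axis=0)  # (n_sub, B, n)
    inst = np.broadcast_to(instance, (n_sub, B, n))
    design = np.where(bits[:, None, :], inst, tiled).reshape(n_sub * B, n)
    preds = predictor.predict(design).reshape(n_sub, B)
    return preds.mean(axis=1)


def exact_shapley(
    predictor: SurrogatePredictor,
    instance: np.ndarray,
    background: np.ndarray,
) -> ShapleyAttribution:
    """Exact Shapley values by full subset enumeration.

    Enumerates all 2^n coalitions (n <= 15) and applies the combinatorial
    weights |S|!(n-|S|-1)!/n!.  The efficiency identity
    ``sum(phi) = f(x) - E[f]`` holds to float precision.
    """
    instance = np.asarray(instance, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n = len(instance)
    if n > MAX_ENUM_FEATURES:
        raise ConfigurationError(
            f"{n} features exceeds the exact-enumeration bound of "
            f"{MAX_ENUM_FEATURES}; use a sampling approximation instead"
        )
    if background.size == 0:
        raise ConfigurationError("background set must be non-empty")
    v = _subset_values(predictor, instance, background)
    masks = np.arange(1 << n)
    sizes = np.array([bin(m).count("1") for m in masks])
    w = np.array(
        [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    )
    phi = np.zeros(n)
    for i in range(n):
        without = (masks & (1 << i)) == 0
        s_masks = masks[without]
        s_sizes = sizes[without]
        phi[i] = np.sum(w[s_sizes] * (v[s_masks | (1 << i)] - v[s_masks]))
    return ShapleyAttribution(
        feature_names=list(predictor.feature_names),
        phi=phi,
        baseline=float(v[0]),
        fx=float(v[-1]),
        background_size=len(background),
    )


def permutation_shapley(
    predictor: SurrogatePredictor,
    instance: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Oracle: average marginal contribution over all n! feature orderings.

    Exponentially slower than :func:`exact_shapley`; intended for
    cross-checking at n <= 5.
    """
    from itertools import permutations

    instance = np.asarray(instance, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n = len(instance)
    phi = np.zeros(n)
    count = 0
    for order in permutations(range(n)):
        s: set[int] = set()
        prev = value_function(predictor, instance, s, background)
        for i in order:
            s.add(i)
            cur = value_function(predictor, instance, s, background)
            phi[i] += cur - prev
            prev = cur
        count += 1
    return phi / count


def shap_summary(
    predictor: SurrogatePredictor,
    instances: pd.DataFrame,
    background: pd.DataFrame,
    max_instances: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute a sample of instances and rank features by mean |phi|.

    Returns ``(values, importance)``: per-(instance, feature) rows with
    the feature value and its phi, and a per-feature mean-|phi| ranking.
    Positive phi raises the predicted service.
    """
    rng = np.random.default_rng(seed)
    X = instances[predictor.feature_names].to_numpy(dtype=float)
    bg = background[predictor.feature_names].to_numpy(dtype=float)
    if len(X) > max_instances:
        take = rng.choice(len(X), size=max_instances, replace=False)
        X = X[take]
    rows = []
    for ridx, x in enumerate(X):
        att = exact_shapley(predictor, x, bg)
        for f, name in enumerate(predictor.feature_names):
            rows.append(
                {"instance": ridx, "feature": name, "value": x[f], "phi": att.phi[f]}
            )
    values = pd.DataFrame(rows)
    importance = (
        values.assign(abs_phi=values["phi"].abs())
        .groupby("feature", as_index=False)["abs_phi"]
        .mean()
        .rename(columns={"abs_phi": "mean_abs_phi"})
        .sort_values("mean_abs_phi", ascending=False)
        .reset_index(drop=True)
    )
    importance["rank"] = np.arange(1, len(importance) + 1)
    return values, importance
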