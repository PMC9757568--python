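"""Model-agnostic Shapley-value feature attributions.

The estimator is permutation sampling with background replacement: for each
sampled feature permutation a background row is drawn, features of the
explained observation are switched on in permutation order, and each
feature's marginal change in the model's decision score is accumulated.  The
estimate satisfies the efficiency identity exactly by construction — per
observation, the attributions sum to (score of the observation) minus (mean
score of the sampled background rows).

Exact enumeration over all 2^p coalitions is provided for small p, both as a
reference for the sampling estimator and for axiom-level verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable

import numpy as np
import pandas as pd

from .data import FeatureTable

ScoreFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class AttributionResult:
    """Signed per-observation, per-feature Shapley values in decision-score units."""

    feature_names: list[str]
    values: np.ndarray  # (n_obs, n_features)
    base_value: float
    y_true: np.ndarray
    feature_values: np.ndarray  # the explained rows, for sign-semantics plots
    efficiency_gap: float  # max |base + sum(attr) - score| over observations

    def mean_abs(self, class_label: int | None = None) -> np.ndarray:
        """Mean |value| per feature, optionally over rows of one true class."""
        vals = self.values
        if class_label is not None:
            vals = vals[self.y_true == class_label]
        if vals.shape[0] == 0:
            return np.zeros(len(self.feature_names))
        return np.abs(vals).mean(axis=0)

    def ranking(self) -> np.ndarray:
        """Feature indices in descending order of overall mean |value|."""
        return np.argsort(-self.mean_abs(), kind="stable")


def _resolve_score_fn(model) -> ScoreFn:
    if callable(model):
        return model
    if hasattr(model, "decision_scores"):  # FittedModel on raw arrays
        return lambda X: model.pipeline.decision_function(X)
    if hasattr(model, "decision_function"):
        return model.decision_function
    raise TypeError("model must be callable or expose decision_function")


def shapley_attributions(model, table: FeatureTable, background: np.ndarray,
                         n_permutations: int = 10, seed: int = 0,
                         exact: bool = False) -> AttributionResult:
    """Shapley values of the model's decision score for every row of *table*.

    background: rows (same features) whose draws replace switched-off
        features.  exact=True enumerates all coalitions (p <= 16 enforced)
        and averages the value function over all background rows.
    """
    if hasattr(model, "feature_names") and model.feature_names != table.feature_names:
        raise ValueError("feature names of the table do not match the fitted model")
    background = np.asarray(background, dtype=np.float64)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D array")
    if background.shape[1] != len(table.feature_names):
        raise ValueError("background feature count does not match the table")
    score = _resolve_score_fn(model)
    X = table.X
    if exact:
        values, base = _exact_shapley(score, X, background)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        fast = _svc_components(model)
        if fast is not None:
            values, base = _sampling_shapley_svc(fast, X, background,
                                                 n_permutations, seed)
        else:
            values, base = _sampling_shapley(score, X, background,
                                             n_permutations, seed)
    gap = float(np.max(np.abs(base + values.sum(axis=1) - score(X))))
    return AttributionResult(
        feature_names=list(table.feature_names),
        values=values,
        base_value=base,
        y_true=table.y.copy(),
        feature_values=X.copy(),
        efficiency_gap=gap,
    )


def _sampling_shapley(score: ScoreFn, X: np.ndarray, background: np.ndarray,
                      n_permutations: int, seed: int) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    n_obs, p = X.shape
    acc = np.zeros((n_obs, p))
    base_scores = []
    # chunk observations so the materialized permutation walk stays bounded
    step_bytes = (p + 1) * p * 8
    chunk = max(1, min(n_obs, int(6e8 // max(step_bytes, 1))))
    steps = np.arange(p + 1)[:, None]
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        z = background[rng.integers(background.shape[0])]
        pos = np.empty(p, dtype=np.int64)
        pos[perm] = np.arange(p)
        # walk[k] has the first k features (in permutation order) switched on
        mask = pos[None, :] < steps  # (p+1, p)
        for lo in range(0, n_obs, chunk):
            Xc = X[lo:lo + chunk]
            walk = np.where(mask[None, :, :], Xc[:, None, :], z[None, None, :])
            scores = score(walk.reshape(-1, p)).reshape(len(Xc), p + 1)
            acc[lo:lo + chunk, perm] += scores[:, 1:] - scores[:, :-1]
            if lo == 0:
                base_scores.append(scores[0, 0])
    values = acc / n_permutations
    base = float(np.mean(base_scores))
    return values, base


def _svc_components(model):
    """Extract (scaler, svc) from a fitted scaler+SVC pipeline when the
    permutation walk can be evaluated in closed form (linear or RBF kernel)."""
    pipeline = getattr(model, "pipeline", None)
    if pipeline is None:
        return None
    try:
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
    except ImportError:  # pragma: no cover
        return None
    if not isinstance(pipeline, Pipeline):
        return None
    steps = dict(pipeline.named_steps)
    scaler, svc = steps.get("scaler"), steps.get("svc")
    if (isinstance(scaler, StandardScaler) and isinstance(svc, SVC)
            and svc.kernel in ("linear", "rbf") and len(svc.classes_) == 2):
        return scaler, svc
    return None


def _sampling_shapley_svc(components, X: np.ndarray, background: np.ndarray,
                          n_permutations: int, seed: int) -> tuple[np.ndarray, float]:
    """Permutation-sampling estimator specialized to standardized SVC scores.

    Identical draws and estimates to the generic walk (up to floating-point
    association): the decision score along a one-feature-at-a-time walk is a
    function of a cumulative sum of per-feature kernel increments, so each
    permutation is a handful of array operations instead of p model calls.
    """
    scaler, svc = components
    rng = np.random.default_rng(seed)
    n_obs, p = X.shape
    Xs = scaler.transform(X)
    SV = svc.support_vectors_
    dual = svc.dual_coef_[0]
    intercept = float(svc.intercept_[0])
    acc = np.zeros((n_obs, p))
    base_scores = []
    if svc.kernel == "linear":
        w = dual @ SV
        for _ in range(n_permutations):
            _ = rng.permutation(p)  # keep the draw sequence aligned
            z = background[rng.integers(background.shape[0])]
            zs = scaler.transform(z[None, :])[0]
            base_scores.append(float(zs @ w + intercept))
            acc += (Xs - zs) * w  # marginal contributions are order-free
        return acc / n_permutations, float(np.mean(base_scores))
    gamma = svc._gamma
    A = (Xs[:, None, :] - SV[None, :, :]) ** 2  # (n_obs, n_sv, p)
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        z = background[rng.integers(background.shape[0])]
        zs = scaler.transform(z[None, :])[0]
        Bz = (zs[None, :] - SV) ** 2  # (n_sv, p)
        inc = (A - Bz[None, :, :])[:, :, perm]
        d2 = np.concatenate([
            np.zeros((n_obs, SV.shape[0], 1)),
            np.cumsum(inc, axis=2),
        ], axis=2) + (Bz.sum(axis=1))[None, :, None]
        scores = np.exp(-gamma * d2).transpose(0, 2, 1) @ dual + intercept
        acc[:, perm] += scores[:, 1:] - scores[:, :-1]
        base_scores.append(float(scores[0, 0]))
    return acc / n_permutations, float(np.mean(base_scores))


def _exact_shapley(score: ScoreFn, X: np.ndarray,
                   background: np.ndarray) -> tuple[np.ndarray, float]:
    n_obs, p = X.shape
    if p > 16:
        raise ValueError(f"exact enumeration is limited to 16 features, got {p}")
    n_bg = background.shape[0]
    n_sets = 1 << p
    # value of every coalition: mean over background rows of the score of
    # (observed features in S, background features elsewhere)
    v = np.empty((n_sets, n_obs))
    for s in range(n_sets):
        mask = np.array([(s >> j) & 1 for j in range(p)], dtype=bool)
        rows = np.repeat(background, n_obs, axis=0)  # (n_bg*n_obs, p)
        obs = np.tile(X, (n_bg, 1))
        rows[:, mask] = obs[:, mask]
        v[s] = score(rows).reshape(n_bg, n_obs).mean(axis=0)
    weights = np.array([comb(p - 1, k) for k in range(p)], dtype=np.float64)
    weights = 1.0 / (p * weights)
    values = np.zeros((n_obs, p))
    sizes = np.array([bin(s).count("1") for s in range(n_sets)])
    for j in range(p):
        bit = 1 << j
        without = np.array([s for s in range(n_sets) if not s & bit])
        w = weights[sizes[without]]
        contrib = v[without | bit] - v[without]
        values[:, j] = (w[:, None] * contrib).sum(axis=0)
    base = float(v[0].mean())
    return values, base


def rank_features(result: AttributionResult, top_k: int | None = None) -> pd.DataFrame:
    """Importance ranking: descending overall mean |value| with per-class split.

    Per-class columns average |value| over the rows whose *true* label is that
    class, mirroring the two-bar (control vs on-effect) importance charts.
    """
    overall = result.mean_abs()
    order = result.ranking()
    df = pd.DataFrame({
        "feature": [result.feature_names[i] for i in order],
        "mean_abs": overall[order],
        "mean_abs_class0": result.mean_abs(0)[order],
        "mean_abs_class1": result.mean_abs(1)[order],
    })
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)


def beeswarm_data(result: AttributionResult, top_k: int = 20) -> pd.DataFrame:
    """Long-form signed per-observation values with feature values for coloring."""
    order = result.ranking()[:top_k]
    records = []
    for rank, j in enumerate(order, start=1):
        for i in range(result.values.shape[0]):
            records.append({
                "rank": rank,
                "feature": result.feature_names[j],
                "shapley_value": float(result.values[i, j]),
                "feature_value": float(result.feature_values[i, j]),
                "true_class": int(result.y_true[i]),
            })
    return pd.DataFrame.from_records(records)
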