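"""Comparison arms: parameter accounting, the parameter-matched dense
baseline, and frozen-embedding regressors.

The dense baseline isolates architecture from capacity: a plain MLP on the
flattened embeddings whose hidden width is searched so its trainable
parameter count matches a reference adapter's within a relative tolerance
(1% by default). The frozen-embedding regressors (an MLP and a
gradient-boosted-tree model on mean-pooled embeddings) measure how much of
a task plain downstream regression can solve without any codon-aware
adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

from .adapters import Adapter, DenseAdapter
from .backbone import BackboneContract
from .errors import InfeasibleBudgetError, ValidationError
from .nnops import ParamDict

__all__ = [
    "ParamBudget",
    "count_params",
    "build_dense_baseline",
    "mean_pool_features",
    "frozen_embedding_regressor",
]


@dataclass(frozen=True)
class ParamBudget:
    """Target trainable-parameter count with a relative tolerance."""

    target_count: int
    tolerance: float = 0.01

    def __post_init__(self):
        if self.target_count < 1:
            raise ValidationError("target_count must be positive")
        if not (0.0 < self.tolerance <= 0.1):
            raise ValidationError("tolerance must lie in (0, 0.1]")


def count_params(component: ParamDict | Adapter | dict) -> int:
    """Exact count of trainable scalars (frozen backbones hold none here).

    Accepts a parameter dict; additive over disjoint components by
    construction.
    """
    if isinstance(component, Adapter):
        raise ValidationError("pass a parameter dict (adapter.init_params(rng))")
    return int(sum(np.asarray(v).size for v in component.values()))


def _dense_count(L: int, D: int, h: int) -> int:
    # (L·D)→h→h→1 with biases
    return L * D * h + h + h * h + h + h + 1


def build_dense_baseline(L: int, D: int, budget: ParamBudget) -> DenseAdapter:
    """Dense MLP adapter whose parameter count matches the budget.

    Deterministic integer search over the hidden width h: the smallest h
    achieving the closest count (ties to smaller h). Raises
    :class:`InfeasibleBudgetError`, reporting the nearest achievable count,
    when no width lands within tolerance.
    """
    if budget.target_count <= L * D:
        raise InfeasibleBudgetError(
            f"budget {budget.target_count} cannot cover even one hidden unit "
            f"over an input of {L * D} features", nearest_count=_dense_count(L, D, 1))
    best_h, best_gap = 1, abs(_dense_count(L, D, 1) - budget.target_count)
    h = 2
    while True:
        count = _dense_count(L, D, h)
        gap = abs(count - budget.target_count)
        if gap < best_gap:
            best_h, best_gap = h, gap
        if count > budget.target_count and gap >= best_gap:
            break
        h += 1
    if best_gap / budget.target_count > budget.tolerance:
        raise InfeasibleBudgetError(
            f"no hidden width matches {budget.target_count} within "
            f"{budget.tolerance:.1%}; nearest achievable count is "
            f"{_dense_count(L, D, best_h)} at h={best_h}",
            nearest_count=_dense_count(L, D, best_h))
    return DenseAdapter(L, D, best_h)


def mean_pool_features(backbone: BackboneContract, sequences: list[str]) -> np.ndarray:
    """Per-sequence features: mean of the backbone's embedding rows."""
    return np.stack([backbone.embed(s).mean(axis=0) for s in sequences])


def frozen_embedding_regressor(features: np.ndarray, targets: np.ndarray,
                               regressor_kind: str = "linear-mlp",
                               seed: int = 0):
    """Fit a standard regressor on frozen, mean-pooled embedding features.

    ``linear-mlp`` fits a small scikit-learn MLP; ``gradient-boosted-trees``
    fits an XGBoost regressor and degrades to a warning + ``None`` when
    xgboost is unavailable. Comparison arm only — hyperparameters are
    ordinary defaults, documented as choices.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.shape[0] != targets.shape[0]:
        raise ValidationError("features and targets disagree in length")
    if features.shape[0] < 10:
        raise ValidationError(
            f"refusing to fit on {features.shape[0]} samples (< 10)")
    if regressor_kind == "linear-mlp":
        # lbfgs: full-batch quasi-Newton, the reliable choice at the small
        # sample sizes these comparison arms see
        model = MLPRegressor(hidden_layer_sizes=(64,), max_iter=2000,
                             solver="lbfgs", random_state=seed)
        return model.fit(features, targets)
    if regressor_kind == "gradient-boosted-trees":
        try:
            from xgboost import XGBRegressor
        except ImportError:
            warnings.warn("xgboost unavailable; skipping gradient-boosted-trees arm")
            return None
        model = XGBRegressor(n_estimators=200, max_depth=4, learning_rate=0.1,
                             random_state=seed, verbosity=0)
        return model.fit(features, targets)
    raise ValidationError(f"unknown regressor_kind {regressor_kind!r}")
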