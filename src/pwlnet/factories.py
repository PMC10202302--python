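"""Estimator adapters for the double-cross-validation harness.

A factory is a callable ``factory(params) -> estimator`` where the
estimator exposes ``fit(X: FeatureMatrix, y: LabelVector)`` and
``predict_proba(X) -> N x C`` with columns in ``y.class_order``.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .containers import FeatureMatrix, LabelVector
from .evaluation import SearchSpace
from .model import ReallocationNetSpec, TrainConfig, fit_pwl


class PWLEstimator:
    def __init__(self, params: dict) -> None:
        self.params = dict(params)
        self.model = None

    def fit(self, X: FeatureMatrix, y: LabelVector) -> "PWLEstimator":
        p = self.params
        spec = ReallocationNetSpec(
            depth=int(p.get("depth", 3)),
            width=int(p.get("width", 16)),
            topology=p.get("topology", "unified"),
            activation=p.get("activation", "tanh"),
            seed=int(p.get("seed", 0)),
        )
        config = TrainConfig(
            mode=p.get("mode", "reallocated"),
            epochs=int(p.get("epochs", 300)),
            lr=float(p.get("lr", 0.05)),
            weight_decay=float(p.get("weight_decay", 1e-4)),
        )
        self.model = fit_pwl(X, y, spec, config)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(X)


class LogisticEstimator:
    """L2-regularised multinomial logistic regression baseline."""

    def __init__(self, params: dict) -> None:
        self.params = dict(params)
        self.est = None
        self.class_order: list[str] = []

    def fit(self, X: FeatureMatrix, y: LabelVector) -> "LogisticEstimator":
        self.class_order = list(y.class_order)
        self.est = LogisticRegression(
            C=float(self.params.get("C", 1.0)), max_iter=2000
        )
        self.est.fit(X.values, y.labels)
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
        proba = self.est.predict_proba(Xv)
        cols = {c: i for i, c in enumerate(self.est.classes_)}
        out = np.zeros((Xv.shape[0], len(self.class_order)))
        for j, c in enumerate(self.class_order):
            if c in cols:
                out[:, j] = proba[:, cols[c]]
        return out


def pwl_factory(params: dict) -> PWLEstimator:
    return PWLEstimator(params)


def logistic_factory(params: dict) -> LogisticEstimator:
    return LogisticEstimator(params)


def default_space(kind: str = "pwl") -> SearchSpace:
    space = SearchSpace()
    if kind == "pwl":
        space.add_int("depth", 2, 8)
        space.add_int("width", 4, 32)
        space.add_float("lr", 1e-3, 0.2, log=True)
        space.add_float("weight_decay", 1e-6, 1e-2, log=True)
    elif kind == "logistic":
        space.add_float("C", 1e-3, 1e3, log=True)
    else:
        raise ValueError(f"unknown estimator kind {kind!r}")
    return space
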