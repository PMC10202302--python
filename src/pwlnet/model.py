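"""Point-wise linear (PWL) models.

A PWL model predicts with a *sample-specific* linear model:

    y(x) = sigma( xi(x) . x ),      xi(x) = w (*) eta(x)

where ``eta`` is a neural network (the reallocation function), ``w`` is a
universal weight vector shared by all samples, and ``(*)`` is the Hadamard
product. Equivalently y = sigma(w . rho) with the reallocated feature
rho = eta(x) (*) x, i.e. the network bends the feature space until a single
hyperplane separates the classes. The per-sample coefficients xi(x) are what
makes the model self-explaining: their magnitudes read as per-sample feature
importances.

The ``straightforward`` variant lets the network emit xi(x) directly with no
universal weight; it is kept as a baseline because it generalises poorly on
nonlinear problems (the network can tailor a weight vector to every sample).

Multiclass uses one shared eta per sample, class-specific universal weights
w_c, and a softmax over the class scores xi_c . x. With two classes a single
weight row and a sigmoid head is the default.

An intercept is handled by augmenting x with a constant 1 feature, so xi
carries a point-wise intercept; ``intercept=False`` gives the strict
equation form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, EtaNetwork
from .containers import FeatureMatrix, LabelVector

__all__ = [
    "ReallocationNetSpec",
    "TrainConfig",
    "PWLModel",
    "PointWiseWeights",
    "predict_logistic",
    "reallocation_forward",
    "pointwise_weights",
    "reallocated_features",
    "predict_pwl",
    "fit_pwl",
]

_TOPOLOGIES = ("unified", "plain")
_ACTIVATIONS = ("tanh", "relu", "selu")


@dataclass(frozen=True)
class ReallocationNetSpec:
    """Architecture of the reallocation network eta.

    ``depth`` counts layers including the output layer and must be >= 2:
    a single-layer eta would make xi an affine function of x and the model
    would lose the ability to solve nonlinear problems.
    """

    depth: int = 3
    width: int = 16
    topology: str = "unified"
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError(
                f"reallocation network depth must be >= 2, got {self.depth}"
            )
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for :func:`fit_pwl`.

    Full-batch cross-entropy with Adam. ``weight_decay`` is L2 on weight
    matrices only. ``head`` is ``"sigmoid"`` (binary), ``"softmax"``, or
    ``None`` to pick sigmoid iff there are exactly two classes.
    """

    mode: str = "reallocated"
    epochs: int = 400
    lr: float = 0.05
    weight_decay: float = 1e-4
    intercept: bool = True
    head: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("reallocated", "straightforward"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.head not in (None, "sigmoid", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")


@dataclass
class PointWiseWeights:
    """Per-sample weights and reallocated features.

    ``xi`` is N x P for a sigmoid head and N x C x P otherwise (P = D, or
    D+1 with the intercept column last); ``eta`` is N x P and ``rho`` is
    eta (*) x_augmented, so xi . x == w . rho per sample and class.
    """

    xi: np.ndarray
    eta: np.ndarray
    rho: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _augment(X: np.ndarray, intercept: bool) -> np.ndarray:
    if not intercept:
        return X
    return np.hstack([X, np.ones((X.shape[0], 1))])


def predict_logistic(w: np.ndarray, X) -> np.ndarray:
    """Plain logistic regression sigma(w . x) for each sample.

    ``w`` of length D is interpreted as intercept-free; length D+1 treats
    the last element as an intercept on an implicit constant-1 feature.
    """
    Xv = _as_values(X)
    w = np.asarray(w, dtype=float).ravel()
    d = Xv.shape[1]
    if w.size == d:
        z = Xv @ w
    elif w.size == d + 1:
        z = Xv @ w[:-1] + w[-1]
    else:
        raise ValueError(
            f"weight length {w.size} does not match feature dimension {d} (or {d + 1})"
        )
    return _sigmoid(z)


class PWLModel:
    """A trained (or explicitly initialised) point-wise linear model."""

    def __init__(
        self,
        spec: ReallocationNetSpec,
        class_order: list[str],
        feature_names: list[str],
        mode: str = "reallocated",
        intercept: bool = True,
        head: str | None = None,
    ) -> None:
        self.spec = spec
        self.class_order = list(class_order)
        self.feature_names = list(feature_names)
        self.mode = mode
        self.intercept = intercept
        C = len(class_order)
        if head is None:
            head = "sigmoid" if C == 2 else "softmax"
        if head == "sigmoid" and C != 2:
            raise ValueError("sigmoid head requires exactly 2 classes")
        self.head = head
        self.n_classes = C
        self._c_eff = 1 if head == "sigmoid" else C
        D = len(feature_names)
        self._p = D + 1 if intercept else D
        rng = np.random.default_rng(spec.seed)
        if mode == "reallocated":
            self.net = EtaNetwork(
                D, self._p, spec.depth, spec.width, spec.topology,
                spec.activation, rng=rng, out_init="unit",
            )
            # small symmetric init; eta starts at exactly 1 so the initial
            # decision function is an ordinary logistic regression in w
            self.universal_weights = rng.normal(0.0, 0.01, size=(self._c_eff, self._p))
        elif mode == "straightforward":
            self.net = EtaNetwork(
                D, self._c_eff * self._p, spec.depth, spec.width, spec.topology,
                spec.activation, rng=rng, out_init="random",
            )
            self.universal_weights = None
        else:
            raise ValueError(f"unknown mode {mode!r}")
        self.loss_history: list[float] = []
        self.fitted = False

    # -- forward pieces -------------------------------------------------

    def _check_features(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix) and X.feature_names != self.feature_names:
            missing = [f for f in self.feature_names if f not in set(X.feature_names)]
            raise ValueError(
                "feature names do not match training-time names; "
                f"missing from input: {missing[:10]}"
            )
        Xv = _as_values(X)
        if Xv.shape[1] != len(self.feature_names):
            raise ValueError(
                f"input has {Xv.shape[1]} features, model expects {len(self.feature_names)}"
            )
        if not np.all(np.isfinite(Xv)):
            raise ValueError("non-finite values in input matrix")
        return Xv

    def eta(self, X) -> np.ndarray:
        """Reallocation vectors, shape N x P (intercept column last)."""
        if self.mode != "reallocated":
            raise ValueError("eta is defined only for reallocated models")
        Xv = self._check_features(X)
        return self.net.forward(Xv)

    def _xi(self, X) -> np.ndarray:
        Xv = self._check_features(X)
        if self.mode == "reallocated":
            eta = self.net.forward(Xv)
            xi = self.universal_weights[None, :, :] * eta[:, None, :]
        else:
            out = self.net.forward(Xv)
            xi = out.reshape(Xv.shape[0], self._c_eff, self._p)
        return xi  # N x C_eff x P

    def pointwise(self, X) -> PointWiseWeights:
        """xi, eta and rho for every sample (eta is all-ones conceptually in
        straightforward mode and is reported as such)."""
        Xv = self._check_features(X)
        Xa = _augment(Xv, self.intercept)
        xi = self._xi(X)
        if self.mode == "reallocated":
            eta = self.net.forward(Xv)
        else:
            eta = np.ones((Xv.shape[0], self._p))
        rho = eta * Xa
        if xi.shape[1] == 1:
            xi = xi[:, 0, :]
        return PointWiseWeights(xi=xi, eta=eta, rho=rho)

    def decision_scores(self, X) -> np.ndarray:
        """Class scores xi_c . x, shape N x C_eff."""
        Xv = self._check_features(X)
        Xa = _augment(Xv, self.intercept)
        xi = self._xi(X)
        return np.einsum("ncp,np->nc", xi, Xa)

    def predict_proba(self, X) -> np.ndarray:
        """Probability matrix N x C in ``class_order`` order."""
        z = self.decision_scores(X)
        if self.head == "sigmoid":
            p1 = _sigmoid(z[:, 0])
            return np.column_stack([1.0 - p1, p1])
        return _softmax(z)

    def predict(self, X) -> list[str]:
        idx = self.predict_proba(X).argmax(axis=1)
        return [self.class_order[i] for i in idx]

    # -- serialisation ---------------------------------------------------

    def state(self) -> dict:
        return {
            "schema_version": 1,
            "spec": dataclasses.asdict(self.spec),
            "class_order": self.class_order,
            "feature_names": self.feature_names,
            "mode": self.mode,
            "intercept": self.intercept,
            "head": self.head,
            "net": self.net.state(),
            "universal_weights": None
            if self.universal_weights is None
            else self.universal_weights.tolist(),
            "loss_history": self.loss_history,
            "fitted": self.fitted,
        }

    @classmethod
    def from_state(cls, state: dict) -> "PWLModel":
        if state.get("schema_version") != 1:
            raise ValueError(f"unsupported schema version {state.get('schema_version')}")
        spec = ReallocationNetSpec(**state["spec"])
        model = cls(
            spec,
            state["class_order"],
            state["feature_names"],
            mode=state["mode"],
            intercept=state["intercept"],
            head=state["head"],
        )
        model.net.load_state(state["net"])
        if state["universal_weights"] is not None:
            model.universal_weights = np.asarray(state["universal_weights"], dtype=float)
        model.loss_history = list(state["loss_history"])
        model.fitted = bool(state["fitted"])
        return model


# -- spec-surface free functions ----------------------------------------


def reallocation_forward(model: PWLModel, X) -> np.ndarray:
    """Reallocation vectors eta(x), shape N x P."""
    return model.eta(X)


def pointwise_weights(model: PWLModel, eta: np.ndarray) -> np.ndarray:
    """Point-wise weights xi = w (*) eta, per class."""
    eta = np.asarray(eta, dtype=float)
    if model.universal_weights is None:
        raise ValueError("straightforward models have no universal weights")
    W = model.universal_weights
    if eta.shape[1] != W.shape[1]:
        raise ValueError(
            f"eta has {eta.shape[1]} columns, universal weights have {W.shape[1]}"
        )
    xi = W[None, :, :] * eta[:, None, :]
    return xi[:, 0, :] if W.shape[0] == 1 else xi


def reallocated_features(eta: np.ndarray, X, intercept: bool = True) -> np.ndarray:
    """rho = eta (*) x (x augmented with a constant 1 when intercept)."""
    eta = np.asarray(eta, dtype=float)
    Xa = _augment(_as_values(X), intercept)
    if eta.shape != Xa.shape:
        raise ValueError(f"eta shape {eta.shape} != augmented X shape {Xa.shape}")
    return eta * Xa


def predict_pwl(model: PWLModel, X) -> np.ndarray:
    """Probability matrix N x C (binary sigmoid head packed as [1-p, p])."""
    return model.predict_proba(X)


def fit_pwl(
    X,
    y: LabelVector,
    spec: ReallocationNetSpec | None = None,
    config: TrainConfig | None = None,
) -> PWLModel:
    """Train a PWL model with full-batch Adam on the cross-entropy loss.

    Deterministic for a fixed ``spec.seed``: identical seed and config give
    bit-identical parameters on the same machine.
    """
    spec = spec or ReallocationNetSpec()
    config = config or TrainConfig()
    Xv = _as_values(X)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite values in training matrix")
    names = (
        X.feature_names
        if isinstance(X, FeatureMatrix)
        else [f"x{j}" for j in range(Xv.shape[1])]
    )
    C = y.n_classes
    n = Xv.shape[0]
    if n < 2 * C:
        raise ValueError(f"need at least {2 * C} samples for {C} classes, got {n}")
    if len(set(y.labels)) < 2:
        raise ValueError("labels must cover at least 2 classes")

    model = PWLModel(
        spec, y.class_order, names,
        mode=config.mode, intercept=config.intercept, head=config.head,
    )
    Xa = _augment(Xv, config.intercept)
    idx = y.to_indices()
    params = dict(model.net.params)
    if model.universal_weights is not None:
        params["W_univ"] = model.universal_weights
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    if model.head == "sigmoid":
        ybin = (idx == 1).astype(float)
    else:
        Y = np.zeros((n, C))
        Y[np.arange(n), idx] = 1.0

    for epoch in range(config.epochs):
        cache: dict = {}
        out = model.net.forward(Xv, cache=cache)
        if model.mode == "reallocated":
            eta = out
            R = eta * Xa
            z = R @ model.universal_weights.T
        else:
            xi = out.reshape(n, model._c_eff, model._p)
            z = np.einsum("ncp,np->nc", xi, Xa)

        if model.head == "sigmoid":
            zz = z[:, 0]
            # stable BCE: log(1+e^-|z|) + max(z,0) - z*y
            loss = float(np.mean(np.log1p(np.exp(-np.abs(zz))) + np.maximum(zz, 0) - zz * ybin))
            dz = ((_sigmoid(zz) - ybin) / n)[:, None]
        else:
            zs = z - z.max(axis=1, keepdims=True)
            logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
            loss = float(-np.mean(logp[np.arange(n), idx]))
            dz = (np.exp(logp) - Y) / n
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (non-finite loss) at epoch {epoch}; "
                "reduce the learning rate or increase weight decay"
            )
        model.loss_history.append(loss)

        if model.mode == "reallocated":
            grads = model.net.backward(cache, (dz @ model.universal_weights) * Xa)
            grads["W_univ"] = dz.T @ R
        else:
            d_xi = dz[:, :, None] * Xa[:, None, :]
            grads = model.net.backward(cache, d_xi.reshape(n, -1))
        opt.step(grads)

    model.fitted = True
    return model
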