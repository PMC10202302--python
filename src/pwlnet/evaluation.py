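"""Model evaluation: per-class AUC, K-fold double cross-validation with an
inner hyperparameter search, and Tukey HSD comparison between models.

Double cross-validation (DCV) measures the performance of the *entire*
learning procedure, hyperparameter selection included. Each of K outer
folds holds out a test split; inside the remaining samples, L_trials
hyperparameter sets are proposed sequentially and each is scored by M-fold
stratified cross-validation with the mean AUC

    MeanAUC = (1/K) sum_k (1/C) sum_t AUC(k, t)

over one-vs-rest per-class AUCs. The best set is then refit on the whole
outer-training split and scored on the held-out fold, so the search never
touches outer test data. The inner loops perform exactly K * L_trials * M
training runs (the final per-fold refits are counted separately).

Samplers: ``random`` draws i.i.d. from the space; ``tpe`` is a
tree-structured-Parzen-estimator-style sampler that, after a startup phase,
splits past trials at a quantile into good/bad groups and proposes the
candidate maximising the good/bad density ratio, independently per
dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import FeatureMatrix, LabelVector

__all__ = [
    "SearchSpace",
    "DCVReport",
    "per_class_auc",
    "mean_auc",
    "inner_cv_objective",
    "double_cross_validate",
    "tukey_comparison",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- metrics


def per_class_auc(scores: np.ndarray, y: LabelVector) -> np.ndarray:
    """One-vs-rest AUC per class (rank statistic, ties counted 1/2).

    A class without both a positive and a negative sample has no defined
    AUC; it is returned as NaN with a warning. If no class is defined an
    error is raised.
    """
    scores = np.asarray(scores, dtype=float)
    idx = y.to_indices()
    C = y.n_classes
    if scores.shape != (len(idx), C):
        raise ValueError(f"scores shape {scores.shape} != ({len(idx)}, {C})")
    out = np.full(C, np.nan)
    for c in range(C):
        pos = idx == c
        n_pos = int(pos.sum())
        n_neg = len(idx) - n_pos
        if n_pos and n_neg:
            # Mann-Whitney rank form; average ranks count ties as 1/2
            ranks = rankdata(scores[:, c])
            out[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if np.all(np.isnan(out)):
        raise ValueError("no class has both positive and negative samples")
    if np.any(np.isnan(out)):
        missing = [y.class_order[c] for c in np.flatnonzero(np.isnan(out))]
        logger.warning("AUC undefined for classes %s; excluded from averages", missing)
    return out


def mean_auc(auc: np.ndarray) -> float:
    """Mean over folds then classes of a K x C AUC matrix (NaNs masked)."""
    auc = np.atleast_2d(np.asarray(auc, dtype=float))
    if auc.size == 0:
        raise ValueError("empty AUC matrix")
    if np.isnan(auc).any():
        logger.warning("missing AUC entries are excluded from the mean")
    with np.errstate(invalid="ignore"):
        per_fold = np.nanmean(auc, axis=1)
    return float(np.nanmean(per_fold))


# ----------------------------------------------------------- search space


@dataclass(frozen=True)
class _Dim:
    kind: str  # int | float | categorical
    low: float | None = None
    high: float | None = None
    log: bool = False
    choices: tuple = ()


@dataclass
class SearchSpace:
    """Named hyperparameter dimensions with ranges or choices."""

    dims: dict[str, _Dim] = field(default_factory=dict)

    def add_int(self, name: str, low: int, high: int) -> "SearchSpace":
        if high < low:
            raise ValueError(f"empty range for {name}")
        self.dims[name] = _Dim("int", low, high)
        return self

    def add_float(self, name: str, low: float, high: float, log: bool = False) -> "SearchSpace":
        if high < low or (log and low <= 0):
            raise ValueError(f"invalid range for {name}")
        self.dims[name] = _Dim("float", low, high, log=log)
        return self

    def add_categorical(self, name: str, choices) -> "SearchSpace":
        choices = tuple(choices)
        if not choices:
            raise ValueError(f"no choices for {name}")
        self.dims[name] = _Dim("categorical", choices=choices)
        return self

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, d in self.dims.items():
            if d.kind == "int":
                out[name] = int(rng.integers(int(d.low), int(d.high) + 1))
            elif d.kind == "float":
                if d.log:
                    out[name] = float(np.exp(rng.uniform(np.log(d.low), np.log(d.high))))
                else:
                    out[name] = float(rng.uniform(d.low, d.high))
            else:
                out[name] = d.choices[int(rng.integers(len(d.choices)))]
        return out


class _RandomSampler:
    def __init__(self, space: SearchSpace, seed: int) -> None:
        self.space = space
        self.rng = np.random.default_rng(seed)

    def propose(self) -> dict:
        return self.space.sample(self.rng)

    def record(self, params: dict, value: float) -> None:
        pass


class _TPESampler:
    """Minimal TPE-style sampler: propose the candidate with the highest
    per-dimension good/bad density ratio among random candidates."""

    def __init__(self, space: SearchSpace, seed: int, gamma: float = 0.25,
                 n_startup: int = 10, n_candidates: int = 24) -> None:
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.gamma, self.n_startup, self.n_candidates = gamma, n_startup, n_candidates
        self.history: list[tuple[dict, float]] = []

    def record(self, params: dict, value: float) -> None:
        self.history.append((params, value))

    def _dim_logratio(self, name: str, d: _Dim, value, good: list[dict], bad: list[dict]) -> float:
        def density(group: list[dict]) -> float:
            vals = [g[name] for g in group]
            if d.kind == "categorical":
                counts = sum(v == value for v in vals)
                return (counts + 1.0) / (len(vals) + len(d.choices))
            x = np.array(
                [np.log(v) if d.log else float(v) for v in vals], dtype=float
            )
            v0 = np.log(value) if d.log else float(value)
            lo = np.log(d.low) if d.log else float(d.low)
            hi = np.log(d.high) if d.log else float(d.high)
            bw = max((hi - lo) / max(np.sqrt(len(x)), 1.0), 1e-12)
            kern = np.exp(-0.5 * ((v0 - x) / bw) ** 2).sum() + 1e-12
            return float(kern)

        return np.log(density(good)) - np.log(density(bad))

    def propose(self) -> dict:
        if len(self.history) < self.n_startup:
            return self.space.sample(self.rng)
        hist = sorted(self.history, key=lambda t: -t[1])
        n_good = max(1, int(np.ceil(self.gamma * len(hist))))
        good = [p for p, _ in hist[:n_good]]
        bad = [p for p, _ in hist[n_good:]] or good
        best, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            cand = self.space.sample(self.rng)
            score = sum(
                self._dim_logratio(name, d, cand[name], good, bad)
                for name, d in self.space.dims.items()
            )
            if score > best_score:
                best, best_score = cand, score
        return best


def _make_sampler(name: str, space: SearchSpace, seed: int):
    if name == "random":
        return _RandomSampler(space, seed)
    if name == "tpe":
        return _TPESampler(space, seed)
    raise ValueError(f"unknown sampler {name!r}; choose 'tpe' or 'random'")


# ------------------------------------------------------------------- DCV


@dataclass
class DCVReport:
    class_order: list[str]
    test_auc: np.ndarray            # K x C
    train_auc: np.ndarray           # K x C
    chosen_hyperparams: list[dict]
    mean_test_auc: float
    mean_train_auc: float
    training_run_count: int         # inner-loop fits only (= K * L * M)
    outer_test_ids: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "test_auc": self.test_auc.tolist(),
            "train_auc": self.train_auc.tolist(),
            "chosen_hyperparams": self.chosen_hyperparams,
            "mean_test_auc": self.mean_test_auc,
            "mean_train_auc": self.mean_train_auc,
            "training_run_count": self.training_run_count,
            "outer_test_ids": self.outer_test_ids,
        }


def _fit_score(factory, params, X, y, train_idx, eval_idx, counter) -> np.ndarray:
    est = factory(params)
    est.fit(X.subset_samples(train_idx), y.subset(train_idx))
    counter[0] += 1
    scores = np.asarray(est.predict_proba(X.subset_samples(eval_idx)))
    return per_class_auc(scores, y.subset(eval_idx))


def inner_cv_objective(
    X: FeatureMatrix,
    y: LabelVector,
    factory,
    params: dict,
    M: int = 10,
    seed: int = 0,
    counter: list | None = None,
) -> float:
    """Mean AUC of ``factory(params)`` under M-fold stratified CV."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    counter = counter if counter is not None else [0]
    skf = StratifiedKFold(n_splits=M, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X.values, y.to_indices()):
        aucs.append(_fit_score(factory, params, X, y, tr, va, counter))
    return mean_auc(np.vstack(aucs))


def double_cross_validate(
    X: FeatureMatrix,
    y: LabelVector,
    factory,
    space: SearchSpace,
    K: int = 10,
    M: int = 10,
    L_trials: int = 100,
    seed: int = 0,
    sampler: str = "tpe",
) -> DCVReport:
    """K-fold double cross-validation with an inner hyperparameter search.

    ``factory(params)`` must return an estimator with ``fit(X, y)`` and
    ``predict_proba(X) -> N x C``. Fold assignment, trial sequence and the
    report are all deterministic for a fixed seed.
    """
    if K < 2 or M < 2:
        raise ValueError("K and M must both be >= 2")
    if L_trials < 1:
        raise ValueError("L_trials must be >= 1")
    if not space.dims:
        raise ValueError("empty search space")
    C = y.n_classes
    outer = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    test_auc = np.full((K, C), np.nan)
    train_auc = np.full((K, C), np.nan)
    chosen: list[dict] = []
    outer_ids: list[list[str]] = []
    counter = [0]
    for k, (tr, te) in enumerate(outer.split(X.values, y.to_indices())):
        X_tr, y_tr = X.subset_samples(tr), y.subset(tr)
        smp = _make_sampler(sampler, space, seed * 1000 + k)
        best_params, best_val = None, -np.inf
        for _ in range(L_trials):
            params = smp.propose()
            val = inner_cv_objective(X_tr, y_tr, factory, params, M=M,
                                     seed=seed * 1000 + k, counter=counter)
            smp.record(params, val)
            if val > best_val:
                best_params, best_val = params, val
        chosen.append(best_params)
        # final refit on the full outer-training split (not part of the
        # K*L*M inner-loop count)
        est = factory(best_params)
        est.fit(X_tr, y_tr)
        test_auc[k] = per_class_auc(
            np.asarray(est.predict_proba(X.subset_samples(te))), y.subset(te)
        )
        train_auc[k] = per_class_auc(np.asarray(est.predict_proba(X_tr)), y_tr)
        outer_ids.append([X.sample_ids[i] for i in te])
    assert counter[0] == K * L_trials * M
    return DCVReport(
        class_order=list(y.class_order),
        test_auc=test_auc,
        train_auc=train_auc,
        chosen_hyperparams=chosen,
        mean_test_auc=mean_auc(test_auc),
        mean_train_auc=mean_auc(train_auc),
        training_run_count=counter[0],
        outer_test_ids=outer_ids,
    )


# ------------------------------------------------------------- Tukey HSD


def tukey_comparison(auc_samples: dict[str, np.ndarray], fwer: float = 0.05) -> pd.DataFrame:
    """Pairwise Tukey honest-significance comparison of per-fold AUCs.

    ``auc_samples`` maps model name -> K-vector of fold-level mean AUCs.
    Returns one row per pair with the mean difference, adjusted p-value and
    a reject flag at the given family-wise error rate.
    """
    names = list(auc_samples)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    lengths = {len(np.asarray(v)) for v in auc_samples.values()}
    if len(lengths) != 1:
        raise ValueError("all models must have the same number of folds")
    values = np.concatenate([np.asarray(auc_samples[n], dtype=float) for n in names])
    groups = np.concatenate([[n] * len(auc_samples[n]) for n in names])
    if all(np.ptp(np.asarray(v, dtype=float)) == 0.0 for v in auc_samples.values()):
        raise ValueError("zero within-group variance in every group; Tukey HSD is degenerate")
    res = pairwise_tukeyhsd(values, groups, alpha=fwer)
    df = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    df = df.rename(columns={"group1": "model_a", "group2": "model_b",
                            "meandiff": "mean_diff", "p-adj": "p_adj"})
    df["reject"] = df["reject"].astype(bool)
    df["p_adj"] = df["p_adj"].astype(float)
    df["mean_diff"] = df["mean_diff"].astype(float)
    return df[["model_a", "model_b", "mean_diff", "p_adj", "reject"]]
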