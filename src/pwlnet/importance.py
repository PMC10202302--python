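"""Feature-importance scoring from point-wise weights.

The point-wise weight vector xi(x) is a per-sample set of regression
coefficients, so xi_k * x_k is the k-th feature's contribution to the
sample's decision score. The sample-wise importance score contrasts that
contribution with its mean over the sample's weight-space neighbourhood
U_(n) -- the set of samples whose linear models are similar:

    s_k(n) = xi_k(n) x_k(n) - (1/|U_(n)|) sum_{i in U_(n)} xi_k(i) x_k(i)

A sample i belongs to U_(n) when ||xi(i) - xi(n)|| / ||xi(n)|| <= 4||sigma||
/ ||xi_bar||, with sigma and xi_bar the element-wise standard deviation and
mean of xi over samples; all norms are Euclidean and the anchor is always a
member.

Group scores are obtained by voting: each member of a group votes for its
ceil(top_fraction * D) highest-s features, and v_k is the fraction of
members voting for feature k. Contrasting a target subtype against the rest
gives the relative score v_rel = v_target^2 - v_others^2 in [-1, 1]; the
top-ranked features by v_rel are the ones that characterise the subtype.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, LabelVector
from .model import PWLModel

__all__ = [
    "NeighborhoodSet",
    "neighborhood_sets",
    "neighborhood_set",
    "samplewise_importance",
    "groupwise_importance",
    "relative_score",
    "rank_features",
    "class_importance_table",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodSet:
    anchor: int
    members: np.ndarray  # sorted sample indices, anchor included
    threshold_value: float


def _neighborhood_threshold(xi: np.ndarray) -> float:
    sigma = xi.std(axis=0, ddof=0)
    xi_bar = xi.mean(axis=0)
    denom = float(np.linalg.norm(xi_bar))
    num = float(np.linalg.norm(sigma))
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        logger.warning("zero-norm mean of xi with nonzero spread; "
                       "neighbourhood threshold is +inf (all samples)")
        return math.inf
    return 4.0 * num / denom


def neighborhood_sets(xi: np.ndarray) -> list[NeighborhoodSet]:
    """U_(n) for every sample, from the N x D point-wise weight matrix."""
    xi = np.asarray(xi, dtype=float)
    n = xi.shape[0]
    thr = _neighborhood_threshold(xi)
    norms = np.linalg.norm(xi, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise ValueError(f"sample {bad} has zero-norm point-wise weights")
    # pairwise distances; N is modest (hundreds) in intended use
    dists = np.linalg.norm(xi[:, None, :] - xi[None, :, :], axis=2)
    rel = dists / norms[:, None]
    out = []
    for i in range(n):
        members = np.flatnonzero(rel[i] <= thr)
        if i not in members:
            members = np.union1d(members, [i])
        out.append(NeighborhoodSet(anchor=i, members=members, threshold_value=thr))
    return out


def neighborhood_set(xi: np.ndarray, n: int) -> NeighborhoodSet:
    """U_(n) for a single sample."""
    return neighborhood_sets(np.asarray(xi, dtype=float))[n]


def samplewise_importance(xi: np.ndarray, X) -> np.ndarray:
    """N x D matrix of sample-wise scores s_k(n)."""
    xi = np.asarray(xi, dtype=float)
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if xi.shape != Xv.shape:
        raise ValueError(f"xi shape {xi.shape} != X shape {Xv.shape}")
    contrib = xi * Xv
    sets = neighborhood_sets(xi)
    s = np.empty_like(contrib)
    for ns in sets:
        s[ns.anchor] = contrib[ns.anchor] - contrib[ns.members].mean(axis=0)
    return s


def groupwise_importance(samplewise: np.ndarray, members, top_fraction: float = 0.10) -> np.ndarray:
    """Voting score v in [0,1]^D: fraction of group members whose top
    ceil(top_fraction*D) sample-wise scores include each feature.

    Ties between equal scores are broken by ascending feature index.
    """
    s = np.asarray(samplewise, dtype=float)
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty group")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    d = s.shape[1]
    k = math.ceil(top_fraction * d)
    votes = np.zeros(d)
    for m in members:
        # stable sort on -s keeps ascending index order among ties
        top = np.argsort(-s[m], kind="stable")[:k]
        votes[top] += 1.0
    return votes / members.size


def relative_score(v_target: np.ndarray, v_others: np.ndarray) -> np.ndarray:
    """v_rel = v_target^2 - v_others^2, element-wise, in [-1, 1]."""
    vt = np.asarray(v_target, dtype=float)
    vo = np.asarray(v_others, dtype=float)
    if vt.shape != vo.shape:
        raise ValueError(f"shape mismatch {vt.shape} vs {vo.shape}")
    for name, v in (("v_target", vt), ("v_others", vo)):
        if np.any((v < 0.0) | (v > 1.0)):
            raise ValueError(f"{name} has entries outside [0, 1]")
    return vt**2 - vo**2


def rank_features(v_rel: np.ndarray, feature_names: list[str], k: int = 500) -> pd.DataFrame:
    """Top-k features by v_rel descending; ties broken by ascending name."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    v = np.asarray(v_rel, dtype=float)
    order = sorted(range(len(v)), key=lambda i: (-v[i], feature_names[i]))[: min(k, len(v))]
    return pd.DataFrame(
        {
            "feature": [feature_names[i] for i in order],
            "v_rel": v[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def class_importance_table(
    model: PWLModel,
    X: FeatureMatrix,
    y: LabelVector,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """One-vs-rest relative scores for every class and feature.

    For each class c the point-wise weights are the class's own xi_c block
    (intercept column excluded -- it is not a gene); the target group is the
    class's samples and the others group is the complement. Returns a tidy
    frame with columns feature, class, v_target, v_others, v_rel.
    """
    pw = model.pointwise(X)
    xi = pw.xi
    if xi.ndim == 2:
        xi = xi[:, None, :]  # sigmoid head: one shared block
    d = X.n_features
    idx = y.to_indices()
    frames = []
    for c, cname in enumerate(y.class_order):
        if xi.shape[1] == 1:
            # sigmoid head: xi scores the second class; flip for the first
            block = xi[:, 0, :d] * (1.0 if c == 1 else -1.0)
        else:
            block = xi[:, c, :d]
        s = samplewise_importance(block, X.values)
        target = np.flatnonzero(idx == c)
        others = np.flatnonzero(idx != c)
        if target.size == 0 or others.size == 0:
            logger.warning("class %s has an empty group; skipped", cname)
            continue
        vt = groupwise_importance(s, target, top_fraction)
        vo = groupwise_importance(s, others, top_fraction)
        frames.append(
            pd.DataFrame(
                {
                    "feature": X.feature_names,
                    "class": cname,
                    "v_target": vt,
                    "v_others": vo,
                    "v_rel": relative_score(vt, vo),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
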