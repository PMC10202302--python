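"""Seeded synthetic datasets.

Three generators cover the regimes the package is exercised on:

* ``make_two_circles`` / ``make_xor`` -- the classic 2-D nonlinear toys a
  logistic regression cannot solve but a PWL model can;
* ``make_subtype_dataset`` -- a tumour-subtype-shaped simulator emulating
  the statistical shape of public expression / copy-number cohorts:
  per-gene mean-centred continuous expression, copy-number integers in
  {-2..2}, several imbalanced classes, and planted class-informative genes
  recorded as ground truth. The ``paired`` mode additionally plants a
  pathway whose expression tracks a class-ordered latent, so the deep
  enrichment pipeline has a recoverable target.

The class-size preset ``BRCA_SHAPE`` mirrors the imbalance of the breast
cancer cohort the method was developed on (22/406/185/131/66 samples for
the five intrinsic subtypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.datasets import make_circles

from .containers import FeatureMatrix, LabelVector
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticDataset",
    "BRCA_SHAPE",
    "make_two_circles",
    "make_xor",
    "make_subtype_dataset",
    "make_gene_set_collection",
]

#: per-class sample counts shaped like the five-subtype breast cancer cohort
BRCA_SHAPE = {
    "Normal-like": 22,
    "Luminal A": 406,
    "Luminal B": 185,
    "Basal-like": 131,
    "Her2-enriched": 66,
}


@dataclass
class SyntheticDataset:
    X: FeatureMatrix
    y: LabelVector
    expression: FeatureMatrix | None = None
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0


def make_two_circles(
    n: int = 500,
    noise_sd: float = 0.05,
    radius_ratio: float = 0.8,
    seed: int = 0,
) -> SyntheticDataset:
    """Two concentric rings: class 0 on radius 1, class 1 on ``radius_ratio``.

    ``radius_ratio`` defaults to 0.8 so the rings overlap slightly at the
    default noise level, which keeps generalization non-trivial.
    """
    if not (0.0 < radius_ratio < 1.0):
        raise ValueError(f"radius_ratio must be in (0, 1), got {radius_ratio}")
    if n % 2:
        raise ValueError(f"n must be even, got {n}")
    X, lab = make_circles(
        n_samples=n,
        noise=noise_sd if noise_sd > 0 else None,
        factor=radius_ratio,
        random_state=seed,
    )
    fm = FeatureMatrix(X, [f"s{i:04d}" for i in range(n)], ["x1", "x2"])
    y = LabelVector([str(v) for v in lab], class_order=["0", "1"])
    return SyntheticDataset(X=fm, y=y, ground_truth={"rule": "radius"}, seed=seed)


def make_xor(n: int = 2000, seed: int = 0) -> SyntheticDataset:
    """Uniform points in [-1, 1]^2; class 1 iff the coordinate signs differ."""
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, 2))
    lab = (X[:, 0] * X[:, 1] < 0).astype(int)
    fm = FeatureMatrix(X, [f"s{i:04d}" for i in range(n)], ["x1", "x2"])
    y = LabelVector([str(v) for v in lab], class_order=["0", "1"])
    return SyntheticDataset(X=fm, y=y, ground_truth={"rule": "xor-of-signs"}, seed=seed)


_CN_BASE = np.array([0.02, 0.13, 0.70, 0.13, 0.02])   # P(-2..2) for null genes
_CN_GAIN = np.array([0.01, 0.04, 0.20, 0.30, 0.45])   # target for amplified genes
_CN_LEVELS = np.array([-2, -1, 0, 1, 2])


def make_subtype_dataset(
    n_per_class,
    D: int = 300,
    n_informative_per_class: int = 10,
    effect_size: float = 1.0,
    mode: str = "expression",
    seed: int = 0,
    class_names: list[str] | None = None,
    nonlinear_xor: bool = False,
    pathway_size: int = 40,
) -> SyntheticDataset:
    """Subtype-structured matrix with planted class-informative genes.

    expression mode
        standard-normal background; informative genes of class c are
        shifted by ``effect_size`` in that class, then every gene is
        mean-centred (log2-style normalised expression).
    copynumber mode
        integers in {-2..2}; null genes follow a diploid-heavy multinomial
        and informative genes are tilted toward amplification in their
        class, with tilt strength min(effect_size, 1).
    paired mode
        copy-number feature matrix plus an expression matrix sharing the
        informative genes; a disjoint planted pathway's expression follows
        a class-ordered latent, giving the enrichment pipeline a target.

    ``nonlinear_xor`` (expression, 2 classes) instead labels samples by the
    XOR of the signs of the first two informative genes, a regime where a
    linear model is blind but a PWL model is not.
    """
    counts = [int(c) for c in n_per_class]
    C = len(counts)
    if C < 2:
        raise ValueError("need at least 2 classes")
    if mode not in ("expression", "copynumber", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    need = C * n_informative_per_class + (pathway_size if mode == "paired" else 0)
    if D < need:
        raise ValueError(f"D={D} too small for {need} planted genes")
    if class_names is None:
        class_names = [f"class{c}" for c in range(C)]
    rng = np.random.default_rng(seed)
    N = sum(counts)
    labels = np.repeat(np.arange(C), counts)
    genes = [f"G{j:05d}" for j in range(D)]
    sample_ids = [f"s{i:04d}" for i in range(N)]
    info = {
        class_names[c]: genes[c * n_informative_per_class:(c + 1) * n_informative_per_class]
        for c in range(C)
    }
    gt: dict = {"informative": info}

    def expression_matrix(plant_pathway: bool) -> np.ndarray:
        E = rng.normal(0.0, 1.0, size=(N, D))
        for c in range(C):
            cols = slice(c * n_informative_per_class, (c + 1) * n_informative_per_class)
            E[labels == c, cols] += effect_size
        if plant_pathway:
            start = C * n_informative_per_class
            cols = slice(start, start + pathway_size)
            latent = np.linspace(-1.0, 1.0, C)[labels]
            E[:, cols] += effect_size * 1.5 * latent[:, None]
            gt["pathway_genes"] = genes[start:start + pathway_size]
            gt["pathway_name"] = "PLANTED_PATHWAY"
        return E - E.mean(axis=0)

    def copynumber_matrix() -> np.ndarray:
        M = rng.choice(_CN_LEVELS, size=(N, D), p=_CN_BASE).astype(float)
        tilt = min(effect_size, 1.0)
        probs = (1.0 - tilt) * _CN_BASE + tilt * _CN_GAIN
        for c in range(C):
            rows = np.flatnonzero(labels == c)
            cols = np.arange(c * n_informative_per_class, (c + 1) * n_informative_per_class)
            M[np.ix_(rows, cols)] = rng.choice(_CN_LEVELS, size=(rows.size, cols.size), p=probs)
        return M

    expression = None
    if mode == "expression":
        X = expression_matrix(plant_pathway=False)
        if nonlinear_xor:
            if C != 2:
                raise ValueError("nonlinear_xor requires exactly 2 classes")
            X = rng.normal(0.0, 1.0, size=(N, D))
            X -= X.mean(axis=0)
            g1, g2 = 0, n_informative_per_class
            labels = ((X[:, g1] > 0) ^ (X[:, g2] > 0)).astype(int)
            gt["xor_genes"] = [genes[g1], genes[g2]]
    elif mode == "copynumber":
        X = copynumber_matrix()
    else:  # paired
        X = copynumber_matrix()
        expression = FeatureMatrix(expression_matrix(plant_pathway=True), sample_ids, genes)

    return SyntheticDataset(
        X=FeatureMatrix(X, sample_ids, genes),
        y=LabelVector([class_names[c] for c in labels], class_order=list(class_names)),
        expression=expression,
        ground_truth=gt,
        seed=seed,
    )


def make_gene_set_collection(
    dataset: SyntheticDataset,
    n_decoy_sets: int = 10,
    set_size: int = 40,
    seed: int = 0,
) -> GeneSetCollection:
    """The planted pathway plus random decoy sets over the same universe."""
    gt = dataset.ground_truth
    if "pathway_genes" not in gt:
        raise ValueError("dataset has no planted pathway (use mode='paired')")
    universe = list(
        dataset.expression.feature_names if dataset.expression is not None
        else dataset.X.feature_names
    )
    rng = np.random.default_rng(seed)
    non_pathway = [g for g in universe if g not in set(gt["pathway_genes"])]
    sets = {gt["pathway_name"]: list(gt["pathway_genes"])}
    for i in range(n_decoy_sets):
        sets[f"DECOY_{i:02d}"] = list(
            rng.choice(non_pathway, size=min(set_size, len(non_pathway)), replace=False)
        )
    return GeneSetCollection(sets=sets, universe=universe)
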