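"""In-memory containers for sample-by-gene matrices and class labels.

The internal orientation is always samples x features. Expression matrices
are expected to hold per-gene mean-centred log2(x+1) values; copy-number
matrices hold GISTIC2-style integers in {-2, -1, 0, 1, 2}. Neither is
enforced numerically here -- only finiteness and shape consistency are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureMatrix", "LabelVector"]


@dataclass
class FeatureMatrix:
    """N x D numeric matrix with sample ids and feature (gene) names.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Dense numeric matrix; must be finite.
    sample_ids : list of str
        One id per row; must be unique.
    feature_names : list of str
        One name per column; must be unique.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError(f"matrix must be at least 1x1, got {n}x{d}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_names) != d:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            dupes = sorted({f for f in self.feature_names if self.feature_names.count(f) > 1})
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.feature_names),
        )


@dataclass
class LabelVector:
    """Categorical class labels for N samples.

    ``class_order`` fixes the column order of probability matrices and of
    per-class scores everywhere downstream. At least two distinct classes
    must be present.
    """

    labels: list[str]
    class_order: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if self.class_order is None:
            # deterministic: first-appearance order
            seen: dict[str, None] = {}
            for l in self.labels:
                seen.setdefault(l, None)
            self.class_order = list(seen)
        else:
            self.class_order = [str(c) for c in self.class_order]
        present = set(self.labels)
        if not present.issubset(self.class_order):
            extra = sorted(present - set(self.class_order))
            raise ValueError(f"labels not in class_order: {extra}")
        # subsets (e.g. CV folds) may cover a single class, but the class
        # vocabulary itself must be at least binary
        if len(self.class_order) < 2:
            raise ValueError("at least 2 distinct classes are required")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids length does not match labels")

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def to_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_order)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def one_hot(self) -> np.ndarray:
        idx = self.to_indices()
        out = np.zeros((len(idx), self.n_classes))
        out[np.arange(len(idx)), idx] = 1.0
        return out

    def subset(self, idx: np.ndarray) -> "LabelVector":
        idx = np.asarray(idx)
        return LabelVector(
            [self.labels[i] for i in idx],
            class_order=list(self.class_order),
            sample_ids=None if self.sample_ids is None else [self.sample_ids[i] for i in idx],
        )
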