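"""Readers and writers for the tab-separated matrix, label, GMT and report
formats, plus sample alignment and model serialisation.

Matrices are stored internally as samples x genes, always. Xena-style
genes x samples files are handled by an explicit ``orientation`` flag --
never by guessing, since a silent transpose is the classic omics bug.
Gene identifiers are opaque symbols; no identifier mapping is attempted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, LabelVector
from .enrichment import GeneSetCollection
from .model import PWLModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_gene_sets",
    "write_gene_sets",
    "align_samples",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


def _dedupe(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
            logger.warning("duplicate %s %r renamed to %r", what, name, out[-1])
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_matrix(path, orientation: str = "samples_by_genes") -> FeatureMatrix:
    """Read a TSV matrix with a header row and an id column.

    ``orientation='genes_by_samples'`` transposes Xena-style input. Missing
    or non-numeric cells are rejected with their coordinates; duplicate
    gene symbols are deterministically suffixed ``.1``, ``.2``, ...
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    if orientation == "genes_by_samples":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_names = _dedupe([str(c) for c in df.columns], "feature name")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        try:
            # numpy's parser is correctly rounded, unlike pd.to_numeric
            values[:, j] = raw[:, j].astype(np.float64)
        except ValueError:
            for i in range(raw.shape[0]):
                try:
                    float(raw[i, j])
                except ValueError:
                    raise ValueError(
                        f"missing or non-numeric value {raw[i, j]!r} at sample "
                        f"{sample_ids[i]!r}, feature {feature_names[j]!r} in {path}"
                    ) from None
            raise
        bad = np.flatnonzero(np.isnan(values[:, j]))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"missing value at sample {sample_ids[i]!r}, "
                f"feature {feature_names[j]!r} in {path}"
            )
    return FeatureMatrix(values, sample_ids, feature_names)


def write_matrix(X: FeatureMatrix, path, orientation: str = "samples_by_genes") -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_names)
    if orientation == "genes_by_samples":
        df = df.T
    df.index.name = "id"
    # shortest round-tripping decimal form of each float64
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_labels(path) -> LabelVector:
    """Two-column TSV (sample id, class label) with a header row."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs at least 2 columns")
    ids = [str(s) for s in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in label table {path}")
    return LabelVector(list(df.iloc[:, 1]), sample_ids=ids)


def write_labels(y: LabelVector, path) -> None:
    if y.sample_ids is None:
        raise ValueError("label vector has no sample ids")
    pd.DataFrame({"sample": y.sample_ids, "label": y.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path, universe: list[str] | None = None) -> GeneSetCollection:
    """GMT reader: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
    if not sets:
        logger.warning("empty gene-set file %s", path)
    return GeneSetCollection(sets=sets, universe=universe or [])


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def align_samples(X: FeatureMatrix, other):
    """Inner-join ``X`` with a LabelVector or second FeatureMatrix on
    sample ids, preserving X's order; returns the aligned pair."""
    if isinstance(other, LabelVector):
        if other.sample_ids is None:
            raise ValueError("label vector has no sample ids to align on")
        other_ids = other.sample_ids
    elif isinstance(other, FeatureMatrix):
        other_ids = other.sample_ids
    else:
        raise TypeError(f"cannot align with {type(other).__name__}")
    lut = {s: i for i, s in enumerate(other_ids)}
    keep = [i for i, s in enumerate(X.sample_ids) if s in lut]
    if not keep:
        raise ValueError("no common sample ids")
    dropped = X.n_samples - len(keep) + len(other_ids) - len(keep)
    if dropped:
        logger.info("align_samples dropped %d unmatched samples", dropped)
    X2 = X.subset_samples(np.array(keep))
    idx = np.array([lut[s] for s in X2.sample_ids])
    if isinstance(other, LabelVector):
        return X2, other.subset(idx)
    return X2, other.subset_samples(idx)


def save_model(model: PWLModel, path) -> None:
    """Single-file JSON archive with a versioned schema."""
    Path(path).write_text(json.dumps(model.state()))


def load_model(path) -> PWLModel:
    return PWLModel.from_state(json.loads(Path(path).read_text()))
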