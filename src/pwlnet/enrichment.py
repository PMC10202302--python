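"""Deep enrichment analysis.

The pipeline interrogates what a trained PWL model's internal representation
encodes, in four steps:

1. extract the reallocation vectors eta (or the reallocated features rho)
   for every sample;
2. compress them to a 1-D axis with UMAP;
3. rank genes by the Spearman correlation between that axis and each gene's
   expression, keeping the top 250 positively and top 250 negatively
   correlated genes (the 1-D axis orientation is arbitrary, so taking both
   tails makes the selection flip-invariant);
4. test the selected genes for over-representation in each gene set of a
   GMT collection with the right-tailed Fisher exact (hypergeometric) test.

Because per-gene correlation signs depend on the arbitrary embedding
orientation, individual rho signs are not meaningful -- only the two-tailed
selection is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix
from .model import PWLModel

__all__ = [
    "EmbeddingResult",
    "GeneSetCollection",
    "extract_inner_vectors",
    "embed_inner_vectors",
    "spearman_per_gene",
    "select_correlated_genes",
    "fisher_enrichment",
    "deep_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # N x d
    n_neighbors: int
    min_dist: float
    seed: int


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe used for counting.

    Set members outside the universe are ignored in enrichment counts.
    """

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)


def extract_inner_vectors(model: PWLModel, X: FeatureMatrix, which: str = "eta") -> np.ndarray:
    """Per-sample inner vectors of the model, shape N x D.

    ``eta`` returns the reallocation vectors; ``rho`` the reallocated
    features eta (*) x. The point-wise intercept column is dropped since it
    corresponds to no gene.
    """
    if not model.fitted:
        raise ValueError("model is not trained")
    if which not in ("eta", "rho"):
        raise ValueError(f"which must be 'eta' or 'rho', got {which!r}")
    eta = model.eta(X)[:, : X.n_features]
    if which == "eta":
        return eta
    return eta * X.values


def embed_inner_vectors(
    H: np.ndarray,
    d: int = 1,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> EmbeddingResult:
    """UMAP embedding of the inner vectors to 1 or 2 dimensions."""
    if d not in (1, 2):
        raise ValueError(f"embedding dimension must be 1 or 2, got {d}")
    H = np.asarray(H, dtype=float)
    if H.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} samples, got {H.shape[0]}"
        )
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=d,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        coords = np.asarray(reducer.fit_transform(H), dtype=float)
    return EmbeddingResult(coords=coords, n_neighbors=n_neighbors,
                           min_dist=min_dist, seed=seed)


def spearman_per_gene(coords1d: np.ndarray, expression: FeatureMatrix) -> pd.DataFrame:
    """Spearman rho between a 1-D axis and every gene column.

    Average ranks are used for ties. A constant gene column has undefined
    correlation; it is reported as rho=0 with ``constant=True``.
    """
    c = np.asarray(coords1d, dtype=float).ravel()
    if c.size != expression.n_samples:
        raise ValueError(
            f"coords length {c.size} != number of samples {expression.n_samples}"
        )
    rc = stats.rankdata(c)
    ranks = np.apply_along_axis(stats.rankdata, 0, expression.values)
    const = np.ptp(expression.values, axis=0) == 0.0
    rc_c = rc - rc.mean()
    rk_c = ranks - ranks.mean(axis=0)
    denom = np.sqrt((rc_c**2).sum() * (rk_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc_c @ rk_c) / denom
    rho = np.where(const | ~np.isfinite(rho), 0.0, rho)
    if const.any():
        logger.warning("%d constant gene columns: rho recorded as 0", int(const.sum()))
    return pd.DataFrame({"gene": expression.feature_names, "rho": rho, "constant": const})


def select_correlated_genes(
    rho: pd.DataFrame | np.ndarray,
    gene_names: list[str] | None = None,
    n_pos: int = 250,
    n_neg: int = 250,
) -> list[str]:
    """Top ``n_pos`` genes with rho > 0 (descending) plus top ``n_neg``
    with rho < 0 (ascending). Genes with rho exactly 0 are never selected.
    """
    if isinstance(rho, pd.DataFrame):
        gene_names = list(rho["gene"])
        rho = rho["rho"].to_numpy()
    rho = np.asarray(rho, dtype=float)
    if gene_names is None:
        raise ValueError("gene_names required when rho is an array")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be >= 0")
    order = np.argsort(-rho, kind="stable")
    pos = [i for i in order if rho[i] > 0][:n_pos]
    neg = [i for i in order[::-1] if rho[i] < 0][:n_neg]
    if len(pos) < n_pos or len(neg) < n_neg:
        logger.warning(
            "only %d positive and %d negative correlated genes available "
            "(requested %d/%d)", len(pos), len(neg), n_pos, n_neg,
        )
    return [gene_names[i] for i in pos] + [gene_names[i] for i in neg]


def fisher_enrichment(query: list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Right-tailed Fisher exact test of the query against every gene set.

    For a universe of U genes, a set with m universe members and a query of
    q universe genes overlapping the set in k genes, the p-value is the
    hypergeometric upper tail P[overlap >= k]. Rows are sorted by ascending
    p; a Benjamini-Hochberg column is included but the raw p is primary.
    """
    universe = list(dict.fromkeys(collection.universe))
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    q_genes = list(dict.fromkeys(query))
    dropped = [g for g in q_genes if g not in uni]
    q_genes = [g for g in q_genes if g in uni]
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    if not q_genes:
        raise ValueError("empty query after restricting to the universe")
    U, q = len(uni), len(q_genes)
    qset = set(q_genes)
    rows = []
    for name, members in collection.sets.items():
        mem = set(members) & uni
        m, k = len(mem), len(set(members) & qset)
        p = float(stats.hypergeom.sf(k - 1, U, m, q)) if m else 1.0
        p = min(p, 1.0)
        rows.append((name, k, m, q, U, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                     "universe_size", "p"])
    df["neg_log10_p"] = -np.log10(df["p"])
    df = df.sort_values("p", kind="stable").reset_index(drop=True)
    df["q_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def deep_enrichment(
    model: PWLModel,
    X: FeatureMatrix,
    expression: FeatureMatrix,
    collection: GeneSetCollection,
    which: str = "eta",
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    n_pos: int = 250,
    n_neg: int = 250,
) -> dict:
    """Run the full four-step pipeline; returns all intermediates."""
    if X.sample_ids != expression.sample_ids:
        raise ValueError("feature and expression matrices must share sample order")
    H = extract_inner_vectors(model, X, which=which)
    emb = embed_inner_vectors(H, d=1, seed=seed, n_neighbors=n_neighbors, min_dist=min_dist)
    rho = spearman_per_gene(emb.coords[:, 0], expression)
    if not collection.universe:
        collection = GeneSetCollection(sets=collection.sets,
                                       universe=list(expression.feature_names))
    selected = select_correlated_genes(rho, n_pos=n_pos, n_neg=n_neg)
    table = fisher_enrichment(selected, collection)
    return {"inner": H, "embedding": emb, "correlation": rho,
            "selected": selected, "enrichment": table}
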