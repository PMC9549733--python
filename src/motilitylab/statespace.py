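"""Motility state-space construction and condition testing.

Feature matrices are median-imputed, standardized and projected onto
principal components; tracks are clustered with Ward-linkage agglomerative
clustering on the components that capture the target variance (capped at
30), labelled so the highest-mean-total-distance cluster is the "motile"
cluster, and condition-versus-cluster proportions are tested with a
Pearson χ² test.  A t-SNE embedding (perplexity 35 by default) is provided
for visualization only and never feeds the clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .features import feature_columns

logger = logging.getLogger(__name__)


@dataclass
class StateSpaceResult:
    """PC basis, clustering and condition-test results for one run."""

    kept_components: int
    explained_variance: np.ndarray
    pc_scores: np.ndarray
    cluster_labels: np.ndarray  # 1..k; cluster k = highest mean total_distance
    silhouette: float
    track_ids: list[str]
    conditions: list[str]
    embedding: np.ndarray | None = None
    contingency: pd.DataFrame | None = None
    chi2: float | None = None
    chi2_df: int | None = None
    chi2_p: float | None = None
    normalized_means: pd.DataFrame | None = None
    imputed_counts: dict = field(default_factory=dict)


def _impute_standardize(fm: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    cols = feature_columns(fm)
    X = fm[cols].to_numpy(dtype=float)
    counts = {}
    for j, c in enumerate(cols):
        nan = np.isnan(X[:, j])
        if nan.any():
            med = np.nanmedian(X[:, j])
            if np.isnan(med):
                med = 0.0
            X[nan, j] = med
            counts[c] = int(nan.sum())
    keep = X.std(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 features with nonzero variance")
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        logger.info("dropping constant feature(s): %s", dropped)
    cols = [c for c, k in zip(cols, keep) if k]
    if counts:
        logger.info("median-imputed missing values: %s", counts)
    Z = StandardScaler().fit_transform(X[:, keep])
    return Z, cols, counts


def reduce_and_cluster(
    fm: pd.DataFrame,
    var_target: float = 0.95,
    max_components: int = 30,
    k: int = 2,
) -> StateSpaceResult:
    """Standardize → PCA → Ward clustering → silhouette.

    Keeps the first ``m`` principal components where ``m`` is the smallest
    count whose cumulative explained variance reaches ``var_target``, capped
    at ``max_components``; Ward-linkage agglomerative clustering with
    Euclidean distance on the kept PC scores is cut at ``k`` clusters.
    Cluster identities are fixed by mean total_distance so cluster ``k`` is
    always the most motile one; the silhouette is computed in the same
    kept-PC space the clustering used.
    """
    if len(fm) < k + 1:
        raise ValueError(f"need at least {k + 1} tracks for k={k} clusters")
    Z, cols, imputed = _impute_standardize(fm)
    pca = PCA(svd_solver="full", random_state=0)
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, var_target) + 1)
    m = min(m, max_components, scores.shape[1])
    kept = scores[:, :m]

    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(kept)
    # relabel so clusters are ordered by ascending mean total distance
    dist = fm["total_distance"].to_numpy(dtype=float) if "total_distance" in fm else (
        kept[:, 0]
    )
    order = np.argsort([np.nanmean(dist[raw == c]) for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]

    sil = float(silhouette_score(kept, labels, metric="euclidean"))
    return StateSpaceResult(
        kept_components=m,
        explained_variance=pca.explained_variance_ratio_[:m],
        pc_scores=kept,
        cluster_labels=labels,
        silhouette=sil,
        track_ids=list(fm.index.astype(str)),
        conditions=list(fm["condition"]) if "condition" in fm else [""] * len(fm),
        imputed_counts=imputed,
    )


def tsne_embed(scores: np.ndarray, perplexity: float = 35.0, seed: int = 0) -> np.ndarray:
    """2D t-SNE embedding of PC scores; visualization only, deterministic
    given the seed.  Requires perplexity < (n − 1) / 3."""
    n = scores.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; needs perplexity < (n-1)/3"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if scores.shape[1] >= 2 else "random",
        n_jobs=1,
    )
    return ts.fit_transform(scores)


def condition_cluster_test(
    labels: np.ndarray, conditions: list[str] | np.ndarray
) -> tuple[pd.DataFrame, float, int, float]:
    """Pearson χ² test (no continuity correction) on the condition × cluster
    contingency table; returns (table, χ², df, p)."""
    table = pd.crosstab(
        pd.Series(conditions, name="condition"), pd.Series(labels, name="cluster")
    )
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 conditions and 2 clusters")
    zero_rows = table.index[table.sum(axis=1) == 0].tolist()
    zero_cols = table.columns[table.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        raise ValueError(
            f"empty margin: conditions {zero_rows} / clusters {zero_cols} have no tracks"
        )
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), int(df), float(p)


def normalized_feature_means(
    fm: pd.DataFrame, groups: list[str] | np.ndarray
) -> pd.DataFrame:
    """Min-max scale each feature to [0, 1] across all tracks, then average
    per group; returns a table with per-group mean and SEM per feature.
    Constant features scale to 0 (logged)."""
    cols = feature_columns(fm)
    X = fm[cols].to_numpy(dtype=float)
    lo = np.nanmin(X, axis=0)
    span = np.nanmax(X, axis=0) - lo
    const = span == 0
    if const.any():
        logger.info(
            "constant feature(s) scaled to 0: %s",
            [c for c, z in zip(cols, const) if z],
        )
    span[const] = 1.0
    S = (X - lo) / span
    S[:, const] = 0.0
    g = np.asarray(groups)
    out = []
    for grp in pd.unique(g):
        sub = S[g == grp]
        n = np.sum(~np.isnan(sub), axis=0)
        mean = np.nanmean(sub, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # singleton groups
            sd = np.nanstd(sub, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        for c, mu, se in zip(cols, mean, sem):
            out.append({"group": grp, "feature": c, "mean": mu, "sem": se})
    return pd.DataFrame(out)


def cluster_1d(values: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray, float]:
    """Ward clustering on a single standardized feature (e.g. total distance
    travelled); returns (labels 1..k ordered by cluster mean, cluster means
    on the original scale, silhouette)."""
    v = np.asarray(values, dtype=float)
    if len(v) < k + 1:
        raise ValueError(f"need at least {k + 1} values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; 1D clustering undefined")
    z = ((v - v.mean()) / v.std()).reshape(-1, 1)
    raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    order = np.argsort([v[raw == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    means = np.array([v[labels == c].mean() for c in range(1, k + 1)])
    sil = float(silhouette_score(z, labels)) if len(np.unique(labels)) > 1 else float("nan")
    return labels, means, sil
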