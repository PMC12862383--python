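"""Sample-level PCA and DSI k-means clustering on the PSI matrix.

Samples (columns) are the PCA observations after row (per-intron) centering,
mirroring how replicate samples cluster by condition. DSIs (rows) are
clustered with k-means on per-intron z-scores; the cluster whose mean PSI in
symbiotic samples is higher is always labeled cluster 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


def build_psi_matrix(
    dsi_ids: list[str],
    psi: pd.DataFrame,
    missing_policy: str = "complete_case",
) -> pd.DataFrame:
    """Assemble the DSI x sample PSI matrix from the long PSI table.

    ``psi`` columns: intron_id, sample_id, psi. ``missing_policy`` is
    "complete_case" (drop rows with any missing sample) or "row_mean"
    (impute with the row mean).
    """
    if not dsi_ids:
        raise ValueError("empty DSI set")
    sub = psi[psi["intron_id"].isin(dsi_ids)]
    mat = sub.pivot_table(index="intron_id", columns="sample_id", values="psi", aggfunc="mean")
    if missing_policy == "complete_case":
        mat = mat.dropna(axis=0)
    elif missing_policy == "row_mean":
        mat = mat.apply(lambda row: row.fillna(row.mean()), axis=1).dropna(axis=0)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if len(mat) < 2:
        raise ValueError("fewer than 2 complete DSI rows")
    return mat


def pca_samples(matrix: pd.DataFrame, n_components: int | None = None, zscore_rows: bool = False):
    """Project samples (columns) on the principal components of the PSI matrix.

    Rows are centered (optionally z-scored); samples are the observations.
    Returns (coordinates DataFrame indexed by sample, explained-variance
    fractions).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise ValueError("need >=2 introns and >=3 samples")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if zscore_rows:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    obs = X.T  # samples as observations
    k = n_components or min(obs.shape)
    k = min(k, *obs.shape)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(obs)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def kmeans_dsis(
    matrix: pd.DataFrame,
    symbiotic_samples: list[str],
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[pd.Series, pd.Series, float]:
    """Cluster DSIs on per-intron z-scored PSI profiles.

    Deterministic under ``seed``; best of ``n_restarts`` initializations by
    within-cluster sum of squares. Labels are 1-based and ordered so that
    cluster 1 has the higher mean PSI (z-score) in the symbiotic samples.
    Returns (labels per intron, cluster sizes, mean silhouette; NaN for k=1).
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of DSIs ({len(matrix)})")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(Z)
    sym_cols = [matrix.columns.get_loc(s) for s in symbiotic_samples if s in matrix.columns]
    sym_means = [Z[raw == c][:, sym_cols].mean() if (raw == c).any() else -np.inf for c in range(k)]
    order = np.argsort(sym_means)[::-1]  # highest symbiotic mean first
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=matrix.index, name="cluster")
    sizes = labels.value_counts().sort_index()
    sil = float(silhouette_score(Z, raw)) if k > 1 and len(set(raw)) > 1 else float("nan")
    return labels, sizes, sil
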