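"""Distance-based organization of cell lines.

Pairwise-complete Euclidean distances, equal-contribution combination of two
distance matrices, 3-NN leave-one-out tissue classification, the Gap
statistic over average-linkage tree cuts, distance-matrix regression
residuals, and thin t-SNE / PCA wrappers (with iterative rank-k SVD
imputation for the PCA path).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    cell_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, NaN where undefined
    n_features_used: np.ndarray | None = None  # per-pair complete-feature count

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.cell_ids), len(self.cell_ids)):
            raise ValueError("distance matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.cell_ids, columns=self.cell_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector (scipy condensed order); NaN not allowed."""
        if np.isnan(self.d[np.triu_indices(self.n, 1)]).any():
            raise ValueError("distance matrix contains missing pairs")
        return squareform(self.d, checks=False)


def pairwise_distance(values: pd.DataFrame, min_complete: int = 1) -> DistanceMatrix:
    """Euclidean distance over pairwise-complete features (analytes x cells).

    d[i,j] uses exactly the features observed in both cells; pairs sharing
    fewer than ``min_complete`` features are missing.  Distances are NOT
    rescaled by the shared-feature count.
    """
    X = values.to_numpy(dtype=float).T  # cells x features
    cells = list(values.columns)
    obs = np.isfinite(X)
    empty = ~obs.any(axis=1)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells have no observed features", stacklevel=2)
    Xz = np.where(obs, X, 0.0)
    # sum over shared features of (x-y)^2 = x^2 + y^2 - 2xy, masked
    sq = Xz**2
    n_shared = obs.astype(float) @ obs.T
    cross = Xz @ Xz.T
    a2 = sq @ obs.T.astype(float)  # sum_i x_i^2 over features observed in both
    d2 = a2 + a2.T - 2 * cross
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    d[n_shared < min_complete] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(cells, d, n_features_used=n_shared.astype(int))


def combine_distances(d1: DistanceMatrix, d2: DistanceMatrix) -> DistanceMatrix:
    """Equal-contribution combination: d1/S1 + d2/S2 with Sk the sum of all
    non-missing entries of dk.  Pairs missing in either input stay missing."""
    if d1.cell_ids != d2.cell_ids:
        raise ValueError("distance matrices must share an identical cell axis")
    s1 = float(np.nansum(d1.d))
    s2 = float(np.nansum(d2.d))
    if s1 == 0 or s2 == 0:
        raise ValueError("zero total distance; cannot weight")
    combined = d1.d / s1 + d2.d / s2
    return DistanceMatrix(list(d1.cell_ids), combined)


def knn_loocv_tissue(
    d: DistanceMatrix, tissues: pd.Series, k: int = 3
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out k-NN tissue classification on a distance matrix.

    Majority vote among the k nearest other cells; ties broken by the
    nearest neighbor among the tied classes.  Cells with no finite distance
    to any other cell are excluded (warned).  Returns overall accuracy and
    the tissue x tissue confusion table (rows = true).
    """
    if d.n < k + 1:
        raise ValueError(f"need at least {k + 1} cells")
    t = tissues.reindex(d.cell_ids).to_numpy()
    labels = sorted(pd.unique(t[pd.notna(t)]))
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n_correct = n_eval = 0
    excluded = 0
    for i in range(d.n):
        row = d.d[i].copy()
        row[i] = np.nan
        finite = np.isfinite(row)
        if not finite.any():
            excluded += 1
            continue
        order = np.argsort(row[finite], kind="stable")
        idx = np.flatnonzero(finite)[order][:k]
        votes = pd.Series(t[idx]).value_counts()
        top = votes[votes == votes.max()].index
        if len(top) == 1:
            pred = top[0]
        else:  # nearest neighbor among tied classes
            pred = next(t[j] for j in idx if t[j] in set(top))
        conf.loc[t[i], pred] += 1
        n_correct += int(pred == t[i])
        n_eval += 1
    if excluded:
        warnings.warn(f"{excluded} cells excluded (no finite distances)", stacklevel=2)
    return n_correct / max(n_eval, 1), conf


def _within_dispersion(d2: np.ndarray, assign: np.ndarray) -> float:
    """W_k = sum over clusters of (sum of pairwise squared distances)/(2*n_r)."""
    w = 0.0
    for c in np.unique(assign):
        idx = np.flatnonzero(assign == c)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        w += sub.sum() / (2.0 * idx.size)
    return w


def gap_statistic(
    X: pd.DataFrame | np.ndarray,
    k_max: int,
    B: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Gap statistic over average-linkage tree cuts, k = 1..k_max.

    ``X`` is observations x features (complete).  Reference sets are drawn
    uniformly over each feature's observed range.  Returns the gap curve
    (k, logW, E_logW, gap, s_k) and the chosen k = smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)

    def logW_curve(data: np.ndarray) -> np.ndarray:
        diff = data[:, None, :] - data[None, :, :]
        d2 = (diff**2).sum(axis=2)
        dcond = squareform(np.sqrt(d2), checks=False)
        Z = average(dcond)
        out = np.empty(k_max)
        for k in range(1, k_max + 1):
            assign = fcluster(Z, t=k, criterion="maxclust")
            out[k - 1] = np.log(max(_within_dispersion(d2, assign), 1e-300))
        return out

    logW = logW_curve(X)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = np.empty((B, k_max))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = logW_curve(Xb)
    e_logW = ref.mean(axis=0)
    sd = ref.std(axis=0)
    s_k = sd * np.sqrt(1 + 1.0 / B)
    gap = e_logW - logW

    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s_k[k]:
            chosen = k
            break
    curve = pd.DataFrame({
        "k": np.arange(1, k_max + 1), "logW": logW, "E_logW": e_logW,
        "gap": gap, "s_k": s_k,
    })
    return curve, chosen


def distance_regression(
    d_target: DistanceMatrix,
    d_predictor: DistanceMatrix,
    tissues: pd.Series | None = None,
    top_n: int = 100,
) -> dict:
    """OLS of target distances on predictor distances over the upper triangle.

    Returns the per-pair residual table, the top_n highest and lowest
    residual pairs, and tissues ranked by the mean residual of their
    within-tissue pairs (when tissues are given).
    """
    if d_target.cell_ids != d_predictor.cell_ids:
        raise ValueError("distance matrices must share an identical cell axis")
    iu = np.triu_indices(d_target.n, 1)
    y = d_target.d[iu]
    x = d_predictor.d[iu]
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 10:
        raise ValueError("need >= 10 shared non-missing pairs")
    if np.all(x[ok] == x[ok][0]):
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(ok.sum()), x[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    resid = y[ok] - X @ beta

    cells = np.asarray(d_target.cell_ids)
    table = pd.DataFrame({
        "cell_a": cells[iu[0][ok]], "cell_b": cells[iu[1][ok]],
        "d_target": y[ok], "d_pred": X @ beta, "residual": resid,
    })
    by_resid = table.sort_values("residual", ascending=False)
    result = {
        "intercept": float(beta[0]), "slope": float(beta[1]),
        "r": float(np.corrcoef(x[ok], y[ok])[0, 1]),
        "residuals": table,
        "top_high": by_resid.head(top_n).reset_index(drop=True),
        "top_low": by_resid.tail(top_n).iloc[::-1].reset_index(drop=True),
    }
    if tissues is not None:
        t = tissues.reindex(d_target.cell_ids)
        ta = t.loc[table["cell_a"]].to_numpy()
        tb = t.loc[table["cell_b"]].to_numpy()
        within = table[ta == tb].assign(tissue=ta[ta == tb])
        ranking = (within.groupby("tissue")["residual"].mean()
                   .sort_values(ascending=False))
        result["tissue_ranking"] = ranking
    return result


def svd_impute(values: pd.DataFrame, rank: int = 5, tol: float = 1e-6,
               max_iter: int = 100) -> pd.DataFrame:
    """Iterative rank-k SVD imputation of missing entries (EM-style)."""
    X = values.to_numpy(dtype=float)
    miss = ~np.isfinite(X)
    if not miss.any():
        return values.copy()
    col_means = np.nanmean(X, axis=0)
    Xf = np.where(miss, np.broadcast_to(col_means, X.shape), X)
    rank = min(rank, min(X.shape) - 1) or 1
    prev = Xf[miss].copy()
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Xf, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        Xf[miss] = approx[miss]
        delta = np.linalg.norm(Xf[miss] - prev) / max(np.linalg.norm(prev), 1e-12)
        if delta < tol:
            break
        prev = Xf[miss].copy()
    return pd.DataFrame(Xf, index=values.index, columns=values.columns)


def embed(
    values: pd.DataFrame,
    method: str = "pca",
    perplexity: float = 30.0,
    iterations: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D embedding of cells (columns of ``values``) by PCA or t-SNE.

    PCA centers and scales features to unit variance after rank-5 SVD
    imputation of missing values.  t-SNE runs on the same imputed, scaled
    matrix.  Returns a (cell, x, y) table.
    """
    X = svd_impute(values.T)  # cells x features
    arr = X.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    arr = (arr - mu) / sd
    if method == "pca":
        from sklearn.decomposition import PCA
        coords = PCA(n_components=2, random_state=seed).fit_transform(arr)
    elif method == "tsne":
        from sklearn.manifold import TSNE
        px = min(perplexity, (arr.shape[0] - 1) / 3)
        coords = TSNE(n_components=2, perplexity=px, max_iter=iterations,
                      random_state=seed, init="pca").fit_transform(arr)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame({"cell": X.index, "x": coords[:, 0], "y": coords[:, 1]})
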