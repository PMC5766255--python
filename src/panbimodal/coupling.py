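"""Bimodal coupling coefficients, the thresholded network, and communities.

The coupling coefficient r_b between two analytes is the Spearman rank
correlation of their per-cell posterior probabilities of the high mixture
component, computed over pairwise-complete cells.  Edges pass into the
network when |r_b| > 0.3 and the (Bonferroni-adjusted by default) p-value is
below alpha.  Communities come from Newman's leading-eigenvector method on
the unsigned binary adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default |r_b| cutoff for network edges (strict inequality)
R_THRESHOLD = 0.3
#: default pairwise-complete cell minimum below which a pair is not tested
MIN_OVERLAP = 30


@dataclass
class CouplingEdge:
    analyte_a: str
    analyte_b: str
    layer_a: str
    layer_b: str
    r_b: float
    n_overlap: int
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class CouplingNetwork:
    nodes: list[str]
    node_attrs: pd.DataFrame  # index = node; columns may include pi_high etc.
    edges: list[CouplingEdge]
    communities: dict[str, int] = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "analyte_a": e.analyte_a, "layer_a": e.layer_a,
            "analyte_b": e.analyte_b, "layer_b": e.layer_b,
            "r_b": e.r_b, "n_overlap": e.n_overlap,
            "p": e.p_value, "p_adj": e.p_adjusted,
        } for e in self.edges])

    def adjacency(self) -> np.ndarray:
        """Unsigned binary adjacency over self.nodes (multi-edges collapsed)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)))
        for e in self.edges:
            i, j = idx[e.analyte_a], idx[e.analyte_b]
            if i != j:
                A[i, j] = A[j, i] = 1.0
        return A


def coupling_coefficient(
    pA: pd.Series | np.ndarray,
    pB: pd.Series | np.ndarray,
    min_overlap: int = MIN_OVERLAP,
) -> tuple[float, int, float]:
    """Spearman r_b over pairwise-complete cells; (nan, n, nan) if untestable.

    Average ranks for ties; p-value from the large-sample t approximation.
    A zero-variance rank vector yields r_b = nan (flagged via the nan).
    """
    a = np.asarray(pA, dtype=float)
    b = np.asarray(pB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("posterior vectors must share the cell axis")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < min_overlap:
        return float("nan"), n, float("nan")
    aa, bb = a[ok], b[ok]
    if np.all(aa == aa[0]) or np.all(bb == bb[0]):
        return float("nan"), n, float("nan")
    res = stats.spearmanr(aa, bb)
    return float(res.statistic), n, float(res.pvalue)


def coupling_matrix(
    postA: pd.DataFrame,
    postB: pd.DataFrame | None = None,
    layerA: str = "protein",
    layerB: str = "mrna",
    pairing: Literal["matched-gene", "all-pairs", "within"] = "all-pairs",
    pairs: pd.DataFrame | None = None,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """Edge table of r_b values between posterior matrices (analytes x cells).

    ``matched-gene`` requires a ``pairs`` table (columns analyte_a, analyte_b)
    as produced by dataio.match_layers; ``all-pairs`` crosses every row of A
    with every row of B; ``within`` takes all unordered pairs inside postA.
    """
    rows = []
    if pairing == "within":
        ids = list(postA.index)
        for a, b in combinations(ids, 2):
            r, n, p = coupling_coefficient(postA.loc[a], postA.loc[b], min_overlap)
            rows.append((a, layerA, b, layerA, r, n, p))
    elif pairing == "matched-gene":
        if pairs is None or pairs.empty:
            raise ValueError("matched-gene pairing requires a non-empty pairs table")
        for _, pr in pairs.iterrows():
            a, b = pr["analyte_a"], pr["analyte_b"]
            if a not in postA.index or b not in postB.index:
                continue
            r, n, p = coupling_coefficient(postA.loc[a], postB.loc[b], min_overlap)
            rows.append((a, layerA, b, layerB, r, n, p))
    elif pairing == "all-pairs":
        if postB is None:
            raise ValueError("all-pairs pairing requires two posterior matrices")
        for a in postA.index:
            for b in postB.index:
                r, n, p = coupling_coefficient(postA.loc[a], postB.loc[b], min_overlap)
                rows.append((a, layerA, b, layerB, r, n, p))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if not rows:
        raise ValueError("empty pairing")
    return pd.DataFrame(
        rows, columns=["analyte_a", "layer_a", "analyte_b", "layer_b",
                       "r_b", "n_overlap", "p"])


def adjust_pvalues(p: np.ndarray, method: Literal["bonferroni", "bh"] = "bonferroni"
                   ) -> np.ndarray:
    """Multiple-testing adjustment over the tested (finite-p) family."""
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return adj
    if method == "bonferroni":
        adj[ok] = np.minimum(1.0, p[ok] * m)
    elif method == "bh":
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.empty(m)
        tmp[order] = np.minimum(1.0, ranked)
        adj[ok] = tmp
    else:
        raise ValueError(f"unknown correction {method!r}")
    return adj


def build_network(
    edges: pd.DataFrame,
    node_attrs: pd.DataFrame | None = None,
    r_threshold: float = R_THRESHOLD,
    alpha: float = 0.05,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> CouplingNetwork:
    """Threshold the edge table into a network: |r_b| > r_threshold AND
    adjusted p < alpha.  Isolated qualifying nodes are retained.

    The multiple-testing family is every tested pair (finite p), not only
    the pairs passing the r threshold.
    """
    edges = edges.copy()
    edges["p_adj"] = adjust_pvalues(edges["p"].to_numpy(), correction)
    keep = (edges["r_b"].abs() > r_threshold) & (edges["p_adj"] < alpha)
    kept = edges[keep.fillna(False)]

    nodes: list[str] = []
    seen = set()
    for col_a, col_l in (("analyte_a", "layer_a"), ("analyte_b", "layer_b")):
        for a in edges[col_a]:
            if a not in seen:
                seen.add(a)
                nodes.append(a)

    edge_objs = [CouplingEdge(
        analyte_a=r.analyte_a, analyte_b=r.analyte_b,
        layer_a=r.layer_a, layer_b=r.layer_b,
        r_b=float(r.r_b), n_overlap=int(r.n_overlap),
        p_value=float(r.p), p_adjusted=float(r.p_adj),
    ) for r in kept.itertuples()]

    attrs = node_attrs.reindex(nodes) if node_attrs is not None else pd.DataFrame(index=nodes)
    return CouplingNetwork(nodes=nodes, node_attrs=attrs, edges=edge_objs)


def _leading_eigenvector_split(A: np.ndarray, degrees: np.ndarray, m2: float,
                               members: np.ndarray, tol: float = 1e-10
                               ) -> tuple[np.ndarray, np.ndarray] | None:
    """One bisection step of Newman's method on the node subset ``members``.

    Builds the generalized modularity matrix of the subset, takes its leading
    eigenvector (dense symmetric solve, deterministic), and splits by sign.
    Returns None when the subset is indivisible (non-positive modularity gain).
    """
    sub = A[np.ix_(members, members)]
    k = degrees[members]
    B = sub - np.outer(k, k) / m2
    Bg = B - np.diag(B.sum(axis=1))
    vals, vecs = np.linalg.eigh(Bg)
    lead = vecs[:, -1]
    if vals[-1] <= tol:
        return None
    # deterministic sign convention for the eigenvector
    pivot = int(np.argmax(np.abs(lead)))
    if lead[pivot] < 0:
        lead = -lead
    s = np.where(lead >= 0, 1.0, -1.0)
    gain = s @ Bg @ s / (2 * m2)
    if gain <= tol:
        return None
    pos = members[s > 0]
    neg = members[s < 0]
    if pos.size == 0 or neg.size == 0:
        return None
    return pos, neg


def detect_communities(net: CouplingNetwork) -> dict[str, int]:
    """Newman leading-eigenvector communities on the unsigned binary adjacency.

    Recursive bisection on each connected component until the modularity gain
    is non-positive; isolated nodes become singleton communities.  Fully
    deterministic (dense symmetric eigendecomposition).  Stores and returns
    the node -> community id map.
    """
    A = net.adjacency()
    n = A.shape[0]
    degrees = A.sum(axis=1)
    m2 = float(degrees.sum())  # 2m
    membership = np.full(n, -1, dtype=int)
    next_id = 0

    if m2 == 0:
        comm = {name: i for i, name in enumerate(net.nodes)}
        net.communities = comm
        return comm

    # connected components (isolated nodes become their own components)
    unvisited = set(range(n))
    components: list[np.ndarray] = []
    while unvisited:
        start = min(unvisited)
        stack, seen = [start], {start}
        while stack:
            v = stack.pop()
            for u in np.flatnonzero(A[v]):
                if u not in seen:
                    seen.add(int(u))
                    stack.append(int(u))
        unvisited -= seen
        components.append(np.array(sorted(seen)))

    for comp in components:
        queue = [comp]
        while queue:
            members = queue.pop()
            if members.size == 1:
                membership[members] = next_id
                next_id += 1
                continue
            split = _leading_eigenvector_split(A, degrees, m2, members)
            if split is None:
                membership[members] = next_id
                next_id += 1
            else:
                queue.extend(split)

    comm = {name: int(c) for name, c in zip(net.nodes, membership)}
    net.communities = comm
    return comm
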