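"""Score-based causal structure learning over analytes.

A two-phase greedy search (forward edge additions, backward deletions)
maximizes the penalized Gaussian score

    local(v | P) = -(n/2) * ln(RSS_v / n) - c * (|P| + 1) * ln(n) / 2

with c the penalty discount; ``depth`` caps the parent-set size examined
jointly.  The learned DAG is reported as its pattern (CPDAG): compelled
edges directed, reversible edges undirected.  Robustness is estimated by a
bootstrap over cells, and graphs are summarized by betweenness, subgraph
centrality, and in/out-degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

PENALTY_DISCOUNT = 4.0
DEPTH = 3


@dataclass
class CausalGraph:
    """Pattern (CPDAG) over analytes with the DAG it was derived from."""

    nodes: list[str]
    directed: set[tuple[str, str]]      # compelled edges
    undirected: set[frozenset[str]]     # reversible edges
    score: float
    penalty_discount: float
    depth: int
    dag_edges: set[tuple[str, str]] = field(default_factory=set)

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def neighbors(self, v: str) -> set[str]:
        out = set()
        for a, b in self.directed:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        for e in self.undirected:
            if v in e:
                out |= set(e) - {v}
        return out

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": a, "target": b, "orientation": "directed"}
                for a, b in sorted(self.directed)]
        rows += [{"source": a, "target": b, "orientation": "undirected"}
                 for a, b in sorted(tuple(sorted(e)) for e in self.undirected)]
        return pd.DataFrame(rows, columns=["source", "target", "orientation"])


@dataclass
class BootstrapEnsemble:
    M: int
    n_success: int
    edge_freq: dict[frozenset[str], float]          # any orientation
    orient_freq: dict[tuple[str, str], float]       # directed a->b
    undirected_freq: dict[frozenset[str], float]
    avg_connectivity: float
    edge_counts: list[int]

    def table(self) -> pd.DataFrame:
        rows = []
        for e, f in sorted(self.edge_freq.items(), key=lambda kv: -kv[1]):
            a, b = sorted(e)
            rows.append({
                "analyte_a": a, "analyte_b": b, "freq_any": f,
                "freq_a_to_b": self.orient_freq.get((a, b), 0.0),
                "freq_b_to_a": self.orient_freq.get((b, a), 0.0),
                "freq_undirected": self.undirected_freq.get(e, 0.0),
            })
        return pd.DataFrame(rows, columns=[
            "analyte_a", "analyte_b", "freq_any", "freq_a_to_b",
            "freq_b_to_a", "freq_undirected"])


class _GaussScorer:
    """Penalized Gaussian local scores from the sample covariance."""

    def __init__(self, data: np.ndarray, penalty_discount: float):
        self.n, self.p = data.shape
        centered = data - data.mean(axis=0)
        self.S = centered.T @ centered / self.n
        self.c = penalty_discount
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def local(self, v: int, parents: frozenset[int]) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        n = self.n
        if parents:
            P = sorted(parents)
            Spp = self.S[np.ix_(P, P)]
            Svp = self.S[v, P]
            try:
                beta = np.linalg.solve(Spp, Svp)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Spp, Svp, rcond=None)[0]
            rss_n = self.S[v, v] - Svp @ beta
        else:
            rss_n = self.S[v, v]
        rss_n = max(float(rss_n), 1e-12)
        score = -(n / 2) * np.log(rss_n) - self.c * (len(parents) + 1) * np.log(n) / 2
        self._cache[key] = score
        return score


class _PDAG:
    """Partially directed graph: directed (pa/ch) plus undirected (ne) edges."""

    def __init__(self, p: int):
        self.p = p
        self.pa: list[set[int]] = [set() for _ in range(p)]
        self.ch: list[set[int]] = [set() for _ in range(p)]
        self.ne: list[set[int]] = [set() for _ in range(p)]

    def adjacent(self, x: int, y: int) -> bool:
        return y in self.pa[x] or y in self.ch[x] or y in self.ne[x]

    def is_clique(self, nodes: set[int]) -> bool:
        ns = list(nodes)
        return all(self.adjacent(a, b)
                   for i, a in enumerate(ns) for b in ns[i + 1:])

    def has_semidirected_path(self, src: int, dst: int, blocked: set[int]) -> bool:
        """Path src ~> dst along directed-out or undirected edges, avoiding
        ``blocked`` (used by the Insert validity condition)."""
        if src == dst:
            return True
        stack, seen = [src], {src} | set(blocked)
        while stack:
            v = stack.pop()
            for w in self.ch[v] | self.ne[v]:
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False


def _order_edges(nodes: list[int], parents: list[set[int]]) -> list[tuple[int, int]]:
    """Total edge order for the compelled-edge labeling (topological)."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for v in nodes:
        g.add_edges_from((p, v) for p in parents[v])
    topo = list(nx.topological_sort(g))
    rank = {v: i for i, v in enumerate(topo)}
    ordered = []
    for y in topo:
        for x in sorted(parents[y], key=lambda u: -rank[u]):
            ordered.append((x, y))
    return ordered


def _label_edges(nodes: list[int], parents: list[set[int]]
                 ) -> tuple[set[tuple[int, int]], set[frozenset[int]]]:
    """Chickering's compelled/reversible labeling of a DAG's edges."""
    ordered = _order_edges(nodes, parents)
    label: dict[tuple[int, int], str] = {e: "unknown" for e in ordered}

    for x, y in ordered:
        if label[(x, y)] != "unknown":
            continue
        done = False
        for w in list(parents[x]):
            if label.get((w, x)) == "compelled":
                if w not in parents[y]:
                    for z in parents[y]:
                        label[(z, y)] = "compelled"
                    done = True
                    break
                label[(w, y)] = "compelled"
        if done:
            continue
        if any(z != x and z not in parents[x] for z in parents[y]):
            new = "compelled"
        else:
            new = "reversible"
        label[(x, y)] = new
        for z in parents[y]:
            if label[(z, y)] == "unknown":
                label[(z, y)] = new

    directed = {e for e, l in label.items() if l == "compelled"}
    undirected = {frozenset(e) for e, l in label.items() if l == "reversible"}
    return directed, undirected


def _extend_to_dag(g: _PDAG) -> list[set[int]]:
    """Consistent DAG extension of a PDAG (Dor & Tarsi sink-elimination)."""
    p = g.p
    dag_pa = [set(g.pa[v]) for v in range(p)]
    pa = [set(s) for s in g.pa]
    ch = [set(s) for s in g.ch]
    ne = [set(s) for s in g.ne]
    remaining = set(range(p))

    def adjacent(x, y):
        return y in pa[x] or y in ch[x] or y in ne[x]

    while remaining:
        sink = None
        for x in sorted(remaining):
            if ch[x]:
                continue
            others = (pa[x] | ne[x])
            if all(all(adjacent(w, z) for z in others if z != w)
                   for w in ne[x]):
                sink = x
                break
        if sink is None:
            raise RuntimeError("PDAG admits no consistent extension")
        for w in ne[sink]:
            dag_pa[sink].add(w)
            ne[w].discard(sink)
        for w in pa[sink]:
            ch[w].discard(sink)
        pa[sink].clear()
        ne[sink].clear()
        remaining.discard(sink)
    return dag_pa


def _pdag_from_dag(p: int, dag_pa: list[set[int]]) -> _PDAG:
    """CPDAG of a DAG: compelled edges directed, reversible undirected."""
    directed, undirected = _label_edges(list(range(p)), dag_pa)
    g = _PDAG(p)
    for a, b in directed:
        g.pa[b].add(a)
        g.ch[a].add(b)
    for e in undirected:
        a, b = tuple(e)
        g.ne[a].add(b)
        g.ne[b].add(a)
    return g


def _subsets(items: list[int], max_size: int):
    from itertools import combinations

    for k in range(0, min(max_size, len(items)) + 1):
        yield from (set(c) for c in combinations(items, k))


def _best_insert(g: _PDAG, scorer: _GaussScorer, depth: int):
    """Best valid Insert(x, y, T) operator and its score improvement."""
    best_delta, best_op = 1e-10, None
    for y in range(g.p):
        pa_y = g.pa[y]
        for x in range(g.p):
            if x == y or g.adjacent(x, y):
                continue
            na = {w for w in g.ne[y] if g.adjacent(w, x)}
            nt = sorted(w for w in g.ne[y] if not g.adjacent(w, x))
            for T in _subsets(nt, depth):
                s = na | T
                if not g.is_clique(s):
                    continue
                if g.has_semidirected_path(y, x, blocked=s):
                    continue
                base = frozenset(pa_y | s)
                delta = (scorer.local(y, frozenset(base | {x}))
                         - scorer.local(y, base))
                if delta > best_delta:
                    best_delta, best_op = delta, (x, y, frozenset(T))
    return best_op, best_delta


def _best_delete(g: _PDAG, scorer: _GaussScorer, depth: int):
    """Best valid Delete(x, y, H) operator and its score improvement."""
    best_delta, best_op = 1e-10, None
    for y in range(g.p):
        pa_y = g.pa[y]
        candidates = sorted(g.pa[y] | g.ne[y])
        for x in candidates:
            na = {w for w in g.ne[y] if g.adjacent(w, x)}
            for H in _subsets(sorted(na), depth):
                if not g.is_clique(na - H):
                    continue
                keep = frozenset((na - H) | (pa_y - {x}))
                delta = (scorer.local(y, keep)
                         - scorer.local(y, frozenset(keep | {x})))
                if delta > best_delta:
                    best_delta, best_op = delta, (x, y, frozenset(H))
    return best_op, best_delta


def greedy_search(
    data: pd.DataFrame,
    penalty_discount: float = PENALTY_DISCOUNT,
    depth: int = DEPTH,
) -> CausalGraph:
    """Two-phase greedy equivalence search for the best-scoring pattern.

    ``data`` is cells x analytes with no missing values.  The forward phase
    applies the best valid Insert operator while the score improves; the
    backward phase applies the best valid Delete operator likewise.  The
    state is always a CPDAG; ``depth`` caps the size of the neighbor subsets
    (T and H) considered jointly when re-evaluating local scores.
    """
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("data contains missing values; impute first")
    names = list(data.columns)
    p = len(names)
    const = [names[j] for j in range(p) if np.var(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant analytes: {const}")
    if X.shape[0] <= p:
        logger.warning("fewer cells (%d) than analytes (%d)", X.shape[0], p)

    scorer = _GaussScorer(X, penalty_discount)
    g = _PDAG(p)

    def apply_insert(x: int, y: int, T: frozenset[int]) -> None:
        g.pa[y].add(x)
        g.ch[x].add(y)
        for t in T:
            g.ne[t].discard(y)
            g.ne[y].discard(t)
            g.pa[y].add(t)
            g.ch[t].add(y)

    def apply_delete(x: int, y: int, H: frozenset[int]) -> None:
        g.pa[y].discard(x)
        g.ch[x].discard(y)
        g.ne[x].discard(y)
        g.ne[y].discard(x)
        for h in H:
            g.ne[y].discard(h)
            g.ne[h].discard(y)
            g.pa[h].add(y)
            g.ch[y].add(h)
            if h in g.ne[x]:
                g.ne[x].discard(h)
                g.ne[h].discard(x)
                g.pa[h].add(x)
                g.ch[x].add(h)

    changed = True
    while changed:
        changed = False
        while True:  # forward equivalence search
            op, _ = _best_insert(g, scorer, depth)
            if op is None:
                break
            apply_insert(*op)
            g = _pdag_from_dag(p, _extend_to_dag(g))
            changed = True
        while True:  # backward equivalence search
            op, _ = _best_delete(g, scorer, depth)
            if op is None:
                break
            apply_delete(*op)
            g = _pdag_from_dag(p, _extend_to_dag(g))
            changed = True

    dag_pa = _extend_to_dag(g)
    total = float(sum(scorer.local(v, frozenset(dag_pa[v])) for v in range(p)))
    directed = {(names[a], names[b]) for b in range(p) for a in g.pa[b]}
    undirected = {frozenset((names[a], names[b]))
                  for a in range(p) for b in g.ne[a] if a < b}
    dag = {(names[a], names[b]) for b in range(p) for a in dag_pa[b]}
    return CausalGraph(
        nodes=names, directed=directed, undirected=undirected,
        score=total, penalty_discount=penalty_discount, depth=depth,
        dag_edges=dag,
    )


def bootstrap_ensemble(
    data: pd.DataFrame,
    M: int = 200,
    seed: int = 0,
    penalty_discount: float = PENALTY_DISCOUNT,
    depth: int = DEPTH,
) -> BootstrapEnsemble:
    """Bootstrap the greedy search: resample cells with replacement M times.

    Edge frequency counts an edge present in either orientation or
    undirected; orientation-specific frequencies are tracked separately.
    Replicates that fail are skipped and logged; fewer than 0.9*M successes
    is an error.
    """
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    any_count: dict[frozenset[str], int] = {}
    orient_count: dict[tuple[str, str], int] = {}
    undir_count: dict[frozenset[str], int] = {}
    edge_counts: list[int] = []
    n_success = 0
    for m in range(M):
        idx = rng.integers(0, n, size=n)
        try:
            g = greedy_search(data.iloc[idx], penalty_discount, depth)
        except Exception as e:  # noqa: BLE001 - skip-and-log per replicate
            logger.warning("bootstrap replicate %d failed: %s", m, e)
            continue
        n_success += 1
        for a, b in g.directed:
            orient_count[(a, b)] = orient_count.get((a, b), 0) + 1
            key = frozenset((a, b))
            any_count[key] = any_count.get(key, 0) + 1
        for e in g.undirected:
            undir_count[e] = undir_count.get(e, 0) + 1
            any_count[e] = any_count.get(e, 0) + 1
        edge_counts.append(len(g.directed) + len(g.undirected))
    if n_success < 0.9 * M:
        raise RuntimeError(f"only {n_success}/{M} bootstrap replicates succeeded")
    return BootstrapEnsemble(
        M=M, n_success=n_success,
        edge_freq={e: c / n_success for e, c in any_count.items()},
        orient_freq={e: c / n_success for e, c in orient_count.items()},
        undirected_freq={e: c / n_success for e, c in undir_count.items()},
        avg_connectivity=float(np.mean(edge_counts)) if edge_counts else 0.0,
        edge_counts=edge_counts,
    )


def centralities(g: CausalGraph) -> pd.DataFrame:
    """Betweenness (directed, unit lengths), subgraph centrality (undirected
    adjacency matrix exponential diagonal), and in/out-degree (directed only)."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    dg.add_edges_from(g.directed)
    btw = nx.betweenness_centrality(dg, normalized=False)

    idx = {v: i for i, v in enumerate(g.nodes)}
    A = np.zeros((len(g.nodes), len(g.nodes)))
    for e in g.skeleton():
        pair = tuple(e)
        if len(pair) == 2:
            a, b = idx[pair[0]], idx[pair[1]]
            A[a, b] = A[b, a] = 1.0
    sc = np.diag(expm(A))

    return pd.DataFrame({
        "analyte": g.nodes,
        "betweenness": [btw[v] for v in g.nodes],
        "subgraph_centrality": sc,
        "in_degree": [dg.in_degree(v) for v in g.nodes],
        "out_degree": [dg.out_degree(v) for v in g.nodes],
    }).set_index("analyte")


def causal_neighborhood(
    g: CausalGraph,
    targets: Sequence[str],
    data: pd.DataFrame | None = None,
    tissues: pd.Series | None = None,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Induced subgraph on targets and their first neighbors, with optional
    per-edge Pearson correlation within each tissue having >= min_cells
    complete observations of both analytes."""
    unknown = [t for t in targets if t not in set(g.nodes)]
    if unknown:
        raise ValueError(f"unknown targets: {unknown}")
    keep = set(targets)
    for t in targets:
        keep |= g.neighbors(t)
    rows = []
    for a, b in g.directed:
        if a in keep and b in keep:
            rows.append({"source": a, "target": b, "orientation": "directed"})
    for e in g.undirected:
        pair = sorted(e)
        if set(pair) <= keep:
            rows.append({"source": pair[0], "target": pair[1],
                         "orientation": "undirected"})
    sub = pd.DataFrame(rows, columns=["source", "target", "orientation"])
    if data is None or tissues is None:
        return sub, None

    tissues = tissues.reindex(data.index)
    corr_rows = []
    for r in sub.itertuples():
        for tis in sorted(tissues.dropna().unique()):
            mask = (tissues == tis).to_numpy()
            x = data.loc[mask, r.source].to_numpy(dtype=float)
            y = data.loc[mask, r.target].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_cells:
                continue
            if np.var(x[ok]) == 0 or np.var(y[ok]) == 0:
                continue
            corr_rows.append({
                "source": r.source, "target": r.target, "tissue": tis,
                "n": int(ok.sum()),
                "pearson_r": float(pearsonr(x[ok], y[ok]).statistic),
            })
    corr = pd.DataFrame(corr_rows,
                        columns=["source", "target", "tissue", "n", "pearson_r"])
    return sub, corr


def compare_ensembles(eA: BootstrapEnsemble, eB: BootstrapEnsemble
                      ) -> dict[str, float]:
    """Pearson and Spearman correlation of edge frequencies over the union of
    edges of either ensemble, restricted to shared nodes (absent edge = 0)."""
    nodes_a = {v for e in eA.edge_freq for v in e}
    nodes_b = {v for e in eB.edge_freq for v in e}
    shared = nodes_a & nodes_b
    if not shared:
        raise ValueError("no shared nodes between ensembles")
    union = {e for e in set(eA.edge_freq) | set(eB.edge_freq)
             if set(e) <= shared}
    fa = np.array([eA.edge_freq.get(e, 0.0) for e in union])
    fb = np.array([eB.edge_freq.get(e, 0.0) for e in union])
    if union and (np.var(fa) > 0 and np.var(fb) > 0):
        pr = float(pearsonr(fa, fb).statistic)
        sr = float(spearmanr(fa, fb).statistic)
    else:
        pr = sr = float("nan")
    return {"pearson": pr, "spearman": sr, "n_edges": len(union)}


def mean_impute(data: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean imputation of residual missingness (warned)."""
    miss = data.isna()
    frac = float(miss.to_numpy().mean())
    if frac > 0:
        logger.warning("imputing %.2f%% missing values with column means", 100 * frac)
        return data.fillna(data.mean())
    return data
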