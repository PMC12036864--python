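"""Score-based structure learning over per-sample cell-type abundances.

A directed acyclic graph over cell types is learned by greedy hill-climbing on
the decomposable linear-Gaussian BIC

    score(G) = sum_v [ -(n/2) log(RSS_v / n) - (|pa(v)| + 2)/2 * log n ]

where RSS_v is the residual sum of squares of regressing variable v on its
parents (intercept included).  Variables are z-scored (ddof=1) before scoring.
Moves are single-edge additions, deletions and reversals; the best move with a
positive score gain is applied until a local optimum; random restarts perturb
the start graph.  Edge confidence comes from nonparametric bootstrap: the
fraction of row-resampled replicates whose learned graph contains the edge in
either direction, with the majority direction retained.  Directionality is
only partially identifiable from observational Gaussian data (Markov
equivalence), so consensus edges whose direction support is below 0.7 are
flagged as undirected-equivalent rather than presented as causal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import FormatError

_RSS_FLOOR = 1e-12
_DIRECTION_CONF = 0.7


@dataclass
class DagModel:
    """Directed acyclic graph over named variables with optional edge confidence."""

    nodes: list[str]
    edges: list[tuple]  # (source, target)
    confidence: dict = field(default_factory=dict)  # edge -> bootstrap support
    directed_flags: dict = field(default_factory=dict)  # edge -> direction confident?
    score: float | None = None
    seed: int | None = None
    n_restarts: int | None = None
    max_indegree: int | None = None

    def __post_init__(self):
        self.nodes = [str(n) for n in self.nodes]
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise FormatError("duplicate node names")
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise FormatError(f"self-loop on {u!r}")
            if u not in nodeset or v not in nodeset:
                raise FormatError(f"edge ({u}, {v}) references unknown node")
            if (u, v) in seen:
                raise FormatError(f"duplicate edge ({u}, {v})")
            seen.add((u, v))
        self.edges = [(str(u), str(v)) for u, v in self.edges]
        if not _is_acyclic(self.nodes, self.edges):
            raise FormatError("graph contains a cycle")

    def parents(self, v: str) -> list[str]:
        return [u for u, w in self.edges if w == v]

    def skeleton(self) -> frozenset:
        return frozenset(frozenset((u, v)) for u, v in self.edges)

    def subgraph(self, keep_nodes) -> "DagModel":
        keep = set(keep_nodes)
        edges = [(u, v) for u, v in self.edges if u in keep and v in keep]
        return DagModel(
            nodes=[n for n in self.nodes if n in keep],
            edges=edges,
            confidence={e: c for e, c in self.confidence.items() if e in edges},
            directed_flags={e: d for e, d in self.directed_flags.items() if e in edges},
            score=None,
            seed=self.seed,
            n_restarts=self.n_restarts,
            max_indegree=self.max_indegree,
        )


def _is_acyclic(nodes, edges) -> bool:
    children: dict[str, list] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    return seen == len(nodes)


def _has_path(edges_set, nodes, src, dst) -> bool:
    """DFS reachability src -> dst over a directed edge set."""
    children: dict[str, list] = {n: [] for n in nodes}
    for u, v in edges_set:
        children[u].append(v)
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in children[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def zscore(data: np.ndarray) -> np.ndarray:
    """Column z-scores with ddof=1; constant columns are centred only."""
    data = np.asarray(data, dtype=float)
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (data - mu) / sd


def _family_rss(X: np.ndarray, v: int, parents: tuple) -> float:
    n = X.shape[0]
    y = X[:, v]
    if not parents:
        resid = y - y.mean()
        return float(resid @ resid)
    design = np.column_stack([np.ones(n)] + [X[:, p] for p in parents])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FormatError(f"singular parent design for node index {v}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def family_score(X: np.ndarray, v: int, parents: tuple) -> float:
    """BIC contribution of one node given its parents (larger is better)."""
    n = X.shape[0]
    rss = max(_family_rss(X, v, parents), _RSS_FLOOR)
    return -(n / 2.0) * np.log(rss / n) - (len(parents) + 2) / 2.0 * np.log(n)


def gaussian_bic(data: np.ndarray, dag: DagModel) -> float:
    """Decomposable network BIC of ``dag`` on (already z-scored) sample x variable data."""
    X = np.asarray(data, dtype=float)
    if X.shape[1] != len(dag.nodes):
        raise FormatError("data column count does not match dag nodes")
    idx = {n: i for i, n in enumerate(dag.nodes)}
    total = 0.0
    for v in dag.nodes:
        parents = tuple(sorted(idx[u] for u in dag.parents(v)))
        try:
            total += family_score(X, idx[v], parents)
        except FormatError:
            raise FormatError(f"singular parent design for node {v!r}")
    return float(total)


class _Search:
    """Greedy hill-climb state over one dataset, with family-score caching."""

    def __init__(self, X, nodes, blacklist, whitelist, max_indegree):
        self.X = X
        self.nodes = nodes
        self.idx = {n: i for i, n in enumerate(nodes)}
        self.blacklist = blacklist
        self.whitelist = whitelist
        self.max_indegree = max_indegree
        self._cache: dict = {}

    def fam(self, v: str, parents: frozenset) -> float:
        key = (v, parents)
        if key not in self._cache:
            self._cache[key] = family_score(
                self.X, self.idx[v], tuple(sorted(self.idx[u] for u in parents))
            )
        return self._cache[key]

    def total(self, parent_map) -> float:
        return sum(self.fam(v, frozenset(parent_map[v])) for v in self.nodes)

    @staticmethod
    def _better(cand, best) -> bool:
        """Strictly larger gain wins; near-ties broken by (source, target, kind)."""
        if best is None:
            return True
        if cand[0] > best[0] + 1e-12:
            return True
        return abs(cand[0] - best[0]) <= 1e-12 and cand[1:] < best[1:]

    def climb(self, start_edges) -> tuple[set, float]:
        edges = set(start_edges)
        pa = {v: {u for u, w in edges if w == v} for v in self.nodes}
        while True:
            best = None  # (delta, src, tgt, kind)
            for u in self.nodes:
                for v in self.nodes:
                    if u == v or (u, v) in edges:
                        continue
                    if (
                        (u, v) in self.blacklist
                        or len(pa[v]) >= self.max_indegree
                        or _has_path(edges, self.nodes, v, u)
                    ):
                        continue
                    delta = self.fam(v, frozenset(pa[v] | {u})) - self.fam(
                        v, frozenset(pa[v])
                    )
                    cand = (delta, u, v, 0)
                    if self._better(cand, best):
                        best = cand
            for (u, v) in sorted(edges):
                if (u, v) in self.whitelist:
                    continue
                base = self.fam(v, frozenset(pa[v]))
                cand = (self.fam(v, frozenset(pa[v] - {u})) - base, u, v, 1)
                if self._better(cand, best):
                    best = cand
                # reversal u->v  =>  v->u
                if (v, u) in self.blacklist or len(pa[u]) >= self.max_indegree:
                    continue
                if _has_path(edges - {(u, v)}, self.nodes, u, v):
                    continue
                delta_rev = (
                    self.fam(v, frozenset(pa[v] - {u}))
                    - base
                    + self.fam(u, frozenset(pa[u] | {v}))
                    - self.fam(u, frozenset(pa[u]))
                )
                cand = (delta_rev, u, v, 2)
                if self._better(cand, best):
                    best = cand
            if best is None or best[0] <= 1e-10:
                break
            _, u, v, kind = best
            if kind == 0:
                edges.add((u, v))
                pa[v].add(u)
            elif kind == 1:
                edges.remove((u, v))
                pa[v].discard(u)
            else:
                edges.remove((u, v))
                pa[v].discard(u)
                edges.add((v, u))
                pa[u].add(v)
        return edges, self.total(pa)


def hill_climb(
    data,
    blacklist=(),
    whitelist=(),
    max_indegree: int = 3,
    restarts: int = 10,
    seed: int = 0,
    node_names=None,
) -> DagModel:
    """Greedy BIC hill-climb with random restarts; deterministic given ``seed``.

    ``data`` is sample x variable (array or DataFrame); variables are z-scored
    internally.  Whitelist edges are always present and never removed;
    blacklist edges are never added.
    """
    import pandas as pd

    if isinstance(data, pd.DataFrame):
        node_names = node_names or list(map(str, data.columns))
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        node_names = node_names or [f"v{i}" for i in range(X.shape[1])]
    n, k = X.shape
    if n < 10:
        warnings.warn(f"only {n} samples; structure estimates will be unstable")
    blacklist = {(str(u), str(v)) for u, v in blacklist}
    whitelist = {(str(u), str(v)) for u, v in whitelist}
    if blacklist & whitelist:
        raise FormatError("whitelist and blacklist overlap")
    if not _is_acyclic(node_names, list(whitelist)):
        raise FormatError("whitelist is cyclic")
    X = zscore(X)
    search = _Search(X, node_names, blacklist, whitelist, max_indegree)
    rng = np.random.default_rng(seed)

    best_edges, best_score = None, -np.inf
    for r in range(max(1, restarts)):
        start = set(whitelist)
        if r > 0:
            n_extra = int(rng.integers(1, k + 1))
            for _ in range(n_extra):
                u, v = [node_names[i] for i in rng.choice(k, size=2, replace=False)]
                e = (u, v)
                pa_v = sum(1 for a, b in start if b == v)
                if (
                    e in start
                    or e in blacklist
                    or pa_v >= max_indegree
                    or _has_path(start, node_names, v, u)
                ):
                    continue
                start.add(e)
        edges, score = search.climb(start)
        if score > best_score + 1e-12:
            best_edges, best_score = edges, score
    return DagModel(
        nodes=list(node_names),
        edges=sorted(best_edges),
        score=float(best_score),
        seed=seed,
        n_restarts=max(1, restarts),
        max_indegree=max_indegree,
    )


def bootstrap_edges(
    data,
    B: int = 200,
    conf_min: float = 0.5,
    seed: int = 0,
    node_names=None,
    blacklist=(),
    whitelist=(),
    max_indegree: int = 3,
    restarts: int = 2,
    ) -> DagModel:
    """Bootstrap consensus network with per-edge confidence.

    Rows are resampled with replacement B times; the learned replicate graphs
    are aggregated per unordered pair (skeleton confidence = fraction of
    replicates containing the pair in either direction).  Pairs at or above
    ``conf_min`` are kept, oriented by the majority direction (ties broken
    lexicographically); any cycle introduced by orientation is resolved by
    dropping the lowest-confidence edge on the cycle.
    """
    import pandas as pd

    if B < 1:
        raise FormatError("B must be >= 1")
    if isinstance(data, pd.DataFrame):
        node_names = node_names or list(map(str, data.columns))
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        node_names = node_names or [f"v{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    pair_count: dict[frozenset, int] = {}
    dir_count: dict[tuple, int] = {}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        dag = hill_climb(
            X[idx, :],
            blacklist=blacklist,
            whitelist=whitelist,
            max_indegree=max_indegree,
            restarts=restarts,
            seed=sub_seed,
            node_names=node_names,
        )
        for u, v in dag.edges:
            key = frozenset((u, v))
            pair_count[key] = pair_count.get(key, 0) + 1
            dir_count[(u, v)] = dir_count.get((u, v), 0) + 1

    edges, confidence, directed_flags = [], {}, {}
    for pair in sorted(pair_count, key=lambda p: tuple(sorted(p))):
        conf = pair_count[pair] / B
        if conf < conf_min:
            continue
        a, b = sorted(pair)
        n_ab = dir_count.get((a, b), 0)
        n_ba = dir_count.get((b, a), 0)
        edge = (a, b) if n_ab >= n_ba else (b, a)
        dir_conf = max(n_ab, n_ba) / max(n_ab + n_ba, 1)
        edges.append(edge)
        confidence[edge] = conf
        directed_flags[edge] = dir_conf >= _DIRECTION_CONF

    # orientation may create cycles across pairs: drop weakest edge per cycle
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(node_names)
    g.add_edges_from(edges)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(((u, v) for u, v, *_ in cycle), key=lambda e: (confidence[e], e))
        g.remove_edge(*weakest)
        edges.remove(weakest)
        confidence.pop(weakest)
        directed_flags.pop(weakest)

    return DagModel(
        nodes=list(node_names),
        edges=sorted(edges),
        confidence=confidence,
        directed_flags=directed_flags,
        score=None,
        seed=seed,
        n_restarts=restarts,
        max_indegree=max_indegree,
    )


def enumerate_dags(nodes) -> list[DagModel]:
    """All DAGs over a (small) node set; oracle helper for exhaustive checks."""
    nodes = list(nodes)
    pairs = list(combinations(range(len(nodes)), 2))
    dags = []

    def build(i, edges):
        if i == len(pairs):
            dags.append(DagModel(nodes=nodes, edges=sorted(edges)))
            return
        a, b = pairs[i]
        build(i + 1, edges)
        for e in ((nodes[a], nodes[b]), (nodes[b], nodes[a])):
            if not _has_path(edges, nodes, e[1], e[0]):
                build(i + 1, edges | {e})

    build(0, set())
    return dags
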