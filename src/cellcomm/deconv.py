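"""Anchored (semi-supervised) deconvolution of bulk expression.

The bulk CPM matrix X (genes x samples) is modelled as X ~ S.P where S is a
non-negative gene x cell-type signature matrix and P a cell-type x sample
proportion matrix whose columns live on the probability simplex.  Prior
knowledge enters as *anchor* genes: an anchor gene of cell type k has its
signature hard-zeroed in every other component, which pins component identity
and makes the factorisation semi-supervised.  Extra unanchored ("free")
components may be requested to absorb unannotated cell populations.

Fitting alternates exact non-negative least squares:

* P-step (per sample): NNLS solve, then Euclidean projection onto the simplex;
* S-step (per gene): NNLS solve with anchored cross-loadings fixed at zero.

Both steps first try the unconstrained least-squares solution and only fall
back to NNLS for the rows/columns that violate non-negativity, which is
numerically identical and much faster at scale.  The trace of the Frobenius
objective is recorded with a monotone safeguard: an iteration that would
increase the objective (possible in principle because the simplex projection
is applied after, not inside, the NNLS solve) reverts to the previous iterate
and stops.

Marker discovery scores each gene's *specificity* for its best component,
S[g,k] / sum_j S[g,j], and reports genes above a specificity floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import ExpressionMatrix, FormatError, GeneSetCollection


@dataclass
class AnchorSet:
    """Cell type -> anchor genes, plus an optional count of free components.

    Anchor sets must be pairwise disjoint; anchors missing from the expression
    matrix are dropped with a warning when fitting (a type losing all its
    anchors is an error).
    """

    anchors: dict[str, frozenset]
    k_free: int = 0

    def __post_init__(self):
        if self.k_free < 0:
            raise FormatError("k_free must be >= 0")
        clean = {}
        seen: set = set()
        for cell, genes in self.anchors.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise FormatError(f"anchor set for {cell!r} is empty")
            clash = genes & seen
            if clash:
                raise FormatError(f"anchor genes shared between cell types: {sorted(clash)}")
            seen |= genes
            clean[str(cell)] = genes
        self.anchors = clean

    @property
    def cell_names(self) -> list[str]:
        return list(self.anchors) + [f"free_{i + 1}" for i in range(self.k_free)]

    @classmethod
    def from_gene_sets(cls, coll: GeneSetCollection, k_free: int = 0) -> "AnchorSet":
        return cls({name: coll[name] for name in coll.names()}, k_free=k_free)


@dataclass
class DeconvResult:
    signatures: pd.DataFrame  # gene x cell type, >= 0
    proportions: pd.DataFrame  # cell type x sample, simplex columns
    objective_trace: list[float]
    restarts_used: int
    seed: int
    converged: bool
    markers: dict[str, list] | None = None
    anchor_types: dict[str, str] = field(default_factory=dict)  # anchor gene -> cell

    @property
    def cell_names(self) -> list[str]:
        return list(self.signatures.columns)

    def marker_sets(self) -> GeneSetCollection:
        if self.markers is None:
            raise FormatError("markers not yet computed; call marker_specificity first")
        return GeneSetCollection(
            {cell: frozenset(g for g, _ in lst) for cell, lst in self.markers.items() if lst}
        )


def _project_simplex_columns(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column of V onto the probability simplex."""
    K, n = V.shape
    U = np.sort(V, axis=0)[::-1, :]
    css = np.cumsum(U, axis=0) - 1.0
    ks = np.arange(1, K + 1)[:, None]
    cond = U - css / ks > 0
    rho = K - 1 - np.argmax(cond[::-1, :], axis=0)  # last index where cond holds
    tau = css[rho, np.arange(n)] / (rho + 1)
    return np.maximum(V - tau[None, :], 0.0)


def _solve_P(S: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-sample NNLS of X on S followed by simplex projection."""
    K = S.shape[1]
    gram = S.T @ S + 1e-12 * np.eye(K)
    P = np.linalg.solve(gram, S.T @ X)
    bad = np.where((P < -1e-10).any(axis=0))[0]
    for j in bad:
        P[:, j], _ = nnls(S, X[:, j])
    np.maximum(P, 0.0, out=P)
    return _project_simplex_columns(P)


def _solve_S(
    P: np.ndarray, X: np.ndarray, anchor_col: np.ndarray, S_out: np.ndarray
) -> np.ndarray:
    """Per-gene NNLS of X on P with hard anchoring.

    ``anchor_col[g]`` is the component index a gene is anchored to, or -1.
    Anchored rows reduce to a one-dimensional non-negative solve.
    """
    K = P.shape[0]
    free_rows = np.where(anchor_col < 0)[0]
    if free_rows.size:
        gram = P @ P.T + 1e-12 * np.eye(K)
        sol = np.linalg.solve(gram, P @ X[free_rows, :].T).T
        bad = np.where((sol < -1e-10).any(axis=1))[0]
        Pt = P.T
        for i in bad:
            sol[i, :], _ = nnls(Pt, X[free_rows[i], :])
        np.maximum(sol, 0.0, out=sol)
        S_out[free_rows, :] = sol
    anch_rows = np.where(anchor_col >= 0)[0]
    if anch_rows.size:
        S_out[anch_rows, :] = 0.0
        for g in anch_rows:
            k = anchor_col[g]
            denom = float(P[k, :] @ P[k, :])
            S_out[g, k] = max(0.0, float(X[g, :] @ P[k, :]) / denom) if denom > 1e-30 else 0.0
    return S_out


def fit_deconvolution(
    mat: ExpressionMatrix,
    anchors: AnchorSet,
    max_iter: int = 200,
    tol: float = 1e-6,
    restarts: int = 5,
    seed: int = 0,
) -> DeconvResult:
    """Alternating anchored NNLS minimising ||X - S.P||_F^2.

    Deterministic given ``seed``.  Restarts redraw only the free components;
    with no free components a single restart is run (the anchored problem has
    a deterministic initialisation).  The best restart by final objective is
    returned.
    """
    if mat.unit != "cpm":
        raise FormatError("fit_deconvolution expects unit='cpm' (mixing is additive in linear space)")
    gidx = mat.gene_index()
    resolved: dict[str, frozenset] = {}
    for cell, genes in anchors.anchors.items():
        present = frozenset(g for g in genes if g in gidx)
        missing = genes - present
        if missing:
            warnings.warn(f"anchors absent from the matrix for {cell!r}: {sorted(missing)}")
        if not present:
            raise FormatError(f"all anchors of cell type {cell!r} are absent from the matrix")
        resolved[cell] = present

    cell_names = list(resolved) + [f"free_{i + 1}" for i in range(anchors.k_free)]
    K = len(cell_names)
    if K < 2:
        raise FormatError("need >= 2 components (cell types + free)")
    X = mat.values
    G, n = X.shape
    if n < K:
        warnings.warn(f"fewer samples ({n}) than components ({K}); proportions may be unstable")

    anchor_col = np.full(G, -1, dtype=int)
    anchor_types: dict[str, str] = {}
    for k, cell in enumerate(resolved):
        for g in resolved[cell]:
            anchor_col[gidx[g]] = k
            anchor_types[g] = cell

    # anchored columns initialised from anchor-weighted mean CPM profiles
    S0 = np.empty((G, K))
    for k, cell in enumerate(resolved):
        rows = [gidx[g] for g in resolved[cell]]
        w = X[rows, :].mean(axis=0)
        w = w / w.sum() if w.sum() > 0 else np.full(n, 1.0 / n)
        S0[:, k] = X @ w
    rng = np.random.default_rng(seed)
    n_restarts = restarts if anchors.k_free > 0 else 1

    best = None
    for r in range(n_restarts):
        S = S0.copy()
        for j in range(anchors.k_free):
            S[:, len(resolved) + j] = rng.exponential(scale=max(X.mean(), 1e-6), size=G)
        # enforce hard anchoring on the start point
        anch = anchor_col >= 0
        keep = S[np.arange(G)[anch], anchor_col[anch]]
        S[anch, :] = 0.0
        S[np.arange(G)[anch], anchor_col[anch]] = keep

        # Per-component scale is indeterminate (S[:,k]*a, P[k,:]/a); pinning each
        # signature column to the data's column-sum scale keeps the NNLS
        # proportions near the simplex, so the projection is a small correction.
        target_mass = float(X.sum(axis=0).mean())

        def _rescale(S_):
            sums = S_.sum(axis=0)
            scale = np.where(sums > 0, target_mass / np.where(sums > 0, sums, 1.0), 1.0)
            return S_ * scale[None, :]

        S = _rescale(S)
        P = _solve_P(S, X)
        prev_obj = float(((X - S @ P) ** 2).sum())
        trace = [prev_obj]
        converged = False
        for _ in range(max_iter):
            S_new = _rescale(_solve_S(P, X, anchor_col, S.copy()))
            P_new = _solve_P(S_new, X)
            obj = float(((X - S_new @ P_new) ** 2).sum())
            if obj > prev_obj * (1 + 1e-12):
                converged = True  # monotone safeguard: keep the previous iterate
                break
            S, P = S_new, P_new
            trace.append(obj)
            if prev_obj > 0 and (prev_obj - obj) / max(prev_obj, 1e-30) < tol:
                converged = True
                prev_obj = obj
                break
            prev_obj = obj
        if best is None or prev_obj < best[0]:
            best = (prev_obj, S, P, trace, converged)

    _, S, P, trace, converged = best
    return DeconvResult(
        signatures=pd.DataFrame(S, index=mat.gene_ids, columns=cell_names),
        proportions=pd.DataFrame(P, index=cell_names, columns=mat.sample_ids),
        objective_trace=trace,
        restarts_used=n_restarts,
        seed=seed,
        converged=converged,
        anchor_types=anchor_types,
    )


def marker_specificity(
    res: DeconvResult, min_signature: float = 10.0, spec_min: float = 0.7
) -> DeconvResult:
    """Populate ``res.markers`` from the fitted signatures.

    specificity(g, k) = S[g,k] / sum_j S[g,j], computed for genes whose top
    signature reaches ``min_signature``; a gene is a marker of its top
    component when specificity >= ``spec_min``.  Marker lists are sorted by
    specificity descending, ties broken lexicographically by gene id.
    """
    S = res.signatures.to_numpy()
    genes = list(res.signatures.index)
    cells = res.cell_names
    totals = S.sum(axis=1)
    tops = S.max(axis=1)
    markers: dict[str, list] = {c: [] for c in cells}
    for i, g in enumerate(genes):
        if totals[i] <= 0 or tops[i] < min_signature:
            continue
        k = int(np.argmax(S[i, :]))
        spec = float(S[i, k] / totals[i])
        if spec >= spec_min:
            markers[cells[k]].append((g, spec))
    for c in cells:
        markers[c].sort(key=lambda t: (-t[1], t[0]))
    res.markers = markers
    return res
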