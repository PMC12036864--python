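"""Differential expression between sample groups and cross-species intersection.

The default test is Welch's unequal-variance t on log2 CPM, with
Benjamini-Hochberg control across genes.  A gene is called up/down when
q < alpha AND |log2 fold change| >= lfc_min.  Conserved genes across species
are the significant genes whose explicit orthologs move in the same direction
in the other species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, FormatError, OrthologyMap, SampleMetadata


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH q-values, order-preserving with the input indexing."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class DEResult:
    """Per-gene differential-expression calls for groupA vs groupB."""

    table: pd.DataFrame  # index: gene; columns: log2fc, p, q, direction
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    method: str
    alpha: float
    lfc_min: float

    def genes(self, direction: str) -> frozenset:
        t = self.table
        return frozenset(t.index[t["direction"] == direction])

    @property
    def up(self) -> frozenset:
        return self.genes("up")

    @property
    def down(self) -> frozenset:
        return self.genes("down")

    @property
    def significant(self) -> frozenset:
        return self.up | self.down

    def direction_of(self, gene: str) -> str:
        return str(self.table.at[gene, "direction"])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


def differential_expression(
    mat: ExpressionMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    method: str = "welch_t",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    by: str = "condition",
) -> DEResult:
    """Two-sided test of groupA vs groupB on logCPM values.

    ``by`` selects the metadata field used for grouping ("condition" or
    "timepoint").  log2fc = mean(A) - mean(B).  Genes with zero variance in
    both groups get p = 1 (no evidence either way).
    """
    if mat.unit != "logcpm":
        raise FormatError("differential_expression expects unit='logcpm'")
    meta.validate_against(mat)
    if by == "condition":
        samples_a = meta.samples_where(condition=group_a)
        samples_b = meta.samples_where(condition=group_b)
    elif by == "timepoint":
        samples_a = meta.samples_where(timepoint=group_a)
        samples_b = meta.samples_where(timepoint=group_b)
    else:
        raise ValueError(f"unknown grouping field {by!r}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise FormatError(
            f"each group needs >= 2 samples (got {len(samples_a)} vs {len(samples_b)})"
        )
    sidx = mat.sample_index()
    A = mat.values[:, [sidx[s] for s in samples_a]]
    B = mat.values[:, [sidx[s] for s in samples_b]]

    log2fc = A.mean(axis=1) - B.mean(axis=1)
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "welch_t":
            _, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        elif method == "wilcoxon":
            _, p = stats.ranksums(A, B, axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
    p = np.asarray(p, dtype=float)
    p[degenerate] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    p = np.clip(p, 0.0, 1.0)
    q = benjamini_hochberg(p)

    direction = np.where(
        (q < alpha) & (np.abs(log2fc) >= lfc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "direction": direction}, index=mat.gene_ids
    )
    return DEResult(
        table=table,
        group_a=str(group_a),
        group_b=str(group_b),
        n_a=len(samples_a),
        n_b=len(samples_b),
        method=method,
        alpha=alpha,
        lfc_min=lfc_min,
    )


def conserved_degs(de_a: DEResult, de_b: DEResult, ortho: OrthologyMap) -> frozenset:
    """Ortholog pairs significant in both species with the same direction.

    Returns (geneA, geneB) tuples; many-to-many orthologs contribute one pair
    per concordant mapping.
    """
    if len(ortho) == 0:
        raise FormatError("orthology map is empty")
    idx_a = set(de_a.table.index)
    idx_b = set(de_b.table.index)
    out = set()
    for a, b in ortho.pairs:
        if a not in idx_a or b not in idx_b:
            continue
        da = de_a.direction_of(a)
        if da == "ns":
            continue
        if de_b.direction_of(b) == da:
            out.add((a, b))
    return frozenset(out)
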