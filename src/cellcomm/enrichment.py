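"""Hypergeometric over-representation analysis.

Links differentially expressed genes and discovered cell-type markers to gene
sets (marker panels, pathways, cytokine programmes).  The test is the
upper-tail hypergeometric probability P(X >= k) for drawing k set members in a
query of size n from a universe of N genes containing K set members; BH
correction is applied across the tested collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import stats

from .diffexpr import DEResult, benjamini_hochberg
from .io import FormatError, GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float
    odds_ratio: float
    genes: list[str] = field(default_factory=list)
    direction: str | None = None  # populated by assign_degs_to_cells


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    # 2x2 table: in-query/in-set, in-query/out, out-query/in-set, out/out
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane correction
    return (a * d) / (b * c)


def hypergeom_enrich(query, sets: GeneSetCollection, universe) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` against every set.

    Query genes outside the universe are dropped with a warning; each target
    set is intersected with the universe before testing.
    """
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise FormatError("empty universe")
    query = frozenset(str(g) for g in query)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
    query &= universe
    if not query:
        raise FormatError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    results = []
    pvals = []
    for name in sets.names():
        members = sets[name] & universe
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = min(max(float(stats.hypergeom.sf(k - 1, N, K, n)), 0.0), 1.0)
        results.append(
            EnrichmentResult(
                set_name=name,
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                q=1.0,
                odds_ratio=_odds_ratio(k, K, n, N),
                genes=overlap,
            )
        )
        pvals.append(p)
    if results:
        qvals = benjamini_hochberg(pvals)
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def assign_degs_to_cells(
    de: DEResult, markers: dict, universe, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Test up- and down-regulated genes separately against per-cell marker sets.

    A cell type is implicated when q < alpha in either direction (see
    :func:`implicated_cells`).  Returns an empty list with a warning when there
    are no significant genes.
    """
    marker_sets = {}
    for cell, genes in markers.items():
        genes = list(genes)
        if genes and isinstance(genes[0], tuple):  # (gene, specificity) pairs
            genes = [g for g, *_ in genes]
        if genes:
            marker_sets[cell] = frozenset(genes)
    if not marker_sets:
        raise FormatError("no non-empty marker sets")
    coll = GeneSetCollection(marker_sets)
    out: list[EnrichmentResult] = []
    for direction in ("up", "down"):
        query = de.genes(direction)
        if not (query & frozenset(str(g) for g in universe)):
            continue
        for r in hypergeom_enrich(query, coll, universe):
            r.direction = direction
            out.append(r)
    if not out:
        warnings.warn("no significant genes in either direction; nothing to assign")
    return out


def implicated_cells(results: list[EnrichmentResult], alpha: float = 0.05) -> frozenset:
    return frozenset(r.set_name for r in results if r.q < alpha)


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tdirection\tk\tK\tn\tN\tp\tq\todds_ratio\tgenes\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.direction or ''}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.10g}\t{r.q:.10g}\t{r.odds_ratio:.10g}\t{';'.join(r.genes)}\n"
            )
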