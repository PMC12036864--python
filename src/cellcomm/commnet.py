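"""Ligand-receptor annotation of the learned cell graph and time-course gating.

A directed cell graph (from structure learning) is turned into a communication
network by annotating each edge A -> B with the ligand-receptor channels whose
ligand marks A and receptor marks B.  A pair's score is the geometric mean
sqrt(mu_ligand * mu_receptor) of mean CPM over the scored samples (a
mass-action convention); the edge weight is the sum of its pair scores.

For time courses, a single consensus graph is learned from all samples and then
*gated* per timepoint: an edge appears on day t only when both endpoint cell
types are significantly more abundant than baseline (one-sided Welch on the
deconvolved proportions) and at least one of its ligands is up-regulated at t.
Because edge direction is often Markov-equivalent, edges whose bootstrap
direction support is weak are annotated in whichever orientation the
ligand-receptor evidence supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayesnet import DagModel, bootstrap_edges, zscore
from .deconv import AnchorSet, fit_deconvolution, marker_specificity
from .diffexpr import DEResult, differential_expression
from .io import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    LRDatabase,
    SampleMetadata,
)
from .preprocess import cpm_normalize, log_transform


@dataclass
class CommEdge:
    source: str
    target: str
    weight: float
    confidence: float = 1.0
    lr_pairs: list = field(default_factory=list)  # (ligand, receptor, score)


@dataclass
class CommunicationNetwork:
    """Directed cell -> cell interaction network with LR annotations."""

    nodes: list[str]
    edges: list[CommEdge]
    condition: str | None = None
    timepoint: float | None = None

    def __post_init__(self):
        nodeset = set(self.nodes)
        for e in self.edges:
            if e.source not in nodeset or e.target not in nodeset:
                raise FormatError(f"edge ({e.source}, {e.target}) references unknown node")
            if e.weight < 0:
                raise FormatError("edge weight must be >= 0")
            total = sum(s for _, _, s in e.lr_pairs)
            if e.lr_pairs and abs(total - e.weight) > 1e-9:
                raise FormatError(
                    f"edge ({e.source}, {e.target}) weight {e.weight} != sum of pair scores {total}"
                )

    def edge_set(self) -> frozenset:
        return frozenset((e.source, e.target) for e in self.edges)

    def get_edge(self, source, target) -> CommEdge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def equal_to(self, other: "CommunicationNetwork", tol: float = 1e-9) -> bool:
        if set(self.nodes) != set(other.nodes) or self.edge_set() != other.edge_set():
            return False
        for e in self.edges:
            o = other.get_edge(e.source, e.target)
            if abs(e.weight - o.weight) > tol:
                return False
            mine = sorted((l, r, round(s, 12)) for l, r, s in e.lr_pairs)
            theirs = sorted((l, r, round(s, 12)) for l, r, s in o.lr_pairs)
            if [(l, r) for l, r, _ in mine] != [(l, r) for l, r, _ in theirs]:
                return False
            if any(abs(a[2] - b[2]) > tol for a, b in zip(mine, theirs)):
                return False
        return True


@dataclass
class ActivityMatrix:
    """Gene-set activity scores (mean member z-score) per sample or timepoint."""

    table: pd.DataFrame  # set name x sample (or x timepoint)
    provenance: str = ""

    def aggregate_timepoints(self, meta: SampleMetadata) -> "ActivityMatrix":
        tps = meta.timepoints()
        cols = {}
        for t in tps:
            samples = meta.samples_where(timepoint=t)
            cols[t] = self.table[samples].mean(axis=1)
        return ActivityMatrix(pd.DataFrame(cols), provenance=self.provenance + "; timepoint means")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g", index_label="set")


@dataclass
class TimecourseSeries:
    timepoints: list[float]
    networks: dict  # timepoint -> CommunicationNetwork
    activity: ActivityMatrix | None
    baseline: float
    consensus: DagModel
    proportions: pd.DataFrame  # cell x sample


def _mean_cpm(expr: ExpressionMatrix, samples: list[str]) -> pd.Series:
    sidx = expr.sample_index()
    cols = [sidx[s] for s in samples]
    return pd.Series(expr.values[:, cols].mean(axis=1), index=expr.gene_ids)


def _annotate(
    source: str,
    target: str,
    marker_sets: dict,
    lrdb: LRDatabase,
    mu: pd.Series,
    up_genes: frozenset | None,
) -> list:
    src_genes = marker_sets.get(source, frozenset())
    tgt_genes = marker_sets.get(target, frozenset())
    pairs = []
    for rec in lrdb.records:
        if rec.ligand in src_genes and rec.receptor in tgt_genes:
            if up_genes is not None and rec.ligand not in up_genes:
                continue
            if rec.ligand not in mu.index or rec.receptor not in mu.index:
                continue
            score = float(np.sqrt(mu[rec.ligand] * mu[rec.receptor]))
            pairs.append((rec.ligand, rec.receptor, score))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return pairs


def build_communication_network(
    dag: DagModel,
    markers: dict,
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    condition,
    lrdb: LRDatabase,
    require_de_up: DEResult | None = None,
    keep_unannotated: bool = False,
    by: str = "condition",
) -> CommunicationNetwork:
    """Annotate each dag edge A -> B with LR pairs (ligand in markers(A),
    receptor in markers(B)), scored as sqrt of the product of condition-mean CPM.

    When ``require_de_up`` is given, only pairs whose ligand is called "up" are
    kept.  Edges whose direction is flagged as undirected-equivalent in the dag
    are tried in both orientations and emitted in the orientation with the
    stronger LR support (stored orientation on ties).
    """
    if expr.unit != "cpm":
        raise FormatError("build_communication_network expects unit='cpm'")
    meta.validate_against(expr)
    if by == "condition":
        samples = meta.samples_where(condition=condition)
    elif by == "timepoint":
        samples = meta.samples_where(timepoint=condition)
    else:
        raise ValueError(f"unknown grouping field {by!r}")
    if not samples:
        raise FormatError(f"no samples for {by} {condition!r}")
    unknown = [n for n in dag.nodes if n not in markers]
    if unknown:
        raise FormatError(f"dag nodes without marker sets: {unknown}")

    marker_sets = {}
    for cell, genes in markers.items():
        genes = list(genes)
        if genes and isinstance(genes[0], tuple):
            genes = [g for g, *_ in genes]
        marker_sets[cell] = frozenset(genes)

    mu = _mean_cpm(expr, samples)
    up = require_de_up.up if require_de_up is not None else None

    edges = []
    for (u, v) in dag.edges:
        conf = float(dag.confidence.get((u, v), 1.0))
        directed = dag.directed_flags.get((u, v), True)
        pairs_fwd = _annotate(u, v, marker_sets, lrdb, mu, up)
        if directed:
            chosen = [(u, v, pairs_fwd)]
        else:
            pairs_rev = _annotate(v, u, marker_sets, lrdb, mu, up)
            w_fwd = sum(s for *_, s in pairs_fwd)
            w_rev = sum(s for *_, s in pairs_rev)
            chosen = [(u, v, pairs_fwd)] if w_fwd >= w_rev else [(v, u, pairs_rev)]
        for a, b, pairs in chosen:
            if not pairs and not keep_unannotated:
                continue
            edges.append(
                CommEdge(a, b, weight=float(sum(s for *_, s in pairs)),
                         confidence=conf, lr_pairs=pairs)
            )
    edges.sort(key=lambda e: (e.source, e.target))
    return CommunicationNetwork(
        nodes=list(dag.nodes),
        edges=edges,
        condition=str(condition) if by == "condition" else None,
        timepoint=float(condition) if by == "timepoint" else None,
    )


def activity_score(mat: ExpressionMatrix, sets: GeneSetCollection) -> ActivityMatrix:
    """Per-set activity: mean of member-gene z-scores (across samples).

    Zero-variance genes are skipped; sets empty after intersection with the
    matrix (or containing only constant genes) are dropped with a warning.
    """
    if mat.unit != "logcpm":
        raise FormatError("activity_score expects unit='logcpm'")
    sd = mat.values.std(axis=1, ddof=1)
    usable = {g for g, s in zip(mat.gene_ids, sd) if s > 0}
    z = zscore(mat.values.T).T  # per-gene z across samples
    gidx = mat.gene_index()
    rows = {}
    dropped = []
    for name in sets.names():
        members = sorted(sets[name] & usable)
        if not members:
            dropped.append(name)
            continue
        rows[name] = z[[gidx[g] for g in members], :].mean(axis=0)
    if dropped:
        warnings.warn(f"gene sets with no usable (non-constant, present) genes: {dropped}")
    if not rows:
        raise FormatError("all gene sets are empty after intersection with the matrix")
    table = pd.DataFrame(rows, index=mat.sample_ids).T
    return ActivityMatrix(table, provenance=f"{len(rows)} sets; mean member z-score")


def _active_nodes(
    prop: pd.DataFrame, samples_t, samples_base, alpha: float = 0.05
) -> frozenset:
    """Cells whose proportions increase at t vs baseline (one-sided Welch, p < alpha)."""
    active = set()
    for cell in prop.index:
        a = prop.loc[cell, samples_t].to_numpy(dtype=float)
        b = prop.loc[cell, samples_base].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            continue
        _, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        if np.isfinite(p) and p < alpha:
            active.add(cell)
    return frozenset(active)


def timepoint_networks(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    anchors: AnchorSet,
    lrdb: LRDatabase,
    sets: GeneSetCollection | None = None,
    baseline: float = 0.0,
    seed: int = 0,
    deconv_params: dict | None = None,
    bootstrap_params: dict | None = None,
    activity_alpha: float = 0.05,
    de_alpha: float = 0.05,
    de_lfc_min: float = 1.0,
    keep_unannotated: bool = False,
    transform: str = "alr",
) -> TimecourseSeries:
    """Time-course pipeline: one deconvolution, one consensus graph, per-day gating.

    Per timepoint t the consensus graph is restricted to cells active at t
    (proportions up vs baseline) and to edges carrying at least one LR pair
    whose ligand is differentially up-regulated at t; pair scores use t's
    samples only.  The baseline network is empty by construction.

    Proportions are compositional (columns sum to one), which makes the raw
    variables exactly collinear and the BIC regressions nearly deterministic;
    by default the consensus graph is therefore learned on additive-log-ratio
    coordinates, using the least-variable cell type as the reference
    (``transform="alr"``).  The reference cell cannot acquire edges — a known
    cost of log-ratio analysis.  ``transform="zscore"`` learns on the raw
    z-scored proportions instead.
    """
    if expr.unit == "counts":
        cpm = cpm_normalize(expr)
    elif expr.unit == "cpm":
        cpm = expr
    else:
        raise FormatError("timepoint_networks expects counts or cpm input")
    meta.validate_against(cpm)
    if not meta.has_timepoint:
        raise FormatError("metadata has no timepoint column")
    tps = meta.timepoints()
    if len(tps) < 2:
        raise FormatError("need >= 2 timepoints")
    if float(baseline) not in tps:
        raise FormatError(f"baseline timepoint {baseline} not present in metadata")
    for t in tps:
        if len(meta.samples_where(timepoint=t)) < 2:
            raise FormatError(f"timepoint {t} has < 2 replicates")

    res = fit_deconvolution(cpm, anchors, seed=seed, **(deconv_params or {}))
    res = marker_specificity(res)
    markers = {c: [g for g, _ in lst] for c, lst in res.markers.items()}

    prop = res.proportions
    if transform == "alr":
        logP = np.log(np.maximum(prop.to_numpy(), 1e-9))
        ref = int(np.argmin(logP.var(axis=1)))
        keep_idx = [i for i in range(logP.shape[0]) if i != ref]
        data = (logP[keep_idx, :] - logP[ref, :]).T
        learn_nodes = [prop.index[i] for i in keep_idx]
    elif transform == "zscore":
        data = prop.T.to_numpy()
        learn_nodes = list(prop.index)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    consensus = bootstrap_edges(
        data,
        node_names=learn_nodes,
        seed=seed + 1,
        **(bootstrap_params or {}),
    )

    logmat = log_transform(cpm)
    base_samples = meta.samples_where(timepoint=baseline)
    networks = {}
    for t in tps:
        samples_t = meta.samples_where(timepoint=t)
        active = _active_nodes(prop, samples_t, base_samples, alpha=activity_alpha)
        de_t = differential_expression(
            logmat, meta, t, baseline, by="timepoint",
            alpha=de_alpha, lfc_min=de_lfc_min,
        )
        gated = consensus.subgraph(active)
        net = build_communication_network(
            gated, markers, cpm, meta, t, lrdb,
            require_de_up=de_t, keep_unannotated=keep_unannotated, by="timepoint",
        )
        net.nodes = list(prop.index)  # keep the shared node universe
        networks[t] = net

    activity = None
    if sets is not None and len(sets) > 0:
        activity = activity_score(logmat, sets).aggregate_timepoints(meta)

    return TimecourseSeries(
        timepoints=tps,
        networks=networks,
        activity=activity,
        baseline=float(baseline),
        consensus=consensus,
        proportions=prop,
    )


@dataclass
class NetworkDiff:
    gained: list  # edges in b, not a
    lost: list  # edges in a, not b
    retained: list  # (edge, weight_a, weight_b, rel_change, flagged)
    threshold: float

    def to_dict(self) -> dict:
        return {
            "gained": [list(e) for e in self.gained],
            "lost": [list(e) for e in self.lost],
            "retained": [
                {
                    "source": e[0],
                    "target": e[1],
                    "weight_a": wa,
                    "weight_b": wb,
                    "rel_change": rc,
                    "flagged": fl,
                }
                for (e, wa, wb, rc, fl) in self.retained
            ],
            "threshold": self.threshold,
        }


def compare_networks(
    a: CommunicationNetwork, b: CommunicationNetwork, rel_threshold: float = 0.1
) -> NetworkDiff:
    """Edge-level diff of two condition networks over a shared node universe.

    "gained" edges are in b but not a, "lost" in a but not b; retained edges
    are flagged when the relative weight change exceeds ``rel_threshold``.
    Swapping the arguments exchanges gained and lost.
    """
    if not (set(a.nodes) & set(b.nodes)):
        raise FormatError("networks share no nodes")
    ea, eb = a.edge_set(), b.edge_set()
    gained = sorted(eb - ea)
    lost = sorted(ea - eb)
    retained = []
    for e in sorted(ea & eb):
        wa = a.get_edge(*e).weight
        wb = b.get_edge(*e).weight
        denom = max(abs(wa), 1e-30)
        rc = abs(wb - wa) / denom
        retained.append((e, wa, wb, rc, rc > rel_threshold))
    return NetworkDiff(gained=gained, lost=lost, retained=retained, threshold=rel_threshold)
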