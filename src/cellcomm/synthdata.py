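"""Seeded synthetic bulk RNA-seq with planted ground truth.

The generator emulates the mixture structure the pipeline is designed to
invert: a log-normal gene x cell-type signature matrix with disjoint planted
marker blocks, per-sample cell-type proportions driven by a linear-Gaussian
structural equation model over a known dependency DAG (mapped onto the simplex
by softmax), Poisson count sampling at a fixed library size, and planted
ligand-receptor channels whose ligands surge during defined activity windows
of a time course.  Signature columns are normalised to a common total so that
CPM mixtures are exactly linear in the proportions (the usual equal
mRNA-content assumption); every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import DagModel
from .deconv import AnchorSet
from .io import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    LRDatabase,
    LRPair,
    SampleMetadata,
)

_SIGNATURE_COLSUM = 1e6  # common per-cell signature mass (equal mRNA content)


@dataclass
class SyntheticTruth:
    """Planted ground truth backing every recovery test."""

    S_true: pd.DataFrame  # gene x cell
    P_true: pd.DataFrame  # cell x sample (simplex columns)
    latent: pd.DataFrame  # cell x sample latent SEM abundances (pre-softmax)
    dag_true: DagModel
    markers: dict  # cell -> list of genes
    lr_channels: list = field(default_factory=list)  # (src cell, tgt cell, ligand, receptor)
    seed: int = 0
    noise: str = "poisson"
    active_windows: dict = field(default_factory=dict)  # cell -> (t0, t1)

    def __post_init__(self):
        P = self.P_true.to_numpy()
        if not np.allclose(P.sum(axis=0), 1.0, atol=1e-8) or (P < 0).any():
            raise FormatError("P_true columns must lie on the simplex")
        S = self.S_true.to_numpy()
        gidx = {g: i for i, g in enumerate(self.S_true.index)}
        cidx = {c: j for j, c in enumerate(self.S_true.columns)}
        for cell, genes in self.markers.items():
            for g in genes:
                row = S[gidx[g], :]
                spec = row[cidx[cell]] / row.sum()
                if spec < 0.9:
                    raise FormatError(
                        f"planted marker {g!r} of {cell!r} has specificity {spec:.3f} < 0.9"
                    )
        marker_lookup = {c: set(gs) for c, gs in self.markers.items()}
        for src, tgt, lig, rec in self.lr_channels:
            if lig not in marker_lookup.get(src, ()) or rec not in marker_lookup.get(tgt, ()):
                raise FormatError(
                    f"LR channel ({src}->{tgt}, {lig}/{rec}) must use planted markers"
                )


def default_dag(cells: list[str]) -> DagModel:
    """Canonical planted dependency graph: a chain with one branching hub.

    For K cells c1..cK the edges are c1->c2, c2->c3, c2->c4, c4->c5, ... —
    a mix of chain and fork structure that exercises collider detection.
    """
    edges = []
    if len(cells) >= 2:
        edges.append((cells[0], cells[1]))
    if len(cells) >= 3:
        edges.append((cells[1], cells[2]))
    if len(cells) >= 4:
        edges.append((cells[1], cells[3]))
    for i in range(4, len(cells)):
        edges.append((cells[i - 1], cells[i]))
    return DagModel(nodes=list(cells), edges=edges)


def make_signatures(
    G: int = 1000, K: int = 4, markers_per_type: int = 25, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Log-normal background with disjoint planted marker blocks.

    Marker rows have their off-type entries tied to a small fraction of the
    own-type value so planted specificity is >= 0.9 by construction even after
    the columns are rescaled to a common total mass.
    """
    if G < K * markers_per_type:
        raise FormatError(
            f"G={G} cannot host {K} disjoint blocks of {markers_per_type} markers"
        )
    rng = np.random.default_rng(seed)
    cells = [f"cell_{i + 1}" for i in range(K)]
    genes = [f"g{i + 1:05d}" for i in range(G)]
    S = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=(G, K))
    markers: dict[str, list] = {}
    for k, cell in enumerate(cells):
        block = range(k * markers_per_type, (k + 1) * markers_per_type)
        markers[cell] = [genes[i] for i in block]
        for i in block:
            own = rng.lognormal(mean=np.log(400.0), sigma=0.5)
            off = own * rng.uniform(0.0, 0.02, size=K)  # tiny leakage off-type
            S[i, :] = off
            S[i, k] = own
    S = S / S.sum(axis=0, keepdims=True) * _SIGNATURE_COLSUM
    df = pd.DataFrame(S, index=genes, columns=cells)
    # construction guarantee: specificity of planted markers survives rescaling
    for cell, genes_k in markers.items():
        spec = df.loc[genes_k, cell] / df.loc[genes_k].sum(axis=1)
        assert (spec >= 0.9).all()
    return df, markers


def make_proportions(
    n: int = 60,
    dag: DagModel | None = None,
    edge_coefs=None,
    noise_sd: float = 0.1,
    seed: int = 0,
    cells: list[str] | None = None,
    root_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simplex proportions from a linear-Gaussian SEM over the dependency DAG.

    Root cells draw N(0, root_sd); each child is the coefficient-weighted sum
    of its parents plus N(0, noise_sd).  Softmax per sample maps latent
    abundances onto the simplex.  ``root_sd`` controls how much cell
    composition varies between samples (replicate CV); the default of 1 gives
    a wide compositional spread.  Returns (P, latent), both cell x sample.
    """
    if dag is None:
        if cells is None:
            raise FormatError("need a dag or an explicit cell list")
        dag = DagModel(nodes=list(cells), edges=[])
    cells = list(dag.nodes)
    edges = list(dag.edges)
    if edge_coefs is None:
        edge_coefs = {e: 1.0 for e in edges}
    elif not isinstance(edge_coefs, dict):
        coefs = list(edge_coefs)
        if len(coefs) != len(edges):
            raise FormatError(
                f"{len(coefs)} coefficients for {len(edges)} edges"
            )
        edge_coefs = dict(zip(edges, coefs))
    elif set(edge_coefs) != set(edges):
        raise FormatError("edge_coefs keys must match the dag edges")

    rng = np.random.default_rng(seed)
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(cells)
    g.add_edges_from(edges)
    order = list(nx.topological_sort(g))
    Z = pd.DataFrame(0.0, index=cells, columns=[f"s{i + 1:03d}" for i in range(n)])
    for cell in order:
        parents = list(g.predecessors(cell))
        if not parents:
            Z.loc[cell] = rng.normal(0.0, root_sd, size=n)
        else:
            mean = sum(edge_coefs[(p, cell)] * Z.loc[p] for p in parents)
            Z.loc[cell] = mean + rng.normal(0.0, noise_sd, size=n)
    expz = np.exp(Z.to_numpy())
    P = pd.DataFrame(expz / expz.sum(axis=0, keepdims=True),
                     index=cells, columns=Z.columns)
    return P, Z


def mix_and_sample(
    S_true: pd.DataFrame,
    P_true: pd.DataFrame,
    library_size: int = 1_000_000,
    noise: str = "poisson",
    seed: int = 0,
) -> ExpressionMatrix:
    """Bulk counts from the mixture S.P: Poisson at ``library_size`` or exact rounding."""
    if list(S_true.columns) != list(P_true.index):
        raise FormatError("S_true columns must match P_true rows")
    X = S_true.to_numpy() @ P_true.to_numpy()
    colsums = X.sum(axis=0)
    if np.any(colsums <= 0):
        raise FormatError("zero expected expression for some sample")
    lam = X / colsums * library_size
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(float)
    elif noise == "none":
        counts = np.rint(lam)
    else:
        raise FormatError(f"unknown noise model {noise!r}")
    return ExpressionMatrix(
        list(S_true.index), list(P_true.columns), counts, unit="counts"
    )


@dataclass
class SyntheticBundle:
    """A ready-to-analyse fixture: counts + metadata + truth + prior inputs."""

    expr: ExpressionMatrix
    meta: SampleMetadata
    truth: SyntheticTruth
    anchors: AnchorSet
    lrdb: LRDatabase
    gene_sets: GeneSetCollection


def _anchors_from_markers(markers: dict, anchors_per_type: int = 5) -> AnchorSet:
    return AnchorSet(
        {cell: frozenset(genes[:anchors_per_type]) for cell, genes in markers.items()}
    )


def _lrdb_with_decoys(
    lr_channels, markers: dict, all_genes: list[str], rng
) -> LRDatabase:
    """Planted channels plus decoy pairs drawn from non-marker genes."""
    records = [LRPair(lig, rec, ("planted",)) for _, _, lig, rec in lr_channels]
    marker_genes = {g for gs in markers.values() for g in gs}
    background = [g for g in all_genes if g not in marker_genes]
    for _ in range(10):
        lig, rec = rng.choice(background, size=2, replace=False)
        records.append(LRPair(str(lig), str(rec), ("decoy",)))
    return LRDatabase(records)


def make_dataset(
    G: int = 1000,
    K: int = 4,
    n: int = 60,
    markers_per_type: int = 25,
    noise: str = "poisson",
    library_size: int = 1_000_000,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticBundle:
    """Default steady-state fixture: K anchored cell types, planted DAG and LR channels."""
    rng = np.random.default_rng(seed)
    s_seed, p_seed, m_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    S, markers = make_signatures(G=G, K=K, markers_per_type=markers_per_type, seed=s_seed)
    cells = list(S.columns)
    dag = default_dag(cells)
    P, Z = make_proportions(n=n, dag=dag, noise_sd=noise_sd, seed=p_seed)
    expr = mix_and_sample(S, P, library_size=library_size, noise=noise, seed=m_seed)
    meta = SampleMetadata(
        pd.DataFrame({"condition": "baseline"}, index=expr.sample_ids)
    )
    lr_channels = []
    if K >= 2:
        src, tgt = cells[0], cells[1]
        lr_channels.append((src, tgt, markers[src][-1], markers[tgt][-1]))
    truth = SyntheticTruth(
        S_true=S, P_true=P, latent=Z, dag_true=dag, markers=markers,
        lr_channels=lr_channels, seed=seed, noise=noise,
    )
    return SyntheticBundle(
        expr=expr,
        meta=meta,
        truth=truth,
        anchors=_anchors_from_markers(markers),
        lrdb=_lrdb_with_decoys(lr_channels, markers, list(S.index), rng),
        gene_sets=GeneSetCollection({c: frozenset(markers[c]) for c in cells}),
    )


def make_timecourse(
    timepoints=(0.0, 0.25, 1.0, 2.0, 3.0),
    replicates: int = 5,
    G: int = 400,
    K: int = 5,
    markers_per_type: int = 20,
    active_windows: dict | None = None,
    multiplier: float = 2.0,
    ligand_boost: float = 4.0,
    noise: str = "poisson",
    library_size: int = 1_000_000,
    noise_sd: float = 0.12,
    seed: int = 0,
) -> SyntheticBundle:
    """Time course with cell-activity windows and a surge of planted ligands.

    Cells inside their active window have proportions multiplied by
    ``multiplier`` (then renormalised); planted ligand genes are additionally
    up-shifted in bulk by ``ligand_boost`` while their source cell is active,
    mimicking an inflammatory cytokine surge.
    """
    timepoints = sorted(float(t) for t in timepoints)
    if len(timepoints) < 2:
        raise FormatError("need >= 2 timepoints")
    if replicates < 2:
        raise FormatError("need >= 2 replicates per timepoint")
    rng = np.random.default_rng(seed)
    s_seed, p_seed, m_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    S, markers = make_signatures(G=G, K=K, markers_per_type=markers_per_type, seed=s_seed)
    cells = list(S.columns)
    if active_windows is None:
        # the two communicating cells share an early window (their planted
        # interaction); a late repair-phase window for another cell keeps the
        # compositional variation from collapsing onto a single direction,
        # as in real inflammation time courses
        early_end = min(1.0, timepoints[-1])
        late = [t for t in timepoints if t > early_end]
        if K >= 3:
            active_windows = {
                cells[1]: (timepoints[1], early_end),
                cells[2]: (timepoints[1], early_end),
            }
            if K >= 4 and late:
                active_windows[cells[3]] = (late[0], timepoints[-1])
        else:
            active_windows = {}
    for cell, (t0, t1) in active_windows.items():
        if cell not in cells:
            raise FormatError(f"active window for unknown cell {cell!r}")
        if t0 > t1 or t1 < timepoints[0] or t0 > timepoints[-1]:
            raise FormatError(f"window ({t0}, {t1}) outside the timepoint range")

    dag = default_dag(cells)
    n = len(timepoints) * replicates
    # replicate proportions vary far less than a unit-variance latent implies;
    # root_sd ~ 0.1 gives realistic replicate CVs (~15%) while keeping the
    # planted dependencies visible to structure learning
    P, Z = make_proportions(n=n, dag=dag, noise_sd=noise_sd, seed=p_seed, root_sd=0.12)
    sample_tp = np.repeat(timepoints, replicates)
    sample_ids = [
        f"t{t:g}_r{r + 1}" for t in timepoints for r in range(replicates)
    ]
    P.columns = sample_ids
    Z.columns = sample_ids

    Pv = P.to_numpy()
    for cell, (t0, t1) in active_windows.items():
        k = cells.index(cell)
        in_window = (sample_tp >= t0) & (sample_tp <= t1)
        Pv[k, in_window] *= multiplier
    Pv = Pv / Pv.sum(axis=0, keepdims=True)
    P = pd.DataFrame(Pv, index=cells, columns=sample_ids)

    # planted LR channel between the two co-activated cells; ligand and
    # receptor are leading (anchor-grade) markers, mirroring canonical
    # cytokine/receptor genes that double as cell-type anchors
    lr_channels = []
    windowed = [c for c in cells if c in active_windows]
    if len(windowed) >= 2:
        src, tgt = windowed[0], windowed[1]
        lr_channels.append((src, tgt, markers[src][0], markers[tgt][0]))

    X = S.to_numpy() @ Pv
    gidx = {g: i for i, g in enumerate(S.index)}
    for src, tgt, lig, rec in lr_channels:
        t0, t1 = active_windows[src]
        in_window = (sample_tp >= t0) & (sample_tp <= t1)
        X[gidx[lig], in_window] *= ligand_boost
    colsums = X.sum(axis=0)
    lam = X / colsums * library_size
    if noise == "poisson":
        counts = np.random.default_rng(m_seed).poisson(lam).astype(float)
    elif noise == "none":
        counts = np.rint(lam)
    else:
        raise FormatError(f"unknown noise model {noise!r}")
    expr = ExpressionMatrix(list(S.index), sample_ids, counts, unit="counts")

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "condition": "challenge",
                "timepoint": sample_tp,
                "replicate": [f"r{r + 1}" for _ in timepoints for r in range(replicates)],
            },
            index=sample_ids,
        )
    )
    truth = SyntheticTruth(
        S_true=S, P_true=P, latent=Z, dag_true=dag, markers=markers,
        lr_channels=lr_channels, seed=seed, noise=noise,
        active_windows=dict(active_windows),
    )
    sets = GeneSetCollection(
        {"planted_ligands": frozenset(lig for *_, lig, _ in lr_channels)
         if lr_channels else frozenset(markers[cells[0]][:3]),
         **{f"markers_{c}": frozenset(markers[c]) for c in cells}}
    )
    return SyntheticBundle(
        expr=expr,
        meta=meta,
        truth=truth,
        anchors=_anchors_from_markers(markers),
        lrdb=_lrdb_with_decoys(lr_channels, markers, list(S.index), rng),
        gene_sets=sets,
    )
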