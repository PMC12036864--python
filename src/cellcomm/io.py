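"""Readers, writers and the validated in-memory data model.

Every on-disk artifact is plain text: TSV matrices, MatrixMarket triplets with
row/column name sidecars, GMT gene-set files, TSV ligand-receptor tables, and
communication networks as GraphML or a JSON edge-list dialect.  All identifiers
are treated as opaque, case-sensitive strings — no symbol normalisation is ever
applied; cross-species bridging goes through an explicit :class:`OrthologyMap`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "cpm", "logcpm")


class FormatError(ValueError):
    """A file or in-memory structure violates its format contract."""


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen = set()
    for i in ids:
        if i == "" or i != i.strip() and i.strip() == "":
            raise FormatError(f"empty {what} identifier")
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression grid with a declared unit.

    The unit drives validation: ``counts`` must be non-negative integers,
    ``cpm`` non-negative reals, ``logcpm`` any finite reals.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str

    def __post_init__(self):
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D grid")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if self.unit in ("counts", "cpm") and np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value {self.values[g, s]} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} (unit={self.unit})"
            )
        if self.unit == "counts" and not np.allclose(self.values, np.rint(self.values)):
            g, s = np.argwhere(~np.isclose(self.values, np.rint(self.values)))[0]
            raise FormatError(
                f"non-integral count {self.values[g, s]} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :].copy(), self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols].copy(), self.unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), unit)


@dataclass
class SampleMetadata:
    """Per-sample annotations: condition label, optional timepoint (days) and replicate."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self):
        t = self.table
        _check_ids(t.index, "sample")
        if "condition" not in t.columns:
            raise FormatError("metadata requires a 'condition' column")
        cond = t["condition"].astype(str)
        if (cond.str.strip() == "").any():
            bad = t.index[cond.str.strip() == ""][0]
            raise FormatError(f"empty condition for sample {bad!r}")
        if "timepoint" in t.columns:
            tp = pd.to_numeric(t["timepoint"], errors="coerce")
            if tp.isna().any():
                bad = t.index[tp.isna()][0]
                raise FormatError(f"non-numeric timepoint for sample {bad!r}")
            if (tp < 0).any():
                bad = t.index[tp < 0][0]
                raise FormatError(f"negative timepoint for sample {bad!r}")
            self.table = t.assign(timepoint=tp.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    @property
    def has_timepoint(self) -> bool:
        return "timepoint" in self.table.columns

    def validate_against(self, mat: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(mat.sample_ids):
            missing = set(mat.sample_ids) - set(self.sample_ids)
            extra = set(self.sample_ids) - set(mat.sample_ids)
            raise FormatError(
                f"metadata/matrix sample mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
            )

    def samples_where(self, condition=None, timepoint=None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"].astype(str) == str(condition)
        if timepoint is not None:
            if not self.has_timepoint:
                raise FormatError("metadata has no timepoint column")
            mask &= np.isclose(self.table["timepoint"].to_numpy(dtype=float),
                               float(timepoint))
        return list(self.table.index[mask].astype(str))

    def timepoints(self) -> list[float]:
        if not self.has_timepoint:
            return []
        return sorted(set(self.table["timepoint"].astype(float)))


@dataclass
class GeneSetCollection:
    """Named gene sets (insertion-ordered), e.g. anchors, markers or pathway panels."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            name = str(name)
            if name == "":
                raise FormatError("empty gene-set name")
            if name in clean:
                raise FormatError(f"duplicate gene-set name: {name!r}")
            genes = frozenset(str(g) for g in genes)
            if not genes or "" in genes:
                raise FormatError(f"gene set {name!r} is empty or contains an empty id")
            clean[name] = genes
        self.sets = clean

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def intersect(self, universe) -> "GeneSetCollection":
        """Restrict every set to ``universe``; drops sets that become empty (with a warning)."""
        universe = set(universe)
        kept, dropped = {}, []
        for name, genes in self.sets.items():
            inter = genes & universe
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"gene sets empty after universe intersection: {dropped}")
        return GeneSetCollection(kept, {k: v for k, v in self.descriptions.items() if k in kept})


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    pathways: tuple = ()


@dataclass
class LRDatabase:
    """Curated ligand-receptor channels; duplicate (ligand, receptor) pairs are collapsed."""

    records: list[LRPair]

    def __post_init__(self):
        merged: dict[tuple, list] = {}
        order = []
        for r in self.records:
            if not r.ligand or not r.receptor:
                raise FormatError("ligand and receptor gene ids must be non-empty")
            key = (r.ligand, r.receptor)
            if key not in merged:
                merged[key] = list(r.pathways)
                order.append(key)
            else:
                for p in r.pathways:
                    if p not in merged[key]:
                        merged[key].append(p)
        self.records = [LRPair(l, r, tuple(merged[(l, r)])) for (l, r) in order]

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> list[tuple]:
        return [(r.ligand, r.receptor) for r in self.records]


@dataclass
class OrthologyMap:
    """Explicit species-A symbol -> species-B symbol pairs; may be many-to-many."""

    pairs: list[tuple]

    def __post_init__(self):
        seen = set()
        out = []
        for a, b in self.pairs:
            a, b = str(a), str(b)
            if not a or not b:
                raise FormatError("orthology symbols must be non-empty")
            if (a, b) not in seen:
                seen.add((a, b))
                out.append((a, b))
        self.pairs = out

    def invert(self) -> "OrthologyMap":
        return OrthologyMap([(b, a) for a, b in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_counts(path, dialect: str = "tsv", genes_path=None, samples_path=None) -> ExpressionMatrix:
    """Read a raw count matrix.

    ``tsv``: header row of sample ids, first column gene ids, tab-separated.
    ``mtx_triplet``: MatrixMarket coordinate file plus two sidecar name files
    (one id per line); sidecars default to ``<path>.genes.txt`` / ``<path>.samples.txt``.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
        gene_ids = _check_ids(df.index, "gene")
        sample_ids = _check_ids(df.columns, "sample")
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(num.isna().to_numpy())
        if bad.size:
            g, s = bad[0]
            raise FormatError(
                f"non-numeric entry {df.iat[g, s]!r} at gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r} in {path}"
            )
        values = num.to_numpy(dtype=float)
    elif dialect == "mtx_triplet":
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        gpath = Path(genes_path) if genes_path else path.with_suffix(path.suffix + ".genes.txt")
        spath = Path(samples_path) if samples_path else path.with_suffix(path.suffix + ".samples.txt")
        gene_ids = [l.strip() for l in gpath.read_text().splitlines() if l.strip() != ""]
        sample_ids = [l.strip() for l in spath.read_text().splitlines() if l.strip() != ""]
        if len(gene_ids) != mat.shape[0]:
            raise FormatError(
                f"gene sidecar {gpath} lists {len(gene_ids)} names but matrix has {mat.shape[0]} rows"
            )
        if len(sample_ids) != mat.shape[1]:
            raise FormatError(
                f"sample sidecar {spath} lists {len(sample_ids)} names but matrix has {mat.shape[1]} columns"
            )
        values = mat
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return ExpressionMatrix(gene_ids, sample_ids, values, unit="counts")


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


def read_expression(path, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    return ExpressionMatrix.from_frame(df, unit)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene...`` per line."""
    sets: dict[str, frozenset] = {}
    descriptions = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, expected >= 3")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
        genes = frozenset(g for g in fields[2:] if g != "")
        if not genes:
            raise FormatError(f"{path}: set {name!r} at line {lineno} has no genes")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            desc = coll.descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + sorted(coll[name])) + "\n")


def read_lr_table(path) -> LRDatabase:
    """Read a ligand-receptor TSV with mandatory columns ligand, receptor and optional pathway."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        warnings.warn(f"{path}: ligand-receptor table is empty")
    records = []
    for _, row in df.iterrows():
        pathways = ()
        if "pathway" in df.columns and isinstance(row["pathway"], str) and row["pathway"]:
            pathways = (row["pathway"],)
        records.append(LRPair(str(row["ligand"]), str(row["receptor"]), pathways))
    return LRDatabase(records)


def write_lr_table(db: LRDatabase, path) -> None:
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\tpathway\n")
        for r in db.records:
            fh.write(f"{r.ligand}\t{r.receptor}\t{';'.join(r.pathways)}\n")


def read_orthology(path) -> OrthologyMap:
    """Two-column TSV (header required); first column species A, second species B."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: orthology map needs two columns")
    a, b = df.columns[:2]
    return OrthologyMap(list(zip(df[a].astype(str), df[b].astype(str))))


# ---------------------------------------------------------------------------
# network serialisation (CommunicationNetwork lives in commnet; imported lazily
# to keep the io layer free of analysis-module dependencies)
# ---------------------------------------------------------------------------

def _net_to_dict(net) -> dict:
    return {
        "condition": net.condition,
        "timepoint": net.timepoint,
        "nodes": list(net.nodes),
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "weight": e.weight,
                "confidence": e.confidence,
                "lr_pairs": [
                    {"ligand": l, "receptor": r, "score": s} for (l, r, s) in e.lr_pairs
                ],
            }
            for e in net.edges
        ],
    }


def _net_from_dict(d) -> "object":
    from .commnet import CommEdge, CommunicationNetwork

    edges = [
        CommEdge(
            source=e["source"],
            target=e["target"],
            weight=float(e["weight"]),
            confidence=float(e.get("confidence", 1.0)),
            lr_pairs=[(p["ligand"], p["receptor"], float(p["score"])) for p in e["lr_pairs"]],
        )
        for e in d["edges"]
    ]
    return CommunicationNetwork(
        nodes=list(d["nodes"]),
        edges=edges,
        condition=d.get("condition"),
        timepoint=d.get("timepoint"),
    )


def write_network(net, path, fmt: str = "edge_json") -> None:
    """Serialise a CommunicationNetwork; round-trip safe for both formats."""
    path = Path(path)
    if fmt == "edge_json":
        with open(path, "w") as fh:
            json.dump(_net_to_dict(net), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        if net.condition is not None:
            g.graph["condition"] = net.condition
        if net.timepoint is not None:
            g.graph["timepoint"] = float(net.timepoint)
        for node in net.nodes:
            g.add_node(node)
        for e in net.edges:
            g.add_edge(
                e.source,
                e.target,
                weight=float(e.weight),
                confidence=float(e.confidence),
                lr_pairs=json.dumps(
                    [{"ligand": l, "receptor": r, "score": s} for (l, r, s) in e.lr_pairs]
                ),
            )
        nx.write_graphml(g, str(path))
    else:
        raise FormatError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "edge_json"):
    path = Path(path)
    if fmt == "edge_json":
        with open(path) as fh:
            return _net_from_dict(json.load(fh))
    elif fmt == "graphml":
        import networkx as nx

        from .commnet import CommEdge, CommunicationNetwork

        g = nx.read_graphml(str(path))
        edges = []
        for u, v, data in g.edges(data=True):
            pairs = [
                (p["ligand"], p["receptor"], float(p["score"]))
                for p in json.loads(data.get("lr_pairs", "[]"))
            ]
            edges.append(
                CommEdge(u, v, float(data["weight"]), float(data.get("confidence", 1.0)), pairs)
            )
        tp = g.graph.get("timepoint")
        return CommunicationNetwork(
            nodes=list(g.nodes),
            edges=edges,
            condition=g.graph.get("condition"),
            timepoint=float(tp) if tp is not None else None,
        )
    raise FormatError(f"unknown network format {fmt!r}")
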