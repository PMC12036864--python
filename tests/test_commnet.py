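"""Communication networks: LR scoring, activity, time-course gating, diffs."""

import numpy as np
import pandas as pd
import pytest

from cellcomm.bayesnet import DagModel
from cellcomm.commnet import (
    CommEdge,
    CommunicationNetwork,
    activity_score,
    build_communication_network,
    compare_networks,
    timepoint_networks,
)
from cellcomm.io import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    LRDatabase,
    LRPair,
    SampleMetadata,
)
from cellcomm.synthdata import make_timecourse


def _cpm(values, genes, samples):
    return ExpressionMatrix(genes, samples, np.asarray(values, float), "cpm")


def _meta(samples, condition="c"):
    return SampleMetadata(pd.DataFrame({"condition": condition}, index=samples))


class TestBuildCommunicationNetwork:
    def test_single_pair_arithmetic(self):
        expr = _cpm([[4.0], [9.0]], ["L1", "R1"], ["s1"])
        dag = DagModel(nodes=["A", "B"], edges=[("A", "B")])
        net = build_communication_network(
            dag, {"A": ["L1"], "B": ["R1"]}, expr, _meta(["s1"]), "c",
            LRDatabase([LRPair("L1", "R1")]),
        )
        assert len(net.edges) == 1
        e = net.edges[0]
        assert e.lr_pairs == [("L1", "R1", pytest.approx(6.0))]
        assert e.weight == pytest.approx(6.0)

    def test_no_match_drops_edge(self):
        expr = _cpm([[4.0], [9.0]], ["L1", "R1"], ["s1"])
        dag = DagModel(nodes=["A", "B"], edges=[("A", "B")])
        net = build_communication_network(
            dag, {"A": ["L1"], "B": ["R1"]}, expr, _meta(["s1"]), "c",
            LRDatabase([LRPair("X", "Y")]),
        )
        assert net.edges == []

    def test_keep_unannotated_flag(self):
        expr = _cpm([[4.0], [9.0]], ["L1", "R1"], ["s1"])
        dag = DagModel(nodes=["A", "B"], edges=[("A", "B")])
        net = build_communication_network(
            dag, {"A": ["L1"], "B": ["R1"]}, expr, _meta(["s1"]), "c",
            LRDatabase([LRPair("X", "Y")]), keep_unannotated=True,
        )
        assert len(net.edges) == 1 and net.edges[0].weight == 0.0

    def test_weights_match_brute_force_enumeration(self, rng):
        """Edge weight equals a triple-loop oracle over (edge, ligand, receptor)."""
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(6)]
        expr = _cpm(rng.uniform(1, 100, size=(20, 6)), genes, samples)
        cells = ["A", "B", "C"]
        markers = {c: list(rng.choice(genes, size=6, replace=False)) for c in cells}
        lrdb = LRDatabase(
            [LRPair(*rng.choice(genes, size=2, replace=False)) for _ in range(10)]
        )
        dag = DagModel(nodes=cells, edges=[("A", "B"), ("B", "C"), ("A", "C")])
        net = build_communication_network(
            dag, markers, expr, _meta(samples), "c", lrdb
        )
        mu = expr.to_frame().mean(axis=1)
        for u, v in dag.edges:
            expected = 0.0
            for rec in lrdb.records:
                for lg in markers[u]:
                    for rg in markers[v]:
                        if rec.ligand == lg and rec.receptor == rg:
                            expected += np.sqrt(mu[lg] * mu[rg])
            e = net.get_edge(u, v)
            got = e.weight if e else 0.0
            assert got == pytest.approx(expected, abs=1e-12)

    def test_require_de_up_filters_ligands(self):
        from cellcomm.diffexpr import DEResult

        expr = _cpm([[4.0], [9.0], [16.0]], ["L1", "L2", "R1"], ["s1"])
        dag = DagModel(nodes=["A", "B"], edges=[("A", "B")])
        de = DEResult(
            pd.DataFrame(
                {"log2fc": [2.0, 0.0, 0.0], "p": [0.001, 1, 1], "q": [0.001, 1, 1],
                 "direction": ["up", "ns", "ns"]},
                index=["L1", "L2", "R1"],
            ),
            "a", "b", 2, 2, "welch_t", 0.05, 1.0,
        )
        net = build_communication_network(
            dag, {"A": ["L1", "L2"], "B": ["R1"]}, expr, _meta(["s1"]), "c",
            LRDatabase([LRPair("L1", "R1"), LRPair("L2", "R1")]),
            require_de_up=de,
        )
        assert [p[:2] for p in net.edges[0].lr_pairs] == [("L1", "R1")]

    def test_undirected_equivalent_edge_oriented_by_lr_support(self):
        expr = _cpm([[4.0], [9.0]], ["L1", "R1"], ["s1"])
        dag = DagModel(
            nodes=["A", "B"], edges=[("B", "A")],
            confidence={("B", "A"): 0.9}, directed_flags={("B", "A"): False},
        )
        # the LR channel runs A -> B; the flipped orientation carries the pairs
        net = build_communication_network(
            dag, {"A": ["L1"], "B": ["R1"]}, expr, _meta(["s1"]), "c",
            LRDatabase([LRPair("L1", "R1")]),
        )
        assert net.edge_set() == frozenset({("A", "B")})

    def test_empty_condition_rejected(self):
        expr = _cpm([[1.0]], ["g"], ["s1"])
        dag = DagModel(nodes=["A", "B"], edges=[])
        with pytest.raises(FormatError):
            build_communication_network(
                dag, {"A": [], "B": []}, expr, _meta(["s1"]), "other",
                LRDatabase([]),
            )


class TestActivityScore:
    def _logmat(self, values, genes):
        samples = [f"s{j}" for j in range(np.asarray(values).shape[1])]
        return ExpressionMatrix(genes, samples, np.asarray(values, float), "logcpm")

    def test_singleton_set_equals_zscores(self, rng):
        vals = rng.normal(size=(1, 8))
        mat = self._logmat(vals, ["g1"])
        act = activity_score(mat, GeneSetCollection({"s": frozenset(["g1"])}))
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(act.table.loc["s"].to_numpy(), z, atol=1e-12)

    def test_two_gene_set_is_mean_of_zvectors(self, rng):
        vals = rng.normal(size=(2, 6))
        mat = self._logmat(vals, ["g1", "g2"])
        act = activity_score(mat, GeneSetCollection({"s": frozenset(["g1", "g2"])}))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(act.table.loc["s"].to_numpy(), z.mean(axis=0), atol=1e-12)

    def test_constant_gene_skipped_and_set_dropped(self, rng):
        vals = np.vstack([np.full(5, 3.0), rng.normal(size=5)])
        mat = self._logmat(vals, ["flat", "var"])
        with pytest.warns(UserWarning):
            act = activity_score(
                mat, GeneSetCollection({"dead": frozenset(["flat"]),
                                        "ok": frozenset(["var", "flat"])})
            )
        assert list(act.table.index) == ["ok"]

    def test_scores_centred(self, rng):
        vals = rng.normal(size=(4, 7))
        mat = self._logmat(vals, [f"g{i}" for i in range(4)])
        act = activity_score(mat, GeneSetCollection({"s": frozenset(mat.gene_ids)}))
        assert abs(act.table.loc["s"].mean()) < 1e-10

    def test_sample_permutation_invariance(self, rng):
        vals = rng.normal(size=(3, 6))
        genes = ["a", "b", "c"]
        mat = self._logmat(vals, genes)
        sets = GeneSetCollection({"s": frozenset(genes)})
        base = activity_score(mat, sets).table
        perm = rng.permutation(6)
        mat_p = ExpressionMatrix(genes, [mat.sample_ids[i] for i in perm],
                                 vals[:, perm], "logcpm")
        permuted = activity_score(mat_p, sets).table[mat.sample_ids]
        np.testing.assert_allclose(base.to_numpy(), permuted.to_numpy(), atol=1e-12)


class TestTimepointNetworks:
    def test_baseline_network_empty_and_planted_window_recovered(self):
        bundle = make_timecourse(seed=11)
        series = timepoint_networks(
            bundle.expr, bundle.meta, bundle.anchors, bundle.lrdb,
            sets=bundle.gene_sets, baseline=0.0, seed=11,
            deconv_params={"restarts": 2, "max_iter": 100},
            bootstrap_params={"B": 30},
        )
        assert series.networks[0.0].edges == []
        src, tgt, lig, rec = bundle.truth.lr_channels[0]
        present = {
            t: any({e.source, e.target} == {src, tgt} for e in series.networks[t].edges)
            for t in series.timepoints
        }
        assert present[0.25] and present[1.0]
        assert not present[0.0] and not present[3.0]
        # activity matrix aggregated to timepoints, ligand set peaks in-window
        act = series.activity.table
        assert list(act.columns) == series.timepoints
        lig_scores = act.loc["planted_ligands"]
        assert lig_scores[[0.25, 1.0]].mean() > lig_scores[[0.0, 3.0]].mean()

    def test_determinism(self):
        bundle = make_timecourse(seed=5, G=200, K=4, replicates=3,
                                 timepoints=(0.0, 1.0, 2.0))
        kwargs = dict(
            sets=None, baseline=0.0, seed=5,
            deconv_params={"restarts": 1, "max_iter": 50},
            bootstrap_params={"B": 10},
        )
        a = timepoint_networks(bundle.expr, bundle.meta, bundle.anchors,
                               bundle.lrdb, **kwargs)
        b = timepoint_networks(bundle.expr, bundle.meta, bundle.anchors,
                               bundle.lrdb, **kwargs)
        for t in a.timepoints:
            assert a.networks[t].equal_to(b.networks[t], tol=0.0)

    def test_too_few_replicates_rejected(self):
        bundle = make_timecourse(seed=1, replicates=2, G=200, K=4)
        meta_t = bundle.meta.table.drop(index=["t0_r2"])
        expr = bundle.expr.subset_samples(list(meta_t.index))
        with pytest.raises(FormatError, match="< 2 replicates"):
            timepoint_networks(expr, SampleMetadata(meta_t), bundle.anchors,
                               bundle.lrdb, baseline=0.0)


class TestCompareNetworks:
    def _net(self, edges):
        return CommunicationNetwork(
            nodes=["A", "B", "C"],
            edges=[CommEdge(u, v, w, 1.0, [("L", "R", w)]) for u, v, w in edges],
        )

    def test_identical_networks_empty_diff(self):
        a = self._net([("A", "B", 6.0)])
        d = compare_networks(a, self._net([("A", "B", 6.0)]))
        assert d.gained == [] and d.lost == []
        assert not any(fl for *_, fl in d.retained)

    def test_gain_loss_antisymmetry(self):
        a = self._net([("A", "B", 6.0)])
        b = self._net([])
        d_ab = compare_networks(a, b)
        d_ba = compare_networks(b, a)
        assert d_ab.lost == [("A", "B")] and d_ab.gained == []
        assert d_ba.gained == [("A", "B")] and d_ba.lost == []

    def test_threshold_boundary(self):
        a = self._net([("A", "B", 6.0)])
        b = self._net([("A", "B", 6.3)])
        at_default = compare_networks(a, b)  # 5% change, threshold 10%
        assert not at_default.retained[0][4]
        tight = compare_networks(a, b, rel_threshold=0.04)
        assert tight.retained[0][4]

    def test_disjoint_nodes_rejected(self):
        a = self._net([])
        b = CommunicationNetwork(nodes=["X"], edges=[])
        with pytest.raises(FormatError):
            compare_networks(a, b)
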