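"""PCIT, correlation, clustering and cell-specificity tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import pcit_oracle, random_correlation_matrix
from neutronet.coexpression import (CorrelationMatrix, PcitResult, build_network,
                                    call_specific_genes, cluster_network,
                                    partial_correlation, pcit_prune, pearson_matrix)
from neutronet.expression import call_enriched_genes
from neutronet.network import RegulatoryNetwork
from test_expression import make_matrix


def cm(values, genes=None):
    a = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(a.shape[0])]
    return CorrelationMatrix(pd.DataFrame(a, index=genes, columns=genes))


class TestPearsonMatrix:
    def test_self_and_anticorrelation(self):
        m = make_matrix([[1, 2, 3], [3, 2, 1]], ["a", "b", "c"], unit="TPM")
        c = pearson_matrix(m)
        assert c.r.loc["g1", "g1"] == pytest.approx(1.0)
        assert c.r.loc["g1", "g2"] == pytest.approx(-1.0)

    def test_hand_value(self):
        m = make_matrix([[1, 2, 3], [1, 2, 4]], ["a", "b", "c"], unit="TPM")
        c = pearson_matrix(m)
        assert c.r.loc["g1", "g2"] == pytest.approx(3 / np.sqrt(2 * 14 / 3), abs=1e-6)

    def test_constant_gene_dropped_with_warning(self):
        m = make_matrix([[1, 2, 3], [5, 5, 5]], ["a", "b", "c"], unit="TPM")
        with pytest.warns(UserWarning):
            c = pearson_matrix(m)
        assert c.dropped_constant == ["g2"]
        assert "g2" not in c.r.index

    def test_too_few_points(self):
        m = make_matrix([[1, 2], [2, 1]], ["a", "b"], unit="TPM")
        with pytest.raises(ValueError):
            pearson_matrix(m)


class TestPartialCorrelation:
    def test_independent_z_identity(self):
        assert partial_correlation(0.4, 0.0, 0.0) == pytest.approx(0.4)

    def test_hand_arithmetic(self):
        assert partial_correlation(0.9, 0.8, 0.8) == pytest.approx(0.26 / 0.36)

    def test_fully_mediated_zero(self):
        assert partial_correlation(0.8 * 0.5, 0.8, 0.5) == pytest.approx(0.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            partial_correlation(0.5, 1.0, 0.2)


class TestPcitPrune:
    def test_symmetric_trio_symmetric_outcome(self):
        c = cm([[1, .9, .9], [.9, 1, .9], [.9, .9, 1]])
        kept = pcit_prune(c).kept.to_numpy()
        assert kept[0, 1] == kept[0, 2] == kept[1, 2]
        assert np.array_equal(kept, kept.T)

    def test_strong_edge_kept_and_matches_hand_evaluation(self):
        # eps = (0.9995 + 0.161 + 0.161)/3 ~= 0.44; the strong edge easily
        # beats eps * 0.1 on both sides.  The weak edges fail only one of the
        # two tolerance comparisons (|r| < |eps * r_other| needs BOTH), so by
        # the rule they also survive the trio - confirmed against the oracle.
        R = np.array([[1, .95, .1], [.95, 1, .1], [.1, .1, 1]])
        kept = pcit_prune(cm(R)).kept
        assert kept.loc["g1", "g2"]
        np.testing.assert_array_equal(kept.to_numpy(), pcit_oracle(R))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(3, 10), st.integers(0, 10_000))
    def test_matches_literal_oracle(self, n, seed):
        R = random_correlation_matrix(np.random.default_rng(seed), n)
        mask = pcit_prune(cm(R)).kept.to_numpy()
        np.testing.assert_array_equal(mask, pcit_oracle(R))

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            pcit_prune(cm([[1.0, 0.5], [0.5, 1.0]]))


class TestBuildNetwork:
    def make_inputs(self):
        R = np.array([[1, .96, .94], [.96, 1, .2], [.94, .2, 1]])
        c = cm(R)
        kept = np.ones((3, 3), bool)
        np.fill_diagonal(kept, False)
        return c, PcitResult(pd.DataFrame(kept, index=c.r.index, columns=c.r.columns))

    def test_threshold_respected(self):
        c, p = self.make_inputs()
        net = build_network(c, p, r_threshold=0.95)
        pairs = set(map(tuple, net.edges[["source", "target"]].to_numpy()))
        assert pairs == {("g1", "g2")}
        assert "g3" not in net.nodes.index  # isolated genes dropped

    def test_edge_count_bound(self):
        c, p = self.make_inputs()
        net = build_network(c, p, r_threshold=0.1)
        n = len(c.r)
        assert len(net.edges) <= n * (n - 1) / 2

    def test_threshold_one_keeps_nothing_imperfect(self):
        c, p = self.make_inputs()
        assert len(build_network(c, p, r_threshold=1.0).edges) == 0


class TestClusterNetwork:
    def modular_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        # two planted modules with distinct cell-type profiles
        base1 = rng.normal(0, 1, 6)
        base2 = rng.normal(0, 1, 6)
        rows, genes = [], []
        for i in range(4):
            rows.append(base1 + rng.normal(0, 0.05, 6) + 5)
            genes.append(f"a{i}")
        for i in range(4):
            rows.append(base2 + rng.normal(0, 0.05, 6) + 5)
            genes.append(f"b{i}")
        vals = pd.DataFrame(np.abs(rows), index=genes,
                            columns=[f"s{j}" for j in range(6)])
        samples = pd.DataFrame({"cell_type": list("xxyyzz"), "replicate": [1, 2] * 3},
                               index=vals.columns)
        from neutronet.expression import ExpressionMatrix
        return ExpressionMatrix(vals, samples, unit="TPM")

    def build(self, m):
        c = pearson_matrix(m)
        p = pcit_prune(c)
        return build_network(c, p, r_threshold=0.9)

    def test_planted_partition_recovered(self):
        m = self.modular_matrix()
        net = self.build(m)
        labels = cluster_network(net, m, k=2)
        a = {labels[g] for g in labels.index if g.startswith("a")}
        b = {labels[g] for g in labels.index if g.startswith("b")}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_order_invariance(self):
        m = self.modular_matrix()
        net = self.build(m)
        labels = cluster_network(net, m, k=2)
        perm = net.nodes.sample(frac=1, random_state=3).index
        net2 = RegulatoryNetwork(nodes=net.nodes.loc[perm], edges=net.edges.iloc[::-1])
        labels2 = cluster_network(net2, m, k=2)
        pd.testing.assert_series_equal(labels, labels2)

    def test_single_clique_one_cluster(self):
        m = self.modular_matrix()
        genes = [g for g in m.values.index if g.startswith("a")]
        from neutronet.expression import ExpressionMatrix
        sub = ExpressionMatrix(m.values.loc[genes], m.samples, unit="TPM")
        net = self.build(sub)
        labels = cluster_network(net, sub, k=1)
        assert set(labels) == {1}

    def test_k_exceeding_nodes_raises(self):
        m = self.modular_matrix()
        net = self.build(m)
        with pytest.raises(ValueError):
            cluster_network(net, m, k=99)


class TestCallSpecificGenes:
    def scenario(self):
        # g1: high in neutrophils, 2.5x over a homogeneous rest, tiny variance
        vals = [[100, 100.4, 40, 40.3, 40.1, 39.8],
                [30, 30.2, 29.9, 30.1, 30.0, 29.8]]
        m = make_matrix(vals, ["neutrophil", "neutrophil", "monocyte_dc",
                               "monocyte_dc", "T", "T"], unit="TPM")
        e = call_enriched_genes(m)
        nodes = pd.DataFrame(index=pd.Index(["g1"], name="gene"))
        net = RegulatoryNetwork(nodes=nodes, edges=pd.DataFrame(
            columns=["source", "target", "edge_type", "r"]))
        return m, e, net

    def test_nsg_call_hand_example(self):
        m, e, net = self.scenario()
        calls = call_specific_genes(e, net, m, tf_list=[])
        assert bool(calls.loc["g1", "nsg"])
        assert calls.loc["g1", "fc_vs_comparator"] == pytest.approx(100.2 / 40.15, rel=0.01)
        assert not calls.loc["g1", "nstf"]  # not in the TF list

    def test_nstf_requires_tf_membership(self):
        m, e, net = self.scenario()
        calls = call_specific_genes(e, net, m, tf_list=["g1"])
        assert bool(calls.loc["g1", "nstf"])
        assert calls.loc["g1", "label"] == "NSTF"

    def test_missing_comparator_raises(self):
        m, e, net = self.scenario()
        with pytest.raises(ValueError):
            call_specific_genes(e, net, m, tf_list=[], comparator="absent_ct")

    def test_nsg_monotone_in_fc_threshold(self):
        m, e, net = self.scenario()
        loose = call_specific_genes(e, net, m, tf_list=[], fc_threshold=2.0)
        tight = call_specific_genes(e, net, m, tf_list=[], fc_threshold=3.0)
        assert set(tight.index[tight.nsg]) <= set(loose.index[loose.nsg])
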