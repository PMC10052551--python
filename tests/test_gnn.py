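import networkx as nx
import numpy as np
import pandas as pd
import pytest

from drivergnn import autodiff as ad
from drivergnn.autodiff import Tensor
from drivergnn.features import FEATURE_SCHEMA, GeneFeatureMatrix
from drivergnn.gnn import (
    DriverGeneClassifier,
    GraphArrays,
    cross_entropy,
    gat_forward,
    sage_forward,
    softmax_rows,
    train,
)
from drivergnn.io import PPIGraph, RunConfig
from drivergnn.labeling import LabelSet
from helpers import dense_gat, dense_sage


def graph_of(edges, genes):
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(edges)
    return PPIGraph(graph=g)


def adjacency(edges, genes, self_loops):
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    a = np.zeros((n, n))
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    if self_loops:
        a += np.eye(n)
    return a


class TestGATLayer:
    def setup_method(self):
        self.genes = list("ABCD")
        self.edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")]
        rng = np.random.default_rng(0)
        self.x = rng.normal(size=(4, 5))
        self.W = rng.normal(size=(5, 3))
        self.a = rng.normal(size=6)
        self.b = rng.normal(size=3)

    def run_layer(self):
        ga = GraphArrays.from_graph(graph_of(self.edges, self.genes), self.genes)
        out, alpha = gat_forward(
            Tensor(self.x), ga, Tensor(self.W), Tensor(self.a), Tensor(self.b)
        )
        return ga, out, alpha

    def test_matches_dense_oracle(self):
        ga, out, _ = self.run_layer()
        expected, _ = dense_gat(
            self.x, adjacency(self.edges, self.genes, True), self.W, self.a, self.b
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        ga, _, alpha = self.run_layer()
        sums = np.zeros(4)
        np.add.at(sums, ga.dst_self, alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_identical_neighbors_get_equal_attention(self):
        genes = list("XYZ")
        edges = [("X", "Y"), ("X", "Z")]
        x = np.array([[1.0, 0.0], [0.5, 2.0], [0.5, 2.0]])  # Y and Z identical
        rng = np.random.default_rng(1)
        W, a, b = rng.normal(size=(2, 2)), rng.normal(size=4), np.zeros(2)
        ga = GraphArrays.from_graph(graph_of(edges, genes), genes)
        _, alpha = gat_forward(Tensor(x), ga, Tensor(W), Tensor(a), Tensor(b))
        coeffs = {}
        for e, (s, d) in enumerate(zip(ga.src_self, ga.dst_self)):
            coeffs[(genes[d], genes[s])] = alpha[e]
        assert coeffs[("X", "Y")] == pytest.approx(coeffs[("X", "Z")], abs=1e-12)

    def test_isolated_node_attends_to_itself(self):
        genes = ["A", "B", "lonely"]
        ga = GraphArrays.from_graph(graph_of([("A", "B")], genes), genes)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 2))
        _, alpha = gat_forward(
            Tensor(x), ga, Tensor(rng.normal(size=(2, 2))), Tensor(rng.normal(size=4)),
            Tensor(np.zeros(2)),
        )
        self_edge = [
            e for e, (s, d) in enumerate(zip(ga.src_self, ga.dst_self)) if s == d == 2
        ]
        assert alpha[self_edge[0]] == pytest.approx(1.0)


class TestSAGELayer:
    def test_matches_dense_oracle_six_nodes(self):
        genes = list("ABCDEF")
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"), ("A", "F"), ("B", "E")]
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4))
        W = rng.normal(size=(8, 3))
        b = rng.normal(size=3)
        ga = GraphArrays.from_graph(graph_of(edges, genes), genes)
        out = sage_forward(Tensor(x), ga, Tensor(W), Tensor(b))
        expected = dense_sage(x, adjacency(edges, genes, False), W, b)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_identical_neighbor_features_aggregate_exactly(self):
        genes = list("VXY")
        edges = [("V", "X"), ("V", "Y")]
        x = np.array([[9.0, 9.0], [2.0, 3.0], [2.0, 3.0]])
        ga = GraphArrays.from_graph(graph_of(edges, genes), genes)
        h_n = ad.spmm(*ga.mean_op, Tensor(x))
        np.testing.assert_allclose(h_n.data[0], [2.0, 3.0])

    def test_isolated_node_aggregates_zero(self):
        genes = ["A", "B", "iso"]
        ga = GraphArrays.from_graph(graph_of([("A", "B")], genes), genes)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 2))
        h_n = ad.spmm(*ga.mean_op, Tensor(x))
        np.testing.assert_allclose(h_n.data[2], 0.0)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """End-to-end gradient of the full model loss vs central differences."""
        genes = list("ABCDE")
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")]
        ga = GraphArrays.from_graph(graph_of(edges, genes), genes)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 3))
        cfg = RunConfig(gat_out=4, sage1_out=4, seed=0, dropout=0.0)
        model = DriverGeneClassifier(config=cfg, n_features=3)
        train_idx = np.array([0, 2, 4])
        y = np.array([1, 0, 1])

        def loss_value():
            from drivergnn.gnn import _ce_loss_tensor

            logits, tensors = model._forward_tensors(x, ga)
            return _ce_loss_tensor(logits, train_idx, y), tensors

        loss, tensors = loss_value()
        loss.backward()
        analytic = [t.grad.copy() for t in tensors]
        eps = 1e-6
        arrays = model.parameter_arrays()
        for arr, grad in zip(arrays, analytic):
            flat = arr.ravel()
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = loss_value()
                flat[k] = orig - eps
                lm, _ = loss_value()
                flat[k] = orig
                fd = (lp.data - lm.data) / (2 * eps)
                assert grad.ravel()[k] == pytest.approx(fd, abs=1e-5, rel=1e-4)


def make_feature_matrix(values, genes):
    cols = [name for name, _ in FEATURE_SCHEMA]
    return GeneFeatureMatrix(values=pd.DataFrame(values, index=genes, columns=cols))


def random_instance(n=30, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n)]
    g = nx.barabasi_albert_graph(n, 2, seed=1)
    ppi = PPIGraph(graph=nx.relabel_nodes(g, {i: genes[i] for i in range(n)}))
    x = rng.random((n, 36))
    labels = pd.Series(
        ["positive" if i < n // 3 else "negative" for i in range(n)], index=genes, dtype=object
    )
    # separable signal: positives high in the first feature
    x[: n // 3, 0] += 2.0
    return make_feature_matrix(x, genes), ppi, LabelSet(labels=labels)


class TestModel:
    def test_softmax_head_rows_sum_to_one(self):
        fm, ppi, labels = random_instance(seed=1)
        model = DriverGeneClassifier(config=RunConfig(gat_out=8, sage1_out=8, seed=0))
        scores = model.forward(fm, ppi)
        assert ((scores["p_driver"] >= 0) & (scores["p_driver"] <= 1)).all()

    def test_parameter_shapes_match_width_config(self):
        model = DriverGeneClassifier(config=RunConfig(gat_out=64, sage1_out=128))
        assert model.params["gat"].W.shape == (36, 64)
        assert model.params["gat"].a.shape == (128,)
        assert model.params["sage1"].W.shape == (128, 128)
        assert model.params["sage2"].W.shape == (256, 2)

    def test_node_permutation_equivariance(self):
        fm, ppi, labels = random_instance(seed=2)
        model = DriverGeneClassifier(config=RunConfig(gat_out=8, sage1_out=8, seed=0))
        s1 = model.forward(fm, ppi)
        rng = np.random.default_rng(3)
        perm = rng.permutation(fm.gene_ids).tolist()
        fm2 = GeneFeatureMatrix(values=fm.values.loc[perm])
        s2 = model.forward(fm2, ppi)
        np.testing.assert_allclose(
            s1.loc[perm, "p_driver"].to_numpy(), s2["p_driver"].to_numpy(), atol=1e-9
        )


class TestCrossEntropy:
    def test_perfect_fit_near_zero(self):
        assert cross_entropy(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-5

    def test_coin_flip_is_log2(self):
        assert cross_entropy(np.full(8, 0.5), np.array([1, 0] * 4)) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_hand_summed_three_genes(self):
        p = np.array([0.9, 0.2, 0.5])
        y = np.array([1, 0, 1])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.5)) / 3
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([]), np.array([]))


class TestTraining:
    def test_separable_instance_converges(self):
        fm, ppi, labels = random_instance(n=40, seed=7)
        cfg = RunConfig(gat_out=8, sage1_out=8, seed=7, epochs=200)
        result = train(fm, ppi, labels, cfg)
        # clean (dropout-free) fit on the training genes
        p = result.scores.loc[result.train_genes, "p_driver"].to_numpy()
        y = labels.binary(result.train_genes)
        assert cross_entropy(p, y) < 0.1
        assert np.mean(result.loss_history[150:]) <= np.mean(result.loss_history[:50])

    def test_same_seed_identical_scores(self):
        fm, ppi, labels = random_instance(n=30, seed=8)
        cfg = RunConfig(gat_out=8, sage1_out=8, seed=5, epochs=20)
        r1 = train(fm, ppi, labels, cfg)
        r2 = train(fm, ppi, labels, cfg)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        assert r1.loss_history == r2.loss_history

    def test_too_few_labeled_genes_error(self):
        fm, ppi, labels = random_instance(n=30, seed=9)
        lab = labels.labels.copy()
        lab[5:] = "unlabeled"
        with pytest.raises(ValueError):
            train(fm, ppi, LabelSet(labels=lab), RunConfig(gat_out=4, sage1_out=4))

    def test_pseudolabel_mode_runs_and_differs(self):
        fm, ppi, labels = random_instance(n=30, seed=10)
        lab = labels.labels.copy()
        lab[20:] = "unlabeled"
        ls = LabelSet(labels=lab)
        cfg = RunConfig(gat_out=8, sage1_out=8, seed=1, epochs=15)
        base = train(fm, ppi, ls, cfg)
        cfg_p = RunConfig(gat_out=8, sage1_out=8, seed=1, epochs=15, pseudolabel_mode=True)
        pseudo = train(fm, ppi, ls, cfg_p)
        assert not base.scores["p_driver"].equals(pseudo.scores["p_driver"])


def test_softmax_rows_normalized():
    rng = np.random.default_rng(11)
    p = softmax_rows(rng.normal(size=(20, 2)) * 10)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
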