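import numpy as np
import pytest

from spillcast import (
    GraphTensors,
    SocialGraph,
    SpilloverGNN,
    load_checkpoint,
    predict_popularity,
    save_checkpoint,
)
from spillcast.autograd import Tensor
from spillcast.features import NodeAttributes
from spillcast.models import (
    ModelParams,
    gat_coefficients,
    gat_layer,
    gcn_layer,
    influ_gate,
    se_head,
)

from dense_reference import (
    dense_coupled_forward,
    dense_gat_coefficients,
    dense_gat_layer,
    dense_gcn_layer,
)


def make_attrs(gt, d_text, d_struct, seed=7):
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((gt.n, 1 + d_text + d_struct))
    return NodeAttributes(nodes=gt.nodes, matrix=M, d_text=d_text, d_struct=d_struct)


class TestGCNLayer:
    def test_isolated_node_identity_weights(self):
        gt = GraphTensors(SocialGraph.from_edges([], nodes=["x"]))
        h0 = np.array([[1.0, -2.0, 0.5]])
        out = gcn_layer(Tensor(h0), gt, Tensor(np.eye(3)))
        assert np.allclose(out.data, np.where(h0 > 0, h0, 0.01 * h0))

    def test_path_closed_neighbourhood_means(self, line_graph):
        gt = GraphTensors(line_graph)
        feats = {"a": 1.0, "b": 2.0, "c": 3.0}
        H = np.array([[feats[v]] for v in gt.nodes])
        out = gcn_layer(Tensor(H), gt, Tensor(np.eye(1)))
        got = {v: out.data[i, 0] for i, v in enumerate(gt.nodes)}
        assert got == pytest.approx({"a": 1.5, "b": 2.0, "c": 2.5})

    def test_permutation_equivariance(self, small_graph):
        gt = GraphTensors(small_graph)
        rng = np.random.default_rng(0)
        H = rng.standard_normal((gt.n, 4))
        W = rng.standard_normal((4, 4))
        out = gcn_layer(Tensor(H), gt, Tensor(W)).data
        # same graph declared with nodes in reversed order
        perm_nodes = list(reversed(gt.nodes))
        g2 = SocialGraph.from_edges(small_graph.edges, nodes=perm_nodes)
        gt2 = GraphTensors(g2)
        H2 = np.stack([H[gt.index[v]] for v in gt2.nodes])
        out2 = gcn_layer(Tensor(H2), gt2, Tensor(W)).data
        for v in gt.nodes:
            assert np.allclose(out[gt.index[v]], out2[gt2.index[v]])

    def test_matches_dense_reference(self, small_graph):
        gt = GraphTensors(small_graph)
        rng = np.random.default_rng(3)
        H = rng.standard_normal((gt.n, 5))
        W = rng.standard_normal((5, 4))
        sparse = gcn_layer(Tensor(H), gt, Tensor(W)).data
        assert np.allclose(sparse, dense_gcn_layer(gt, H, W), atol=1e-6)


class TestGATLayer:
    def test_identical_representations_split_attention_evenly(self):
        gt = GraphTensors(SocialGraph.from_edges([("v", "u")]))
        H = np.ones((2, 3))
        rng = np.random.default_rng(1)
        W, gamma = rng.standard_normal((3, 2)), rng.standard_normal(4)
        coef = gat_coefficients(Tensor(H), gt, Tensor(W), Tensor(gamma))
        v = gt.index["v"]
        weights = [c for c, d in zip(coef, gt.closed_dst) if d == v]
        assert np.allclose(weights, [0.5, 0.5])

    def test_coefficients_sum_to_one_per_node(self, small_graph):
        gt = GraphTensors(small_graph)
        rng = np.random.default_rng(2)
        H = rng.standard_normal((gt.n, 4))
        coef = gat_coefficients(
            Tensor(H), gt, Tensor(rng.standard_normal((4, 3))),
            Tensor(0.1 * rng.standard_normal(6)),
        )
        sums = np.zeros(gt.n)
        np.add.at(sums, gt.closed_dst, coef)
        assert np.allclose(sums, 1.0)

    def test_star_fixture_matches_dense_softmax(self):
        edges = [(f"leaf{i}", "hub") for i in range(3)] + [("hub", f"leaf{i}") for i in range(3)]
        gt = GraphTensors(SocialGraph.from_edges(edges))
        rng = np.random.default_rng(4)
        H = rng.standard_normal((gt.n, 3))
        W, gamma = rng.standard_normal((3, 2)), 0.3 * rng.standard_normal(4)
        coef = gat_coefficients(Tensor(H), gt, Tensor(W), Tensor(gamma))
        assert np.allclose(coef, dense_gat_coefficients(gt, H, W, gamma), atol=1e-6)

    def test_layer_matches_dense_reference(self, small_graph):
        gt = GraphTensors(small_graph)
        rng = np.random.default_rng(5)
        H = rng.standard_normal((gt.n, 4))
        W, gamma = rng.standard_normal((4, 4)), 0.2 * rng.standard_normal(8)
        sparse = gat_layer(Tensor(H), gt, Tensor(W), Tensor(gamma)).data
        assert np.allclose(sparse, dense_gat_layer(gt, H, W, gamma), atol=1e-6)


class TestSEHead:
    def _zero_params(self, d_h=3, d_z=2, hd=2):
        p = ModelParams()
        p.add("W_h", np.zeros((d_h, hd)))
        p.add("W_z", np.zeros((d_z, hd)))
        p.add("head_W1", np.zeros((2 * hd, 4)))
        p.add("head_b1", np.zeros(4))
        p.add("head_W2", np.zeros((4, 3)))
        p.add("head_b2", np.zeros(3))
        p.add("head_W3", np.zeros((3, 1)))
        p.add("head_b3", np.zeros(1))
        return p

    def test_members_pinned_to_one_nonmembers_at_sigmoid_zero(self):
        p = self._zero_params()
        Hk = Tensor(np.ones((2, 3)))
        s = se_head(Hk, np.ones(2), np.array([1.0, 0.0]), p)
        assert s.data[0] == 1.0
        assert s.data[1] == pytest.approx(0.5)  # sigmoid(0) with all-zero head

    def test_nonmember_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(6)
        p = self._zero_params()
        for k in p:
            p[k].data = rng.standard_normal(p[k].data.shape)
        s = se_head(Tensor(rng.standard_normal((4, 3))), rng.standard_normal(2),
                    np.array([0.0, 1.0, 0.0, 0.0]), p)
        open_vals = s.data[[0, 2, 3]]
        assert np.all((open_vals > 0) & (open_vals < 1))


class TestInfluGate:
    def test_zero_beta_gives_zero_gate(self):
        r = Tensor(np.ones((3, 2)))
        W = Tensor(np.eye(2))
        zero = Tensor(np.zeros(2))
        g = influ_gate(r, r, zero, zero, W)
        assert np.allclose(g.data, 0.0)

    def test_se_gate_with_zero_message_reduces_to_plain(self):
        rng = np.random.default_rng(7)
        r_u, r_v = Tensor(rng.standard_normal((4, 3))), Tensor(rng.standard_normal((4, 3)))
        W = Tensor(rng.standard_normal((3, 2)))
        bu, bv, bz = (Tensor(rng.standard_normal(2)) for _ in range(3))
        plain = influ_gate(r_u, r_v, bu, bv, W)
        se = influ_gate(r_u, r_v, bu, bv, W, beta_z=bz, Wz_zm=Tensor(np.zeros(2)))
        assert np.allclose(plain.data, se.data)

    def test_hand_computed_dot_product(self):
        r_u = Tensor(np.array([[1.0, 2.0]]))
        r_v = Tensor(np.array([[3.0, -1.0]]))
        W = Tensor(np.eye(2))
        bu, bv = Tensor(np.array([1.0, 0.5])), Tensor(np.array([-1.0, 2.0]))
        # gate = bu.(r_u) + bv.(r_v) = (1 + 1) + (-3 - 2) = -3
        assert influ_gate(r_u, r_v, bu, bv, W).data[0] == pytest.approx(-3.0)

    def test_se_mode_requires_message_term(self):
        r = Tensor(np.ones((1, 2)))
        with pytest.raises(ValueError):
            influ_gate(r, r, Tensor(np.ones(2)), Tensor(np.ones(2)),
                       Tensor(np.eye(2)), beta_z=Tensor(np.ones(2)))


class TestCoupledModel:
    def test_fully_observed_cascade_saturates_readout(self, small_graph):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("CGNN", 4, 3, k=2, hidden=5, seed=0)
        pred = model.predict(gt, attrs, set(gt.nodes))
        assert pred.size == pytest.approx(gt.n)
        assert np.allclose(pred.statuses, 1.0)

    def test_zero_mixing_collapses_to_half(self, small_graph):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("CGNN", 4, 3, k=2, hidden=5, seed=0)
        for ell in range(2):
            model.params[f"mu_s{ell}"].data = np.array(0.0)
            model.params[f"mu_a{ell}"].data = np.array(0.0)
        s = model.forward(gt, attrs, {gt.nodes[0]})
        non_members = s.data[1:]
        assert np.allclose(non_members, 0.5)

    @pytest.mark.parametrize("variant", ["CGNN", "SE-CGNN"])
    def test_matches_dense_loop_reference(self, small_graph, variant):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN(variant, 4, 3, k=2, hidden=5, head_dim=4, seed=1)
        zm = np.random.default_rng(2).standard_normal(4)
        mask = gt.mask({gt.nodes[0], gt.nodes[3]})
        H0 = attrs.matrix.copy()
        H0[:, 0] = mask
        if not model.se:
            H0[:, 1:5] = 0.0
        ref = dense_coupled_forward(gt, model.params, mask, H0, k=2,
                                    se=model.se, zm=zm if model.se else None)
        got = model.forward(gt, attrs, {gt.nodes[0], gt.nodes[3]},
                            zm if model.se else None)
        assert np.allclose(got.data, ref, atol=1e-6)


class TestPredictPopularity:
    @pytest.mark.parametrize("variant", ["GCN", "GAT", "CGNN", "SE-GCN", "SE-GAT", "SE-CGNN"])
    def test_prediction_bounded_by_prefix_and_graph(self, small_graph, variant):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN(variant, 4, 3, k=2, hidden=5, head_dim=4, seed=0)
        prefix = set(gt.nodes[:3])
        zm = np.zeros(4) if model.se else None
        pred = predict_popularity(model, small_graph, attrs, prefix, zm)
        assert len(prefix) <= pred.size <= gt.n

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            SpilloverGNN("SE-GIN", 4, 3)

    def test_all_members_predicts_exactly_prefix_size(self, small_graph):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("GCN", 4, 3, k=2, hidden=5, seed=0)
        pred = model.predict(gt, attrs, set(gt.nodes))
        assert pred.size == pytest.approx(gt.n)

    def test_member_status_invariant_to_nonmember_features(self, small_graph):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("SE-CGNN", 4, 3, k=2, hidden=5, seed=0)
        member = gt.nodes[0]
        zm = np.ones(4)
        s1 = model.forward(gt, attrs, {member}, zm).data[gt.index[member]]
        attrs.matrix[gt.index[gt.nodes[5]], 1:] += 100.0
        s2 = model.forward(gt, attrs, {member}, zm).data[gt.index[member]]
        assert s1 == s2 == 1.0

    def test_se_variant_requires_message_embedding(self, small_graph):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("SE-GAT", 4, 3, k=2, hidden=5, seed=0)
        with pytest.raises(ValueError):
            model.forward(gt, attrs, {gt.nodes[0]}, None)


class TestBatchedExecution:
    @pytest.mark.parametrize("variant", ["GCN", "GAT", "CGNN", "SE-GCN", "SE-GAT", "SE-CGNN"])
    def test_batched_forward_agrees_with_per_sample(self, small_graph, variant):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        rng = np.random.default_rng(9)
        model = SpilloverGNN(variant, 4, 3, k=3, hidden=5, head_dim=4, seed=2)
        prefixes = [{gt.nodes[0]}, set(gt.nodes[:4]), {gt.nodes[7]}]
        zms = [rng.standard_normal(4) for _ in prefixes]
        batched = model.forward_batch(gt, attrs, prefixes, zms if model.se else None)
        for b, (p, z) in enumerate(zip(prefixes, zms)):
            single = model.forward(gt, attrs, p, z if model.se else None)
            assert np.allclose(batched.data[:, b], single.data, atol=1e-9)


class TestCheckpoints:
    def test_reload_reproduces_predictions_bitwise(self, small_graph, tmp_path):
        gt = GraphTensors(small_graph)
        attrs = make_attrs(gt, 4, 3)
        model = SpilloverGNN("SE-CGNN", 4, 3, k=2, hidden=5, head_dim=4, seed=3)
        zm = np.random.default_rng(1).standard_normal(4)
        before = model.predict(gt, attrs, {gt.nodes[0]}, zm)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        after = loaded.predict(gt, attrs, {gt.nodes[0]}, zm)
        assert np.array_equal(before.statuses, after.statuses)
        assert loaded.config() == model.config()


def test_per_layer_cost_scales_with_edges_not_shape():
    """Star and path graphs with equal |E| yield equal per-layer work."""
    n = 30
    star = SocialGraph.from_edges(
        [("hub", f"l{i}") for i in range(n - 1)] + [(f"l{i}", "hub") for i in range(n - 1)]
    )
    path = SocialGraph.from_edges(
        [(f"p{i}", f"p{i+1}") for i in range(n - 1)] + [(f"p{i+1}", f"p{i}") for i in range(n - 1)]
    )
    gs, gp = GraphTensors(star), GraphTensors(path)
    assert gs.n == gp.n and len(gs.src) == len(gp.src)
    # per-layer message count (edge operations) is n + |E| for both
    assert len(gs.closed_src) == len(gp.closed_src) == gs.n + len(gs.src)
    assert gs.A_mean.nnz == gp.A_mean.nnz
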