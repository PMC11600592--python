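"""Network module: conv oracles, gradients, forward contracts, losses."""

import numpy as np
import pytest

from treegnn.nn import autodiff as ad
from treegnn.nn.layers import GRU, BatchNorm1d, GATConv, LayerNorm, Linear
from treegnn.nn.model import (
    ArchitectureConfig,
    Batch,
    LossSpec,
    TreeSequenceNet,
    collate,
    count_parameters,
    gat_attention,
    gat_conv,
    gcn_conv_reference,
    load_checkpoint,
    loss,
    save_checkpoint,
)
from treegnn.featurize import FeaturizedSequence

from conftest import random_tree_arrays


def loop_gat_oracle(X, edges, theta_s, theta_t, att, bias, slope=0.2):
    """Brute-force per-node evaluation of the attention convolution."""
    n = X.shape[0]
    children = {}
    for c, p in zip(edges[0], edges[1]):
        children.setdefault(int(p), []).append(int(c))
    out = np.zeros((n, theta_s.shape[1]))
    for i in range(n):
        kids = children.get(i, [])
        scores = []
        for j in [i] + kids:
            pre = theta_s.T @ X[i] + theta_t.T @ X[j]
            act = np.where(pre > 0, pre, slope * pre)
            scores.append(att @ act)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        acc = alpha[0] * (theta_s.T @ X[i])
        for w, j in zip(alpha[1:], kids):
            acc += w * (theta_t.T @ X[j])
        out[i] = acc + bias
    return out


class TestReferenceConv:
    def test_isolated_node_identity(self):
        X = np.array([[1.0, -2.0]])
        edges = np.zeros((2, 0), dtype=int)
        out = gcn_conv_reference(X, edges, np.eye(2))
        np.testing.assert_allclose(out, X)

    def test_single_parent_child_weights(self):
        # parent (node 1) with one child (node 0): d_p = 2, d_c = 1
        X = np.array([[1.0], [10.0]])
        edges = np.array([[0], [1]])
        out = gcn_conv_reference(X, edges, np.eye(1))
        assert out[1, 0] == pytest.approx(10.0 / 2 + 1.0 / np.sqrt(2))
        assert out[0, 0] == pytest.approx(1.0)  # leaf: self term only

    def test_matrix_and_nodewise_forms_agree_on_random_trees(self, rng):
        for _ in range(50):
            n_leaves = int(rng.integers(2, 11))
            _, edges = random_tree_arrays(rng, n_leaves)
            n = 2 * n_leaves - 1
            X = rng.standard_normal((n, 3))
            theta = rng.standard_normal((3, 4))
            m = gcn_conv_reference(X, edges, theta, form="matrix")
            nw = gcn_conv_reference(X, edges, theta, form="nodewise")
            np.testing.assert_allclose(m, nw, atol=1e-6)


class TestAttention:
    def test_leaf_gets_weight_one(self, rng):
        d = 3
        alpha = gat_attention(
            rng.standard_normal(d),
            np.empty((0, d)),
            rng.standard_normal((d, d)),
            rng.standard_normal((d, d)),
            rng.standard_normal(d),
        )
        np.testing.assert_allclose(alpha, [1.0])

    def test_weights_sum_to_one_for_every_node(self, rng):
        for _ in range(10):
            n_leaves = int(rng.integers(2, 9))
            _, edges = random_tree_arrays(rng, n_leaves)
            n = 2 * n_leaves - 1
            X = rng.standard_normal((n, 3))
            ts, tt, a = (
                rng.standard_normal((3, 3)),
                rng.standard_normal((3, 3)),
                rng.standard_normal(3),
            )
            children = {}
            for c, p in zip(edges[0], edges[1]):
                children.setdefault(int(p), []).append(int(c))
            for i in range(n):
                kids = children.get(i, [])
                alpha = gat_attention(X[i], X[kids] if kids else np.empty((0, 3)), ts, tt, a)
                assert abs(alpha.sum() - 1.0) < 1e-6

    def test_two_child_node_matches_scalar_arithmetic(self):
        # 1-d features so the softmax argument is hand-checkable
        ts = np.array([[0.5]])
        tt = np.array([[2.0]])
        a = np.array([1.0])
        x_i = np.array([1.0])
        kids = np.array([[1.0], [-1.0]])
        # scores over {self, kid1, kid2}: leaky(0.5 + 2*x_j) with slope 0.2
        raw = [0.5 + 2.0, 0.5 + 2.0, 0.5 - 2.0]
        act = [v if v > 0 else 0.2 * v for v in raw]
        e = np.exp(np.array(act) - max(act))
        expected = e / e.sum()
        alpha = gat_attention(x_i, kids, ts, tt, a)
        np.testing.assert_allclose(alpha, expected, atol=1e-12)


class TestGatConv:
    def test_leaf_reduces_to_theta_s_x(self, rng):
        X = rng.standard_normal((1, 3))
        edges = np.zeros((2, 0), dtype=int)
        out = gat_conv(X, edges, np.eye(3), rng.standard_normal((3, 3)), rng.standard_normal(3))
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_matches_loop_oracle_on_50_random_trees(self, rng):
        for _ in range(50):
            n_leaves = int(rng.integers(2, 11))
            _, edges = random_tree_arrays(rng, n_leaves)
            n = 2 * n_leaves - 1
            X = rng.standard_normal((n, 3))
            conv = GATConv(3, 4, rng)
            fused = conv(ad.Tensor(X), edges).data
            vectorized = gat_conv(
                X, edges, conv.theta_s.data, conv.theta_t.data, conv.att.data, conv.bias.data
            )
            oracle = loop_gat_oracle(
                X, edges, conv.theta_s.data, conv.theta_t.data, conv.att.data, conv.bias.data
            )
            np.testing.assert_allclose(fused, oracle, atol=1e-6)
            np.testing.assert_allclose(vectorized, oracle, atol=1e-6)

    def test_output_width_is_declared_d_prime(self, rng):
        conv = GATConv(5, 7, rng)
        _, edges = random_tree_arrays(rng, 4)
        out = conv(ad.Tensor(rng.standard_normal((7, 5))), edges)
        assert out.shape == (7, 7)

    def test_permutation_equivariance(self, rng):
        _, edges = random_tree_arrays(rng, 6)
        n = 11
        X = rng.standard_normal((n, 4))
        conv = GATConv(4, 4, rng)
        base = conv(ad.Tensor(X), edges).data
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        edges_p = inv[edges]
        permuted = conv(ad.Tensor(X[perm]), edges_p).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestGradients:
    """Central finite differences against every layer's analytic gradients."""

    @pytest.mark.parametrize("layer_kind", ["linear", "gat", "layernorm", "batchnorm", "gru"])
    def test_parameter_gradients_match_finite_differences(self, layer_kind, rng):
        eps = 1e-6
        if layer_kind == "linear":
            layer = Linear(3, 4, rng)
            x = rng.standard_normal((5, 3))
            fwd = lambda: layer(ad.Tensor(x))
        elif layer_kind == "gat":
            layer = GATConv(3, 3, rng)
            _, edges = random_tree_arrays(rng, 4)
            x = rng.standard_normal((7, 3))
            fwd = lambda: layer(ad.Tensor(x), edges)
        elif layer_kind == "layernorm":
            layer = LayerNorm(4)
            layer.weight.data = rng.standard_normal(4)
            layer.bias.data = rng.standard_normal(4)
            x = rng.standard_normal((5, 4))
            fwd = lambda: layer(ad.Tensor(x))
        elif layer_kind == "batchnorm":
            layer = BatchNorm1d(4)
            layer.weight.data = rng.standard_normal(4)
            x = rng.standard_normal((6, 4))
            fwd = lambda: layer(ad.Tensor(x))
        else:
            layer = GRU(3, 4, rng)
            x = rng.standard_normal((3, 5, 3))
            lengths = np.array([5, 3, 1])
            fwd = lambda: layer(ad.Tensor(x), lengths=lengths)

        def value():
            if layer_kind == "batchnorm":
                layer.running_mean[:] = 0  # keep eval-independent state fixed
            out = fwd()
            return ad.sum_(ad.mul(out, out))

        for name, p in layer.named_parameters():
            layer.zero_grad()
            value().backward()
            analytic = p.grad.copy()
            flat_idx = np.unravel_index(
                np.argmax(np.abs(analytic)), analytic.shape
            )
            orig = p.data[flat_idx]
            p.data[flat_idx] = orig + eps
            fp = float(value().data)
            p.data[flat_idx] = orig - eps
            fm = float(value().data)
            p.data[flat_idx] = orig
            numeric = (fp - fm) / (2 * eps)
            assert analytic[flat_idx] == pytest.approx(numeric, abs=1e-5, rel=1e-5), name

    def test_input_gradient_through_stacked_layers(self, rng):
        conv = GATConv(3, 3, rng)
        norm = LayerNorm(3)
        _, edges = random_tree_arrays(rng, 4)
        x = rng.standard_normal((7, 3))

        def f(arr):
            out = ad.relu(norm(conv(ad.Tensor(arr, requires_grad=isinstance(arr, np.ndarray) and arr is x), edges)))
            return out

        xt = ad.Tensor(x, requires_grad=True)
        out = ad.relu(norm(conv(xt, edges)))
        ad.sum_(ad.mul(out, out)).backward()
        eps = 1e-6
        i, j = 2, 1
        xp, xm = x.copy(), x.copy()
        xp[i, j] += eps
        xm[i, j] -= eps
        vp = float((ad.relu(norm(conv(ad.Tensor(xp), edges))).data ** 2).sum())
        vm = float((ad.relu(norm(conv(ad.Tensor(xm), edges))).data ** 2).sum())
        assert xt.grad[i, j] == pytest.approx((vp - vm) / (2 * eps), abs=1e-5)


def make_sequences(rng, n_seqs, tree_counts, n_leaves=4, F=4, M=1, labels=None):
    seqs = []
    n_nodes = 2 * n_leaves - 1
    for s in range(n_seqs):
        T = tree_counts[s % len(tree_counts)]
        node_features, edge_indices, summaries = [], [], []
        for _ in range(T):
            _, edges = random_tree_arrays(rng, n_leaves)
            node_features.append(rng.standard_normal((n_nodes, F)))
            edge_indices.append(edges)
            summaries.append(rng.standard_normal(12))
        label = None if labels is None else np.atleast_1d(labels[s])
        seqs.append(
            FeaturizedSequence(
                node_features=node_features,
                edge_indices=edge_indices,
                tree_summaries=np.array(summaries),
                global_summary=rng.standard_normal(37),
                label=label,
            )
        )
    return seqs


SMALL_ARCH = dict(tree_hidden=8, sequence_hidden=8, head_width=8, n_conv_layers=2)


class TestForward:
    def test_unequal_length_batch_produces_m_vectors(self, rng):
        seqs = make_sequences(rng, 2, [3, 7])
        model = TreeSequenceNet(ArchitectureConfig(n_node_features=4, output_size=2, **SMALL_ARCH), rng)
        out = model(collate(seqs))
        assert out.shape == (2, 2)

    def test_padding_invariance_in_evaluation_mode(self, rng):
        seqs = make_sequences(rng, 3, [2, 9, 5])
        model = TreeSequenceNet(ArchitectureConfig(n_node_features=4, output_size=1, **SMALL_ARCH), rng)
        model.eval()
        alone = model(collate([seqs[0]])).data
        batched = model(collate(seqs)).data
        np.testing.assert_allclose(alone[0], batched[0], atol=1e-5)

    def test_all_ablation_switches_off_still_well_formed(self, rng):
        seqs = make_sequences(rng, 2, [3, 4])
        cfg = ArchitectureConfig(
            n_node_features=4, output_size=3,
            use_graph_conv=False, use_tree_summary=False, use_global_summary=False,
            **SMALL_ARCH,
        )
        model = TreeSequenceNet(cfg, rng)
        out = model(collate(seqs))
        assert out.shape == (2, 3)
        assert np.isfinite(out.data).all()

    def test_without_graph_conv_output_ignores_topology(self, rng):
        seqs = make_sequences(rng, 2, [4])
        cfg = ArchitectureConfig(n_node_features=4, output_size=1, use_graph_conv=False, **SMALL_ARCH)
        model = TreeSequenceNet(cfg, rng)
        model.eval()
        base = model(collate(seqs)).data
        shuffled = [
            FeaturizedSequence(
                node_features=s.node_features,
                edge_indices=[e[:, rng.permutation(e.shape[1])] for e in s.edge_indices],
                tree_summaries=s.tree_summaries,
                global_summary=s.global_summary,
                label=s.label,
            )
            for s in seqs
        ]
        np.testing.assert_allclose(model(collate(shuffled)).data, base, atol=1e-12)

    def test_with_graph_conv_output_depends_on_topology(self, rng):
        seqs = make_sequences(rng, 1, [4])
        model = TreeSequenceNet(ArchitectureConfig(n_node_features=4, output_size=1, **SMALL_ARCH), rng)
        model.eval()
        base = model(collate(seqs)).data
        rewired = FeaturizedSequence(
            node_features=seqs[0].node_features,
            edge_indices=[e[:, ::-1].copy() * 0 + e[::-1] for e in seqs[0].edge_indices],
            tree_summaries=seqs[0].tree_summaries,
            global_summary=seqs[0].global_summary,
            label=None,
        )
        assert not np.allclose(model(collate([rewired])).data, base)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        seqs = make_sequences(rng, 2, [3])
        model = TreeSequenceNet(ArchitectureConfig(n_node_features=4, output_size=1, **SMALL_ARCH), rng)
        model.eval()
        before = model(collate(seqs)).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        restored = load_checkpoint(path)
        restored.eval()
        np.testing.assert_allclose(restored(collate(seqs)).data, before, atol=1e-12)


class TestLoss:
    def test_perfect_one_hot_posterior_gives_zero(self):
        logits = np.array([[100.0, 0.0, 0.0]])
        val = loss(logits, np.array([0]), LossSpec("categorical_cross_entropy"))
        assert float(val.data) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("M", [2, 3, 5])
    def test_uniform_posterior_gives_log_m(self, M):
        logits = np.zeros((4, M))
        val = loss(logits, np.zeros(4, dtype=int), LossSpec("categorical_cross_entropy"))
        assert float(val.data) == pytest.approx(np.log(M), abs=1e-9)

    @pytest.mark.parametrize("d,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5)])
    def test_smooth_l1_piecewise_closed_form(self, d, expected):
        val = loss(np.array([[d]]), np.array([[0.0]]), LossSpec("smooth_l1", beta=1.0))
        assert float(val.data) == pytest.approx(expected, abs=1e-12)

    def test_class_index_out_of_range_raises(self):
        with pytest.raises(ValueError):
            loss(np.zeros((2, 3)), np.array([0, 3]), LossSpec("categorical_cross_entropy"))

    def test_unknown_loss_kind_rejected(self):
        with pytest.raises(ValueError):
            LossSpec("l2")


class TestParameterCount:
    def test_lone_linear_4_to_26(self, rng):
        assert count_parameters(Linear(4, 26, rng)) == 4 * 26 + 26 == 130

    @pytest.mark.parametrize("I,H", [(3, 4), (34, 64), (268, 256)])
    def test_gru_closed_form(self, I, H, rng):
        assert count_parameters(GRU(I, H, rng)) == 3 * (I * H + H * H + 2 * H)

    def test_itemized_sum_equals_total(self, rng):
        model = TreeSequenceNet(ArchitectureConfig(n_node_features=4, output_size=1), rng)
        report = model.parameter_report()
        assert sum(report.values()) == count_parameters(model)
        # independent second traversal over the weight containers
        total = sum(p.data.size for _, p in model.named_parameters())
        assert total == count_parameters(model)


class TestAutodiffOps:
    def test_segment_softmax_matches_per_segment_numpy(self, rng):
        scores = rng.standard_normal(12)
        seg = np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3])
        out = ad.softmax_segments(ad.Tensor(scores), seg, 4).data
        for s in range(4):
            mask = seg == s
            e = np.exp(scores[mask] - scores[mask].max())
            np.testing.assert_allclose(out[mask], e / e.sum(), atol=1e-12)

    def test_elementwise_op_gradients_match_finite_differences(self, rng):
        ops = [
            lambda t: ad.exp(t),
            lambda t: ad.log(ad.add(ad.mul(t, t), 1.0)),
            lambda t: ad.tanh(t),
            lambda t: ad.sigmoid(t),
            lambda t: ad.leaky_relu(t, 0.2),
            lambda t: ad.power(ad.add(ad.mul(t, t), 0.5), -0.5),
            lambda t: ad.div(t, ad.add(ad.mul(t, t), 2.0)),
        ]
        x = rng.standard_normal((3, 4))
        eps = 1e-6
        for op in ops:
            xt = ad.Tensor(x, requires_grad=True)
            ad.sum_(op(xt)).backward()
            i, j = 1, 2
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            numeric = (op(ad.Tensor(xp)).data.sum() - op(ad.Tensor(xm)).data.sum()) / (2 * eps)
            assert xt.grad[i, j] == pytest.approx(numeric, abs=1e-6)
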